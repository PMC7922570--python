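import numpy as np
import pandas as pd
import pytest
from scipy import stats

from milkmir.effects import (
    contrast_from_summary,
    fit_fixed_effects,
    ls_means,
    pairwise_contrasts_scheffe,
    scheffe_adjusted_p,
    type3_effect_tests,
)
from milkmir.errors import DegenerateVariableError, InvalidArgumentError

TREATMENTS = ["TR1", "TR2", "TR3", "TR4"]


def rcbd_design(n_starts=2, blocks_per_start=6):
    """The trial layout: one cow per treatment in every block."""
    rows = []
    for start in range(1, n_starts + 1):
        for block in range(1, blocks_per_start + 1):
            for trt in TREATMENTS:
                rows.append({"cow_id": f"c{len(rows)}", "treatment": trt,
                             "start": start, "block": f"B{block}"})
    return pd.DataFrame(rows)


def sequential_ss_oracle(design, y):
    """Independent oracle: sequential sums of squares via incremental
    least-squares projections (types coincide on balanced data)."""
    def dummies(labels):
        levels = sorted(set(labels))
        return np.column_stack([[1.0 if l == lv else 0.0 for l in labels]
                                for lv in levels[:-1]])

    n = len(y)
    blocks_within = [f"{s}/{b}" for s, b in zip(design["start"], design["block"])]
    terms = [np.ones((n, 1)),
             dummies(list(design["treatment"])),
             dummies([str(s) for s in design["start"]]),
             dummies(blocks_within)]
    sse, out = None, []
    x = np.empty((n, 0))
    for t in terms:
        x = np.hstack([x, t])
        resid = y - x @ np.linalg.lstsq(x, y, rcond=None)[0]
        new_sse = float(resid @ resid)
        if sse is not None:
            out.append(sse - new_sse)
        sse = new_sse
    return out, sse  # [SS_trt, SS_start, SS_block], SSE


class TestFitFixedEffects:
    def test_balanced_cell_means_recovered_exactly(self):
        design = rcbd_design()
        means = {"TR1": 1.0, "TR2": 2.0, "TR3": 3.0, "TR4": 4.0}
        y = design["treatment"].map(means).to_numpy(dtype=float)
        m = fit_fixed_effects(design, y)
        lsm = ls_means(m)
        np.testing.assert_allclose(lsm["estimate"],
                                   [means[t] for t in TREATMENTS], atol=1e-10)

    def test_zero_response_gives_zero_fit(self):
        design = rcbd_design()
        m = fit_fixed_effects(design, np.zeros(len(design)))
        assert m.sse == pytest.approx(0.0, abs=1e-20)
        np.testing.assert_allclose(m.results.params, 0.0, atol=1e-12)

    def test_residual_df_of_full_trial_design(self):
        design = rcbd_design()
        m = fit_fixed_effects(design, np.random.default_rng(0).normal(size=48))
        # 48 - (1 + 3 treatment + 1 start + 2*5 blocks-in-start) = 33
        assert m.df_resid == 33

    def test_sse_matches_explicit_projection(self):
        design = rcbd_design()
        y = np.random.default_rng(1).normal(size=len(design))
        m = fit_fixed_effects(design, y)
        _, sse = sequential_ss_oracle(design, y)
        assert m.sse == pytest.approx(sse, rel=1e-10)


class TestType3Tests:
    def test_equals_classical_anova_on_balanced_data(self):
        design = rcbd_design()
        rng = np.random.default_rng(2)
        y = rng.normal(size=len(design)) + design["treatment"].map(
            {"TR1": 0, "TR2": 0.5, "TR3": 1.0, "TR4": 0}).to_numpy()
        m = fit_fixed_effects(design, y)
        table = type3_effect_tests(m).set_index("effect")
        (ss_trt, ss_start, ss_block), sse = sequential_ss_oracle(design, y)
        mse = sse / m.df_resid
        assert table.loc["treatment", "F"] == pytest.approx(ss_trt / 3 / mse, rel=1e-9)
        assert table.loc["start", "F"] == pytest.approx(ss_start / 1 / mse, rel=1e-9)
        assert table.loc["block", "F"] == pytest.approx(ss_block / 10 / mse, rel=1e-9)

    def test_type_one_error_rate_near_nominal(self):
        design = rcbd_design()
        rng = np.random.default_rng(3)
        rejections = 0
        n_sim = 1000
        for _ in range(n_sim):
            y = rng.normal(size=len(design))
            table = type3_effect_tests(fit_fixed_effects(design, y))
            p = table.set_index("effect").loc["treatment", "p_value"]
            rejections += p <= 0.05
        lo, hi = stats.binom.interval(0.99, n_sim, 0.05)
        assert lo <= rejections <= hi

    def test_pure_treatment_contrast_gives_vanishing_p(self):
        design = rcbd_design()
        rng = np.random.default_rng(4)
        y = design["treatment"].map(
            {"TR1": 1.0, "TR2": -1.0, "TR3": 1.0, "TR4": -1.0}).to_numpy()
        y = y + 1e-9 * rng.normal(size=len(y))
        table = type3_effect_tests(fit_fixed_effects(design, y))
        assert table.set_index("effect").loc["treatment", "p_value"] < 1e-12

    def test_zero_mse_rejected(self):
        design = rcbd_design()
        m = fit_fixed_effects(design, np.zeros(len(design)))
        with pytest.raises(DegenerateVariableError):
            type3_effect_tests(m)


class TestLsMeans:
    def test_balanced_ls_means_equal_group_means(self):
        design = rcbd_design()
        rng = np.random.default_rng(5)
        y = rng.normal(size=len(design))
        lsm = ls_means(fit_fixed_effects(design, y)).set_index("treatment")
        for trt in TREATMENTS:
            grp = y[(design["treatment"] == trt).to_numpy()]
            assert lsm.loc[trt, "estimate"] == pytest.approx(grp.mean(), rel=1e-9)

    def test_t_is_estimate_over_se_and_sum_to_zero(self):
        design = rcbd_design()
        y = np.random.default_rng(6).normal(size=len(design))
        lsm = ls_means(fit_fixed_effects(design, y))
        np.testing.assert_allclose(lsm["t_value"], lsm["estimate"] / lsm["se"],
                                   atol=1e-9)
        centered = lsm["estimate"] - lsm["estimate"].mean()
        assert abs(centered.sum()) < 1e-9


class TestScheffe:
    def test_printed_worked_examples(self):
        # published LS-mean difference rows: estimate, SE, df=30, 4 groups
        assert scheffe_adjusted_p(2.1442 / 0.68, 4, 30) == pytest.approx(
            0.0332, abs=5e-5)
        assert scheffe_adjusted_p(-1.8784 / 0.6579, 4, 30) == pytest.approx(
            0.0622, abs=5e-5)
        assert scheffe_adjusted_p(1.9597 / 0.7027, 4, 30) == pytest.approx(
            0.0711, abs=1e-4)

    def test_zero_statistic_gives_one(self):
        assert scheffe_adjusted_p(0.0, 4, 30) == 1.0

    def test_large_statistic_vanishes(self):
        assert scheffe_adjusted_p(50.0, 4, 30) < 1e-12

    def test_two_groups_equals_raw_t_test(self):
        for t in (0.5, 1.3, 2.7):
            raw = 2 * stats.t.sf(t, 25)
            assert scheffe_adjusted_p(t, 2, 25) == pytest.approx(raw, rel=1e-12)

    def test_monotone_decreasing_in_t(self):
        ps = [scheffe_adjusted_p(t, 4, 30) for t in np.linspace(0, 6, 30)]
        assert all(a >= b for a, b in zip(ps, ps[1:]))

    def test_invalid_arguments(self):
        with pytest.raises(InvalidArgumentError):
            scheffe_adjusted_p(1.0, 1, 30)
        with pytest.raises(InvalidArgumentError):
            scheffe_adjusted_p(1.0, 4, 0)


class TestPairwiseContrasts:
    def test_adjusted_never_below_raw(self):
        design = rcbd_design()
        rng = np.random.default_rng(7)
        for _ in range(20):
            y = rng.normal(size=len(design))
            table = pairwise_contrasts_scheffe(fit_fixed_effects(design, y))
            assert (table["p_scheffe"] >= table["p_raw"] - 1e-12).all()

    def test_antisymmetry_via_ls_means(self):
        design = rcbd_design()
        y = np.random.default_rng(8).normal(size=len(design))
        m = fit_fixed_effects(design, y)
        lsm = ls_means(m).set_index("treatment")["estimate"]
        table = pairwise_contrasts_scheffe(m)
        for row in table.itertuples():
            assert row.estimate == pytest.approx(
                lsm[row.level_a] - lsm[row.level_b], rel=1e-9)

    def test_contrast_from_summary_matches_printed_rows(self):
        out = contrast_from_summary(2.1442, 0.68, df=30, g=4)
        assert out["p_raw"] == pytest.approx(0.0037, abs=5e-5)
        assert out["p_scheffe"] == pytest.approx(0.0332, abs=5e-5)


def test_injected_shift_recovered_with_power():
    """A TR3 shift of 2 residual SDs is declared significant in >= 80% of
    200 simulated trials at alpha = 0.05."""
    design = rcbd_design()
    rng = np.random.default_rng(9)
    shift = (design["treatment"] == "TR3").to_numpy() * 2.0
    hits = 0
    for _ in range(200):
        y = shift + rng.normal(size=len(design))
        table = type3_effect_tests(fit_fixed_effects(design, y))
        hits += table.set_index("effect").loc["treatment", "p_value"] <= 0.05
    assert hits >= 160
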