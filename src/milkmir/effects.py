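"""Fixed-effects testing of PC scores: the trial model, LS means, Scheffé.

Each retained component's score vector Y is fitted to the trial model

    Y_ijk = mu + trt_i + start_j + block_k(j) + e_ijk

with treatment (tie-rail configuration), start period, and block nested
within start all as fixed effects; after per-cow window averaging no random
term remains, so the "mixed" analysis reduces to ordinary least squares.
Sum-to-zero coding is used throughout, which makes the least-squares mean
of treatment level i simply ``mu + trt_i`` and keeps Type-III tests
well-defined in unbalanced data.

Pairwise treatment comparisons are adjusted with Scheffé's method: a
contrast with statistic t among g levels is referred to
P(F_{g-1, df} >= t^2 / (g-1)), which protects every contrast in the
(g-1)-dimensional treatment space simultaneously.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .errors import (
    DegenerateVariableError,
    InvalidArgumentError,
    NonEstimableError,
    SingularDesignError,
)

__all__ = [
    "EffectsModel",
    "cow_design",
    "fit_fixed_effects",
    "type3_effect_tests",
    "ls_means",
    "pairwise_contrasts_scheffe",
    "scheffe_adjusted_p",
    "contrast_from_summary",
]

EFFECTS = ("treatment", "start", "block")


def cow_design(metadata: pd.DataFrame) -> pd.DataFrame:
    """Collapse per-sample metadata to the cow-level design table."""
    cols = ["cow_id", "treatment", "start", "block"]
    d = metadata.drop_duplicates("cow_id")[cols].reset_index(drop=True)
    for col in cols[1:]:
        if d[col].isna().any():
            raise InvalidArgumentError(f"missing {col} in design")
    return d


def _sum_code(level, levels) -> np.ndarray:
    """Sum-to-zero contrast row for one observation (len(levels)-1 columns)."""
    k = len(levels)
    row = np.zeros(k - 1)
    if level == levels[-1]:
        row[:] = -1.0
    else:
        row[levels.index(level)] = 1.0
    return row


def _design_matrix(design: pd.DataFrame):
    """Build the sum-to-zero design matrix with block nested in start.

    Returns ``(X, blocks, levels)`` where ``blocks`` maps effect name to the
    list of column indices it owns and ``levels`` holds factor levels.
    """
    trt_levels = sorted(design["treatment"].astype(str).unique())
    start_levels = sorted(design["start"].astype(str).unique())
    if len(trt_levels) < 2:
        raise InvalidArgumentError("treatment needs at least 2 levels")
    block_levels = {
        s: sorted(design.loc[design["start"].astype(str) == s, "block"].astype(str).unique())
        for s in start_levels
    }
    n = len(design)
    cols = [np.ones((n, 1))]
    blocks = {"intercept": [0]}
    idx = 1

    def add(effect, mat):
        nonlocal idx
        cols.append(mat)
        blocks[effect] = list(range(idx, idx + mat.shape[1]))
        idx += mat.shape[1]

    add("treatment", np.vstack([
        _sum_code(t, trt_levels) for t in design["treatment"].astype(str)
    ]))
    if len(start_levels) > 1:
        add("start", np.vstack([
            _sum_code(s, start_levels) for s in design["start"].astype(str)
        ]))
    else:
        blocks["start"] = []
    block_cols = []
    for s in start_levels:
        lv = block_levels[s]
        if len(lv) < 2:
            continue
        mat = np.zeros((n, len(lv) - 1))
        in_s = design["start"].astype(str) == s
        for i in np.flatnonzero(in_s.to_numpy()):
            mat[i] = _sum_code(str(design["block"].iloc[i]), lv)
        block_cols.append(mat)
    if block_cols:
        mat = np.hstack(block_cols)
        cols.append(mat)
        blocks["block"] = list(range(idx, idx + mat.shape[1]))
        idx += mat.shape[1]
    else:
        blocks["block"] = []
    x = np.hstack(cols)
    levels = {"treatment": trt_levels, "start": start_levels, "block": block_levels}
    return x, blocks, levels


@dataclass
class EffectsModel:
    """A fitted trial model for one response (one PC's scores)."""

    design: pd.DataFrame
    response: np.ndarray
    x: np.ndarray
    blocks: dict
    levels: dict
    results: object  # statsmodels RegressionResults

    @property
    def df_resid(self) -> int:
        return int(self.results.df_resid)

    @property
    def mse(self) -> float:
        return float(self.results.ssr / self.results.df_resid)

    @property
    def sse(self) -> float:
        return float(self.results.ssr)


def fit_fixed_effects(design: pd.DataFrame, response) -> EffectsModel:
    """Ordinary least-squares fit of the trial model to a response vector."""
    y = np.asarray(response, dtype=float)
    if y.ndim != 1 or len(y) != len(design):
        raise InvalidArgumentError("response length must match the design table")
    x, blocks, levels = _design_matrix(design)
    rank = np.linalg.matrix_rank(x)
    if rank < x.shape[1]:
        raise SingularDesignError(
            f"design matrix rank {rank} < {x.shape[1]} columns"
        )
    if len(y) <= x.shape[1]:
        raise InvalidArgumentError("need more observations than model parameters")
    results = sm.OLS(y, x).fit()
    return EffectsModel(design=design.reset_index(drop=True), response=y,
                        x=x, blocks=blocks, levels=levels, results=results)


def type3_effect_tests(model: EffectsModel) -> pd.DataFrame:
    """Type-III F tests for treatment, start and block.

    Each effect is tested by comparing the full model against the model
    with that effect's columns removed (all other terms retained):
    ``F = [(SSE_reduced - SSE_full)/df_effect] / MSE_full``.
    """
    if model.mse == 0:
        raise DegenerateVariableError([], "zero residual variance: F tests undefined")
    rows = []
    for effect in EFFECTS:
        cols = model.blocks.get(effect, [])
        if not cols:
            continue
        keep = [j for j in range(model.x.shape[1]) if j not in cols]
        reduced = sm.OLS(model.response, model.x[:, keep]).fit()
        df_e = len(cols)
        f = ((reduced.ssr - model.sse) / df_e) / model.mse
        f = max(f, 0.0)
        rows.append({
            "effect": effect,
            "F": f,
            "df_num": df_e,
            "df_den": model.df_resid,
            "p_value": float(stats.f.sf(f, df_e, model.df_resid)),
        })
    return pd.DataFrame(rows)


def _lsmean_contrast(model: EffectsModel, level: str) -> np.ndarray:
    """Row vector whose dot with beta is the LS mean of a treatment level.

    Under sum-to-zero coding, averaging the prediction with equal weight
    over start levels and blocks within start zeroes every non-treatment
    column, leaving intercept + treatment coding.
    """
    trt_levels = model.levels["treatment"]
    if level not in trt_levels:
        raise NonEstimableError(f"treatment level {level!r} not in the fitted design")
    c = np.zeros(model.x.shape[1])
    c[model.blocks["intercept"][0]] = 1.0
    code = _sum_code(level, trt_levels)
    for j, v in zip(model.blocks["treatment"], code):
        c[j] = v
    return c


def ls_means(model: EffectsModel, factor: str = "treatment") -> pd.DataFrame:
    """Least-squares means of the treatment levels with SE, t and p (H0: mean = 0)."""
    if factor != "treatment":
        raise InvalidArgumentError("LS means are implemented for the treatment factor")
    cov = model.results.cov_params()
    beta = model.results.params
    rows = []
    for level in model.levels["treatment"]:
        c = _lsmean_contrast(model, level)
        est = float(c @ beta)
        se = float(np.sqrt(c @ cov @ c))
        t = est / se
        rows.append({
            "treatment": level,
            "estimate": est,
            "se": se,
            "df": model.df_resid,
            "t_value": t,
            "p_value": float(2 * stats.t.sf(abs(t), model.df_resid)),
        })
    return pd.DataFrame(rows)


def scheffe_adjusted_p(t: float, g: int, df: int) -> float:
    """Scheffé-adjusted two-sided p for a contrast among ``g`` levels.

    Returns ``P(F_{g-1, df} >= t^2 / (g-1))``; monotone decreasing in |t|,
    and identical to the raw two-sided t-test p when g = 2.
    """
    if g < 2:
        raise InvalidArgumentError("need at least 2 factor levels")
    if df < 1:
        raise InvalidArgumentError("residual df must be >= 1")
    return float(stats.f.sf(t**2 / (g - 1), g - 1, df))


def contrast_from_summary(estimate: float, se: float, df: int, g: int) -> dict:
    """Recompute t, raw p and Scheffé p from a reported estimate and SE.

    Useful for checking published LS-mean difference tables.
    """
    if se <= 0:
        raise InvalidArgumentError("standard error must be positive")
    t = estimate / se
    return {
        "t_value": t,
        "p_raw": float(2 * stats.t.sf(abs(t), df)),
        "p_scheffe": scheffe_adjusted_p(t, g, df),
    }


def pairwise_contrasts_scheffe(model: EffectsModel,
                               factor: str = "treatment") -> pd.DataFrame:
    """All pairwise LS-mean differences with raw and Scheffé-adjusted p-values."""
    if factor != "treatment":
        raise InvalidArgumentError("contrasts are implemented for the treatment factor")
    levels = model.levels["treatment"]
    g = len(levels)
    cov = model.results.cov_params()
    beta = model.results.params
    rows = []
    for a, b in combinations(levels, 2):
        c = _lsmean_contrast(model, a) - _lsmean_contrast(model, b)
        est = float(c @ beta)
        se = float(np.sqrt(c @ cov @ c))
        t = est / se
        rows.append({
            "level_a": a,
            "level_b": b,
            "estimate": est,
            "se": se,
            "df": model.df_resid,
            "t_value": t,
            "p_raw": float(2 * stats.t.sf(abs(t), model.df_resid)),
            "p_scheffe": scheffe_adjusted_p(t, g, model.df_resid),
        })
    return pd.DataFrame(rows)
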