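import numpy as np
import pandas as pd
import pytest

from milkmir.bands import BandLibrary, load_band_library
from milkmir.errors import (
    InsufficientDataError,
    InvalidArgumentError,
    WrongPretreatmentError,
)
from milkmir.grid import make_instrument_grid
from milkmir.interpret import (
    assign_bands,
    estimate_noise,
    fit_peaks,
    integrate_loading,
    pseudo_voigt,
    second_derivative_band_centers,
    variance_spectrum,
)
from milkmir.spectra import SpectraSet


def _series(grid, values, ids=None):
    values = np.atleast_2d(values)
    ids = ids or [f"s{i}" for i in range(values.shape[0])]
    return SpectraSet(sample_ids=ids, grid=grid, values=values)


class TestIntegrateLoading:
    def test_constant_loading_integrates_to_span(self):
        g = make_instrument_grid(21, 1000, 1100)
        out = integrate_loading(np.ones(21), g, "fd")
        assert out.values[0] == 0.0
        assert out.values[-1] == pytest.approx(100.0)

    def test_zero_loading_stays_zero(self):
        g = make_instrument_grid(10, 0, 9)
        np.testing.assert_array_equal(integrate_loading(np.zeros(10), g, "vnfd").values,
                                      np.zeros(10))

    def test_inverts_first_derivative_of_analytic_band(self):
        g = make_instrument_grid(400, 1000, 1600)
        f = pseudo_voigt(g.points, 1300.0, 1.0, 40.0, 0.3)
        deriv = np.gradient(f, g.points)
        rebuilt = integrate_loading(deriv, g, "fd").values
        # cumulative trapezoid of f' reproduces f - f(x0) up to O(d^2 f'')
        d = g.spacing
        max_f2 = np.max(np.abs(np.gradient(deriv, g.points)))
        tol = d**2 * max_f2 * len(g)
        np.testing.assert_allclose(rebuilt, f - f[0], atol=tol)

    def test_segments_integrate_independently(self):
        g = make_instrument_grid(6, 0, 5)
        g2 = type(g)(points=np.array([0.0, 1, 2, 10, 11, 12]), spacing=1.0,
                     segment_bounds=((0.0, 2.0), (10.0, 12.0)))
        out = integrate_loading(np.ones(6), g2, "fd")
        assert out.values[3] == 0.0  # second segment restarts at zero

    def test_raw_loading_rejected(self):
        g = make_instrument_grid(10, 0, 9)
        with pytest.raises(WrongPretreatmentError):
            integrate_loading(np.ones(10), g, "raw")


class TestEstimateNoise:
    def test_white_noise_recovered(self):
        rng = np.random.default_rng(0)
        sigma = 0.37
        est = estimate_noise(rng.normal(0, sigma, size=500))
        assert est == pytest.approx(sigma, rel=0.15)

    def test_smooth_band_is_essentially_noiseless(self):
        g = make_instrument_grid(500, 1000, 1600)
        band = pseudo_voigt(g.points, 1300.0, 1.0, 80.0, 0.5)
        assert estimate_noise(band, g) <= 1e-4  # <= 1e-4 of unit band height

    def test_constant_vector_gives_zero(self):
        assert estimate_noise(np.full(50, 2.5)) == 0.0

    def test_too_few_points_rejected(self):
        with pytest.raises(InsufficientDataError):
            estimate_noise(np.ones(5))


class TestFitPeaks:
    def test_single_band_recovered(self):
        g = make_instrument_grid(1060, 925, 5008)
        rng = np.random.default_rng(1)
        truth = dict(center=1405.0, height=1.0, fwhm=20.0, eta=0.5)
        y = pseudo_voigt(g.points, **truth) + rng.normal(0, 0.01, len(g))
        res = fit_peaks(y, g, region=(1320, 1500), max_peaks=3)
        assert res.n_peaks >= 1
        main = res.peaks.iloc[(res.peaks["center"] - 1405).abs().argmin()]
        assert abs(main["center"] - 1405) <= g.spacing
        assert main["fwhh"] == pytest.approx(20.0, rel=0.10)

    def test_two_separated_bands_found(self):
        g = make_instrument_grid(1060, 925, 5008)
        rng = np.random.default_rng(2)
        y = (pseudo_voigt(g.points, 1300.0, 1.0, 20.0, 0.4)
             + pseudo_voigt(g.points, 1360.0, 0.8, 20.0, 0.4)
             + rng.normal(0, 0.005, len(g)))
        res = fit_peaks(y, g, region=(1240, 1430), max_peaks=4)
        centers = sorted(res.peaks["center"])
        assert any(abs(c - 1300) <= 2 * g.spacing for c in centers)
        assert any(abs(c - 1360) <= 2 * g.spacing for c in centers)

    def test_flat_zero_signal_yields_no_peaks(self):
        g = make_instrument_grid(200, 1000, 1600)
        res = fit_peaks(np.zeros(200), g, region=(1100, 1500), noise=1e-6)
        assert res.n_peaks == 0

    def test_residual_rms_never_exceeds_input_rms(self):
        g = make_instrument_grid(300, 1000, 1600)
        rng = np.random.default_rng(3)
        y = pseudo_voigt(g.points, 1250.0, 1.0, 30.0, 0.6) + rng.normal(0, 0.02, 300)
        res = fit_peaks(y, g, region=(1150, 1400), max_peaks=3)
        mask = (g.points >= 1150) & (g.points <= 1400)
        assert res.residual_rms <= np.sqrt(np.mean(y[mask] ** 2)) + 1e-12

    def test_region_outside_segment_rejected(self):
        g = make_instrument_grid(100, 1000, 1200)
        with pytest.raises(InvalidArgumentError):
            fit_peaks(np.zeros(100), g, region=(1150, 1400))


class TestSecondDerivativeBandCenters:
    def _growing_band_series(self, noise=0.0, direction=1.0):
        g = make_instrument_grid(400, 1000, 1600)
        rng = np.random.default_rng(4)
        rows = []
        for level in (0.0, 0.5, 1.0, 2.0):
            base = 0.2 + 0.1 * np.exp(-0.5 * ((g.points - 1300) / 200) ** 2)
            band = direction * level * pseudo_voigt(g.points, 1405.0, 0.05, 18.0, 0.5)
            rows.append(base + band + rng.normal(0, noise, len(g)))
        return _series(g, np.vstack(rows)), [0.0, 0.5, 1.0, 2.0], g

    def test_growing_band_center_recovered(self):
        series, conc, g = self._growing_band_series(noise=5e-4)
        centers = [c for c, _ in second_derivative_band_centers(series, conc)]
        assert any(abs(c - 1405) <= g.spacing for c in centers)

    def test_identical_spectra_give_empty_list(self):
        g = make_instrument_grid(200, 1000, 1600)
        row = 0.3 + pseudo_voigt(g.points, 1405.0, 0.1, 18.0, 0.5)
        series = _series(g, np.tile(row, (4, 1)))
        assert second_derivative_band_centers(series, [1, 2, 3, 4]) == []

    def test_shrinking_band_excluded(self):
        series, conc, g = self._growing_band_series(noise=0.0, direction=-1.0)
        # make absorbance actually decrease at the band by subtracting
        centers = [c for c, _ in second_derivative_band_centers(series, conc)]
        assert not any(abs(c - 1405) <= g.spacing for c in centers)

    def test_unordered_concentrations_rejected(self):
        series, _, _ = self._growing_band_series()
        with pytest.raises(InvalidArgumentError):
            second_derivative_band_centers(series, [0.0, 1.0, 0.5, 2.0])


class TestVarianceSpectrum:
    def test_identical_spectra_have_zero_variance(self):
        g = make_instrument_grid(50, 1000, 1200)
        series = _series(g, np.tile(np.linspace(0, 1, 50), (5, 1)))
        np.testing.assert_allclose(variance_spectrum(series).values,
                                   np.zeros(50), atol=1e-30)

    def test_variance_peaks_at_varying_band(self):
        g = make_instrument_grid(300, 1000, 1600)
        rows = [0.2 + a * pseudo_voigt(g.points, 1405.0, 0.1, 18.0, 0.5)
                for a in (0, 1, 2, 3)]
        vs = variance_spectrum(_series(g, np.vstack(rows)))
        assert abs(vs.grid.points[np.argmax(vs.values)] - 1405) <= g.spacing
        assert (vs.values >= 0).all()

    def test_single_spectrum_rejected(self):
        g = make_instrument_grid(10, 0, 9)
        with pytest.raises(InsufficientDataError):
            variance_spectrum(_series(g, np.ones((1, 10))))


@pytest.fixture(scope="module")
def library():
    return load_band_library()


class TestAssignBands:
    def test_bhb_band_is_exact_match(self, library):
        out = assign_bands([(1405.0, +1)], library)
        top = out.iloc[0]
        assert top["molecule"] == "bhb"
        assert top["delta"] == 0.0
        assert top["medium"] == "milk"

    def test_acetone_within_tolerance(self, library):
        out = assign_bands([(1237.0, +1)], library)
        acetone = out[out["molecule"] == "acetone"]
        assert not acetone.empty
        assert acetone["delta"].min() == pytest.approx(2.0)

    def test_far_feature_unassigned(self, library):
        out = assign_bands([(2500.0, -1)], library)
        assert list(out["molecule"]) == ["unassigned"]

    def test_region_annotation_for_unassigned(self, library):
        out = assign_bands([(1150.5, -1)], BandLibrary(
            pd.DataFrame({"molecule": ["x"], "medium": ["milk"],
                          "center_cm1": [3000.0]})),
            region_annotations={"lactose region": (1000, 1200)})
        assert out.iloc[0]["note"] == "lactose region"

    def test_stable_under_library_permutation(self, library):
        shuffled = BandLibrary(library.table.sample(frac=1, random_state=3)
                               .reset_index(drop=True))
        a = assign_bands([(1405.0, 1), (1237.0, 1), (1077.0, -1)], library)
        b = assign_bands([(1405.0, 1), (1237.0, 1), (1077.0, -1)], shuffled)
        pd.testing.assert_frame_equal(a.reset_index(drop=True),
                                      b.reset_index(drop=True))

    def test_empty_library_rejected(self):
        with pytest.raises(InvalidArgumentError):
            BandLibrary(pd.DataFrame(columns=["molecule", "medium", "center_cm1"]))

    def test_non_positive_tolerance_rejected(self, library):
        with pytest.raises(InvalidArgumentError):
            assign_bands([(1405.0, 1)], library, tolerance=0.0)


def test_band_library_contents():
    lib = load_band_library()
    assert {"bhb", "acetone", "citrate", "urea", "lactose"} - set(lib.molecules) \
        == {"lactose"}  # lactose is a major component, not in the minor library
    assert lib.centers("bhb", "milk") == [1077, 1316, 1405, 1554, 2926]
    assert 1239 in lib.centers("acetone", "milk")
    assert lib.table["center_cm1"].between(900, 3100).all()
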