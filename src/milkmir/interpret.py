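"""Chemical interpretation of loading spectra.

A principal component that shows a significant treatment effect is read
chemically through its loading spectrum.  Loadings from derivative
datasets are first re-integrated (cumulative trapezoid, per segment) so
bands reappear as humps; humps without clear maxima are deconvolved into
pseudo-Voigt peaks; candidate band centers from spiking series are found
as second-derivative minima whose intensity grows with concentration; and
every feature is finally matched against the molecule band library within
a wavenumber tolerance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.integrate import cumulative_trapezoid
from scipy.signal import find_peaks, savgol_filter

from .bands import BandLibrary
from .errors import (
    InsufficientDataError,
    InvalidArgumentError,
    WrongPretreatmentError,
)
from .grid import WavenumberGrid
from .spectra import SpectraSet, Spectrum

__all__ = [
    "IntegratedLoading",
    "PeakFitResult",
    "integrate_loading",
    "estimate_noise",
    "pseudo_voigt",
    "fit_peaks",
    "second_derivative_band_centers",
    "variance_spectrum",
    "assign_bands",
    "region_mass",
    "plot_integrated_loading",
]

#: Broad-region annotations applied to otherwise unassigned features.
DEFAULT_REGION_ANNOTATIONS = {
    "lactose region": (1000.0, 1200.0),
    "CH stretch region": (2800.0, 3000.0),
}


@dataclass
class IntegratedLoading:
    """Cumulative integral of a derivative-dataset loading spectrum."""

    grid: WavenumberGrid
    values: np.ndarray
    component_index: int
    pretreatment: str


@dataclass
class PeakFitResult:
    """Result of deconvolving one region into pseudo-Voigt peaks."""

    peaks: pd.DataFrame  # columns: center, height, fwhh, eta
    region: tuple[float, float]
    residual_rms: float
    noise: float
    converged: bool = True
    narrowest_fwhh: float | None = field(default=None)

    @property
    def n_peaks(self) -> int:
        return len(self.peaks)


def integrate_loading(loading, grid: WavenumberGrid, source_pretreatment: str,
                      component_index: int = 0) -> IntegratedLoading:
    """Cumulative trapezoidal integral of an FD/VN-FD loading, per segment.

    Each segment's integral starts at 0; the integral never crosses a
    segment gap.  Loadings from raw or vector-normalized datasets are
    interpreted directly and must not be integrated.
    """
    if source_pretreatment not in ("fd", "vnfd"):
        raise WrongPretreatmentError(
            "only first-derivative loadings are integrated; raw/vn loadings "
            "are interpreted directly"
        )
    v = np.asarray(loading, dtype=float)
    if v.size != len(grid):
        raise InvalidArgumentError("loading length must equal grid length")
    out = np.empty_like(v)
    for sl in grid.segment_slices:
        out[sl] = cumulative_trapezoid(v[sl], grid.points[sl], initial=0.0)
    return IntegratedLoading(grid=grid, values=out,
                             component_index=component_index,
                             pretreatment=source_pretreatment)


def estimate_noise(values, grid: WavenumberGrid | None = None) -> float:
    """Robust high-frequency noise SD of a spectrum.

    Second differences of a smooth signal are tiny while those of white
    noise with SD sigma have SD ``sqrt(6) * sigma``; the estimate is
    ``1.4826 * median|second difference| / sqrt(6)``, computed within
    segments only.
    """
    v = np.asarray(values, dtype=float)
    slices = grid.segment_slices if grid is not None else (slice(0, v.size),)
    d2 = [np.diff(v[sl], n=2) for sl in slices if sl.stop - sl.start >= 3]
    d2 = np.concatenate(d2) if d2 else np.array([])
    if v.size < 8 or d2.size < 5:
        raise InsufficientDataError("noise estimation needs at least 8 points")
    return float(1.4826 * np.median(np.abs(d2)) / np.sqrt(6.0))


def pseudo_voigt(x, center, height, fwhm, eta):
    """Unit-height pseudo-Voigt profile scaled by ``height``.

    Linear mix ``eta * Lorentzian + (1 - eta) * Gaussian``, both with full
    width at half height ``fwhm`` and height 1 at ``center``.
    """
    u = (x - center) / (fwhm / 2.0)
    lor = 1.0 / (1.0 + u**2)
    gau = np.exp(-np.log(2.0) * u**2)
    return height * (eta * lor + (1.0 - eta) * gau)


def _second_derivative(values, spacing, window=5, polyorder=2):
    return savgol_filter(values, window_length=window, polyorder=polyorder,
                         deriv=2, delta=spacing)


def fit_peaks(values, grid: WavenumberGrid, region, max_peaks: int = 6,
              sensitivity: str = "low", noise: float | None = None) -> PeakFitResult:
    """Deconvolve one spectral region into a sum of pseudo-Voigt peaks.

    Candidate centers are seeded at minima of the smoothed second
    derivative (``high`` sensitivity lowers the prominence threshold so
    weaker shoulders seed peaks too).  Peaks are added one at a time, the
    whole sum refitted by nonlinear least squares with no baseline term,
    until the residual RMS falls to twice the noise estimate or
    ``max_peaks`` is reached.
    """
    import lmfit

    if sensitivity not in ("low", "high"):
        raise InvalidArgumentError("sensitivity must be 'low' or 'high'")
    lo, hi = float(min(region)), float(max(region))
    v = np.asarray(values, dtype=float)
    if v.size != len(grid):
        raise InvalidArgumentError("values length must equal grid length")
    if not np.all(np.isfinite(v)):
        raise InvalidArgumentError("values must be finite")
    seg = None
    for sl in grid.segment_slices:
        pts = grid.points[sl]
        if pts[0] - 1e-9 <= lo and hi <= pts[-1] + 1e-9:
            seg = sl
            break
    if seg is None:
        raise InvalidArgumentError(
            f"region ({lo}, {hi}) is not contained in a single grid segment"
        )
    if noise is None:
        noise = estimate_noise(v[seg])
    mask = (grid.points >= lo) & (grid.points <= hi)
    x, y = grid.points[mask], v[mask]
    if x.size < 5:
        raise InsufficientDataError("region holds too few points to fit")

    d2 = _second_derivative(y, grid.spacing)
    scale = np.std(d2)
    frac = 0.5 if sensitivity == "low" else 0.1
    if scale > 0:
        idx, props = find_peaks(-d2, prominence=frac * scale)
        order = np.argsort(props["prominences"])[::-1]
        candidates = list(idx[order])
    else:
        candidates = []

    target = 2.0 * noise
    rms = float(np.sqrt(np.mean(y**2)))
    if not candidates or rms <= target:
        return PeakFitResult(
            peaks=pd.DataFrame(columns=["center", "height", "fwhh", "eta"]),
            region=(lo, hi), residual_rms=rms, noise=noise)

    width0 = max(4 * grid.spacing, (hi - lo) / 10)
    best = None
    used = []
    converged = True
    for k, cand in enumerate(candidates[:max_peaks]):
        used.append(cand)
        model, params = None, lmfit.Parameters()
        for j, ci in enumerate(used):
            m = lmfit.Model(pseudo_voigt, prefix=f"p{j}_")
            model = m if model is None else model + m
            params.add(f"p{j}_center", value=float(x[ci]), min=lo, max=hi)
            h0 = float(y[ci]) if y[ci] != 0 else float(np.max(np.abs(y)))
            params.add(f"p{j}_height", value=h0)
            params.add(f"p{j}_fwhm", value=width0, min=grid.spacing,
                       max=2 * (hi - lo))
            params.add(f"p{j}_eta", value=0.5, min=0.0, max=1.0)
        try:
            fit = model.fit(y, params, x=x)
        except Exception:
            converged = False
            break
        rms = float(np.sqrt(np.mean(fit.residual**2)))
        best = fit
        if rms <= target:
            break
    if best is None:
        return PeakFitResult(
            peaks=pd.DataFrame(columns=["center", "height", "fwhh", "eta"]),
            region=(lo, hi), residual_rms=float(np.sqrt(np.mean(y**2))),
            noise=noise, converged=False)

    rows = []
    for j in range(len(used)):
        if f"p{j}_center" not in best.params:
            continue
        rows.append({
            "center": float(best.params[f"p{j}_center"].value),
            "height": float(best.params[f"p{j}_height"].value),
            "fwhh": float(best.params[f"p{j}_fwhm"].value),
            "eta": float(best.params[f"p{j}_eta"].value),
        })
    peaks = pd.DataFrame(rows).sort_values("center").reset_index(drop=True)
    rms = float(np.sqrt(np.mean(best.residual**2)))
    return PeakFitResult(peaks=peaks, region=(lo, hi), residual_rms=rms,
                         noise=noise, converged=converged,
                         narrowest_fwhh=float(peaks["fwhh"].min()))


def second_derivative_band_centers(series: SpectraSet, concentrations,
                                   rho_min: float = 0.9,
                                   min_amplitude: float | None = None,
                                   ) -> list[tuple[float, str]]:
    """Band centers that grow with concentration in a spiking series.

    Candidate centers are local minima of the mean smoothed second
    derivative (window 5, quadratic) across the series; a center is
    retained when the absorbance magnitude at that wavenumber increases
    monotonically with concentration (Spearman rho > ``rho_min``) and its
    growth exceeds ``min_amplitude`` (default: 3x the series' estimated
    noise SD, so chance-monotone noise never qualifies).
    """
    conc = np.asarray(concentrations, dtype=float)
    if series.n_samples < 3 or conc.size != series.n_samples:
        raise InvalidArgumentError("need >= 3 spectra with one concentration each")
    if not np.all(np.diff(conc) > 0):
        raise InvalidArgumentError("concentrations must be strictly increasing")
    if min_amplitude is None:
        try:
            min_amplitude = 3.0 * float(np.median([
                estimate_noise(row, series.grid) for row in series.values
            ]))
        except InsufficientDataError:
            min_amplitude = 0.0

    centers = []
    for sl in series.grid.segment_slices:
        if sl.stop - sl.start < 5:
            continue
        d2 = np.vstack([
            _second_derivative(row[sl], series.grid.spacing)
            for row in series.values
        ])
        mean_d2 = d2.mean(axis=0)
        scale = np.std(mean_d2)
        if scale == 0:
            continue
        idx, _ = find_peaks(-mean_d2, prominence=0.05 * scale)
        for i in idx:
            col = np.abs(series.values[:, sl.start + i])
            if np.ptp(col) <= min_amplitude:
                continue
            rho = stats.spearmanr(conc, col).statistic
            if np.isfinite(rho) and rho > rho_min:
                centers.append((float(series.grid.points[sl.start + i]), "increasing"))
    return sorted(centers)


def variance_spectrum(series: SpectraSet) -> Spectrum:
    """Per-wavenumber sample variance across a series of spectra."""
    if series.n_samples < 2:
        raise InsufficientDataError("variance spectrum needs at least 2 spectra")
    return Spectrum(grid=series.grid,
                    values=series.values.var(axis=0, ddof=1))


def assign_bands(features, library: BandLibrary, tolerance: float = 5.0,
                 region_annotations: dict | None = None) -> pd.DataFrame:
    """Match spectral features to library molecules within a tolerance.

    ``features`` is a list of ``(wavenumber, sign)`` pairs (sign = sign of
    the loading there).  Every molecule with a milk or aqueous band center
    within ``tolerance`` cm^-1 is listed, ranked by |delta|; a wavenumber
    near no library band is reported as unassigned, annotated with a broad
    region name when ``region_annotations`` is supplied.
    """
    if tolerance <= 0:
        raise InvalidArgumentError("tolerance must be positive")
    lib = library.table.sort_values(
        ["molecule", "medium", "center_cm1"]).reset_index(drop=True)
    rows = []
    for wavenumber, sign in features:
        w = float(wavenumber)
        delta = (lib["center_cm1"] - w).abs()
        hits = lib[delta <= tolerance].copy()
        if hits.empty:
            note = ""
            for name, (lo, hi) in (region_annotations or {}).items():
                if lo <= w <= hi:
                    note = name
                    break
            rows.append({"wavenumber": w, "sign": int(np.sign(sign)),
                         "molecule": "unassigned", "medium": "",
                         "center_cm1": np.nan, "delta": np.nan, "note": note})
            continue
        hits["delta"] = (hits["center_cm1"] - w).abs()
        hits = hits.sort_values(["delta", "molecule", "medium"])
        for rank, (_, h) in enumerate(hits.iterrows(), start=1):
            rows.append({"wavenumber": w, "sign": int(np.sign(sign)),
                         "molecule": h["molecule"], "medium": h["medium"],
                         "center_cm1": float(h["center_cm1"]),
                         "delta": float(h["delta"]), "note": f"rank {rank}"})
    return pd.DataFrame(rows)


def region_mass(values, grid: WavenumberGrid, low: float, high: float) -> float:
    """Mean of a (loading-integral) curve over a wavenumber window."""
    mask = (grid.points >= low) & (grid.points <= high)
    if not mask.any():
        raise InvalidArgumentError(f"no grid points in ({low}, {high})")
    return float(np.mean(np.asarray(values, dtype=float)[mask]))


def plot_integrated_loading(il: IntegratedLoading, assignments=None, path=None):
    """Plot an integrated loading spectrum with shaded assigned regions."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(9, 4))
    for sl in il.grid.segment_slices:
        ax.plot(il.grid.points[sl], il.values[sl], color="tab:blue", lw=1.0)
    ax.axhline(0.0, color="grey", lw=0.5)
    if assignments is not None and len(assignments):
        for w in pd.unique(assignments["wavenumber"]):
            ax.axvspan(w - 5, w + 5, color="tab:orange", alpha=0.25)
    ax.set_xlabel("wavenumber (cm$^{-1}$)")
    ax.set_ylabel("integrated loading")
    ax.invert_xaxis()  # spectroscopy display convention
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
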