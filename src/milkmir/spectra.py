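"""Spectral data model, CSV I/O, region retention and the outlier screen.

The central container is :class:`SpectraSet`: a samples x wavenumbers
absorbance matrix on a shared :class:`~milkmir.grid.WavenumberGrid`,
tagged with the pretreatment applied so far (``raw``, ``vn``, ``fd`` or
``vnfd``).  Sample metadata (cow, week, treatment, start period, block,
parity, stage of lactation) and analyzer composition records travel as
plain :class:`pandas.DataFrame` objects with validated column sets.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats

from .errors import (
    EmptySelectionError,
    InsufficientDataError,
    InvalidArgumentError,
)
from .grid import WavenumberGrid

__all__ = [
    "PRETREATMENTS",
    "Spectrum",
    "SpectraSet",
    "select_regions",
    "screen_outliers",
    "summarize_composition",
    "read_spectra_csv",
    "write_spectra_csv",
    "read_metadata_csv",
    "read_composition_csv",
    "validate_metadata",
    "validate_composition",
]

#: Pretreatment tags: raw absorbance, vector normalized, first derivative,
#: vector-normalized first derivative.
PRETREATMENTS = ("raw", "vn", "fd", "vnfd")

#: Informative milk mid-IR regions (cm^-1): the CH-stretch window, the
#: carbonyl window and the fingerprint region.  Everything else is dominated
#: by water absorption or noise.
DEFAULT_REGIONS = ((925.0, 1612.0), (1681.0, 1797.0), (2803.0, 3061.0))

METADATA_COLUMNS = [
    "sample_id", "cow_id", "week", "treatment", "start", "block", "parity", "dim_class",
]
COMPOSITION_COLUMNS = [
    "cow_id", "week", "fat_pct", "protein_pct", "lactose_pct", "urea_mgdl", "bhb_mmoll",
]
ANALYTES = ["fat_pct", "protein_pct", "lactose_pct", "urea_mgdl", "bhb_mmoll"]


@dataclass
class Spectrum:
    """A single spectrum on a wavenumber grid."""

    grid: WavenumberGrid
    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1 or self.values.size != len(self.grid):
            raise InvalidArgumentError("spectrum length must equal grid length")
        if not np.all(np.isfinite(self.values)):
            raise InvalidArgumentError("spectrum values must be finite")


@dataclass
class SpectraSet:
    """Matrix of absorbance spectra on a shared wavenumber grid."""

    sample_ids: list
    grid: WavenumberGrid
    values: np.ndarray
    pretreatment: str = "raw"

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.sample_ids = list(self.sample_ids)
        if self.values.ndim != 2:
            raise InvalidArgumentError("values must be a 2-D samples x wavenumbers array")
        if self.values.shape[0] != len(self.sample_ids):
            raise InvalidArgumentError("row count does not match number of sample ids")
        if self.values.shape[1] != len(self.grid):
            raise InvalidArgumentError("column count does not match grid length")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise InvalidArgumentError("duplicate sample ids")
        if self.pretreatment not in PRETREATMENTS:
            raise InvalidArgumentError(
                f"pretreatment must be one of {PRETREATMENTS}, got {self.pretreatment!r}"
            )
        if not np.all(np.isfinite(self.values)):
            raise InvalidArgumentError("absorbance values must be finite")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_wavenumbers(self) -> int:
        return self.values.shape[1]

    def row(self, sample_id) -> np.ndarray:
        return self.values[self.sample_ids.index(sample_id)]

    def copy_with(self, **kwargs) -> "SpectraSet":
        return replace(self, **kwargs)


def select_regions(spectra: SpectraSet, regions=DEFAULT_REGIONS,
                   edge_tolerance: float | None = None) -> SpectraSet:
    """Retain only the wavenumbers inside the informative regions.

    A grid point ``p`` is kept when ``low - tol <= p <= high + tol`` for some
    region.  Region boundaries published for milk spectra are rounded grid
    coordinates, so the default tolerance of half a grid spacing treats a
    boundary as the nearest grid point; on the 1060-point 925-5008 cm^-1
    grid with the default regions this retains exactly 278 wavenumbers.

    The output grid has one segment per region, ascending.
    """
    regions = sorted((float(lo), float(hi)) for lo, hi in regions)
    for (a, b), (c, d) in zip(regions, regions[1:]):
        if c <= b:
            raise InvalidArgumentError("regions overlap after sorting")
    for lo, hi in regions:
        if hi <= lo:
            raise InvalidArgumentError(f"region bounds reversed: ({lo}, {hi})")
    tol = spectra.grid.spacing / 2 if edge_tolerance is None else float(edge_tolerance)
    if tol < 0:
        raise InvalidArgumentError("edge_tolerance must be >= 0")

    pts = spectra.grid.points
    keep = np.zeros(pts.size, dtype=bool)
    bounds = []
    for lo, hi in regions:
        m = (pts >= lo - tol) & (pts <= hi + tol)
        if m.any():
            keep |= m
            seg = pts[m]
            bounds.append((float(seg[0]), float(seg[-1])))
    if not keep.any():
        raise EmptySelectionError("no grid point falls inside the requested regions")
    new_grid = WavenumberGrid(points=pts[keep], spacing=spectra.grid.spacing,
                              segment_bounds=tuple(bounds))
    return SpectraSet(sample_ids=spectra.sample_ids, grid=new_grid,
                      values=spectra.values[:, keep], pretreatment=spectra.pretreatment)


def screen_outliers(spectra: SpectraSet, quantile: float = 0.999) -> pd.DataFrame:
    """Advisory PCA-based spectral outlier screen.

    Fits a 2-component PCA to the column-standardized spectra and flags
    samples whose squared Mahalanobis distance in the (PC1, PC2) score
    plane exceeds the chi-square(2) quantile.  In a clean dataset the
    scores cluster at the origin.  The screen only reports; nothing is
    removed.

    Returns a frame with ``sample_id``, ``distance2``, ``threshold`` and
    boolean ``flagged``.
    """
    if not 0 < quantile < 1:
        raise InvalidArgumentError("quantile must be in (0, 1)")
    if spectra.n_samples < 3:
        raise InsufficientDataError("outlier screen needs at least 3 samples")
    from sklearn.decomposition import PCA

    x = spectra.values
    sd = x.std(axis=0, ddof=1)
    sd_safe = np.where(sd > 0, sd, 1.0)  # constant columns carry no outlier signal
    z = (x - x.mean(axis=0)) / sd_safe
    pca = PCA(n_components=2, svd_solver="full")
    scores = pca.fit_transform(z)
    var = scores.var(axis=0, ddof=1)
    var = np.where(var > 0, var, 1.0)
    d2 = (scores**2 / var).sum(axis=1)
    thr = stats.chi2.ppf(quantile, df=2)
    return pd.DataFrame({
        "sample_id": spectra.sample_ids,
        "distance2": d2,
        "threshold": thr,
        "flagged": d2 > thr,
    })


# ---------------------------------------------------------------------------
# metadata / composition tables


def validate_metadata(meta: pd.DataFrame, weeks: range | None = None) -> pd.DataFrame:
    missing = [c for c in METADATA_COLUMNS if c not in meta.columns]
    if missing:
        raise InvalidArgumentError(f"metadata is missing columns: {missing}")
    if meta.empty:
        raise InvalidArgumentError("metadata table is empty")
    for col in ("treatment", "start", "block"):
        if meta[col].isna().any():
            raise InvalidArgumentError(f"metadata column {col!r} has missing values")
    if meta["sample_id"].duplicated().any():
        raise InvalidArgumentError("duplicate sample_id in metadata")
    wk = meta["week"].astype(int)
    if weeks is not None and (~wk.isin(list(weeks))).any():
        raise InvalidArgumentError("metadata contains weeks outside the trial length")
    out = meta.copy()
    out["week"] = wk
    return out


def validate_composition(comp: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in COMPOSITION_COLUMNS if c not in comp.columns]
    if missing:
        raise InvalidArgumentError(f"composition table is missing columns: {missing}")
    for col in ANALYTES:
        if (comp[col] < 0).any():
            raise InvalidArgumentError(f"negative values in {col}")
    for col in ("fat_pct", "protein_pct", "lactose_pct"):
        if (comp[col] >= 100).any():
            raise InvalidArgumentError(f"{col} must be a percentage below 100")
    out = comp.copy()
    out["week"] = out["week"].astype(int)
    return out


def summarize_composition(composition: pd.DataFrame, metadata: pd.DataFrame,
                          weeks) -> pd.DataFrame:
    """Per-treatment, per-week mean +/- SD of each analyte, plus a window average.

    The window average row (``week == 'avg'``) is the unweighted mean of the
    per-week means, the convention of trial composition tables; it is
    returned at full precision with a 2-decimal ``display`` column.  Weeks
    with no records yield a warning and are simply absent from the output.
    """
    weeks = sorted(int(w) for w in weeks)
    if not weeks:
        raise InvalidArgumentError("weeks must be non-empty")
    comp = validate_composition(composition)
    meta = validate_metadata(metadata)
    cow_trt = meta.drop_duplicates("cow_id").set_index("cow_id")["treatment"]
    unknown = set(comp["cow_id"]) - set(cow_trt.index)
    if unknown:
        raise InvalidArgumentError(f"composition rows with no metadata cow: {sorted(unknown)}")
    df = comp[comp["week"].isin(weeks)].copy()
    df["treatment"] = df["cow_id"].map(cow_trt)

    rows = []
    for trt, sub in df.groupby("treatment", sort=True):
        for analyte in ANALYTES:
            weekly_means = []
            for week in weeks:
                cell = sub.loc[sub["week"] == week, analyte]
                if cell.empty:
                    warnings.warn(
                        f"no {analyte} records for treatment {trt}, week {week}",
                        stacklevel=2,
                    )
                    continue
                mean = float(cell.mean())
                sd = float(cell.std(ddof=1)) if len(cell) > 1 else 0.0
                weekly_means.append(mean)
                rows.append({"treatment": trt, "week": week, "analyte": analyte,
                             "mean": mean, "sd": sd, "n": len(cell)})
            if weekly_means:
                avg = float(np.mean(weekly_means))
                rows.append({"treatment": trt, "week": "avg", "analyte": analyte,
                             "mean": avg, "sd": np.nan, "n": len(weekly_means)})
    out = pd.DataFrame(rows)
    if not out.empty:
        out["display"] = out["mean"].round(2)
    return out


# ---------------------------------------------------------------------------
# CSV dialects


def write_spectra_csv(spectra: SpectraSet, path) -> None:
    """Wide CSV: first column ``sample_id``, headers = wavenumbers (2 decimals)."""
    df = pd.DataFrame(spectra.values,
                      columns=[f"{w:.2f}" for w in spectra.grid.points])
    df.insert(0, "sample_id", spectra.sample_ids)
    df.to_csv(path, index=False)


def read_spectra_csv(path, pretreatment: str = "raw") -> SpectraSet:
    """Read the wide spectra CSV, reconstructing the segment structure.

    Segment breaks are inferred wherever the header wavenumber step exceeds
    1.5x the median step.
    """
    df = pd.read_csv(path)
    if df.columns[0] != "sample_id":
        raise InvalidArgumentError("first column of a spectra CSV must be 'sample_id'")
    wn = np.array([float(c) for c in df.columns[1:]])
    if wn.size < 2:
        raise InvalidArgumentError("spectra CSV needs at least two wavenumber columns")
    order = np.argsort(wn)
    wn = wn[order]
    values = df.iloc[:, 1:].to_numpy(dtype=float)[:, order]
    diffs = np.diff(wn)
    spacing0 = float(np.median(diffs))
    breaks = np.where(diffs > 1.5 * spacing0)[0]
    starts = np.r_[0, breaks + 1]
    stops = np.r_[breaks + 1, wn.size]
    # Headers carry 2 decimals, so rounding error makes raw diffs non-uniform;
    # re-estimate the spacing from all within-segment steps and snap each
    # segment back to a uniform axis anchored at its first header value.
    inseg = np.ones(diffs.size, dtype=bool)
    inseg[breaks] = False
    spacing = float(diffs[inseg].mean()) if inseg.any() else spacing0
    snapped = np.empty_like(wn)
    for a, b in zip(starts, stops):
        snapped[a:b] = wn[a] + spacing * np.arange(b - a)
    wn = snapped
    bounds = tuple((float(wn[a]), float(wn[b - 1])) for a, b in zip(starts, stops))
    grid = WavenumberGrid(points=wn, spacing=spacing, segment_bounds=bounds)
    return SpectraSet(sample_ids=df["sample_id"].tolist(), grid=grid,
                      values=values, pretreatment=pretreatment)


def read_metadata_csv(path) -> pd.DataFrame:
    return validate_metadata(pd.read_csv(path))


def read_composition_csv(path) -> pd.DataFrame:
    return validate_composition(pd.read_csv(path))
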