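"""Spectral pretreatments and per-cow window averaging.

Four variants of every spectral dataset are analysed in parallel:

* ``raw`` — absorbance as recorded;
* ``vn`` — vector normalized (each spectrum scaled to unit Euclidean norm,
  removing multiplicative intensity effects such as path-length variation);
* ``fd`` — first derivative, a one-step finite difference that sharpens
  overlapping bands and removes additive baselines;
* ``vnfd`` — vector-normalized first derivative (derivative first, then
  normalization).

Because milk composition drifts along lactation, the analysis operates on
per-cow *window averages*: the mean spectrum of each cow over an early
window (weeks 1-3, short-term) or a late window (weeks 8-10, long-term).
Averaging follows pretreatment; the two orders differ for normalized
variants and the pretreat-then-average order is the one this pipeline
fixes.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .errors import (
    DegenerateSegmentError,
    EmptyWindowError,
    InvalidArgumentError,
    NormalizationError,
    WrongPretreatmentError,
)
from .grid import WavenumberGrid
from .spectra import SpectraSet, validate_metadata

__all__ = [
    "first_derivative",
    "vector_normalize",
    "make_pretreatment_variants",
    "window_average",
    "SHORT_TERM_WEEKS",
    "LONG_TERM_WEEKS",
]

SHORT_TERM_WEEKS = (1, 2, 3)
LONG_TERM_WEEKS = (8, 9, 10)


def first_derivative(spectra: SpectraSet) -> SpectraSet:
    """One-step finite-difference first derivative, per segment.

    ``d_i = (v_{i+1} - v_i) / spacing`` within each contiguous segment; the
    derivative never crosses a segment gap.  Output values live on the
    midpoints of adjacent input points, so each segment loses one point.
    """
    if spectra.pretreatment not in ("raw", "vn"):
        raise WrongPretreatmentError(
            f"first derivative expects raw or vn input, got {spectra.pretreatment!r}"
        )
    spacing = spectra.grid.spacing
    out_vals, out_pts, bounds = [], [], []
    for sl in spectra.grid.segment_slices:
        if sl.stop - sl.start < 2:
            lo = spectra.grid.points[sl.start]
            raise DegenerateSegmentError(
                f"segment starting at {lo:.2f} cm^-1 has a single point"
            )
        seg = spectra.values[:, sl]
        out_vals.append(np.diff(seg, axis=1) / spacing)
        mid = (spectra.grid.points[sl][1:] + spectra.grid.points[sl][:-1]) / 2
        out_pts.append(mid)
        bounds.append((float(mid[0]), float(mid[-1])))
    grid = WavenumberGrid(points=np.concatenate(out_pts), spacing=spacing,
                          segment_bounds=tuple(bounds))
    tag = "fd" if spectra.pretreatment == "raw" else "vnfd"
    return SpectraSet(sample_ids=spectra.sample_ids, grid=grid,
                      values=np.hstack(out_vals), pretreatment=tag)


def vector_normalize(spectra: SpectraSet) -> SpectraSet:
    """Scale each spectrum to unit Euclidean norm over the retained columns."""
    norms = np.linalg.norm(spectra.values, axis=1)
    bad = np.where(norms == 0)[0]
    if bad.size:
        names = [spectra.sample_ids[i] for i in bad]
        raise NormalizationError(f"zero-norm spectra cannot be normalized: {names}")
    tag = {"raw": "vn", "fd": "vnfd", "vn": "vn", "vnfd": "vnfd"}[spectra.pretreatment]
    return SpectraSet(sample_ids=spectra.sample_ids, grid=spectra.grid,
                      values=spectra.values / norms[:, None], pretreatment=tag)


def make_pretreatment_variants(spectra: SpectraSet) -> dict[str, SpectraSet]:
    """Build the four analysis variants from raw spectra.

    ``vn = VN(raw)``, ``fd = FD(raw)``, ``vnfd = VN(FD(raw))``.
    """
    if spectra.pretreatment != "raw":
        raise WrongPretreatmentError("variants are derived from raw spectra")
    fd = first_derivative(spectra)
    return {
        "raw": spectra,
        "vn": vector_normalize(spectra),
        "fd": fd,
        "vnfd": vector_normalize(fd),
    }


def window_average(spectra: SpectraSet, metadata: pd.DataFrame, weeks) -> SpectraSet:
    """Per-cow mean spectrum over the weekly samples inside ``weeks``.

    Returns one row per cow (sample ids become cow ids, sorted).  Cows with
    at least one sample in the window are averaged over whatever weeks they
    have; cows with none are dropped with a warning.
    """
    weeks = {int(w) for w in weeks}
    if not weeks:
        raise InvalidArgumentError("weeks must be non-empty")
    meta = validate_metadata(metadata)
    meta = meta.set_index("sample_id")
    missing = [s for s in spectra.sample_ids if s not in meta.index]
    if missing:
        raise InvalidArgumentError(f"samples without metadata: {missing[:5]}")

    by_cow: dict = {}
    for i, sid in enumerate(spectra.sample_ids):
        row = meta.loc[sid]
        if int(row["week"]) in weeks:
            by_cow.setdefault(row["cow_id"], []).append(i)
    all_cows = meta.loc[[s for s in spectra.sample_ids], "cow_id"].unique()
    dropped = [c for c in all_cows if c not in by_cow]
    if dropped:
        warnings.warn(f"cows with no sample in window {sorted(weeks)}: {dropped}",
                      stacklevel=2)
    if not by_cow:
        raise EmptyWindowError(f"no cow has a sample in weeks {sorted(weeks)}")
    cows = sorted(by_cow, key=str)
    values = np.vstack([spectra.values[by_cow[c]].mean(axis=0) for c in cows])
    return SpectraSet(sample_ids=cows, grid=spectra.grid, values=values,
                      pretreatment=spectra.pretreatment)
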