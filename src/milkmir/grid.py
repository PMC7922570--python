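"""Wavenumber grids.

A mid-infrared milk spectrum lives on a uniformly spaced wavenumber axis
(cm^-1).  After informative-region selection the axis is no longer
contiguous: it consists of several uniformly spaced *segments* separated by
gaps, and derivative / integration operations must never cross a gap.
:class:`WavenumberGrid` records the retained points together with the
segment structure.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import InvalidArgumentError

__all__ = ["WavenumberGrid", "make_instrument_grid"]


@dataclass(frozen=True)
class WavenumberGrid:
    """Strictly increasing wavenumber axis split into contiguous segments.

    Parameters
    ----------
    points
        Wavenumbers in cm^-1, strictly increasing.
    spacing
        Step between adjacent points inside any segment (cm^-1).
    segment_bounds
        ``(low, high)`` wavenumber pairs, one per contiguous run, ascending
        and non-overlapping.  The bounds are the first and last point of the
        run.
    """

    points: np.ndarray
    spacing: float
    segment_bounds: tuple[tuple[float, float], ...]
    _slices: tuple[slice, ...] = field(init=False, repr=False, compare=False)

    def __post_init__(self):
        pts = np.asarray(self.points, dtype=float)
        if pts.size == 0:
            raise InvalidArgumentError("grid must contain at least one point")
        if pts.size > 1 and not np.all(np.diff(pts) > 0):
            raise InvalidArgumentError("grid points must be strictly increasing")
        object.__setattr__(self, "points", pts)
        slices = []
        start = 0
        for low, high in self.segment_bounds:
            if high < low:
                raise InvalidArgumentError(f"segment bounds reversed: ({low}, {high})")
            stop = int(np.searchsorted(pts, high + 1e-9 * max(1.0, abs(high))))
            seg = pts[start:stop]
            if seg.size == 0:
                raise InvalidArgumentError(f"segment ({low}, {high}) contains no points")
            if seg.size > 1:
                diffs = np.diff(seg)
                if not np.allclose(diffs, self.spacing, rtol=1e-9, atol=1e-9 * self.spacing):
                    raise InvalidArgumentError(
                        f"segment ({low}, {high}) is not uniform at spacing {self.spacing}"
                    )
            slices.append(slice(start, stop))
            start = stop
        if start != pts.size:
            raise InvalidArgumentError("segment bounds do not cover all grid points")
        if len(slices) > 1:
            for (a, b), (c, d) in zip(self.segment_bounds, self.segment_bounds[1:]):
                if c <= b:
                    raise InvalidArgumentError("segments overlap or are unordered")
        object.__setattr__(self, "_slices", tuple(slices))

    def __len__(self) -> int:
        return self.points.size

    @property
    def segment_slices(self) -> tuple[slice, ...]:
        """Index slices of ``points`` corresponding to each segment."""
        return self._slices

    def segments(self):
        """Yield the wavenumber array of each contiguous segment."""
        for sl in self._slices:
            yield self.points[sl]

    def nearest_index(self, wavenumber: float) -> int:
        """Index of the grid point closest to ``wavenumber``."""
        return int(np.argmin(np.abs(self.points - wavenumber)))

    def __eq__(self, other):
        if not isinstance(other, WavenumberGrid):
            return NotImplemented
        return (
            len(self) == len(other)
            and np.allclose(self.points, other.points, rtol=1e-9, atol=1e-9)
            and self.segment_bounds == other.segment_bounds
        )

    def __hash__(self):  # dataclass(frozen) would use fields; arrays unhashable
        return hash((len(self), round(self.spacing, 9), self.segment_bounds))


def make_instrument_grid(n_points: int, low: float, high: float) -> WavenumberGrid:
    """Build the uniform single-segment grid of an FTIR milk analyzer.

    The standard milk mid-IR instrument records 1060 points between 925 and
    5008 cm^-1 (spacing ~3.8556 cm^-1).

    Parameters
    ----------
    n_points
        Number of grid points (>= 2).
    low, high
        First and last wavenumber in cm^-1 (``high > low``).
    """
    if n_points < 2:
        raise InvalidArgumentError(f"n_points must be >= 2, got {n_points}")
    if high <= low:
        raise InvalidArgumentError(f"need high > low, got ({low}, {high})")
    spacing = (high - low) / (n_points - 1)
    points = low + spacing * np.arange(n_points)
    points[-1] = high  # exact endpoint
    return WavenumberGrid(points=points, spacing=spacing, segment_bounds=((low, high),))
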