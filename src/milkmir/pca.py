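"""Correlation-matrix principal component analysis of average spectra.

The spectral matrix X (cows x wavenumbers) is decomposed as

    X = f1 q1' + f2 q2' + ... + fK qK' + E

where the f_l are component scores, the q_l orthonormal loading vectors,
and E collects the discarded noise components.  Variables are standardized
to zero mean and unit variance (divisor n-1) before decomposition, so each
eigenvalue measures how many original variables' worth of variance a
component carries and the classical eigenvalue >= 1 retention rule applies.

With fewer samples than wavenumbers (the usual case: ~48 cows, ~278
retained wavenumbers) the decomposition is computed by SVD of the
standardized matrix, yielding at most n-1 non-zero eigenvalues.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DegenerateVariableError, GridMismatchError, InsufficientDataError
from .spectra import SpectraSet

__all__ = ["PCAModel", "fit_pca", "retain_components", "project", "eigen_table"]


@dataclass
class PCAModel:
    """Fitted standardized PCA.

    Attributes
    ----------
    column_means, column_scales
        Per-wavenumber mean and SD (divisor n-1) used for standardization.
    loadings
        (wavenumbers x components) orthonormal loading vectors q_l, each
        oriented so its largest-magnitude entry is positive.
    eigenvalues
        Variance of each score column (divisor n-1), non-increasing.
    scores
        (samples x components) projections f_l of the training samples.
    explained_pct
        100 * eigenvalue / n_variables.
    """

    column_means: np.ndarray
    column_scales: np.ndarray
    loadings: np.ndarray
    eigenvalues: np.ndarray
    scores: np.ndarray
    explained_pct: np.ndarray
    n_variables: int
    grid_points: np.ndarray
    sample_ids: list
    pretreatment: str

    @property
    def n_components(self) -> int:
        return self.loadings.shape[1]


def fit_pca(averages: SpectraSet) -> PCAModel:
    """Fit a correlation-matrix PCA to a set of average spectra.

    Raises :class:`DegenerateVariableError` listing the offending
    wavenumbers if any column has zero variance (standardization would be
    undefined), and :class:`InsufficientDataError` below 3 samples.
    """
    x = averages.values
    n, p = x.shape
    if n < 3:
        raise InsufficientDataError("PCA needs at least 3 samples")
    means = x.mean(axis=0)
    scales = x.std(axis=0, ddof=1)
    dead = np.where(scales == 0)[0]
    if dead.size:
        wns = [round(float(averages.grid.points[i]), 2) for i in dead]
        raise DegenerateVariableError(wns)
    z = (x - means) / scales

    rank = min(n - 1, p)
    u, s, vt = np.linalg.svd(z, full_matrices=False)
    u, s, vt = u[:, :rank], s[:rank], vt[:rank]
    eigenvalues = s**2 / (n - 1)
    loadings = vt.T
    # resolve sign indeterminacy: largest-|entry| of each loading positive
    flip = np.sign(loadings[np.abs(loadings).argmax(axis=0), np.arange(rank)])
    flip[flip == 0] = 1.0
    loadings = loadings * flip
    scores = z @ loadings
    return PCAModel(
        column_means=means,
        column_scales=scales,
        loadings=loadings,
        eigenvalues=eigenvalues,
        scores=scores,
        explained_pct=100.0 * eigenvalues / p,
        n_variables=p,
        grid_points=averages.grid.points.copy(),
        sample_ids=list(averages.sample_ids),
        pretreatment=averages.pretreatment,
    )


def retain_components(model: PCAModel, eigen_min: float = 1.0,
                      pct_min: float | None = None) -> list[int]:
    """Indices (0-based, in component order) of the meaningful components.

    The operative rule is eigenvalue >= ``eigen_min``; an explained-variance
    floor can be added via ``pct_min`` (percent) but is off by default, since
    published eigenvalue tables retain sub-1% components whenever their
    eigenvalue clears 1.
    """
    keep = model.eigenvalues >= eigen_min
    if pct_min is not None:
        keep &= model.explained_pct >= pct_min
    return [int(i) for i in np.flatnonzero(keep)]


def retained_from_eigenvalues(eigenvalues, n_variables: int,
                              eigen_min: float = 1.0,
                              pct_min: float | None = None) -> list[int]:
    """Apply the retention rule to a bare eigenvalue list (e.g. a published table)."""
    eig = np.asarray(eigenvalues, dtype=float)
    keep = eig >= eigen_min
    if pct_min is not None:
        keep &= 100.0 * eig / n_variables >= pct_min
    return [int(i) for i in np.flatnonzero(keep)]


def project(model: PCAModel, spectra: SpectraSet) -> np.ndarray:
    """Score new spectra with a fitted model (standardize, then rotate)."""
    if spectra.n_wavenumbers != model.n_variables or not np.allclose(
        spectra.grid.points, model.grid_points, rtol=1e-9, atol=1e-6
    ):
        raise GridMismatchError("spectra are not on the model's wavenumber grid")
    z = (spectra.values - model.column_means) / model.column_scales
    return z @ model.loadings


def eigen_table(model: PCAModel) -> pd.DataFrame:
    """Eigenvalue / explained % / cumulative % table for reporting."""
    return pd.DataFrame({
        "component": [f"PC{i + 1}" for i in range(model.n_components)],
        "eigenvalue": model.eigenvalues,
        "explained_pct": model.explained_pct,
        "cumulative_pct": np.cumsum(model.explained_pct),
    })
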