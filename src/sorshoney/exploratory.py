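"""Exploratory PCA of preprocessed spectra.

PCA is run on the SNV-normalised, replicate-averaged matrix with column
mean-centring only (rows are already standardised by SNV).  Component signs
follow a fixed convention — the largest-magnitude loading element of each
component is made positive — so scores and loadings are reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .spectra_io import SpectraSet


class PCAError(ValueError):
    pass


@dataclass
class PCAResult:
    """Scores, loadings (features x components), variance ratios, centre."""

    axis: np.ndarray
    scores: np.ndarray
    loadings: np.ndarray
    explained_variance_ratio: np.ndarray
    centre: np.ndarray


def pca_fit(sset: SpectraSet, n_components: int) -> PCAResult:
    """Column-mean-centred SVD of the intensity matrix.

    Deterministic: full SVD, with the sign of each component fixed so that
    its largest-|loading| element is positive.
    """
    X = sset.intensities
    n, p = X.shape
    if not 1 <= n_components <= min(n - 1, p):
        raise PCAError(f"n_components must be in [1, {min(n - 1, p)}], got {n_components}")
    centre = X.mean(axis=0)
    Xc = X - centre
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    loadings = Vt[:n_components].T  # p x k
    scores = Xc @ loadings
    total_var = np.sum(s**2)
    ratio = s[:n_components] ** 2 / total_var if total_var > 0 else np.zeros(n_components)
    for k in range(n_components):
        j = np.argmax(np.abs(loadings[:, k]))
        if loadings[j, k] < 0:
            loadings[:, k] *= -1
            scores[:, k] *= -1
    return PCAResult(sset.axis.copy(), scores, loadings, ratio, centre)


def top_loadings(result: PCAResult, n: int, components: tuple[int, ...] = (0, 1)) -> list[tuple[float, int, float]]:
    """Top-n axis points by max |loading| over the chosen components.

    Returns ``(wavenumber, component, loading)`` triples, descending by
    |loading|; ``component`` is the component achieving the max for that
    wavenumber.
    """
    if not components:
        raise PCAError("empty component set")
    if n > result.axis.size:
        raise PCAError(f"n ({n}) exceeds axis length ({result.axis.size})")
    comps = list(components)
    sub = result.loadings[:, comps]  # p x len(comps)
    best = np.argmax(np.abs(sub), axis=1)
    values = sub[np.arange(sub.shape[0]), best]
    order = np.argsort(-np.abs(values), kind="stable")[:n]
    return [(float(result.axis[i]), comps[best[i]], float(values[i])) for i in order]


def level_score_correlation(result: PCAResult, levels: np.ndarray, n_components: int | None = None) -> tuple[int, float]:
    """Spearman correlation between adulteration level and PC scores.

    Returns ``(component, rho)`` for the most level-discriminating component
    (largest |rho|) among the first ``n_components`` fitted ones.
    """
    levels = np.asarray(levels, dtype=float)
    k = result.scores.shape[1] if n_components is None else n_components
    best_comp, best_rho = 0, 0.0
    for comp in range(k):
        rho = stats.spearmanr(levels, result.scores[:, comp]).statistic
        if np.isfinite(rho) and abs(rho) > abs(best_rho):
            best_comp, best_rho = comp, float(rho)
    return best_comp, best_rho


def confidence_ellipse(scores_2d: np.ndarray, level: float = 0.95) -> tuple[np.ndarray, float, float, float]:
    """95% (by default) confidence ellipse of a 2-D score cloud.

    Returns ``(centre, width, height, angle_deg)`` — full axis lengths of the
    chi-square(2 df) quantile ellipse of the group covariance — suitable for
    matplotlib's Ellipse patch.
    """
    scores_2d = np.asarray(scores_2d, dtype=float)
    if scores_2d.ndim != 2 or scores_2d.shape[1] != 2 or scores_2d.shape[0] < 3:
        raise PCAError("need an n x 2 score matrix with n >= 3")
    centre = scores_2d.mean(axis=0)
    cov = np.cov(scores_2d, rowvar=False)
    eigval, eigvec = np.linalg.eigh(cov)
    q = stats.chi2.ppf(level, df=2)
    width, height = 2 * np.sqrt(q * eigval[1]), 2 * np.sqrt(q * eigval[0])
    angle = float(np.degrees(np.arctan2(eigvec[1, 1], eigvec[0, 1])))
    return centre, float(width), float(height), angle
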