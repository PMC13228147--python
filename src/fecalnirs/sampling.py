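"""Dataset structure tools: PCA scores, standardized Mahalanobis H screening,
Kennard-Stone subset selection and interleaved cross-validation folds."""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist

from .datasets import SpectraSet

__all__ = [
    "pca_scores",
    "mahalanobis_h",
    "screen_outliers",
    "kennard_stone",
    "interleaved_folds",
    "SplitResult",
    "OutlierReport",
]

log = logging.getLogger(__name__)


@dataclass
class SplitResult:
    """Disjoint calibration/validation id sets produced by a selection rule."""

    calibration_ids: np.ndarray
    validation_ids: np.ndarray
    method: str

    def __post_init__(self):
        if set(self.calibration_ids) & set(self.validation_ids):
            raise ValueError("calibration and validation ids overlap")


@dataclass
class OutlierReport:
    """Per-sample standardized Mahalanobis H against a calibration centroid."""

    sample_ids: np.ndarray
    h_values: np.ndarray
    threshold: float
    n_components: int

    @property
    def excluded_ids(self) -> np.ndarray:
        return self.sample_ids[self.h_values > self.threshold]

    @property
    def kept_ids(self) -> np.ndarray:
        return self.sample_ids[self.h_values <= self.threshold]


def pca_scores(X, variance_target: float = 0.99):
    """Centered PCA scores retaining the smallest component count whose
    cumulative explained variance reaches ``variance_target``.

    Returns ``(scores, explained_variance_ratio)`` where the ratio vector
    covers all non-trivial components (non-increasing, sums to <= 1).
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("need a 2-D matrix with at least 2 samples")
    Xc = X - X.mean(axis=0)
    if not np.any(np.abs(Xc) > 1e-14):
        raise ValueError("degenerate input: all rows identical (zero variance)")
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    var = s**2
    evr = var / var.sum()
    ncomp = int(np.searchsorted(np.cumsum(evr), variance_target - 1e-12) + 1)
    ncomp = min(ncomp, len(s))
    return U[:, :ncomp] * s[:ncomp], evr


def mahalanobis_h(scores_new, training_scores) -> np.ndarray | float:
    """Standardized Mahalanobis distance H = D^2 / p to the training centroid.

    ``D^2`` uses the training-score covariance (sample, n-1); dividing by the
    dimensionality ``p`` gives the convention in which the training-set mean H
    is ~1 for large n, so a fixed cutoff (H > 3) flags spectral outliers.
    """
    T = np.asarray(training_scores, dtype=float)
    if T.ndim != 2:
        raise ValueError("training_scores must be 2-D")
    p = T.shape[1]
    if p < 1:
        raise ValueError("need at least one score dimension")
    q = np.atleast_2d(np.asarray(scores_new, dtype=float))
    if q.shape[1] != p:
        raise ValueError("dimensionality mismatch between query and training scores")
    centroid = T.mean(axis=0)
    cov = np.cov(T, rowvar=False, ddof=1).reshape(p, p)
    try:
        cov_inv = np.linalg.inv(cov)
    except np.linalg.LinAlgError:
        raise ValueError(
            "singular training-score covariance; retain fewer components"
        ) from None
    d = q - centroid
    d2 = np.einsum("ij,jk,ik->i", d, cov_inv, d)
    h = d2 / p
    return float(h[0]) if np.asarray(scores_new).ndim == 1 else h


def screen_outliers(
    spectra: SpectraSet,
    reference_calibration: SpectraSet,
    threshold: float = 3.0,
    variance_target: float = 0.99,
) -> OutlierReport:
    """Flag samples spectrally dissimilar from a calibration set (H > threshold).

    Both sets must carry identically preprocessed spectra.  The score space is
    the calibration PCA retaining ``variance_target`` cumulative variance; each
    query sample is projected into it and its standardized H computed.
    """
    if not np.array_equal(spectra.wavelengths_nm, reference_calibration.wavelengths_nm):
        raise ValueError("query and calibration sets are on different wavelength grids")
    Xc = reference_calibration.absorbance
    center = Xc.mean(axis=0)
    scores_cal, evr = pca_scores(Xc, variance_target)
    ncomp = scores_cal.shape[1]
    _, _, Vt = np.linalg.svd(Xc - center, full_matrices=False)
    loadings = Vt[:ncomp].T
    scores_query = (spectra.absorbance - center) @ loadings
    h = mahalanobis_h(scores_query, scores_cal)
    report = OutlierReport(
        sample_ids=spectra.sample_ids,
        h_values=np.atleast_1d(h),
        threshold=threshold,
        n_components=ncomp,
    )
    n_out = len(report.excluded_ids)
    log.info(
        "H screening: %d of %d samples exceed H > %g (%d-component space)",
        n_out, spectra.n_samples, threshold, ncomp,
    )
    return report


def kennard_stone(X, n_select: int, ids=None, select: str = "validation") -> SplitResult:
    """Classic Kennard-Stone maximin selection (Euclidean distances).

    Starts from the two most mutually distant samples, then repeatedly adds
    the sample whose minimum distance to the selected set is largest; ties are
    broken by the lowest sample index.  By default the selected set becomes the
    *validation* subset and the remainder the calibration subset; pass
    ``select="calibration"`` for the conventional calibration-side use.
    """
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    if not 2 <= n_select <= n:
        raise ValueError(f"n_select must be in [2, {n}]")
    if select not in ("validation", "calibration"):
        raise ValueError("select must be 'validation' or 'calibration'")
    ids = np.arange(n) if ids is None else np.asarray(ids)
    D = cdist(X, X)
    # initial pair: maximum distance; np.argmax picks the row-major first
    # occurrence, i.e. the lowest index pair on ties
    i, j = np.unravel_index(np.argmax(D), D.shape)
    chosen = [min(i, j), max(i, j)]
    min_dist = np.minimum(D[chosen[0]], D[chosen[1]])
    while len(chosen) < n_select:
        min_dist[chosen] = -1.0
        nxt = int(np.argmax(min_dist))
        chosen.append(nxt)
        min_dist = np.minimum(min_dist, D[nxt])
    mask = np.zeros(n, dtype=bool)
    mask[chosen] = True
    selected, remainder = ids[mask], ids[~mask]
    if select == "validation":
        return SplitResult(remainder, selected, method="kennard-stone")
    return SplitResult(selected, remainder, method="kennard-stone")


def interleaved_folds(n: int, n_folds: int = 5) -> np.ndarray:
    """Venetian-blind fold assignment: fold(i) = i mod n_folds in row order."""
    if n < n_folds:
        raise ValueError(f"cannot split {n} samples into {n_folds} folds")
    if n_folds < 2:
        raise ValueError("need at least 2 folds")
    return np.arange(n) % n_folds
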