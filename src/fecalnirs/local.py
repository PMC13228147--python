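"""Locally weighted PLS calibration (LWPLSR, KNN-LWPLSR, KNN-LWPLSR-AGG).

For every sample to be predicted a dedicated weighted PLS model is fitted:

1. a preliminary global PLS defines a latent score space (its dimension equals
   the candidate ``nlv`` unless ``dist_nlv`` overrides it);
2. standardized distances from the target to every calibration sample are
   computed in that space (per-component scores scaled by the training score
   SDs, i.e. a diagonal Mahalanobis metric);
3. optionally only the ``k`` nearest calibration samples are kept
   (KNN variants; ties broken by lower row index);
4. the retained samples receive negative-exponential weights
   ``w_i = exp(-d_i / (h * median(d)))`` — ``h`` tunes sharp (0.5) to flat
   (infinite, i.e. the global model) weighting, and weights below ``1e-4`` of
   the maximum are truncated to zero;
5. a weighted PLS with ``nlv`` components is fitted and the target predicted.

The AGG variant averages KNN-LWPLSR predictions over a range of component
counts, re-selecting neighbors and weights in each count's own score space.

Everything is exposed both as model classes (``LWPLSR(y, X, h=...).fit()``)
and as the functional wrappers ``lwplsr_predict`` / ``knn_lwplsr_predict`` /
``knn_lwplsr_agg_predict``.  :func:`cross_validate` runs the interleaved
five-fold grid search used for hyperparameter tuning.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .pls import PLS
from .sampling import interleaved_folds

__all__ = [
    "local_weights",
    "lwplsr_predict",
    "knn_lwplsr_predict",
    "knn_lwplsr_agg_predict",
    "LocalModelSpec",
    "TuningGrid",
    "TuningResult",
    "cross_validate",
    "LWPLSR",
    "KNNLWPLSR",
    "KNNLWPLSRAgg",
    "LocalPLSResults",
]

log = logging.getLogger(__name__)

METHODS = ("PLS", "LWPLSR", "KNN-LWPLSR", "KNN-LWPLSR-AGG")
_TRUNC = 1e-4


def local_weights(distances, h) -> np.ndarray:
    """Negative-exponential weights from distances; ``h = inf`` gives all 1."""
    d = np.asarray(distances, dtype=float)
    if d.size == 0:
        raise ValueError("need at least one distance")
    if np.any(d < 0):
        raise ValueError("distances must be non-negative")
    if h <= 0:
        raise ValueError("h must be positive")
    if math.isinf(h):
        return np.ones_like(d)
    scale = float(np.median(d))
    if scale <= 0:
        scale = float(np.mean(d))
    if scale <= 0:
        return np.ones_like(d)
    w = np.exp(-d / (h * scale))
    w[w < _TRUNC * w.max()] = 0.0
    return w


# ---------------------------------------------------------------------------
# prediction engine


def _local_predict_matrix(Xcal, ycal, Xnew, h, k, nlv_list, dist_nlv=None):
    """Predictions for every target at every requested component count.

    Returns an array of shape ``(n_new, len(nlv_list))``.  The preliminary
    global PLS is fitted once at the largest needed dimension; its components
    are nested, so each candidate ``nlv`` slices the same score space, and the
    cumulative squared standardized score differences give every dimension's
    distances in one pass.
    """
    Xcal = np.asarray(Xcal, dtype=float)
    ycal = np.asarray(ycal, dtype=float).ravel()
    Xnew = np.atleast_2d(np.asarray(Xnew, dtype=float))
    n = Xcal.shape[0]
    nlv_list = list(nlv_list)
    if k is not None:
        if k < 2:
            raise ValueError("k must be at least 2")
        if k > n:
            raise ValueError(f"k={k} exceeds the calibration size {n}")
    if Xcal.shape[1] > n:
        # PLS predictions and scores are invariant under an orthonormal change
        # of the spectral basis, and every fitted coefficient vector lies in
        # the span of the calibration rows; working in that span (rank <= n)
        # gives identical results at a fraction of the cost
        _, _, Vt = np.linalg.svd(Xcal, full_matrices=False)
        Xcal = Xcal @ Vt.T
        Xnew = Xnew @ Vt.T
    a_max = max(nlv_list + ([dist_nlv] if dist_nlv else []))
    prelim = PLS(ycal, Xcal).fit(a_max)
    T = prelim.training_scores
    sds = np.where(prelim.score_sds > 0, prelim.score_sds, 1.0)
    Tn = prelim.scores(Xnew, nlv=a_max)
    out = np.empty((Xnew.shape[0], len(nlv_list)))
    for i in range(Xnew.shape[0]):
        diff2 = ((T - Tn[i]) / sds) ** 2
        d2cum = np.cumsum(diff2, axis=1)
        for j, a in enumerate(nlv_list):
            dim = dist_nlv if dist_nlv else a
            d = np.sqrt(d2cum[:, dim - 1])
            if k is not None and k < n:
                # stable sort => ties keep the lower calibration index
                neigh = np.sort(np.argsort(d, kind="stable")[:k])
            else:
                neigh = slice(None)
            w = local_weights(d[neigh], h)
            nz = w > 0
            if np.count_nonzero(nz) < 2:
                raise ValueError(
                    "fewer than 2 calibration samples received nonzero weight; "
                    "increase h (flatter weighting) or k"
                )
            Xs = Xcal[neigh][nz]
            ys = ycal[neigh][nz]
            ws = w[nz]
            a_eff = min(a, np.count_nonzero(nz) - 1, Xs.shape[1])
            res = PLS(ys, Xs, weights=ws).fit(a_eff)
            out[i, j] = res.predict(Xnew[i][None, :])[0]
    return out


def lwplsr_predict(Xcal, ycal, Xnew, h, nlv) -> np.ndarray:
    """Locally weighted PLS prediction using the whole calibration set."""
    return _local_predict_matrix(Xcal, ycal, Xnew, h, None, [nlv])[:, 0]


def knn_lwplsr_predict(Xcal, ycal, Xnew, h, k, nlv) -> np.ndarray:
    """LWPLSR restricted to each target's k nearest calibration samples."""
    return _local_predict_matrix(Xcal, ycal, Xnew, h, k, [nlv])[:, 0]


def knn_lwplsr_agg_predict(Xcal, ycal, Xnew, h, k, nlv_min, nlv_max) -> np.ndarray:
    """Average of KNN-LWPLSR predictions over nlv in [nlv_min, nlv_max]."""
    if nlv_min > nlv_max:
        raise ValueError("nlv_min must not exceed nlv_max")
    nlvs = list(range(nlv_min, nlv_max + 1))
    preds = _local_predict_matrix(Xcal, ycal, Xnew, h, k, nlvs)
    return preds.mean(axis=1)


# ---------------------------------------------------------------------------
# model / results classes


class _LocalBase:
    """Shared lazy-learner plumbing for the locally weighted variants."""

    method = "LWPLSR"

    def __init__(self, endog, exog, h=2.0, nlv=6, k=None, dist_nlv=None):
        self.endog = np.asarray(endog, dtype=float).ravel()
        self.exog = np.asarray(exog, dtype=float)
        if self.exog.shape[0] != len(self.endog):
            raise ValueError("endog/exog length mismatch")
        if h <= 0:
            raise ValueError("h must be positive")
        self.h = float(h)
        self.nlv = int(nlv)
        self.k = None if k is None else int(k)
        self.dist_nlv = dist_nlv

    def fit(self) -> "LocalPLSResults":
        return LocalPLSResults(self)

    def _predict(self, Xnew) -> np.ndarray:
        return _local_predict_matrix(
            self.exog, self.endog, Xnew, self.h, self.k, [self.nlv], self.dist_nlv
        )[:, 0]


class LWPLSR(_LocalBase):
    """Locally weighted PLS regression over the full calibration set."""

    method = "LWPLSR"

    def __init__(self, endog, exog, h=2.0, nlv=6, dist_nlv=None):
        super().__init__(endog, exog, h=h, nlv=nlv, k=None, dist_nlv=dist_nlv)


class KNNLWPLSR(_LocalBase):
    """Locally weighted PLS restricted to the k nearest calibration spectra."""

    method = "KNN-LWPLSR"

    def __init__(self, endog, exog, h=2.0, k=100, nlv=6, dist_nlv=None):
        super().__init__(endog, exog, h=h, nlv=nlv, k=k, dist_nlv=dist_nlv)


class KNNLWPLSRAgg(_LocalBase):
    """KNN-LWPLSR averaged over a range of latent-variable counts."""

    method = "KNN-LWPLSR-AGG"

    def __init__(self, endog, exog, h=2.0, k=100, nlv_min=1, nlv_max=15, dist_nlv=None):
        if nlv_min > nlv_max:
            raise ValueError("nlv_min must not exceed nlv_max")
        super().__init__(endog, exog, h=h, nlv=nlv_max, k=k, dist_nlv=dist_nlv)
        self.nlv_min = int(nlv_min)
        self.nlv_max = int(nlv_max)

    def _predict(self, Xnew) -> np.ndarray:
        return knn_lwplsr_agg_predict(
            self.exog, self.endog, Xnew, self.h, self.k, self.nlv_min, self.nlv_max
        )


class LocalPLSResults:
    """Results facade for the lazy local learners: prediction + settings."""

    def __init__(self, model: _LocalBase):
        self.model = model

    def predict(self, exog) -> np.ndarray:
        return self.model._predict(exog)

    def summary(self) -> str:
        m = self.model
        rows = [
            f"{m.method} local calibration",
            "=" * 42,
            f"{'calibration samples':<26}{m.exog.shape[0]:>16}",
            f"{'spectral channels':<26}{m.exog.shape[1]:>16}",
            f"{'weight shape h':<26}{m.h:>16g}",
        ]
        if m.k is not None:
            rows.append(f"{'neighbors k':<26}{m.k:>16}")
        if isinstance(m, KNNLWPLSRAgg):
            rows.append(f"{'nlv range':<26}{f'{m.nlv_min}-{m.nlv_max}':>16}")
        else:
            rows.append(f"{'latent variables':<26}{m.nlv:>16}")
        return "\n".join(rows)


# ---------------------------------------------------------------------------
# hyperparameter grids and cross-validation


@dataclass(frozen=True)
class LocalModelSpec:
    """One tuning point: method plus its hyperparameters."""

    method: str
    h: float = math.inf
    k: int | None = None
    nlv: int | None = None
    nlv_min: int | None = None
    nlv_max: int | None = None

    def __post_init__(self):
        if self.method not in METHODS:
            raise ValueError(f"unknown method {self.method!r}")
        if self.h <= 0:
            raise ValueError("h must be positive")
        if self.method == "KNN-LWPLSR-AGG":
            if self.nlv_min is None or self.nlv_max is None:
                raise ValueError("AGG requires nlv_min and nlv_max")
            if self.nlv_min > self.nlv_max:
                raise ValueError("nlv_min must not exceed nlv_max")
        elif self.nlv is None:
            raise ValueError(f"{self.method} requires nlv")

    @property
    def nlv_span(self) -> int:
        if self.method == "KNN-LWPLSR-AGG":
            return self.nlv_max - self.nlv_min
        return 0

    def sort_key(self, rmsecv: float):
        """RMSECV-first ordering with the documented tie-break: fewer latent
        variables, then smaller k, then smaller h, then narrower nlv range."""
        nlv_eff = self.nlv_max if self.method == "KNN-LWPLSR-AGG" else self.nlv
        return (
            round(rmsecv, 12),
            nlv_eff,
            self.k if self.k is not None else np.inf,
            self.h,
            self.nlv_span,
        )


@dataclass
class TuningGrid:
    """Per-method hyperparameter candidates.

    :meth:`full` holds the complete grids; :meth:`reduced` is the
    package's desk-scale default profile.
    """

    pls_nlv: list = field(default_factory=lambda: list(range(1, 31)))
    lw_h: list = field(default_factory=lambda: [0.5, 1, 2, 3, 4, 5, 6])
    lw_nlv: list = field(default_factory=lambda: list(range(1, 31)))
    knn_h: list = field(default_factory=lambda: [0.5, 1, 2, 3, 4, 5, 6, math.inf])
    knn_k: list = field(default_factory=lambda: [50, 100, 150, 200, 250])
    knn_nlv: list = field(default_factory=lambda: list(range(1, 31)))
    agg_nlv_min: list = field(default_factory=lambda: [1, 2, 3, 4, 5])
    agg_nlv_max: list = field(default_factory=lambda: [15, 20, 25, 30])

    @classmethod
    def full(cls) -> "TuningGrid":
        return cls()

    @classmethod
    def tiny(cls, nlv_max: int = 4, k: int = 40) -> "TuningGrid":
        """Minimal grid for smoke runs and small synthetic datasets."""
        nlvs = list(range(1, nlv_max + 1))
        return cls(
            pls_nlv=nlvs,
            lw_h=[0.5, 2],
            lw_nlv=nlvs,
            knn_h=[0.5, 2],
            knn_k=[k],
            knn_nlv=nlvs,
            agg_nlv_min=[1],
            agg_nlv_max=[nlv_max],
        )

    @classmethod
    def reduced(cls, nlv_max: int = 15) -> "TuningGrid":
        nlvs = list(range(1, nlv_max + 1))
        return cls(
            pls_nlv=nlvs,
            lw_h=[0.5, 2, 6],
            lw_nlv=nlvs,
            knn_h=[0.5, 2, 6],
            knn_k=[100, 200],
            knn_nlv=nlvs,
            agg_nlv_min=[1],
            agg_nlv_max=[nlv_max],
        )

    def specs(self, method: str, n_cal: int | None = None) -> list[LocalModelSpec]:
        """Expand the grid for one method, dropping infeasible k with a note."""
        if method == "PLS":
            return [LocalModelSpec("PLS", h=math.inf, nlv=a) for a in self.pls_nlv]
        if method == "LWPLSR":
            return [
                LocalModelSpec("LWPLSR", h=h, nlv=a)
                for h in self.lw_h
                for a in self.lw_nlv
            ]
        ks = list(self.knn_k)
        if n_cal is not None:
            feasible = [k for k in ks if k <= n_cal]
            dropped = sorted(set(ks) - set(feasible))
            if dropped:
                log.info("dropping k candidates %s (> %d available samples)", dropped, n_cal)
            ks = feasible
        if not ks:
            raise ValueError("no feasible k candidates for the calibration size")
        if method == "KNN-LWPLSR":
            return [
                LocalModelSpec("KNN-LWPLSR", h=h, k=k, nlv=a)
                for h in self.knn_h
                for k in ks
                for a in self.knn_nlv
            ]
        if method == "KNN-LWPLSR-AGG":
            return [
                LocalModelSpec("KNN-LWPLSR-AGG", h=h, k=k, nlv_min=lo, nlv_max=hi)
                for h in self.knn_h
                for k in ks
                for lo in self.agg_nlv_min
                for hi in self.agg_nlv_max
            ]
        raise ValueError(f"unknown method {method!r}")


@dataclass
class TuningResult:
    """Cross-validation table plus the selected tuning point."""

    table: pd.DataFrame
    selected: LocalModelSpec
    selection_rule: str = "min RMSECV; ties -> fewer nlv, smaller k, smaller h, narrower range"

    @property
    def selected_rmsecv(self) -> float:
        return float(self.table.loc[self.table["selected"], "rmsecv"].iloc[0])

    @property
    def selected_r2cv(self) -> float:
        return float(self.table.loc[self.table["selected"], "r2cv"].iloc[0])


def _oof_predictions(specs, X, y, folds, n_folds):
    """Pooled out-of-fold predictions for every spec, sharing fold-level work."""
    n = len(y)
    preds = {s: np.empty(n) for s in specs}
    # organize specs so each (method, h, k) family shares one engine call
    families: dict[tuple, list[LocalModelSpec]] = {}
    for s in specs:
        key = (s.method, s.h, s.k)
        families.setdefault(key, []).append(s)
    for f in range(n_folds):
        test = folds == f
        train = ~test
        Xtr, ytr, Xte = X[train], y[train], X[test]
        for (method, h, k), members in families.items():
            if method == "PLS":
                a_max = max(s.nlv for s in members)
                res = PLS(ytr, Xtr).fit(min(a_max, len(ytr) - 1, X.shape[1]))
                for s in members:
                    a = min(s.nlv, res.nlv)
                    preds[s][test] = res.predict(Xte, nlv=a)
                continue
            k_eff = None if k is None else min(k, len(ytr))
            if method == "KNN-LWPLSR-AGG":
                nlvs = sorted({a for s in members for a in range(s.nlv_min, s.nlv_max + 1)})
                mat = _local_predict_matrix(Xtr, ytr, Xte, h, k_eff, nlvs)
                col = {a: j for j, a in enumerate(nlvs)}
                for s in members:
                    cols = [col[a] for a in range(s.nlv_min, s.nlv_max + 1)]
                    preds[s][test] = mat[:, cols].mean(axis=1)
            else:
                nlvs = sorted({s.nlv for s in members})
                mat = _local_predict_matrix(Xtr, ytr, Xte, h, k_eff, nlvs)
                col = {a: j for j, a in enumerate(nlvs)}
                for s in members:
                    preds[s][test] = mat[:, col[s.nlv]]
    return preds


def cross_validate(spec_grid, X, y, n_folds: int = 5) -> TuningResult:
    """Interleaved k-fold grid search; selects the minimum-RMSECV tuning point.

    ``spec_grid`` is a sequence of :class:`LocalModelSpec` (use
    :meth:`TuningGrid.specs` to expand a grid).  RMSECV and R2CV are computed
    on the pooled out-of-fold predictions.
    """
    specs = list(spec_grid)
    if not specs:
        raise ValueError("empty tuning grid")
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    folds = interleaved_folds(len(y), n_folds)
    # guard: largest k must survive fold removal
    n_min_train = min(int(np.sum(folds != f)) for f in range(n_folds))
    usable, skipped = [], []
    for s in specs:
        if s.k is not None and s.k > n_min_train:
            skipped.append(s)
        else:
            usable.append(s)
    if skipped:
        log.info("skipping %d grid points whose k exceeds the smallest training fold", len(skipped))
    if not usable:
        raise ValueError("no grid point is feasible for this calibration size")
    preds = _oof_predictions(usable, X, y, folds, n_folds)
    sst = float(np.sum((y - y.mean()) ** 2))
    rows = []
    for s in usable:
        e = preds[s] - y
        rmsecv = float(np.sqrt(np.mean(e**2)))
        r2cv = 1.0 - float(np.sum(e**2)) / sst
        rows.append((s, rmsecv, r2cv))
    best = min(rows, key=lambda r: r[0].sort_key(r[1]))[0]
    table = pd.DataFrame(
        {
            "method": [s.method for s, _, _ in rows],
            "h": [s.h for s, _, _ in rows],
            "k": [s.k for s, _, _ in rows],
            "nlv": [s.nlv for s, _, _ in rows],
            "nlv_min": [s.nlv_min for s, _, _ in rows],
            "nlv_max": [s.nlv_max for s, _, _ in rows],
            "rmsecv": [r for _, r, _ in rows],
            "r2cv": [r2 for _, _, r2 in rows],
            "selected": [s == best for s, _, _ in rows],
        }
    )
    return TuningResult(table=table, selected=best)


def predictor_for(spec: LocalModelSpec, Xcal, ycal):
    """Build the fitted model implied by a spec; returns an object with
    ``predict(Xnew)``."""
    ycal = np.asarray(ycal, dtype=float).ravel()
    Xcal = np.asarray(Xcal, dtype=float)
    if spec.method == "PLS":
        return PLS(ycal, Xcal).fit(spec.nlv)
    if spec.method == "LWPLSR":
        return LWPLSR(ycal, Xcal, h=spec.h, nlv=spec.nlv).fit()
    if spec.method == "KNN-LWPLSR":
        k = min(spec.k, Xcal.shape[0]) if spec.k is not None else None
        return KNNLWPLSR(ycal, Xcal, h=spec.h, k=k, nlv=spec.nlv).fit()
    k = min(spec.k, Xcal.shape[0]) if spec.k is not None else None
    return KNNLWPLSRAgg(
        ycal, Xcal, h=spec.h, k=k, nlv_min=spec.nlv_min, nlv_max=spec.nlv_max
    ).fit()
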