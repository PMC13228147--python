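"""PLS1 regression with optional observation weights.

The model is univariate-response partial least squares fitted by NIPALS-style
sequential score extraction on mean-centered data (no variance scaling, the
NIRS convention).  Components are nested: a model fitted with ``nlv``
components can predict with any smaller number.  Observation weights enter the
centering means and every cross-product, which is what the locally weighted
variants in :mod:`fecalnirs.local` build on; uniform weights reproduce the
ordinary fit exactly, and zero-weight samples drop out exactly.

Usage follows the model/results idiom::

    res = PLS(y, X).fit(nlv=10)
    yhat = res.predict(X_new)          # at the fitted component count
    yhat5 = res.predict(X_new, nlv=5)  # any nested count
"""

from __future__ import annotations

import numpy as np

__all__ = ["PLS", "PLSResults", "fit_pls", "predict_pls"]

_EPS = 1e-12


class PLS:
    """PLS1 model specification: response ``endog`` (n,), predictors ``exog``
    (n, p), optional non-negative ``weights`` (normalized internally)."""

    def __init__(self, endog, exog, weights=None):
        self.endog = np.asarray(endog, dtype=float).ravel()
        self.exog = np.asarray(exog, dtype=float)
        if self.exog.ndim != 2:
            raise ValueError("exog must be 2-D")
        n = self.exog.shape[0]
        if len(self.endog) != n:
            raise ValueError("endog/exog length mismatch")
        if n < 2:
            raise ValueError("need at least 2 samples")
        if weights is None:
            self.weights = np.full(n, 1.0 / n)
        else:
            w = np.asarray(weights, dtype=float)
            if w.shape != (n,):
                raise ValueError("weights must be one per sample")
            if np.any(w < 0):
                raise ValueError("weights must be non-negative")
            tot = w.sum()
            if tot <= 0:
                raise ValueError("weights sum to zero")
            self.weights = w / tot

    def fit(self, nlv: int) -> "PLSResults":
        """Extract ``nlv`` latent variables and return a results object."""
        y, X, w = self.endog, self.exog, self.weights
        n, p = X.shape
        n_eff = int(np.count_nonzero(w))
        max_nlv = min(n_eff - 1, p)
        if not 1 <= nlv <= max_nlv:
            raise ValueError(
                f"nlv={nlv} infeasible: must be in [1, {max_nlv}] for "
                f"{n_eff} (weighted) samples and {p} variables"
            )
        x_mean = w @ X
        y_mean = float(w @ y)
        Xc = X - x_mean
        yc = y - y_mean
        W = np.zeros((p, nlv))
        P = np.zeros((p, nlv))
        q = np.zeros(nlv)
        T = np.zeros((n, nlv))
        rank = nlv
        for a in range(nlv):
            wa = Xc.T @ (w * yc)
            nrm = np.linalg.norm(wa)
            if nrm <= _EPS:
                # y-residual orthogonal to remaining X variation (e.g. constant
                # y, or X exhausted): later components are null
                rank = a
                break
            wa /= nrm
            t = Xc @ wa
            tt = float(w @ (t * t))
            if tt <= _EPS**2:
                rank = a
                break
            pa = (Xc.T @ (w * t)) / tt
            qa = float((w * yc) @ t) / tt
            Xc -= np.outer(t, pa)
            yc = yc - qa * t
            W[:, a], P[:, a], q[a], T[:, a] = wa, pa, qa, t
        if rank == 0:
            R = np.zeros((p, nlv))
            coefs = np.zeros((p, nlv))
        else:
            PtW = P[:, :rank].T @ W[:, :rank]
            R = np.zeros((p, nlv))
            R[:, :rank] = W[:, :rank] @ np.linalg.inv(PtW)
            coefs = np.cumsum(R * q, axis=1)
        score_sds = np.sqrt(np.clip(w @ (T * T), 0.0, None))
        return PLSResults(
            model=self,
            nlv=nlv,
            effective_rank=rank,
            x_mean=x_mean,
            y_mean=y_mean,
            x_weights=W,
            x_loadings=P,
            y_loadings=q,
            projection=R,
            coefs_by_nlv=coefs,
            training_scores=T,
            score_sds=score_sds,
        )


class PLSResults:
    """Fitted PLS1 model: coefficients per nested component count, training
    scores and their SDs (used for standardized distances downstream)."""

    def __init__(self, model, nlv, effective_rank, x_mean, y_mean, x_weights,
                 x_loadings, y_loadings, projection, coefs_by_nlv,
                 training_scores, score_sds):
        self.model = model
        self.nlv = nlv
        self.effective_rank = effective_rank
        self.x_mean = x_mean
        self.y_mean = y_mean
        self.x_weights = x_weights
        self.x_loadings = x_loadings
        self.y_loadings = y_loadings
        self.projection = projection  # R = W (P'W)^-1 ; scores = Xc @ R
        self.coefs_by_nlv = coefs_by_nlv
        self.training_scores = training_scores
        self.score_sds = score_sds

    @property
    def params(self) -> np.ndarray:
        """Regression coefficients at the fitted component count."""
        return self.coefs_by_nlv[:, self.nlv - 1]

    @property
    def intercept(self) -> float:
        return self.y_mean - float(self.x_mean @ self.params)

    @property
    def fittedvalues(self) -> np.ndarray:
        return self.predict(self.model.exog)

    @property
    def resid(self) -> np.ndarray:
        return self.fittedvalues - self.model.endog

    @property
    def rmsec(self) -> float:
        """Root mean square error of calibration (training fit, n denominator)."""
        return float(np.sqrt(np.mean(self.resid**2)))

    def coefficients(self, nlv: int | None = None) -> np.ndarray:
        nlv = self.nlv if nlv is None else nlv
        if not 1 <= nlv <= self.nlv:
            raise ValueError(f"nlv must be in [1, {self.nlv}]")
        return self.coefs_by_nlv[:, nlv - 1]

    def predict(self, exog, nlv: int | None = None) -> np.ndarray:
        X = np.atleast_2d(np.asarray(exog, dtype=float))
        if X.shape[1] != len(self.x_mean):
            raise ValueError(
                f"exog has {X.shape[1]} columns, model was trained with {len(self.x_mean)}"
            )
        b = self.coefficients(nlv)
        return self.y_mean + (X - self.x_mean) @ b

    def scores(self, exog, nlv: int | None = None) -> np.ndarray:
        """Latent-variable scores of new samples in the training score space."""
        nlv = self.nlv if nlv is None else nlv
        X = np.atleast_2d(np.asarray(exog, dtype=float))
        return (X - self.x_mean) @ self.projection[:, :nlv]

    def summary(self) -> str:
        lines = [
            "PLS1 regression results",
            "=" * 46,
            f"{'n samples':<28}{self.model.exog.shape[0]:>18}",
            f"{'n predictors':<28}{self.model.exog.shape[1]:>18}",
            f"{'latent variables (nlv)':<28}{self.nlv:>18}",
            f"{'effective rank':<28}{self.effective_rank:>18}",
            f"{'y mean':<28}{self.y_mean:>18.5f}",
            f"{'RMSEC':<28}{self.rmsec:>18.5f}",
            "-" * 46,
            f"{'component':<12}{'score SD':>16}{'y loading':>18}",
        ]
        for a in range(self.nlv):
            lines.append(
                f"{a + 1:<12}{self.score_sds[a]:>16.5g}{self.y_loadings[a]:>18.5g}"
            )
        return "\n".join(lines)


def fit_pls(X, y, nlv: int, weights=None) -> PLSResults:
    """Functional wrapper: ``PLS(y, X, weights).fit(nlv)``."""
    return PLS(y, X, weights=weights).fit(nlv)


def predict_pls(results: PLSResults, X_new, nlv: int | None = None) -> np.ndarray:
    """Functional wrapper around :meth:`PLSResults.predict`."""
    return results.predict(X_new, nlv=nlv)
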