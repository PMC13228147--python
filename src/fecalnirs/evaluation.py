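"""Prediction metrics, paired model comparison, prediction intervals and the
two-means power analysis.

Conventions: errors are ``predicted - observed``; RMSEP uses the n
denominator; the bias-corrected error RMSEP(C) (the SEP) uses n-1, so that
``n * RMSEP^2 = n * bias^2 + (n-1) * RMSEP(C)^2`` holds exactly.  R2 is
``1 - SSE/SST`` (penalizes bias), not a squared correlation.  The paired model
comparison follows the classic two-part scheme: a paired t-test on the error
difference for bias, and the Pitman-Morgan correlated-variances test for the
SEP ratio.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "EvaluationReport",
    "evaluate",
    "prediction_interval",
    "minimum_detectable_difference",
    "ComparisonResult",
    "compare_models",
    "compact_letter_display",
    "PowerQuery",
    "animals_required",
    "REFERENCE_METHOD_SE",
]

#: Standard error of the in vivo reference digestibility method (g/g),
#: the floor below which no spectral prediction error can fall.
REFERENCE_METHOD_SE = 0.0135


@dataclass
class EvaluationReport:
    """Prediction statistics for one model on one sample set (all g/g except
    percentages and R2)."""

    label: str
    n: int
    rmsep: float
    rmsep_pct: float
    bias: float
    rmsep_c: float
    r2: float
    ip: float  # +/- half-width of the 95% individual prediction interval

    def to_row(self) -> dict:
        return {
            "model": self.label,
            "RMSEP": self.rmsep,
            "RMSEP%": self.rmsep_pct,
            "Bias": self.bias,
            "RMSEP(C)": self.rmsep_c,
            "R2P": self.r2,
            "IP": self.ip,
        }

    def summary(self) -> str:
        return (
            f"{self.label}: n={self.n}  RMSEP={self.rmsep:.4f} g/g "
            f"({self.rmsep_pct:.2f}%)  bias={self.bias:+.4f}  "
            f"RMSEP(C)={self.rmsep_c:.4f}  R2={self.r2:.3f}  IP=±{self.ip:.3f}"
        )


def evaluate(predicted, observed, label: str = "model") -> EvaluationReport:
    """Standard chemometric prediction statistics for one model."""
    p = np.asarray(predicted, dtype=float).ravel()
    o = np.asarray(observed, dtype=float).ravel()
    if p.shape != o.shape:
        raise ValueError("predicted and observed lengths differ")
    n = len(p)
    if n < 2:
        raise ValueError("need at least 2 samples")
    e = p - o
    rmsep = float(np.sqrt(np.mean(e**2)))
    bias = float(np.mean(e))
    rmsep_c = float(np.sqrt(np.sum((e - bias) ** 2) / (n - 1)))
    sst = float(np.sum((o - o.mean()) ** 2))
    r2 = 1.0 - float(np.sum(e**2)) / sst if sst > 0 else float("nan")
    return EvaluationReport(
        label=label,
        n=n,
        rmsep=rmsep,
        rmsep_pct=100.0 * rmsep / float(np.mean(o)),
        bias=bias,
        rmsep_c=rmsep_c,
        r2=r2,
        ip=prediction_interval(rmsep),
    )


def prediction_interval(rmse: float) -> float:
    """95% half-width (+/-) of an individual prediction: 1.96 x RMSE."""
    if rmse < 0:
        raise ValueError("rmse must be non-negative")
    return 1.96 * rmse


def minimum_detectable_difference(rmse: float) -> float:
    """Smallest difference between two values resolvable at 95%: 2 x 1.96 x RMSE."""
    if rmse < 0:
        raise ValueError("rmse must be non-negative")
    return 2.0 * 1.96 * rmse


# ---------------------------------------------------------------------------
# paired model comparison (bias t-test + Pitman-Morgan SEP ratio)


@dataclass
class ComparisonResult:
    """Paired comparison of two models' prediction errors on the same samples."""

    label_a: str
    label_b: str
    n: int
    bias_difference: float
    bias_t: float
    bias_df: int
    bias_p: float
    bias_ci: tuple[float, float]
    sd_ratio: float
    sep_t: float
    sep_df: int
    sep_p: float
    sep_ci: tuple[float, float]
    exactly_offset: bool = False

    def summary(self) -> str:
        return (
            f"{self.label_a} vs {self.label_b} (n={self.n}): "
            f"bias diff {self.bias_difference:+.4f} g/g "
            f"(t={self.bias_t:.2f}, p={self.bias_p:.3f}); "
            f"SEP ratio {self.sd_ratio:.3f} "
            f"(Pitman-Morgan t={self.sep_t:.2f}, p={self.sep_p:.3f})"
        )


def _pitman_ci(ea_c, eb_c, alpha):
    """Invert the Pitman-Morgan test for a CI on sigma_a / sigma_b.

    cov(e_a + lam*e_b, e_a - lam*e_b) = var_a - lam^2 var_b vanishes exactly at
    lam = sigma_a/sigma_b, so the CI is the set of lam whose correlation-based
    t statistic stays below the critical value.
    """
    n = len(ea_c)
    tcrit = stats.t.ppf(1 - alpha / 2, n - 2)
    rcrit = tcrit / math.sqrt(n - 2 + tcrit**2)
    ratio = np.std(ea_c, ddof=1) / np.std(eb_c, ddof=1)

    def corr_at(lam):
        u = ea_c + lam * eb_c
        v = ea_c - lam * eb_c
        su, sv = np.std(u, ddof=1), np.std(v, ddof=1)
        if su <= 0 or sv <= 0:
            return 0.0
        return float(np.corrcoef(u, v)[0, 1])

    lo_bracket, hi_bracket = ratio * 1e-6, ratio * 1e6
    try:
        lower = optimize.brentq(lambda l: corr_at(l) - rcrit, lo_bracket, ratio)
    except ValueError:
        lower = 0.0
    try:
        upper = optimize.brentq(lambda l: corr_at(l) + rcrit, ratio, hi_bracket)
    except ValueError:
        upper = math.inf
    return lower, upper


def compare_models(
    errors_a,
    errors_b,
    label_a: str = "A",
    label_b: str = "B",
    alpha: float = 0.05,
) -> ComparisonResult:
    """Fearn-style paired comparison of two prediction-error vectors.

    Bias: paired t-test on the elementwise error difference with a
    ``1 - alpha`` CI.  Precision: Pitman-Morgan correlated-variances test on
    the bias-centered errors (t on the correlation of their sum and
    difference), with a CI for the SD ratio.
    """
    ea = np.asarray(errors_a, dtype=float).ravel()
    eb = np.asarray(errors_b, dtype=float).ravel()
    if ea.shape != eb.shape:
        raise ValueError("error vectors must be paired (same samples, same order)")
    n = len(ea)
    if n < 3:
        raise ValueError("need at least 3 paired errors")
    sa, sb = np.std(ea, ddof=1), np.std(eb, ddof=1)
    if sa <= 0 and sb <= 0:
        raise ValueError("both error vectors have zero variance")

    delta = ea - eb
    bias_diff = float(np.mean(delta))
    sd_delta = float(np.std(delta, ddof=1))
    df = n - 1
    tcrit = stats.t.ppf(1 - alpha / 2, df)
    exactly_offset = False
    if sd_delta <= 1e-14 * max(1.0, float(np.max(np.abs(delta), initial=0.0))):
        # the two models differ by a constant: no sampling variation to test
        if abs(bias_diff) <= 1e-14:
            bias_t, bias_p = 0.0, 1.0
        else:
            bias_t, bias_p = math.nan, math.nan
            exactly_offset = True
        bias_ci = (bias_diff, bias_diff)
    else:
        se = sd_delta / math.sqrt(n)
        bias_t = bias_diff / se
        bias_p = float(2 * stats.t.sf(abs(bias_t), df))
        bias_ci = (bias_diff - tcrit * se, bias_diff + tcrit * se)

    ea_c = ea - ea.mean()
    eb_c = eb - eb.mean()
    sep_df = n - 2
    if sa <= 0 or sb <= 0:
        raise ValueError("one error vector has zero variance; SEP ratio undefined")
    sd_ratio = float(sa / sb)
    u = ea_c + eb_c
    v = ea_c - eb_c
    su, sv = np.std(u, ddof=1), np.std(v, ddof=1)
    if su <= 0 or sv <= 0:
        # identical centered errors: ratio exactly 1, no evidence against it
        sep_t, sep_p = 0.0, 1.0
        sep_ci = (1.0, 1.0)
    else:
        r = float(np.corrcoef(u, v)[0, 1])
        r = max(min(r, 1.0), -1.0)
        if abs(r) >= 1.0:
            sep_t, sep_p = math.inf * np.sign(r), 0.0
        else:
            sep_t = r * math.sqrt(sep_df) / math.sqrt(1 - r**2)
            sep_p = float(2 * stats.t.sf(abs(sep_t), sep_df))
        sep_ci = _pitman_ci(ea_c, eb_c, alpha)

    return ComparisonResult(
        label_a=label_a,
        label_b=label_b,
        n=n,
        bias_difference=bias_diff,
        bias_t=float(bias_t),
        bias_df=df,
        bias_p=float(bias_p),
        bias_ci=bias_ci,
        sd_ratio=sd_ratio,
        sep_t=float(sep_t),
        sep_df=sep_df,
        sep_p=float(sep_p),
        sep_ci=sep_ci,
        exactly_offset=exactly_offset,
    )


def compact_letter_display(labels, p_values: dict, alpha: float = 0.05,
                           order=None) -> dict:
    """Assign significance letters from pairwise p-values (insert-absorb).

    ``p_values`` maps frozenset({a, b}) -> p.  Models sharing a letter do not
    differ at level ``alpha``.  ``order`` fixes the letter ordering (defaults
    to the given label order).
    """
    labels = list(labels)
    order = labels if order is None else list(order)
    groups = [set(labels)]
    for pair, p in p_values.items():
        a, b = tuple(pair)
        if not (p < alpha):
            continue
        new_groups = []
        for g in groups:
            if a in g and b in g:
                new_groups.extend([g - {a}, g - {b}])
            else:
                new_groups.append(g)
        # absorb groups contained in others
        groups = []
        for g in sorted(new_groups, key=len, reverse=True):
            if g and not any(g <= kept for kept in groups):
                groups.append(g)
    # deterministic letter order: by best-ranked member
    rank = {m: i for i, m in enumerate(order)}
    groups.sort(key=lambda g: min(rank[m] for m in g))
    letters = {m: "" for m in labels}
    for i, g in enumerate(groups):
        ch = chr(ord("a") + i)
        for m in labels:
            if m in g:
                letters[m] += ch
    return letters


# ---------------------------------------------------------------------------
# power analysis


@dataclass
class PowerQuery:
    """Two-means sample-size question: detect a difference ``d`` given
    measurement SD ``sd`` at the stated normal deviates."""

    sd: float
    d: float
    z_alpha: float = 1.96
    z_beta: float = 1.28


def animals_required(q: PowerQuery) -> int:
    """Animals per treatment: ceil(2 (z_a + z_b)^2 sd^2 / d^2), floor of 2."""
    if q.sd <= 0 or q.d <= 0:
        raise ValueError("sd and d must be positive")
    raw = 2.0 * (q.z_alpha + q.z_beta) ** 2 * (q.sd**2 / q.d**2)
    return max(2, math.ceil(raw))


def power_table(rmseps: dict, d: float, z_alpha: float = 1.96,
                z_beta: float = 1.28) -> pd.DataFrame:
    """Animals-per-treatment table for several models' RMSEPs at effect size d."""
    rows = [
        {
            "model": label,
            "RMSEP": r,
            "effect_size": d,
            "animals_per_treatment": animals_required(
                PowerQuery(sd=r, d=d, z_alpha=z_alpha, z_beta=z_beta)
            ),
        }
        for label, r in rmseps.items()
    ]
    return pd.DataFrame(rows)
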