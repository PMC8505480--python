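"""Psychometric fitting and threshold statistics.

Per-session, per-condition trial data are fit with a cumulative Weibull

    p(c) = gamma + (1 - gamma - lambda) * (1 - exp(-(c / alpha)^beta))

by maximum likelihood, with the guess rate gamma fixed at 0.5 (two-interval
forced choice), the lapse rate lambda free in [0, 0.05] and the slope beta
unrestricted.  Threshold is the contrast at 70.71% correct (sqrt(1/2), the
conventional 2IFC criterion), inverted in closed form.  Thresholds become
just-noticeable differences (JNDs) by multiplying with the background's LMS
content, and JNDs are normalized so that the low-melanopic condition's
median is unity.  Summary uncertainty follows the notched-box-plot rule
CI = median +/- 1.58 * IQR / sqrt(n) with type-7 quantiles.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize

GUESS_RATE = 0.5
LAPSE_MAX = 0.05
#: 2IFC threshold criterion, sqrt(1/2); displayed as 70.71% correct.
CRITERION = np.sqrt(0.5)


def weibull_p(
    contrast, alpha: float, beta: float, lapse: float, guess: float = GUESS_RATE
):
    """Probability correct at each contrast under the cumulative Weibull."""
    c = np.asarray(contrast, dtype=float)
    with np.errstate(divide="ignore"):
        z = np.where(c > 0, (c / alpha) ** beta, 0.0)
    return guess + (1.0 - guess - lapse) * (1.0 - np.exp(-z))


@dataclass(frozen=True)
class PsychometricFit:
    alpha: float
    beta: float
    lapse: float
    guess: float
    neg_log_likelihood: float
    n_trials: int
    converged: bool

    def predict(self, contrast):
        return weibull_p(contrast, self.alpha, self.beta, self.lapse, self.guess)


@dataclass(frozen=True)
class ThresholdResult:
    participant: str
    session: int
    condition: str
    fit: PsychometricFit
    threshold_contrast: float
    background_lms_content: float
    jnd: float


@dataclass(frozen=True)
class SummaryStats:
    median: float
    iqr: float
    ci_low: float
    ci_high: float
    n: int


def _aggregate(contrasts: np.ndarray, correct: np.ndarray):
    """Collapse Bernoulli trials to per-level binomial counts (same likelihood)."""
    levels, inv = np.unique(contrasts, return_inverse=True)
    n = np.bincount(inv, minlength=levels.size).astype(float)
    k = np.bincount(inv, weights=correct.astype(float), minlength=levels.size)
    return levels, n, k


def _nll(params, levels, n, k):
    alpha, beta, lapse = params
    p = weibull_p(levels, alpha, beta, lapse)
    p = np.clip(p, 1e-12, 1.0 - 1e-12)
    return -np.sum(k * np.log(p) + (n - k) * np.log1p(-p))


def fit_weibull(
    records: pd.DataFrame,
    *,
    contrast_col: str = "nominal_contrast",
    correct_col: str = "correct",
) -> PsychometricFit:
    """Maximum-likelihood cumulative Weibull fit to a block of 2IFC trials.

    Optimizes (alpha, beta, lambda) with gamma fixed at 0.5 and lambda in
    [0, 0.05] by bounded L-BFGS-B started from the best points of a coarse
    5 alphas x 5 betas x 3 lapses grid; the best optimum is returned, ties
    broken toward the smallest alpha.  Trials are first collapsed to
    per-level binomial counts, which leaves the likelihood unchanged.
    """
    contrasts = records[contrast_col].to_numpy(dtype=float)
    correct = records[correct_col].to_numpy(dtype=bool)
    if np.unique(contrasts).size < 2:
        raise ValueError("need >= 2 distinct contrast levels to fit")
    if correct.all() or not correct.any():
        raise ValueError(
            "degenerate data: responses are all correct or all incorrect; "
            "the likelihood is maximized on the guess/lapse boundary and "
            "alpha is unidentified"
        )
    levels, n, k = _aggregate(contrasts, correct)
    c_pos = contrasts[contrasts > 0]
    c_lo, c_hi = np.quantile(c_pos, [0.05, 0.95])
    c_lo = max(c_lo, 1e-5)
    alphas = np.geomspace(c_lo, max(c_hi, 2 * c_lo), 5)
    betas = np.linspace(0.5, 8.0, 5)
    lapses = np.array([0.0, 0.025, 0.05])
    starts = sorted(
        ((a0, b0, l0) for a0 in alphas for b0 in betas for l0 in lapses),
        key=lambda p: _nll(p, levels, n, k),
    )
    bounds = [(1e-6, 1.0), (0.05, 50.0), (0.0, LAPSE_MAX)]
    best = None
    for start in starts[:5]:
        res = minimize(
            _nll,
            np.asarray(start),
            args=(levels, n, k),
            method="L-BFGS-B",
            bounds=bounds,
        )
        key = (round(res.fun, 9), res.x[0])
        if best is None or key < best[0]:
            best = (key, res)
    res = best[1]
    alpha, beta, lapse = res.x
    return PsychometricFit(
        alpha=float(alpha),
        beta=float(beta),
        lapse=float(lapse),
        guess=GUESS_RATE,
        neg_log_likelihood=float(res.fun),
        n_trials=int(contrasts.size),
        converged=bool(res.success),
    )


def threshold_at_criterion(fit: PsychometricFit, criterion: float = CRITERION) -> float:
    """Contrast at which the fitted function reaches the criterion (closed form).

    ``c* = alpha * (-ln(1 - (criterion - gamma)/(1 - gamma - lambda)))^(1/beta)``.
    The criterion must lie strictly between the guess rate and the fit's
    ceiling ``1 - lambda``.
    """
    ceiling = 1.0 - fit.lapse
    if not (fit.guess < criterion < ceiling):
        raise ValueError(
            f"criterion {criterion:.4f} unattainable: the fitted function "
            f"spans ({fit.guess:.4f}, {ceiling:.4f})"
        )
    frac = (criterion - fit.guess) / (1.0 - fit.guess - fit.lapse)
    return float(fit.alpha * (-np.log1p(-frac)) ** (1.0 / fit.beta))


def jnd(threshold_contrast: float, background_lms_content: float) -> float:
    """JND = threshold contrast x background LMS content.

    Expresses the detection threshold as the absolute difference in LMS
    stimulation between stimulus and background that is just noticeable.
    """
    return threshold_contrast * background_lms_content


def normalize_jnds(jnds_by_condition: dict[str, np.ndarray], low_condition: str = "low"):
    """Divide every JND by the low-condition median, so its median is unity."""
    low = np.asarray(jnds_by_condition[low_condition], dtype=float)
    if low.size == 0:
        raise ValueError("low condition has no JNDs")
    denom = float(np.median(low))
    if denom <= 0:
        raise ValueError(f"low-condition median JND is {denom}; cannot normalize")
    return {
        cond: np.asarray(vals, dtype=float) / denom
        for cond, vals in jnds_by_condition.items()
    }


def within_session_differences(
    results: pd.DataFrame,
    *,
    value_col: str = "normalized_jnd",
    high_condition: str = "high",
    low_condition: str = "low",
) -> pd.Series:
    """Per-session (high - low) differences of a per-condition value.

    ``results`` needs columns ``session``, ``condition`` and ``value_col``
    with exactly one row per session x condition.  Raises on any session
    missing either condition.
    """
    wide = results.pivot(index="session", columns="condition", values=value_col)
    for cond in (low_condition, high_condition):
        if cond not in wide.columns:
            raise ValueError(f"no sessions with condition {cond!r}")
    missing = wide.index[wide[[low_condition, high_condition]].isna().any(axis=1)]
    if len(missing):
        raise ValueError(f"unpaired sessions (missing a condition): {list(missing)}")
    return wide[high_condition] - wide[low_condition]


def summarize(values) -> SummaryStats:
    """Median, type-7 IQR, and the CI = median +/- 1.58 IQR / sqrt(n)."""
    vals = np.asarray(values, dtype=float)
    if vals.size < 2:
        raise ValueError("need n >= 2 values to summarize")
    med = float(np.median(vals))
    q1, q3 = np.quantile(vals, [0.25, 0.75])  # numpy default = type-7
    iqr = float(q3 - q1)
    half = 1.58 * iqr / np.sqrt(vals.size)
    return SummaryStats(
        median=med,
        iqr=iqr,
        ci_low=med - half,
        ci_high=med + half,
        n=int(vals.size),
    )
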