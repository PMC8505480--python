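"""Artifact-prediction analyses: what stimulus imprecision alone would do.

Silent substitution is only as good as device calibration; residual
("splatter") contrast on nominally silenced receptors can mimic or mask a
real melanopsin effect.  Three predictors each assume melanopsin has *no*
effect on sensitivity and ask what the measured stimulus deviations alone
predict for the normalized JNDs:

1. background splatter — the low-condition nominal threshold contrast is
   held constant across conditions and multiplied by each background's
   measured LMS content (a Weber's-law prediction);
2. flicker splatter — the constant threshold contrast is additionally
   multiplied by each condition's measured/nominal flicker-contrast ratio;
3. L-M chromatic mediation — detection is assumed to be carried entirely by
   the chromatic |L-M| splatter of the flicker, so the predicted LMS
   threshold scales inversely with each condition's |(L-M)/LMS| ratio.

All predictions are normalized like the experimental JNDs: the low
condition's median is unity.  Feeding predictor 1 melanopsin excitations
instead of LMS contents turns it into the Weber-law positive-control
prediction (a 350% melanopic pair predicts a 4.5x JND fold change).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .synthetic_data import SessionArtifacts


def _normalize(low: np.ndarray, high: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    denom = float(np.median(low))
    if denom <= 0:
        raise ValueError("low-condition median prediction is non-positive")
    return low / denom, high / denom


def predict_jnd_background_splatter(
    nominal_threshold_low,
    measured_bg_low,
    measured_bg_high,
) -> dict[str, np.ndarray]:
    """Normalized JNDs predicted from measured background content alone.

    Per session: the low-condition nominal threshold contrast is taken as
    the threshold for both conditions (no melanopsin effect) and multiplied
    by that condition's measured background content; predictions are then
    normalized to a low-condition median of one.
    """
    thr = np.atleast_1d(np.asarray(nominal_threshold_low, dtype=float))
    bg_lo = np.atleast_1d(np.asarray(measured_bg_low, dtype=float))
    bg_hi = np.atleast_1d(np.asarray(measured_bg_high, dtype=float))
    if not (thr.shape == bg_lo.shape == bg_hi.shape):
        raise ValueError("per-session inputs must have matching shapes")
    if np.any(np.isnan(bg_lo)) or np.any(np.isnan(bg_hi)):
        raise ValueError("missing background measurement")
    low, high = _normalize(thr * bg_lo, thr * bg_hi)
    return {"low": low, "high": high}


def predict_jnd_flicker_splatter(
    nominal_threshold_low,
    measured_over_nominal_low,
    measured_over_nominal_high,
    measured_bg_low,
    measured_bg_high,
) -> dict[str, np.ndarray]:
    """Normalized JNDs predicted from flicker measured/nominal contrast ratios.

    The constant low-condition threshold contrast is multiplied by each
    condition's measured-over-nominal flicker LMS ratio (the contrast the
    device actually delivered at that nominal setting), then by the
    measured background content, and normalized.
    """
    thr = np.atleast_1d(np.asarray(nominal_threshold_low, dtype=float))
    r_lo = np.atleast_1d(np.asarray(measured_over_nominal_low, dtype=float))
    r_hi = np.atleast_1d(np.asarray(measured_over_nominal_high, dtype=float))
    bg_lo = np.atleast_1d(np.asarray(measured_bg_low, dtype=float))
    bg_hi = np.atleast_1d(np.asarray(measured_bg_high, dtype=float))
    if np.any(r_lo <= 0) or np.any(r_hi <= 0):
        raise ValueError("measured/nominal flicker ratios must be positive")
    low, high = _normalize(thr * r_lo * bg_lo, thr * r_hi * bg_hi)
    return {"low": low, "high": high}


def predict_jnd_lm_mediation(
    measured_lm_at_threshold_low,
    lm_over_lms_low,
    lm_over_lms_high,
    measured_bg_low,
    measured_bg_high,
) -> dict[str, np.ndarray]:
    """Normalized JNDs under the null that |L-M| splatter mediates detection.

    The |L-M| contrast measured at the low-condition threshold is held
    constant across conditions; dividing by each condition's |(L-M)/LMS|
    ratio gives the LMS contrast at which that chromatic signal would be
    reached, which is then converted to a JND and normalized.  More
    chromatic splatter on the high background therefore predicts a *lower*
    threshold there.
    """
    lm_thr = np.abs(np.atleast_1d(np.asarray(measured_lm_at_threshold_low, float)))
    ratio_lo = np.atleast_1d(np.asarray(lm_over_lms_low, dtype=float))
    ratio_hi = np.atleast_1d(np.asarray(lm_over_lms_high, dtype=float))
    bg_lo = np.atleast_1d(np.asarray(measured_bg_low, dtype=float))
    bg_hi = np.atleast_1d(np.asarray(measured_bg_high, dtype=float))
    if np.any(ratio_lo == 0) or np.any(ratio_hi == 0):
        raise ValueError(
            "zero (L-M)/LMS ratio: chromatic mediation cannot set a threshold"
        )
    low, high = _normalize(
        lm_thr / np.abs(ratio_lo) * bg_lo, lm_thr / np.abs(ratio_hi) * bg_hi
    )
    return {"low": low, "high": high}


SPLATTER_COLUMNS = [
    "participant",
    "session",
    "condition",
    "bg_lms_content",
    "flicker_ratio",
    "lm_over_lms",
    "pred_bg",
    "pred_flicker",
    "pred_lm",
]


def sem_of_median(values: np.ndarray) -> float:
    """Standard error of the median, via the 1.2533 * SD / sqrt(n) approximation."""
    vals = np.asarray(values, dtype=float)
    return float(1.2533 * np.std(vals, ddof=1) / np.sqrt(vals.size))


def splatter_report(
    sessions: list[SessionArtifacts],
    thresholds: dict[int, float] | None = None,
    *,
    low_condition: str = "low",
    high_condition: str = "high",
) -> pd.DataFrame:
    """Run all three artifact predictors over a participant's sessions.

    Measured contents and ratios come from each session's "measured"
    (perturbed-device) spectra, already computed into the session
    artifacts.  ``thresholds`` maps session id to the low-condition nominal
    threshold contrast used as the constant predicted threshold (typically
    the psychometric-fit threshold); when omitted, the preliminary
    staircase-reversal threshold stands in.  The at-threshold flicker
    spectra behind the measured flicker ratios are always reconstructed
    from the reversal threshold, not from a fit.  Returns one tidy row per
    session x condition with the measured quantities and the three
    normalized predictions.
    """
    if thresholds is None:
        thr_low = np.array(
            [s.reversal_thresholds[low_condition] for s in sessions]
        )
    else:
        thr_low = np.array([thresholds[s.session] for s in sessions])
    bg_lo = np.array(
        [s.conditions[low_condition].measured_bg_lms_content for s in sessions]
    )
    bg_hi = np.array(
        [s.conditions[high_condition].measured_bg_lms_content for s in sessions]
    )
    r_lo = np.array([s.conditions[low_condition].flicker_ratio for s in sessions])
    r_hi = np.array([s.conditions[high_condition].flicker_ratio for s in sessions])
    lm_lo = np.array(
        [s.conditions[low_condition].measured_lm_over_lms for s in sessions]
    )
    lm_hi = np.array(
        [s.conditions[high_condition].measured_lm_over_lms for s in sessions]
    )
    pred_bg = predict_jnd_background_splatter(thr_low, bg_lo, bg_hi)
    pred_fl = predict_jnd_flicker_splatter(thr_low, r_lo, r_hi, bg_lo, bg_hi)
    # Sessions with no measurable chromatic splatter in either condition
    # (|L-M|/LMS below numerical noise) cannot support chromatic mediation;
    # their L-M prediction degenerates to the background prediction rather
    # than dividing noise by noise.
    lm_floor = 1e-9
    degenerate = np.maximum(np.abs(lm_lo), np.abs(lm_hi)) < lm_floor
    lm_lo_eff = np.where(degenerate, 1.0, lm_lo)
    lm_hi_eff = np.where(degenerate, 1.0, lm_hi)
    # measured L-M contrast of the at-threshold flicker on the low background:
    # the measured LMS contrast there is thr * ratio, times the (L-M)/LMS ratio
    lm_at_thr = thr_low * r_lo * lm_lo_eff
    pred_lm = predict_jnd_lm_mediation(
        lm_at_thr, lm_lo_eff, lm_hi_eff, bg_lo, bg_hi
    )
    rows = []
    for i, sess in enumerate(sessions):
        for cond, bg, ratio, lm, p1, p2, p3 in (
            (low_condition, bg_lo, r_lo, lm_lo, pred_bg["low"], pred_fl["low"],
             pred_lm["low"]),
            (high_condition, bg_hi, r_hi, lm_hi, pred_bg["high"], pred_fl["high"],
             pred_lm["high"]),
        ):
            rows.append(
                {
                    "participant": sess.participant,
                    "session": sess.session,
                    "condition": cond,
                    "bg_lms_content": bg[i],
                    "flicker_ratio": ratio[i],
                    "lm_over_lms": lm[i],
                    "pred_bg": p1[i],
                    "pred_flicker": p2[i],
                    "pred_lm": p3[i],
                }
            )
    return pd.DataFrame(rows, columns=SPLATTER_COLUMNS)


def participant_medians(report: pd.DataFrame) -> pd.DataFrame:
    """Median and SE-of-median of each prediction per participant x condition."""
    out = []
    for (participant, condition), grp in report.groupby(["participant", "condition"]):
        row = {"participant": participant, "condition": condition, "n": len(grp)}
        for col in ("pred_bg", "pred_flicker", "pred_lm"):
            vals = grp[col].to_numpy()
            row[f"{col}_median"] = float(np.median(vals))
            row[f"{col}_sem"] = sem_of_median(vals) if len(grp) > 1 else 0.0
        out.append(row)
    return pd.DataFrame(out)
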