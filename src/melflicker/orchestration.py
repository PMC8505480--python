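"""End-to-end experiment runs: simulate, fit, summarize, splatter-check.

Ties the stages together into the three experiment layouts:

* Experiment 1 — blocked low/high melanopic backgrounds (plus an optional
  low/high luminance positive control), 4 sessions;
* Experiment 2 — trialwise-interleaved steady background vs. pulsed
  high-melanopic pedestal, 4 sessions;
* Experiment 3 — as Experiment 2 but with the flicker produced by an
  independent admixed source, so flicker splatter cannot correlate with
  the melanopic condition, 6 sessions.

A :class:`RunConfig` (YAML/JSON-serializable) fully determines a run; the
master seed deterministically spawns every per-stage seed, so reruns are
bit-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import threshold as thr
from .colorimetry import ReceptorSensitivitySet, synthetic_sensitivities
from .splatter import participant_medians, splatter_report
from .stimulus_design import (
    DeviceModel,
    TimelineSegment,
    TrialTimeline,
    flicker_waveform,
    pedestal_waveform,
)
from .synthetic_data import (
    ObserverModel,
    StudyConfig,
    StudyDataset,
    generate_study,
    make_synthetic_device,
    write_trial_log,
)


@dataclass(frozen=True)
class RunConfig:
    """Complete, serializable description of one end-to-end run."""

    experiment: str = "exp1"
    seed: int = 0
    n_participants: int = 3
    n_sessions: int = 4
    trials_per_condition: int = 120
    mel_contrast: float = 3.5
    lms_max_contrast: float = 0.05
    n_primaries: int = 8
    gain_sd: float = 0.01
    peak_shift_sd_nm: float = 0.5
    observer_alpha: float = 0.013
    observer_beta: float = 3.0
    observer_lapse: float = 0.01
    condition_effect: float = 1.0
    lm_weight: float = 0.0
    include_lms_control: bool = True
    pedestal_ramp_ms: float = 500.0
    sensitivities_csv: str | None = None
    device_csv: str | None = None

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        text = Path(path).read_text()
        data = yaml.safe_load(text)  # YAML is a JSON superset
        return cls(**data)

    def to_file(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self)))

    def config_hash(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]

    def observer(self) -> ObserverModel:
        return ObserverModel(
            alpha=self.observer_alpha,
            beta=self.observer_beta,
            lapse=self.observer_lapse,
            condition_effect=self.condition_effect,
            lm_weight=self.lm_weight,
        )

    def study_config(self, **overrides) -> StudyConfig:
        base = dict(
            n_participants=self.n_participants,
            n_sessions=self.n_sessions,
            trials_per_condition=self.trials_per_condition,
            seed=self.seed,
            experiment=self.experiment,
            mel_contrast=self.mel_contrast,
            lms_max_contrast=self.lms_max_contrast,
            n_primaries=self.n_primaries,
            gain_sd=self.gain_sd,
            peak_shift_sd_nm=self.peak_shift_sd_nm,
            observer=self.observer(),
        )
        base.update(overrides)
        return StudyConfig(**base)

    def load_sensitivities(self) -> ReceptorSensitivitySet:
        if self.sensitivities_csv:
            return ReceptorSensitivitySet.from_csv(self.sensitivities_csv)
        return synthetic_sensitivities()

    def load_device(self, sens: ReceptorSensitivitySet) -> DeviceModel:
        if self.device_csv:
            df = pd.read_csv(self.device_csv)
            wl = df["wavelength_nm"].to_numpy(dtype=float)
            basis = df.drop(columns="wavelength_nm").to_numpy(dtype=float)
            from .colorimetry import SpectralSamples

            return DeviceModel(wl, basis, SpectralSamples.zeros(wl))
        return make_synthetic_device(
            n_primaries=self.n_primaries,
            wavelengths=sens.wavelengths,
            seed=self.seed,
        )


RESULT_COLUMNS = [
    "participant",
    "session",
    "condition",
    "alpha",
    "beta",
    "lambda",
    "threshold_contrast",
    "bg_lms_content",
    "jnd",
    "normalized_jnd",
]


def fit_study(dataset: StudyDataset) -> pd.DataFrame:
    """Fit every session x condition block and derive (normalized) JNDs.

    Thresholds use the 70.71%-correct criterion; JND = threshold contrast x
    that condition's *measured* background LMS content; normalization is
    per participant to the low-condition median JND.
    """
    rows = []
    for sess in dataset.sessions:
        for condition, art in sess.conditions.items():
            block = sess.trials[sess.trials["condition"] == condition]
            fit = thr.fit_weibull(block)
            t = thr.threshold_at_criterion(fit)
            rows.append(
                {
                    "participant": sess.participant,
                    "session": sess.session,
                    "condition": condition,
                    "alpha": fit.alpha,
                    "beta": fit.beta,
                    "lambda": fit.lapse,
                    "threshold_contrast": t,
                    "bg_lms_content": art.measured_bg_lms_content,
                    "jnd": thr.jnd(t, art.measured_bg_lms_content),
                }
            )
    results = pd.DataFrame(rows)
    normalized = []
    for participant, grp in results.groupby("participant", sort=False):
        jnds = {
            cond: g["jnd"].to_numpy() for cond, g in grp.groupby("condition")
        }
        norm = thr.normalize_jnds(jnds, low_condition="low")
        g = grp.copy()
        for cond in norm:
            g.loc[g["condition"] == cond, "normalized_jnd"] = norm[cond]
        normalized.append(g)
    return pd.concat(normalized, ignore_index=True)[RESULT_COLUMNS]


def participant_summaries(results: pd.DataFrame) -> pd.DataFrame:
    """Within-session (high - low) differences summarized per participant."""
    rows = []
    for participant, grp in results.groupby("participant", sort=False):
        diffs = thr.within_session_differences(grp)
        stats = thr.summarize(diffs.to_numpy())
        high_median = float(
            np.median(grp.loc[grp["condition"] == "high", "normalized_jnd"])
        )
        rows.append(
            {
                "participant": participant,
                "high_over_low_median": high_median,
                "diff_median": stats.median,
                "diff_iqr": stats.iqr,
                "ci_low": stats.ci_low,
                "ci_high": stats.ci_high,
                "n_sessions": stats.n,
                "ci_covers_zero": stats.ci_low <= 0.0 <= stats.ci_high,
            }
        )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class ExperimentArtifacts:
    config: RunConfig
    dataset: StudyDataset
    results: pd.DataFrame
    summaries: pd.DataFrame
    splatter: pd.DataFrame
    splatter_medians: pd.DataFrame
    control_results: pd.DataFrame | None = None
    control_summaries: pd.DataFrame | None = None


def _interleave_presentation(trials: pd.DataFrame, seed: int) -> pd.DataFrame:
    """Assign a pseudorandom trialwise presentation order across conditions.

    Within each (participant, session), the two conditions' trial streams
    are merged in a seeded random order (each stream keeping its internal
    order), emulating the trialwise pedestal/no-pedestal interleave.
    """
    rng = np.random.default_rng(seed)
    out = []
    for (_, _), grp in trials.groupby(["participant", "session"], sort=False):
        conds = [g.sort_values("trial_index") for _, g in grp.groupby("condition")]
        draws = np.concatenate(
            [np.full(len(g), i) for i, g in enumerate(conds)]
        )
        rng.shuffle(draws)
        pointers = [0] * len(conds)
        order = []
        for which in draws:
            order.append(conds[which].iloc[pointers[which]])
            pointers[which] += 1
        merged = pd.DataFrame(order).reset_index(drop=True)
        merged["presentation_index"] = np.arange(len(merged))
        out.append(merged)
    return pd.concat(out, ignore_index=True)


def run_experiment(config: RunConfig, out_dir=None) -> ExperimentArtifacts:
    """Run one full experiment per the config; optionally write artifacts.

    Experiment 1 runs blocked melanopic conditions plus, if configured, the
    low/high luminance (LMS-driven) positive control.  Experiments 2 and 3
    interleave the conditions trialwise; Experiment 3 additionally makes
    the flicker splatter independent of the melanopic condition.
    """
    exp = config.experiment
    if exp not in ("exp1", "exp2", "exp3"):
        raise ValueError(f"unknown experiment {exp!r}")
    sens = config.load_sensitivities()
    device = config.load_device(sens)
    overrides = {}
    if exp == "exp3":
        overrides["flicker_independent_of_condition"] = True
    dataset = generate_study(
        config.study_config(**overrides), device=device, sens=sens
    )
    trials = dataset.trials
    if exp in ("exp2", "exp3"):
        trials = _interleave_presentation(trials, seed=config.seed + 1)
        dataset = dataclasses.replace(dataset, trials=trials)
    results = fit_study(dataset)
    summaries = participant_summaries(results)
    spl_rows = []
    for participant in sorted({s.participant for s in dataset.sessions}):
        sessions = [s for s in dataset.sessions if s.participant == participant]
        fit_thr = results[
            (results["participant"] == participant)
            & (results["condition"] == "low")
        ].set_index("session")["threshold_contrast"].to_dict()
        spl_rows.append(splatter_report(sessions, thresholds=fit_thr))
    spl = pd.concat(spl_rows, ignore_index=True)
    spl_medians = participant_medians(spl)
    control_results = control_summaries = None
    if exp == "exp1" and config.include_lms_control:
        control = generate_study(
            config.study_config(
                driven_receptors=("L", "M", "S"),
                experiment="exp1-lms-control",
                seed=config.seed + 7,
            ),
            sens=sens,
        )
        control_results = fit_study(control)
        control_summaries = participant_summaries(control_results)
    artifacts = ExperimentArtifacts(
        config=config,
        dataset=dataset,
        results=results,
        summaries=summaries,
        splatter=spl,
        splatter_medians=spl_medians,
        control_results=control_results,
        control_summaries=control_summaries,
    )
    if out_dir is not None:
        write_artifacts(artifacts, out_dir)
    return artifacts


def write_artifacts(artifacts: ExperimentArtifacts, out_dir) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg = artifacts.config
    cfg.to_file(out / "config.yaml")
    if "presentation_index" in artifacts.dataset.trials.columns:
        artifacts.dataset.trials.to_csv(out / "trials.csv", index=False)
    else:
        write_trial_log(artifacts.dataset.trials, out / "trials.csv")
    artifacts.results.to_csv(out / "thresholds.csv", index=False)
    artifacts.summaries.to_csv(out / "summaries.csv", index=False)
    artifacts.splatter.to_csv(out / "splatter.csv", index=False)
    artifacts.splatter_medians.to_csv(out / "splatter_medians.csv", index=False)
    if artifacts.control_results is not None:
        artifacts.control_results.to_csv(out / "control_thresholds.csv", index=False)
        artifacts.control_summaries.to_csv(out / "control_summaries.csv", index=False)
    (out / "report.txt").write_text(render_report(artifacts))


def render_report(artifacts: ExperimentArtifacts) -> str:
    cfg = artifacts.config
    lines = [
        f"experiment: {cfg.experiment}",
        f"seed: {cfg.seed}",
        f"config hash: {cfg.config_hash()}",
        "",
        "Per-participant within-session (high - low) normalized JND differences:",
    ]
    for _, row in artifacts.summaries.iterrows():
        covers = "covers 0" if row["ci_covers_zero"] else "EXCLUDES 0"
        lines.append(
            f"  {row['participant']}: median {row['diff_median']:+.3f}, "
            f"95% CI [{row['ci_low']:.3f}, {row['ci_high']:.3f}] ({covers}); "
            f"high/low median JND ratio {row['high_over_low_median']:.3f}"
        )
    if artifacts.control_summaries is not None:
        lines.append("")
        lines.append("Luminance (LMS x4.5) positive control:")
        for _, row in artifacts.control_summaries.iterrows():
            lines.append(
                f"  {row['participant']}: high/low median normalized JND "
                f"{row['high_over_low_median']:.3f} (Weber prediction 4.5)"
            )
    lines.append("")
    lines.append("Splatter predictions (median per participant, high condition):")
    high = artifacts.splatter_medians[
        artifacts.splatter_medians["condition"] == "high"
    ]
    for _, row in high.iterrows():
        lines.append(
            f"  {row['participant']}: background {row['pred_bg_median']:.3f}, "
            f"flicker {row['pred_flicker_median']:.3f}, "
            f"L-M {row['pred_lm_median']:.3f}"
        )
    return "\n".join(lines) + "\n"


def run_experiment1(config: RunConfig, out_dir=None) -> ExperimentArtifacts:
    return run_experiment(dataclasses.replace(config, experiment="exp1"), out_dir)


def run_experiment2_3(
    config: RunConfig, mode: str = "exp2", out_dir=None
) -> ExperimentArtifacts:
    if mode not in ("exp2", "exp3"):
        raise ValueError("mode must be 'exp2' or 'exp3'")
    n_sessions = 6 if mode == "exp3" else config.n_sessions
    cfg = dataclasses.replace(config, experiment=mode, n_sessions=n_sessions)
    return run_experiment(cfg, out_dir)


def build_trial_timeline(
    spec,
    nominal_contrast: float,
    *,
    pedestal: tuple[np.ndarray, np.ndarray] | None = None,
    ramp_ms: float = 500.0,
    interval_ms: float = 500.0,
    isi_ms: float = 500.0,
    pedestal_delay_ms: float = 250.0,
    frame_rate: float = 60.0,
    frequency: float = 5.0,
    target_interval: int = 1,
) -> TrialTimeline:
    """Frame-accurate settings timeline for one 2IFC trial.

    Two ``interval_ms`` intervals separated by an ISI; the target interval
    carries the sinusoidal flicker, the other shows the steady background.
    With ``pedestal=(low, high)`` the trial is wrapped in half-cosine ramps
    to and from the high-melanopic settings with ``pedestal_delay_ms`` of
    steady pedestal before and after the intervals.
    """
    def steady(duration, label):
        n = int(round(duration / 1000.0 * frame_rate))
        frames = np.tile(spec.background_settings, (n, 1))
        return TimelineSegment(label=label, duration_ms=float(duration), frames=frames)

    def interval(i):
        label = f"interval-{i}"
        if i == target_interval:
            return flicker_waveform(
                spec,
                nominal_contrast,
                frequency=frequency,
                duration_ms=interval_ms,
                frame_rate=frame_rate,
                label=label,
            )
        return flicker_waveform(
            spec, 0.0, frequency=frequency, duration_ms=interval_ms,
            frame_rate=frame_rate, label=label,
        )

    segments = [interval(1), steady(isi_ms, "isi"), interval(2)]
    if pedestal is not None:
        low, high = pedestal
        segments = (
            [
                pedestal_waveform(low, high, ramp_ms, frame_rate),
                steady(pedestal_delay_ms, "pedestal-hold"),
            ]
            + segments
            + [
                steady(pedestal_delay_ms, "pedestal-hold"),
                pedestal_waveform(low, high, ramp_ms, frame_rate, descending=True),
            ]
        )
    return TrialTimeline(frame_rate=frame_rate, segments=segments)
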