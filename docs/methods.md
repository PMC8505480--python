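# Methods

This package re-creates, in simulation, the full measurement chain of a
melanopsin flicker-sensitivity experiment: photoreceptor-directed stimulus
design on a multiprimary light source, an adaptive-staircase two-interval
forced-choice (2IFC) task, maximum-likelihood psychometric fitting, and the
stimulus-imprecision ("splatter") analyses that separate a real melanopsin
effect from a device artifact.  This note records the model, the defaults,
and the design choices made where the procedure was genuinely open.

## Colorimetry

A stimulus is a spectral power distribution Φ(λ) on a uniform wavelength
grid (default 380–780 nm in 2 nm steps).  Receptor excitations are
rectangle-rule sums

    e_r = Σ_λ S_r(λ) Φ(λ) Δλ,    r ∈ {L, M, S, Mel},

with every sensitivity S_r normalized to a peak of 1.  Excitations
therefore carry arbitrary units; all downstream statistics are Weber
contrasts c_r = (e_mod − e_bg)/e_bg or normalized JNDs, which are invariant
to the units (and to whether Δλ is included — documented convention:
included).  The **LMS content** of a stimulus is the unweighted *mean* of
the three cone excitations, and the **LMS contrast** of a modulation is the
mean of the three cone contrasts, so that a modulation delivering +5% on
each cone has LMS contrast 0.05.  The sum convention differs by a fixed
factor of 3; every normalized quantity is invariant to the choice, and a
test demonstrates this.  The chromatic-splatter ratio is
(c_L − c_M)/c_LMS.

Sensitivities are pluggable tabulated CSV inputs (columns
`wavelength_nm, L, M, S, Mel`).  The packaged fixture set consists of four
synthetic log-normal-shaped curves peaking near 560/530/440/480 nm for
L/M/S/Mel — physiologically shaped, but not a standards table; field size
(27.5°), observer age and pupil diameter (6 mm) travel as metadata only,
since nothing in the analysis needs absolute retinal irradiance.

Age-dependent lens density is modelled as a packaged synthetic optical
density template D(λ) (smooth, monotone decreasing, negligible beyond
~650 nm) with linear age scaling s(age) = 1 + 0.02(age − 32) about a
reference age of 32 years, valid 20–80 years.  Curves are multiplied by the
transmittance change 10^(−(s−1)D) relative to the reference observer and
re-normalized, so the reference age is an exact identity.  Any tabulated
template on the working grid can replace the synthetic one.

## Device model and silent substitution

The light source is linear: output = `primary_basis @ settings + ambient`,
settings ∈ [0,1] per primary.  The synthetic default has 8 Gaussian
primaries (FWHM 30 nm) evenly spaced over 400–700 nm with ±10% seeded peak
power jitter.  Because excitations are affine in settings, both design
problems are quadratic programs with linear constraints, solved with SLSQP:

* **Background pair.** Find low/high settings whose exchange gives Weber
  contrast 3.5 (i.e. a 4.5× excitation ratio) on melanopsin while the three
  cone contrasts stay within `cone_tolerance` (default 1e-6; the silencing
  contract is an inequality band, implemented with a 1% inner margin so the
  returned pair is strictly inside it).  The solve carries auxiliary arm
  variables so that each background provably admits ±5% LMS flicker arms
  inside the gamut (headroom as an explicit constraint, not post-hoc
  rejection).  A `max` mode instead maximizes the silenced-receptor
  contrast (two stages: raw ratio maximization, then a fixed-target
  re-solve just below the raw optimum to restore strict feasibility —
  SLSQP line searches stall close to the gamut boundary, so acceptance is
  by verified constraints, not the optimizer's status flag).  Setting
  `driven=("L","M","S")` swaps roles and yields the luminance
  positive-control pair (equal cone contrast, melanopsin silenced).
* **Flicker arms.** The arm deviation d solves the linear system
  M d = (0.05·e_LMS(bg), 0); the minimum-norm solution is taken
  (pseudoinverse), with a constrained fallback when it would leave the
  gamut.  The negative arm mirrors the positive one.

Additive scatter light (e.g. 2.63 cd/m²-scale projector leakage) dilutes
Weber contrast; `apply_scatter_correction` re-solves the arms against the
device-plus-scatter output so the delivered contrasts are nominal.
Staircase-requested contrasts are snapped to the 0.1% grid (half away from
zero) and realized by scaling the arm deviation in settings space.
Temporal waveforms are built in settings space (how a synthesizer is
driven): sinusoidal flicker at 5 Hz over 500 ms intervals drawn at 60 Hz,
and half-cosine pedestal ramps w(t) = low + ½(1 − cos(πt/T))(high − low)
with T defaulting to 500 ms (a 250 ms variant is a config override; the
source protocol is ambiguous between the two).  Settings quantization
(e.g. 8-bit, 256 levels) is explicit and opt-in: designs are solved
continuously, and quantization-induced splatter is measured and reported
rather than silently absorbed.

## Task and staircases

Each 2IFC trial presents two 500 ms intervals separated by a 500 ms ISI;
the target interval carries the flicker.  Contrast is scheduled by three
interleaved staircases on the 0–5% grid, distinguished by their up rule:
3, 2 or 1 consecutive incorrect responses raise the contrast, any correct
response lowers it.  Unstated protocol details were fixed as: step = 2
grid units (0.2%), start levels 5%/2.5%/5% for rules 3/2/1, 120 trials
split 40/40/40 in a seeded pseudorandom interleave — all overridable.  A
preliminary threshold is the mean contrast at the last 4 direction
reversals per staircase, pooled.  The conservative rule-3 staircase often
never reverses within its 40 trials (three consecutive errors are rare
above threshold), so the pipeline pools only staircases that did reverse;
the strict ≥2-reversals-per-staircase contract is still the default of
`reversal_threshold`.  Note the rule-1 staircase equilibrates where
p(correct) = 0.5, i.e. near zero contrast in 2IFC — the reversal threshold
is deliberately a crude, fit-free quantity used only to reconstruct
at-threshold stimulus spectra.

## Psychometric model

Detection follows a cumulative Weibull,

    p(c) = γ + (1 − γ − λ)(1 − exp(−(c/α)^β)),

with guess rate γ fixed at 0.5 (2IFC), lapse λ ∈ [0, 0.05] and slope β
free.  Fitting maximizes the Bernoulli likelihood (trials are collapsed to
per-level binomial counts, which leaves the likelihood identical) with
L-BFGS-B polished from the best points of a coarse 5×5×3 multistart grid;
ties break toward the smaller α.  Threshold is the closed-form inverse at
the criterion √½ ≈ 70.71% correct.  JND = threshold contrast × background
LMS content; JNDs are normalized so the participant's low-condition median
is 1.  Summary uncertainty uses the notched-box-plot interval
CI = median ± 1.58·IQR/√n with type-7 quantiles (numpy's default, matching
the default of the statistics environment this convention comes from).

A caution that the package makes measurable instead of hiding: this CI is
an asymptotic heuristic.  At the study's n = 4 sessions per participant its
actual coverage of a null effect is far below nominal — normal-theory
Monte-Carlo gives ≈75% at n = 4 (≈85% at n = 12), and the full simulated
pipeline measures ≈71% per participant.  Coverage is scale-invariant, so no
noise setting changes this; occasional null participants whose CI excludes
zero are expected behavior of the formula, not evidence of an effect.

## Synthetic observers and studies

The simulated observer is the generative mirror of the fitted model:
Bernoulli per trial with the Weibull above, defaults α = 0.013, β = 3,
λ = 0.01 — placing thresholds in the 1–2% contrast range typical of
trained observers on such tasks (a fixture choice).  `condition_effect`
multiplies α in the high-melanopic condition (1.0 = null; 4.5 = the
Weber-law upper bound).  An optional `lm_weight` adds chromatic
hypersensitivity (effective signal c_LMS + w·|c_L − c_M|) to reproduce the
chromatic-mediation confound scenario; default 0.  Inter-trial dependence,
adaptation dynamics, reaction times and lapse structure beyond the constant
λ are deliberately not modelled, so passing tests speak to the analysis
chain, not to those aspects of real data.

A study is participants × sessions × conditions, 120 trials per condition
(4 sessions blocked low/high in the first experiment; 240 trialwise
interleaved per session in the pedestal experiments, 6 sessions in the
admixed-flicker variant).  Because the observer is Bernoulli per trial,
interleaving cannot change any statistic; the interleave is realized as a
seeded presentation order over the two condition streams.  Device
calibration error — the source of splatter — is a per-session perturbed
copy of the device (lognormal per-primary gain, σ = 1%, and normal spectral
shift, σ = 0.5 nm); "measured" spectra are nominal settings rendered
through the perturbed device, and the observer responds to the *achieved*
contrast, so artifacts propagate into behavior as they would physically.
The nominal design is solved once per study (it depends only on the nominal
device); session-to-session variation enters through the perturbations.
Everything is reproducible bit-for-bit from a master seed.

## Splatter predictors

All three predictors assume melanopsin has no effect and convert measured
stimulus deviations into predicted normalized JNDs: (1) constant
low-condition threshold contrast × measured background LMS content;
(2) additionally × the measured/nominal flicker-contrast ratio of each
condition; (3) the |L−M| contrast at the low-condition threshold held
constant, divided by each condition's |(L−M)/LMS| ratio (more chromatic
splatter predicts a lower threshold).  Predictions are normalized to the
low-condition median.  The constant predicted threshold is the
psychometric-fit threshold when supplied, the reversal threshold otherwise;
the at-threshold flicker spectra behind the measured ratios always come
from the reversal threshold.  With measured = nominal spectra the
predictors return exactly 1 per condition pair (for a constant threshold,
exactly 1 everywhere).  Sessions whose chromatic splatter is below 1e-9 in
both conditions cannot support chromatic mediation; their L−M prediction
degenerates to the background prediction instead of dividing numerical
noise by numerical noise.  Feeding predictor (1) melanopsin excitations of
the designed 350% pair instead of LMS contents yields the Weber-law
positive-control prediction: a 4.5× JND fold change.  Per-participant
aggregation is the median over sessions with the standard error of the
median approximated as 1.2533·SD/√n.

## Problem sizes and numerics

The shipped analysis drivers use 3 participants × 4 sessions (6 for the
admixed variant) × 2 conditions × 120 trials — the study's own structure —
and the replicate-based properties (parameter recovery, CI coverage) use
100 seeded single-observer replicates, enough to estimate a median relative
error or a coverage proportion to a few percent.  Solver tolerances:
silencing 1e-6 (Weber units), round-trip closure asserted at the same
level; fit bounds α ∈ [1e-6, 1], β ∈ [0.5·10⁻¹, 50], λ ∈ [0, 0.05] with
closed boundary treatment.  Degenerate inputs fail loudly: all-correct or
all-incorrect blocks (α unidentified), single-level data, zero background
excitations, criterion outside (γ, 1−λ), unpaired sessions, off-grid
spectra.

## Known limitations

* The sensitivity curves and lens template are synthetic, shaped like the
  physiological ones; absolute excitations are not comparable to any real
  calibrated device.  Real tabulated fundamentals drop in via CSV.
* The notch CI under-covers at small n (see above); it is retained because
  it is the convention this analysis chain defines, not because it is a
  good small-sample interval.
* The device model is linear with additive ambient; DLP gamma, optical
  cross-talk and temporal response are out of scope, as are adaptation
  dynamics and sequential dependencies in the observer.
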