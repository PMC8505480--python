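"""Silent-substitution stimulus design on a multiprimary device model.

A spectral synthesizer is modelled as a linear device: its output spectrum
is ``primary_basis @ settings + ambient`` with settings in [0, 1] per
primary.  Receptor excitations are therefore affine in the settings, which
makes the two design problems of the experiment tractable:

* a *background pair* — two spectra whose exchange produces a large target
  Weber contrast on melanopsin while silencing the L, M and S cones; and
* a *flicker modulation* — positive/negative arms around a background that
  put equal Weber contrast on all three cone classes while silencing
  melanopsin.

Both are solved jointly as a quadratic program with linear excitation
constraints (SLSQP), including explicit headroom constraints so that every
background admits its full-amplitude flicker arms inside the device gamut.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy.optimize import minimize

from .colorimetry import (
    CONE_LABELS,
    RECEPTOR_LABELS,
    GridMismatchError,
    ReceptorSensitivitySet,
    SpectralSamples,
    _same_grid,
    excitation,
    weber_contrast,
)

_L, _M, _S, _MEL = range(4)


class InfeasibleDesignError(RuntimeError):
    """A requested stimulus cannot be produced within the device gamut."""


@dataclass(frozen=True)
class DeviceModel:
    """Linear multiprimary light source with optional settings quantization.

    ``primary_basis`` has one column per primary on the wavelength grid
    (power per unit setting); ``ambient`` is a fixed spectrum added to every
    output (e.g. projector scatter light).  ``quantization_levels`` of None
    means continuous settings; an integer (e.g. 256 for an 8-bit driver)
    makes :meth:`quantize` round to that uniform grid.
    """

    wavelengths: np.ndarray
    primary_basis: np.ndarray
    ambient: SpectralSamples
    quantization_levels: int | None = None

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelengths, dtype=float)
        basis = np.asarray(self.primary_basis, dtype=float)
        if basis.ndim != 2 or basis.shape[0] != wl.size:
            raise ValueError(
                f"primary basis shape {basis.shape} does not match grid ({wl.size})"
            )
        if np.any(basis < 0):
            raise ValueError("primary spectra must be nonnegative")
        _same_grid(wl, self.ambient.wavelengths, "device grid and ambient")
        if self.quantization_levels is not None and self.quantization_levels < 2:
            raise ValueError("quantization_levels must be >= 2 (or None)")
        object.__setattr__(self, "wavelengths", wl)
        object.__setattr__(self, "primary_basis", basis)

    @property
    def n_primaries(self) -> int:
        return self.primary_basis.shape[1]

    def spectrum(self, settings: np.ndarray) -> SpectralSamples:
        """Render a settings vector to the emitted spectrum (incl. ambient)."""
        s = self._check_settings(settings)
        return SpectralSamples(
            self.wavelengths, self.primary_basis @ s + self.ambient.power
        )

    def quantize(self, settings: np.ndarray) -> np.ndarray:
        """Round settings to the device's uniform driver levels, clamped to [0,1]."""
        s = np.clip(np.asarray(settings, dtype=float), 0.0, 1.0)
        if self.quantization_levels is None:
            return s
        q = self.quantization_levels - 1
        return np.round(s * q) / q

    def excitation_system(
        self, sens: ReceptorSensitivitySet
    ) -> tuple[np.ndarray, np.ndarray]:
        """Affine map settings -> excitations: returns (M, e0) with e = M s + e0.

        Rows follow the L, M, S, Mel label order.
        """
        _same_grid(self.wavelengths, sens.wavelengths, "device and sensitivities")
        dl = float(self.wavelengths[1] - self.wavelengths[0])
        M = sens.matrix @ self.primary_basis * dl
        e0 = sens.matrix @ self.ambient.power * dl
        return M, e0

    def with_extra_ambient(self, extra: SpectralSamples) -> "DeviceModel":
        return replace(self, ambient=self.ambient + extra)

    def _check_settings(self, settings: np.ndarray) -> np.ndarray:
        s = np.asarray(settings, dtype=float)
        if s.shape != (self.n_primaries,):
            raise ValueError(
                f"settings shape {s.shape} does not match {self.n_primaries} primaries"
            )
        if np.any(s < -1e-9) or np.any(s > 1 + 1e-9):
            raise ValueError("settings outside device gamut [0, 1]")
        return np.clip(s, 0.0, 1.0)


@dataclass(frozen=True)
class ModulationSpec:
    """A background with symmetric flicker arms and their nominal contrasts."""

    device: DeviceModel
    background_settings: np.ndarray
    positive_arm_settings: np.ndarray
    negative_arm_settings: np.ndarray
    nominal_contrasts: dict[str, float]
    max_contrast: float = 0.05
    contrast_step: float = 0.001

    @property
    def arm_deviation(self) -> np.ndarray:
        """Settings-space deviation of the positive arm from the background."""
        return self.positive_arm_settings - self.background_settings


@dataclass(frozen=True)
class TimelineSegment:
    """One stretch of a trial: per-frame settings plus an interval flag."""

    label: str  # "interval-1", "isi", "interval-2", "ramp-up", ...
    duration_ms: float
    frames: np.ndarray  # (n_frames, n_primaries)


@dataclass(frozen=True)
class TrialTimeline:
    frame_rate: float
    segments: list[TimelineSegment]

    @property
    def duration_ms(self) -> float:
        return float(sum(seg.duration_ms for seg in self.segments))

    def all_frames(self) -> np.ndarray:
        return np.concatenate([seg.frames for seg in self.segments], axis=0)


def snap_contrast(nominal: float, step: float = 0.001) -> float:
    """Snap a nominal contrast to the step grid, rounding half away from zero."""
    sign = -1.0 if nominal < 0 else 1.0
    return sign * np.floor(abs(nominal) / step + 0.5) * step


def _contrasts_of_settings(device, sens, bg_settings, mod_settings):
    bg = excitation(device.spectrum(bg_settings), sens)
    mod = excitation(device.spectrum(mod_settings), sens)
    return weber_contrast(bg, mod)


def solve_background_pair(
    device: DeviceModel,
    sens: ReceptorSensitivitySet,
    target_mel_contrast: float = 3.5,
    cone_tolerance: float = 1e-6,
    *,
    max_contrast: float = 0.05,
    mode: str = "target",
    driven: tuple[str, ...] = ("Mel",),
    n_starts: int = 4,
    seed: int = 0,
    _report_max: bool = True,
) -> tuple[np.ndarray, np.ndarray]:
    """Design a silent-substitution low/high background pair.

    By default solves for low and high settings such that the high-vs-low
    Weber contrast is ``target_mel_contrast`` on melanopsin and zero on the
    L, M and S cones, with joint headroom constraints guaranteeing that
    each background admits melanopsin-silenced LMS flicker arms of
    amplitude ``max_contrast`` inside the gamut.  ``driven=('L','M','S')``
    swaps the roles (the luminance positive-control pair: equal contrast on
    every cone, melanopsin silenced).  ``mode='max'`` instead maximizes the
    driven contrast subject to the same constraints.

    Returns ``(low_settings, high_settings)``.  Raises
    :class:`InfeasibleDesignError` (reporting the best achievable driven
    contrast) when the target cannot be met.
    """
    if device.n_primaries < 4:
        warnings.warn(
            "fewer than 4 primaries: cone silencing and melanopsin direction "
            "may be unachievable simultaneously",
            stacklevel=2,
        )
    if mode not in ("target", "max"):
        raise ValueError(f"unknown mode {mode!r}")
    M, e0 = device.excitation_system(sens)
    P = device.n_primaries
    driven_idx = [RECEPTOR_LABELS.index(l) for l in driven]
    silent_idx = [i for i in range(4) if i not in driven_idx]
    if not driven_idx:
        raise ValueError("need at least one driven receptor")

    def unpack(x):
        return x[:P], x[P : 2 * P], x[2 * P : 3 * P], x[3 * P :]

    def cone_silence(x):
        # |Weber contrast| of each silenced receptor <= cone_tolerance,
        # written as two linear inequalities: tol * e_lo +/- (e_hi - e_lo) >= 0
        s_lo, s_hi, _, _ = unpack(x)
        e_lo = M[silent_idx] @ s_lo + e0[silent_idx]
        delta = M[silent_idx] @ (s_hi - s_lo)
        # 1% inner margin keeps the returned pair strictly within tolerance
        tol = 0.99 * cone_tolerance
        return np.concatenate([tol * e_lo - delta, tol * e_lo + delta])

    def make_mel_target(T):
        def mel_target(x):
            s_lo, s_hi, _, _ = unpack(x)
            return (M[driven_idx] @ s_hi + e0[driven_idx]) - (1.0 + T) * (
                M[driven_idx] @ s_lo + e0[driven_idx]
            )

        return mel_target

    def arm_constraints(x):
        s_lo, s_hi, d_lo, d_hi = unpack(x)
        out = np.empty(8)
        for i, (s, d) in enumerate(((s_lo, d_lo), (s_hi, d_hi))):
            e_bg = M[:_MEL] @ s + e0[:_MEL]
            out[4 * i : 4 * i + 3] = M[:_MEL] @ d - max_contrast * e_bg
            out[4 * i + 3] = M[_MEL] @ d
        return out

    def gamut(x):
        s_lo, s_hi, d_lo, d_hi = unpack(x)
        vals = []
        for s, d in ((s_lo, d_lo), (s_hi, d_hi)):
            vals.extend([s + d, 1.0 - (s + d), s - d, 1.0 - (s - d)])
        return np.concatenate(vals)

    with_arms = max_contrast > 0
    constraints = [{"type": "ineq", "fun": cone_silence}]
    if with_arms:
        # with zero arm amplitude the constraints M d = 0 are rank-deficient
        # (redundant equalities break SLSQP), so they are dropped and the
        # arm variables pinned at zero instead
        constraints.append({"type": "eq", "fun": arm_constraints})
        constraints.append({"type": "ineq", "fun": gamut})
    if mode == "target":
        constraints.append({"type": "eq", "fun": make_mel_target(target_mel_contrast)})

        def objective(x):
            s_lo, s_hi, d_lo, d_hi = unpack(x)
            return (
                np.sum((s_lo - 0.5) ** 2)
                + np.sum((s_hi - 0.5) ** 2)
                + 0.1 * (np.sum(d_lo**2) + np.sum(d_hi**2))
            )

    else:

        drv = driven_idx[0]

        def objective(x):
            s_lo, s_hi, _, _ = unpack(x)
            lo = M[drv] @ s_lo + e0[drv]
            hi = M[drv] @ s_hi + e0[drv]
            # maximize Weber contrast hi/lo - 1 <=> minimize lo/hi
            return lo / hi

        if len(driven_idx) > 1:
            # keep the driven contrasts equal to each other in max mode
            def driven_equal(x):
                s_lo, s_hi, _, _ = unpack(x)
                e_lo = M[driven_idx] @ s_lo + e0[driven_idx]
                e_hi = M[driven_idx] @ s_hi + e0[driven_idx]
                contrasts = e_hi / e_lo
                return contrasts[1:] - contrasts[0]

            constraints.append({"type": "eq", "fun": driven_equal})

    arm_bound = (-1.0, 1.0) if with_arms else (0.0, 0.0)
    bounds = [(0.0, 1.0)] * (2 * P) + [arm_bound] * (2 * P)
    rng = np.random.default_rng(seed)
    silent_labels = [RECEPTOR_LABELS[i] for i in silent_idx]
    best = None
    for start in range(n_starts):
        if start == 0:
            s0 = np.full(2 * P, 0.5)
        else:
            s0 = rng.uniform(0.15, 0.85, 2 * P)
        x0 = np.concatenate([s0, np.zeros(2 * P)])
        res = minimize(
            objective,
            x0,
            method="SLSQP",
            bounds=bounds,
            constraints=constraints,
            options={"maxiter": 600, "ftol": 1e-14},
        )
        s_lo, s_hi, _, _ = unpack(res.x)
        try:
            c = _contrasts_of_settings(device, sens, s_lo, s_hi)
        except ValueError:
            continue
        silence_err = max(abs(c[l]) for l in silent_labels)
        achieved = float(np.mean([c[RECEPTOR_LABELS[i]] for i in driven_idx]))
        if mode == "target":
            # the returned pair must strictly satisfy the contract
            if not res.success or silence_err > cone_tolerance + 1e-15:
                continue
            key = res.fun
        else:
            # ratio maximization: keep the best raw optimum even when SLSQP
            # stops on a line-search failure; it is polished to strict
            # feasibility below by a fixed-target re-solve
            key = -achieved
        if best is None or key < best[0]:
            best = (key, s_lo.copy(), s_hi.copy(), achieved, silence_err)
    if mode == "max":
        if best is None:
            raise InfeasibleDesignError(
                f"maximization of {'+'.join(driven)} contrast failed: no "
                "feasible point found"
            )
        achieved, silence_err = best[3], best[4]
        if silence_err <= cone_tolerance + 1e-15:
            pair = best[1], best[2]
        else:
            # polish: fix the driven contrast slightly below the raw optimum
            # and re-solve for strict feasibility, warm-started from it
            pair = None
            x_warm = np.concatenate([best[1], best[2], np.zeros(2 * P)])
            for backoff in (1.0 - 1e-9, 0.999, 0.99, 0.95, 0.9, 0.75, 0.5):
                polish_cons = constraints[:1 + (2 if with_arms else 0)] + [
                    {"type": "eq", "fun": make_mel_target(achieved * backoff)}
                ]
                res = minimize(
                    lambda x: np.sum((unpack(x)[0] - 0.5) ** 2)
                    + np.sum((unpack(x)[1] - 0.5) ** 2),
                    x_warm,
                    method="SLSQP",
                    bounds=bounds,
                    constraints=polish_cons,
                    options={"maxiter": 600, "ftol": 1e-14},
                )
                s_lo, s_hi, _, _ = unpack(res.x)
                try:
                    c = _contrasts_of_settings(device, sens, s_lo, s_hi)
                except ValueError:
                    continue
                # accept on verified constraints, not on the SLSQP status
                # flag (line-search stalls are common this close to the
                # gamut boundary)
                got = float(np.mean([c[RECEPTOR_LABELS[i]] for i in driven_idx]))
                ok_silence = (
                    max(abs(c[l]) for l in silent_labels)
                    <= cone_tolerance + 1e-15
                )
                ok_target = abs(got - achieved * backoff) <= 1e-6 * (
                    1 + abs(achieved)
                )
                if not (ok_silence and ok_target):
                    continue
                if with_arms:
                    try:
                        for bg in (s_lo, s_hi):
                            solve_flicker_modulation(
                                device, sens, bg, lms_target=max_contrast
                            )
                    except InfeasibleDesignError:
                        continue
                pair = s_lo.copy(), s_hi.copy()
                break
            if pair is None:
                raise InfeasibleDesignError(
                    f"maximization of {'+'.join(driven)} contrast found "
                    f"{achieved:.4g} but no strictly feasible pair near it"
                )
        c = _contrasts_of_settings(device, sens, *pair)
        got = float(np.mean([c[RECEPTOR_LABELS[i]] for i in driven_idx]))
        if got < target_mel_contrast - 1e-9:
            warnings.warn(
                f"maximized {'+'.join(driven)} contrast {got:.4g} falls short "
                f"of the requested target {target_mel_contrast:.3g}",
                stacklevel=2,
            )
        return pair
    if best is None or abs(best[3] - target_mel_contrast) > 1e-6:
        if not _report_max:
            raise InfeasibleDesignError(
                f"target {target_mel_contrast:.4g} infeasible"
            )
        achievable = _max_achievable(
            device, sens, cone_tolerance, max_contrast, driven, seed
        )
        raise InfeasibleDesignError(
            f"silenced-receptor contrast target {target_mel_contrast:.3g} on "
            f"{'+'.join(driven)} not achievable on this device; best "
            f"achievable ≈ {achievable:.4g}"
        )
    return best[1], best[2]


def _max_achievable(
    device, sens, cone_tolerance, max_contrast, driven, seed
) -> float:
    try:
        lo, hi = solve_background_pair(
            device,
            sens,
            target_mel_contrast=0.0,
            cone_tolerance=cone_tolerance,
            max_contrast=max_contrast,
            mode="max",
            driven=driven,
            seed=seed,
        )
    except InfeasibleDesignError:
        return 0.0
    c = _contrasts_of_settings(device, sens, lo, hi)
    return float(np.mean([c[l] for l in driven]))


def solve_flicker_modulation(
    device: DeviceModel,
    sens: ReceptorSensitivitySet,
    background_settings: np.ndarray,
    lms_target: float = 0.05,
    mel_tolerance: float = 1e-6,
    *,
    contrast_step: float = 0.001,
) -> ModulationSpec:
    """Design melanopsin-silenced LMS flicker arms around a background.

    The positive arm puts Weber contrast ``+lms_target`` on each of L, M
    and S while holding melanopsin constant; the negative arm mirrors it.
    Excitations are affine in settings, so the arm deviation solves a
    linear system; the minimum-norm solution is taken, with a constrained
    fallback when it would leave the gamut.
    """
    bg = np.asarray(background_settings, dtype=float)
    M, e0 = device.excitation_system(sens)
    e_bg = M @ bg + e0
    if np.any(e_bg[:_MEL] <= 0):
        raise InfeasibleDesignError("background has zero cone excitation")
    target = np.empty(4)
    target[:_MEL] = lms_target * e_bg[:_MEL]
    target[_MEL] = 0.0
    # minimum-norm deviation solving M d = target
    d, *_ = np.linalg.lstsq(M, target, rcond=None)
    if _out_of_gamut(bg, d):
        d = _constrained_arm(M, target, bg)
    pos = bg + d
    neg = bg - d
    c_pos = _contrasts_of_settings(device, sens, bg, pos)
    residual = max(
        max(abs(c_pos[l] - lms_target) for l in CONE_LABELS), abs(c_pos["Mel"])
    )
    if abs(c_pos["Mel"]) > mel_tolerance or residual > max(mel_tolerance, 1e-6):
        raise InfeasibleDesignError(
            f"flicker arms infeasible at LMS target {lms_target:.3g}: residual "
            f"contrast error {residual:.3g} (melanopsin {c_pos['Mel']:.3g})"
        )
    nominal = {l: lms_target for l in CONE_LABELS}
    nominal["Mel"] = 0.0
    return ModulationSpec(
        device=device,
        background_settings=bg,
        positive_arm_settings=pos,
        negative_arm_settings=neg,
        nominal_contrasts=nominal,
        max_contrast=abs(lms_target),
        contrast_step=contrast_step,
    )


def _out_of_gamut(bg: np.ndarray, d: np.ndarray, tol: float = 1e-12) -> bool:
    return bool(
        np.any(bg + d > 1 + tol)
        or np.any(bg + d < -tol)
        or np.any(bg - d > 1 + tol)
        or np.any(bg - d < -tol)
    )


def _constrained_arm(M: np.ndarray, target: np.ndarray, bg: np.ndarray) -> np.ndarray:
    P = bg.size
    cons = [
        {"type": "eq", "fun": lambda d: M @ d - target},
        {
            "type": "ineq",
            "fun": lambda d: np.concatenate(
                [bg + d, 1 - (bg + d), bg - d, 1 - (bg - d)]
            ),
        },
    ]
    res = minimize(
        lambda d: np.sum(d**2),
        np.zeros(P),
        method="SLSQP",
        constraints=cons,
        options={"maxiter": 400, "ftol": 1e-16},
    )
    if not res.success:
        raise InfeasibleDesignError(
            "flicker arms cannot be fit inside the device gamut"
        )
    return res.x


def scale_modulation(
    spec: ModulationSpec, nominal_contrast: float
) -> tuple[SpectralSamples, SpectralSamples]:
    """Render the arm spectra at a staircase-requested nominal contrast.

    The contrast is first snapped to the 0.1% grid (rounding half away from
    zero), then the settings-space arm deviations are scaled by
    ``nominal / max_contrast`` and rendered through the device.
    """
    if nominal_contrast < 0 or nominal_contrast > spec.max_contrast + 1e-12:
        raise ValueError(
            f"nominal contrast {nominal_contrast} outside [0, {spec.max_contrast}]"
        )
    snapped = snap_contrast(nominal_contrast, spec.contrast_step)
    scale = snapped / spec.max_contrast
    d = spec.arm_deviation * scale
    pos = spec.device.spectrum(spec.background_settings + d)
    neg = spec.device.spectrum(spec.background_settings - d)
    return pos, neg


def apply_scatter_correction(
    spec: ModulationSpec,
    scatter: SpectralSamples,
    sens: ReceptorSensitivitySet,
) -> ModulationSpec:
    """Re-solve the flicker arms so contrasts hold on (device output + scatter).

    Additive scatter light (e.g. from an admixed projector) dilutes Weber
    contrast; the corrected arms restore the nominal receptor contrasts as
    computed on the physically delivered spectrum.
    """
    _same_grid(
        spec.device.wavelengths, scatter.wavelengths, "device and scatter spectrum"
    )
    corrected_device = spec.device.with_extra_ambient(scatter)
    lms_target = spec.nominal_contrasts["L"]
    return solve_flicker_modulation(
        corrected_device,
        sens,
        spec.background_settings,
        lms_target=lms_target,
        contrast_step=spec.contrast_step,
    )


def pedestal_waveform(
    low_settings: np.ndarray,
    high_settings: np.ndarray,
    ramp_ms: float = 500.0,
    frame_rate: float = 60.0,
    *,
    descending: bool = False,
) -> TimelineSegment:
    """Half-cosine ramp between two backgrounds, interpolated in settings space.

    ``w(t) = low + 0.5 (1 - cos(pi t / T)) (high - low)`` sampled on an
    inclusive frame grid over [0, T], so the first frame is exactly ``low``
    and the last exactly ``high`` (reversed when ``descending``).
    """
    if ramp_ms <= 0:
        raise ValueError("ramp duration must be positive")
    low = np.asarray(low_settings, dtype=float)
    high = np.asarray(high_settings, dtype=float)
    n_frames = int(round(ramp_ms / 1000.0 * frame_rate)) + 1
    t = np.linspace(0.0, ramp_ms, n_frames)
    w = 0.5 * (1.0 - np.cos(np.pi * t / ramp_ms))
    frames = low[None, :] + w[:, None] * (high - low)[None, :]
    if descending:
        frames = frames[::-1]
    label = "ramp-down" if descending else "ramp-up"
    return TimelineSegment(label=label, duration_ms=float(ramp_ms), frames=frames)


def flicker_waveform(
    spec: ModulationSpec,
    nominal_contrast: float,
    frequency: float = 5.0,
    duration_ms: float = 500.0,
    frame_rate: float = 60.0,
    *,
    label: str = "interval",
) -> TimelineSegment:
    """Sinusoidal flicker segment around the background at a nominal contrast.

    Frame ``f`` at time ``t = f / frame_rate`` shows the background plus
    ``sin(2 pi frequency t)`` times the scaled positive-arm deviation (the
    negative half-cycles are the mirrored negative arm).  A zero contrast
    yields constant background frames — the reference interval.
    """
    if frequency > frame_rate / 2.0:
        raise ValueError(
            f"flicker frequency {frequency} Hz exceeds the Nyquist limit "
            f"of the {frame_rate} Hz frame rate"
        )
    snapped = snap_contrast(nominal_contrast, spec.contrast_step)
    if snapped < 0 or snapped > spec.max_contrast + 1e-12:
        raise ValueError(
            f"nominal contrast {nominal_contrast} outside [0, {spec.max_contrast}]"
        )
    scale = snapped / spec.max_contrast
    n_frames = int(round(duration_ms / 1000.0 * frame_rate))
    t = np.arange(n_frames) / frame_rate
    weights = scale * np.sin(2.0 * np.pi * frequency * t)
    frames = (
        spec.background_settings[None, :]
        + weights[:, None] * spec.arm_deviation[None, :]
    )
    return TimelineSegment(label=label, duration_ms=float(duration_ms), frames=frames)
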