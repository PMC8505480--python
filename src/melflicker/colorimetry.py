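"""Photoreceptor colorimetry: excitations and Weber contrasts from spectra.

The quantities computed here are the basic currency of silent-substitution
work: a spectral power distribution is converted to one excitation per
photoreceptor class (L, M, S cones and melanopsin) by multiplying with the
class's spectral sensitivity and summing over wavelength, and stimuli are
compared through Weber contrasts of those excitations.  All sensitivities
are normalized to a peak of one, so excitations are in (power units x nm)
and carry no absolute photometric meaning; every downstream statistic is a
contrast or a normalized ratio, which is why that suffices.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

RECEPTOR_LABELS = ("L", "M", "S", "Mel")
CONE_LABELS = ("L", "M", "S")

#: Default wavelength support, nm.
DEFAULT_WL_START = 380.0
DEFAULT_WL_STOP = 780.0
DEFAULT_WL_STEP = 2.0

_GRID_ATOL = 1e-9


def default_wavelength_grid() -> np.ndarray:
    """The 380-780 nm grid in 2 nm steps used throughout the package."""
    n = int(round((DEFAULT_WL_STOP - DEFAULT_WL_START) / DEFAULT_WL_STEP)) + 1
    return DEFAULT_WL_START + DEFAULT_WL_STEP * np.arange(n)


class GridMismatchError(ValueError):
    """Raised when two spectral objects live on different wavelength grids."""


def _check_grid(wavelengths: np.ndarray) -> float:
    """Validate a strictly ascending uniform grid; return its spacing."""
    wl = np.asarray(wavelengths, dtype=float)
    if wl.ndim != 1 or wl.size < 2:
        raise ValueError("wavelength grid must be 1-D with at least 2 samples")
    steps = np.diff(wl)
    if np.any(steps <= 0):
        raise ValueError("wavelength grid must be strictly ascending")
    if np.ptp(steps) > _GRID_ATOL:
        raise ValueError(
            f"wavelength grid spacing not uniform (spread {np.ptp(steps):.3g} nm)"
        )
    return float(steps[0])


def _same_grid(a: np.ndarray, b: np.ndarray, what: str = "operands") -> None:
    if a.shape != b.shape or not np.allclose(a, b, atol=_GRID_ATOL, rtol=0.0):
        raise GridMismatchError(
            f"wavelength grids of {what} differ: "
            f"[{a[0]}..{a[-1]}] n={a.size} vs [{b[0]}..{b[-1]}] n={b.size}"
        )


@dataclass(frozen=True)
class SpectralSamples:
    """A nonnegative spectral power distribution on a uniform wavelength grid."""

    wavelengths: np.ndarray
    power: np.ndarray

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelengths, dtype=float)
        p = np.asarray(self.power, dtype=float)
        _check_grid(wl)
        if p.shape != wl.shape:
            raise ValueError(
                f"power has {p.shape} samples but grid has {wl.shape}"
            )
        if np.any(p < 0):
            raise ValueError("spectral power must be nonnegative everywhere")
        object.__setattr__(self, "wavelengths", wl)
        object.__setattr__(self, "power", p)

    @property
    def delta_lambda(self) -> float:
        """Grid spacing in nm."""
        return float(self.wavelengths[1] - self.wavelengths[0])

    def __add__(self, other: "SpectralSamples") -> "SpectralSamples":
        _same_grid(self.wavelengths, other.wavelengths, "spectra being added")
        return SpectralSamples(self.wavelengths, self.power + other.power)

    def scaled(self, factor: float) -> "SpectralSamples":
        if factor < 0:
            raise ValueError("scale factor must be nonnegative")
        return SpectralSamples(self.wavelengths, self.power * factor)

    @classmethod
    def zeros(cls, wavelengths: np.ndarray) -> "SpectralSamples":
        wl = np.asarray(wavelengths, dtype=float)
        return cls(wl, np.zeros_like(wl))

    @classmethod
    def from_csv(cls, path) -> "SpectralSamples":
        """Read a spectrum CSV with columns ``wavelength_nm, power``."""
        df = pd.read_csv(path)
        return cls(df["wavelength_nm"].to_numpy(), df["power"].to_numpy())

    def to_csv(self, path) -> None:
        pd.DataFrame(
            {"wavelength_nm": self.wavelengths, "power": self.power}
        ).to_csv(path, index=False)


@dataclass(frozen=True)
class ReceptorSensitivitySet:
    """L, M, S and melanopsin spectral sensitivities, each peak-normalized to 1.

    ``field_size``, ``observer_age`` and ``pupil_diameter`` are carried as
    metadata only: the analyses work in Weber contrast and normalized JNDs,
    so no retinal-irradiance conversion is ever performed.
    """

    wavelengths: np.ndarray
    curves: dict[str, np.ndarray]
    field_size: float = 27.5
    observer_age: float = 32.0
    pupil_diameter: float = 6.0

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelengths, dtype=float)
        _check_grid(wl)
        normalized: dict[str, np.ndarray] = {}
        for label in RECEPTOR_LABELS:
            if label not in self.curves:
                raise ValueError(f"missing sensitivity curve for {label!r}")
            curve = np.asarray(self.curves[label], dtype=float)
            if curve.shape != wl.shape:
                raise ValueError(
                    f"curve {label!r} has {curve.shape} samples, grid has {wl.shape}"
                )
            if np.any(curve < 0):
                raise ValueError(f"curve {label!r} has negative values")
            peak = curve.max()
            if peak <= 0:
                raise ValueError(f"curve {label!r} is identically zero")
            normalized[label] = curve / peak
        object.__setattr__(self, "wavelengths", wl)
        object.__setattr__(self, "curves", normalized)

    @property
    def matrix(self) -> np.ndarray:
        """Sensitivities stacked as a (4, n_wavelengths) array in L,M,S,Mel order."""
        return np.stack([self.curves[l] for l in RECEPTOR_LABELS])

    @classmethod
    def from_csv(cls, path, **metadata) -> "ReceptorSensitivitySet":
        """Read sensitivities from a CSV with columns wavelength_nm, L, M, S, Mel."""
        df = pd.read_csv(path)
        curves = {l: df[l].to_numpy() for l in RECEPTOR_LABELS}
        return cls(df["wavelength_nm"].to_numpy(), curves, **metadata)

    def to_csv(self, path) -> None:
        out = {"wavelength_nm": self.wavelengths}
        out.update({l: self.curves[l] for l in RECEPTOR_LABELS})
        pd.DataFrame(out).to_csv(path, index=False)


@dataclass(frozen=True)
class ReceptorExcitations:
    """One nonnegative excitation per receptor class, units power x nm."""

    values: dict[str, float]

    def __post_init__(self) -> None:
        vals = {l: float(self.values[l]) for l in RECEPTOR_LABELS}
        object.__setattr__(self, "values", vals)

    def __getitem__(self, label: str) -> float:
        return self.values[label]

    def as_array(self) -> np.ndarray:
        return np.array([self.values[l] for l in RECEPTOR_LABELS])


@dataclass(frozen=True)
class ReceptorContrasts:
    """Per-receptor Weber contrasts plus the derived LMS summary scalars."""

    values: dict[str, float]
    lms_contrast: float
    lm_contrast: float
    lm_over_lms: float | None

    def __getitem__(self, label: str) -> float:
        return self.values[label]


def excitation(
    spd: SpectralSamples, sens: ReceptorSensitivitySet
) -> ReceptorExcitations:
    """Receptor excitations of a spectrum: e_r = sum_lambda S_r * Phi * d_lambda.

    A rectangle-rule sum over the shared uniform grid; exactly linear in the
    spectrum.
    """
    _same_grid(spd.wavelengths, sens.wavelengths, "spectrum and sensitivities")
    dl = spd.delta_lambda
    vals = sens.matrix @ spd.power * dl
    return ReceptorExcitations(dict(zip(RECEPTOR_LABELS, vals)))


def weber_contrast(
    background: ReceptorExcitations, modulated: ReceptorExcitations
) -> ReceptorContrasts:
    """Per-receptor Weber contrast (e_mod - e_bg)/e_bg and LMS summaries.

    ``lms_contrast`` is the equally weighted mean of the three cone
    contrasts, so a nominal modulation of +5% on each cone has
    ``lms_contrast == 0.05``.  ``lm_over_lms`` is the chromatic-splatter
    ratio (c_L - c_M)/lms_contrast, or None when lms_contrast is zero.
    """
    vals: dict[str, float] = {}
    for label in RECEPTOR_LABELS:
        bg = background[label]
        if bg <= 0:
            raise ValueError(
                f"Weber contrast undefined: background excitation for {label!r} "
                f"is {bg} (must be > 0)"
            )
        vals[label] = (modulated[label] - bg) / bg
    lms = float(np.mean([vals[l] for l in CONE_LABELS]))
    lm = vals["L"] - vals["M"]
    ratio = lm / lms if lms != 0.0 else None
    return ReceptorContrasts(vals, lms_contrast=lms, lm_contrast=lm, lm_over_lms=ratio)


def lms_content(exc: ReceptorExcitations, *, convention: str = "mean") -> float:
    """Combined LMS cone coordinate of a stimulus.

    The package convention is the unweighted mean of the L, M and S
    excitations; the sum differs only by a fixed factor of 3, and every
    normalized quantity downstream is invariant to the choice.
    """
    cone_vals = [exc[l] for l in CONE_LABELS]
    if convention == "mean":
        return float(np.mean(cone_vals))
    if convention == "sum":
        return float(np.sum(cone_vals))
    raise ValueError(f"unknown convention {convention!r} (use 'mean' or 'sum')")


def lms_contrast(
    background: ReceptorExcitations, modulated: ReceptorExcitations
) -> float:
    """Equally weighted mean of the three cone Weber contrasts."""
    return weber_contrast(background, modulated).lms_contrast


def lm_over_lms(
    background: ReceptorExcitations, modulated: ReceptorExcitations
) -> float:
    """Chromatic splatter ratio (c_L - c_M) / lms_contrast of a modulation."""
    c = weber_contrast(background, modulated)
    if c.lm_over_lms is None:
        raise ValueError("lm_over_lms undefined: LMS contrast is zero")
    return c.lm_over_lms


# --- age-dependent lens density adjustment ----------------------------------

#: Validity range, years, of the lens-density age model.
LENS_AGE_RANGE = (20.0, 80.0)
LENS_REFERENCE_AGE = 32.0


def lens_density_template(wavelengths: np.ndarray) -> np.ndarray:
    """Synthetic lens optical-density template (density units, base-10).

    A smooth, physiologically shaped stand-in for a tabulated human lens
    density curve: monotonically decreasing with wavelength, substantial in
    the violet and negligible beyond ~650 nm.  It is a synthetic fixture,
    not a standards-body table; the adjustment machinery accepts any
    tabulated template on the working grid in its place.
    """
    wl = np.asarray(wavelengths, dtype=float)
    return 1.6 * np.exp(-(wl - 380.0) / 60.0)


def lens_adjusted_sensitivities(
    base: ReceptorSensitivitySet,
    observer_age: float,
    *,
    template: np.ndarray | None = None,
) -> ReceptorSensitivitySet:
    """Adjust sensitivities for age-predicted lens density.

    The base curves are taken to describe a reference observer of age 32;
    for another age the curves are multiplied by the transmittance change
    relative to that reference, ``10**(-(s(age) - 1) * D(lambda))`` with the
    linear age scaling ``s(age) = 1 + 0.02 * (age - 32)``, then renormalized
    to peak 1.  At the reference age the curves are unchanged exactly.
    """
    lo, hi = LENS_AGE_RANGE
    if not (lo <= observer_age <= hi):
        raise ValueError(
            f"observer age {observer_age} outside lens-model validity range "
            f"[{lo}, {hi}] years"
        )
    if template is None:
        template = lens_density_template(base.wavelengths)
    template = np.asarray(template, dtype=float)
    if template.shape != base.wavelengths.shape:
        raise GridMismatchError("lens density template not on the sensitivity grid")
    scale = 1.0 + 0.02 * (observer_age - LENS_REFERENCE_AGE)
    transmittance = 10.0 ** (-(scale - 1.0) * template)
    curves = {l: base.curves[l] * transmittance for l in RECEPTOR_LABELS}
    return replace(base, curves=curves, observer_age=float(observer_age))


def synthetic_sensitivities(
    wavelengths: np.ndarray | None = None, **metadata
) -> ReceptorSensitivitySet:
    """Synthetic physiologically shaped L/M/S/Mel sensitivity fixture.

    Four smooth unimodal (log-normal in wavelength) curves peaking near
    560/530/440/480 nm for L/M/S/Mel, peak-normalized.  Shaped like real
    photoreceptor fundamentals but not taken from any standards table;
    real tabulated fundamentals drop in via ReceptorSensitivitySet.from_csv.
    """
    if wavelengths is None:
        wavelengths = default_wavelength_grid()
    wl = np.asarray(wavelengths, dtype=float)
    peaks = {"L": 560.0, "M": 530.0, "S": 440.0, "Mel": 480.0}
    widths = {"L": 0.055, "M": 0.055, "S": 0.050, "Mel": 0.060}
    curves = {
        label: np.exp(-0.5 * (np.log(wl / peaks[label]) / widths[label]) ** 2)
        for label in RECEPTOR_LABELS
    }
    return ReceptorSensitivitySet(wl, curves, **metadata)
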