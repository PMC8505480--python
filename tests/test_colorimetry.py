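import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from melflicker.colorimetry import (
    GridMismatchError,
    ReceptorExcitations,
    ReceptorSensitivitySet,
    SpectralSamples,
    default_wavelength_grid,
    excitation,
    lens_adjusted_sensitivities,
    lens_density_template,
    lm_over_lms,
    lms_content,
    lms_contrast,
    synthetic_sensitivities,
    weber_contrast,
)


def flat_sens(wl, value=1.0):
    curves = {l: np.full_like(wl, value) for l in ("L", "M", "S", "Mel")}
    return ReceptorSensitivitySet(wl, curves)


class TestSpectralSamples:
    def test_rejects_negative_power(self):
        wl = default_wavelength_grid()
        with pytest.raises(ValueError, match="nonnegative"):
            SpectralSamples(wl, np.full_like(wl, -1.0))

    def test_rejects_nonuniform_grid(self):
        wl = np.array([380.0, 382.0, 385.0])
        with pytest.raises(ValueError, match="uniform"):
            SpectralSamples(wl, np.ones(3))

    def test_csv_round_trip(self, tmp_path):
        wl = default_wavelength_grid()
        spd = SpectralSamples(wl, np.linspace(0, 2, wl.size))
        spd.to_csv(tmp_path / "s.csv")
        back = SpectralSamples.from_csv(tmp_path / "s.csv")
        np.testing.assert_allclose(back.power, spd.power)


class TestExcitation:
    def test_flat_spectrum_rectangle_rule(self):
        # 11-point grid, step 10 nm, unit sensitivity, unit power -> 11*10
        wl = 400.0 + 10.0 * np.arange(11)
        spd = SpectralSamples(wl, np.ones(11))
        exc = excitation(spd, flat_sens(wl))
        for label in ("L", "M", "S", "Mel"):
            assert exc[label] == pytest.approx(110.0)

    def test_zero_spectrum_gives_zero(self, sens):
        exc = excitation(SpectralSamples.zeros(sens.wavelengths), sens)
        assert all(exc[l] == 0.0 for l in ("L", "M", "S", "Mel"))

    def test_grid_mismatch_is_explicit(self, sens):
        wl = 400.0 + 10.0 * np.arange(11)
        with pytest.raises(GridMismatchError, match="grids"):
            excitation(SpectralSamples(wl, np.ones(11)), sens)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(
        a=st.floats(0.0, 10.0, allow_subnormal=False),
        b=st.floats(0.0, 10.0, allow_subnormal=False),
        seed=st.integers(0, 2**16),
    )
    def test_linearity(self, sens, a, b, seed):
        """excitation(a*p1 + b*p2) == a*excitation(p1) + b*excitation(p2)."""
        rng = np.random.default_rng(seed)
        wl = sens.wavelengths
        p1 = SpectralSamples(wl, rng.uniform(0, 1, wl.size))
        p2 = SpectralSamples(wl, rng.uniform(0, 1, wl.size))
        combo = SpectralSamples(wl, a * p1.power + b * p2.power)
        e1, e2, ec = (excitation(p, sens) for p in (p1, p2, combo))
        np.testing.assert_allclose(
            ec.as_array(), a * e1.as_array() + b * e2.as_array(),
            rtol=1e-12, atol=1e-12,
        )


class TestWeberContrast:
    def test_350_percent_is_4p5_fold(self):
        bg = ReceptorExcitations({"L": 1, "M": 1, "S": 1, "Mel": 1.0})
        mod = ReceptorExcitations({"L": 1, "M": 1, "S": 1, "Mel": 4.5})
        assert weber_contrast(bg, mod)["Mel"] == pytest.approx(3.5)

    def test_self_contrast_zero_and_sign(self):
        bg = ReceptorExcitations({"L": 2, "M": 2, "S": 2, "Mel": 2})
        assert all(weber_contrast(bg, bg)[l] == 0.0 for l in ("L", "M", "S", "Mel"))
        mod = ReceptorExcitations({"L": 1, "M": 2, "S": 2, "Mel": 2})
        assert weber_contrast(bg, mod)["L"] == pytest.approx(-0.5)

    def test_zero_background_is_error(self):
        bg = ReceptorExcitations({"L": 0, "M": 1, "S": 1, "Mel": 1})
        with pytest.raises(ValueError, match="undefined"):
            weber_contrast(bg, bg)

    def test_scale_invariance(self, sens):
        rng = np.random.default_rng(5)
        wl = sens.wavelengths
        p1 = SpectralSamples(wl, rng.uniform(0.1, 1, wl.size))
        p2 = SpectralSamples(wl, rng.uniform(0.1, 1, wl.size))
        c1 = weber_contrast(excitation(p1, sens), excitation(p2, sens))
        c2 = weber_contrast(
            excitation(p1.scaled(3.7), sens), excitation(p2.scaled(3.7), sens)
        )
        for l in ("L", "M", "S", "Mel"):
            assert c1[l] == pytest.approx(c2[l], rel=1e-12)


class TestLmsSummaries:
    def test_lms_content_conventions(self):
        exc = ReceptorExcitations({"L": 1, "M": 2, "S": 3, "Mel": 0.1})
        assert lms_content(exc) == pytest.approx(2.0)
        assert lms_content(exc, convention="sum") == pytest.approx(6.0)

    @pytest.mark.parametrize(
        "cones, expected",
        [((0.05, 0.05, 0.05), 0.05), ((0.05, -0.05, 0.0), 0.0),
         ((0.03, 0.04, 0.05), 0.04)],
    )
    def test_lms_contrast_is_mean_of_cone_contrasts(self, cones, expected):
        bg = ReceptorExcitations({"L": 1, "M": 1, "S": 1, "Mel": 1})
        mod = ReceptorExcitations(
            {"L": 1 + cones[0], "M": 1 + cones[1], "S": 1 + cones[2], "Mel": 1}
        )
        assert lms_contrast(bg, mod) == pytest.approx(expected)

    def test_lm_over_lms(self):
        bg = ReceptorExcitations({"L": 1, "M": 1, "S": 1, "Mel": 1})
        mod = ReceptorExcitations({"L": 1.055, "M": 1.050, "S": 1.045, "Mel": 1})
        assert lm_over_lms(bg, mod) == pytest.approx(0.1)
        # homogeneity: scaling the modulation deviation leaves the ratio fixed
        mod2 = ReceptorExcitations({"L": 1.11, "M": 1.10, "S": 1.09, "Mel": 1})
        assert lm_over_lms(bg, mod2) == pytest.approx(0.1)

    def test_lm_over_lms_zero_lms_is_error(self):
        bg = ReceptorExcitations({"L": 1, "M": 1, "S": 1, "Mel": 1})
        mod = ReceptorExcitations({"L": 1.05, "M": 0.95, "S": 1.0, "Mel": 1})
        with pytest.raises(ValueError, match="zero"):
            lm_over_lms(bg, mod)

    def test_normalized_ratio_invariant_to_sum_vs_mean(self, sens):
        """The sum and mean conventions differ by a fixed factor of 3, so any
        normalized content ratio is identical under either convention."""
        rng = np.random.default_rng(11)
        wl = sens.wavelengths
        excs = [
            excitation(SpectralSamples(wl, rng.uniform(0.1, 1, wl.size)), sens)
            for _ in range(4)
        ]
        mean_vals = np.array([lms_content(e) for e in excs])
        sum_vals = np.array([lms_content(e, convention="sum") for e in excs])
        np.testing.assert_allclose(
            mean_vals / np.median(mean_vals), sum_vals / np.median(sum_vals),
            rtol=1e-12,
        )


class TestLensAdjustment:
    def test_reference_age_is_identity(self, sens):
        adjusted = lens_adjusted_sensitivities(sens, 32.0)
        for l in ("L", "M", "S", "Mel"):
            np.testing.assert_allclose(adjusted.curves[l], sens.curves[l])

    def test_all_ones_template_is_identity(self, sens):
        template = np.zeros_like(sens.wavelengths)  # zero density = unit transmittance
        adjusted = lens_adjusted_sensitivities(sens, 60.0, template=template)
        for l in ("L", "M", "S", "Mel"):
            np.testing.assert_allclose(adjusted.curves[l], sens.curves[l])

    def test_age_outside_range_errors(self, sens):
        with pytest.raises(ValueError, match=r"\[20.0, 80.0\]"):
            lens_adjusted_sensitivities(sens, 15.0)

    def test_aging_depresses_short_wavelengths(self, sens):
        """Ratio of sensitivity at 420 nm vs 560 nm is non-increasing in age,
        checked against direct multiplication by the packaged template."""
        wl = sens.wavelengths
        i420 = int(np.argmin(np.abs(wl - 420)))
        i560 = int(np.argmin(np.abs(wl - 560)))
        prev = np.inf
        for age in (25, 32, 45, 60, 75):
            adj = lens_adjusted_sensitivities(sens, age)
            ratio = adj.curves["Mel"][i420] / adj.curves["Mel"][i560]
            # oracle: direct multiplication by the template transmittance
            t = 10 ** (-(0.02 * (age - 32)) * lens_density_template(wl))
            direct = (sens.curves["Mel"] * t)
            assert ratio == pytest.approx(direct[i420] / direct[i560], rel=1e-12)
            assert ratio <= prev + 1e-15
            prev = ratio


def test_synthetic_sensitivities_are_valid_and_peak_normalized():
    s = synthetic_sensitivities()
    for label, peak_nm in (("S", 440), ("Mel", 480), ("M", 530), ("L", 560)):
        curve = s.curves[label]
        assert curve.max() == pytest.approx(1.0)
        peak_at = s.wavelengths[np.argmax(curve)]
        assert abs(peak_at - peak_nm) <= 2.0
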