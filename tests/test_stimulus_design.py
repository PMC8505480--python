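import numpy as np
import pytest

from melflicker.colorimetry import (
    SpectralSamples,
    excitation,
    lms_contrast,
    weber_contrast,
)
from melflicker.stimulus_design import (
    DeviceModel,
    InfeasibleDesignError,
    apply_scatter_correction,
    flicker_waveform,
    pedestal_waveform,
    scale_modulation,
    snap_contrast,
    solve_background_pair,
    solve_flicker_modulation,
)
from melflicker.synthetic_data import make_synthetic_device


def contrasts(device, sens, s_lo, s_hi):
    return weber_contrast(
        excitation(device.spectrum(s_lo), sens),
        excitation(device.spectrum(s_hi), sens),
    )


class TestDeviceModel:
    def test_output_is_basis_times_settings_plus_ambient(self, sens):
        wl = sens.wavelengths
        basis = np.ones((wl.size, 3))
        ambient = SpectralSamples(wl, np.full(wl.size, 0.25))
        dev = DeviceModel(wl, basis, ambient)
        out = dev.spectrum(np.array([0.1, 0.2, 0.3]))
        np.testing.assert_allclose(out.power, 0.6 + 0.25)

    def test_quantize_rounds_to_driver_levels(self, sens):
        wl = sens.wavelengths
        dev = DeviceModel(
            wl, np.ones((wl.size, 2)), SpectralSamples.zeros(wl),
            quantization_levels=256,
        )
        q = dev.quantize(np.array([0.5001, 1.2]))
        assert np.all(q * 255 == np.round(q * 255))
        assert q[1] == 1.0  # clamped

    def test_settings_out_of_gamut_rejected(self, device):
        with pytest.raises(ValueError, match="gamut"):
            device.spectrum(np.full(device.n_primaries, 1.5))


class TestBackgroundPair:
    def test_melanopic_pair_hits_350_percent_with_silent_cones(
        self, device, sens, background_pair
    ):
        low, high = background_pair
        c = contrasts(device, sens, low, high)
        assert c["Mel"] == pytest.approx(3.5, abs=1e-6)
        for l in ("L", "M", "S"):
            assert abs(c[l]) <= 1e-6
        e_lo = excitation(device.spectrum(low), sens)
        e_hi = excitation(device.spectrum(high), sens)
        assert e_hi["Mel"] / e_lo["Mel"] == pytest.approx(4.5, abs=1e-5)

    def test_target_zero_accepts_identity(self, device, sens):
        low, high = solve_background_pair(device, sens, target_mel_contrast=0.0)
        c = contrasts(device, sens, low, high)
        assert abs(c["Mel"]) < 1e-9

    def test_headroom_admits_full_arms(self, device, sens, background_pair):
        for bg in background_pair:
            spec = solve_flicker_modulation(device, sens, bg, lms_target=0.05)
            for arm in (spec.positive_arm_settings, spec.negative_arm_settings):
                assert np.all(arm >= -1e-9) and np.all(arm <= 1 + 1e-9)

    def test_infeasible_target_reports_best_achievable(self, device, sens):
        with pytest.raises(InfeasibleDesignError, match="best"):
            solve_background_pair(device, sens, target_mel_contrast=500.0)

    def test_max_mode_beats_grid_search_oracle_on_toy_device(self, sens):
        """Brute-force oracle: exhaustive pair search over a coarse settings
        grid on a 3-primary device with a loose silencing tolerance."""
        tol = 0.05
        dev = make_synthetic_device(
            n_primaries=3, peak_range_nm=(430.0, 610.0), bandwidth_nm=60.0,
            seed=1, wavelengths=sens.wavelengths,
        )
        M, e0 = dev.excitation_system(sens)
        grid = np.linspace(0.05, 1.0, 21)
        pts = np.stack(np.meshgrid(grid, grid, grid), -1).reshape(-1, 3)
        exc = pts @ M.T + e0  # (n, 4) in L,M,S,Mel order
        best = 0.0
        cone, mel = exc[:, :3], exc[:, 3]
        for i in range(len(pts)):
            cone_ok = np.all(np.abs(cone - cone[i]) <= tol * cone[i], axis=1)
            best = max(best, (mel[cone_ok] / mel[i]).max() - 1.0)
        lo, hi = solve_background_pair(
            dev, sens, target_mel_contrast=0.0, cone_tolerance=tol,
            max_contrast=0.0, mode="max", n_starts=8,
        )
        solver_best = contrasts(dev, sens, lo, hi)["Mel"]
        assert solver_best >= best - 1e-6
        assert best > 0  # the oracle itself found a feasible modulation


class TestFlickerModulation:
    def test_round_trip_closure(self, device, sens, background_pair, flicker_spec):
        low, _ = background_pair
        e_bg = excitation(device.spectrum(low), sens)
        c = weber_contrast(
            e_bg, excitation(device.spectrum(flicker_spec.positive_arm_settings), sens)
        )
        for l in ("L", "M", "S"):
            assert c[l] == pytest.approx(0.05, abs=1e-6)
        assert abs(c["Mel"]) <= 1e-6
        c_neg = weber_contrast(
            e_bg, excitation(device.spectrum(flicker_spec.negative_arm_settings), sens)
        )
        for l in ("L", "M", "S"):
            assert c_neg[l] == pytest.approx(-0.05, abs=1e-6)

    def test_matches_linear_algebra_oracle(self, device, sens, background_pair):
        """The arm deviation must solve the linearized excitation system
        M d = (0.05 * e_LMS(bg), 0); check against the pseudoinverse."""
        low, _ = background_pair
        spec = solve_flicker_modulation(device, sens, low, lms_target=0.05)
        M, e0 = device.excitation_system(sens)
        e_bg = M @ low + e0
        target = np.append(0.05 * e_bg[:3], 0.0)
        np.testing.assert_allclose(
            M @ spec.arm_deviation, target, rtol=1e-9, atol=1e-12
        )

    def test_zero_target_returns_background(self, device, sens, background_pair):
        low, _ = background_pair
        spec = solve_flicker_modulation(device, sens, low, lms_target=0.0)
        np.testing.assert_allclose(spec.positive_arm_settings, low, atol=1e-9)


class TestScaleModulation:
    def test_snap_rounds_half_away_from_zero(self):
        assert snap_contrast(0.0234) == pytest.approx(0.023)
        assert snap_contrast(0.0235) == pytest.approx(0.024)
        assert snap_contrast(-0.0015) == pytest.approx(-0.002)

    def test_identity_and_zero_scales(self, device, sens, flicker_spec):
        pos, _ = scale_modulation(flicker_spec, 0.05)
        np.testing.assert_allclose(
            pos.power, device.spectrum(flicker_spec.positive_arm_settings).power
        )
        pos0, neg0 = scale_modulation(flicker_spec, 0.0)
        bg = device.spectrum(flicker_spec.background_settings)
        np.testing.assert_allclose(pos0.power, bg.power)
        np.testing.assert_allclose(neg0.power, bg.power)

    def test_intermediate_contrast_snaps_then_scales(self, device, sens, flicker_spec):
        pos, _ = scale_modulation(flicker_spec, 0.0234)
        e_bg = excitation(
            device.spectrum(flicker_spec.background_settings), sens
        )
        assert lms_contrast(e_bg, excitation(pos, sens)) == pytest.approx(
            0.023, abs=1e-9
        )

    def test_out_of_range_contrast_errors(self, flicker_spec):
        with pytest.raises(ValueError):
            scale_modulation(flicker_spec, 0.06)
        with pytest.raises(ValueError):
            scale_modulation(flicker_spec, -0.01)


class TestScatterCorrection:
    def test_zero_scatter_leaves_spec_unchanged(self, device, sens, flicker_spec):
        corrected = apply_scatter_correction(
            flicker_spec, SpectralSamples.zeros(device.wavelengths), sens
        )
        np.testing.assert_allclose(
            corrected.positive_arm_settings,
            flicker_spec.positive_arm_settings,
            atol=1e-9,
        )

    def test_scatter_equal_to_background_halves_uncorrected_contrast(
        self, device, sens, flicker_spec
    ):
        scatter = device.spectrum(flicker_spec.background_settings)
        with_scatter = device.with_extra_ambient(scatter)
        e_bg = excitation(
            with_scatter.spectrum(flicker_spec.background_settings), sens
        )
        uncorrected = lms_contrast(
            e_bg,
            excitation(
                with_scatter.spectrum(flicker_spec.positive_arm_settings), sens
            ),
        )
        assert uncorrected == pytest.approx(0.025, abs=1e-9)

    def test_correction_restores_nominal_contrast(self, device, sens, flicker_spec):
        rng = np.random.default_rng(2)
        scatter = SpectralSamples(
            device.wavelengths, 0.1 * rng.uniform(0.5, 1, device.wavelengths.size)
        )
        corrected = apply_scatter_correction(flicker_spec, scatter, sens)
        with_scatter = device.with_extra_ambient(scatter)
        e_bg = excitation(
            with_scatter.spectrum(flicker_spec.background_settings), sens
        )
        achieved = lms_contrast(
            e_bg,
            excitation(
                with_scatter.spectrum(corrected.positive_arm_settings), sens
            ),
        )
        assert achieved == pytest.approx(0.05, abs=1e-6)


class TestWaveforms:
    def test_pedestal_endpoints_and_midpoint(self, background_pair):
        low, high = background_pair
        seg = pedestal_waveform(low, high, ramp_ms=500.0, frame_rate=60.0)
        np.testing.assert_allclose(seg.frames[0], low, atol=1e-12)
        np.testing.assert_allclose(seg.frames[-1], high, atol=1e-12)
        mid = seg.frames[len(seg.frames) // 2]
        np.testing.assert_allclose(mid, 0.5 * (low + high), atol=1e-9)

    def test_pedestal_melanopic_excitation_monotone(
        self, device, sens, background_pair
    ):
        low, high = background_pair
        seg = pedestal_waveform(low, high)
        mels = [
            excitation(device.spectrum(f), sens)["Mel"] for f in seg.frames
        ]
        assert np.all(np.diff(mels) >= -1e-12)

    def test_pedestal_rejects_bad_duration(self, background_pair):
        low, high = background_pair
        with pytest.raises(ValueError, match="positive"):
            pedestal_waveform(low, high, ramp_ms=0.0)

    def test_flicker_5hz_500ms_is_2p5_cycles(self, flicker_spec):
        seg = flicker_waveform(
            flicker_spec, 0.05, frequency=5.0, duration_ms=500.0, frame_rate=60.0
        )
        assert seg.frames.shape[0] == 30
        # 2.5 cycles: the sin weight sequence crosses zero 5 times
        w = (seg.frames - flicker_spec.background_settings).dot(
            flicker_spec.arm_deviation
        )
        assert np.sum(np.abs(np.diff(np.sign(w[np.abs(w) > 1e-12]))) > 0) == 4

    def test_zero_contrast_is_constant_background(self, flicker_spec):
        seg = flicker_waveform(flicker_spec, 0.0)
        np.testing.assert_allclose(
            seg.frames, np.tile(flicker_spec.background_settings, (30, 1))
        )

    def test_peak_frame_matches_positive_arm(self, device, sens, flicker_spec):
        # 3 Hz at 60 Hz frames hits sin=1 exactly at frame 5 (t=1/12 s)
        seg = flicker_waveform(flicker_spec, 0.05, frequency=3.0)
        np.testing.assert_allclose(
            seg.frames[5], flicker_spec.positive_arm_settings, atol=1e-9
        )
        e_peak = excitation(device.spectrum(seg.frames[5]), sens)
        e_pos = excitation(
            device.spectrum(flicker_spec.positive_arm_settings), sens
        )
        assert e_peak["L"] == pytest.approx(e_pos["L"], abs=1e-9)

    def test_aliasing_frequency_rejected(self, flicker_spec):
        with pytest.raises(ValueError, match="Nyquist"):
            flicker_waveform(flicker_spec, 0.05, frequency=40.0, frame_rate=60.0)

    def test_gamut_safety_every_frame(self, device, flicker_spec, background_pair):
        low, high = background_pair
        segs = [
            flicker_waveform(flicker_spec, 0.05),
            pedestal_waveform(low, high),
        ]
        for seg in segs:
            q = np.stack([device.quantize(f) for f in seg.frames])
            assert np.all(q >= 0) and np.all(q <= 1)


def test_quantization_splatter_is_bounded_and_measurable(sens, background_pair):
    """8-bit settings quantization perturbs achieved contrasts by a small,
    reportable amount rather than silently."""
    dev8 = make_synthetic_device(
        wavelengths=sens.wavelengths, seed=0, quantization_levels=256
    )
    low, high = background_pair
    c_exact = weber_contrast(
        excitation(dev8.spectrum(low), sens), excitation(dev8.spectrum(high), sens)
    )
    c_quant = weber_contrast(
        excitation(dev8.spectrum(dev8.quantize(low)), sens),
        excitation(dev8.spectrum(dev8.quantize(high)), sens),
    )
    dev_mel = abs(c_quant["Mel"] - c_exact["Mel"])
    dev_cones = max(abs(c_quant[l] - c_exact[l]) for l in ("L", "M", "S"))
    assert 0 < dev_cones < 0.02  # measurable splatter, bounded
    assert dev_mel < 0.2
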