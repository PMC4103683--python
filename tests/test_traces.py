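"""Trace correction chain: background, bleach fit/correction, %ΔF/F0."""

import numpy as np
import pytest

import spiculate as sp
from spiculate.datatypes import BleachModel, DualChannelTrace, EventLog
from spiculate.traces import (
    correct_red,
    default_f0_window,
    fit_bleach_decay,
    ratiometric_dff,
    restrained_summary,
    single_channel_dff,
    subtract_background,
)


def _trace(time, green, red, gbg=None, rbg=None):
    return DualChannelTrace(time, green, red, gbg, rbg)


class TestSubtractBackground:
    def test_cell_free_roi_goes_to_zero(self):
        t = np.arange(0, 1, 0.05)
        bg = np.full(t.size, 40.0)
        out = subtract_background(_trace(t, bg, bg + 5, bg, bg + 5))
        assert np.allclose(out.green, 0.0)
        assert np.allclose(out.red, 0.0)

    def test_constant_offset_preserved(self):
        t = np.arange(0, 1, 0.05)
        bg = np.full(t.size, 40.0)
        out = subtract_background(_trace(t, bg + 100, bg + 100, bg, bg))
        assert np.allclose(out.green, 100.0)

    def test_algebraic_inverse_on_random_trace(self):
        rng = np.random.default_rng(0)
        t = np.arange(0, 2, 0.05)
        bg_g = rng.uniform(10, 20, t.size)
        bg_r = rng.uniform(10, 20, t.size)
        g = bg_g + rng.uniform(50, 150, t.size)
        r = bg_r + rng.uniform(50, 150, t.size)
        out = subtract_background(_trace(t, g, r, bg_g, bg_r))
        assert np.allclose(out.green + bg_g, g, atol=1e-12)
        assert np.allclose(out.red + bg_r, r, atol=1e-12)

    def test_missing_background_rejected(self):
        t = np.arange(0, 1, 0.05)
        with pytest.raises(ValueError, match="background"):
            subtract_background(_trace(t, np.ones(t.size), np.ones(t.size)))


class TestBleachFit:
    def test_exact_exponential_recovered_to_six_digits(self):
        t = np.arange(0, 60, 0.05)
        red = 200.0 * np.exp(-t / 30.0) + 50.0
        model = fit_bleach_decay(red, t)
        assert model.amplitude == pytest.approx(200.0, rel=1e-6)
        assert model.tau_s == pytest.approx(30.0, rel=1e-6)
        assert model.offset == pytest.approx(50.0, rel=1e-6)

    def test_constant_input_degenerate_model(self):
        t = np.arange(0, 10, 0.05)
        model = fit_bleach_decay(np.full(t.size, 80.0), t)
        assert model.amplitude == 0.0
        assert model.offset == pytest.approx(80.0)
        assert model.degenerate

    def test_noisy_exponential_tau_within_ten_percent(self):
        t = np.arange(0, 60, 0.05)
        clean = 200.0 * np.exp(-t / 30.0) + 50.0
        taus = []
        for seed in range(100):
            rng = np.random.default_rng(seed)
            noisy = clean * (1 + rng.normal(0, 0.02, t.size))
            taus.append(fit_bleach_decay(noisy, t).tau_s)
        rel_err = np.abs(np.array(taus) - 30.0) / 30.0
        assert np.mean(rel_err < 0.10) >= 0.95
        assert np.median(rel_err) < 0.05

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError, match="10 samples"):
            fit_bleach_decay(np.arange(5.0), np.arange(5.0))


class TestCorrectRed:
    def test_pure_model_input_becomes_constant(self):
        t = np.arange(0, 60, 0.05)
        model = BleachModel(200.0, 30.0, 50.0)
        corrected = correct_red(model.predict(t), model, t)
        assert np.allclose(corrected, 250.0, rtol=1e-12)

    def test_zero_amplitude_model_is_identity(self):
        t = np.arange(0, 10, 0.05)
        red = np.linspace(100, 90, t.size)
        model = BleachModel(0.0, float("nan"), 95.0)
        assert np.allclose(correct_red(red, model, t), red)

    def test_nonpositive_model_rejected(self):
        t = np.arange(0, 100, 1.0)
        model = BleachModel(200.0, 10.0, -50.0)  # goes negative at large t
        with pytest.raises(ValueError, match="non-positive"):
            correct_red(np.ones(t.size) * 100, model, t)


class TestRatiometricDff:
    def test_proportional_channels_give_zero(self):
        t = np.arange(0, 20, 0.05)
        base = 100.0 + 10.0 * np.sin(t)
        model = BleachModel(0.0, float("nan"), 1.0)
        trace = _trace(t, 2.0 * base, base)
        dff = ratiometric_dff(trace, model, (0.0, 2.0))
        assert np.allclose(dff.dff_percent, 0.0, atol=1e-9)

    def test_green_step_gives_fifty_percent(self):
        t = np.arange(0, 20, 0.05)
        green = np.where(t < 10, 100.0, 150.0)
        red = np.full(t.size, 100.0)
        model = BleachModel(0.0, float("nan"), 100.0)
        dff = ratiometric_dff(_trace(t, green, red), model, (0.0, 2.0))
        assert dff.dff_percent[t < 10] == pytest.approx(0.0, abs=1e-9)
        assert dff.dff_percent[t >= 10] == pytest.approx(50.0, abs=1e-9)

    def test_baseline_mean_is_zero_by_construction(self):
        rng = np.random.default_rng(1)
        t = np.arange(0, 20, 0.05)
        green = 100 + rng.normal(0, 3, t.size)
        red = 100 + rng.normal(0, 3, t.size)
        model = BleachModel(0.0, float("nan"), 100.0)
        dff = ratiometric_dff(_trace(t, green, red), model, (0.0, 5.0))
        assert abs(np.mean(dff.dff_percent[t < 5])) < 1e-9

    def test_empty_window_rejected(self):
        t = np.arange(0, 10, 0.05)
        model = BleachModel(0.0, float("nan"), 100.0)
        with pytest.raises(ValueError, match="window"):
            ratiometric_dff(
                _trace(t, np.full(t.size, 100.0), np.full(t.size, 100.0)),
                model,
                (20.0, 25.0),
            )

    def test_full_noiseless_bout_recovers_peak_amplitude(self, spc_noiseless_result):
        preset, result = spc_noiseless_result
        assert np.max(result.dff.dff_percent) == pytest.approx(
            preset.peak_amplitude, abs=0.5
        )

    def test_scale_invariance_of_dff(self, spc_noiseless):
        preset, trace, events = spc_noiseless
        sub = subtract_background(trace)
        model = fit_bleach_decay(sub.red, sub.time_s)
        window = default_f0_window(sub.time_s, events)
        dff1 = ratiometric_dff(sub, model, window, events)
        scaled = _trace(sub.time_s, 3.7 * sub.green, 3.7 * sub.red)
        model2 = fit_bleach_decay(scaled.red, scaled.time_s)
        dff2 = ratiometric_dff(scaled, model2, window, events)
        assert np.allclose(dff1.dff_percent, dff2.dff_percent, atol=1e-6)


class TestBleachOnlyFlatness:
    @pytest.mark.parametrize("noise_sd", [0.0, 1.0, 3.0])
    def test_corrected_ratio_flat_within_noise_envelope(self, noise_sd):
        preset = sp.make_preset("ray_flat").with_(noise_sd=noise_sd)
        trace, events = sp.simulate_bout(preset, 5.0, 45.0, 0.05, seed=7)
        result = sp.BoutKinetics(trace, events).fit()
        d = result.dff.dff_percent
        if noise_sd == 0:
            assert np.max(np.abs(d)) < 1e-6
        else:
            # two independent channels: dff noise SD is sqrt(2) * noise_sd
            assert d.std() <= 1.6 * noise_sd
            assert np.max(np.abs(d)) <= 6.0 * noise_sd

    def test_generator_bleach_tau_recovered_noiseless(self):
        preset = sp.make_preset("ray_flat").with_(noise_sd=0.0)
        trace, _ = sp.simulate_bout(preset, 5.0, 45.0, 0.05, seed=0)
        sub = subtract_background(trace)
        model = fit_bleach_decay(sub.red, sub.time_s)
        assert model.tau_s == pytest.approx(preset.red_bleach_tau_s, rel=0.05)


class TestSingleChannelDff:
    def test_constant_green_gives_zero(self):
        t = np.arange(0, 10, 0.05)
        dff = single_channel_dff(np.full(t.size, 120.0), t, (0.0, 2.0))
        assert np.allclose(dff.dff_percent, 0.0)

    def test_doubling_gives_hundred(self):
        t = np.arange(0, 10, 0.05)
        green = np.where(t < 5, 100.0, 200.0)
        dff = single_channel_dff(green, t, (0.0, 2.0))
        assert dff.dff_percent[-1] == pytest.approx(100.0)

    def test_synthetic_valve_bout_peak_within_half_percent(self):
        preset = sp.make_preset("valve").with_(noise_sd=0.0, red_bleach_floor=0.99)
        trace, events = sp.simulate_bout(preset, 5.0, 45.0, 0.05, seed=0)
        green = trace.green - trace.green_bg
        dff = single_channel_dff(green, trace.time_s, (3.0, 5.0), events)
        assert np.max(dff.dff_percent) == pytest.approx(preset.peak_amplitude, abs=0.5)


class TestRestrainedSummary:
    def test_flat_trace_gives_zeros(self, flat_dff):
        out = restrained_summary(flat_dff, 20.0)
        assert out == {"max_change_from_t0": 0.0, "sd": 0.0}

    def test_sinusoid_closed_form(self):
        from spiculate.datatypes import DffTrace

        t = np.arange(0, 60, 0.001)
        dff = DffTrace(t, 10.0 * np.sin(2 * np.pi * t), 1.0)
        out = restrained_summary(dff, 60.0)
        assert out["max_change_from_t0"] == pytest.approx(10.0, rel=0.02)
        assert out["sd"] == pytest.approx(10.0 / np.sqrt(2.0), rel=0.02)

    def test_step_change_detected(self):
        from spiculate.datatypes import DffTrace

        t = np.arange(0, 60, 0.05)
        dff = DffTrace(t, np.where(t < 30, 0.0, 20.0), 1.0)
        assert restrained_summary(dff, 60.0)["max_change_from_t0"] == pytest.approx(20.0)

    def test_window_longer_than_trace_rejected(self, flat_dff):
        with pytest.raises(ValueError, match="window"):
            restrained_summary(flat_dff, 1000.0)


class TestImageRoundTrip:
    def test_pipeline_identical_via_rendered_frames(self, spc_noiseless):
        from spiculate.imaging import RoiBox, extract_roi_means, render_frames

        _, trace, events = spc_noiseless
        short = DualChannelTrace(
            trace.time_s[:200], trace.green[:200], trace.red[:200],
            trace.green_bg[:200], trace.red_bg[:200],
        )
        stack = render_frames(short, RoiBox(20, 10, 8, 6))
        recovered = extract_roi_means(stack)
        assert np.allclose(recovered.green, short.green)
        assert np.allclose(recovered.red, short.red)
        assert np.allclose(recovered.green_bg, short.green_bg)
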