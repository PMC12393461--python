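import numpy as np
import pytest

from dgkit import (IntrinsicSimParams, ap_threshold_and_shape,
                   firing_rate_and_accommodation, input_resistance,
                   membrane_tau, profile_from_protocols, rmp_from_ramp,
                   sag_ratio, simulate_intrinsic_protocols)
from dgkit.ephys_intrinsic import SpikeError

FS = 20000.0


class TestSpikeShape:
    def test_threshold_recovered_from_generator_waveform(self):
        p = IntrinsicSimParams(threshold_mv=-42.0, noise_sd_mv=0.05)
        protocols, truth = simulate_intrinsic_protocols(p, seed=1)
        shape = ap_threshold_and_shape(protocols.rheobase_sweep.sweeps[0],
                                       FS)
        assert shape["threshold_mv"] == pytest.approx(truth.threshold_mv,
                                                      abs=0.5)
        assert shape["ap_amplitude_mv"] == pytest.approx(
            truth.ap_peak_mv - truth.threshold_mv, abs=1.0)
        assert shape["max_upstroke"] > 100.0
        assert shape["max_downstroke"] < 0.0
        assert shape["ahp_mv"] > 0.0

    def test_spikeless_sweep_raises(self):
        with pytest.raises(SpikeError, match="no spike"):
            ap_threshold_and_shape(np.full(1000, -70.0), FS)

    def test_threshold_stable_under_doubled_sampling_rate(self):
        p = IntrinsicSimParams(noise_sd_mv=0.0)
        t1 = ap_threshold_and_shape(
            simulate_intrinsic_protocols(p, seed=2)[0]
            .rheobase_sweep.sweeps[0], FS)["threshold_mv"]
        p2 = IntrinsicSimParams(noise_sd_mv=0.0, fs=2 * FS)
        t2 = ap_threshold_and_shape(
            simulate_intrinsic_protocols(p2, seed=2)[0]
            .rheobase_sweep.sweeps[0], 2 * FS)["threshold_mv"]
        assert abs(t1 - t2) < 0.5

    def test_peak_equals_threshold_plus_amplitude(self):
        protocols, _ = simulate_intrinsic_protocols(seed=3)
        v = protocols.rheobase_sweep.sweeps[0]
        shape = ap_threshold_and_shape(v, FS)
        assert v[shape["peak_idx"]] == pytest.approx(
            shape["threshold_mv"] + shape["ap_amplitude_mv"])


class TestSagRatio:
    def _sweep(self, v_base, v_peak, v_ss, fs=1000.0):
        # 0.2 s baseline, 1 s step with an instant peak then steady state
        v = np.full(int(1.4 * fs), float(v_base))
        s0, s1 = int(0.2 * fs), int(1.2 * fs)
        v[s0:s1] = v_ss
        v[s0:s0 + int(0.05 * fs)] = v_peak
        return v, fs

    def test_deflection_convention_closed_form(self):
        v, fs = self._sweep(-70.0, -100.0, -90.0)
        r = sag_ratio(v, fs, (0.0, 0.2), (0.2, 1.2))
        assert r == pytest.approx((-90 + 70) / (-100 + 70))   # 0.667

    def test_no_sag_gives_ratio_one(self):
        v, fs = self._sweep(-70.0, -100.0, -100.0)
        assert sag_ratio(v, fs, (0.0, 0.2), (0.2, 1.2)) == pytest.approx(1.0)

    def test_raw_convention_divides_absolute_voltages(self):
        v, fs = self._sweep(-70.0, -100.0, -90.0)
        r = sag_ratio(v, fs, (0.0, 0.2), (0.2, 1.2), convention="raw")
        assert r == pytest.approx(90.0 / 100.0)

    def test_depolarizing_step_rejected(self):
        v, fs = self._sweep(-70.0, -50.0, -55.0)
        with pytest.raises(ValueError, match="hyperpolarising"):
            sag_ratio(v, fs, (0.0, 0.2), (0.2, 1.2))

    def test_generator_sag_fraction_recovered(self):
        p = IntrinsicSimParams(sag_frac=0.3)
        protocols, _ = simulate_intrinsic_protocols(p, seed=4)
        r = sag_ratio(protocols.sag_sweep.sweeps[0], FS, (0.0, 0.2),
                      (0.2, 1.2))
        assert r == pytest.approx(0.7, abs=0.03)


class TestFiring:
    def test_accommodation_closed_form(self):
        # spikes with ISIs 20, 25, 40, 50 ms -> 20 / mean(40, 50)
        fs = FS
        v = np.full(int(0.3 * fs), -70.0)
        t = 0.05
        for isi in (0.0, 0.020, 0.025, 0.040, 0.050):
            t += isi
            i = int(t * fs)
            v[i - 4:i + 5] = np.concatenate([
                np.linspace(-70, 30, 5), np.linspace(30, -70, 4)])
        out = firing_rate_and_accommodation(v[None, :], fs, step_dur_s=1.0)
        assert out["accommodation"] == pytest.approx(0.020 / 0.045, rel=0.02)

    def test_regular_train_has_accommodation_one(self):
        fs = FS
        v = np.full(int(1.2 * fs), -70.0)
        for k in range(10):
            i = int((0.1 + 0.05 * k) * fs)
            v[i - 4:i + 5] = np.concatenate([
                np.linspace(-70, 30, 5), np.linspace(30, -70, 4)])
        out = firing_rate_and_accommodation(v[None, :], fs)
        assert out["max_rate_hz"] == 10.0
        assert out["accommodation"] == pytest.approx(1.0, rel=0.01)

    def test_generator_rate_and_accommodation_recovered(self):
        protocols, truth = simulate_intrinsic_protocols(seed=5)
        out = firing_rate_and_accommodation(protocols.firing_steps.sweeps,
                                            FS)
        assert out["max_rate_hz"] == truth.max_rate_hz
        assert out["accommodation"] == pytest.approx(truth.accommodation,
                                                     rel=0.02)

    def test_depolarization_block_sweep_excluded(self):
        fs = FS
        good = np.full(int(1.2 * fs), -70.0)
        for k in range(5):
            i = int((0.1 + 0.1 * k) * fs)
            good[i - 4:i + 5] = np.concatenate([
                np.linspace(-70, 30, 5), np.linspace(30, -70, 4)])
        blocked = np.full(int(1.2 * fs), -70.0)
        for k in range(20):
            i = int((0.1 + 0.04 * k) * fs)
            amp = 30.0 if k < 3 else -45.0   # collapsing spikes
            blocked[i - 4:i + 5] = np.concatenate([
                np.linspace(-70, amp, 5), np.linspace(amp, -70, 4)])
        out = firing_rate_and_accommodation(np.stack([good, blocked]), fs)
        assert out["max_rate_hz"] == 5.0


class TestPassiveProperties:
    def test_exact_linear_iv_slope(self):
        i = np.linspace(-100, 100, 20)
        v = 0.15 * i - 70.0    # 0.15 mV/pA = 150 MΩ
        assert input_resistance(i, v) == pytest.approx(150.0)

    def test_two_point_slope_is_analytic(self):
        assert input_resistance([-50.0, 50.0],
                                [-75.0, -65.0]) == pytest.approx(100.0)

    def test_noisy_fit_within_5pct(self, rng):
        i = np.linspace(-100, -5, 20)
        v = 0.2 * i - 70.0 + rng.normal(0, 0.1, 20)
        assert input_resistance(i, v) == pytest.approx(200.0, rel=0.05)

    def test_single_level_rejected(self):
        with pytest.raises(ValueError):
            input_resistance([10.0], [-69.0])

    def test_noiseless_tau_recovered_within_1pct(self):
        fs = FS
        t = np.arange(int(0.4 * fs)) / fs * 1e3
        v = -73.0 + 3.0 * np.exp(-t / 15.0)
        assert membrane_tau(v, fs, 0) == pytest.approx(15.0, rel=0.01)

    def test_flat_response_raises(self):
        with pytest.raises(ValueError, match="flat|degenerate"):
            membrane_tau(np.full(1000, -70.0), FS, 0)

    @pytest.mark.parametrize("noise", [0.1, 0.5])
    def test_tau_bias_small_under_noise(self, noise, rng):
        fs = FS
        t = np.arange(int(0.4 * fs)) / fs * 1e3
        taus = []
        for _ in range(10):
            avg = np.mean([
                -73.0 + 3.0 * np.exp(-t / 15.0)
                + rng.normal(0, noise, len(t)) for _ in range(20)], axis=0)
            taus.append(membrane_tau(avg, fs, 0))
        assert np.mean(taus) == pytest.approx(15.0, rel=0.05)


class TestRampReversal:
    def _iv(self, g_k=10.0, e_k=-90.0, g_leak=2.0, noise=0.0, seed=0):
        rng = np.random.default_rng(seed)
        v = np.linspace(100.0, -200.0, 2000)
        act = 1.0 / (1.0 + np.exp((v + 60.0) / 8.0))
        i = g_leak * v + g_k * act * (v - e_k) + rng.normal(0, noise,
                                                            len(v))
        return v, i

    def test_reversal_recovered_within_1mv(self):
        v, i = self._iv(noise=5.0, seed=1)
        assert rmp_from_ramp(v, i) == pytest.approx(-90.0, abs=1.0)

    def test_pure_leak_has_no_crossing(self):
        v = np.linspace(100.0, -200.0, 2000)
        with pytest.raises(ValueError):
            rmp_from_ramp(v, 2.0 * v)

    def test_doubling_conductance_leaves_reversal_unchanged(self):
        v1, i1 = self._iv(g_k=10.0, noise=2.0, seed=2)
        v2, i2 = self._iv(g_k=20.0, noise=2.0, seed=2)
        assert rmp_from_ramp(v1, i1) == pytest.approx(
            rmp_from_ramp(v2, i2), abs=0.5)


class TestFullProfile:
    def test_all_parameters_recovered_from_protocol_battery(self):
        p = IntrinsicSimParams(tau_ms=22.0, rin_mohm=220.0,
                               threshold_mv=-40.0, sag_frac=0.25,
                               reversal_mv=-92.0)
        protocols, truth = simulate_intrinsic_protocols(p, seed=6)
        prof = profile_from_protocols(protocols)
        assert prof.tau_ms == pytest.approx(truth.tau_ms, rel=0.05)
        assert prof.rin_mohm == pytest.approx(truth.rin_mohm, rel=0.05)
        assert prof.threshold_mv == pytest.approx(truth.threshold_mv,
                                                  abs=1.0)
        assert prof.rmp_mv == pytest.approx(truth.reversal_mv, abs=1.0)
        assert prof.sag_ratio == pytest.approx(1 - truth.sag_frac, abs=0.03)
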