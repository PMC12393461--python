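"""Synthetic imaging sessions and patch-clamp sweeps with ground truth.

Every generator is a pure function of (parameters, seed), and its
output passes the validators of :mod:`dgkit.session_io` unmodified, so
each downstream estimator can be scored against known truth.

Imaging sessions emulate head-fixed VR running on a 3 m track at 30 Hz:
alternating run/pause bouts with per-bout speeds of 10–30 cm/s, laps
ending in a teleport to the track start, and a 1 s teleport pause.
Place cells fire on a ``reliability`` fraction of laps at a position
drawn from a truncated Gaussian inside their field; transients are
instantaneous onsets convolved with a two-exponential GCaMP kernel
(20 ms rise, 400 ms decay, 6f-like) with lognormal amplitudes, riding
on a slowly drifting baseline with additive Gaussian noise:

    F(t) = baseline · (1 + drift(t)) · (1 + signal(t)) + noise(t)

Ephys generators emulate paired-recording trains (25 pulses at 50 Hz)
with mixed synchronous/asynchronous quantal release and failures, and
the standard intrinsic-property protocols (step families, sag step,
rheobase spike, firing steps, voltage ramp) from a leaky-exponential
membrane model with known τ, R_in, threshold, sag and K⁺ reversal.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .ephys_synaptic import SweepSet
from .session_io import SessionData

__all__ = [
    "ImagingSimParams", "ImagingGroundTruth",
    "simulate_session", "simulate_context_session",
    "UipscSimParams", "IntrinsicSimParams", "EphysGroundTruth",
    "IntrinsicProtocols", "simulate_uipsc_trains",
    "simulate_intrinsic_protocols", "gcamp_kernel",
]


# ---------------------------------------------------------------------------
# imaging sessions

@dataclass
class ImagingSimParams:
    n_cells: int = 50
    frac_tuned: float = 0.5
    n_laps: int = 10
    frame_rate: float = 30.0
    track_length: float = 300.0
    field_width_cm: float = 45.0      # FWHM of the firing-position kernel
    reliability: float = 0.8          # fraction of laps with in-field firing
    event_rate_per_min: float = 2.0   # background rate of untuned cells
    amp_median: float = 1.0           # ΔF/F transient amplitude, lognormal
    amp_sigma: float = 0.3
    amp_min: float = 0.0              # lower clamp on amplitudes
    kernel_rise_ms: float = 20.0
    kernel_decay_ms: float = 400.0
    noise_sd: float = 0.05            # in ΔF/F units
    baseline: float = 100.0           # raw fluorescence units
    drift_amp: float = 0.05           # peak fractional baseline drift (≤0.1)
    run_speed_range: tuple = (10.0, 30.0)   # cm/s, drawn per bout
    run_bout_s: float = 4.0           # mean running-bout duration
    pause_s: float = 1.0              # mean pause duration
    teleport_pause_s: float = 1.0
    min_session_s: float = 120.0      # pad short sessions so the 60 s
                                      # baseline window is well defined

    def validate(self) -> None:
        if not 0.0 <= self.reliability <= 1.0:
            raise ValueError(f"reliability must be in [0, 1], "
                             f"got {self.reliability}")
        if self.field_width_cm <= 0:
            raise ValueError("field width must be positive")
        if self.n_laps < 1:
            raise ValueError("at least one lap is required")


@dataclass
class ImagingGroundTruth:
    tuned: np.ndarray                     # (cells,) bool
    field_center_cm: np.ndarray           # (cells,), NaN if untuned
    field_width_cm: float
    reliability: np.ndarray               # (cells,)
    onset_frames: list                    # per cell, int arrays
    amplitudes: list                      # per cell, ΔF/F units
    noise_sd: float
    kernel_rise_ms: float
    kernel_decay_ms: float
    lap_context: np.ndarray | None = None     # per lap, context sessions
    centers_by_context: dict | None = None    # {"familiar": arr, "novel": arr}
    remapped: np.ndarray | None = None

    def field_bounds(self, cell: int, context: str | None = None) -> tuple:
        c = (self.field_center_cm[cell] if context is None
             else self.centers_by_context[context][cell])
        h = self.field_width_cm / 2.0
        return c - h, c + h


def gcamp_kernel(rise_ms: float, decay_ms: float, frame_rate: float,
                 ) -> np.ndarray:
    """Two-exponential calcium-indicator kernel, peak-normalised."""
    dur_s = (rise_ms + 8 * decay_ms) / 1e3
    t = np.arange(max(2, int(round(dur_s * frame_rate)))) / frame_rate * 1e3
    k = (1 - np.exp(-t / rise_ms)) * np.exp(-t / decay_ms)
    return k / k.max()


def _simulate_behavior(p: ImagingSimParams, rng: np.random.Generator):
    """Lap-structured run/pause behavior; returns position, velocity."""
    dt = 1.0 / p.frame_rate
    pos_list, vel_list = [], []
    pos = 0.0
    lap = 0
    running = True
    speed = rng.uniform(*p.run_speed_range)
    bout_left = max(1, int(round(rng.exponential(p.run_bout_s) / dt)))
    while lap < p.n_laps:
        if running:
            pos_list.append(pos)
            vel_list.append(speed)
            pos += speed * dt
            if pos >= p.track_length:
                pos = 0.0
                lap += 1
                running = False
                bout_left = max(1, int(round(p.teleport_pause_s / dt)))
                continue
        else:
            pos_list.append(pos)
            vel_list.append(0.0)
        bout_left -= 1
        if bout_left <= 0:
            running = not running
            if running:
                speed = rng.uniform(*p.run_speed_range)
                bout_left = max(1, int(round(
                    rng.exponential(p.run_bout_s) / dt)))
            else:
                bout_left = max(1, int(round(
                    rng.exponential(p.pause_s) / dt)))
    # pad to the minimum session length with a terminal pause
    n_min = int(round(p.min_session_s * p.frame_rate))
    if len(pos_list) < n_min:
        pad = n_min - len(pos_list)
        pos_list.extend([pos_list[-1]] * pad)
        vel_list.extend([0.0] * pad)
    return np.asarray(pos_list), np.asarray(vel_list)


def _truncated_normal(rng, center, sd, lo, hi, max_tries=50):
    for _ in range(max_tries):
        x = rng.normal(center, sd)
        if lo <= x <= hi:
            return x
    return float(np.clip(rng.normal(center, sd), lo, hi))


def _draw_amp(rng, p: ImagingSimParams) -> float:
    a = rng.lognormal(math.log(p.amp_median), p.amp_sigma)
    return max(a, p.amp_min)


def _kernel_centroid_s(p: ImagingSimParams) -> float:
    k = gcamp_kernel(p.kernel_rise_ms, p.kernel_decay_ms, p.frame_rate)
    t = np.arange(len(k)) / p.frame_rate
    return float((t * k).sum() / k.sum())


def _event_frames_tuned(rng, p, lap_index, position, velocity, center,
                        laps, reliability, lag_s):
    """One onset per firing lap, placed so the resulting calcium
    transient is centered on a truncated-Gaussian draw around the field
    center.

    The stored ground-truth field describes the ΔF/F signal (what the
    tuning analysis estimates), so the onset leads the drawn position
    by the kernel's temporal centroid — the indicator integrates and
    would otherwise displace the apparent field downstream of the true
    one by several bins at running speed.
    """
    sd = p.field_width_cm / (2.0 * math.sqrt(2.0 * math.log(2.0)))
    half = p.field_width_cm / 2.0
    lo = max(0.0, center - half)
    hi = min(p.track_length - 1e-6, center + half)
    onsets = []
    for lap in laps:
        if rng.random() >= reliability:
            continue
        target = _truncated_normal(rng, center, sd, lo, hi)
        in_lap = np.flatnonzero((lap_index == lap) & (velocity > 0)
                                & (position >= target))
        if in_lap.size:
            cross = int(in_lap[0])
            lap_start = int(np.argmax(lap_index == lap))
            onset = max(lap_start, cross - int(round(lag_s
                                                     * p.frame_rate)))
            onsets.append(onset)
    return np.asarray(sorted(onsets), dtype=int)


def _assemble_traces(p, rng, n_frames, onset_frames, amplitudes):
    kernel = gcamp_kernel(p.kernel_rise_ms, p.kernel_decay_ms, p.frame_rate)
    t = np.arange(n_frames) / p.frame_rate
    fluor = np.empty((p.n_cells, n_frames))
    # slow sinusoid + linear trend, per cell phase, bounded by drift_amp
    for i in range(p.n_cells):
        phase = rng.uniform(0, 2 * math.pi)
        drift = 0.5 * p.drift_amp * np.sin(2 * math.pi * t / 300.0 + phase)
        drift = drift + 0.5 * p.drift_amp * (t / max(t[-1], 1.0))
        sig = np.zeros(n_frames)
        if onset_frames[i].size:
            np.add.at(sig, onset_frames[i], amplitudes[i])
            sig = np.convolve(sig, kernel)[:n_frames]
        noise = rng.normal(0.0, p.noise_sd * p.baseline, n_frames)
        fluor[i] = p.baseline * (1.0 + drift) * (1.0 + sig) + noise
    return fluor


def _simulate_imaging(p: ImagingSimParams, seed: int,
                      lap_context: np.ndarray | None,
                      remap_prob: float | None,
                      rng: np.random.Generator) -> tuple:
    position, velocity = _simulate_behavior(p, rng)
    n_frames = len(position)
    lap_index = np.concatenate(
        [[0], np.cumsum(np.diff(position) < -p.track_length / 2)]).astype(int)
    n_laps = int(lap_index[-1]) + 1
    if lap_context is None:
        context = np.full(n_frames, "familiar", dtype="U8")
        lap_ctx = None
    else:
        lap_ctx = lap_context[:n_laps]
        context = lap_ctx[lap_index]

    n_tuned = int(round(p.frac_tuned * p.n_cells))
    tuned = np.zeros(p.n_cells, dtype=bool)
    tuned[:n_tuned] = True
    margin = p.field_width_cm / 2.0 + 1.0
    centers = np.full(p.n_cells, np.nan)
    centers[tuned] = rng.uniform(margin, p.track_length - margin, n_tuned)
    reliability = np.where(tuned, p.reliability, np.nan)

    centers_by_ctx = None
    remapped = None
    if remap_prob is not None:
        remapped = np.zeros(p.n_cells, dtype=bool)
        nov = centers.copy()
        for i in range(p.n_cells):
            if tuned[i] and rng.random() < remap_prob:
                remapped[i] = True
                nov[i] = rng.uniform(margin, p.track_length - margin)
        centers_by_ctx = {"familiar": centers, "novel": nov}

    duration_min = n_frames / p.frame_rate / 60.0
    lag_s = _kernel_centroid_s(p)
    onset_frames, amplitudes = [], []
    for i in range(p.n_cells):
        if tuned[i]:
            if centers_by_ctx is None:
                onsets = _event_frames_tuned(
                    rng, p, lap_index, position, velocity, centers[i],
                    np.arange(n_laps), p.reliability, lag_s)
            else:
                parts = []
                for ctx in ("familiar", "novel"):
                    laps = np.flatnonzero(lap_ctx == ctx)
                    parts.append(_event_frames_tuned(
                        rng, p, lap_index, position, velocity,
                        centers_by_ctx[ctx][i], laps, p.reliability, lag_s))
                onsets = np.asarray(sorted(np.concatenate(parts)), dtype=int)
        else:
            n_ev = rng.poisson(p.event_rate_per_min * duration_min)
            onsets = np.sort(rng.integers(0, n_frames, size=n_ev))
        onset_frames.append(onsets)
        amplitudes.append(np.array([_draw_amp(rng, p) for _ in onsets]))

    fluor = _assemble_traces(p, rng, n_frames, onset_frames, amplitudes)
    session = SessionData(
        fluor=fluor, position=position, velocity=velocity, context=context,
        frame_rate=p.frame_rate, track_length=p.track_length)
    truth = ImagingGroundTruth(
        tuned=tuned, field_center_cm=centers,
        field_width_cm=p.field_width_cm, reliability=reliability,
        onset_frames=onset_frames, amplitudes=amplitudes,
        noise_sd=p.noise_sd, kernel_rise_ms=p.kernel_rise_ms,
        kernel_decay_ms=p.kernel_decay_ms, lap_context=lap_ctx,
        centers_by_context=centers_by_ctx, remapped=remapped)
    return session, truth


def simulate_session(params: ImagingSimParams | None = None,
                     seed: int = 0) -> tuple[SessionData, ImagingGroundTruth]:
    """Single-context (familiar) imaging session with ground truth."""
    p = params or ImagingSimParams()
    p.validate()
    rng = np.random.default_rng(seed)
    return _simulate_imaging(p, seed, None, None, rng)


def simulate_context_session(params: ImagingSimParams | None = None,
                             remap_prob: float = 0.5, seed: int = 0,
                             ) -> tuple[SessionData, ImagingGroundTruth]:
    """Familiar/novel session: laps alternate contexts pseudo-randomly
    (balanced), and each tuned cell redraws its field center in the
    novel context with probability ``remap_prob``."""
    p = params or ImagingSimParams()
    p.validate()
    if not 0.0 <= remap_prob <= 1.0:
        raise ValueError(f"remap_prob must be in [0, 1], got {remap_prob}")
    rng = np.random.default_rng(seed)
    n_f = p.n_laps // 2 + p.n_laps % 2
    lap_context = np.array(["familiar"] * n_f
                           + ["novel"] * (p.n_laps - n_f), dtype="U8")
    rng.shuffle(lap_context)
    return _simulate_imaging(p, seed, lap_context, remap_prob, rng)


# ---------------------------------------------------------------------------
# synaptic ephys

@dataclass
class UipscSimParams:
    n_trials: int = 10
    n_pulses: int = 25
    rate_hz: float = 50.0
    p_fail: float = 0.2
    sync_frac: float = 0.8
    sync_latency_ms: float = 1.5
    sync_jitter_ms: float = 0.2
    async_tau_ms: float = 5.0        # spreads release over the 20 ms IPI
    n_quanta: int = 5                # quanta per successful release
    quantal_pa: float = 20.0
    kernel_rise_ms: float = 0.5
    kernel_decay_ms: float = 8.0
    noise_sd_pa: float = 2.0
    fs: float = 20000.0
    pre_s: float = 0.05
    post_s: float = 0.1

    def validate(self) -> None:
        if not 0.0 <= self.sync_frac <= 1.0:
            raise ValueError(f"sync_frac must be in [0, 1], "
                             f"got {self.sync_frac}")
        if not 0.0 <= self.p_fail <= 1.0:
            raise ValueError("p_fail must be in [0, 1]")
        if self.n_pulses < 1:
            raise ValueError("need at least one pulse")


@dataclass
class EphysGroundTruth:
    # quantal-train truth
    event_times: list | None = None       # per trial, arrays of seconds
    event_labels: list | None = None      # per trial, 'sync'/'async'
    event_pulse: list | None = None       # per trial, pulse index per event
    failures: np.ndarray | None = None    # (trials, pulses) bool
    quantal_pa: float | None = None
    sync_latency_ms: float | None = None
    sync_jitter_ms: float | None = None
    sync_window_ms: float = 5.0           # sync events fall within this
    noise_sd: float | None = None
    # intrinsic-protocol truth
    tau_ms: float | None = None
    rin_mohm: float | None = None
    threshold_mv: float | None = None
    ap_peak_mv: float | None = None
    sag_frac: float | None = None
    reversal_mv: float | None = None
    rmp_mv: float | None = None
    max_rate_hz: float | None = None
    accommodation: float | None = None


def _ipsc_kernel(rise_ms: float, decay_ms: float, fs: float) -> np.ndarray:
    dur = (rise_ms + 10 * decay_ms) / 1e3
    t = np.arange(int(round(dur * fs))) / fs * 1e3
    k = (1 - np.exp(-t / rise_ms)) * np.exp(-t / decay_ms)
    return k / k.max()


def simulate_uipsc_trains(params: UipscSimParams | None = None,
                          seed: int = 0) -> tuple[SweepSet, EphysGroundTruth]:
    """Quantal IPSC trains (default 25 pulses at 50 Hz) with failures and
    mixed synchronous/asynchronous release.

    Per pulse, with probability 1 − p_fail, ``n_quanta`` quanta are
    released: a fraction ``sync_frac`` at a jittered short latency, the
    rest at latency + Exp(``async_tau_ms``) truncated to the inter-pulse
    interval.  Quanta are convolved with the IPSC kernel (positive-going,
    peak ``quantal_pa``) and Gaussian noise is added.
    """
    p = params or UipscSimParams()
    p.validate()
    rng = np.random.default_rng(seed)
    ipi = 1.0 / p.rate_hz
    pulse_times = p.pre_s + np.arange(p.n_pulses) * ipi
    n = int(round((p.pre_s + p.n_pulses * ipi + p.post_s) * p.fs))
    kernel = _ipsc_kernel(p.kernel_rise_ms, p.kernel_decay_ms, p.fs)
    lat = p.sync_latency_ms / 1e3

    sweeps = np.empty((p.n_trials, n))
    ev_times, ev_labels, ev_pulse = [], [], []
    failures = np.zeros((p.n_trials, p.n_pulses), dtype=bool)
    for tr in range(p.n_trials):
        times, labels, pulses = [], [], []
        impulses = np.zeros(n)
        for pi, t0 in enumerate(pulse_times):
            if rng.random() < p.p_fail:
                failures[tr, pi] = True
                continue
            for _ in range(p.n_quanta):
                if rng.random() < p.sync_frac:
                    t_ev = t0 + lat + rng.normal(0.0, p.sync_jitter_ms / 1e3)
                    t_ev = max(t_ev, t0)
                    label = "sync"
                else:
                    for _ in range(50):
                        dt_async = rng.exponential(p.async_tau_ms / 1e3)
                        if lat + dt_async < ipi:
                            break
                    t_ev = t0 + lat + min(dt_async, ipi - lat - 1e-4)
                    label = "async"
                times.append(t_ev)
                labels.append(label)
                pulses.append(pi)
                impulses[min(n - 1, int(round(t_ev * p.fs)))] += p.quantal_pa
        trace = np.convolve(impulses, kernel)[:n]
        if p.noise_sd_pa > 0:
            trace = trace + rng.normal(0.0, p.noise_sd_pa, n)
        sweeps[tr] = trace
        order = np.argsort(times) if times else []
        ev_times.append(np.asarray(times)[order] if times else np.zeros(0))
        ev_labels.append(np.asarray(labels)[order] if times
                         else np.zeros(0, dtype="U5"))
        ev_pulse.append(np.asarray(pulses)[order] if times
                        else np.zeros(0, dtype=int))
    sweep_set = SweepSet(sweeps=sweeps, fs=p.fs, pulse_times=pulse_times,
                         protocol="train")
    truth = EphysGroundTruth(
        event_times=ev_times, event_labels=ev_labels, event_pulse=ev_pulse,
        failures=failures, quantal_pa=p.quantal_pa,
        sync_latency_ms=p.sync_latency_ms, sync_jitter_ms=p.sync_jitter_ms,
        noise_sd=p.noise_sd_pa)
    return sweep_set, truth


# ---------------------------------------------------------------------------
# intrinsic protocols

@dataclass
class IntrinsicSimParams:
    tau_ms: float = 15.0
    rin_mohm: float = 150.0
    threshold_mv: float = -42.0
    ap_peak_mv: float = 38.0
    ahp_depth_mv: float = 8.0
    sag_frac: float = 0.3
    sag_tau_ms: float = 150.0
    reversal_mv: float = -90.0
    v_rest_mv: float = -70.0
    fs: float = 20000.0
    noise_sd_mv: float = 0.05
    noise_sd_pa: float = 5.0
    g_leak_ns: float = 2.0
    g_k_ns: float = 10.0

    def validate(self) -> None:
        for name in ("tau_ms", "rin_mohm", "fs", "sag_tau_ms"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0.0 <= self.sag_frac <= 1.0:
            raise ValueError("sag_frac must be in [0, 1]")


@dataclass
class IntrinsicProtocols:
    """One cell's worth of stimulus protocols."""

    rin_steps: SweepSet          # family of subthreshold current steps
    tau_sweeps: SweepSet         # 20 repeats of a small 400 ms step
    sag_sweep: SweepSet          # 1 s hyperpolarising step to −100 mV
    rheobase_sweep: SweepSet     # single sweep with one spike
    firing_steps: SweepSet       # family of 1 s suprathreshold steps
    ramp_v_mv: np.ndarray        # voltage-ramp command
    ramp_i_pa: np.ndarray        # recorded ramp current
    step_onset_s: float = 0.1
    step_dur_s: float = 1.0
    tau_step_dur_s: float = 0.4


def _step_response(p, i_pa, onset, dur, total, rng):
    """Passive exponential voltage response to a current step."""
    n = int(round(total * p.fs))
    t = np.arange(n) / p.fs
    dv = i_pa * p.rin_mohm / 1e3   # pA × MΩ → mV/1000
    v = np.full(n, p.v_rest_mv)
    on = int(round(onset * p.fs))
    off = min(n, int(round((onset + dur) * p.fs)))
    tt = t[on:off] - t[on]
    v[on:off] += dv * (1 - np.exp(-tt * 1e3 / p.tau_ms))
    tt2 = t[off:] - t[off]
    v_off = v[off - 1] - p.v_rest_mv
    v[off:] += v_off * np.exp(-tt2 * 1e3 / p.tau_ms)
    if p.noise_sd_mv > 0:
        v = v + rng.normal(0.0, p.noise_sd_mv, n)
    return v


def _spike_template(p) -> tuple[np.ndarray, int]:
    """Stereotyped spike waveform starting at threshold; returns the
    waveform (relative to threshold) and the peak sample index.

    The upstroke starts at 30 mV/ms and accelerates, so the dV/dt >
    10 mV/ms criterion fires at the threshold sample itself.
    """
    dt_ms = 1e3 / p.fs
    amp = p.ap_peak_mv - p.threshold_mv
    up = [0.0]
    v = 0.0
    while v < amp:
        rate = 30.0 + 270.0 * (v / amp)
        v = v + rate * dt_ms
        up.append(min(v, amp))
    up = np.asarray(up)
    peak_idx = len(up) - 1
    # repolarisation to the AHP trough, then partial recovery
    down = [amp]
    v = amp
    trough = -p.ahp_depth_mv
    while v > trough + 0.05:
        v = trough + (v - trough) * math.exp(-dt_ms / 0.8)
        down.append(v)
    rec = []
    v = down[-1]
    for _ in range(int(round(0.01 * p.fs))):
        v = -2.0 + (v + 2.0) * math.exp(-dt_ms / p.tau_ms)
        rec.append(v)
    wave = np.concatenate([up, down[1:], rec])
    return wave, peak_idx


def _rheobase_sweep(p, rng) -> np.ndarray:
    n = int(round(0.4 * p.fs))
    t = np.arange(n) / p.fs
    on = int(round(0.1 * p.fs))
    v_target = p.threshold_mv + 5.0
    v = np.full(n, p.v_rest_mv)
    tt = (t[on:] - t[on]) * 1e3
    v[on:] = v_target + (p.v_rest_mv - v_target) * np.exp(-tt / p.tau_ms)
    cross = np.flatnonzero(v >= p.threshold_mv)
    i0 = int(cross[0])
    wave, _ = _spike_template(p)
    end = min(n, i0 + len(wave))
    v[i0:end] = p.threshold_mv + wave[:end - i0]
    if end < n:
        # settle below threshold after the spike
        tt2 = (t[end:] - t[end]) * 1e3
        v[end:] = (p.threshold_mv - 2.0) + (v[end - 1]
                                            - (p.threshold_mv - 2.0)) \
            * np.exp(-tt2 / p.tau_ms)
        v[end:] = np.minimum(v[end:], p.threshold_mv - 1.0)
    if p.noise_sd_mv > 0:
        v = v + rng.normal(0.0, p.noise_sd_mv, n)
    return v


def _sag_sweep(p, rng) -> np.ndarray:
    onset, dur, total = 0.2, 1.0, 1.5
    n = int(round(total * p.fs))
    t = np.arange(n) / p.fs
    on = int(round(onset * p.fs))
    off = int(round((onset + dur) * p.fs))
    D = -100.0 - p.v_rest_mv                  # deflection to −100 mV
    v = np.full(n, p.v_rest_mv)
    tt = (t[on:off] - t[on]) * 1e3
    fast = D * (1 - np.exp(-tt / p.tau_ms))
    delay_ms = 5 * p.tau_ms
    reb = np.where(tt > delay_ms,
                   p.sag_frac * (-D) * (1 - np.exp(-(tt - delay_ms)
                                                   / p.sag_tau_ms)),
                   0.0)
    v[on:off] += fast + reb
    tt2 = (t[off:] - t[off]) * 1e3
    v[off:] += (v[off - 1] - p.v_rest_mv) * np.exp(-tt2 / p.tau_ms)
    if p.noise_sd_mv > 0:
        v = v + rng.normal(0.0, p.noise_sd_mv, n)
    return v


def _firing_steps(p, rng) -> tuple[np.ndarray, np.ndarray, float, float]:
    """1 s depolarising step family with prescribed accommodating trains."""
    wave, peak_idx = _spike_template(p)
    onset, dur, total = 0.1, 1.0, 1.3
    n = int(round(total * p.fs))
    levels = np.array([100.0, 200.0, 300.0, 400.0])
    rates = np.array([8, 16, 28, 37])
    accom_growth = 1.5      # last ISIs this much longer than the first
    sweeps = np.empty((len(levels), n))
    best = np.argmax(rates)
    truth_acc = None
    for si, n_spk in enumerate(rates):
        v = np.full(n, p.v_rest_mv)
        on = int(round(onset * p.fs))
        off = int(round((onset + dur) * p.fs))
        v[on:off] = p.threshold_mv - 2.0
        # ISI sequence growing linearly by accom_growth, scaled to fit 1 s
        w = 1.0 + (accom_growth - 1.0) * np.arange(n_spk - 1) / max(
            1, n_spk - 2)
        isis = 0.95 * dur * w / w.sum()
        times = onset + 0.01 + np.concatenate([[0.0], np.cumsum(isis)])
        for t_spk in times:
            i0 = int(round(t_spk * p.fs))
            end = min(n, i0 + len(wave))
            v[i0:end] = p.threshold_mv + wave[:end - i0]
        if si == best:
            truth_acc = float(isis[0] / isis[-2:].mean())
        if p.noise_sd_mv > 0:
            v = v + rng.normal(0.0, p.noise_sd_mv, n)
        sweeps[si] = v
    return sweeps, levels, float(rates.max() / dur), truth_acc


def _ramp_iv(p, rng) -> tuple[np.ndarray, np.ndarray]:
    n = int(round(0.1 * p.fs))
    v = np.linspace(100.0, -200.0, n)
    act = 1.0 / (1.0 + np.exp((v + 60.0) / 8.0))   # rectifier, shut when
    i = p.g_leak_ns * v + p.g_k_ns * act * (v - p.reversal_mv)  # depolarised
    if p.noise_sd_pa > 0:
        i = i + rng.normal(0.0, p.noise_sd_pa, n)
    return v, i


def simulate_intrinsic_protocols(params: IntrinsicSimParams | None = None,
                                 seed: int = 0,
                                 ) -> tuple[IntrinsicProtocols,
                                            EphysGroundTruth]:
    """Generate the full intrinsic-property protocol battery for one
    model cell with known τ, R_in, threshold, sag and K⁺ reversal."""
    p = params or IntrinsicSimParams()
    p.validate()
    rng = np.random.default_rng(seed)
    no_pulses = np.zeros(0)

    i_levels = np.linspace(-100.0, -5.0, 20)
    rin_sweeps = np.stack([_step_response(p, i, 0.1, 0.5, 0.8, rng)
                           for i in i_levels])
    rin_steps = SweepSet(sweeps=rin_sweeps, fs=p.fs, pulse_times=no_pulses,
                         protocol="rin", stim_levels=i_levels)

    tau_sweeps = np.stack([_step_response(p, -20.0, 0.1, 0.4, 0.7, rng)
                           for _ in range(20)])
    tau_set = SweepSet(sweeps=tau_sweeps, fs=p.fs, pulse_times=no_pulses,
                       protocol="tau")

    sag_set = SweepSet(sweeps=_sag_sweep(p, rng)[None, :], fs=p.fs,
                       pulse_times=no_pulses, protocol="sag")
    rheo_set = SweepSet(sweeps=_rheobase_sweep(p, rng)[None, :], fs=p.fs,
                        pulse_times=no_pulses, protocol="rheobase")
    fire_sweeps, fire_levels, max_rate, accom = _firing_steps(p, rng)
    fire_set = SweepSet(sweeps=fire_sweeps, fs=p.fs, pulse_times=no_pulses,
                        protocol="firing", stim_levels=fire_levels)
    ramp_v, ramp_i = _ramp_iv(p, rng)

    protocols = IntrinsicProtocols(
        rin_steps=rin_steps, tau_sweeps=tau_set, sag_sweep=sag_set,
        rheobase_sweep=rheo_set, firing_steps=fire_set,
        ramp_v_mv=ramp_v, ramp_i_pa=ramp_i)
    truth = EphysGroundTruth(
        tau_ms=p.tau_ms, rin_mohm=p.rin_mohm, threshold_mv=p.threshold_mv,
        ap_peak_mv=p.ap_peak_mv, sag_frac=p.sag_frac,
        reversal_mv=p.reversal_mv, rmp_mv=p.v_rest_mv,
        max_rate_hz=max_rate, accommodation=accom, noise_sd=p.noise_sd_mv)
    return protocols, truth
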