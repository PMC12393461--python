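"""Intrinsic membrane and firing properties from current/voltage-clamp
protocol sweeps.

Extractors implement the standard slice-physiology definitions: spike
threshold at the dV/dt > 10 mV/ms crossing of the first rheobase spike;
sag ratio as the steady-state over peak deflection of a 1 s
hyperpolarising step; maximum sustained firing over 1 s depolarising
steps with depolarisation-block sweeps excluded; accommodation as the
first interspike interval over the mean of the last two; input
resistance as the I–V slope across a step family; membrane tau from a
single-exponential fit to an averaged small step; and the K⁺ reversal
potential as the zero crossing of a voltage-ramp current after leak
subtraction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit
from scipy.signal import find_peaks

__all__ = [
    "IntrinsicProfile", "ap_threshold_and_shape", "sag_ratio",
    "firing_rate_and_accommodation", "input_resistance", "membrane_tau",
    "rmp_from_ramp", "profile_from_protocols", "SpikeError",
]


class SpikeError(ValueError):
    pass


@dataclass
class IntrinsicProfile:
    rmp_mv: float | None = None
    threshold_mv: float | None = None
    ap_amplitude_mv: float | None = None
    ahp_mv: float | None = None
    max_upstroke: float | None = None      # mV/ms
    max_downstroke: float | None = None    # mV/ms
    sag_ratio: float | None = None
    max_rate_hz: float | None = None
    accommodation: float | None = None
    rin_mohm: float | None = None
    tau_ms: float | None = None


def _dvdt(v: np.ndarray, fs: float) -> np.ndarray:
    """Centered-difference first derivative in mV/ms."""
    return np.gradient(np.asarray(v, dtype=float)) * fs / 1e3


def _spike_peaks(v: np.ndarray, height: float = -10.0,
                 prominence: float = 20.0) -> np.ndarray:
    peaks, _ = find_peaks(v, height=height, prominence=prominence)
    return peaks


def ap_threshold_and_shape(v: np.ndarray, fs: float,
                           dvdt_thresh: float = 10.0,
                           ahp_win_ms: float = 50.0) -> dict:
    """Threshold, amplitude, AHP and upstroke/downstroke of the first
    spike in a rheobase sweep.

    The threshold is the voltage at the start of the contiguous
    suprathreshold-dV/dt run leading into the spike peak; amplitude is
    peak − threshold, AHP is threshold − post-spike minimum.
    """
    v = np.asarray(v, dtype=float)
    peaks = _spike_peaks(v)
    if len(peaks) == 0:
        raise SpikeError("no spike in sweep")
    peak = int(peaks[0])
    dv = _dvdt(v, fs)
    above = np.flatnonzero(dv[:peak + 1] > dvdt_thresh)
    if above.size == 0:
        raise SpikeError(f"dV/dt never exceeds {dvdt_thresh} mV/ms before "
                         "the spike peak")
    # start of the final contiguous run before the peak
    idx = above[-1]
    run_start = idx
    k = len(above) - 1
    while k > 0 and above[k - 1] == above[k] - 1:
        k -= 1
        run_start = above[k]
    thr_idx = int(run_start)
    threshold = float(v[thr_idx])
    amplitude = float(v[peak] - threshold)
    end = min(len(v), peak + int(round(ahp_win_ms / 1e3 * fs)))
    nxt = peaks[1] if len(peaks) > 1 else end
    end = min(end, int(nxt))
    ahp = float(threshold - v[peak:end].min())
    spike_dv = dv[thr_idx:end]
    return {
        "threshold_mv": threshold,
        "ap_amplitude_mv": amplitude,
        "ahp_mv": ahp,
        "max_upstroke": float(spike_dv.max()),
        "max_downstroke": float(spike_dv.min()),
        "peak_idx": peak,
        "threshold_idx": thr_idx,
    }


def sag_ratio(v: np.ndarray, fs: float, baseline_win_s: tuple,
              step_win_s: tuple, ss_ms: float = 100.0,
              convention: str = "deflection") -> float:
    """Sag ratio of a hyperpolarising step (an I_h proxy).

    Under the deflection convention, (V_ss − V_base)/(V_peak − V_base)
    with V_ss the mean of the last ``ss_ms`` of the step and V_peak the
    step minimum; 1.0 means no sag.  ``raw`` divides the absolute
    voltages V_ss/V_peak instead.
    """
    v = np.asarray(v, dtype=float)
    b0, b1 = (int(round(t * fs)) for t in baseline_win_s)
    s0, s1 = (int(round(t * fs)) for t in step_win_s)
    v_base = v[b0:b1].mean()
    v_peak = v[s0:s1].min()
    ss0 = max(s0, s1 - int(round(ss_ms / 1e3 * fs)))
    v_ss = v[ss0:s1].mean()
    if v_peak >= v_base:
        raise ValueError("step is not hyperpolarising (no negative "
                         "deflection)")
    if convention == "deflection":
        return float((v_ss - v_base) / (v_peak - v_base))
    if convention == "raw":
        return float(v_ss / v_peak)
    raise ValueError(f"unknown sag convention {convention!r}")


def firing_rate_and_accommodation(sweeps: np.ndarray, fs: float,
                                  step_dur_s: float = 1.0,
                                  block_amp_frac: float = 0.5) -> dict:
    """Maximum sustained firing rate and accommodation ratio over a
    family of 1 s depolarising steps.

    Sweeps entering depolarisation block — any spike whose prominence
    falls below ``block_amp_frac`` of the first spike's — are excluded
    from the rate maximisation.  Accommodation (first ISI over the mean
    of the last two) is computed at the max-rate sweep and requires ≥ 4
    spikes there.
    """
    sweeps = np.atleast_2d(np.asarray(sweeps, dtype=float))
    best_rate = 0.0
    best_isis = None
    for v in sweeps:
        peaks, props = find_peaks(v, height=-10.0, prominence=20.0)
        if len(peaks) == 0:
            continue
        prom = props["prominences"]
        if (prom < block_amp_frac * prom[0]).any():
            continue  # depolarization block: not sustained firing
        rate = len(peaks) / step_dur_s
        if rate > best_rate:
            best_rate = rate
            best_isis = np.diff(peaks) / fs
    accommodation = None
    if best_isis is not None and len(best_isis) >= 3:
        accommodation = float(best_isis[0] / best_isis[-2:].mean())
    return {"max_rate_hz": float(best_rate), "accommodation": accommodation}


def input_resistance(i_pa: np.ndarray, v_ss_mv: np.ndarray) -> float:
    """Input resistance (MΩ) as the least-squares I–V slope.

    ``i_pa`` are injected step currents (pA) and ``v_ss_mv`` the
    steady-state voltages; slope mV/pA = GΩ, returned × 1000 in MΩ.
    """
    i = np.asarray(i_pa, dtype=float)
    v = np.asarray(v_ss_mv, dtype=float)
    if i.size < 2 or np.ptp(i) == 0:
        raise ValueError("need >= 2 distinct current levels for an I-V fit")
    slope = np.polyfit(i, v, 1)[0]
    return float(slope * 1e3)


def membrane_tau(v: np.ndarray, fs: float, step_onset_idx: int,
                 step_end_idx: int | None = None) -> float:
    """Membrane time constant (ms) from a single-exponential fit to an
    averaged small-step response, V(t) = V∞ + A·e^(−t/τ).

    The fit runs from the step onset to ``step_end_idx`` (or the trace
    end); including post-step samples corrupts the fit, so pass the
    step offset when the sweep extends beyond it.
    """
    v = np.asarray(v, dtype=float)[step_onset_idx:step_end_idx]
    if np.ptp(v) < 1e-9:
        raise ValueError("flat response: exponential fit is degenerate")
    t = np.arange(len(v)) / fs * 1e3  # ms
    v_inf0 = v[-len(v) // 10:].mean()
    a0 = v[0] - v_inf0
    if abs(a0) < 1e-9:
        raise ValueError("zero-amplitude step: exponential fit is degenerate")

    def model(t, v_inf, a, tau):
        return v_inf + a * np.exp(-t / tau)

    try:
        popt, _ = curve_fit(model, t, v, p0=(v_inf0, a0, 20.0),
                            maxfev=10000)
    except RuntimeError as err:
        raise ValueError(f"exponential fit did not converge: {err}")
    tau = float(popt[2])
    if tau <= 0:
        raise ValueError(f"non-physical tau {tau} ms from fit")
    return tau


def rmp_from_ramp(v_mv: np.ndarray, i_pa: np.ndarray,
                  leak_frac: float = 0.3) -> float:
    """K⁺ reversal potential from a voltage-ramp I–V after leak
    subtraction.

    The linear leak is fitted over the most depolarised ``leak_frac``
    of the ramp (where the rectifying K⁺ conductance is shut) and
    subtracted; the reversal is the zero crossing of the residual
    current.  A sample-by-sample sign scan is biased by noise (the
    residual changes by far less than the noise s.d. between adjacent
    ramp samples), so the coarse crossing from a smoothed residual is
    refined by a local linear fit of the residual over ±10 mV.
    """
    v = np.asarray(v_mv, dtype=float)
    i = np.asarray(i_pa, dtype=float)
    order = np.argsort(v)
    v, i = v[order], i[order]
    n = len(v)
    n_leak = max(2, int(round(leak_frac * n)))
    slope, intercept = np.polyfit(v[-n_leak:], i[-n_leak:], 1)
    resid = i - (slope * v + intercept)
    # coarse crossing on a lightly smoothed residual (~1 mV window)
    v_span = v[-1] - v[0]
    w = max(1, int(round(n / max(v_span, 1.0))))
    smooth = np.convolve(resid, np.ones(w) / w, mode="same")
    start = int(np.argmin(smooth))
    # the inward residual must stand clear of the leak-fit scatter
    floor = max(1e-6, 5.0 * np.abs(smooth[-n_leak:]).max())
    if smooth[start] > -floor:
        raise ValueError("no inward residual current: reversal undefined")
    k = start
    while k < n - 1 and smooth[k + 1] < 0:
        k += 1
    if k == n - 1:
        raise ValueError("residual current never crosses zero")
    near = np.abs(v - v[k]) <= 10.0
    if near.sum() >= 3 and np.ptp(v[near]) > 0:
        a, b = np.polyfit(v[near], resid[near], 1)
        if a > 0:
            return float(-b / a)
    v0, v1 = v[k], v[k + 1]
    r0, r1 = smooth[k], smooth[k + 1]
    return float(v0 - r0 * (v1 - v0) / (r1 - r0))


def profile_from_protocols(protocols, dvdt_thresh: float = 10.0,
                           sag_convention: str = "deflection",
                           block_amp_frac: float = 0.5,
                           leak_frac: float = 0.3) -> IntrinsicProfile:
    """Run every extractor over a full protocol battery.

    ``protocols`` is any object exposing ``rin_steps``, ``tau_sweeps``,
    ``sag_sweep``, ``rheobase_sweep``, ``firing_steps`` sweep sets plus
    ``ramp_v_mv``/``ramp_i_pa`` and the step timing attributes (the
    synthetic-protocol container has this shape).
    """
    profile = IntrinsicProfile()
    fs = protocols.rin_steps.fs

    shape = ap_threshold_and_shape(protocols.rheobase_sweep.sweeps[0],
                                   protocols.rheobase_sweep.fs,
                                   dvdt_thresh=dvdt_thresh)
    profile.threshold_mv = shape["threshold_mv"]
    profile.ap_amplitude_mv = shape["ap_amplitude_mv"]
    profile.ahp_mv = shape["ahp_mv"]
    profile.max_upstroke = shape["max_upstroke"]
    profile.max_downstroke = shape["max_downstroke"]

    profile.sag_ratio = sag_ratio(
        protocols.sag_sweep.sweeps[0], protocols.sag_sweep.fs,
        baseline_win_s=(0.0, 0.2), step_win_s=(0.2, 1.2),
        convention=sag_convention)

    fire = firing_rate_and_accommodation(
        protocols.firing_steps.sweeps, protocols.firing_steps.fs,
        step_dur_s=protocols.step_dur_s, block_amp_frac=block_amp_frac)
    profile.max_rate_hz = fire["max_rate_hz"]
    profile.accommodation = fire["accommodation"]

    on = protocols.step_onset_s
    ss0 = int(round((on + 0.4) * fs))
    ss1 = int(round((on + 0.5) * fs))
    v_ss = protocols.rin_steps.sweeps[:, ss0:ss1].mean(axis=1)
    profile.rin_mohm = input_resistance(protocols.rin_steps.stim_levels, v_ss)

    avg = protocols.tau_sweeps.sweeps.mean(axis=0)
    tau_fs = protocols.tau_sweeps.fs
    profile.tau_ms = membrane_tau(
        avg, tau_fs, int(round(on * tau_fs)),
        int(round((on + protocols.tau_step_dur_s) * tau_fs)))

    profile.rmp_mv = rmp_from_ramp(protocols.ramp_v_mv, protocols.ramp_i_pa,
                                   leak_frac=leak_frac)
    return profile
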