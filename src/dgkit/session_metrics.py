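"""Session-level metrics: activity–velocity cross-correlation and
familiar/novel remapping statistics.

Cross-correlation sweeps integer frame shifts over ±5 s and reports the
signed Pearson r at the shift of maximum |r|; negative lag means
activity trails velocity, positive lag means activity leads.

Remapping compares spatial tuning within the familiar context
(split-half correlation r_ff) against tuning across contexts (familiar
vs novel correlation r_fn); Δ stability = r_ff − r_fn.  Cells whose
familiar tuning outlives the context switch have Δ near 0; cells that
remap have r_fn near 0 and Δ near r_ff.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .dff import boxcar_smooth
from .session_io import SessionData, lap_context_labels
from .spatial import TuningCurve, tuning_curve

__all__ = [
    "XcorrResult", "RemapResult",
    "activity_velocity_xcorr", "split_half_curves", "remap_stats",
    "remap_population_summary",
]


@dataclass
class XcorrResult:
    r: float                  # signed Pearson r at the optimal shift
    lag_s: float              # negative: activity trails velocity
    lags_s: np.ndarray        # shift grid, seconds
    profile: np.ndarray       # Pearson r per shift (NaN where excluded)


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    a = a - a.mean()
    b = b - b.mean()
    denom = math.sqrt((a @ a) * (b @ b))
    if denom == 0:
        return np.nan
    return float((a @ b) / denom)


def activity_velocity_xcorr(dff_row: np.ndarray, velocity: np.ndarray,
                            frame_rate: float, max_lag_s: float = 5.0,
                            smooth_s: float = 0.5,
                            min_overlap: int = 30) -> XcorrResult:
    """Pearson correlation between ΔF/F and smoothed velocity over a
    ±``max_lag_s`` sweep of integer frame shifts.

    The profile at lag k·Δt correlates ΔF/F(t) with velocity(t + k):
    at positive k the activity pattern precedes (leads) the velocity
    pattern.  Shifts whose overlap is shorter than ``min_overlap``
    frames are excluded from the maximisation.
    """
    x = np.asarray(dff_row, dtype=float)
    v = boxcar_smooth(np.asarray(velocity, dtype=float),
                      max(1, int(round(smooth_s * frame_rate))))
    T = len(x)
    L = int(round(max_lag_s * frame_rate))
    if T <= 2 * L:
        raise ValueError(f"trace of {T} frames too short for ±{max_lag_s} s "
                         "lag sweep")
    if np.ptp(x) == 0 or np.ptp(v) == 0:
        raise ValueError("zero-variance input: correlation undefined")
    ks = np.arange(-L, L + 1)
    profile = np.full(len(ks), np.nan)
    for i, k in enumerate(ks):
        if k >= 0:
            a, b = x[: T - k], v[k:]
        else:
            a, b = x[-k:], v[: T + k]
        if len(a) < min_overlap:
            continue
        profile[i] = _pearson(a, b)
    if np.all(np.isnan(profile)):
        raise ValueError("no admissible shift: all overlaps too short")
    best = int(np.nanargmax(np.abs(profile)))
    return XcorrResult(r=float(profile[best]), lag_s=float(ks[best] / frame_rate),
                       lags_s=ks / frame_rate, profile=profile)


def split_half_curves(dff_row: np.ndarray, session: SessionData,
                      context: str | None = "familiar",
                      mode: str = "contiguous",
                      **curve_kwargs) -> tuple[TuningCurve, TuningCurve]:
    """Tuning curves from the two halves of a context's laps.

    ``contiguous`` puts the first ⌈n/2⌉ laps in the first half;
    ``interleaved`` alternates laps between halves.
    """
    lap_ctx = lap_context_labels(session)
    laps = (np.arange(session.n_laps) if context is None
            else np.flatnonzero(lap_ctx == context))
    if len(laps) < 2:
        raise ValueError(f"need >= 2 laps in context {context!r}, "
                         f"got {len(laps)}")
    if mode == "contiguous":
        n_first = math.ceil(len(laps) / 2)
        halves = (laps[:n_first], laps[n_first:])
    elif mode == "interleaved":
        halves = (laps[::2], laps[1::2])
    else:
        raise ValueError(f"unknown split mode {mode!r}")
    curves = []
    for half in halves:
        mask = np.isin(session.lap_index, half)
        curves.append(tuning_curve(dff_row, session, context=context,
                                   frame_mask=mask, **curve_kwargs))
    return curves[0], curves[1]


@dataclass
class RemapResult:
    cell_id: str
    r_ff: float               # within-familiar split-half correlation
    r_fn: float               # familiar-vs-novel correlation
    delta_stability: float    # r_ff − r_fn
    klass: str                # decrease / increase / no_change
    valid: bool = True


def remap_stats(fam_half1: TuningCurve, fam_half2: TuningCurve,
                fam_full: TuningCurve, nov_full: TuningCurve,
                cell_id: str = "", tol: float = 0.01) -> RemapResult:
    """Within- vs between-context tuning stability for one tuned cell.

    ``decrease`` means stability decreases across contexts (Δ > tol,
    familiar tuning is the more stable), ``increase`` the converse, and
    |Δ| ≤ tol is ``no_change``.  Zero-variance curves make a correlation
    undefined; the cell is flagged invalid and excluded from summaries.
    """
    def corr(a: TuningCurve, b: TuningCurve) -> float:
        if np.ptp(a.values) == 0 or np.ptp(b.values) == 0:
            return np.nan
        return float(stats.pearsonr(a.values, b.values).statistic)

    r_ff = corr(fam_half1, fam_half2)
    r_fn = corr(fam_full, nov_full)
    if np.isnan(r_ff) or np.isnan(r_fn):
        return RemapResult(cell_id, r_ff, r_fn, np.nan, "undefined",
                           valid=False)
    delta = r_ff - r_fn
    if delta > tol:
        klass = "decrease"
    elif delta < -tol:
        klass = "increase"
    else:
        klass = "no_change"
    return RemapResult(cell_id, r_ff, r_fn, delta, klass)


def remap_population_summary(results: list[RemapResult]) -> dict:
    """Class proportions over valid cells plus mean Δ stability ± s.e.m."""
    valid = [r for r in results if r.valid]
    if not valid:
        raise ValueError("no valid remap results to summarise")
    n = len(valid)
    props = {k: sum(r.klass == k for r in valid) / n
             for k in ("decrease", "increase", "no_change")}
    deltas = np.array([r.delta_stability for r in valid])
    sem = deltas.std(ddof=1) / math.sqrt(n) if n > 1 else np.nan
    return {"proportions": props, "mean_delta": float(deltas.mean()),
            "sem_delta": float(sem), "n": n,
            "n_excluded": len(results) - n}
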