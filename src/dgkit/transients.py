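"""Significant calcium-transient detection.

Candidate events open when ΔF/F exceeds ``onset_sd`` (default 3) noise
standard deviations and close when it next falls below ``offset_sd``
(default 0.5) s.d.  Significance is duration-based: the false-positive
rate at duration d is estimated as the ratio of negative-going to
positive-going events of duration ≥ d (negative excursions of a
baseline-corrected trace can only be noise, so they calibrate the noise
tail), and events are retained where that rate is below ``alpha``
(default 5%).

Because the counts at long durations are tiny for a single cell, the
ratio is meant to be computed over a pool of events — typically every
cell in a session (:func:`detect_session_transients` does this).  The
curve degenerates for a single trace, where the longest positive
excursion of pure noise has no negative counterpart about half the
time.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .dff import DffTraces

__all__ = [
    "TransientEvent", "FprCurve", "TransientSet",
    "detect_candidates", "estimate_noise_sd", "fpr_by_duration",
    "select_significant", "transient_frequency", "detect_session_transients",
    "estimate_noise_stats",
    "NoiseEstimateError",
]


class NoiseEstimateError(ValueError):
    pass


@dataclass
class TransientEvent:
    cell_id: str
    sign: int                # +1 or -1
    onset: int               # first frame above onset threshold
    offset: int              # first subsequent frame below offset threshold
    peak: float              # extreme ΔF/F within [onset, offset)
    truncated: bool = False  # closed by trace end, not by threshold

    @property
    def duration(self) -> int:
        return self.offset - self.onset


def detect_candidates(x: np.ndarray, sd: float, onset_k: float = 3.0,
                      offset_k: float = 0.5, sign: int = 1,
                      cell_id: str = "") -> list[TransientEvent]:
    """Scan one trace for threshold-crossing events of the given sign.

    An event opens at the first frame where ``sign * x`` exceeds
    ``onset_k * sd`` and closes at the first later frame below
    ``offset_k * sd``; an event still open at the trace end is closed at
    the last frame and flagged ``truncated``.
    """
    if sd <= 0:
        raise NoiseEstimateError(f"noise s.d. must be positive, got {sd}")
    y = sign * np.asarray(x, dtype=float)
    n = len(y)
    on_idx = np.flatnonzero(y > onset_k * sd)
    off_idx = np.flatnonzero(y < offset_k * sd)
    events: list[TransientEvent] = []
    pos = 0
    i_on = 0
    while i_on < len(on_idx):
        if on_idx[i_on] < pos:
            i_on += 1
            continue
        onset = int(on_idx[i_on])
        j = np.searchsorted(off_idx, onset + 1)
        if j < len(off_idx):
            offset = int(off_idx[j])
            truncated = False
        else:
            offset = n
            truncated = True
        peak = float(sign * y[onset:offset].max())
        events.append(TransientEvent(cell_id=cell_id, sign=sign, onset=onset,
                                     offset=offset, peak=peak,
                                     truncated=truncated))
        pos = offset + 1
        i_on = np.searchsorted(on_idx, pos)
    return events


def estimate_noise_stats(x: np.ndarray, onset_k: float = 3.0,
                         offset_k: float = 0.5, max_iters: int = 5,
                         method: str = "excise") -> tuple[float, float]:
    """Noise center and s.d. of a ΔF/F trace with transients excised.

    The rolling-minimum baseline leaves ΔF/F with a small positive
    offset (F0 tracks the noise minimum, not its mean), so thresholds
    stated in s.d. units are referenced to the estimated center rather
    than to zero — otherwise positive and negative excursions are not
    exchangeable and the negative-event FPR calibration breaks.

    ``excise`` iterates: estimate center/s.d., detect candidate events
    of both signs at the working thresholds on the centered trace, drop
    their frames, and re-estimate, until the s.d. stabilises
    (≤ ``max_iters`` rounds).  ``mad`` uses the median and
    1.4826 · MAD instead.  Returns ``(center, sd)``.
    """
    x = np.asarray(x, dtype=float)
    if method == "mad":
        mu = float(np.median(x))
        sd = 1.4826 * np.median(np.abs(x - mu))
        if sd <= 0:
            raise NoiseEstimateError("degenerate (constant) trace")
        return mu, float(sd)
    if method != "excise":
        raise ValueError(f"unknown noise estimator {method!r}")
    mu = float(np.mean(x))
    sd = float(np.std(x))
    if sd <= 0:
        raise NoiseEstimateError("degenerate (constant) trace")
    for _ in range(max_iters):
        keep = np.ones(len(x), dtype=bool)
        for sign in (1, -1):
            for ev in detect_candidates(x - mu, sd, onset_k, offset_k, sign):
                keep[ev.onset:ev.offset] = False
        if not keep.any():
            raise NoiseEstimateError("all frames excised during noise "
                                     "estimation")
        new_mu = float(np.mean(x[keep]))
        new_sd = float(np.std(x[keep]))
        if new_sd <= 0:
            raise NoiseEstimateError("degenerate trace after excision")
        converged = abs(new_sd - sd) <= 1e-4 * sd
        mu, sd = new_mu, new_sd
        if converged:
            break
    return mu, sd


def estimate_noise_sd(x: np.ndarray, onset_k: float = 3.0,
                      offset_k: float = 0.5, max_iters: int = 5,
                      method: str = "excise") -> float:
    """Noise s.d. of a ΔF/F trace with transients excised (see
    :func:`estimate_noise_stats`)."""
    return estimate_noise_stats(x, onset_k, offset_k, max_iters, method)[1]


@dataclass
class FprCurve:
    """Duration-conditional false-positive rate.

    ``fpr[d - 1]`` is (# negative events with duration ≥ d) /
    (# positive events with duration ≥ d), for d = 1 … max duration;
    ``inf`` where no positive event reaches d.
    """

    fpr: np.ndarray
    n_pos: np.ndarray
    n_neg: np.ndarray

    def rate(self, duration: int) -> float:
        if duration < 1:
            raise ValueError("duration must be a positive integer")
        if duration > len(self.fpr):
            return 0.0 if self.n_neg.size and self.n_neg[-1] == 0 else np.inf
        return float(self.fpr[duration - 1])


def _cum_counts(durations: np.ndarray, max_dur: int) -> np.ndarray:
    # counts[d-1] = number of events with duration >= d
    hist = np.bincount(durations, minlength=max_dur + 1)[1:max_dur + 1]
    return np.cumsum(hist[::-1])[::-1]


def fpr_by_duration(pos: list[TransientEvent],
                    neg: list[TransientEvent]) -> FprCurve:
    """Cumulative negative/positive event-count ratio by duration.

    Event lists may be pooled over any number of traces detected at the
    same thresholds; pooling across all cells of a session is how the
    curve is normally built.
    """
    pos_d = np.array([e.duration for e in pos], dtype=int)
    neg_d = np.array([e.duration for e in neg], dtype=int)
    max_dur = int(max(pos_d.max() if pos_d.size else 0,
                      neg_d.max() if neg_d.size else 0))
    if max_dur == 0:
        return FprCurve(fpr=np.zeros(0), n_pos=np.zeros(0, int),
                        n_neg=np.zeros(0, int))
    n_pos = _cum_counts(pos_d, max_dur) if pos_d.size else np.zeros(max_dur, int)
    n_neg = _cum_counts(neg_d, max_dur) if neg_d.size else np.zeros(max_dur, int)
    with np.errstate(divide="ignore", invalid="ignore"):
        fpr = np.where(n_pos > 0, n_neg / np.maximum(n_pos, 1), np.inf)
    fpr[(n_pos == 0) & (n_neg == 0)] = np.inf
    return FprCurve(fpr=fpr, n_pos=n_pos, n_neg=n_neg)


@dataclass
class TransientSet:
    """Significant events for one or more cells, with provenance."""

    events: list[TransientEvent]
    noise_sd: dict                     # cell_id -> s.d. used for detection
    params: dict = field(default_factory=dict)
    min_significant_duration: int | None = None

    def events_for(self, cell_id: str) -> list[TransientEvent]:
        return [e for e in self.events if e.cell_id == cell_id]

    def frame_mask(self, cell_id: str, n_frames: int) -> np.ndarray:
        """Boolean mask of frames covered by this cell's events."""
        m = np.zeros(n_frames, dtype=bool)
        for e in self.events_for(cell_id):
            m[e.onset:e.offset] = True
        return m


def select_significant(pos: list[TransientEvent], curve: FprCurve,
                       alpha: float = 0.05,
                       noise_sd: dict | None = None) -> TransientSet:
    """Retain positive events whose duration-conditional FPR is < alpha."""
    kept = [e for e in pos if curve.rate(e.duration) < alpha]
    sig_durations = [d for d in range(1, len(curve.fpr) + 1)
                     if curve.fpr[d - 1] < alpha]
    return TransientSet(
        events=kept,
        noise_sd=noise_sd or {},
        params={"alpha": alpha},
        min_significant_duration=min(sig_durations) if sig_durations else None,
    )


def transient_frequency(tset: TransientSet, duration_s: float,
                        cell_ids: list[str] | None = None):
    """Events per minute per cell; zero-event cells are flagged excluded.

    Returns ``{cell_id: (freq_per_min, excluded)}``; cells with no
    significant transient are excluded from frequency statistics.
    """
    if duration_s <= 0:
        raise ValueError("duration_s must be positive")
    if cell_ids is None:
        cell_ids = sorted({e.cell_id for e in tset.events})
    counts = {c: 0 for c in cell_ids}
    for e in tset.events:
        if e.cell_id in counts:
            counts[e.cell_id] += 1
    minutes = duration_s / 60.0
    return {c: (n / minutes, n == 0) for c, n in counts.items()}


def detect_session_transients(dff: DffTraces, cell_ids: list[str],
                              onset_k: float = 3.0, offset_k: float = 0.5,
                              alpha: float = 0.05,
                              noise_method: str = "excise") -> TransientSet:
    """Full detection for a session with the FPR pooled across cells.

    Per cell: estimate the noise s.d., detect positive and negative
    candidates; then build one duration-FPR curve from all cells' events
    and keep each cell's positive events passing ``FPR < alpha``.
    """
    pos_all: list[TransientEvent] = []
    neg_all: list[TransientEvent] = []
    sds: dict = {}
    for i, cid in enumerate(cell_ids):
        mu, sd = estimate_noise_stats(dff.dff[i], onset_k, offset_k,
                                      method=noise_method)
        sds[cid] = sd
        x = dff.dff[i] - mu
        pos_all.extend(detect_candidates(x, sd, onset_k, offset_k, 1, cid))
        neg_all.extend(detect_candidates(x, sd, onset_k, offset_k, -1, cid))
    curve = fpr_by_duration(pos_all, neg_all)
    tset = select_significant(pos_all, curve, alpha, noise_sd=sds)
    tset.params.update({"onset_k": onset_k, "offset_k": offset_k,
                        "noise_method": noise_method, "pooled": True})
    return tset
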