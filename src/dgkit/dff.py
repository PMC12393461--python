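"""ΔF/F conversion with a smoothed rolling-minimum baseline.

The baseline follows the Jia et al. scheme: the raw trace is boxcar-
smoothed over a centered window of t1 = 3 s, the baseline F0(t) is the
minimum of the smoothed trace over the trailing window [t − t2, t] with
t2 = 60 s, and ΔF/F = (F − F0)/F0.  Frames more than ``mask_sd``
standard deviations above the provisional trace's mean are treated as
putative transients: they are bridged by linear interpolation before
smoothing/minimum-taking so events do not contaminate the baseline, and
the exclude-and-recompute cycle runs twice.

Windows are truncated at trace boundaries (no padding is fabricated
outside the session).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import minimum_filter1d

__all__ = ["DffTraces", "compute_dff", "boxcar_smooth", "trailing_min",
           "DffError"]


class DffError(ValueError):
    pass


def boxcar_smooth(x: np.ndarray, width: int) -> np.ndarray:
    """Centered uniform (boxcar) average, truncated at the edges.

    The window at frame t is [t - width//2, t + (width - width//2) - 1]
    clipped to the trace; the mean uses only the frames present.
    """
    x = np.asarray(x, dtype=float)
    if width <= 1:
        return x.copy()
    n = x.shape[-1]
    c = np.concatenate([np.zeros(x.shape[:-1] + (1,)), np.cumsum(x, axis=-1)],
                       axis=-1)
    half = width // 2
    lo = np.clip(np.arange(n) - half, 0, n)
    hi = np.clip(np.arange(n) - half + width, 0, n)
    return (c[..., hi] - c[..., lo]) / (hi - lo)


def trailing_min(x: np.ndarray, width: int) -> np.ndarray:
    """Minimum over the trailing window [t - width + 1, t], truncated at
    the trace start."""
    x = np.asarray(x, dtype=float)
    if width <= 1:
        return x.copy()
    # 'nearest' padding repeats x[0], which the truncated window always
    # contains, so edge values equal the true truncated-window minimum;
    # origin (w-1)//2 shifts the centered window to end at t
    return minimum_filter1d(x, size=width, mode="nearest",
                            origin=(width - 1) // 2, axis=-1)


def _interpolate_masked(x: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Bridge masked frames by linear interpolation (edges held flat)."""
    if not mask.any():
        return x
    if mask.all():
        raise DffError("all frames masked during baseline estimation")
    out = x.copy()
    idx = np.arange(len(x))
    out[mask] = np.interp(idx[mask], idx[~mask], x[~mask])
    return out


@dataclass
class DffTraces:
    """Relative fluorescence change with its baseline and mask."""

    dff: np.ndarray          # (cells, frames), dimensionless
    f0: np.ndarray           # (cells, frames), baseline in raw units
    noise_sd: np.ndarray     # (cells,), robust per-cell ΔF/F noise scale
    mask: np.ndarray         # (cells, frames), True = excluded from baseline
    frame_rate: float

    def __post_init__(self):
        self.dff = np.atleast_2d(np.asarray(self.dff, dtype=float))
        self.f0 = np.atleast_2d(np.asarray(self.f0, dtype=float))
        self.mask = np.atleast_2d(np.asarray(self.mask, dtype=bool))
        self.noise_sd = np.atleast_1d(np.asarray(self.noise_sd, dtype=float))

    @property
    def n_cells(self) -> int:
        return self.dff.shape[0]

    @property
    def n_frames(self) -> int:
        return self.dff.shape[1]


def _dff_row(raw: np.ndarray, w1: int, w2: int, mask_sd: float,
             n_mask_iters: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    clean = raw
    mask = np.zeros(raw.shape, dtype=bool)
    for _ in range(n_mask_iters):
        mu = clean.mean()
        sd = clean.std()
        mask = mask | (clean > mu + mask_sd * sd)
        clean = _interpolate_masked(raw, mask)
    f0 = trailing_min(boxcar_smooth(clean, w1), w2)
    if (f0 <= 0).any():
        frame = int(np.argmax(f0 <= 0))
        raise DffError(f"nonpositive baseline F0 at frame {frame}")
    return (raw - f0) / f0, f0, mask


def compute_dff(raw: np.ndarray, frame_rate: float, t1_s: float = 3.0,
                t2_s: float = 60.0, mask_sd: float = 2.0,
                n_mask_iters: int = 2) -> DffTraces:
    """Convert raw fluorescence (cells × frames, or one row) to ΔF/F.

    Parameters
    ----------
    raw
        Positive raw fluorescence, shape ``(cells, frames)`` or
        ``(frames,)``.
    frame_rate
        Acquisition rate in Hz.
    t1_s, t2_s
        Boxcar smoothing and rolling-minimum baseline windows (seconds).
    mask_sd, n_mask_iters
        Transient-masking threshold (s.d. above the provisional mean)
        and number of exclude-and-recompute passes.
    """
    raw = np.atleast_2d(np.asarray(raw, dtype=float))
    n = raw.shape[1]
    w1 = max(1, int(round(t1_s * frame_rate)))
    w2 = max(1, int(round(t2_s * frame_rate)))
    if n <= w2:
        raise DffError(
            f"trace of {n} frames is shorter than the baseline window "
            f"({w2} frames = {t2_s} s at {frame_rate} Hz)")
    if (raw <= 0).any():
        raise DffError("raw fluorescence must be strictly positive")
    dff = np.empty_like(raw)
    f0 = np.empty_like(raw)
    mask = np.zeros(raw.shape, dtype=bool)
    for i in range(raw.shape[0]):
        dff[i], f0[i], mask[i] = _dff_row(raw[i], w1, w2, mask_sd,
                                          n_mask_iters)
    # robust noise scale per cell; the transient detector refines this
    med = np.median(dff, axis=1, keepdims=True)
    noise_sd = 1.4826 * np.median(np.abs(dff - med), axis=1)
    return DffTraces(dff=dff, f0=f0, noise_sd=noise_sd, mask=mask,
                     frame_rate=frame_rate)
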