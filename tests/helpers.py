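"""Shared independent oracles for the test suite.

These deliberately re-derive quantities with direct, window-by-window
computations so they stay independent of the vectorised implementation
paths they check.
"""

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


def oracle_dff(raw, frame_rate, t1_s=3.0, t2_s=60.0, mask_sd=2.0,
               n_mask_iters=2):
    """Brute-force boxcar + rolling-minimum ΔF/F baseline.

    Materialises every smoothing/minimum window explicitly (NaN / +inf
    padding plus nanmean / min over the window axis) instead of the
    cumulative-sum and running-minimum filters the implementation uses.
    """
    raw = np.asarray(raw, dtype=float)
    n = len(raw)
    w1 = max(1, int(round(t1_s * frame_rate)))
    w2 = max(1, int(round(t2_s * frame_rate)))
    idx = np.arange(n)
    clean = raw.copy()
    mask = np.zeros(n, dtype=bool)
    for _ in range(n_mask_iters):
        mask = mask | (clean > clean.mean() + mask_sd * clean.std())
        clean = raw.copy()
        if mask.any():
            clean[mask] = np.interp(idx[mask], idx[~mask], raw[~mask])
    half = w1 // 2
    padded = np.concatenate([np.full(half, np.nan), clean,
                             np.full(w1 - half - 1, np.nan)])
    sm = np.nanmean(sliding_window_view(padded, w1), axis=1)
    padded_min = np.concatenate([np.full(w2 - 1, np.inf), sm])
    f0 = sliding_window_view(padded_min, w2).min(axis=1)
    return (raw - f0) / f0, f0


def oracle_tuning_curve(dff_row, position, velocity, bin_cm, n_bins,
                        speed_thresh, frame_keep=None):
    """Per-lap-free direct binned mean (no smoothing, no interpolation)."""
    keep = velocity > speed_thresh
    if frame_keep is not None:
        keep = keep & frame_keep
    sums = np.zeros(n_bins)
    counts = np.zeros(n_bins)
    for x, p, k in zip(np.asarray(dff_row, float), position, keep):
        if not k:
            continue
        b = min(int(p // bin_cm), n_bins - 1)
        sums[b] += x
        counts[b] += 1
    with np.errstate(invalid="ignore"):
        return sums / counts, counts
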