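# Methods

This note documents the models and procedures implemented in `dgkit`,
the defaults and why they were chosen, what the synthetic-data
generators do and do not emulate, and the numerical decisions made
where the underlying analysis conventions leave latitude.

## ΔF/F baseline (`dgkit.dff`)

The baseline follows the smoothed rolling-minimum scheme standard in
2-photon imaging: the raw trace is boxcar-averaged over a centered
window of t1 = 3 s, F0(t) is the minimum of the smoothed trace over
the trailing window [t − t2, t] with t2 = 60 s, and
ΔF/F = (F − F0)/F0.  Before the baseline is taken, frames more than
`mask_sd` = 2 standard deviations above the provisional trace's mean
are treated as putative transients, bridged by linear interpolation,
and the mask/recompute cycle runs `n_mask_iters` = 2 times so events do
not drag the baseline up.  Choices:

* **Edge handling.** Windows truncate at the trace boundaries; no
  pre-session samples are fabricated.  A consequence is that within
  the first t1/2 of a session the centered smoother can average future
  frames, so the usual "ΔF/F ≥ 0 for nondecreasing F" property holds
  only after that edge.
* **Centered t1 window.** Causal versus centered smoothing is a free
  choice; centered introduces no systematic onset delay.
* **Masking statistics.** The masking s.d. is that of the full
  provisional trace, recomputed each iteration.
* The rolling-minimum implementation (cumulative sums + running-minimum
  filter) is verified against an explicit window-by-window oracle to
  ~1e-13; trace length must exceed t2.

Because F0 tracks the minimum of smoothed noise, ΔF/F carries a small
positive offset (≈ 0.35 noise s.d. at the default windows).  All
threshold-based detection downstream is therefore referenced to an
estimated trace center, not to zero (below).

## Transient detection (`dgkit.transients`)

Candidate events open when the centered ΔF/F exceeds `onset_sd` = 3
noise s.d. and close when it next falls below `offset_sd` = 0.5 s.d.;
both polarities are scanned.  Significance is duration-conditional:
FPR(d) = (# negative events of duration ≥ d)/(# positive events of
duration ≥ d), and positive events with FPR(d) < α = 0.05 are retained.
Negative deflections of a baselined trace can only be noise, so they
calibrate the noise tail at zero parametric cost.

* **Noise scale and center.** The estimator excises detected candidate
  events of both signs and iterates mean/s.d. on the remaining frames
  (≤ 5 rounds); a robust 1.4826·MAD alternative sits behind
  `noise_estimator="mad"`.  Centering matters: without it the
  baseline's positive offset makes positive events systematically more
  frequent and longer than negative ones and the FPR calibration
  breaks.
* **Pooling.** The FPR curve is computed from events pooled across all
  cells of a session.  Per-trace curves are statistically degenerate:
  the longest excursion of a pure-noise trace is positive with
  probability ~1/2 and then has FPR 0 by construction, flagging ~half
  of noise-only cells.  Pooled across hundreds of cells, the measured
  cell-level false-positive rate on noise-only sessions is ≲ 0.5%.
* **Cumulative counts** (duration ≥ d rather than = d) keep the curve
  monotone and stable where durations are sparse.
* Events still open at the trace end are kept but flagged truncated;
  events separated by under 2 sub-threshold frames are not merged.

Transient frequency is events/min over the session; cells with zero
significant events are flagged and excluded from frequency statistics.

## Spatial tuning (`dgkit.spatial`)

Tuning curves: per-bin mean ΔF/F over 100 half-open 3 cm bins using
frames with speed > 1 cm/s (and matching context where requested),
Gaussian-smoothed with σ = 3 bins.  Empty bins are filled by linear
interpolation before smoothing and flagged.  Smoothing reflects at the
track ends — the teleport breaks spatial continuity, so the track is
linear, not circular.  Sessions with ≤ 5 laps carry a warning flag.

The null rotates the behavior streams relative to ΔF/F by a uniform
random offset in [`min_shift`, T − `min_shift`] frames
(`min_shift_s` = 10 s keeps short-offset autocorrelation out of the
null), rebuilds the curve 1,000 times, and takes the per-bin 95th
percentile.  Because occupancy is invariant under rotation, only the
numerator is recomputed per shuffle, which makes the 1,000-shuffle null
cheap.  A cell is **tuned** when (i) its curve strictly exceeds the
null in ≥ 5 consecutive bins (ties favor the null; the longest run is
the field, ties between runs resolved by higher mean) and (ii) a
significant transient lies inside the field on ≥ 25% of laps while the
animal runs.

Two properties of this criterion, measured on simulated data, shaped
the implementation:

* The run-length condition alone is **not** a 5% test.  Per-bin
  exceedance of the null is calibrated at 5%, but σ = 3 smoothing
  makes exceedances arrive in runs, and the longest supra-null run
  reaches 5 bins for roughly half of unmodulated cells (even pure-noise
  cells with no events).  All of the classifier's specificity comes
  from the lap-reliability condition.
* **Where a transient "is" decides the error rate.** A detected
  transient spans 20–30 cm of travel at running speed; if any frame of
  the event may sit in the field, sparse unmodulated activity (2
  events/min) satisfies the 25%-of-laps rule often enough that
  12–15% of untuned cells classify as tuned.  Locating each transient
  at its **onset** position (the default, `reliability_mode="onset"`)
  restores a ~4% false-positive rate at undiminished power (100% for
  45 cm fields at 0.8 lap reliability over 20 laps).  The any-frame
  variant remains available as `reliability_mode="any_frame"`.

Field width is the bin span above half of the curve maximum around the
peak, times 3 cm.  Heatmap ordering sorts tuned cells stably by peak
bin.

## Velocity coupling and remapping (`dgkit.session_metrics`)

The activity–velocity cross-correlation sweeps integer frame shifts
over ±5 s against a velocity trace smoothed with a 0.5 s uniform
window, computes the Pearson correlation on the overlapping segment of
each shift (shifts with < 30 overlapping frames are excluded), and
reports the signed r at the shift maximising |r|.  Negative lag means
activity trails velocity.

Remapping statistics: laps of the familiar context are split into a
first ⌈n/2⌉ and remaining half (contiguous split; interleaved available
behind `split_half_mode`), r_ff is the Pearson correlation of the two
half-curves, r_fn that of the full familiar and novel curves, and
Δ = r_ff − r_fn.  Cells classify as `decrease` (Δ > 0.01, familiar more
stable), `increase` (Δ < −0.01), or `no_change`; zero-variance curves
make the correlation undefined and such cells are flagged and excluded
from summaries rather than binned into `no_change`.  Note a structural
bias: the half-curves average half the laps of the full curves, so with
few laps E[r_ff] < E[r_fn] even without remapping (Δ ≈ −0.08 at 20
laps, ≈ −0.04 at 56 laps ≈ a 20-minute session).  Remapping contrasts
should therefore be read against a matched no-remapping baseline, which
is exactly what the verification suite computes.

## Synaptic electrophysiology (`dgkit.ephys_synaptic`)

Sweeps are positive-going IPSCs in pA, trials × samples at 10–20 kHz,
with 25 pulse onsets at 50 Hz.  uIPSC metrics over ≥ 10 trials: the
per-trial first-pulse amplitude is the maximum of a 1 ms rolling mean
within the inter-pulse window minus the 5 ms pre-pulse baseline (a raw
sample maximum over a few hundred noise samples is biased ~3 noise s.d.
upward, which would hide failures); failures — amplitude below
`failure_k` = 3 × the raw pre-stimulus noise s.d. — count as 0 pA in
the mean and in CV.  PPR divides the second-pulse mean (failures
included) by the first.  Latency runs from the presynaptic spike peak
to the first sample exceeding 10% of the trial's peak on a 0.3 ms
smoothed trace; jitter is the latency s.d.  Single-quantum trains with
0.2 ms true jitter are recovered within 10%.

Deconvolution: the sweep is smoothed by `n_smooth` = 20 repetitions of
a Gaussian of σ = 0.5 ms per pass (≈ one 2.2 ms Gaussian), then
D(f) = T(f)·K*(f)/(|K(f)|² + ε·max|K|²) is inverted, with K the
spectrum of the artificial mIPSC — shape
(1 − e^(−t/τ_rise))·e^(−t/τ_decay), peak scaled to 20 pA.  ε = 10⁻³ by
default; plain division (ε = 0) is exact on noise-free data but
amplifies high-frequency noise without bound.  The release-rate
histogram is in quanta per sample: convolving it back with the kernel
reconstructs the smoothed trace (round-trip NRMSE ~1e-14 noise-free),
and a 20 pA kernel integrates to one quantum.  Synchronicity ratio per
pulse i = AUC(onset_i, +5 ms)/AUC(next onset − 15 ms, next onset), the
last pulse using a virtual next onset 20 ms on; non-positive
asynchronous areas flag the pulse NaN.  AUCs use a zero baseline on the
deconvolved trace, whose noise is approximately zero-mean.

DSI is 100·mean(post)/mean(baseline) ("% of baseline") and its
complement ("suppression") from eIPSC amplitudes bracketing the 2 s
depolarisation.

## Intrinsic properties (`dgkit.ephys_intrinsic`)

Spike threshold: voltage at the start of the final contiguous run of
centered-difference dV/dt > 10 mV/ms preceding the first spike peak of
the rheobase sweep; amplitude = peak − threshold; AHP = threshold −
post-spike minimum (≤ 50 ms, bounded by the next spike); upstroke and
downstroke are the dV/dt extremes.  Sag ratio uses the deflection
convention (V_ss − V_base)/(V_peak − V_base), V_ss the mean of the last
100 ms of the 1 s step (raw-voltage ratio behind `sag_convention`).
Maximum sustained rate excludes depolarisation-block sweeps (any spike
prominence < 50% of the first's); accommodation = first ISI over the
mean of the last two at the max-rate sweep (needs ≥ 4 spikes).  Input
resistance is the least-squares I–V slope over the step family
(mV/pA → ×10³ MΩ).  Membrane τ is a single-exponential least-squares
fit from the step onset to the step end of the 20-sweep average.  The
K⁺ reversal comes from a 100 ms voltage ramp: a linear leak is fitted
over the most depolarised 30% of the ramp (the rectifier is shut
there), subtracted, and the residual's zero crossing taken.  The
crossing uses a ~1 mV-smoothed residual for the coarse bracket and a
local linear fit over ±10 mV for the estimate — adjacent ramp samples
differ by far less than the noise s.d., so a plain sign scan stops
~0.5–1 mV early; the refined estimator recovers the reversal within
0.5 mV at 5 pA noise.

## Synthetic data (`dgkit.synthgen`)

All generators are pure functions of (parameters, seed) and emit
containers that pass the I/O validators unchanged.

**Imaging sessions.** Behavior is a run/pause state machine on a 3 m
track at 30 Hz: per-bout speeds uniform in 10–30 cm/s, exponential bout
(mean 4 s) and pause (mean 1 s) durations, a 1 s teleport pause at each
lap end, and padding to ≥ 2 min so the 60 s baseline is defined.  Place
cells fire on a `reliability` fraction of laps at a position drawn from
a truncated Gaussian with FWHM = `field_width_cm` (default 45 cm)
around their center; untuned cells fire homogeneously at
`event_rate_per_min` = 2.  Onsets are convolved with a peak-normalised
two-exponential GCaMP kernel (rise 20 ms, decay 400 ms, 6f-like) with
lognormal amplitudes (median 1.0 ΔF/F, σ_log = 0.3), and traces are
F = baseline·(1 + drift)·(1 + signal) + noise with a ≤ 10% sinusoid +
trend drift and Gaussian noise of 0.05 ΔF/F.  Because the indicator
integrates, a transient's ΔF/F mass sits downstream of its onset by the
kernel's temporal centroid (~0.42 s ≈ 3–4 bins at running speed); the
generator defines the ground-truth field center in the **measurement
(ΔF/F) domain** and leads each onset by that centroid, so "field
center" means the same thing to the generator and to the tuning
analysis.  Context sessions alternate familiar/novel laps in a balanced
pseudo-random order, and each tuned cell redraws its novel-context
center with probability `remap_prob`.

**Limits of realism.** The generator omits spike-to-calcium
nonlinearity and indicator saturation, neuropil and motion artifacts,
position-dependent speed profiles, theta-timescale spike timing, and
bursty within-field firing (one onset per traversal).  Passing tests
therefore demonstrate correctness of the estimators under their own
assumptions — linear kernels, additive noise, slow multiplicative
drift — not robustness to every artifact of real movies.

**uIPSC trains.** Per pulse, with probability 1 − `p_fail` (default
0.2), `n_quanta` = 5 quanta are released: a fraction `sync_frac` at
latency 1.5 ms + N(0, 0.2 ms), the rest at latency + Exp(5 ms)
truncated to the 20 ms inter-pulse interval — the 5 ms asynchronous tail
populates the 15 ms pre-pulse window the synchronicity ratio measures.
Quanta convolve with a 0.5 ms/8 ms difference-of-exponentials kernel
(peak 20 pA) plus 2 pA noise.  Electrode artifacts, series-resistance
filtering and vesicle depletion are not modeled.

**Intrinsic protocols.** A leaky-exponential membrane (τ = 15 ms,
R_in = 150 MΩ, rest −70 mV) generates the step family, tau step and sag
step (delayed rebound component, τ_sag = 150 ms, so the measured
deflection ratio equals 1 − `sag_frac` to ~1%).  The rheobase spike is
a parametric waveform whose upstroke starts at 30 mV/ms exactly at the
nominal threshold, making the dV/dt criterion land on the threshold
sample; firing steps carry prescribed accommodating ISI sequences; the
ramp I–V is linear leak plus a Boltzmann-gated inward rectifier
(half-activation −60 mV, slope 8 mV) reversing at E_K.  Voltage noise
defaults to 0.05 mV (averaged-sweep scale), current noise to 5 pA.

## Verification scale

The verification suite (`tests/test_acceptance.py`,
`scripts/acceptance.py`) runs at the scales the properties are stated
for: 100 × 10,000-frame traces for the baseline oracle; 1,000 noise-only
and 100 event-bearing 10-minute cells for detection error rates; one
400-cell, 20-lap session with 1,000-shuffle nulls for classifier type
I/power; 200-cell, 56-lap (≈ 20 min) context sessions for remapping;
50 trials per condition for release analyses; and 100 random cells for
intrinsic-parameter recovery.  Everything completes in about a minute
on one CPU.
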