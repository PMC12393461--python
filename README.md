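# dgkit

Quantitative analysis of dentate-gyrus circuit experiments: 2-photon
calcium imaging of mossy cells and granule cells on a virtual linear
track, and whole-cell patch-clamp recordings of their synapses and
membranes.  The package is written for systems-neuroscience labs that
have fluorescence traces from upstream segmentation (e.g. suite2p) and
digitized patch-clamp sweeps, and want the downstream statistics —
transient detection, place-field classification, remapping, release
kinetics, intrinsic properties — as tested, scriptable building blocks.
A synthetic-data module generates imaging sessions and sweep sets with
full ground truth, so every estimator ships with a quantitative
verification of its false-positive rate, sensitivity and bias.

## What it computes

**Imaging.** Raw fluorescence F is converted to ΔF/F = (F − F0)/F0,
where F0(t) is the minimum over the trailing 60 s of the 3 s
boxcar-smoothed trace; putative transients (> 2 s.d. above the mean)
are masked and the baseline recomputed, twice.  Calcium transients open
where ΔF/F exceeds 3 noise s.d. and close below 0.5 s.d.; an event of
duration d is significant when FPR(d) < 5%, with FPR(d) the ratio of
negative- to positive-going events of duration ≥ d pooled over the
session's cells (negative deflections of a baselined trace can only be
noise).  Spatial tuning curves are the occupancy-normalised mean ΔF/F
in 100 × 3 cm bins over running frames (> 1 cm/s), smoothed with a
Gaussian (σ = 3 bins).  A cell is spatially tuned when its curve beats
the per-bin 95th percentile of 1,000 circularly-shuffled curves in ≥ 5
consecutive bins and a significant transient starts inside that field
on ≥ 25% of laps; field width is the span above half-maximum.
Activity–velocity coupling is the signed Pearson r at the lag of
maximum |r| over ±5 s (negative lag = activity trails velocity).
Context remapping is Δ = r_ff − r_fn, the split-half familiar
correlation minus the familiar–novel correlation of tuning curves.

**Electrophysiology.** Unitary IPSC amplitude (failures counted as
0 pA), paired-pulse ratio, latency and jitter from the presynaptic
spike peak, CV and failure rate over ≥ 10 trials of 25-pulse 50 Hz
trains.  Release kinetics by spectral deconvolution: the sweep's FFT is
divided by the FFT of an artificial mIPSC (difference of exponentials,
peak 20 pA) and inverted to a release-rate histogram; the per-pulse
synchronicity ratio is the release area in the 5 ms after a pulse over
the area in the 15 ms before the next one.  DSI as the eIPSC amplitude
just after a 2 s depolarisation, in % of baseline.  Intrinsic
properties: spike threshold at dV/dt > 10 mV/ms, AP amplitude/AHP,
max upstroke/downstroke, sag ratio (steady-state over peak deflection),
maximum sustained firing rate and accommodation ratio (first ISI over
the mean of the last two), input resistance from the I–V slope,
membrane τ by single-exponential fit, and the K⁺ reversal potential
from a leak-subtracted voltage ramp.

## Worked example

Simulate a 20-cell session in which half the cells are place cells
(45 cm fields, firing on 80% of 20 laps), then run the imaging
pipeline:

```python
import numpy as np
from dgkit import (ImagingSimParams, compute_dff, detect_session_transients,
                   simulate_session, tuning_curve, shuffle_null,
                   classify_tuned, transient_frequency)

params = ImagingSimParams(n_cells=20, frac_tuned=0.5, n_laps=20,
                          reliability=0.8)
session, truth = simulate_session(params, seed=7)
dff = compute_dff(session.fluor, session.frame_rate)
events = detect_session_transients(dff, session.cell_ids)

n_tuned = 0
for i, cid in enumerate(session.cell_ids):
    curve = tuning_curve(dff.dff[i], session)
    null = shuffle_null(dff.dff[i], session, n_shuffles=1000, seed=7 + i)
    res = classify_tuned(curve, null, events, session, cid)
    n_tuned += res.tuned
```

which prints, for the first tuned cells and the session summary:

```
cell0000: tuned, peak bin 25 (76 cm), width 42 cm, reliability 0.70
cell0001: tuned, peak bin 26 (80 cm), width 45 cm, reliability 0.70
cell0002: tuned, peak bin 36 (110 cm), width 57 cm, reliability 0.70
375 significant transients in 20 cells (6.7 min session)
mean transient frequency 2.80 events/min
10/20 cells spatially tuned (10 simulated as place cells)
```

Here `peak bin` is the location of the tuning-curve maximum along the
3 m track, `width` the half-maximum span of the place field,
`reliability` the fraction of laps with a significant transient inside
the field, and the classifier recovered exactly the ten simulated place
cells.  The same stages are available from the shell:

```sh
dgkit simulate --kind session --out session.h5 --seed 7
dgkit run-all --in session.h5 --out results.csv --seed 7
dgkit simulate --kind uipsc --out trains.h5 --seed 7
dgkit synaptic --in trains.h5 --out synaptic.json
```

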