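# Methods

## Problem setting

Post-PVI mapping must decide, site by site along the circumferential
ablation line, whether residual electrical activity indicates a surviving
conduction gap or only far-field pickup.  The discriminating physics:
near-field activity from tissue under the electrodes is brief and
high-frequency but may be very low amplitude; far-field from distant tissue
is broad, low-frequency, and can be large.  Amplitude criteria therefore
misclassify in both directions; frequency criteria do not.

## Wavelet core

The scalogram uses a complex analytic Morlet wavelet defined in the Fourier
domain as `Psi(w) = exp(-B (w - 2*pi*C)^2 / 4)` for `w > 0` (zero
otherwise), with centre frequency `C = 1` and bandwidth parameter `B = 1.5`
by default.  Scales are L1-normalised, so a unit-amplitude sinusoid yields
ridge magnitude 0.5 (the analytic half) at every analysis frequency — this
is what lets magnitudes be compared across frequency and thresholded in mV.
Analysis frequencies default to 64 log-spaced points on [30, 500] Hz
(adjacent bins differ by a factor 1.046).  The transform is evaluated by
FFT with reflection padding of 4 time-SDs of the widest wavelet; the outer
2 SDs (~58 ms at 30 Hz, fs 2000 Hz) are flagged edge-unreliable and
excluded from the PF trace.

**Ridge-restricted qualification.**  At each sample the PF trace takes the
highest-frequency *spectral ridge* (local maximum of `|W|` along frequency)
whose magnitude reaches `max(rel_frac * global_max, floor(f))`.  Restricting
to ridges is essential: the Morlet frequency response decays smoothly, so
the raw above-threshold set extends to ~1.5x the component frequency,
whereas each oscillatory component contributes exactly one ridge within one
grid bin of its frequency.  With `abs_floor = 0` the trace is exactly
amplitude-invariant (the threshold scales with the signal); raising
`rel_frac` can only remove ridges, so the trace is monotone non-increasing
in it.

**Noise floor.**  For white noise of SD `sigma`, `E|W(f,t)|^2` grows
linearly in `f`, so a flat floor tuned to the top frequency over-suppresses
the near-field band.  The floor is therefore referenced to the top grid
frequency and scaled per row as `abs_floor * sqrt(f/f_max)` — a
constant-false-alarm-rate floor.  The pipeline default `abs_floor = 0.02 mV`
is 2x the simulator's unipolar noise SD (0.01 mV); empirically the
record-maximum of noise-only scalogram ridges is 0.014 mV on the bipolar
path and 0.016 mV on the omnipolar path, so the default clears the noise
extreme with margin ~1.2 on every row.  Because the scalar PF annotation is
a running maximum of the trace, a floor at or below the noise *extreme*
(not the typical value) lets single noise excursions at high frequency
masquerade as near-field components; time-smoothing the scalogram was
evaluated as an alternative and rejected — the wavelet envelope already
matches the deflection timescale, so smoothing buys < 5% extremes reduction
before it attenuates the signal.

The scalar annotation of a window is the maximum of the trace over it
(half-open `[t0, t1)` in ms; default the full record, which holds a single
sinus-rhythm activation).  Peak-to-peak voltage is annotated on the same
windows.

## Bipolar and omnipolar modalities

A single bipole is direction-dependent: a wavefront propagating
perpendicular to the bipole axis cancels in the subtraction, destroying the
near-field information for voltage and PF alike.  Grid-catheter practice
therefore annotates the orthogonal bipole pairs of the 2x2 clique: `V_bi`
is the largest peak-to-peak over the four side bipoles, and `PF_bi` the
larger PF of the per-axis maximal-voltage bipoles.

The omnipolar signal comes from the in-plane electric-field loop
`E = -grad(phi)`.  The gradient is fitted per 3-electrode sub-clique (for
which the least-squares fit interpolates the potentials exactly), keeping
the sub-clique whose projected loop attains the largest peak-to-peak over
orientations (1-degree grid on `[0, pi)`, ties toward smaller angle).
Fitting on sub-cliques rather than averaging over the whole clique matters
because the local wavelength of a propagating deflection
(v = 0.5 mm/ms at 180-400 Hz gives 1.2-2.8 mm) is comparable to the 2 mm
pitch: the clique-mean gradient averages phase-shifted parallel bipoles
against each other and can leave the omnipolar voltage below individual
bipoles.  With the maximal sub-clique, every pitch-normalised clique bipole
is one orientation's projection of the loop, so
`V_omni >= max(pitch-normalised bipoles)` holds by construction, and
common-mode input gives an exactly zero loop.  Multiplying projections by
the physical pitch keeps `V_omni` in mV, commensurate with bipolar cutoffs.
Orientation recovery from the loop is only physically meaningful for
spatially well-sampled wavefronts (wavelength >> pitch); the high-frequency
near-field itself is spatially aliased on this clique, which affects
direction estimates but not peak-to-peak or PF annotation.

## Synthetic cohort generator

Each site is four unipolar channels: a common-mode far-field burst
(Gaussian-enveloped sinusoid; band 40-120 Hz, peak 0.1-1.5 mV, envelope SD
15 ms) identical across electrodes up to per-electrode amplitude jitter
(default 4.5%, the top of the sub-5% band — the far-field residue this
leaves in bipolar/omnipolar signals is what makes voltage criteria
fallible, while its frequency stays in the far-field band so PF is not
fooled); plus, at gap sites only, a near-field burst (180-400 Hz,
0.03-0.5 mV, envelope SD 3 ms) crossing the clique as a planar wavefront at
0.5 mm/ms in a random direction; plus white noise (SD 0.01 mV).  Sampling
is 2000 Hz for 500 ms with the activation centred at 35-65% of the record,
clear of the wavelet edge margins.  Labels are i.i.d. Bernoulli with
configurable gap prevalence; segment ids tile 16 PV-line segments
round-robin, and the pipeline's phase-2 unit is the patient-segment
(patients tiled over site ids, 16 segments each), which reproduces
per-segment denominators of the order 37 gap / 155 block at 192 sites.

What the generator does **not** emulate: multi-beat or fibrillatory
signals, catheter motion/contact artefacts, anatomy-dependent far-field
correlation structure, fractionated multi-deflection electrograms, and any
calibrated clinical amplitude distribution.  Passing tests therefore show
that the annotation chain behaves correctly under the stated signal model —
not that clinical sensitivities or cutoffs would be reproduced; clinical
cutoff values enter only as classifier configuration defaults.

## Evaluation

ROC analysis sweeps thresholds over the unique observed scores plus
sentinels, with the positive call `score >= threshold`.  AUC is the
trapezoidal area traversed in ascending (FPR, SE) order, which equals the
Mann-Whitney pair-concordance probability with ties at half credit.  The
Youden cutoff maximises `J = SE + SP - 1`; ties break toward higher
specificity, and the reported cutoff is the midpoint between the optimal
threshold and the next lower unique score (the convention of clinical ROC
software; the raw observed threshold is available via
`interpolate=False`).  Contingency metrics are exact fractions internally;
one-decimal rounding (half away from zero, matching printed clinical
tables) happens only at the reporting layer.  A metric with a zero
denominator is an error (or omitted from phase-2 reports), never 0.
Significance testing of AUC differences is out of scope.

`reconstruct_counts` inverts printed (SE, SP, PPV, NPV) rows: given the
positive-class size and a shared unknown negative-class size, it enumerates
`tp` in `[0, n_gap]`, `n_block` in `[1, 1000]`, `fp` in `[0, n_block]`,
keeps parameter sets whose four metrics all round to the printed values
simultaneously for every row, and asserts the minimal-`n_block` solution is
unique.  Sensitivity alone pins `tp` to a handful of candidates, so the
search runs in well under a second.

## Numerical and design choices

- Tie at a criterion cutoff is called gap (the safer clinical direction).
- Voltage criteria read `>= cutoff => gap`: residual voltage on an ablation
  line indicates surviving tissue.
- Segment aggregation is existential (any gap site makes a gap segment).
- Interchange is CSV plus a JSON sidecar; floats are written as `%.17g` and
  parsed in round-trip mode, so write/read cycles are bit-exact.  Every
  output carries the config hash and seed; reruns are byte-identical.
- Problem sizes used by the test suite and the acceptance script (cohorts
  of 200-400 sites, 20 seeds for the ordering check, 10 000 label draws for
  prevalence) were chosen to make Monte-Carlo assertions stable at desk
  scale.

## Known limitations

The PF scalar is a running maximum of the trace, so it is an extreme
statistic: detection behaviour near the noise floor is governed by noise
*extremes*, and the floor trades sensitivity to sub-0.06 mV near-field
against false high-frequency calls.  The omnipolar construction assumes a
planar in-plane field across one clique; non-planar or strongly curved
wavefronts are out of scope.  The generator's parameter ranges are
simulator conventions, not clinical claims.
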