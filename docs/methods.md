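# Methods

This note documents the models, algorithms, parameter defaults and numerical
choices behind `zfephys`, and what its synthetic-data validation does and
does not demonstrate about real recordings.

## Spike detection chain

**Filtering.** Band-pass 200 Hz–3 kHz. Only the cut-offs are part of the
acquisition convention; the realization here is a 4th-order Butterworth
applied forward–backward (`sosfiltfilt`), i.e. zero-phase, so detected spike
times are not shifted by filter delay. Zero-phase filtering squares the
single-pass magnitude response; the first and last 100 ms of each trace are
excluded from detection to avoid edge transients.

**Noise calibration.** The detection threshold is 5.5 × the background-noise
RMS. "Background" matters: a plain RMS over a trace that contains spikes
overestimates the noise floor. The default estimator is therefore the
median-absolute-deviation form, median(|x|)/0.6745, which equals the standard
deviation for Gaussian noise and is insensitive to sparse large excursions.
The plain RMS is available (`DetectorSpec(robust=False)`). Calibration is
fixed per recording; a rolling/time-varying threshold is intentionally not
the default, since acquisition systems differ on this and a fixed calibration
is reproducible.

**Detection.** With polarity "both" (honouring the ± of the threshold
convention), an event is a contiguous excursion of |x| beyond the threshold;
its time is the extreme sample and its amplitude the signed extreme. Events
closer than the 2 ms dead time merge, keeping the larger |amplitude| (ties go
to the earlier event). Raising the multiplier can only shrink the excursion
set, so detected counts are monotone non-increasing in the multiplier.

## Spike-train metrics

- **Analysis window**: the contiguous 5-min window maximizing total spike
  count, scanned on a 1 s start lattice (exhaustive and cheap); ties break to
  the earliest start.
- **Active electrode**: rate ≥ 5 spikes/min, *inclusive* — 5 spikes in 60 s
  qualifies, matching the usual vendor reading of "threshold of 5".
- **WMFR**: arithmetic mean of active electrodes' rates. A well with no
  active electrode reports NaN, never 0: silence is ambiguity, not a measured
  zero rate.
- **Bursts**: maximal runs of ≥ 5 consecutive spikes on one electrode with
  every ISI strictly < 100 ms. Runs are maximal by construction (split
  exactly at non-qualifying ISIs), hence disjoint. Bursts on inactive
  electrodes are discarded.
- **Network bursts**: same run rule on the pooled, time-sorted train across
  electrodes, plus ≥ 2 distinct contributing electrodes and contributing
  fraction ≥ 10%. The involvement denominator is all electrodes in the well
  (64) by default; a flag switches it to the active set. Note that in
  densely firing wells the pooled ISI criterion is met almost continuously,
  so pooled runs become long and few — the metric is most informative at the
  low well-wide rates typical of whole-larva recordings.
- **Strict-inequality tie handling**: ISIs are compared with a 1 ns
  tolerance, so a train constructed at exactly the cut-off (k × 0.100 s,
  not exactly representable in binary) is classified by the mathematical
  rule: 100 ms is *not* a qualifying ISI.
- **Head-region hyperactivity**: no published quantitative rule exists for
  calling a larva's brain region hyperactive from the grid, so the package
  defines one and labels it as its own convention: WMFR over the head-mask
  electrodes ≥ 2.0 × WMFR over the complement (both restricted to active
  electrodes). A region with no active electrode makes the call
  *indeterminate*, which is deliberately distinct from "not hyperactive".
  The default head mask is the two grid columns under the head for a
  laterally mounted larva; real mounting orientation varies, so the mask is
  an argument everywhere.

## Locomotor metrics

Distance is the sum of successive Euclidean displacements; velocity is
distance over elapsed time. Mobility compares per-frame speed to a 0.5 mm/s
threshold — a package convention, since pixel-change "mobility" measures are
not reproducible from centroid tracks; mobile and immobile durations always
sum to the analysed duration.

**Rotations.** One rotation event = a full 360° cumulative turn in one
direction. Headings are computed between *accepted* points (≥ 1 mm apart, the
minimum-distance filter), signed heading changes accumulate, and an opposing
turn exceeding 45° resets the accumulator without counting; small
counter-wiggles within the tolerance merely subtract. The alternative reading
of the tracking-software parameters — each 45° turn is an event — is
selectable via `full_turn_deg=45`. Because accepted points are ≥ 1 mm apart,
heading changes are discretized in ~(step/radius) increments: a path must
slightly exceed one geometric circle before the accumulator reaches 360°,
which the tests account for by traversing 1.2 circles. Counts are invariant
under rotation and translation of the coordinates; mirroring swaps CW and
CCW.

**Phase bins.** The dark-to-light protocol (5-min dark acclimation, then
2-min alternating bins over 12 min) is data, never inferred from the signal.
Bins tile the recording; the boundary sample is shared so per-bin distances
sum exactly to the total when frames align with bin edges.

## Group statistics

Standard tests are delegated: Welch t (scipy), Welch one-way ANOVA
(pingouin), two-way ANOVA via an OLS fit with type-II sums of squares and
Tukey HSD on the four genotype × treatment cells (statsmodels; unbalanced
cells get the Tukey–Kramer form), repeated-measures one-way ANOVA
(statsmodels `AnovaRM`, complete cases only; for two conditions it equals the
squared paired t). The Brown–Forsythe test *for means* (F\* with Satterthwaite
denominator df) is implemented directly, as is ROUT, since no installed
package provides them. All p values are reported raw; nothing thresholds
silently.

**ROUT.** The published procedure targets robust nonlinear regression; group
comparison is a constant-model fit, so the specialization here is: robust
location by minimizing the Lorentzian merit function (iterating with the
robust scale), robust scale RSDR = 68.27th percentile of |residuals| ×
N/(N−1), then an FDR-style sweep over the largest residuals (at most 30% of
the sample): residual of rank j is tested against a two-tailed t probability
threshold Q(N−j+1)/N, and all points at least as extreme as the last
significant rank are flagged. At Q = 1% on clean Gaussian samples of n = 100
this flags ≤ 5 points in ≥ 95% of seeded runs (verified in the suite).
Outlier removal is always an explicit call that returns the partition.

## Synthetic-data generator

The generator's purpose is parameter recovery: every downstream number can be
checked against known truth. It emulates four conditions — control, a
hyperexcitable crispant (napb_cr), and both after 15 mM PTZ — at the standard
acquisition geometry (8×8 grid, 12.5 kHz, 10-min spontaneous / 30-min PTZ
recordings; 30 fps trajectories in an ~8 mm-radius well with the 5-min dark +
six 2-min alternating-bin schedule).

**Voltage model.** White Gaussian noise at a configurable RMS (default 3 µV;
an optional 1/f admixture is off by default) plus linearly superposed
biphasic templates — one zero-mean sine cycle, 1 ms wide, negative peak
first, which keeps its energy near 1 kHz, inside the detection passband
(numerically ≥ 70% peak retention through the filter; in practice ≈ 100%).
Tonic firing is a gamma renewal process (shape 2) with a 2 ms absolute
refractory period, preventing degenerate ISIs. Burst episodes insert
fixed-ISI runs (default 8 spikes at 50 ms) with a guaranteed ≥ 1 s
inter-episode gap, clear of the trace edges, so episode counts are
unambiguous. Network events recruit ⌈involvement × 64⌉ random electrodes,
each firing 3 spikes within a 10 ms jitter window, placing pooled ISIs far
below the 100 ms criterion. In crispant scenarios the head-mask electrodes
carry a 3× tonic *and* burst rate multiplier and a 1.5× amplitude multiplier
— brain-region hyperactivity affects both how often and how strongly head
electrodes fire, and the amplitude gradient is what makes the grid heatmap
hot over the head. PTZ scenarios multiply all rates globally.

Rates, amplitudes and noise levels are order-of-magnitude physiological
choices (tonic 0.5 spikes/s, spikes at 8× noise RMS, bursts at 2/min,
network events at 0.5/min for control): no published numeric magnitudes exist
to calibrate them against, and none of the validation depends on their exact
values.

**Trajectory model.** Correlated random walk: gamma-distributed step lengths
(mean = speed × Δt, CV 0.6), wrapped-normal heading increments with SD
1/√κ (κ = 8 control, 3 crispant). Thigmotaxis is modelled by steering the
heading toward the wall tangent in the outer 20% of the radius, weighted by
`wall_affinity` (0.7 control — organized wall-following; 0.1 crispant —
irregular swimming). Circling bouts start as a Poisson process
(`rotation_bias` per second: 0.02 control, 0.12 crispant) and impose a 270°/s
signed turn for 2 s. The PTZ effect multiplies speed by
1 + (m−1)·2^(−t/τ), τ = 300 s, matching an effect that wears off over the
recording. Wall crossings reflect specularly (the radial overshoot is
mirrored back inside), so all emitted positions satisfy ‖(x,y)‖ ≤ R.

**Determinism.** Both generators draw every variate from one
`numpy.random.default_rng(seed)`; identical configuration and seed give
bit-identical outputs.

**What passing tests show — and what they don't.** The generator shares no
code with the detectors, so recovery tests are genuine round trips; but its
noise is (near-)white and Gaussian, spikes are a fixed template, and there
are no movement or agarose-contact artifacts, electrode drift, or
non-stationary noise. Passing recovery tests therefore validates the
*algorithms*, not the detectability of spikes in any particular real
preparation.

## Validation problem sizes

The suite validates WMFR recovery on a full 64-electrode, 5-min recording;
the false-positive bound on an 8-electrode, 10-min pure-noise recording
(electrode noise is i.i.d., and the bound is per electrode); burst-count
recovery on 8 electrodes over 5 min; oracle equivalence on 1000 random small
instances against exhaustive enumerators; behavioral contrasts over 20 seeds
per scenario and PTZ decay over 50 seeds; Welch type-I calibration over 2000
null simulations and ROUT false-discovery behavior over 200.

## Known limitations

- No spike sorting: electrodes, not units, are the analysis grain.
- The network-burst rule degenerates in densely firing wells (see above).
- The head-region hyperactivity criterion and the mobility threshold are
  package conventions and should be reported as such alongside results.
- The recording container is the package's own flat-binary + JSON format;
  proprietary acquisition formats need external conversion.
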