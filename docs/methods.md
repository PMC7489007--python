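# Methods

This note documents the models, operational definitions, and numerical
choices behind `swdkit`, and what the synthetic-data generator does and
does not emulate.

## Scientific setting

Mouse models of amyloid pathology frequently show non-convulsive
epileptiform activity: brief sharp EEG transients ("epileptiform spikes")
and rhythmic spike-and-wave discharges (SWDs) typical of absence-type
seizures, alongside spatial-learning deficits. Quantifying these requires
(i) a spike detector with explicit amplitude and sharpness criteria,
(ii) rules that group spikes into SWD events, (iii) spectral analysis of
the SWD rhythm, (iv) a ranking scheme that condenses a learning curve into
one number per animal, and (v) a prespecified statistical decision tree
for comparing genotype/treatment groups. No animal recordings ship with
this package; a generator with exact ground truth stands in for them.

## Spike detection

A deflection is an epileptiform spike when both criteria hold:

* **Amplitude.** The peak absolute deviation from the local background
  level is at least `amplitude_ratio_threshold` (default 4) times the
  local *baseline amplitude*. Baseline amplitude is the median absolute
  deviation times 1.4826 (the Gaussian consistency constant) over
  artifact-free samples in tiling windows of `baseline_window` = 10 s.
  A robust statistic is essential here: the spikes being detected would
  inflate a standard deviation, and the raw trace mean is ~0, so "average
  baseline" is operationalized as robust amplitude, not a mean voltage.
  The deviation is measured from the window mean, which makes detection
  invariant to DC offsets; peak-to-peak measurement is available via
  `amplitude_mode`.
* **Sharpness.** The absolute second central finite difference of the
  lightly smoothed voltage (moving average of 2×`smoothing_halfwidth`+1 =
  5 samples), expressed in V/s², must reach `sharpness_threshold`.
  Acquisition-software spike macros quote such thresholds in internal
  units that do not transfer between systems; ours is calibrated on the
  generator: biphasic template spikes measure ~13–16 V/s² after smoothing,
  while peaks of the default AR(2) background measure below ~2.5 V/s², so
  the default threshold of 4 V/s² separates them with about a three-fold
  margin on either side. Users reading "second derivative of the slope"
  literally as a third derivative can set `derivative_order = 3`.

Candidate deflections are local extrema above `candidate_floor_ratio`
(2×) baseline; extrema closer than `min_separation` = 50 ms collapse to
the larger one, which prevents double-counting the two lobes of one
biphasic transient. Candidates inside annotated artifact intervals are
flagged `excluded_artifact` and omitted from every count — the
annotation-based analogue of removing movement artifacts by blinded video
review. Sampling rates below 200 Hz are rejected because the sharpness
estimate becomes meaningless.

Solitary-spike frequency (spikes/h) counts retained, non-artifact spikes
that are *not* members of an SWD, divided by the analyzed duration
(recording length minus artifact-covered time).

## SWD clustering

An SWD is operationally a cluster of ≥ `min_components` = 4
spike-and-wave components within ≤ `max_cluster_span` = 1 s, where a
"component" is a detected spike (the slow wave is not independently
verified). The algorithm chains spikes with inter-spike intervals ≤
`max_component_interval` = 250 ms (four components in one second imply a
mean interval ≤ 333 ms; the cap stops chains of unrelated sparse spikes),
qualifies a chain if any sub-window of 1 s holds ≥ 4 of its spikes, and
keeps maximal chains — trailing components beyond the qualifying window
stay in the event. Qualified events whose last-to-first gap is < 500 ms
merge into one; a gap of exactly 500 ms or more keeps them separate.
Event length is defined first-to-last component; whether a terminal slow
wave should extend the length is ambiguous, and excluding it keeps length
a pure function of component times. A brute-force enumeration oracle in
the test suite pins these semantics exactly.

## Spectral analysis

PSDs are averaged periodograms over non-overlapping 1 s Hann windows
(partial trailing windows dropped), one-sided, density-normalized in
µV²/Hz so the integral over frequency equals the signal variance
(checked by a Parseval test on stationary noise). The 1 s window gives
1 Hz resolution, matching the integer-Hz precision at which SWD rhythms
are conventionally reported; it is configurable. SWD segments shorter
than one window — common, since a 5–10 component train at 12 Hz lasts
0.3–0.8 s — are extended by symmetric reflection to one window and the
result flagged `padded`; reflection preserves the local periodicity that
carries the rhythm, and the alternative (skipping short segments) is
available. The spectral peak is searched in 1–50 Hz by default so the
detrended low-frequency shoulder does not mask the SWD fundamental.

## Behavioral rank scoring

Per trial, each mouse's raw measure is converted to a percentile rank
among all mice of all groups in that trial, with spreadsheet
PERCENTRANK-inclusive semantics: member values rank as (count strictly
below)/(n−1) — so ties share the lower rank, the minimum is 0 and the
maximum is 1 — and non-member values interpolate linearly between
bracketing members. One score per mouse is the mean of its per-trial
ranks over the non-excluded trials (water-maze analyses conventionally
drop trial 1, the very beginning of acquisition; the exclusion set is an
argument). When all values are distinct the scores average exactly 0.5,
a useful identity test. Scores are computed on the raw measure; whether
high is "worse" (shock-zone entrances) or "better" (avoidance time) is a
reporting-time interpretation. Mice missing any non-excluded trial are an
error: implicit imputation would silently bias ranks.

Probe-trial metrics: the target preference index divides the target
quadrant's time fraction by the *mean* of the three non-target fractions,
so chance = 1.0 (the sum convention, chance = 1/3, is available via
`denominator="sum"`); mean distance to target is the arithmetic mean of
per-second distances from the former platform location.

## Statistical decision tree

Normality is gated per group by the D'Agostino–Pearson omnibus test at
`gate_alpha` = 0.05 (the conventional level; gates are configurable
separately from the decision α). If any group fails and all values are
positive, the natural log is tried and kept only if every group then
passes. Groups smaller than the omnibus test's minimum (n = 8) are
declared non-normal with a warning — failing toward robust tests is the
safer error. Variance equality uses the F test (two normal groups),
Bartlett (≥3 normal groups) or Brown–Forsythe (median-centered Levene,
non-normal data), again at `gate_alpha`.

The mapping to tests: two normal groups get the unpaired two-tailed t
(equal variances) or Welch t; three or more normal groups get one-way
ANOVA with Holm–Šidák-corrected pairwise t tests (equal variances) or
pairwise Welch t with Holm–Šidák; non-normal data get Kruskal–Wallis with
Dunn's rank comparisons (equal variances) or two-sided permutation tests
with Holm–Šidák (unequal). Two non-normal groups — a case the plan leaves
open — fall through to the same non-normal branches, which degenerate
gracefully at k = 2. Every gate's statistic and p-value is recorded in a
decision trace from which the chosen test is replayable.

Details that were genuinely open and are therefore explicit choices:

* the permutation statistic is the absolute difference of group means
  (a Welch-t statistic is available via `permutation_statistic`); the
  test enumerates all C(n_a+n_b, n_a) arrangements when that count is ≤
  `exact_enumeration_limit` = 20 000, else uses `n_permutations` = 10 000
  Monte-Carlo shuffles with the (count+1)/(N+1) estimator;
* Holm–Šidák is the step-down form: sorted ascending,
  adj₍ᵢ₎ = 1−(1−p₍ᵢ₎)^(m−i+1), running-maximum monotonicity, capped at 1;
* Dunn's comparisons use pooled-rank z statistics with the tie
  correction and Bonferroni scaling (the convention of the original
  procedure and of common biostatistics software);
* post-hoc comparisons are reported whether or not the omnibus test is
  significant (the omnibus p is reported alongside), so the family-wise
  error is controlled by the correction itself;
* zero-variance groups short-circuit the variance gate to "unequal" with
  a warning, which routes fully degenerate data to the permutation test,
  where identical groups correctly give p = 1.

Under a Gaussian null (3 groups, n = 12, 2000 simulated datasets) the
full tree — gates included — rejects (any adjusted pairwise p < 0.05)
at a measured rate of 0.040, inside the binomial band expected of a
calibrated α = 0.05 procedure.

## Assay normalization

Western-blot lanes: level = (target/loading) ÷ mean(target/loading of the
standard lanes on the same blot). Standards then average exactly 1.0 per
blot and a uniform gain on one blot cancels exactly — the identities the
test suite asserts. Any number ≥ 1 of standard lanes per blot is accepted
(two is typical). Plate background: the control-group mean signal is
subtracted; corrected controls average 0 and sub-background values stay
negative unless clipping is requested, since flooring at zero would bias
group means upward. Relative expression: division by the control-group
mean, fixing the control mean at 1.0.

## Synthetic data

The generator emulates, with exact ground truth:

* **Background EEG** — white, AR(2) (default) or spectrally-shaped pink
  noise at `baseline_rms` = 20 µV. The AR(2) uses a double pole at 0.9
  (coefficients 1.8, −0.81): a 1/f-like falling spectrum with a ~16 Hz
  corner, which leaves realistic low-frequency power but little energy at
  spike-curvature scales — white noise would make the sharpness criterion
  meaningless in the opposite direction (everything sharp).
* **Spikes** — difference-of-Gaussians biphasic transients (~25 ms total
  width) with peak deviation `spike_amplitude_ratio` = 6 × baseline RMS:
  clearly epileptiform relative to a 4× criterion, without being
  artifact-sized.
* **SWDs** — trains of 5–10 cycles at `swd_component_freq` = 12 Hz, each
  cycle a fixed-width (~25 ms) sharp spike followed by an opposite-polarity
  half-sine slow wave at half amplitude filling the period. The spike
  width does not scale with the period: slower rhythms keep sharp spikes.
* **Artifacts** — large (12× baseline) slow irregular bursts of 0.5–2 s,
  annotated so the analysis can exclude them the way hand-marked movement
  artifacts are excluded.

Event onsets are homogeneous Poisson (defaults: 120 spikes/h, 30 SWDs/h,
10 artifacts/h) with rejection of placements that violate a 1 s guard
between events (2 s around artifacts), keeping ground truth unambiguous:
no detected event can straddle two injected ones. Everything is
deterministic given `seed`.

Behavioral learning curves decay exponentially toward a group asymptote
(start = 3× asymptote by default; flat at the asymptote when the learning
rate is 0); entrance counts are Poisson around the curve, continuous
measures lognormal around it. Group measurement samples come from normal,
lognormal or t₃ (heavy-tailed) families, giving the statistics tree both
branches of every gate.

What the generator does **not** emulate — and what passing tests
therefore do not show about real data: thalamocortical dynamics, state
dependence (sleep/wake), electrode drift and line noise, inter-channel
correlation (events are injected on one channel), convulsive seizure
morphologies, amplitude variability across events of one animal, and
video-trackable behavior (only per-trial scalars are produced). Detector
performance numbers on synthetic data are upper bounds with respect to
these omissions.

## Problem sizes and runtimes

The test suite validates the detector on a 1 h default-parameter
recording (sensitivity and precision ≥ 0.95 against ground truth, SWD
count recovered exactly) and on 10-minute recordings for invariance
properties; clustering is checked against the brute-force oracle on 500
random spike lists of ≤ 20 spikes; the decision tree's type-I error uses
2000 simulated null datasets; the spectral sweep covers fundamentals of
6–12 Hz on 5-minute recordings. The acceptance script regenerates a
10-minute recording with ~30 SWD trains and reports the detected-SWD
spectral peak. These sizes keep the full suite in the low minutes while
leaving every estimate's Monte-Carlo error well inside the asserted
tolerances.

## Known limitations

* Single-channel analysis; no multichannel consensus detection.
* Sharpness threshold units are instrument-convention-dependent;
  transferring the detector to real recordings requires re-calibrating
  `sharpness_threshold` (and possibly `amplitude_mode`) against a
  hand-scored sample.
* The SWD "wave" morphology is not verified — a rhythmic polyspike run
  satisfying the timing rules would be called an SWD.
* Two-way designs are out of scope for the selection tree; only one
  grouping factor is compared.
* The EDF writer is minimal (16-bit, µV, 1 s records, integer sampling
  rates); it exists for interchange of synthetic data, not as a general
  EDF library.
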