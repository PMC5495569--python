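# Methods

`fearext` re-creates, as tested and reusable code, the analysis chain of a
multi-session rodent fear-extinction experiment: synthetic cohorts with
planted ground truth are generated, then scored for freezing behaviour, unit
isolation quality, z-scored peri-event responses, neuron-type composition,
slice-electrophysiology metrics, and the accompanying nonparametric
statistics. This note records the models, the parameters that matter, the
numerical conventions, and the design choices that were genuinely open.

## Protocols and recall epochs

Three protocol presets cover the experimental variants:

| preset     | Cond                      | Ext1  | Ext2/Ext3 | ITI (s)  |
|------------|---------------------------|-------|-----------|----------|
| recording  | 5 CS/US, 0.5 mA, 0.5 s    | 20 CS | 20 CS     | 80–120   |
| slice      | 3 CS/US, 1 mA, 1 s        | 20 CS | 15 CS     | 100      |
| lesion     | 4 CS/US, 0.4 mA, 1 s      | 20 CS | 20 CS     | 100      |

The CS is a 30-s tone; in the pip dialect it is a train of 27 pips (200 ms,
0.9 Hz). The US co-terminates with the CS and is allowed only in Cond. The
recording preset adds a 5-CS habituation session and a 5-CS final test. The
leading 5 CSs of each post-conditioning session form the recall epochs
(post-Cond, post-Ext1, post-Ext2, post-Ext3); habituation is its own epoch.
Ext2/Ext3 CS counts in the recording preset default to 20 and are
configurable, since only Ext1's count is pinned by the protocol description.
The `n_cs >= retention_window` constraint applies to sessions that host a
recall epoch — Cond is exempt because its CSs are conditioning trials, not
retention probes (the slice protocol has only 3 of them).

## Synthetic cohorts

**Spike trains.** Units fire as inhomogeneous Poisson processes with
piecewise-constant rate: a baseline rate everywhere, switching to the
session's evoked rate inside `[latency, latency + duration]` after every
aligned event (tone onsets in the tone dialect, every pip in the pip
dialect). Excitation is realized by superposing an independent Poisson
process at rate `evoked − baseline` inside the response windows; suppression
by thinning the baseline process to `evoked / baseline` — both exact
constructions, in double-precision seconds. Defaults: baseline 8 Hz (typical
of basal-amygdala units), evoked = 10× baseline in the phenotype's active
session, latency 10 ms, duration 50 ms. The phenotype-to-epoch mapping is
the generative mirror of the classifier: fear units are active in the session
whose leading CSs form the post-Cond epoch, extinction units in the
post-Ext1 session, session-selective units in their target epoch's session.

**Waveforms.** Each unit owns a 32-sample biphasic template with amplitude
drawn from 80–200 µV. Inter-session drift is planted *exactly*: consecutive
session templates are constructed in the standardized (zero-mean, unit-norm)
space as `r·current + sqrt(1 − r²)·orthogonal noise`, so the sample Pearson
correlation between consecutive templates equals the requested `r`. This lets
tests place units deliberately above or below the 0.97 stability gate.

**Freezing.** Immobility is sampled on a 0.1-s grid, which makes the 2-s
scoring rule exact (human scoring has no declared sampling rate). For each CS
a target percentage is drawn from the session's (mean, SD); the corresponding
frozen duration is realized as immobility bouts each ≥ 2 s, so the scorer
recovers the drawn value exactly and the expected score equals the target
mean. Draws below one bout length score zero — targets near 0% are therefore
reproduced faithfully rather than inflated. Default session targets follow
the conditioning/extinction dynamics (successful recall: 5 → 40 → 65 → 25 →
15 → 10%; poor recall stays above 50% after Ext1).

**Slice sweeps.** Evoked EPSCs use a finite-support sin² transient (20 ms
wide, grid-aligned peak), so noiseless round trips are exact: planted
paired-pulse ratio, AMPA/NMDA ratio and I/O slope are recovered to machine
precision at zero noise. The NMDA component at +50 mV is a slow
double-exponential (τ_rise 5 ms, τ_decay 80 ms) normalized so that its value
exactly 50 ms after the stimulus encodes the planted ratio; the fast AMPA
component has fully decayed by then. Continuous traces carry Poisson-timed
miniature events (default 5 Hz, 30 ± 5 pA, 10-ms kernels, 1-kHz sampling,
2 pA Gaussian noise). Defaults echo the magnitudes typical of such
recordings (PPR 0.8, AMPA/NMDA 2.0, I/O slope 5.28 pA/µA).

**Determinism.** One global seed fans out to per-unit/per-rat/per-stage
substreams by CRC-32 tag hashing of `(seed, tags)` into a `SeedSequence`, so
identical (config, seed) gives byte-identical tables and adding a unit never
perturbs another unit's stream.

## Analysis conventions

**Freezing score.** A maximal immobility run qualifies if its total length is
≥ 2 s; qualifying time is intersected with the 30-s CS window and normalized
to CS duration. The score is monotone in immobility and invariant under grid
refinement.

**Recall grouping.** "Upper 99% confidence interval" is interpreted as the
upper bound of the two-sided 99% t-interval of the across-rat mean of
post-Ext1 freezing (the estimator is not otherwise pinned down; across-rat
rather than across-trial variation is used). Successful recall requires
freezing *strictly* below the bound. Note the bound is honest about small
cohorts: with only a handful of rats the interval is wide and may not
separate a planted split.

**Unit QC.** J3 = J2/J1 with J1 the pooled within-cluster scatter and J2 the
between-cluster scatter; DB is the standard Davies-Bouldin index with s_k =
mean distance to centroid. Both are frozen here because the sorting software
that popularized them does not publish formulas. J1 = 0 yields a +inf J3
sentinel; coincident centroids yield a flagged result rather than a silent
NaN. PC projection uses the top-2 components of the pooled snippet
covariance. The numeric J3/DB acceptance cut is deliberately left as
configuration (no published threshold exists); the default gate is
stability-only: every consecutive-session template correlation must exceed
r = 0.97, and a zero-variance template is unstable with a reason code.

**z-scored PETHs.** Trials are averaged first, then z-scored (the
alternative, z-scoring each trial before averaging, is not used). The tone
dialect bins at 100 ms and normalizes to the mean and *sample* SD (n−1) of
the four pre-tone bins of the trial-averaged histogram. The pip dialect bins
at 20 ms, averages over all pips of the trial set (135 for 5 CSs × 27 pips)
and takes baseline statistics from the 25 trial-averaged 20-ms bins of the
500 ms preceding each tone. Bins are half-open `[left, right)`; the onset
belongs to the first post-onset bin. A baseline SD of zero flags the
histogram degenerate and masks z — no epsilon inflation, which keeps null
simulations honest.

**CS-responsiveness and typing.** The responsiveness test is a two-sided
unpaired t test (pooled variance) of per-event spike counts in the 100 ms
after event onset against an equal-duration window immediately before onset
(the baseline sample for the test is not otherwise specified; a rate-matched
pre-onset window is the symmetric choice). The whole 100-ms window is tested,
not individual bins (per-bin testing remains an option). Under the null this
test fires at its nominal α — the suite measures 0.05 ± 0.02 over 10,000
simulated units.

Typing requires more than bare significance. With five recall epochs tested
at α = 0.05, a pure p-gated rule would label ~23% of completely unmodulated
units (the family-wise expectation — the suite measures the ungated rate and
confirms it), which is inconsistent with treating fear/extinction cells as
rare, *strong* responders. Classification therefore additionally requires
the epoch's peak windowed |z| (the largest-|z| bin in 0–100 ms for the pip
dialect, 0–400 ms for tone — the same statistic used for cell-based
comparisons of CS responses) to reach `min_abs_z` (default 3, matching the
latency criterion). With the gate, null units stay untyped in ≥ 95% of
simulations while planted phenotypes at 10× modulation are recovered with
≥ 90% accuracy (measured at 100% over 200 seeds per phenotype).
`min_abs_z=None` restores the ungated behaviour.

Typing rules: fear = excitatory in post-Cond, silent in habituation and all
post-extinction epochs; extinction = excitatory in post-Ext1, silent in
habituation and post-Cond (later epochs unconstrained, since extinction
responses may persist or fade); exactly one active epoch otherwise =
session-selective; anything else non-responsive. Fear and extinction
definitions require absence in habituation, matching the published
exemplars. Response latency is the left edge of the first bin with z ≥ 3
inside the dialect window.

**Slice metrics.** PPR = |peak 2| / |peak 1| of the averaged,
baseline-subtracted trace, each peak searched up to the next stimulus; the
inter-pulse interval defaults to 50 ms (configurable; stimulus artefact
scale bars do not pin it down). AMPA/NMDA = |peak| of the averaged −70 mV
trace over the averaged +50 mV current exactly 50 ms post-stimulus.
Mini detection is amplitude-thresholding of the median-baselined,
polarity-rectified trace with a refractory minimum interval (template
matching is out of scope); the count is non-increasing in threshold, and
closely spaced events (closer than the refractory interval) merge — at 1 Hz
this loss is negligible, at 5 Hz it is ~2.5%. Cumulative distributions are
emitted as sorted per-event amplitude lists (per-cell frequencies by
default; inter-event intervals available) for KS comparison. I/O slope is
the OLS line of mean |EPSC| vs stimulus intensity with free intercept.
Series-resistance QC discards a cell when |Rs_t − Rs_0|/Rs_0 exceeds 20%
strictly. All amplitudes are reported as magnitudes.

**Statistics battery.** All p-values are two-sided. Mann-Whitney U uses
midranks, reports U = min(U_x, U_y), and computes exact p by enumerating the
null U distribution (Gaussian-binomial recursion, verified exhaustively
against brute-force enumeration for all n ≤ 8) whenever both samples are
≤ 10 and tie-free; otherwise a normal approximation with tie and continuity
corrections (within 0.02 of exact at n = 8, 8). Kruskal-Wallis is
tie-corrected with χ² reference (H = 0 when every observation is tied).
Friedman uses the uncorrected midrank formula
χ²_F = 12/(nk(k+1))·ΣR_j² − 3n(k+1). Dunn's pairwise z statistics use the
pooled-rank variance with tie correction for independent designs and the
within-block rank variance k(k+1)/(6n) for repeated designs; decisions come
from the Benjamini-Krieger-Yekutieli two-stage linear step-up at level q
(first pass at q/(1+q), m₀ re-estimated, second pass), which is sandwiched
between Bonferroni and unadjusted decisions. Repeated-measures one-way
ANOVA removes the subject effect (df = (k−1, (k−1)(n−1))); Newman-Keuls
post-tests use studentized-range quantiles computed numerically, with
stretch-dependent critical values and non-significance inherited by nested
ranges. Empirical type-I error of each omnibus test at α = 0.05 stays within
[0.03, 0.07] over 10,000 null replicates (measured in the suite).

## What the generator does and does not emulate

The generator reproduces the *statistical* structure the analysis consumes:
session protocols, Poisson spiking with epoch-locked rate changes, template
drift, bout-structured immobility, and sweep shapes with planted metrics. It
does not emulate biophysical membrane dynamics, raw extracellular voltage,
LFPs, spike-sorting errors, bursting/refractoriness, within-session learning
curves inside a CS, or correlated noise across electrodes. Passing recovery
tests therefore demonstrates that the analysis chain is correct and
calibrated on data matching its assumptions — not that it is robust to every
pathology of real recordings.

## Problem sizes used by the test suite and acceptance script

The default cohort mirrors the recorded population: 130 units (8 fear, 6
extinction, 21 session-selective), 14 + 5 rats, full six-session pip
protocol — about 10⁷ spikes, run end-to-end in seconds. Recovery curves use
200 units per phenotype in the suite and 100 in the acceptance script; null
calibration uses 10,000 t tests in the suite and 5,000 in the script; the
type-I sweeps use 10,000 replicates per test.

## Known limitations

- The Newman-Keuls `p_raw` column reports the tail probability of the
  observed studentized range at its own stretch; decisions, not these raw
  values, carry the stepwise logic.
- Exact Mann-Whitney enumeration requires tie-free data; ties always route
  to the corrected normal approximation.
- The recall-group CI bound is computed across rats; with very small cohorts
  it is wide by construction.
- Mini "frequency" cumulative comparisons default to per-cell frequencies;
  inter-event-interval distributions are available as an option.
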