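# Methods

## Time base and conventions

All intervals are half-open `[start, end)` seconds from session start.
Frame `f` at rate `r` covers `[f/r, (f+1)/r)`; frames and 1-s bins are
assigned to epochs by the *midpoint rule* (containment for full-second
epochs and 1-s bins). Cell ids are 0-based integers stable within a
session; registration maps reference these ids and are injective on both
sides. All tables are TSV with `#`-prefixed provenance headers.

## Freezing classification

**Online (closed-loop) rule.** Per-part speed is the Euclidean
displacement since the previous frame times the frame rate; the first
frame's speed is defined as 0 (no predecessor — conservative for
freezing). A frame is freezing iff at least `min_immobile_parts` of the
10 parts are slower than 0.5 cm/s. The freezing-tag criterion uses 7
parts and the no-freezing-tag criterion 6, so each tagged population errs
toward purity; lowering the threshold can only grow the freezing set, so
the 6-part set always contains the 7-part set.

**Post-hoc rule.** The original post-hoc classifier exposes five
parameters (velocity 0.3 cm/s, angle 12°/frame, window 32 frames, count
10 frames, minimum duration 0.5 s) but not its internals; the contract
here is this package's definition, not a port. A frame *passes* when its
centroid speed is under the velocity threshold and the nose–neck vector
rotates less than the angle threshold since the previous frame. A frame
is a *candidate* when it passes **and** at least `count_threshold` frames
in its centered `window_width` window (truncated at track edges) pass —
the windowed count validates a frame against its neighborhood, so
isolated sub-threshold frames inside motion are not freezing, while
requiring the frame itself keeps candidate runs aligned with genuine
still intervals (a 0.4-s blip therefore really is rejected by the 0.5-s
minimum duration, which it would not be if candidacy depended on the
window count alone). Candidate runs shorter than `min_duration` are
discarded. Degenerate nose–neck vectors carry the previous angle
forward. The classifier is invariant under rigid translation.

Δfreezing is the mean freezing percentage over ON-labeled epochs minus
the mean over OFF-labeled epochs.

## Tagging-epoch scheduling

Protocol timelines carry the published shock times (FC: 420 s, 2-s shocks
at 120/180/240/300 s; immediate: shocks at 2/8/14/20 s of a 40-s session;
grouped: 120/126/132/138 s of a 300-s session; recall and neutral
contexts: 480/420 s, no shocks). Condition rules: pre-shock is the 120 s
before the first shock; shock is one 10-s epoch from each shock onset
(2-s shock + 8 s after, 4 × 10 = 40 s); freezing accumulates freezing
bouts from the *offset* of the third shock (light during the shock itself
belongs to the shock condition); no-freezing accumulates non-freezing
time from the second shock's offset; the recall conditions accumulate
over the whole session. Budgeted conditions truncate the final epoch so
the accumulated total equals min(budget, eligible time) exactly in
floating point (the final take is computed as `budget − accumulated`);
a shortfall flag marks plans whose eligible time could not fill the
budget. No minimum bout length is imposed before light onset (the
protocol does not state one).

## Event extraction

Traces are averaged into non-overlapping 1-s bins (trailing partial
window dropped), each cell's binned series is z-scored against its own
mean and population SD (divisor *n*), values below 2 SD are zeroed, and
events are the strict local maxima of the surviving values (boundary bins
compare against their single neighbor; plateaus of tied values yield no
event). The order — bin, then z-score, then threshold — makes the 2-SD
cut scale-free at the bin level, and the raster is invariant under any
positive rescaling of the trace. Zero-variance cells come back as
flagged all-zero rows, never silently dropped. No prominence or width
constraints are applied beyond the 2-SD floor.

**Known bias.** Event rates recovered through this chain are unbiased at
the sparse rates typical of these recordings (at 0.02 events/s, recovery
is 0.0198 over 50 simulated seeds) but compress at higher rates: at
0.1 events/s recovery is ≈ 0.069, because events landing late within a
second leave too little kernel mass in their bin to clear the 2-SD cut,
and events in adjacent bins merge into a single peak. The extractor
never over-counts.

## Ensemble detection

**Activity ranking.** Per cell, the raw trace is averaged over the
condition epochs (the putative tagging period; raw samples and 1-s bins
agree for full-second epochs). Members are cells whose in-epoch mean
*strictly* exceeds the across-cell mean plus one population SD of those
means — so a flat distribution yields an empty group. On i.i.d. normal
in-epoch means this admits Φ(1) ≈ 15.9% of cells.

**Statistical.** Per cell, the statistic is mean binned activity inside
the condition epochs over mean outside, computed on the binned
pre-threshold series (the detection target is the calcium trace, not the
event raster). The null applies `n_shifts` = 1000 circular shifts with
offsets uniform on [1, n_bins−1]; membership requires the real ratio to
strictly exceed the nearest-rank 95th percentile of the null. A shifted
replicate with non-positive out-of-epoch activity has an undefined ratio
and is resampled; a *real* series with positive in-epoch and non-positive
out-of-epoch activity is trivially a member (its ratio is treated as
+∞ — the "resample" rule cannot apply to the observed series); all-zero
cells are flagged non-members. For exchangeable stationary series the
false-positive rate is 51/1001 ≈ 5.1% by construction. Constant cells
tie their entire null and are never members.

Recall ensembles reuse the same machinery with epochs = recall freezing
bouts (frz-recall) or their complement (no-frz-recall); an empty epoch
set is an error, not an empty group.

**Topography.** The mean nearest-neighbor distance from group X to group
Y averages, over X, each cell's distance to the closest Y cell
(self-distances excluded when the groups share a cell); it is asymmetric
by construction.

## Overlap statistics

Overlap defaults to Jaccard |A∩B|/|A∪B| (configurable to /min(|A|,|B|)
or /n_cells; verdicts are robust to the choice because the null uses the
same metric). The null draws, per resample, two independent uniform
subsets of the observed sizes without replacement (1000 resamples,
matching the 1000 circular shifts used elsewhere); its intersection
counts follow the hypergeometric law (mean s_A·s_B/n). Verdicts compare
the observed overlap to the nearest-rank 95th/5th percentiles.

**Tie-breaking.** Overlap proportions of small groups are discrete — for
14-cell groups among 90 cells, P(∩ = 0) ≈ 0.096 — so strict percentile
cuts alone are conservative: the attainable rates are ≈ 2.6% for
"overlapped" and ≈ 0% for "non-overlapped", and no deterministic
tie-handling calibrates both tails. `overlap_test` therefore breaks ties
with seeded i.i.d. jitter of 1e-12 (far below the smallest gap between
distinct overlap values, far above double rounding error) — the standard
randomized-test construction, giving each verdict exact 5% size under
exchangeable draws while leaving separated comparisons untouched. The
deterministic strict rule remains available (`verdict(..., rng=None)`).
No multiple-testing correction is applied across pairs.

## Cross-session reactivation

Relative reactivation R(g) = (tracked fraction of group g) / (overall
tracked fraction); chance = 1, and under uniform random tracking its mean
over many animals is 1 (verified at 10,000 simulated animals, ±0.05).
Recall activity rows report per-group mean event rates over tracked
members — whole session, freezing-bout bins, and non-freezing bins — with
the group in/out ratio formed from the two mean rates and *flagged*
(None + `ratio_undefined`) when the out-rate is zero, never silently
dropped. Group composition reports the percentage of each FC group's
tracked cells that are frz-recall members. The "others" group (tracked
cells in no FC group) is included for parity; being defined from tracked
cells it is fully tracked, so its relative value is 1/overall-fraction by
construction. Metrics are computed per animal; group-level statistics
across animals are left to the caller.

## Correlations and their null

Pearson r is computed for every unordered pair of cells with nonzero
variance on the binary event arrays (so observed and null statistics use
the same object; zero-variance cells go to an exclusion report). The
null shifts every cell independently by a uniform offset in
[1, n_bins−1] per replicate (1000 replicates), conserving per-cell event
counts exactly while destroying pairwise timing. Because a circular
shift changes only the cross term, null correlations are evaluated from
each pair's full circular cross-correlation (one FFT per cell, rounded
back to exact integer counts) indexed at the replicate's relative offset;
`materialize_replicate` reconstructs the explicitly shifted raster and
the test suite verifies the fast path against direct correlation of those
arrays. A group slice is significant when its observed mean r strictly
exceeds the nearest-rank 95th percentile of the per-replicate mean r
(one-sided, α = 0.05) — the test statistic is this package's definition,
as the source protocol names none. Nulls with fewer than 20 replicates
are flagged underpowered. Sorted observed and pooled null r values are
exported for cumulative-distribution plots.

## Synthetic data: what it emulates, and what it does not

The generator reproduces the *statistical* structure the pipeline
consumes, with these defaults as the study conditions:

| parameter | default | why |
|---|---|---|
| session layouts | published protocol timelines | printed shock times/durations |
| cells per session | 90 | reported per-session average |
| trace sampling | 20 Hz | typical miniscope rate; binning is 1 s regardless |
| behavior frame rate | 15 Hz | closed-loop tracking rate |
| freezing dwell | exp. bouts 5 s / inter-bouts 10 s | ≈ 1/3 time frozen, typical post-shock contextual fear; stationary fraction = bout/(bout+inter) |
| baseline event rate | 0.02 events/s | sparse CA1-like rate at which extraction is unbiased |
| in-period gain | 10× | free parameter (no effect sizes are reported for tagged cells); chosen a priori from a Poisson power calculation — 40-s condition epochs give in-epoch counts ~Poisson(8) vs. background ~Poisson(0.8), separating planted cells unambiguously, where gain 5 is marginal |
| planted group size | 16 of 90 (≈ 17.8%) | matches the Φ(1) ≈ 15.9% fraction the mean+1SD ranking rule itself designates; also the smallest prevalence at which a calibrated 5%-false-positive detector can reach precision 0.8 (at 10/90, TP ≤ 10 vs. FP ≈ 0.05·80 caps precision near 0.72) |
| calcium kernel | single exponential, τ = 0.5 s, amplitude 1 | fast-indicator-like; configurable |
| trace noise | Gaussian, SD 0.05 | small relative to the ≈ 0.3–0.4 binned event amplitude |
| registration keep probability | 0.7 | uniform per-cell drop-out; per-group probabilities available for power tests |

Freezing bouts are drawn in continuous time as an alternating exponential
dwell process started from its stationary distribution, bouts shorter
than one frame dropped, then rasterized by the midpoint rule; a bout mean
of 0 is the degenerate never-freezes chain (negative dwell parameters are
rejected). The pose track is a 10-part rigid ring on a centroid random
walk whose per-frame displacement encodes the frame's freezing state, so
the online classifier recovers the generated labels frame-for-frame
(except frame 0, whose speed is 0 by definition). Planted cells fire
Poisson events at gain × baseline inside their condition's epochs — the
scheduler's light epochs for FC conditions, whole freezing periods (and
complement) for recall — and each event adds an exponential kernel before
noise. Paired experiments keep freezing-/no-freezing-tuned identities
across the registration map while shock- and pre-shock-tuned cells revert
to background at recall, their driving condition being absent.

Not emulated: raw video, place-field spatial coding, biophysical
indicator dynamics, realistic anatomy, pose-estimation noise models, or
non-uniform registration errors. Passing tests therefore certify the
*statistics* of the pipeline under the planted model, not robustness to
real-recording artifacts (motion, crosstalk, segmentation errors).

## Problem sizes in the test suite and acceptance script

Calibration checks use 2000 random group pairs (90 cells, sizes 14) with
1000-resample nulls; 1000 stationary cells with 1000 circular shifts;
50-seed planted-recovery runs at the defaults above; 1000 calibration
runs of the correlation test at 10 cells × 1000 bins × 1000 replicates;
and 10,000 simulated animals for the reactivation chance calibration.
These sizes keep Monte-Carlo error well inside the asserted bands.

## Known limitations

- Event-rate compression above ≈ 0.05 events/s (see event extraction);
  rate comparisons between conditions remain valid as both sides share
  the bias direction.
- The online classifier labels frame 0 by its defined zero speed, so a
  session that starts mid-movement contributes one spurious freezing
  frame.
- The statistical detector's circular-shift null assumes circular
  stationarity; the kernel truncation at the session edge introduces a
  negligible edge effect at these durations.
- The pipeline driver orchestrates synthetic experiments end-to-end;
  file-based data enter through the per-stage library functions and CLI
  subcommands rather than the driver.
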