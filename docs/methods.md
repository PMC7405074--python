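# Methods

## Signal model and bout definitions

The input is one non-negative integer per frame per animal (Δ pixels), at
a known frame rate (default 25 Hz).  The method assumes inactivity
registers exactly zero, so the trace partitions uniquely into alternating
*active* bouts (all frames > 0) and *inactive* bouts (all frames = 0);
data whose baseline is not exactly zero must be thresholded upstream.
Frames are 0-based and all intervals half-open `[start, end)`.

Two cleaning steps precede segmentation.  The artifact ceiling (default
200 Δ px, configurable) zeroes every active run containing even one frame
above it — a single implausible frame invalidates the whole movement, since
such spikes come from tracking artifacts rather than behavior.  Masked
intervals (e.g. water changes) are zeroed and remembered; segmentation
flags any bout overlapping a mask (`masked`) or a ceiling-zeroed run
(`artifact`), and leading/trailing bouts are flagged `at_edge` because
their true extent is censored.  Flagged bouts are kept in the bout table —
exclusion is the downstream stages' decision, not the segmenter's: module
sequences carry excluded bouts as impassable gaps, and clustering never
uses them as probes or templates but still labels them.

Active bouts carry six features: length (s), mean, SD, total, minimum and
maximum Δ pixels per frame.  The SD is the population SD (`ddof=0`), so a
one-frame bout has SD 0 and every bout is featurizable.  Inactive bouts
are described by length alone.

## Module clustering

Active features are z-scored per animal (population SD; a zero within-
animal SD raises an error naming the animal and feature), pooled, centered
and PCA-projected.  The component count is the scree knee, computed as the
largest drop between successive explained-variance fractions — a
reproducible stand-in for the visual knee judgment; it can be overridden
with a fixed count.  Inactive bouts are clustered on `log10` of their
length in frames: inactive lengths span orders of magnitude and are only
meaningfully compared on a log scale.  Because frame counts are integers,
short lengths form zero-variance spikes that degenerate mixture components
would latch onto; lengths are therefore dequantized with additive U(0,1)
dither (seeded, switchable) before the log, restoring the underlying
continuous time scale.

Evidence accumulation then proceeds identically for both spaces: a probe
set is drawn once; each of `n_models` Gaussian mixtures is fit to an
independently drawn training subsample of uniformly random size within
`sample_range`, with a uniformly random component count in `k_range`, full
covariances, k-means++ initialization and the best of `n_init = 5`
restarts by log-likelihood; probe points are assigned to their maximum-
posterior component and pairwise co-assignments accumulate.  The mixture
regularization default is 1e-6; the packaged study configuration uses 0.01
on the (unit-scale) clustering spaces so that point masses from quantized
features cannot support near-zero-variance components.

The co-assignment matrix is converted to a dissimilarity
(`n_models − counts`), clustered by average linkage, and cut at the
maximum cluster lifetime: K clusters persist while the merge threshold
sits between consecutive merge heights, and the K with the widest such gap
wins, ties resolving to the larger K.  A matrix with all-equal heights at
zero (all points always co-assigned) returns K=1 with a warning; with two
probes the single merge decides K directly.  Clusters are size-normalized
by sampling the smallest cluster's size from each, every bout is assigned
the mode of its 50 nearest templates (Euclidean; vote ties go to the
lowest module id), and modules are relabeled 1..K by ascending mean bout
length, ties broken by smaller mean total Δ pixels.

Parameter defaults on the library functions (`n_probe` 40,000, `n_models`
200, `k_range` 2–20, `sample_range` 40,000–100,000, 50-NN) suit datasets
of tens of millions of bouts.  The packaged desk-scale study uses
`n_probe` 2,000, `n_models` 50, samples 2,000–4,000 and `k` 2–10 — sizes
chosen so the ensemble still averages ~25 votes per model pair on ~10⁵
bouts; recovery on the synthetic study is ≥ 99% with either scale of
ensemble, and these are the sizes the test suite runs.

## Hierarchical compression

Module sequences are compressed by repeatedly substituting the most
compressive motif.  Candidates are all contiguous runs of 2..10 symbols of
the *current* sequence (so rules may contain earlier rule symbols — the
nesting mechanism, which surfaces terminal motifs beyond 10 modules);
occurrences are counted non-overlapping, left-to-right greedy, because the
replacement must be realizable; savings are `W·N − (W+1+N)`; the argmax is
replaced everywhere it was counted by a fresh symbol; iteration stops when
no candidate saves anything.  Ties prefer the longer motif, then the
lexicographically smallest token tuple, making output deterministic.
Compressibility is total savings over original length, in [0, 1).  The
implementation scans candidates with a vectorized 64-bit rolling hash,
shortlists by an upper bound on savings (the overlapping count), and
verifies each shortlisted candidate exactly — hash collisions are resolved
by token comparison, so results equal the exhaustive scan (the test suite
checks this against a brute-force oracle on every 3-symbol sequence up to
length 10 and on longer random sequences).

Candidate motifs never span excluded-bout gaps: sequences are split at
mask boundaries first, and segment boundaries are unique sentinels no
window can cross.  Because compressibility varies non-linearly with
sequence length, samples of different sizes are compared on non-overlapping
500-module blocks (trailing partial blocks dropped, so per-block savings
stay comparable).  Δ-compressibility is the real value minus the mean over
the 10 paired shuffles of the same window.

The motif library is the union of every animal's terminal rule expansions,
deduplicated and canonically ordered by length then lexicographically.  On
strictly alternating sequences, the greedy heuristic first merges
active–inactive pairs and then pairs of pairs, so terminal expansions are
almost always even-length and anchored on an active module; odd-length
motifs essentially never enter the library.  This is a property of the
offline most-compressive heuristic itself, worth knowing when choosing
motifs to plant or interpret.

## Shuffled nulls and enrichment scores

For each animal the module sequence is divided into windows — day/night or
hourly — and shuffled 10 times within each window, permuting active ids
among active slots and inactive ids among inactive slots independently.
This preserves each window's module multisets and the alternation
structure exactly, destroying only sequential order; windows with one
module of a kind are necessarily unchanged.  Motif counts use sliding
(overlapping) matches by default so the count is independent of any
replacement order; a non-overlapping convention is available.

The enrichment/constraint score is `Z = (x − mean(shuffles)) / SD(shuffles)`.
The SD uses the sample convention (`ddof=1`): integer shuffle counts with
mean 4.5 can only produce the printed SD of 1.58 under n−1 (e.g.
`[2,3,3,4,4,5,5,6,6,7]` gives exactly √2.5 = 1.581 and Z = 3.48), whereas
no integer counts give a population SD rounding to 1.58.  When the shuffle
SD is zero the score is ±√(1 + n_shuffles) = ±3.32 by sign of the
deviation, and 0 when the real count equals the shuffle mean — so motifs
absent from both real and shuffled data score 0, not ±3.32.  Shuffle-self
scores leave each shuffle out of its own null.  The matrix of samples
(animal × window) by motifs is column-normalized (population SD; constant
columns zeroed and flagged) before selection.

## Supervised motif selection

Scores are discretized per column into 3 states at mean ± 1 SD (the
classic preprocessing for continuous mRMR) and ranked greedily: the first
motif maximizes mutual information with the class labels; later motifs
maximize relevance minus mean redundancy to those already chosen (MID;
the quotient variant MIQ is available).  Linear-discriminant classifiers
(pooled covariance with a mild ridge, shrinkage 1e-4, for rank-deficient
prefixes) are evaluated under stratified 10-fold cross-validation as
ranked motifs are added; folds are grouped by animal by default so one
animal's windows never straddle train and test (a plain row-wise split is
a flag away).  The error curve is smoothed with a 3-wide centered running
average whose windows shrink symmetrically at the edges (endpoints
unsmoothed at width 3), and the first minimum picks the motif count.
Baselines: the majority-class error `100·(1 − max class fraction)` with
its SE of proportion, and the mean ± SD over 10 classifiers built from
random motif subsets of the selected size.

## The synthetic generator

`SimulationSpec` describes frame rate, a labeled window schedule, per-
module length/amplitude distributions (positive integers; amplitudes
within the plausible 3–165 Δ px range), per-window categorical module
probabilities, and planted motifs with per-window insertion rates.  All
randomness flows from one seed through a splittable generator, with
per-animal children derived from the seed and animal index, so parallel
and serial simulation agree bit-for-bit.

Motif planting overwrites kind-compatible module runs at uniformly chosen
non-overlapping positions (lengths redrawn from the overwritten-in
modules' templates), rather than inserting new modules; this keeps module
counts, window bookkeeping and ground truth exact.  The default study
conditions are one 14 h day / 10 h night cycle at 25 Hz with five active
modules (graded length × amplitude) and five inactive modules (log-spaced
~0.1 s to ~1 min), day behavior favoring short modules and night behavior
long ones — roughly 20,000 modules per animal per cycle and the familiar
diurnal activity profile.  The night never uses the shortest active or
inactive module, and the two default planted motifs are 6-module,
active-anchored sequences built from rare modules plus those day-exclusive
ones, planted day-only at ~2 occurrences per hour.  That composition is
deliberate: a planted motif's score column only dominates its own derived
sub- and super-motifs in the mRMR ranking when its night scores are
structurally zero, its chance background under shuffled marginals is low
enough (~10⁻⁶ per position) that spurious finite-Z spikes — which inflate
the column SD past the ±3.32 bulk of the discretization — are rare, and
its day presence sits near 80–90% of hourly windows so the bulk clears the
mean+SD threshold.

For the real-vs-shuffled compressibility study, planting must also clear
the sampling noise of a single sequence's compressibility, which scales
like 1/√n; the packaged conditions (2,000 modules, rates 0.05 and 0.03)
put the planted signal more than five standard deviations above zero.

What the generator does *not* emulate: amplitude autocorrelation within a
bout (frames are i.i.d. given the module), gradual module drift across
development, inter-animal variability in module shapes (all animals share
templates; per-animal z-scoring makes this mild), and multi-animal
interactions.  Passing recovery tests therefore shows the pipeline is
correct and well-calibrated under its own assumptions, not that real
recordings satisfy those assumptions.

## Numerical and degenerate-input conventions

- Empty recording → no bouts; empty sequence → compressibility 0, empty
  grammar; sequence shorter than one block → empty block table with a
  warning.
- Overlapping masks merge with a warning; `n_probe` larger than the data
  raises; a smallest cluster below `k_nn` reduces `k_nn` with a warning;
  classes smaller than the fold count reduce the folds with a warning.
- All tie-breaks are documented and deterministic: compression prefers
  longer then lexicographically smaller motifs; the lifetime cut prefers
  larger K; k-NN votes and mRMR ties prefer the lowest id; the error-curve
  minimum prefers the smallest count.
- CSV artifacts carry a `# config=<hash>` provenance line; the hash covers
  the scientific configuration only, so re-runs and parallel runs are
  byte-identical.

## Known limitations

- The offline most-compressive heuristic is greedy; it is exact per
  iteration (verified against exhaustive search) but the sequence of
  replacements is not globally optimal, and alternative "best motif"
  objectives (most frequent, longest) are not implemented.
- The evidence-accumulation ensemble at its large-scale defaults is quadratic
  in the probe count; probe sets beyond ~20,000 need substantial memory.
- mRMR relevance is estimated from 3-state discretized scores; strongly
  heavy-tailed score columns can be under-ranked relative to their true
  separability, a known property of the discretization discussed above.
- The CLI ingests the generic frames × animals CSV; vendor-specific export
  dialects must be converted upstream.
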