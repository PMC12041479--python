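# Methods

This note documents the models, conventions and design choices behind
`mea_netpharm`, in the order the pipeline applies them.

## Spike detection and artifact handling

Raw traces (25 kHz in the targeted recording setup) are cleaned by blanking:
every sample above a user-supplied positive threshold marks an artifact, and
the closed interval from 6 ms before to 25 ms after it is zeroed.  The
interval is mapped to sample indices by rounding outward (conservative
blanking); the operation is idempotent.  Spike detection then thresholds at
−5 × SD of the cleaned trace.  The SD is computed over all samples including
blanked zeros by default — the blanked signal *is* the artifact-free signal —
with a flag to exclude the zero stretches instead.  A spike is stamped at the
first sample at or below threshold in each negative-going crossing (the
leading edge; stamping the waveform trough instead would shift all times by a
near-constant and change nothing downstream), and a refractory dead time
(default 1 ms) suppresses re-crossings within one waveform.  Electrodes are
"active" with ≥ 1 spike (configurable); manually excluded electrodes are
carried in the data model.

The per-chip positive artifact thresholds of any concrete rig are
user-supplied parameters, not constants of the package.

## Synthetic paired recordings

The generator emulates the study design the pipeline targets: 9 chips × two
conditions × 600 s, up to 60 electrodes.  Per electrode, background spikes
are homogeneous Poisson (0.5 Hz).  Chip-wide burst events arrive as a Poisson
process (0.2 Hz pre-drug); at each event every electrode participates with
probability 0.4, and a participating electrode emits 5 spikes at the event
time plus independent Gaussian jitter (SD 50 ms pre-drug), clipped to the
recording.  The drug condition raises the burst rate to 0.4 Hz and
participation to 0.9 and tightens jitter to 10 ms — more, larger, sharper
network bursts, the signature of disinhibition.  Both conditions of a chip
share one multiplicative `exp(N(0, 0.2²))` random effect on all rates
(chips differ, conditions stay paired — mirroring the random intercept of
the downstream LMM), and 10 % of electrodes per chip are silenced in both
conditions to emulate uncovered electrodes.  Jittered spikes are sorted and
deduplicated at 0.1 ms so per-electrode trains stay valid.  A `null()`
configuration sets the drug parameters equal to baseline, giving
exchangeable conditions for calibration experiments.

What the generator does *not* emulate: refractoriness, bursty single-unit
ISI structure, distance-dependent connectivity, nonstationarity over the
recording, or waveform-level noise.  Consequences for interpretation: at a
0.5 correlation threshold and millisecond bins the synthetic pairwise
coincidence rates produce very sparse graphs, so the discriminative signal
concentrates in the synchrony feature; passing end-to-end tests demonstrates
correct mechanics of the workflow (leak-free CV, calibrated statistics,
faithful attributions), not that graph topology separates conditions in real
recordings.

## Windowing and binning

All intervals are half-open `[start, end)`; a spike exactly at a boundary
belongs to the next window/bin, so nothing is counted twice.  Window k of a
spec (window, overlap) covers `[k·step, k·step+window)` with
`step = window·(1−overlap/100)`; only fully contained windows are emitted
(trailing remainder dropped, keeping windows identically sized), giving
`floor((T−window)/step)+1` windows.  Binning marks a bin 1 if the electrode
spiked at least once in it; the trailing partial bin is dropped.  Floor
operations carry a 1e-9 relative guard so boundary spikes are not
misassigned by floating-point representation error.

## Connectivity

Binary rows are correlated pairwise.  Pearson on 0/1 rows equals the phi
coefficient and is computed from the sparse co-occurrence counts (identical
values, much faster on long windows).  Spearman ranks rows first.  The
"canonical" method is a documented stand-in: pairwise CCA of two univariate
binary series degenerates to |Pearson|, so each row is lag-embedded
(lags 0–5 bins) and a soft-thresholded power iteration (sparsity 0.1)
returns the first sparse canonical correlation; the construction is
pluggable.  Zero-variance (silent) rows correlate 0 with every partner,
keeping silent electrodes isolated instead of propagating NaNs.

Graphs use the *raw* correlation values, thresholded at 0.5 (signed rule:
strong negative correlation is no edge; ties are edges).  Standardizing
correlation matrices before thresholding would make a fixed 0.5 threshold
data-dependent, so feature-matrix standardization happens downstream instead;
a `standardize_before_threshold` switch preserves the alternative ordering
for comparison.  Only electrodes active within the window become nodes.

## Graph features

17 scalar measures and 8 community measures per graph (definitions in
`net_features`).  Non-obvious conventions:

* `complexity` = ⟨k²⟩/⟨k⟩ (degree-heterogeneity ratio), chosen for
  consistency with SMD = ⟨k²⟩ being a separate feature; overridable.
* `ed` is the Shannon entropy (bits) of the empirical degree distribution.
* Per-node measures (betweenness, closeness, eigenvector centrality, hub
  score, neighbor degree, eccentricity) reduce to a scalar by arithmetic
  mean (median available).  Betweenness is normalized by (n−1)(n−2)/2;
  closeness uses the within-component convention with isolated nodes at 0;
  `knn` averages over non-isolated nodes.
* Eigenvector centrality and hub score are computed by power iteration from
  the all-ones start vector and max-normalized.  The canonical start makes
  results deterministic and permutation-equivariant even when the dominant
  eigenvalue is degenerate (bipartite or disconnected graphs), where
  ARPACK-style random starts return an arbitrary vector of the eigenspace.
* Disconnected graphs: APL, diameter and eccentricity are evaluated on the
  largest component; efficiency uses 1/∞ = 0 over all ordered pairs;
  edgeless graphs score 0 on all distance measures.  Assortativity of a
  regular graph (undefined correlation) is 0.
* Community features: each of eight algorithms (fastgreedy, infomap, leading
  eigenvector, label propagation, edge betweenness, spinglass, multilevel,
  spanning tree) partitions the graph; the feature is the average path
  length within the largest community (ties broken toward the community
  containing the smallest node id; singleton/edgeless communities score 0).
  Spinglass requires connectivity and runs on the largest component with
  remaining nodes as singletons.  The spanning-tree method is a documented
  stand-in: iteratively remove the spanning-forest edge with highest edge
  betweenness and keep the forest-component partition maximizing modularity
  of the original graph.  Stochastic methods are seeded per window from the
  master seed; heuristic community detection is only label-invariant when
  the partition is unambiguous, which the tests respect.

## Spike-Contrast

Bin sizes scan geometrically from T/2 down to 10 ms (shrink 0.9), each with
half-overlapping bins (step Δt/2, trailing partial bin dropped).  With θ_k
the population spike count in bin k and n_k the number of active trains,

* Contrast(Δt) = Σ|θ_{k+1} − θ_k| / (2 · Σθ'), where Σθ' counts each spike
  once.  Because half-overlapping bins count each spike twice, this equals
  Σ|Δθ| / Σθ over the overlapped series — the normalization under which an
  isolated synchronous event contributes exactly its spike count to both
  numerator and denominator, so perfectly synchronous trains reach 1.
* ActiveST(Δt) = (Σn_kθ_k/Σθ_k − 1)/(N − 1), clipped to [0, 1] against
  floating-point undershoot.

Synchrony is max over Δt of the product; range [0, 1]; identical trains give
exactly 1, independent Poisson trains roughly 1/N at their best scale.  All
scan parameters are configurable.  Note that the measure is not exactly
invariant under duplicating every train: ActiveST maps the θ-weighted mean
active-train count m through (m−1)/(N−1), and (2m−1)/(2N−1) differs unless
m = N; invariance holds in the synchronous regime (m → N), which is what the
tests assert.

## Classification and attribution

Features are standardized per chip against that chip's pre-drug windows
(mean, sample SD) — post-drug values then express drug shifts in units of
baseline variability; a pooled per-chip variant is available.  Outer CV is
grouped leave-one-chip-out (all windows of one chip, both conditions, form
one validation set); hyperparameters come from a small fixed grid tuned by an
inner leave-one-chip-out over the training chips, maximizing mean AUC.  ROC
uses decision scores (margins or probabilities), never hard labels.  The
summary score is the 2.5th percentile of 1000 bootstrap means of the
per-split AUCs — a deliberately conservative "lower-CI AUC".  A disjointness
assertion between train and validation chip sets runs on every split.

Model defaults (grids in parentheses): SVM RBF (C ∈ {0.1, 1, 10}), RF 500
trees (depth ∈ {∞, 8}), XGBoost 200 rounds (depth ∈ {3, 6}), kNN
(k ∈ {3, 5, 9}), logistic regression (C ∈ {0.1, 1, 10}), Gaussian NB, MLP
(one hidden layer of 100, early stopping).  All seeds derive from the master
seed by hashing stage identifiers, so each stage is independently
reproducible.

Shapley attributions use the interventional coalition value: features outside
the coalition are replaced by background rows (a per-split subsample of the
training set) and scores averaged.  Exact mode enumerates all subsets
(≤ 12 features); sampled mode averages marginal contributions over feature
permutations, satisfying the efficiency identity exactly per permutation.
The pipeline reports class-1 (post-drug) validation windows, 64 permutations
and 16 background rows per split by default — enough for stable rankings of
26 features at pipeline scale; the standalone function defaults to 2000
permutations.  Rankings use the median across splits of per-split median
|φ|, with min/max across splits and the sign of the post-vs-pre feature
shift.  Cross-model agreement is the Pearson correlation between
median-|φ| vectors.

## Mixed-model statistics

Each feature is tested at window level (no pre-averaging — the windows'
dependence is exactly what the model absorbs) with a random-intercept-per-
chip LMM fit by maximum likelihood, against the condition-free null, via a
1-df likelihood-ratio test.  LRT over Wald: estimator-agnostic and easy to
verify by simulation; ML over REML because REML likelihoods of models with
different fixed effects are not comparable.  Constant features and
non-convergent fits are flagged, never starred.  Star codes: `ns` p > 0.05,
`*` ≤ 0.05, `**` ≤ 0.01, `***` ≤ 1e-3, `****` ≤ 1e-4, boundaries to the
stricter bin.  Per-feature codes are uncorrected (matching how such tables
are conventionally reported); a Benjamini–Hochberg q-value column is emitted
alongside.

## Problem sizes

Unit tests run on scaled-down generators (4–6 chips, 12–20 electrodes,
60–180 s).  The end-to-end effect-recovery experiment and the acceptance
script use the full study geometry — 9 chips × 600 s × 60 electrodes at the
recommended preprocessing (240 s windows, 75 % overlap, 1 ms bins, Pearson),
i.e. 126 feature rows per dataset — with a strong-effect and a null
generator.  LMM calibration uses 200 simulated null features; Spike-Contrast
calibration uses 20-train Poisson ensembles over 20 seeds and jitter ladders
from the generator.

## Known limitations

* The canonical-correlation connectivity and the spanning-tree community
  method are documented stand-ins for under-specified upstream constructs.
* Heuristic community detection is not label-permutation invariant when the
  modularity landscape has ties.
* The synthetic generator's coincidence statistics make 1 ms-bin graphs very
  sparse; graph-feature sensitivity on real recordings is not established by
  these tests.
* No directed/causal connectivity (transfer entropy, Granger, TSPE) and no
  weighted-graph measure variants.
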