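# Methods

`brainlayers` implements a multilayer-network analysis of frequency-specific
resting-state functional connectivity, of the kind used to compare two groups
of subjects (for example, musically trained versus untrained participants)
from source-space MEG region time courses. This note documents the models,
the numerical choices, and what the synthetic benchmarks do and do not show.

## Connectivity model

The link weight between two regions in a frequency band is the amplitude
envelope correlation (AEC): the Pearson correlation between the slow
amplitude envelopes of the band-limited signals. The chain, per band:

1. **Band-pass filtering.** Zero-phase (forward–backward) Butterworth SOS
   filter, order 4 per direction. Zero phase protects envelope timing; the
   squared magnitude response gives well over 20 dB attenuation one octave
   outside the band. The five default bands are theta (6.5–8 Hz), alpha1
   (8.5–10), alpha2 (10.5–12), beta1 (12.5–16), beta2 (16.5–20).
2. **Leakage correction.** Source-reconstructed region signals share
   zero-lag variance (field spread). We use the symmetric multivariate
   correction: find the set of mutually orthogonal signals closest to the
   input in least squares, by alternating the polar (closest
   orthonormal-columns) step with a per-region amplitude refit, to a 1e−9
   relative-residual tolerance (max 100 iterations). All regions are treated
   symmetrically; no seed is privileged. Input rows are demeaned, so outputs
   are exactly zero-lag orthogonal with zero mean. Rank-deficient input
   (e.g. a duplicated region) is an error naming the offending pair, rather
   than a silent spurious result. Correction is applied per band, after
   filtering.
3. **Envelopes.** Magnitude of the analytic signal (Hilbert transform).
4. **Down-sampling to 4 Hz** by non-overlapping window averaging (not
   decimation), robust to envelope aliasing.
5. **Correlation.** Pearson correlation of envelope pairs; diagonal forced
   to zero. The first and last 2 s of the down-sampled envelopes are
   discarded to drop filter/Hilbert transients.

## Multilayer network and normalization

The f = 5 band networks over N shared nodes form an fN×fN block
supra-adjacency: per-band adjacencies (absolute-valued) on the diagonal
blocks and c·I on every off-diagonal block — each node couples only to
itself across layers (no cross-frequency coupling between different
regions). Results are computed over a sweep of the interlayer coupling c.

**Normalization.** Groups can differ in mean connectivity, which biases
supra-adjacency comparisons. The correction rescales by the largest singular
value λ₁: Ã = U(10/λ₁ Λ)Vᵀ, identical to the scalar rescale (10/λ₁)·A
(implemented that way; a full-SVD path is retained behind a flag for
verification). The factor 10 keeps weights in a convenient range.

One consequence shaped the pipeline's ordering: multilayer modularity is
*invariant* under a uniform rescaling of the whole supra-adjacency, coupling
included. Normalizing after the coupling is attached would therefore leave Q
untouched. The pipeline instead rescales each subject's connectivity layers
by 10/λ₁ of the coupling-free (block-diagonal) stack and attaches c to the
normalized layers — so a given c carries the same relative weight for every
subject, which is the point of the correction. `svd_normalize` (whole-block
rescale) and `normalize_layers` (layers-then-coupling) are both exposed; the
pipeline uses the latter.

A utility keeps the strongest fraction of links for display
(`threshold_top_fraction`); the link count is the ceiling of
fraction × N(N−1)/2 (ceiling rather than floor — the convention is
documented and tested), with ties resolved by stable node-index order.

## Multilayer modularity and community detection

The quality function is the standard multilayer modularity for layered
networks with diagonal coupling:

Q = (1/2μ) Σ_{ijlk} [ (Ã_{l,ij} − γ_l s_{il}s_{jl}/(2m_l)) δ_{lk} + δ_{ij} c ] δ(g_{il}, g_{jk})

with the Newman–Girvan null per layer, γ_l = 1 throughout, and 2μ the total
weight of the whole supra-adjacency (within-layer weight plus interlayer
coupling weight). The 2μ convention is isolated in one function
(`supra_modularity_matrix`) so it can be flipped if a different reading of
"total link weight" is preferred.

**Optimization** is a generalized Louvain on the supra-modularity matrix:
greedy single-node moves in random sweep order (including isolation moves to
an empty community), accepted on strict gain > 1e−10, followed by graph
aggregation, iterated to a local maximum. Quality is asserted non-decreasing
across passes. The algorithm is repeated (default 100 runs) with different
sweep orders; every run's Q matches an independent evaluation of the quality
function to 1e−12. On instances small enough to solve exactly, the best of
100 runs attains the global maximum computed by an exhaustive
subset-dynamic-program over all set partitions (tests).

**Group-level consensus.** Per layer, an agreement matrix holds the fraction
of partitions (all subjects × all runs of a group) in which two nodes share
a community; the collapsed agreement matrix is the element-wise mean over
layers. Consensus clustering re-runs single-layer Louvain (γ = 1) on the
agreement matrix and rebuilds the agreement from those runs, iterating until
all runs return the bit-identical partition (read literally; no agreement
thresholding is applied). Non-convergence within 50 iterations is an
explicit error with diagnostics.

**Across the coupling sweep**, consensus module labels are aligned by
maximum-overlap (Hungarian) matching to the partition at the median c; each
node's module frequency is tabulated and its final module is the modal
aligned label, flagged when the modal frequency does not exceed the chance
level 1/(final module count). The flag is reported, not tested — no
distributional claim is attached to it.

## Group statistics

- **Modularity curves**: per c, two-sided Wilcoxon rank-sum (normal
  approximation with tie and continuity corrections; exact tie-aware
  enumeration of all labelings when both groups have n ≤ 10), rank-biserial
  r = 2U/(n₁n₂) − 1 (negative when the first group tends lower), and the
  summary Cohen's d = 2r̄/√(1−r̄²) of the mean r.
- **Partition agreement**: Hubert–Arabie adjusted Rand index between the two
  groups' consensus partitions, averaged over c.
- **Covariates**: Spearman correlations of modularity with age, years of
  training, and starting age, with a rank-residual partial variant
  controlling for age. The pooled variant (every subject × c × run
  observation) reproduces the common practice of pooling non-independent
  observations and is flagged `pseudoreplicated`; a subject-level mean
  variant is reported alongside as the defensible alternative.
- **Classifier**: a univariate threshold rule on mean modularity over c —
  the minimal model consistent with a single scalar feature — implemented as
  a scikit-learn estimator and evaluated with stratified 4-fold
  cross-validation (apparent and held-out accuracy reported).

## Network-based statistics

Single-layer NBS per band: pooled-variance two-sample t per unique link; the
test statistic is the size of the largest connected component of
supra-threshold links, measured in links ("extent"; node count via a flag).
The null is built from random relabelings of subjects (M permutations), and
p = (1 + #{null ≥ observed})/(M + 1) — never exactly zero, and within 1/M of
the plain /M convention. The two-sided analysis is reported as two one-sided
analyses (t > thr and t < −thr) per threshold. Benjamini–Hochberg FDR is
applied across bands at each (threshold, direction), not across thresholds.
Calibration is verified by simulation: on exchangeable nulls the rejection
rate at α = 0.05 stays inside the 95% binomial band, and a +2-pooled-SD
planted 5-node subgraph is detected in ≥ 90% of repetitions.

## Synthetic cohorts

The generator defines the benchmark conditions; it is not tuned per test.

- **Adjacency mode** (default): each subject's per-band matrix is a planted
  block structure — intra-community weight 0.6, inter-community weight 0.15
  (AEC-scale values), truncated-Gaussian link noise of SD 0.05 (negative
  draws re-drawn) — identical across the five layers. Group A carries 2
  equal modules, group B 3 modules; the default desk-scale cohort is N = 20
  nodes, f = 5 layers, 15 subjects per group (scaled down from 78 nodes and
  31 per group; full scale available via configuration). An optional uniform
  connectivity offset on one group exercises the normalization.
- **Time-course mode**: per band, each region carries a tone at a distinct
  frequency in the middle of the band (random phase), amplitude-modulated by
  a slow (< 1 Hz, order-4 low-pass at 0.8 Hz) positive process
  1 + 0.3·z rectified at 0.02, where the Gaussian processes z are
  empirically whitened and mixed to the target correlation matrix (nearest
  positive-semidefinite repair by eigenvalue clipping). Envelope correlation
  is then linear in the mixed processes, so the measured AEC tracks the
  target within ~±0.02 for planted couplings at 300 s. A log-normal
  modulator was considered and rejected: nonlinear transforms of heavily
  autocorrelated slow processes (only a few hundred effective samples in
  5 minutes) produce spurious sample correlations of several tenths, far
  outside any useful tolerance. Residual spurious AEC in the null is ~0.05
  (SD), occasionally ~0.15 at the max over many pairs — tests use fixed
  seeds and tolerances consistent with this.
- **Covariates**: age ~ N(28, 6²) years; years of training ~ N(13.25,
  5.04²) truncated at ≥ 5 for the trained group (0 for the untrained);
  starting age = age − years of training.

What the synthetic data does *not* emulate: 1/f background spectra, burst
dynamics, true source leakage (regions are generated independently, so the
leakage-correction stage is exercised only for its no-harm property on the
synthetic signals), volume conduction, and subject-level spatial
heterogeneity of module boundaries. Passing recovery tests therefore shows
the chain is correct and calibrated on its stated model, not that real MEG
effects of this size would be detected.

## Problem sizes and determinism

Desk-scale defaults keep the full pipeline in minutes: c grid 0:0.1:1 (11
values — also the grid used for module-frequency maps; 0:0.01:1 available by
configuration), 100 Louvain runs per subject and c, 100 consensus runs,
desk-scale NBS grids (the canonical t = 0.5:0.1:5.0 with M = 5000 is
available through the `nbs` API/CLI). All randomness derives from one master
seed through named SeedSequence substreams keyed by (stage, subject, c), so
a rerun with the same configuration reproduces every table bit-identically
and results do not depend on iteration order.

## Region table

The packaged AAL table lists the 116 regions in standard atlas order with
hemisphere and cortical flags; the 78 cortical nodes (the 38 excluded are
the six bilateral subcortical structures plus cerebellum/vermis) are ordered
left block then right block for matrix displays. Seed-region defaults
(bilateral SMA and precentral gyrus) are keyed by label, because numeric
node indices depend on an ordering convention that varies between software
stacks; any convention can be reproduced by reordering the table.

## Known limitations

- Louvain is a heuristic; global optimality is only guaranteed where the
  exhaustive oracle can verify it (small instances). Repeated runs plus
  consensus mitigate, not eliminate, local maxima.
- Consensus stability is defined as bit-identical agreement across all runs;
  pathological agreement matrices can legitimately fail to stabilize (an
  explicit error, tested).
- The pooled covariate correlations are pseudo-replicated by construction;
  they are reproduced for fidelity and flagged, with the subject-level
  variant as the honest alternative.
- The permutation p floor is 1/(M+1); small effects need large M.
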