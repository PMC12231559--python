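# brainlayers

Multilayer frequency-band brain-network analysis: from band-limited region
time courses through amplitude-envelope-correlation (AEC) connectivity,
SVD-normalized supra-adjacency matrices and multilayer modularity with
consensus community detection across an interlayer-coupling sweep, to group
statistics and single-layer network-based statistics (NBS).

## Who this is for

Researchers comparing frequency-specific resting-state networks between two
groups of subjects (e.g. trained vs. untrained cohorts) from source-space
M/EEG region time courses — and anyone who wants a tested, reproducible
implementation of the multilayer community pipeline with a synthetic cohort
generator, so every stage runs and is verifiable without any recordings.

## The model in brief

Per band α, an N×N AEC matrix A_α is built (band-pass → symmetric leakage
correction → Hilbert envelope → 4 Hz window averaging → Pearson r). The f
bands form an fN×fN block supra-adjacency with one-to-one interlayer
coupling H_kl = cI. Connectivity is rescaled by its largest singular value
(λ₁ → 10) so group comparisons are not biased by mean connectivity.
Community structure maximizes multilayer modularity

> Q = (1/2μ) Σ_{ijlk} [ (Ã_{l,ij} − γ_l s_{il}s_{jl}/(2m_l)) δ_{lk} + δ_{ij}c ] δ(g_{il}, g_{jk})

via generalized Louvain (100 randomized runs), aggregated into per-layer and
collapsed agreement matrices per group, consensus-clustered until stable,
and summarized as per-node module frequencies across the c sweep. Group
inference: per-c Wilcoxon rank-sum on Q with rank-biserial r and Cohen's d,
adjusted Rand index between group partitions, Spearman/partial-Spearman
covariate correlations, a threshold classifier on mean Q, and permutation
NBS with FDR across bands. Details and design rationale: `docs/methods.md`.

## Worked example

```python
import numpy as np
from brainlayers import RunConfig, generate_cohort, run_group_module_analysis

# two groups of 10 subjects, 20 regions, 5 bands; group A carries a planted
# 2-module structure, group B a 3-module structure
cohort = generate_cohort(n_per_group=10, seed=7)
cfg = RunConfig(seed=7, c_grid=np.round(np.arange(0, 1.01, 0.25), 10),
                n_runs=50, consensus_runs=50,
                nbs_thresholds=np.array([2.0]), nbs_M=500)
report = run_group_module_analysis(cohort, cfg)

print("module counts:", report.module_counts())
print("mean ARI between groups:", round(report.mean_ari, 4))
print(report.group_comparison.table.round(4).to_string(index=False))
print("classifier 4-fold CV:", report.classifier.cv_accuracy)
```

prints

```
module counts: {'A': 2, 'B': 3}
mean ARI between groups: 0.3871
   c       z   p    r
0.00 -3.7418 0.0 -1.0
0.25 -3.7418 0.0 -1.0
0.50 -3.7418 0.0 -1.0
0.75 -3.7418 0.0 -1.0
1.00 -3.7418 0.0 -1.0
classifier 4-fold CV: 1.0
```

Reading this: group consensus recovers the planted 2 vs. 3 modules; the two
groups' consensus partitions agree only partially (ARI 0.39 — the 2-module
split nests inside the 3-module one); at every coupling value the 2-module
group has significantly lower modularity (rank-sum z ≈ −3.74; exact p ≈
1e−5, printed as 0.0 at 4 decimals; rank-biserial r = −1 is complete
separation, so the Cohen's-d equivalent is unbounded), and one scalar —
mean Q over c — classifies group membership perfectly under stratified
4-fold cross-validation. On this synthetic effect the single-layer NBS also
detects the group difference: the planted modules differ at the link level,
unlike weaker real-data effects that only the multilayer analysis resolves.

The same run is available from the shell:

```sh
brainlayers run-all --seed 7 --out results/demo
brainlayers simulate --seed 1 --out results/cohort
brainlayers nbs --cohort results/cohort --thresholds 0.5:0.1:5.0 --m 5000 --seed 1 --out results/nbs.csv
```

## Layout

| module | contents |
| --- | --- |
| `brainlayers.synthgen` | planted-structure cohorts, envelope time-course generator |
| `brainlayers.envconn` | band-pass, leakage correction, envelopes, AEC |
| `brainlayers.mlnet` | supra-adjacency assembly, λ₁ normalization, top-fraction thresholding |
| `brainlayers.community` | multilayer modularity, generalized Louvain, agreement/consensus, module frequencies |
| `brainlayers.nbs` | link t-stats, largest supra-threshold component, permutation test, sweep |
| `brainlayers.groupstats` | rank-sum, effect sizes, ARI, Spearman, threshold classifier |
| `brainlayers.pipeline` | end-to-end orchestration, seed-based comparison, study report |
| `brainlayers.atlas` | AAL region table (116 regions, 78 cortical nodes) |
| `brainlayers.cli` | `brainlayers` command: simulate / connectivity / multilayer / community / nbs / stats / run-all |
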