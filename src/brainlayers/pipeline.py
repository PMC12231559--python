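"""End-to-end study orchestration.

Runs the full multilayer analysis on a two-group cohort: per subject and per
interlayer coupling value, assemble the supra-adjacency, normalize it by its
largest singular value, and optimize multilayer modularity with repeated
generalized-Louvain runs; per group and coupling value, build per-layer
agreement matrices, collapse them, and derive an iterative consensus
partition; across the coupling sweep, align module labels and tabulate
per-node module frequencies. On top of that: the per-c rank-sum comparison of
modularity curves with effect sizes, the adjusted Rand index between the two
groups' consensus partitions, a single-layer NBS sweep, covariate
correlations, and the modularity threshold classifier.

Every random step derives its seed deterministically from the master seed, so
a rerun with the same config reproduces the report bit-identically.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field
from typing import Any

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from . import groupstats
from .atlas import DEFAULT_SEED_LABELS, load_region_list
from .community import (
    ModuleFrequencies,
    Partition,
    agreement_per_layer,
    collapse_agreement,
    consensus_partition,
    genlouvain,
    module_frequency_across_c,
)
from .envconn import connectivity_pipeline
from .mlnet import build_block, normalize_layers
from .nbs import nbs_sweep
from .synthgen import CohortDataset

__all__ = ["RunConfig", "StudyReport", "run_group_module_analysis", "seed_comparison", "load_region_list"]

log = logging.getLogger("brainlayers.pipeline")


@dataclass
class RunConfig:
    """Parameters of one full study run.

    The c grid defaults to 0:0.1:1 (the grid used for the module-frequency
    maps); a 0:0.01:1 grid is available by passing it explicitly. NBS
    defaults are desk-scale; widen ``nbs_thresholds``/``nbs_M`` for a full
    sweep.
    """

    c_grid: np.ndarray = field(
        default_factory=lambda: np.round(np.arange(0.0, 1.0 + 1e-9, 0.1), 10)
    )
    n_runs: int = 100
    gamma: float = 1.0
    normalize: bool = True
    consensus_runs: int = 100
    nbs_thresholds: np.ndarray = field(default_factory=lambda: np.array([1.0, 2.0, 3.0]))
    nbs_M: int = 500
    k_folds: int = 4
    seed: int = 0
    run_nbs: bool = True
    run_classifier: bool = True
    run_covariates: bool = True

    def to_dict(self) -> dict[str, Any]:
        return {
            "c_grid": list(map(float, self.c_grid)),
            "n_runs": self.n_runs,
            "gamma": self.gamma,
            "normalize": self.normalize,
            "consensus_runs": self.consensus_runs,
            "nbs_thresholds": list(map(float, self.nbs_thresholds)),
            "nbs_M": self.nbs_M,
            "k_folds": self.k_folds,
            "seed": self.seed,
            "run_nbs": self.run_nbs,
            "run_classifier": self.run_classifier,
            "run_covariates": self.run_covariates,
        }


@dataclass
class StudyReport:
    """All tables produced by one run; regenerable from config + seed."""

    config: dict[str, Any]
    q_curves: pd.DataFrame  # subject, group, c, run, Q
    consensus_by_c: dict[str, dict[float, Partition]]
    module_maps: dict[str, ModuleFrequencies]
    module_table: pd.DataFrame  # region, group, module, frequency, flagged
    group_comparison: groupstats.GroupComparisonResult
    ari_by_c: pd.DataFrame
    mean_ari: float
    nbs_table: pd.DataFrame | None = None
    classifier: groupstats.ClassifierResult | None = None
    covariate_table: pd.DataFrame | None = None

    def module_counts(self) -> dict[str, int]:
        """Final module count per group (distinct final labels)."""
        return {g: int(np.unique(m.final).size) for g, m in self.module_maps.items()}


def _derive_seed(*keys: int) -> int:
    return int(np.random.SeedSequence(list(keys)).generate_state(1)[0]) & 0x7FFFFFFF


def _subject_layers(subject, cohort: CohortDataset) -> list[np.ndarray]:
    if subject.adjacency is not None:
        return [subject.adjacency[b.name] for b in cohort.bands]
    if subject.timecourse is None:
        raise ValueError(f"{subject.subject_id}: no adjacency and no time course")
    layers = connectivity_pipeline(subject.timecourse, bands=cohort.bands)
    return [l.weights for l in layers]


def run_group_module_analysis(cohort: CohortDataset, config: RunConfig | None = None) -> StudyReport:
    """Run the full multilayer community analysis on a cohort."""
    cfg = config or RunConfig()
    ga, gb = cohort.group_labels
    subjects = cohort.subjects()
    subj_layers = {s.subject_id: _subject_layers(s, cohort) for s in subjects}
    if cfg.normalize:
        # per-subject λ₁ rescale of the connectivity layers; the coupling is
        # attached afterwards so c is comparable across subjects
        subj_layers = {sid: normalize_layers(ls)[0] for sid, ls in subj_layers.items()}
    subj_index = {s.subject_id: k for k, s in enumerate(subjects)}

    q_rows = []
    consensus_by_c: dict[str, dict[float, Partition]] = {ga: {}, gb: {}}
    for ci, c in enumerate(cfg.c_grid):
        t0 = time.perf_counter()
        group_partitions: dict[str, list[Partition]] = {ga: [], gb: []}
        for s in subjects:
            net = build_block(subj_layers[s.subject_id], c)
            run_seed = _derive_seed(cfg.seed, 1, subj_index[s.subject_id], ci)
            results = genlouvain(net, gamma=cfg.gamma, n_runs=cfg.n_runs, seed=run_seed)
            for run, res in enumerate(results):
                q_rows.append(
                    {"subject": s.subject_id, "group": s.group, "c": float(c), "run": run, "Q": res.Q}
                )
            group_partitions[s.group].extend(r.partition for r in results)
        for gi, g in enumerate((ga, gb)):
            per_layer = agreement_per_layer(group_partitions[g])
            collapsed = collapse_agreement(per_layer)
            cons_seed = _derive_seed(cfg.seed, 2, gi, ci)
            consensus_by_c[g][float(c)] = consensus_partition(
                collapsed, n_runs=cfg.consensus_runs, seed=cons_seed
            )
        log.info("c=%.3g done in %.1fs", c, time.perf_counter() - t0)

    q_curves = pd.DataFrame(q_rows)

    module_maps = {g: module_frequency_across_c(consensus_by_c[g]) for g in (ga, gb)}
    mod_rows = []
    for g, mf in module_maps.items():
        for i, region in enumerate(cohort.region_labels):
            mod_rows.append(
                {
                    "region": region,
                    "group": g,
                    "module": int(mf.final[i]),
                    "frequency": float(mf.frequencies[i].max()),
                    "flagged": bool(mf.flagged[i]),
                }
            )
    module_table = pd.DataFrame(mod_rows)

    # per-subject mean Q over runs, subjects × c
    mean_q = q_curves.groupby(["group", "subject", "c"])["Q"].mean().reset_index()
    QA = mean_q[mean_q["group"] == ga].pivot(index="subject", columns="c", values="Q")
    QB = mean_q[mean_q["group"] == gb].pivot(index="subject", columns="c", values="Q")
    cs = np.array(sorted(QA.columns))
    comparison = groupstats.compare_modularity_curves(
        QA[cs].to_numpy(), QB[cs].to_numpy(), c_values=cs
    )

    ari_rows = [
        {
            "c": float(c),
            "ari": groupstats.adjusted_rand(consensus_by_c[ga][float(c)], consensus_by_c[gb][float(c)]),
        }
        for c in cfg.c_grid
    ]
    ari_by_c = pd.DataFrame(ari_rows)
    mean_ari = float(ari_by_c["ari"].mean())

    nbs_table = None
    if cfg.run_nbs:
        nbs_table = nbs_sweep(
            cohort,
            thresholds=cfg.nbs_thresholds,
            M=cfg.nbs_M,
            seed=_derive_seed(cfg.seed, 3),
        )

    classifier = None
    if cfg.run_classifier:
        subj_mean = q_curves.groupby(["group", "subject"])["Q"].mean().reset_index()
        classifier = groupstats.modularity_classifier(
            subj_mean["Q"].to_numpy(),
            subj_mean["group"].to_numpy(),
            k_folds=cfg.k_folds,
            seed=_derive_seed(cfg.seed, 4),
        )

    covariate_table = None
    if cfg.run_covariates and len(cohort.covariates):
        covariate_table = _covariate_correlations(q_curves, cohort.covariates, ga)

    return StudyReport(
        config=cfg.to_dict(),
        q_curves=q_curves,
        consensus_by_c=consensus_by_c,
        module_maps=module_maps,
        module_table=module_table,
        group_comparison=comparison,
        ari_by_c=ari_by_c,
        mean_ari=mean_ari,
        nbs_table=nbs_table,
        classifier=classifier,
        covariate_table=covariate_table,
    )


def _covariate_correlations(
    q_curves: pd.DataFrame, covariates: pd.DataFrame, trained_group: str
) -> pd.DataFrame:
    """Spearman correlations of modularity with covariates.

    The ``pooled`` variant correlates every (subject, c, run) modularity value
    with the subject's covariate — observations are not independent
    (``pseudoreplicated`` is True) — and the ``subject_mean`` variant uses one
    mean Q per subject.
    """
    cov = covariates.set_index("subject_id")
    rows = []

    def _one(df: pd.DataFrame, covariate: str, subset: pd.Index, variant: str, control=None):
        d = df[df["subject"].isin(subset)]
        x = d["Q"].to_numpy()
        y = cov.loc[d["subject"], covariate].to_numpy(dtype=float)
        ok = np.isfinite(y)
        if ok.sum() < 4 or np.unique(y[ok]).size < 2:
            return
        ctrl = cov.loc[d["subject"], control].to_numpy(dtype=float)[ok] if control else None
        r, p = groupstats.spearman(x[ok], y[ok], controlling_for=ctrl)
        rows.append(
            {
                "covariate": covariate,
                "controlling_for": control or "",
                "variant": variant,
                "pseudoreplicated": variant == "pooled",
                "n_obs": int(ok.sum()),
                "r": r,
                "p": p,
            }
        )

    pooled = q_curves
    subj_mean = q_curves.groupby(["group", "subject"])["Q"].mean().reset_index()
    subj_mean = subj_mean.rename(columns={"subject": "subject"})
    all_subjects = pd.Index(cov.index)
    trained = pd.Index(cov.index[cov["group"] == trained_group])

    for df, variant in ((pooled, "pooled"), (subj_mean, "subject_mean")):
        _one(df, "age", all_subjects, variant)
        _one(df, "years_experience", trained, variant)
        _one(df, "age_started", trained, variant)
        _one(df, "years_experience", trained, variant, control="age")
    return pd.DataFrame(rows)


def seed_comparison(
    cohort: CohortDataset, seed_labels: tuple[str, ...] | None = None
) -> pd.DataFrame:
    """Group comparison of seed-to-seed envelope correlations.

    For every unordered pair of seed regions and every band, the per-subject
    AEC weight is extracted and the groups compared with a rank-sum test;
    Benjamini–Hochberg FDR is applied across all pair × band tests.
    Seed regions default to bilateral SMA and precentral gyrus when those
    labels exist in the cohort's region list.
    """
    labels = seed_labels or DEFAULT_SEED_LABELS
    missing = [l for l in labels if l not in cohort.region_labels]
    if missing:
        raise ValueError(f"seed label(s) not in region list: {', '.join(missing)}")
    idx = [cohort.region_labels.index(l) for l in labels]
    ga, gb = cohort.group_labels
    rows = []
    for b in cohort.bands:
        for a in range(len(idx)):
            for d in range(a + 1, len(idx)):
                xs = [s.adjacency[b.name][idx[a], idx[d]] for s in cohort.groups[ga]]
                ys = [s.adjacency[b.name][idx[a], idx[d]] for s in cohort.groups[gb]]
                z, p = groupstats.ranksum(xs, ys)
                rows.append(
                    {
                        "seed_a": labels[a],
                        "seed_b": labels[d],
                        "band": b.name,
                        "z": z,
                        "p_raw": p,
                    }
                )
    df = pd.DataFrame(rows)
    df["p_fdr"] = multipletests(df["p_raw"].to_numpy(), method="fdr_bh")[1]
    return df
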