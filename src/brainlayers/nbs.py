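"""Single-layer Network-Based Statistics (NBS).

A permutation test for group differences in weighted adjacency matrices whose
test statistic is the size of the largest connected component formed by
supra-threshold links: link-wise two-sample t statistics are thresholded, the
biggest component of the resulting graph is measured (in links by default,
the "extent" convention; node count available via ``extent="nodes"``), and a
null distribution is built by randomly relabeling subjects across groups.
P-values use the +1 permutation correction, p = (1 + #{null ≥ obs})/(M + 1),
so they are never exactly zero and differ from a plain /M convention by at
most 1/M.

Directionality: a one-sided analysis retains links with t > threshold
(``tail="greater"``, group A > group B) or −t > threshold (``tail="less"``);
the sweep reports both directions separately.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components
from statsmodels.stats.multitest import multipletests

from .envconn import LayerAdjacency

__all__ = ["NBSResult", "link_tstats", "largest_component", "nbs_test", "nbs_sweep"]


def _stack_links(group: list) -> tuple[np.ndarray, int]:
    """Subjects × unique-links matrix from a list of adjacencies."""
    mats = [
        (g.weights if isinstance(g, LayerAdjacency) else np.asarray(g, dtype=float))
        for g in group
    ]
    n = mats[0].shape[0]
    if any(m.shape != (n, n) for m in mats):
        raise ValueError("all adjacencies must share N")
    ii, jj = np.triu_indices(n, k=1)
    return np.vstack([m[ii, jj] for m in mats]), n


def _pooled_t(sumA, sumsqA, nA, sumB, sumsqB, nB):
    """Vectorized pooled-variance two-sample t (A minus B)."""
    meanA, meanB = sumA / nA, sumB / nB
    ssA = sumsqA - nA * meanA**2
    ssB = sumsqB - nB * meanB**2
    sp2 = (ssA + ssB) / (nA + nB - 2)
    denom = np.sqrt(sp2 * (1.0 / nA + 1.0 / nB))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (meanA - meanB) / denom
    return np.where(denom > 0, t, 0.0)


def link_tstats(groupA: list, groupB: list) -> np.ndarray:
    """Independent-samples pooled-variance t per unique link (A minus B).

    Returns a symmetric N×N matrix with zero diagonal. Links with zero pooled
    variance get t = 0 with a warning.
    """
    XA, n = _stack_links(groupA)
    XB, n2 = _stack_links(groupB)
    if n != n2:
        raise ValueError("groups have different node counts")
    if XA.shape[0] < 2 or XB.shape[0] < 2:
        raise ValueError("need at least 2 subjects per group")
    t = _pooled_t(
        XA.sum(0), (XA**2).sum(0), XA.shape[0], XB.sum(0), (XB**2).sum(0), XB.shape[0]
    )
    sp_zero = (XA.var(axis=0) == 0) & (XB.var(axis=0) == 0)
    if sp_zero.any():
        warnings.warn(
            f"{int(sp_zero.sum())} link(s) with zero pooled variance: t set to 0",
            stacklevel=2,
        )
    ii, jj = np.triu_indices(n, k=1)
    T = np.zeros((n, n))
    T[ii, jj] = t
    return T + T.T


def _largest_component_links(
    tvals: np.ndarray, threshold: float, n: int, ii: np.ndarray, jj: np.ndarray,
    extent: str = "links",
) -> tuple[np.ndarray, int]:
    sel = np.where(tvals > threshold)[0]
    if sel.size == 0:
        return np.array([], dtype=int), 0
    A = coo_matrix((np.ones(sel.size), (ii[sel], jj[sel])), shape=(n, n))
    ncomp, lab = connected_components(A + A.T, directed=False)
    edge_counts = np.bincount(lab[ii[sel]], minlength=ncomp)
    if extent == "links":
        best = int(np.argmax(edge_counts))
        size = int(edge_counts[best])
    elif extent == "nodes":
        node_counts = np.bincount(lab, minlength=ncomp)
        node_counts[edge_counts == 0] = 0  # isolated nodes are not components of interest
        best = int(np.argmax(node_counts))
        size = int(node_counts[best])
    else:
        raise ValueError("extent must be 'links' or 'nodes'")
    return np.where(lab == best)[0], size


def largest_component(
    t_matrix: np.ndarray, threshold: float, extent: str = "links"
) -> tuple[np.ndarray, int]:
    """Largest supra-threshold component of the graph with links t > threshold.

    Returns (node indices, size), size in links by default.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    T = np.asarray(t_matrix, dtype=float)
    n = T.shape[0]
    ii, jj = np.triu_indices(n, k=1)
    return _largest_component_links(T[ii, jj], threshold, n, ii, jj, extent)


@dataclass
class NBSResult:
    t_matrix: np.ndarray
    threshold: float
    component_nodes: np.ndarray
    component_size: int
    p_value: float
    M: int
    tail: str = "greater"
    extent: str = "links"
    null_distribution: np.ndarray | None = None


def _perm_null(
    X: np.ndarray, nA: int, M: int, rng: np.random.Generator, chunk: int = 512
) -> np.ndarray:
    """Permutation t statistics (M × n_links) under random group relabeling."""
    n_subj, L = X.shape
    Xsq = X**2
    out = np.empty((M, L))
    done = 0
    while done < M:
        m = min(chunk, M - done)
        P = np.zeros((m, n_subj))
        for r in range(m):
            P[r, rng.permutation(n_subj)[:nA]] = 1.0
        sumA = P @ X
        sumsqA = P @ Xsq
        sumB = X.sum(0) - sumA
        sumsqB = Xsq.sum(0) - sumsqA
        out[done : done + m] = _pooled_t(sumA, sumsqA, nA, sumB, sumsqB, n_subj - nA)
        done += m
    return out


def nbs_test(
    groupA: list,
    groupB: list,
    threshold: float,
    M: int = 5000,
    seed: int | None = None,
    tail: str = "greater",
    extent: str = "links",
    keep_null: bool = False,
) -> NBSResult:
    """NBS permutation test at one t threshold.

    Observed statistic: size of the largest component of links whose t (A−B,
    or B−A for ``tail="less"``) exceeds *threshold*; null from M random
    relabelings of subjects.
    """
    if M < 100:
        warnings.warn(f"M={M} permutations is very low for a permutation test", stacklevel=2)
    XA, n = _stack_links(groupA)
    XB, _ = _stack_links(groupB)
    X = np.vstack([XA, XB])
    nA = XA.shape[0]
    ii, jj = np.triu_indices(n, k=1)
    T = link_tstats(groupA, groupB)
    tvec = T[ii, jj]
    sgn = 1.0 if tail == "greater" else -1.0
    if tail not in ("greater", "less"):
        raise ValueError("tail must be 'greater' or 'less'")
    nodes, obs = _largest_component_links(sgn * tvec, threshold, n, ii, jj, extent)
    rng = np.random.default_rng(seed)
    tperm = _perm_null(X, nA, M, rng)
    null = np.empty(M, dtype=int)
    for m in range(M):
        _, null[m] = _largest_component_links(sgn * tperm[m], threshold, n, ii, jj, extent)
    p = (1.0 + np.sum(null >= obs)) / (M + 1.0)
    return NBSResult(
        t_matrix=T,
        threshold=float(threshold),
        component_nodes=nodes,
        component_size=int(obs),
        p_value=float(p),
        M=M,
        tail=tail,
        extent=extent,
        null_distribution=null if keep_null else None,
    )


def nbs_sweep(
    cohort,
    thresholds: np.ndarray | None = None,
    bands: list[str] | None = None,
    M: int = 5000,
    seed: int | None = None,
    extent: str = "links",
):
    """NBS over a (band × threshold × direction) grid with per-threshold FDR.

    *cohort* is a :class:`~brainlayers.synthgen.CohortDataset` with per-band
    adjacencies. Benjamini–Hochberg adjustment is applied across the bands at
    each (threshold, direction). Returns a tidy DataFrame with columns
    band, threshold, direction, component_size, p_raw, p_fdr.
    """
    import pandas as pd

    if thresholds is None:
        thresholds = np.round(np.arange(0.5, 5.0 + 1e-9, 0.1), 10)
    thresholds = np.atleast_1d(np.asarray(thresholds, dtype=float))
    band_names = bands if bands is not None else cohort.band_names()
    ga, gb = cohort.group_labels
    rows = []
    for bi, band in enumerate(band_names):
        A = [s.adjacency[band] for s in cohort.groups[ga]]
        B = [s.adjacency[band] for s in cohort.groups[gb]]
        XA, n = _stack_links(A)
        XB, _ = _stack_links(B)
        X = np.vstack([XA, XB])
        ii, jj = np.triu_indices(n, k=1)
        T = link_tstats(A, B)
        tvec = T[ii, jj]
        rng = np.random.default_rng(None if seed is None else seed + bi)
        tperm = _perm_null(X, XA.shape[0], M, rng)
        for thr in thresholds:
            for direction, sgn in (("greater", 1.0), ("less", -1.0)):
                _, obs = _largest_component_links(sgn * tvec, thr, n, ii, jj, extent)
                null = np.empty(M, dtype=int)
                for m in range(M):
                    _, null[m] = _largest_component_links(
                        sgn * tperm[m], thr, n, ii, jj, extent
                    )
                p = (1.0 + np.sum(null >= obs)) / (M + 1.0)
                rows.append(
                    {
                        "band": band,
                        "threshold": float(thr),
                        "direction": direction,
                        "component_size": int(obs),
                        "p_raw": float(p),
                    }
                )
    df = pd.DataFrame(rows)
    df["p_fdr"] = np.nan
    for (thr, direction), idx in df.groupby(["threshold", "direction"]).groups.items():
        pvals = df.loc[idx, "p_raw"].to_numpy()
        df.loc[idx, "p_fdr"] = multipletests(pvals, method="fdr_bh")[1]
    return df
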