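"""Independent brute-force oracles used only by the tests.

These deliberately avoid the package's own code paths: exact subset-DP
maximization of modularity over all set partitions, flood-fill connected
components, naive two-pass Pearson correlation, direct pair counting for the
rank-biserial, exhaustive label-permutation null for the rank-sum test, and
a hand contingency-table adjusted Rand index.
"""

from __future__ import annotations

from itertools import combinations
from math import comb

import numpy as np


def exhaustive_max_quality(B: np.ndarray) -> float:
    """Exact maximum of Σ_{p,q same community} B_pq over ALL set partitions.

    Subset dynamic program, O(3^n); equivalent to enumerating every partition
    of the n items. Includes the diagonal of B (constant across partitions).
    """
    n = B.shape[0]
    full = (1 << n) - 1
    # w[S] = sum of B over ordered pairs within S (incl. diagonal)
    w = np.zeros(1 << n)
    for S in range(1, full + 1):
        i = (S & -S).bit_length() - 1  # lowest set bit
        T = S & ~(1 << i)
        cross = 0.0
        R = T
        while R:
            j = (R & -R).bit_length() - 1
            cross += B[i, j] + B[j, i]
            R &= R - 1
        w[S] = w[T] + cross + B[i, i]
    best = np.full(1 << n, -np.inf)
    best[0] = 0.0
    for S in range(1, full + 1):
        i_bit = S & -S
        rest = S & ~i_bit
        # iterate over all subsets T of S that contain the lowest element
        sub = rest
        while True:
            T = sub | i_bit
            cand = w[T] + best[S & ~T]
            if cand > best[S]:
                best[S] = cand
            if sub == 0:
                break
            sub = (sub - 1) & rest
    return float(best[full])


def flood_fill_components(adj: np.ndarray) -> list[set[int]]:
    """Connected components of a boolean adjacency via explicit flood fill."""
    n = adj.shape[0]
    seen = [False] * n
    comps = []
    for s in range(n):
        if seen[s]:
            continue
        stack, comp = [s], set()
        seen[s] = True
        while stack:
            v = stack.pop()
            comp.add(v)
            for u in range(n):
                if adj[v, u] and not seen[u]:
                    seen[u] = True
                    stack.append(u)
        comps.append(comp)
    return comps


def largest_component_links_bruteforce(t_matrix: np.ndarray, thr: float) -> int:
    """Link count of the largest supra-threshold component, by flood fill."""
    A = t_matrix > thr
    np.fill_diagonal(A, False)
    best = 0
    for comp in flood_fill_components(A):
        links = sum(
            1 for a, b in combinations(sorted(comp), 2) if A[a, b]
        )
        best = max(best, links)
    return best


def naive_pearson(x: np.ndarray, y: np.ndarray) -> float:
    """Two-pass textbook Pearson correlation."""
    mx, my = x.mean(), y.mean()
    num = float(np.sum((x - mx) * (y - my)))
    den = float(np.sqrt(np.sum((x - mx) ** 2) * np.sum((y - my) ** 2)))
    return num / den


def pair_count_rank_biserial(x, y) -> float:
    """(favorable − unfavorable) / (n_x · n_y) by direct pair enumeration."""
    fav = sum(1 for a in x for b in y if a > b)
    unf = sum(1 for a in x for b in y if a < b)
    return (fav - unf) / (len(x) * len(y))


def exact_ranksum_pvalue(x, y) -> float:
    """Two-sided exact rank-sum p by enumerating all group labelings."""
    x, y = list(x), list(y)
    pooled = x + y
    n1 = len(x)
    obs = pair_count_rank_biserial(x, y)
    count = 0
    total = comb(len(pooled), n1)
    for idx in combinations(range(len(pooled)), n1):
        xs = [pooled[i] for i in idx]
        ys = [pooled[i] for i in range(len(pooled)) if i not in idx]
        if abs(pair_count_rank_biserial(xs, ys)) >= abs(obs) - 1e-12:
            count += 1
    return count / total


def hand_adjusted_rand(a, b) -> float:
    """Hubert–Arabie ARI from the contingency table, written out."""
    a, b = np.asarray(a), np.asarray(b)
    la, lb = np.unique(a), np.unique(b)
    n = a.size
    nij = np.array([[np.sum((a == i) & (b == j)) for j in lb] for i in la])
    ai = nij.sum(axis=1)
    bj = nij.sum(axis=0)
    sum_ij = sum(comb(int(v), 2) for v in nij.ravel())
    sum_a = sum(comb(int(v), 2) for v in ai)
    sum_b = sum(comb(int(v), 2) for v in bj)
    expected = sum_a * sum_b / comb(n, 2)
    max_index = 0.5 * (sum_a + sum_b)
    if max_index == expected:
        return 0.0
    return (sum_ij - expected) / (max_index - expected)
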