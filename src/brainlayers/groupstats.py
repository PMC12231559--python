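"""Group-level inference on modularity curves, partitions and covariates.

Wilcoxon rank-sum tests (normal approximation with tie and continuity
corrections; exact enumeration automatically when both samples have n ≤ 10),
rank-biserial and Cohen's-d effect sizes, the adjusted Rand index between
partitions, plain and partial Spearman correlations, a univariate threshold
classifier on a scalar modularity feature, and the per-coupling-value group
comparison of modularity curves.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sst
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.metrics import adjusted_rand_score
from sklearn.model_selection import StratifiedKFold
from sklearn.utils.validation import check_is_fitted

from .community import Partition

__all__ = [
    "ranksum",
    "rank_biserial",
    "cohens_d_from_r",
    "adjusted_rand",
    "spearman",
    "ThresholdClassifier",
    "modularity_classifier",
    "ClassifierResult",
    "GroupComparisonResult",
    "compare_modularity_curves",
]


def _tie_corrected_sigma(n1: int, n2: int, pooled: np.ndarray) -> float:
    n = n1 + n2
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = np.sum(counts**3 - counts) / (n * (n - 1)) if n > 1 else 0.0
    return float(np.sqrt(n1 * n2 / 12.0 * ((n + 1) - tie_term)))


def _u_statistic(x: np.ndarray, y: np.ndarray) -> float:
    """U of x: number of (x, y) pairs with x > y, ties counted 1/2."""
    diff = x[:, None] - y[None, :]
    return float(np.sum(diff > 0) + 0.5 * np.sum(diff == 0))


def ranksum(x, y) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum (Mann–Whitney) test.

    Returns (z, p). z uses the normal approximation with tie correction and
    a 0.5 continuity correction; p is the exact enumeration p-value when both
    samples have n ≤ 10 and the asymptotic one otherwise. Sign convention:
    z < 0 when x tends below y.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each sample needs at least 2 values")
    n1, n2 = x.size, y.size
    U = _u_statistic(x, y)
    mu = n1 * n2 / 2.0
    sigma = _tie_corrected_sigma(n1, n2, np.concatenate([x, y]))
    if sigma == 0.0:  # all values identical across both samples
        return 0.0, 1.0
    cc = 0.5 * np.sign(U - mu)
    z = (U - mu - cc) / sigma
    if n1 <= 10 and n2 <= 10:
        p = _exact_ranksum_p(x, y, U)
    else:
        p = float(2.0 * sst.norm.sf(abs(z)))
    return float(z), min(p, 1.0)


def _exact_ranksum_p(x: np.ndarray, y: np.ndarray, U_obs: float) -> float:
    """Exact two-sided p by enumerating every group labeling (tie-aware).

    U for a labeling is the midrank sum of the first group minus n1(n1+1)/2;
    the two-sided p counts labelings at least as far from the null mean.
    """
    from itertools import combinations

    pooled = np.concatenate([x, y])
    n1 = x.size
    ranks = sst.rankdata(pooled)
    combos = np.array(list(combinations(range(pooled.size), n1)))
    U_all = ranks[combos].sum(axis=1) - n1 * (n1 + 1) / 2.0
    mu = n1 * y.size / 2.0
    return float(np.mean(np.abs(U_all - mu) >= np.abs(U_obs - mu) - 1e-9))


def rank_biserial(x, y) -> float:
    """Rank-biserial effect size for the rank-sum test.

    r = 2U/(n₁n₂) − 1 with U the number of (x, y) pairs where x > y (ties
    half-weighted); equivalently (favorable − unfavorable)/(n₁n₂). Negative
    when x tends below y; −1 at complete separation x < y.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each sample needs at least 2 values")
    return float(2.0 * _u_statistic(x, y) / (x.size * y.size) - 1.0)


def cohens_d_from_r(r: float) -> float:
    """Convert a correlation-type effect size to Cohen's d: d = 2r/√(1−r²)."""
    if abs(r) >= 1.0:
        raise ValueError("|r| must be < 1 (d diverges at complete separation)")
    return float(2.0 * r / np.sqrt(1.0 - r * r))


def adjusted_rand(p1, p2) -> float:
    """Hubert–Arabie adjusted Rand index between two partitions.

    Accepts :class:`~brainlayers.community.Partition` objects or flat label
    arrays over the same node set.
    """
    a = p1.flat() if isinstance(p1, Partition) else np.asarray(p1).reshape(-1)
    b = p2.flat() if isinstance(p2, Partition) else np.asarray(p2).reshape(-1)
    if a.size != b.size:
        raise ValueError("partitions must cover the same node set")
    return float(adjusted_rand_score(a, b))


def spearman(x, y, controlling_for=None) -> tuple[float, float]:
    """Spearman rank correlation, optionally partial.

    Plain: tie-corrected Spearman rho with its t-approximation p-value.
    Partial: Pearson correlation of the rank residuals of x and y after
    regressing out the ranks of the control variable; p from the
    t approximation with df = n − 3.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    if n < 4 or y.size != n:
        raise ValueError("need paired samples with n >= 4")
    rx, ry = sst.rankdata(x), sst.rankdata(y)
    if rx.std() == 0 or ry.std() == 0:
        raise ValueError("zero rank variance: correlation undefined")
    if controlling_for is None:
        rho, p = sst.spearmanr(x, y)
        return float(rho), float(p)
    z = np.asarray(controlling_for, dtype=float)
    if z.size != n:
        raise ValueError("control variable must match sample size")
    rz = sst.rankdata(z)
    D = np.column_stack([np.ones(n), rz])
    res_x = rx - D @ np.linalg.lstsq(D, rx, rcond=None)[0]
    res_y = ry - D @ np.linalg.lstsq(D, ry, rcond=None)[0]
    denom = np.linalg.norm(res_x) * np.linalg.norm(res_y)
    if denom == 0:
        return 0.0, 1.0
    r = float(res_x @ res_y / denom)
    df = n - 3
    if abs(r) >= 1.0:
        return r, 0.0
    t = r * np.sqrt(df / (1.0 - r * r))
    return r, float(2.0 * sst.t.sf(abs(t), df))


class ThresholdClassifier(BaseEstimator, ClassifierMixin):
    """Univariate threshold rule on a single scalar feature.

    The decision threshold is placed at the midpoint between consecutive
    sorted training values that maximizes training accuracy; among equally
    accurate candidates the median midpoint is used. Both orientations
    (class above or below the threshold) are tried. The minimal model
    consistent with one scalar feature per subject.
    """

    def fit(self, X, y):
        X = np.asarray(X, dtype=float).reshape(-1)
        y = np.asarray(y)
        self.classes_ = np.unique(y)
        if self.classes_.size != 2:
            raise ValueError("ThresholdClassifier is binary")
        yb = (y == self.classes_[1]).astype(int)
        order = np.argsort(X)
        xs = X[order]
        cands = np.concatenate(
            [[xs[0] - 1.0], 0.5 * (xs[:-1] + xs[1:]), [xs[-1] + 1.0]]
        )
        best_acc, best_list = -1.0, []
        for thr in cands:
            for hi_is_1 in (True, False):
                pred = (X > thr).astype(int) if hi_is_1 else (X <= thr).astype(int)
                acc = float(np.mean(pred == yb))
                if acc > best_acc + 1e-12:
                    best_acc, best_list = acc, [(thr, hi_is_1)]
                elif abs(acc - best_acc) <= 1e-12:
                    best_list.append((thr, hi_is_1))
        thr, hi = best_list[len(best_list) // 2]
        self.threshold_ = float(thr)
        self.high_is_positive_ = bool(hi)
        self.train_accuracy_ = best_acc
        return self

    def predict(self, X):
        check_is_fitted(self, "threshold_")
        X = np.asarray(X, dtype=float).reshape(-1)
        mask = X > self.threshold_ if self.high_is_positive_ else X <= self.threshold_
        return np.where(mask, self.classes_[1], self.classes_[0])


@dataclass
class ClassifierResult:
    accuracy: float  # apparent (train = test on all subjects)
    cv_accuracy: float
    fold_accuracies: list[float]
    k_folds: int


def modularity_classifier(
    features, labels, k_folds: int = 4, seed: int | None = None
) -> ClassifierResult:
    """Classify group membership from one scalar per subject.

    Stratified k-fold cross-validation of :class:`ThresholdClassifier`;
    reports apparent accuracy (threshold fit and evaluated on all subjects)
    and the mean held-out accuracy.
    """
    X = np.asarray(features, dtype=float).reshape(-1)
    y = np.asarray(labels)
    classes, counts = np.unique(y, return_counts=True)
    if classes.size != 2:
        raise ValueError("need exactly two classes")
    if counts.min() < k_folds:
        raise ValueError(f"k_folds={k_folds} exceeds the smaller class size {counts.min()}")
    clf = ThresholdClassifier().fit(X, y)
    apparent = float(np.mean(clf.predict(X) == y))
    skf = StratifiedKFold(n_splits=k_folds, shuffle=True, random_state=seed)
    fold_accs = []
    for tr, te in skf.split(X.reshape(-1, 1), y):
        m = ThresholdClassifier().fit(X[tr], y[tr])
        fold_accs.append(float(np.mean(m.predict(X[te]) == y[te])))
    return ClassifierResult(
        accuracy=apparent,
        cv_accuracy=float(np.mean(fold_accs)),
        fold_accuracies=fold_accs,
        k_folds=k_folds,
    )


@dataclass
class GroupComparisonResult:
    """Per-c rank-sum comparison of two groups' modularity curves."""

    table: pd.DataFrame  # columns: c, z, p, r
    mean_r: float
    cohens_d: float


def compare_modularity_curves(
    groupA_Q: np.ndarray, groupB_Q: np.ndarray, c_values: np.ndarray | None = None
) -> GroupComparisonResult:
    """Rank-sum test and rank-biserial r at every interlayer coupling value.

    Inputs are subjects × c matrices of modularity; the summary is the mean
    rank-biserial r over c and its Cohen's-d equivalent. r < 0 means group A
    tends below group B.
    """
    QA = np.atleast_2d(np.asarray(groupA_Q, dtype=float))
    QB = np.atleast_2d(np.asarray(groupB_Q, dtype=float))
    if QA.shape[1] != QB.shape[1]:
        raise ValueError("groups must share the c grid")
    C = QA.shape[1]
    cs = np.arange(C, dtype=float) if c_values is None else np.asarray(c_values, dtype=float)
    if cs.size != C:
        raise ValueError("c_values length mismatch")
    rows = []
    for k in range(C):
        z, p = ranksum(QA[:, k], QB[:, k])
        r = rank_biserial(QA[:, k], QB[:, k])
        rows.append({"c": cs[k], "z": z, "p": p, "r": r})
    table = pd.DataFrame(rows)
    mean_r = float(table["r"].mean())
    d = cohens_d_from_r(mean_r) if abs(mean_r) < 1 else float(np.sign(mean_r) * np.inf)
    return GroupComparisonResult(table=table, mean_r=mean_r, cohens_d=d)
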