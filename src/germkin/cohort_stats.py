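"""Cohort-level statistics: proportion t-tests, quality classes, clustering.

Germinability (G, percentage of diaspores with embryo protrusion) and
viability (V, percentage staining positive in the tetrazolium assay) are
binomial proportions compared with the unpooled two-sample t statistic

    t = (p1 - p2) / sqrt(p1 q1 / n1 + p2 q2 / n2),

valid under the normal approximation, i.e. when n*p and n*q exceed 5 in
both samples; the two-sided critical value uses n1 + n2 - 2 degrees of
freedom.  Letter grouping follows the sorted-greedy convention standard in
agronomy tables: proportions sorted descending, one letter per maximal run
of pairwise non-significant samples.

Samples are grouped by hierarchical clustering of the biophysical triplet
(D/rho^2, v_m, a_m) using Ward's objective generalised to the Minkowski-p
metric: the linkage applies the Lance-Williams Ward update to squared
Minkowski-p inter-point distances (p = 2 recovers classic Ward exactly).
Columns are z-standardised first — the three features differ by orders of
magnitude — and the dendrogram is cut at 10 % of the maximum merge height.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist
from scipy.stats import t as t_dist
from sklearn.base import BaseEstimator, ClusterMixin

__all__ = [
    "ProportionTestResult",
    "ClusterResult",
    "proportion_t_test",
    "assign_letters",
    "classify_quality",
    "minkowski_ward_cluster",
    "WardMinkowskiClustering",
]


@dataclass(frozen=True)
class ProportionTestResult:
    X1: int
    n1: int
    X2: int
    n2: int
    p_hat1: float
    p_hat2: float
    q_hat1: float
    q_hat2: float
    t_stat: float
    df: int
    t_crit: float
    normality_ok: bool
    significant: bool | None
    alpha: float


def proportion_t_test(
    X1: int, n1: int, X2: int, n2: int, alpha: float = 0.05
) -> ProportionTestResult:
    """Two-sample unpooled t test for binomial proportions.

    ``significant`` is only decided when the normal-approximation guard
    (all of n*p_hat > 5 and n*q_hat > 5) holds; otherwise it is ``None``
    and a warning is emitted.  The statistic is antisymmetric under
    swapping the samples and zero for equal proportions.
    """
    for X, n, lbl in ((X1, n1, "1"), (X2, n2, "2")):
        if n < 1:
            raise ValueError(f"sample {lbl}: n must be >= 1")
        if not (0 <= X <= n):
            raise ValueError(f"sample {lbl}: count X={X} outside [0, n={n}]")
    p1, p2 = X1 / n1, X2 / n2
    q1, q2 = 1.0 - p1, 1.0 - p2
    var = p1 * q1 / n1 + p2 * q2 / n2
    if p1 == p2:
        t_stat = 0.0
    elif var == 0.0:
        t_stat = float(np.inf) if p1 > p2 else float(-np.inf)
    else:
        t_stat = (p1 - p2) / np.sqrt(var)
    normality_ok = all(
        x > 5 for x in (n1 * p1, n1 * q1, n2 * p2, n2 * q2)
    )
    df = n1 + n2 - 2
    t_crit = float(t_dist.ppf(1.0 - alpha / 2.0, df))
    if normality_ok:
        significant = bool(abs(t_stat) > t_crit)
    else:
        significant = None
        warnings.warn(
            "normal approximation not justified (some n*p_hat or n*q_hat <= 5); "
            "significance left undetermined",
            stacklevel=2,
        )
    return ProportionTestResult(
        X1=X1, n1=n1, X2=X2, n2=n2,
        p_hat1=p1, p_hat2=p2, q_hat1=q1, q_hat2=q2,
        t_stat=float(t_stat), df=df, t_crit=t_crit,
        normality_ok=normality_ok, significant=significant, alpha=alpha,
    )


def _pairwise_differs(percents: np.ndarray, n: np.ndarray, alpha: float) -> np.ndarray:
    """Boolean matrix: does |t| exceed the critical value for pair (i, j)?

    The letter display reports the t comparison for every pair, as printed
    agronomy tables do, regardless of the normality guard (which is
    available separately through :func:`proportion_t_test`).
    """
    k = percents.size
    differs = np.zeros((k, k), dtype=bool)
    for i in range(k):
        for j in range(i + 1, k):
            Xi = int(round(percents[i] * n[i] / 100.0))
            Xj = int(round(percents[j] * n[j] / 100.0))
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = proportion_t_test(Xi, int(n[i]), Xj, int(n[j]), alpha)
            differs[i, j] = differs[j, i] = abs(res.t_stat) > res.t_crit
    return differs


def assign_letters(percents, n, alpha: float = 0.05) -> list[str]:
    """Compact letter display for a column of proportions (percent).

    Samples sharing a letter do not differ by the proportion t test at
    ``alpha``.  Sorted descending; ties keep input order; a sample may
    carry several letters when groups overlap.  Returns labels in the
    original input order.
    """
    percents = np.asarray(percents, dtype=float)
    if percents.size < 2:
        raise ValueError("letter grouping needs at least 2 samples")
    n = np.broadcast_to(np.asarray(n, dtype=int), percents.shape)
    order = np.argsort(-percents, kind="stable")
    sp = percents[order]
    sn = n[order]
    differs = _pairwise_differs(sp, sn, alpha)

    # maximal runs of pairwise non-significant samples in sorted order
    k = sp.size
    runs: list[tuple[int, int]] = []
    for i in range(k):
        j = i
        while j + 1 < k and not differs[i:j + 2, i:j + 2].any():
            j += 1
        runs.append((i, j))
    maximal = [
        (a, b)
        for a, b in runs
        if not any((c <= a and b <= d) and (c, d) != (a, b) for c, d in runs)
    ]
    maximal = sorted(set(maximal))
    letters = "abcdefghijklmnopqrstuvwxyz"
    sorted_labels = ["" for _ in range(k)]
    for li, (a, b) in enumerate(maximal):
        for s in range(a, b + 1):
            sorted_labels[s] += letters[li]
    labels = ["" for _ in range(k)]
    for pos, orig in enumerate(order):
        labels[orig] = sorted_labels[pos]
    return labels


def classify_quality(V: float, G: float) -> str:
    """Physiological quality class from viability and germinability (%).

    high when both exceed 90 %, low when V <= 60 % and G <= 50 %,
    intermediate otherwise.  Monotone: raising V or G never lowers the
    class.
    """
    for name, x in (("V", V), ("G", G)):
        if not (0.0 <= x <= 100.0):
            raise ValueError(f"{name} must lie in [0, 100], got {x}")
    if V > 90.0 and G > 90.0:
        return "high"
    if V <= 60.0 and G <= 50.0:
        return "low"
    return "intermediate"


@dataclass(frozen=True, eq=False)
class ClusterResult:
    feature_matrix: np.ndarray
    p: float
    linkage: np.ndarray  # scipy linkage matrix, merge heights non-decreasing
    cut_fraction: float
    cut_height: float
    labels: np.ndarray
    standardized: bool


def _canonical_labels(raw: np.ndarray) -> np.ndarray:
    """Relabel clusters 1, 2, ... in order of first appearance."""
    out = np.empty_like(raw)
    seen: dict[int, int] = {}
    for i, r in enumerate(raw):
        if r not in seen:
            seen[r] = len(seen) + 1
        out[i] = seen[r]
    return out


def minkowski_ward_cluster(
    features,
    p: float = 2.0,
    cut_fraction: float = 0.10,
    standardize: bool = True,
) -> ClusterResult:
    """Ward-objective hierarchical clustering under the Minkowski-p metric.

    The agglomeration applies the Lance-Williams Ward update to squared
    Minkowski-p distances (for p = 2 this is exactly classic Ward on
    Euclidean distances); clusters are the subtrees below
    ``cut_fraction x (maximum merge height)``.
    """
    X = np.asarray(features, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("features must be a 2-D matrix with at least 2 samples")
    if p < 1:
        raise ValueError("Minkowski order p must be >= 1")
    Z_input = X
    if standardize:
        mu = X.mean(axis=0)
        sd = X.std(axis=0, ddof=0)
        sd = np.where(sd == 0, 1.0, sd)
        Z_input = (X - mu) / sd
    d = pdist(Z_input, metric="minkowski", p=p)
    Z = linkage(d, method="ward")
    hmax = float(Z[:, 2].max())
    if hmax == 0.0:
        labels = np.ones(X.shape[0], dtype=int)
        cut_height = 0.0
    else:
        cut_height = cut_fraction * hmax
        labels = fcluster(Z, t=cut_height, criterion="distance")
    return ClusterResult(
        feature_matrix=X,
        p=float(p),
        linkage=Z,
        cut_fraction=float(cut_fraction),
        cut_height=float(cut_height),
        labels=_canonical_labels(np.asarray(labels, dtype=int)),
        standardized=bool(standardize),
    )


class WardMinkowskiClustering(ClusterMixin, BaseEstimator):
    """Scikit-learn estimator facade over :func:`minkowski_ward_cluster`.

    Attributes after ``fit``: ``labels_``, ``linkage_``, ``cut_height_``,
    ``n_clusters_``.
    """

    def __init__(self, p: float = 2.0, cut_fraction: float = 0.10,
                 standardize: bool = True):
        self.p = p
        self.cut_fraction = cut_fraction
        self.standardize = standardize

    def fit(self, X, y=None):
        res = minkowski_ward_cluster(
            X, p=self.p, cut_fraction=self.cut_fraction,
            standardize=self.standardize,
        )
        self.result_ = res
        self.labels_ = res.labels
        self.linkage_ = res.linkage
        self.cut_height_ = res.cut_height
        self.n_clusters_ = int(res.labels.max())
        return self
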