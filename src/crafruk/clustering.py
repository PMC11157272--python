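"""Model-free 1-D clustering of mass estimates and stoichiometry calls.

The AFM mass distributions are one-dimensional, and the optimal
within-cluster-sum-of-squares partition of 1-D data into k classes is
always contiguous in sorted order.  That makes an exact dynamic program
possible (O(k n^2) with prefix sums), so no iterative k-means heuristic
is needed: the partition returned here is the global WCSS optimum, and
it is deterministic.

The top class can be pinned to a fixed number of largest observations
(``fixed_top_class_size``), reproducing the constrained three-class fit
used for the DNA-bound population (upper class of exactly 7 particles);
the remaining observations are then partitioned optimally into k-1
classes.

Class means are matched to a reference mass ladder to call the complex
stoichiometry; two ladder entries closer than 10% of each other relative
to the class mean produce a deliberately ambiguous dual label, because
the Cra and FruK homodimers differ by only ~12% in mass and cannot be
told apart from AFM volumes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.utils.validation import check_is_fitted

from .volumetry import ReferenceLadder

__all__ = [
    "ClusterResult",
    "StoichiometryCall",
    "ContiguousKMeans1D",
    "cluster_1d",
    "choose_k",
    "assign_stoichiometry",
]


@dataclass(frozen=True)
class ClusterResult:
    """Outcome of an exact 1-D WCSS-optimal partition."""

    k: int
    assignments: np.ndarray          # class index per observation (input order)
    means: np.ndarray                # strictly increasing class means
    sds: np.ndarray                  # per-class SD (ddof=0)
    sizes: np.ndarray
    wcss: float
    fixed_top_class_size: int | None = None


@dataclass(frozen=True)
class StoichiometryCall:
    """Mapping of cluster classes to reference-ladder entries."""

    labels: list[str]                # primary label per class
    alternatives: list[list[str]]    # all labels within the ambiguity band
    residuals_da: np.ndarray         # |class mean - primary ladder mass|
    ambiguous: np.ndarray            # bool per class


def _prefix(v: np.ndarray):
    s = np.concatenate([[0.0], np.cumsum(v)])
    s2 = np.concatenate([[0.0], np.cumsum(v * v)])
    return s, s2


def _seg_cost(s, s2, i, j):
    """WCSS of sorted[i:j] in O(1) via prefix sums."""
    n = j - i
    tot = s[j] - s[i]
    return (s2[j] - s2[i]) - tot * tot / n


def _dp_partition(v_sorted: np.ndarray, k: int):
    """Exact minimal-WCSS contiguous partition of sorted values into k runs.

    Returns (boundaries, wcss) where boundaries are the k+1 split indices.
    """
    n = v_sorted.size
    s, s2 = _prefix(v_sorted)
    # cost[j][i] implicit; D[m, j] = min WCSS of first j points in m classes
    D = np.full((k + 1, n + 1), np.inf)
    back = np.zeros((k + 1, n + 1), dtype=int)
    D[0, 0] = 0.0
    for m in range(1, k + 1):
        for j in range(m, n + 1):
            best, arg = np.inf, m - 1
            for i in range(m - 1, j):
                cand = D[m - 1, i] + _seg_cost(s, s2, i, j)
                if cand < best:
                    best, arg = cand, i
            D[m, j] = best
            back[m, j] = arg
    bounds = [n]
    j = n
    for m in range(k, 0, -1):
        j = back[m, j]
        bounds.append(j)
    return np.array(bounds[::-1]), float(D[k, n])


class ContiguousKMeans1D(ClusterMixin, BaseEstimator):
    """Exact optimal 1-D k-means via dynamic programming.

    Unlike Lloyd-style k-means this is deterministic and globally optimal:
    classes are contiguous intervals of the sorted data minimizing the
    within-cluster sum of squares.

    Parameters
    ----------
    n_clusters:
        Number of classes k.
    fixed_top_class_size:
        If given, the top class is constrained to exactly this many
        largest observations and the DP runs on the remainder with k-1
        classes.

    Attributes
    ----------
    labels_ : class index per observation, 0 = lowest-mean class.
    cluster_centers_ : (k, 1) strictly increasing class means.
    cluster_sds_ : per-class standard deviation.
    cluster_sizes_ : observations per class.
    inertia_ : within-cluster sum of squares of the partition.
    """

    def __init__(self, n_clusters: int = 2, fixed_top_class_size: int | None = None):
        self.n_clusters = n_clusters
        self.fixed_top_class_size = fixed_top_class_size

    def fit(self, X, y=None):
        v = np.asarray(X, dtype=float).ravel()
        n = v.size
        k = self.n_clusters
        if k < 1:
            raise ValueError("n_clusters must be >= 1")
        if k > n:
            raise ValueError(f"n_clusters={k} exceeds n_obs={n}")
        top = self.fixed_top_class_size
        if top is not None:
            if not 1 <= top < n:
                raise ValueError("fixed_top_class_size must be in [1, n_obs)")
            if k < 2:
                raise ValueError("fixed top class requires n_clusters >= 2")
            if k - 1 > n - top:
                raise ValueError("not enough observations below the fixed top class")

        order = np.argsort(v, kind="stable")
        v_sorted = v[order]
        if top is None:
            bounds, wcss = _dp_partition(v_sorted, k)
        else:
            cut = n - top
            bounds_lo, wcss_lo = _dp_partition(v_sorted[:cut], k - 1)
            s, s2 = _prefix(v_sorted)
            wcss = wcss_lo + _seg_cost(s, s2, cut, n)
            bounds = np.concatenate([bounds_lo, [n]])

        labels_sorted = np.empty(n, dtype=int)
        means, sds, sizes = [], [], []
        for j in range(k):
            i0, i1 = bounds[j], bounds[j + 1]
            labels_sorted[i0:i1] = j
            seg = v_sorted[i0:i1]
            means.append(seg.mean())
            sds.append(seg.std())
            sizes.append(i1 - i0)
        labels = np.empty(n, dtype=int)
        labels[order] = labels_sorted

        self.labels_ = labels
        self.cluster_centers_ = np.asarray(means)[:, None]
        self.cluster_sds_ = np.asarray(sds)
        self.cluster_sizes_ = np.asarray(sizes, dtype=int)
        self.inertia_ = float(wcss)
        self.n_features_in_ = 1
        return self

    def predict(self, X):
        """Assign new values to the nearest fitted class mean."""
        check_is_fitted(self, "cluster_centers_")
        v = np.asarray(X, dtype=float).ravel()
        return np.argmin(np.abs(v[:, None] - self.cluster_centers_.ravel()[None, :]), axis=1)


def cluster_1d(
    values,
    k: int,
    fixed_top_class_size: int | None = None,
) -> ClusterResult:
    """Exact optimal contiguous partition of 1-D values into k classes."""
    est = ContiguousKMeans1D(n_clusters=k, fixed_top_class_size=fixed_top_class_size).fit(values)
    return ClusterResult(
        k=k,
        assignments=est.labels_,
        means=est.cluster_centers_.ravel(),
        sds=est.cluster_sds_,
        sizes=est.cluster_sizes_,
        wcss=est.inertia_,
        fixed_top_class_size=fixed_top_class_size,
    )


def choose_k(values, k_range) -> tuple[int, "np.ndarray"]:
    """Pick a class count by BIC under an equal-variance Gaussian model.

    For each k in ``k_range`` the exact WCSS partition is computed; the
    hard-assignment classification likelihood with shared variance
    ``WCSS/n`` and free mixing proportions gives
    ``BIC = -2 logL + 2k ln(n)`` (k means, k-1 proportions, 1 variance).
    Returns ``(best_k, diagnostics)`` where diagnostics is a structured
    array of (k, wcss, bic).  Deterministic for a fixed input.
    """
    v = np.asarray(values, dtype=float).ravel()
    n = v.size
    ks = sorted(set(int(k) for k in k_range))
    if not ks:
        raise ValueError("empty k_range")
    if ks[0] < 1 or ks[-1] > n:
        raise ValueError("k_range must lie within [1, n_obs]")
    rows = []
    for k in ks:
        res = cluster_1d(v, k)
        sigma2 = max(res.wcss / n, 1e-300)
        logl = -0.5 * n * (np.log(2 * np.pi * sigma2) + 1.0)
        logl += float(np.sum(res.sizes * np.log(res.sizes / n)))
        bic = -2.0 * logl + 2.0 * k * np.log(n)
        rows.append((k, res.wcss, bic))
    diag = np.array(rows, dtype=[("k", int), ("wcss", float), ("bic", float)])
    best_k = int(diag["k"][np.argmin(diag["bic"])])
    return best_k, diag


def assign_stoichiometry(
    result: ClusterResult,
    ladder: ReferenceLadder,
    ambiguity_rel: float = 0.10,
) -> StoichiometryCall:
    """Map each class mean to the nearest reference-ladder mass.

    Ties break toward the smaller complex.  When more than one ladder
    entry lies within ``ambiguity_rel`` of the class mean (relative to
    that mean), the call carries all such labels (``ambiguous`` set),
    mirroring the fact that the two homodimers cannot be distinguished
    by AFM volume.
    """
    if not ladder.entries:
        raise ValueError("ladder is empty")
    names = sorted(ladder.entries, key=lambda k: (ladder.entries[k], k))
    masses = np.array([ladder.entries[nm] for nm in names])
    labels, alts, residuals, ambiguous = [], [], [], []
    for mean in result.means:
        dist = np.abs(masses - mean)
        best = int(np.argmin(dist))  # argmin takes first, i.e. smaller complex, on ties
        near = [nm for nm, d in zip(names, dist) if d <= ambiguity_rel * mean]
        if names[best] not in near:
            near = [names[best]]
        labels.append(names[best])
        alts.append(near)
        residuals.append(dist[best])
        ambiguous.append(len(near) > 1)
    return StoichiometryCall(
        labels=labels,
        alternatives=alts,
        residuals_da=np.asarray(residuals),
        ambiguous=np.asarray(ambiguous, dtype=bool),
    )
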