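"""Equal-size peer cohorts by balanced (constrained) K-means.

Farms are clustered on z-scored KPI so that cohort sizes differ by at
most one (exactly n/k farms per cohort when k divides n).  Each
iteration solves the point-to-cluster assignment exactly as a
minimum-cost transportation problem on squared Euclidean distance, with
cluster sizes bounded between floor(n/k) and ceil(n/k); centroids are
then recomputed.  The within-cluster sum of squares is non-increasing
across iterations because both alternating steps are exact
minimizations, and convergence is followed by a pairwise-exchange
polish of the labeling.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.optimize import linear_sum_assignment, linprog
from sklearn.cluster import kmeans_plusplus

__all__ = [
    "DEFAULT_FEATURES",
    "Scaler",
    "CohortAssignment",
    "standardize_features",
    "balanced_kmeans",
    "cluster_farms",
    "cohort_summary",
    "manual_cohort",
]

#: Default clustering feature set: the farm-snapshot KPI columns.
DEFAULT_FEATURES = [
    "n_cows",
    "mean_lactation",
    "mean_age_days",
    "milk_lb",
    "fat_pct",
    "protein_pct",
    "scc_kcells",
    "dmi_lb",
    "fe",
    "milk_price_cwt",
    "feed_cost_day",
    "iofc_day",
]


@dataclass(frozen=True)
class Scaler:
    """Recoverable z-scoring (population sd) of a feature matrix."""

    mean: np.ndarray
    scale: np.ndarray  # population sd, 1.0 where the feature is constant
    feature_names: tuple[str, ...]

    def transform(self, X: np.ndarray) -> np.ndarray:
        return (X - self.mean) / self.scale

    def inverse(self, Z: np.ndarray) -> np.ndarray:
        return Z * self.scale + self.mean


@dataclass
class CohortAssignment:
    """A farm -> cohort map with the equal-size guarantee.

    Cohort indices run 1..k and are ordered by ascending mean milk yield,
    so cohort 1 is the lowest-producing peer group.  ``centroids`` holds
    per-cohort means of the (unscaled) clustering features.
    """

    k: int
    assignment: dict[str, int]
    centroids: np.ndarray
    feature_names: tuple[str, ...]
    seed: int
    wcss: float = field(default=float("nan"))

    def cohort_of(self, farm_id: str) -> int:
        return self.assignment[farm_id]

    def members(self, cohort: int) -> list[str]:
        return [f for f, c in self.assignment.items() if c == cohort]

    def sizes(self) -> dict[int, int]:
        out: dict[int, int] = {c: 0 for c in range(1, self.k + 1)}
        for c in self.assignment.values():
            out[c] += 1
        return out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"farm_id": list(self.assignment), "cohort": list(self.assignment.values())}
        )


def standardize_features(
    snapshots: pd.DataFrame, feature_names: list[str] | None = None
) -> tuple[np.ndarray, Scaler]:
    """Z-score snapshot features (population sd); constant features -> zeros.

    Returns the score matrix and a :class:`Scaler` whose ``inverse``
    recovers the original values exactly.
    """
    names = list(feature_names or DEFAULT_FEATURES)
    if len(snapshots) < 2:
        raise ValueError("need at least 2 farms to standardize")
    for name in names:
        if name not in snapshots.columns:
            raise ValueError(f"unknown feature: {name!r}")
        if not np.issubdtype(snapshots[name].dtype, np.number):
            raise ValueError(f"non-numeric feature: {name!r}")
    X = snapshots[names].to_numpy(dtype=float)
    mean = X.mean(axis=0)
    sd = X.std(axis=0)  # population sd (ddof=0)
    constant = sd == 0
    if constant.any():
        warnings.warn(
            f"constant feature(s) {[n for n, c in zip(names, constant) if c]}: "
            "z-scores set to 0",
            stacklevel=2,
        )
    scale = np.where(constant, 1.0, sd)
    scaler = Scaler(mean=mean, scale=scale, feature_names=tuple(names))
    return scaler.transform(X), scaler


def _balanced_assign(X: np.ndarray, centroids: np.ndarray, k: int) -> np.ndarray:
    """Exact min-cost assignment of points to size-bounded clusters.

    Solves the transportation problem: every point to exactly one
    cluster, each cluster size between floor(n/k) and ceil(n/k), total
    squared-distance cost minimal.  The constraint matrix is totally
    unimodular, so the LP relaxation has an integral optimal vertex;
    which clusters take the extra point (when k does not divide n) is
    part of the optimization.  When k divides n this is the equal-size
    assignment exactly.
    """
    n = len(X)
    floor, extra = divmod(n, k)
    d2 = ((X[:, None, :] - centroids[None, :, :]) ** 2).sum(axis=2)
    if extra == 0:
        # fixed equal capacities: plain assignment on duplicated columns
        slot_cluster = np.repeat(np.arange(k), floor)
        rows, cols = linear_sum_assignment(d2[:, slot_cluster])
        labels = np.empty(n, dtype=int)
        labels[rows] = slot_cluster[cols]
        return labels

    # one-point row sums (equality) + cluster-size bounds [floor, floor+1]
    row_idx = np.repeat(np.arange(n), k)
    col_idx = np.arange(n * k)
    a_eq = sparse.csr_matrix((np.ones(n * k), (row_idx, col_idx)), shape=(n, n * k))
    cluster_of_var = np.tile(np.arange(k), n)
    a_size = sparse.csr_matrix(
        (np.ones(n * k), (cluster_of_var, col_idx)), shape=(k, n * k)
    )
    a_ub = sparse.vstack([a_size, -a_size])
    b_ub = np.concatenate([np.full(k, floor + 1), np.full(k, -floor)])
    res = linprog(
        d2.ravel(), A_eq=a_eq, b_eq=np.ones(n), A_ub=a_ub, b_ub=b_ub,
        bounds=(0, 1), method="highs",
    )
    if not res.success:  # pragma: no cover
        raise RuntimeError(f"balanced assignment LP failed: {res.message}")
    x = res.x.reshape(n, k)
    labels = x.argmax(axis=1)
    # integral vertex: every row is a clean indicator
    if not np.allclose(x[np.arange(n), labels], 1.0, atol=1e-6):  # pragma: no cover
        raise RuntimeError("balanced assignment LP returned a fractional solution")
    return labels


def _refine_exchanges(X: np.ndarray, labels: np.ndarray, k: int) -> np.ndarray:
    """Best-improvement exchange polish of a balanced labeling.

    Repeatedly applies the single pairwise swap (or, when sizes are
    unequal, single-point move between a large and a small cluster) that
    most reduces the true within-cluster sum of squares, until no
    exchange improves it.  Swaps preserve sizes exactly; moves only go
    from a ceil-size to a floor-size cluster, so the size bounds hold
    throughout.  Deltas use the identity WCSS_j = sum ||x||^2 -
    ||s_j||^2 / n_j per cluster.
    """
    labels = labels.copy()
    n = len(X)
    floor = n // k
    sq = (X**2).sum(axis=1)
    sums = np.stack([X[labels == j].sum(axis=0) for j in range(k)])
    counts = np.bincount(labels, minlength=k)
    tol = 1e-10 * max(1.0, float(sq.sum()))
    for _ in range(20 * n):  # each pass applies one exchange
        best_delta, best_op = -tol, None
        members = [np.where(labels == j)[0] for j in range(k)]
        for a in range(k):
            ia = members[a]
            xa, sa, ca = X[ia], sums[a], counts[a]
            for b in range(a + 1, k):
                ib = members[b]
                xb, sb, cb = X[ib], sums[b], counts[b]
                # swap i in a <-> j in b
                diff_a = sa[None, :] - xa
                ma = (diff_a**2).sum(1)[:, None] + 2 * (diff_a @ xb.T) + sq[ib][None, :]
                delta_a = (sq[ib][None, :] - sq[ia][:, None]) - (ma - sa @ sa) / ca
                diff_b = sb[None, :] - xb
                mb = (diff_b**2).sum(1)[:, None] + 2 * (diff_b @ xa.T) + sq[ia][None, :]
                delta_b = (sq[ia][None, :] - sq[ib][:, None]) - (mb - sb @ sb) / cb
                d = delta_a + delta_b.T
                i, j = np.unravel_index(int(d.argmin()), d.shape)
                if d[i, j] < best_delta:
                    best_delta = float(d[i, j])
                    best_op = ("swap", int(ia[i]), int(ib[j]), a, b)
                # move one point from the larger to the smaller cluster
                for (u, iu, xu, su, cu), (v, sv, cv) in (
                    ((a, ia, xa, sa, ca), (b, sb, cb)),
                    ((b, ib, xb, sb, cb), (a, sa, ca)),
                ):
                    if not (cu == floor + 1 and cv == floor):
                        continue
                    shrink = ((su[None, :] - xu) ** 2).sum(1) / (cu - 1) - (su @ su) / cu
                    grow = ((sv[None, :] + xu) ** 2).sum(1) / (cv + 1) - (sv @ sv) / cv
                    d1 = -(shrink + grow)
                    m = int(d1.argmin())
                    if d1[m] < best_delta:
                        best_delta = float(d1[m])
                        best_op = ("move", int(iu[m]), u, v)
        if best_op is None:
            break
        if best_op[0] == "swap":
            _, i, j, a, b = best_op
            labels[i], labels[j] = b, a
            sums[a] += X[j] - X[i]
            sums[b] += X[i] - X[j]
        else:
            _, m, u, v = best_op
            labels[m] = v
            sums[u] -= X[m]
            sums[v] += X[m]
            counts[u] -= 1
            counts[v] += 1
    return labels


def balanced_kmeans(
    X: np.ndarray, k: int, seed: int, max_iter: int = 100
) -> tuple[np.ndarray, np.ndarray, float, int]:
    """Balanced K-means: equal-size clusters via exact min-cost assignment.

    Initialization is k-means++ from ``seed``; each iteration assigns
    points to cluster slots (capacities floor(n/k) or ceil(n/k)) by an
    exact minimum-cost assignment on squared Euclidean distance, then
    recomputes centroids; stops when the assignment no longer changes or
    after ``max_iter`` iterations.  The size invariant holds at every
    iteration and the objective is non-increasing.

    Returns
    -------
    (labels, centroids, wcss, n_iter) with 0-based labels.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    n = len(X)
    if k == 0:
        raise ValueError("k must be >= 1")
    if k > n:
        raise ValueError(f"k={k} exceeds number of points n={n}")
    centroids, _ = kmeans_plusplus(X, n_clusters=k, random_state=seed)
    labels = np.full(n, -1, dtype=int)
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        new_labels = _balanced_assign(X, centroids, k)
        if np.array_equal(new_labels, labels):
            break
        labels = new_labels
        centroids = np.stack([X[labels == j].mean(axis=0) for j in range(k)])
    labels = _refine_exchanges(X, labels, k)
    centroids = np.stack([X[labels == j].mean(axis=0) for j in range(k)])
    wcss = float(((X - centroids[labels]) ** 2).sum())
    return labels, centroids, wcss, n_iter


def cluster_farms(
    snapshots: pd.DataFrame,
    k: int,
    seed: int,
    feature_names: list[str] | None = None,
    max_iter: int = 100,
) -> CohortAssignment:
    """Form equal-size peer cohorts from farm snapshots.

    Features are z-scored before clustering; after convergence cohorts
    are relabeled 1..k by ascending mean milk yield (removing label-
    permutation nondeterminism and matching benchmark-table ordering).
    """
    names = list(feature_names or DEFAULT_FEATURES)
    Z, _ = standardize_features(snapshots, names)
    labels, _, wcss, _ = balanced_kmeans(Z, k, seed, max_iter)
    milk = snapshots["milk_lb"].to_numpy(dtype=float)
    order = np.argsort([milk[labels == j].mean() for j in range(k)], kind="stable")
    relabel = np.empty(k, dtype=int)
    relabel[order] = np.arange(1, k + 1)
    cohorts = relabel[labels]
    X = snapshots[names].to_numpy(dtype=float)
    centroids = np.stack([X[cohorts == c].mean(axis=0) for c in range(1, k + 1)])
    assignment = dict(zip(snapshots["farm_id"].astype(str), (int(c) for c in cohorts)))
    return CohortAssignment(
        k=k,
        assignment=assignment,
        centroids=centroids,
        feature_names=tuple(names),
        seed=seed,
        wcss=wcss,
    )


def cohort_summary(snapshots: pd.DataFrame, assignment: CohortAssignment) -> pd.DataFrame:
    """Per-cohort mean KPI table, ordered by ascending mean milk yield."""
    df = snapshots.copy()
    df["cohort"] = df["farm_id"].astype(str).map(assignment.assignment)
    if df["cohort"].isna().any():
        raise ValueError("assignment does not cover every snapshot")
    numeric = [
        c for c in df.columns
        if c not in ("farm_id", "month", "cohort") and np.issubdtype(df[c].dtype, np.number)
    ]
    grouped = df.groupby("cohort")
    out = grouped[numeric].mean()
    out.insert(0, "n_farms", grouped.size())
    out = out.sort_values("milk_lb").reset_index()
    return out


def manual_cohort(
    snapshots: pd.DataFrame,
    cow_range: tuple[float | None, float | None] = (None, None),
    milk_range: tuple[float | None, float | None] = (None, None),
) -> pd.DataFrame:
    """User-defined cohort: farms inside herd-size and milk windows.

    Both ranges are inclusive at the ends; a bound of None is unbounded.
    """
    for lo, hi in (cow_range, milk_range):
        if lo is not None and hi is not None and lo > hi:
            raise ValueError(f"invalid range: [{lo}, {hi}]")
    mask = pd.Series(True, index=snapshots.index)
    lo, hi = cow_range
    if lo is not None:
        mask &= snapshots["n_cows"] >= lo
    if hi is not None:
        mask &= snapshots["n_cows"] <= hi
    lo, hi = milk_range
    if lo is not None:
        mask &= snapshots["milk_lb"] >= lo
    if hi is not None:
        mask &= snapshots["milk_lb"] <= hi
    return snapshots[mask].reset_index(drop=True)
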