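"""Trajectory clustering and age-position (conjunction point) detection.

Smoothed per-probe trajectories are standardized to mean zero and clustered
with Lloyd-style K-means under two metrics:

* ``euclidean`` — groups trajectories by shape *and* direction, exposing the
  major age-associated trends;
* ``abscorr``   — distance ``1 - |pearson(a, b)|``, which treats a trend and
  its mirror image as identical. This unites the rising and falling arms of
  a symmetric expression change, and the age where the two arms meet (the
  conjunction point) is read out as the *age-position*: the age at which the
  major expression changes occur.

The implementation is deterministic given its seed: farthest-point seeding,
a fixed number of restarts scored by total within-cluster distance, and
index-based tie-breaking throughout.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import List, Optional, Sequence

import numpy as np

from .datamodel import ValidationError

__all__ = [
    "standardize_trajectories",
    "abs_correlation_distance",
    "kmeans_trends",
    "TrendCluster",
    "clusters_from_labels",
    "merge_redundant_clusters",
    "label_inclinations",
    "AgePosition",
    "find_conjunctions",
    "detect_age_position",
]


def standardize_trajectories(trajectories: np.ndarray) -> np.ndarray:
    """Center each trajectory (row) to mean zero over the age grid."""
    t = np.asarray(trajectories, dtype=float)
    return t - t.mean(axis=1, keepdims=True)


def _rowwise_correlation(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Pearson correlation between every row of A and every row of B."""
    Ac = A - A.mean(axis=1, keepdims=True)
    Bc = B - B.mean(axis=1, keepdims=True)
    An = np.linalg.norm(Ac, axis=1)
    Bn = np.linalg.norm(Bc, axis=1)
    denom = np.outer(An, Bn)
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = (Ac @ Bc.T) / denom
    return np.clip(np.nan_to_num(corr, nan=0.0), -1.0, 1.0)


def abs_correlation_distance(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """``1 - |pearson|`` distance matrix between rows of A and rows of B."""
    return 1.0 - np.abs(_rowwise_correlation(np.atleast_2d(A), np.atleast_2d(B)))


def _distances(traj: np.ndarray, centroids: np.ndarray, metric: str) -> np.ndarray:
    if metric == "euclidean":
        d2 = (
            (traj**2).sum(axis=1)[:, None]
            - 2.0 * traj @ centroids.T
            + (centroids**2).sum(axis=1)[None, :]
        )
        return np.sqrt(np.maximum(d2, 0.0))
    return abs_correlation_distance(traj, centroids)


def _update_centroids(traj, labels, centroids, k, metric):
    new = centroids.copy()
    for c in range(k):
        members = np.flatnonzero(labels == c)
        if members.size == 0:
            continue
        sub = traj[members]
        if metric == "abscorr":
            # flip members negatively correlated with the current centroid
            corr = _rowwise_correlation(sub, centroids[c][None, :])[:, 0]
            signs = np.where(corr < 0, -1.0, 1.0)
            new[c] = (sub * signs[:, None]).mean(axis=0)
        else:
            new[c] = sub.mean(axis=0)
    return new


def _farthest_point_seeds(traj, k, metric, rng):
    n = traj.shape[0]
    first = int(rng.integers(n))
    chosen = [first]
    mind = _distances(traj, traj[first][None, :], metric)[:, 0]
    for _ in range(1, k):
        # ties resolved to the lowest index by argmax
        nxt = int(np.argmax(mind))
        chosen.append(nxt)
        d = _distances(traj, traj[nxt][None, :], metric)[:, 0]
        mind = np.minimum(mind, d)
    return traj[chosen].copy()


def kmeans_trends(
    trajectories: np.ndarray,
    k: int,
    metric: str = "euclidean",
    seed: int = 0,
    n_restarts: int = 5,
    max_iter: int = 100,
):
    """Deterministic Lloyd K-means over trajectories.

    Returns ``(labels, centroids, inertia)`` where inertia is the summed
    within-cluster distance of the best restart. Under ``abscorr`` each
    centroid is the mean of its members after flipping the sign of members
    negatively correlated with the current centroid.
    """
    traj = np.atleast_2d(np.asarray(trajectories, dtype=float))
    n = traj.shape[0]
    if k < 1:
        raise ValidationError("k must be >= 1")
    if k > n:
        raise ValidationError(f"k={k} exceeds the {n} available trajectories")
    if metric not in ("euclidean", "abscorr"):
        raise ValidationError("metric must be 'euclidean' or 'abscorr'")
    if metric == "abscorr":
        flat = np.flatnonzero(traj.std(axis=1) == 0)
        if flat.size:
            raise ValidationError(
                f"constant trajectory at row {flat[0]} has no correlation distance"
            )

    best = None
    for r in range(n_restarts):
        rng = np.random.default_rng((seed * 1000003 + r) % (2**31))
        centroids = _farthest_point_seeds(traj, k, metric, rng)
        labels = np.zeros(n, dtype=int)
        for _ in range(max_iter):
            d = _distances(traj, centroids, metric)
            new_labels = np.argmin(d, axis=1)  # ties -> lowest cluster index
            centroids = _update_centroids(traj, new_labels, centroids, k, metric)
            if np.array_equal(new_labels, labels):
                labels = new_labels
                break
            labels = new_labels
        inertia = float(
            _distances(traj, centroids, metric)[np.arange(n), labels].sum()
        )
        if best is None or inertia < best[2] - 1e-12:
            best = (labels, centroids, inertia)
    return best


@dataclass
class TrendCluster:
    """A group of standardized trajectories with a common trend."""

    cluster_id: int
    member_indices: np.ndarray
    centroid: np.ndarray
    inclination: Optional[str] = None

    @property
    def size(self) -> int:
        return int(len(self.member_indices))


def clusters_from_labels(labels, trajectories, metric: str = "euclidean") -> List[TrendCluster]:
    """Materialize TrendCluster objects from a K-means labeling."""
    traj = np.atleast_2d(np.asarray(trajectories, dtype=float))
    out: List[TrendCluster] = []
    for c in sorted(set(int(l) for l in labels)):
        members = np.flatnonzero(np.asarray(labels) == c)
        sub = traj[members]
        if metric == "abscorr" and sub.shape[0] > 1:
            ref = sub[0]
            corr = _rowwise_correlation(sub, ref[None, :])[:, 0]
            signs = np.where(corr < 0, -1.0, 1.0)
            centroid = (sub * signs[:, None]).mean(axis=0)
        else:
            centroid = sub.mean(axis=0)
        out.append(TrendCluster(cluster_id=c, member_indices=members, centroid=centroid))
    return out


def merge_redundant_clusters(
    clusters: Sequence[TrendCluster],
    trajectories: np.ndarray,
    corr_threshold: float = 0.9,
) -> List[TrendCluster]:
    """Merge clusters whose centroids correlate >= threshold; drop singletons.

    Merging is iterative and greedy on the highest *signed* centroid
    correlation, so mirrored (opposite-inclination) trends are never merged.
    Merged centroids are recomputed from the pooled member trajectories.
    """
    traj = np.atleast_2d(np.asarray(trajectories, dtype=float))
    work = [
        TrendCluster(c.cluster_id, np.array(c.member_indices, dtype=int), c.centroid.copy())
        for c in clusters
    ]
    while len(work) > 1:
        cent = np.vstack([c.centroid for c in work])
        corr = _rowwise_correlation(cent, cent)
        np.fill_diagonal(corr, -np.inf)
        i, j = np.unravel_index(np.argmax(corr), corr.shape)
        if corr[i, j] < corr_threshold:
            break
        a, b = sorted((int(i), int(j)))
        merged_members = np.sort(
            np.concatenate([work[a].member_indices, work[b].member_indices])
        )
        merged = TrendCluster(
            cluster_id=work[a].cluster_id,
            member_indices=merged_members,
            centroid=traj[merged_members].mean(axis=0),
        )
        work = [c for idx, c in enumerate(work) if idx not in (a, b)]
        work.append(merged)
        work.sort(key=lambda c: c.cluster_id)
    survivors = [c for c in work if c.size >= 2]
    for new_id, c in enumerate(survivors):
        c.cluster_id = new_id
    return survivors


def label_inclinations(clusters: Sequence[TrendCluster]) -> List[TrendCluster]:
    """Label each cluster by the sign of its centroid's endpoint change."""
    for c in clusters:
        d = c.centroid[-1] - c.centroid[0]
        c.inclination = "positive" if d > 0 else "negative" if d < 0 else "ambiguous"
    return list(clusters)


# ---------------------------------------------------------------------------
# Age-position detection
# ---------------------------------------------------------------------------

@dataclass
class AgePosition:
    """The age at which the opposite-inclination trajectories conjoin."""

    age: float
    cluster_id: int
    method: str  # "trajectory-crossing" or "quadratic-vertex"
    secondary: List[float] = field(default_factory=list)
    n_positive: int = 0
    n_negative: int = 0

    @property
    def decade(self) -> int:
        # decade d spans ages [10(d-1), 10d): the "seventh decade" is 60-69
        return int(math.floor(self.age / 10.0)) + 1


def find_conjunctions(diff: np.ndarray, grid: np.ndarray):
    """Locate the ages where a difference curve changes sign on a grid.

    Returns a list of ``(age, slope)`` pairs. Strict sign changes between
    adjacent grid points are refined by linear interpolation. Exact zeros
    are treated with conjunction semantics: a zero run flanked by opposite
    signs crosses at the run's midpoint, while a zero run that borders a
    nonzero stretch on one side only (two curves coinciding, then
    diverging) conjoins at the run boundary adjacent to the divergence.
    """
    diff = np.asarray(diff, dtype=float)
    grid = np.asarray(grid, dtype=float)
    out = []
    sign = np.sign(diff)
    n = len(diff)
    # strict crossings
    for i in range(n - 1):
        if sign[i] * sign[i + 1] < 0:
            frac = diff[i] / (diff[i] - diff[i + 1])
            age = grid[i] + frac * (grid[i + 1] - grid[i])
            slope = (diff[i + 1] - diff[i]) / (grid[i + 1] - grid[i])
            out.append((float(age), float(slope)))
    # zero runs
    i = 0
    while i < n:
        if sign[i] == 0:
            j = i
            while j + 1 < n and sign[j + 1] == 0:
                j += 1
            left = sign[i - 1] if i > 0 else 0
            right = sign[j + 1] if j + 1 < n else 0
            if left != 0 and right != 0 and left != right:
                age = 0.5 * (grid[i] + grid[j])
                slope = (diff[j + 1] - diff[i - 1]) / (grid[j + 1] - grid[i - 1])
                out.append((float(age), float(slope)))
            elif right != 0 and left == 0:
                slope = (diff[j + 1] - diff[j]) / (grid[j + 1] - grid[j])
                out.append((float(grid[j]), float(slope)))
            elif left != 0 and right == 0:
                slope = (diff[i] - diff[i - 1]) / (grid[i] - grid[i - 1])
                out.append((float(grid[i]), float(slope)))
            i = j + 1
        else:
            i += 1
    out.sort(key=lambda t: t[0])
    return out


def detect_age_position(
    trajectories: np.ndarray,
    age_grid: np.ndarray,
    k: int = 10,
    seed: int = 0,
    n_restarts: int = 5,
    method: str = "trajectory-crossing",
) -> Optional[AgePosition]:
    """Detect the age-position from trajectories of significant probes.

    Procedure: cluster under absolute correlation; take the largest cluster;
    split its members by the sign of their correlation with the centroid;
    form the mean trajectory of each sign group; the age-position is where
    the two mean trajectories cross (conjoin). When multiple crossings
    exist, the one with the steepest difference slope is primary and the
    rest are reported as secondary. Returns None when either sign group is
    empty or the mean trajectories never cross.

    ``method='quadratic-vertex'`` instead returns the vertex ``-beta/(2
    gamma)`` of a quadratic fitted to the sign-aligned mean trajectory,
    provided it falls inside the age range.
    """
    traj = np.atleast_2d(np.asarray(trajectories, dtype=float))
    grid = np.asarray(age_grid, dtype=float)
    if traj.shape[0] < 2:
        return None
    k_eff = min(k, traj.shape[0])
    labels, _, _ = kmeans_trends(
        traj, k_eff, metric="abscorr", seed=seed, n_restarts=n_restarts
    )
    clusters = clusters_from_labels(labels, traj, metric="abscorr")
    clusters.sort(key=lambda c: (-c.size, c.cluster_id))
    main = clusters[0]
    members = traj[main.member_indices]
    corr = _rowwise_correlation(members, main.centroid[None, :])[:, 0]
    pos = members[corr >= 0]
    neg = members[corr < 0]
    if len(pos) == 0 or len(neg) == 0:
        return None

    if method == "quadratic-vertex":
        aligned = np.vstack([pos, -neg]).mean(axis=0)
        coef = np.polyfit(grid, aligned, 2)  # [gamma, beta, alpha]
        if coef[0] == 0:
            return None
        vertex = -coef[1] / (2.0 * coef[0])
        if not (grid[0] <= vertex <= grid[-1]):
            return None
        return AgePosition(
            age=float(vertex),
            cluster_id=main.cluster_id,
            method=method,
            n_positive=len(pos),
            n_negative=len(neg),
        )

    diff = pos.mean(axis=0) - neg.mean(axis=0)
    crossings = find_conjunctions(diff, grid)
    if not crossings:
        return None
    # primary: steepest |slope| at the crossing; ties -> youngest age
    primary = max(crossings, key=lambda t: (abs(t[1]), -t[0]))
    secondary = [age for age, _ in crossings if age != primary[0]]
    return AgePosition(
        age=primary[0],
        cluster_id=main.cluster_id,
        method="trajectory-crossing",
        secondary=secondary,
        n_positive=len(pos),
        n_negative=len(neg),
    )
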