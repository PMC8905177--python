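"""Functional-type clustering of chirp responses.

Units are compared by the mean SPIKE dissimilarity over all cross-unit
pairs of chirp trials; the resulting distance matrix is clustered by
average-linkage agglomeration, and the number of clusters is selected with
the gap statistic.  Because the gap statistic needs a geometric null, the
distance matrix is embedded by classical multidimensional scaling (MDS,
positive eigenvalues only, capped at 10 dimensions) and reference datasets
are drawn uniformly over the embedding's bounding box.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist, squareform

from .errors import ConfigurationError
from .spikedist import spike_distance

__all__ = [
    "DistanceMatrix",
    "GapCurve",
    "ClusterResult",
    "unit_distance_matrix",
    "hierarchical_cluster",
    "gap_statistic",
    "cluster_report",
]


@dataclass
class DistanceMatrix:
    unit_ids: list[int]
    D: np.ndarray

    def __post_init__(self) -> None:
        D = np.asarray(self.D, dtype=float)
        if D.ndim != 2 or D.shape[0] != D.shape[1] or D.shape[0] != len(self.unit_ids):
            raise ConfigurationError("distance matrix shape mismatch")
        if not np.allclose(D, D.T, atol=1e-12) or np.any(np.diag(D) != 0):
            raise ConfigurationError("distance matrix must be symmetric with zero diagonal")
        if np.any(D < 0):
            raise ConfigurationError("distances must be nonnegative")
        self.D = D

    def __len__(self) -> int:
        return len(self.unit_ids)


@dataclass
class GapCurve:
    k_values: np.ndarray
    gap: np.ndarray
    s: np.ndarray
    log_w: np.ndarray
    chosen_k: int
    converged: bool  # False when no k satisfied the gap criterion (k_max used)


@dataclass
class ClusterResult:
    unit_ids: list[int]
    labels: np.ndarray
    linkage: np.ndarray
    gap_curve: GapCurve | None = None
    cluster_psth: dict[int, np.ndarray] = field(default_factory=dict)
    psth_time: np.ndarray | None = None
    feature_summary: pd.DataFrame | None = None

    @property
    def n_clusters(self) -> int:
        return len(np.unique(self.labels))


def unit_distance_matrix(trials_by_unit: dict[int, list[np.ndarray]],
                         interval: tuple[float, float]) -> DistanceMatrix:
    """Mean cross-trial SPIKE distance between every pair of units.

    ``D[a, b]`` averages ``spike_distance`` over all n x n cross-unit trial
    pairs; the diagonal is zero by convention (within-unit trial
    variability is *not* subtracted).
    """
    unit_ids = list(trials_by_unit)
    n_trials = {uid: len(trials) for uid, trials in trials_by_unit.items()}
    counts = set(n_trials.values())
    if len(counts) > 1:
        offender = min(uid for uid, c in n_trials.items() if c != max(counts))
        raise ConfigurationError(
            f"unit {offender} has {n_trials[offender]} trials; all units need the same count")
    n = len(unit_ids)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            ta, tb = trials_by_unit[unit_ids[i]], trials_by_unit[unit_ids[j]]
            vals = [spike_distance(x, y, interval) for x in ta for y in tb]
            D[i, j] = D[j, i] = float(np.mean(vals)) if vals else 0.0
    return DistanceMatrix(unit_ids, D)


def hierarchical_cluster(dm: DistanceMatrix, k: int,
                         method: str = "average") -> tuple[np.ndarray, np.ndarray]:
    """Average-linkage agglomeration on the precomputed distances.

    Returns 0-based labels from cutting the dendrogram at ``k`` clusters and
    the scipy linkage matrix.
    """
    n = len(dm)
    if not 1 <= k <= n:
        raise ConfigurationError(f"k={k} outside 1..{n}")
    if n == 1:
        return np.zeros(1, dtype=int), np.empty((0, 4))
    Z = hierarchy.linkage(squareform(dm.D, checks=False), method=method)
    labels = hierarchy.fcluster(Z, t=k, criterion="maxclust") - 1
    return labels, Z


def _within_dispersion(D: np.ndarray, labels: np.ndarray) -> float:
    """W = sum over clusters of (sum of pairwise distances) / (2 * size)."""
    w = 0.0
    for lab in np.unique(labels):
        members = np.flatnonzero(labels == lab)
        if len(members) > 1:
            sub = D[np.ix_(members, members)]
            w += sub.sum() / (2.0 * len(members))
    return w


def _mds_embed(D: np.ndarray, max_dim: int = 10) -> np.ndarray:
    n = len(D)
    J = np.eye(n) - np.full((n, n), 1.0 / n)
    B = -0.5 * J @ (D**2) @ J
    vals, vecs = np.linalg.eigh(B)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    pos = vals > max(1e-9 * max(vals.max(), 1e-30), 0.0)
    if not np.any(pos):
        raise ConfigurationError("degenerate MDS embedding: all points coincident")
    d = min(int(np.count_nonzero(pos)), max_dim)
    return vecs[:, :d] * np.sqrt(vals[:d])


def gap_statistic(dm: DistanceMatrix, k_max: int, B: int = 50,
                  seed: int = 0, method: str = "average") -> GapCurve:
    """Gap-statistic selection of the cluster number.

    ``gap(k) = mean_b log W*_k(b) - log W_k`` with W from average-linkage
    labels, reference datasets drawn uniformly over the bounding box of the
    MDS embedding of the distance matrix (Euclidean distances, same
    clustering routine); ``s(k) = sd_b(log W*) * sqrt(1 + 1/B)``.  The
    chosen k is the smallest k with ``gap(k) >= gap(k+1) - s(k+1)``.
    """
    n = len(dm)
    if n < 3:
        raise ConfigurationError("gap statistic needs at least 3 units")
    if not 1 <= k_max < n:
        raise ConfigurationError(f"k_max={k_max} must be in 1..{n - 1}")
    ks = np.arange(1, k_max + 1)

    def _log_w_curve(D: np.ndarray) -> np.ndarray:
        Z = hierarchy.linkage(squareform(D, checks=False), method=method)
        out = np.empty(len(ks))
        for i, k in enumerate(ks):
            labels = hierarchy.fcluster(Z, t=int(k), criterion="maxclust") - 1
            w = _within_dispersion(D, labels)
            out[i] = np.log(w) if w > 0 else -np.inf
        return out

    log_w = _log_w_curve(dm.D)
    X = _mds_embed(dm.D)
    lo, hi = X.min(axis=0), X.max(axis=0)
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0x6A9]))
    log_w_ref = np.empty((B, len(ks)))
    for b in range(B):
        Xb = rng.uniform(lo, hi, size=X.shape)
        log_w_ref[b] = _log_w_curve(squareform(pdist(Xb)))

    gap = log_w_ref.mean(axis=0) - log_w
    s = log_w_ref.std(axis=0, ddof=0) * np.sqrt(1.0 + 1.0 / B)
    chosen, converged = int(k_max), False
    for i in range(len(ks) - 1):
        if gap[i] >= gap[i + 1] - s[i + 1]:
            chosen, converged = int(ks[i]), True
            break
    return GapCurve(ks, gap, s, log_w, chosen, converged)


def cluster_report(unit_ids: list[int], labels: np.ndarray,
                   features: pd.DataFrame | None = None,
                   psths: dict[int, np.ndarray] | None = None,
                   psth_time: np.ndarray | None = None,
                   linkage: np.ndarray | None = None,
                   gap_curve: GapCurve | None = None) -> ClusterResult:
    """Per-cluster mean chirp PSTH and feature means/SDs.

    ``features`` is indexed by unit_id; summarized columns are those the
    validation scatter plots use (bias index, response duration, baseline,
    burst/rate change, OSI) plus anything else numeric present.
    """
    labels = np.asarray(labels)
    result = ClusterResult(unit_ids=list(unit_ids), labels=labels,
                           linkage=np.empty((0, 4)) if linkage is None else linkage,
                           gap_curve=gap_curve, psth_time=psth_time)
    for lab in np.unique(labels):
        members = [uid for uid, l in zip(unit_ids, labels) if l == lab]
        if psths is not None and members:
            result.cluster_psth[int(lab)] = np.mean([psths[uid] for uid in members], axis=0)
    if features is not None:
        num = features.select_dtypes(include=[np.number])
        rows = []
        for lab in np.unique(labels):
            members = [uid for uid, l in zip(unit_ids, labels) if l == lab]
            sub = num.loc[members]
            row = {"cluster": int(lab), "n_units": len(members)}
            for col in sub.columns:
                row[f"{col}_mean"] = float(sub[col].mean())
                row[f"{col}_sd"] = float(sub[col].std(ddof=0)) if len(sub) else np.nan
            rows.append(row)
        result.feature_summary = pd.DataFrame(rows)
    return result
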