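import numpy as np
import pytest
from scipy.spatial.distance import pdist, squareform

from oracles import spike_distance_oracle
from rgcpipe.clustering import (DistanceMatrix, cluster_report, gap_statistic,
                                hierarchical_cluster, unit_distance_matrix)
from rgcpipe.errors import ConfigurationError
from rgcpipe.spikedist import spike_distance


def _trials(rng, n_trials=3, rate=20.0, t1=2.0):
    return [np.sort(rng.uniform(0, t1, rng.poisson(rate * t1))) for _ in range(n_trials)]


# ----------------------------------------------------------------------
# unit distance matrix

def test_matrix_equals_brute_force_triple_loop():
    rng = np.random.default_rng(0)
    trials = {uid: _trials(rng) for uid in (0, 1, 2)}
    dm = unit_distance_matrix(trials, (0.0, 2.0))
    for i, a in enumerate(dm.unit_ids):
        for j, b in enumerate(dm.unit_ids):
            if i == j:
                assert dm.D[i, j] == 0.0
            else:
                ref = np.mean([spike_distance_oracle(x, y, (0.0, 2.0))
                               for x in trials[a] for y in trials[b]])
                assert dm.D[i, j] == pytest.approx(ref, abs=1e-6)


def test_identical_trial_sets_hit_self_similarity_floor():
    """Two units with the same trials: D equals the mean cross-trial distance
    within the trial set (not zero)."""
    rng = np.random.default_rng(1)
    t = _trials(rng, n_trials=4)
    dm = unit_distance_matrix({0: t, 1: [x.copy() for x in t]}, (0.0, 2.0))
    floor = np.mean([spike_distance(a, b, (0.0, 2.0)) for a in t for b in t])
    assert dm.D[0, 1] == pytest.approx(floor)
    assert dm.D[0, 1] > 0.0


def test_empty_trials_vs_copy_is_zero():
    empty = [np.empty(0), np.empty(0)]
    dm = unit_distance_matrix({0: empty, 1: [np.empty(0), np.empty(0)]}, (0.0, 1.0))
    assert dm.D[0, 1] == 0.0


def test_mismatched_trial_counts_rejected():
    rng = np.random.default_rng(2)
    with pytest.raises(ConfigurationError, match="unit 1"):
        unit_distance_matrix({0: _trials(rng, 3), 1: _trials(rng, 2)}, (0.0, 2.0))


# ----------------------------------------------------------------------
# hierarchical clustering

def _block_matrix(sizes, within=0.1, between=0.9, seed=0):
    rng = np.random.default_rng(seed)
    n = sum(sizes)
    labels = np.repeat(np.arange(len(sizes)), sizes)
    D = np.where(labels[:, None] == labels[None, :], within, between).astype(float)
    D += rng.uniform(0, 0.01, (n, n))
    D = (D + D.T) / 2
    np.fill_diagonal(D, 0.0)
    return DistanceMatrix(list(range(n)), D), labels


def test_two_block_matrix_recovered():
    dm, truth = _block_matrix([8, 7])
    labels, Z = hierarchical_cluster(dm, 2)
    assert len(np.unique(labels)) == 2
    for lab in np.unique(truth):
        assert len(np.unique(labels[truth == lab])) == 1
    assert np.all(np.diff(Z[:, 2]) >= -1e-12)  # non-decreasing merge heights


def test_k_extremes():
    dm, _ = _block_matrix([4, 4])
    labels, _ = hierarchical_cluster(dm, 1)
    assert len(np.unique(labels)) == 1
    labels, _ = hierarchical_cluster(dm, 8)
    assert len(np.unique(labels)) == 8
    with pytest.raises(ConfigurationError):
        hierarchical_cluster(dm, 9)


def test_invalid_distance_matrix_rejected():
    with pytest.raises(ConfigurationError):
        DistanceMatrix([0, 1], np.array([[0.0, 1.0], [2.0, 0.0]]))  # asymmetric
    with pytest.raises(ConfigurationError):
        DistanceMatrix([0, 1], np.array([[0.5, 1.0], [1.0, 0.0]]))  # nonzero diag


# ----------------------------------------------------------------------
# gap statistic

def test_single_gaussian_cluster_selects_k1():
    hits = 0
    for seed in range(20):
        rng = np.random.default_rng(seed)
        X = rng.normal(0.0, 1.0, (40, 2))
        dm = DistanceMatrix(list(range(40)), squareform(pdist(X)))
        gap = gap_statistic(dm, 6, B=50, seed=seed)
        hits += gap.chosen_k == 1
    assert hits >= 18


def test_three_separated_blobs_select_k3():
    centers = np.array([[0.0, 0.0], [10.0, 0.0], [0.0, 10.0]])
    hits = 0
    for seed in range(20):
        rng = np.random.default_rng(seed)
        X = np.vstack([c + 0.3 * rng.normal(size=(20, 2)) for c in centers])
        dm = DistanceMatrix(list(range(60)), squareform(pdist(X)))
        gap = gap_statistic(dm, 8, B=50, seed=seed)
        hits += gap.chosen_k == 3
    assert hits >= 18


def test_gap_curve_finite_with_positive_error_terms():
    rng = np.random.default_rng(3)
    X = rng.uniform(0, 1, (30, 3))
    dm = DistanceMatrix(list(range(30)), squareform(pdist(X)))
    gap = gap_statistic(dm, 6, B=30, seed=1)
    assert np.all(np.isfinite(gap.gap))
    assert np.all(gap.s > 0)
    assert 1 <= gap.chosen_k <= 6


def test_clustering_invariant_to_unit_ordering():
    rng = np.random.default_rng(4)
    trials = {uid: _trials(rng) for uid in range(9)}
    dm = unit_distance_matrix(trials, (0.0, 2.0))
    base_labels, _ = hierarchical_cluster(dm, 3)
    base = {uid: lab for uid, lab in zip(dm.unit_ids, base_labels)}
    for shuffle_seed in range(10):
        order = np.random.default_rng(shuffle_seed).permutation(9)
        shuffled = {int(uid): trials[int(uid)] for uid in order}
        dm2 = unit_distance_matrix(shuffled, (0.0, 2.0))
        labels2, _ = hierarchical_cluster(dm2, 3)
        got = {uid: lab for uid, lab in zip(dm2.unit_ids, labels2)}
        # same partition up to label renaming
        for a in range(9):
            for b in range(9):
                assert (base[a] == base[b]) == (got[a] == got[b])


# ----------------------------------------------------------------------
# reports

def test_cluster_report_means_match_brute_force():
    import pandas as pd

    rng = np.random.default_rng(5)
    uids = list(range(6))
    labels = np.array([0, 0, 1, 1, 1, 2])
    feats = pd.DataFrame({"bias_index": rng.normal(size=6),
                          "baseline_hz": rng.uniform(0, 10, 6)}, index=uids)
    psths = {u: rng.uniform(0, 1, 50) for u in uids}
    rep = cluster_report(uids, labels, features=feats, psths=psths)
    for lab in (0, 1, 2):
        members = [u for u, l in zip(uids, labels) if l == lab]
        np.testing.assert_allclose(rep.cluster_psth[lab],
                                   np.mean([psths[u] for u in members], axis=0))
        row = rep.feature_summary[rep.feature_summary.cluster == lab].iloc[0]
        assert row["bias_index_mean"] == pytest.approx(feats.loc[members, "bias_index"].mean())
        assert row["n_units"] == len(members)
    # singleton cluster has zero SD
    single = rep.feature_summary[rep.feature_summary.cluster == 2].iloc[0]
    assert single["bias_index_sd"] == 0.0


def test_merged_cluster_psth_is_weighted_average():
    rng = np.random.default_rng(6)
    uids = [0, 1, 2]
    psths = {u: rng.uniform(0, 1, 20) for u in uids}
    split = cluster_report(uids, np.array([0, 1, 1]), psths=psths)
    merged = cluster_report(uids, np.array([0, 0, 0]), psths=psths)
    weighted = (1 * split.cluster_psth[0] + 2 * split.cluster_psth[1]) / 3
    np.testing.assert_allclose(merged.cluster_psth[0], weighted)
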