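import numpy as np
import pandas as pd
import pytest

from rgcpipe.activity import activity_table
from rgcpipe.blobs import BlobSet
from rgcpipe.errors import ConfigurationError
from rgcpipe.matching import (classify_matches, density_map, distance_change_profile,
                              match_counts, pairwise_unit_blob_distances)
from rgcpipe.synthetic import SceneConfig, make_scene, simulate_spikes


def _changes(values):
    return pd.DataFrame({"unit_id": np.arange(len(values)), "change_pct": values})


def _nearest(ids, dists):
    return pd.DataFrame({"nearest_blob_id": ids, "distance_um": dists})


# ----------------------------------------------------------------------
# distances

def test_distance_examples():
    blobs = BlobSet.from_points_um(np.array([[160.0, 100.0]]))
    dmat, nearest = pairwise_unit_blob_distances(np.array([[100.0, 100.0]]), blobs)
    assert dmat[0, 0] == pytest.approx(60.0)
    assert nearest.distance_um[0] == pytest.approx(60.0)
    dmat, _ = pairwise_unit_blob_distances(np.array([[160.0, 100.0]]), blobs)
    assert dmat[0, 0] == 0.0


def test_distance_matrix_equals_double_loop():
    rng = np.random.default_rng(0)
    units = rng.uniform(0, 1000, (12, 2))
    pts = rng.uniform(0, 1000, (5, 2))
    dmat, nearest = pairwise_unit_blob_distances(units, BlobSet.from_points_um(pts))
    for i in range(12):
        for j in range(5):
            assert dmat[i, j] == pytest.approx(np.hypot(*(units[i] - pts[j])))
        assert nearest.distance_um[i] == pytest.approx(dmat[i].min())


def test_empty_blob_set_gives_nan_distances():
    dmat, nearest = pairwise_unit_blob_distances(
        np.array([[1.0, 2.0]]), BlobSet.from_points_um(np.empty((0, 2))))
    assert dmat.shape == (1, 0)
    assert np.isnan(nearest.distance_um[0])


# ----------------------------------------------------------------------
# two-factor rule

def test_two_factor_rule_cases():
    table = classify_matches(
        _changes([80.0, 200.0, 30.0]),
        _nearest([0, 0, 0], [40.0, 70.0, 10.0]))
    assert list(table.category) == ["match", "confound", "quiet"]
    assert list(table.is_match) == [True, False, False]
    assert match_counts(table) == {"match": 1, "confound": 1, "quiet": 1}


def test_boundary_change_must_exceed_threshold():
    table = classify_matches(_changes([50.0, 50.001]), _nearest([0, 0], [10.0, 10.0]))
    assert list(table.category) == ["quiet", "match"]


def test_boundary_distance_inclusive():
    table = classify_matches(_changes([100.0, 100.0]), _nearest([0, 0], [60.0, 60.001]))
    assert list(table.category) == ["match", "confound"]


def test_infinite_change_from_silence_passes_gate():
    table = classify_matches(_changes([np.inf]), _nearest([0], [10.0]))
    assert table.is_match[0]


def test_no_blobs_means_no_matches():
    table = classify_matches(_changes([120.0, 10.0]), _nearest([-1, -1], [np.nan, np.nan]))
    assert list(table.category) == ["confound", "quiet"]


def test_monotone_in_radius_and_threshold():
    rng = np.random.default_rng(1)
    changes = _changes(rng.uniform(-20, 200, 50))
    nearest = _nearest(np.zeros(50, int), rng.uniform(0, 150, 50))
    base = classify_matches(changes, nearest, radius_um=60, change_thresh_pct=50)
    wider = classify_matches(changes, nearest, radius_um=90, change_thresh_pct=50)
    lower = classify_matches(changes, nearest, radius_um=60, change_thresh_pct=30)
    assert wider.is_match.sum() >= base.is_match.sum()
    assert lower.is_match.sum() >= base.is_match.sum()


def test_nearest_only_keeps_closest_unit_per_blob():
    changes = _changes([100.0, 100.0, 100.0])
    nearest = _nearest([0, 0, 1], [20.0, 10.0, 5.0])
    table = classify_matches(changes, nearest, nearest_only=True)
    assert list(table.is_match) == [False, True, True]


# ----------------------------------------------------------------------
# planted-truth recovery

def _match_scene(clearance, seed, protocol):
    cfg = SceneConfig(confound_clearance_um=clearance)
    scene = make_scene(cfg, seed)
    ds = simulate_spikes(scene, protocol, seed, epoch_kinds=("spont_pre", "spont_cno"))
    changes = activity_table(ds)
    blobs = BlobSet.from_points_um(scene.soma_xy[scene.is_dreadd])
    cents = np.array([u.centroid_um for u in ds.units])
    _, nearest = pairwise_unit_blob_distances(cents, blobs)
    table = classify_matches(changes, nearest)
    return table.is_match.to_numpy(), ds.truth.is_dreadd.to_numpy()


def test_planted_scene_perfect_recovery(protocol):
    """Default planted scene (gain ~2x, AIS <= 30 µm, confounds cleared):
    precision = recall = 1."""
    pred, truth = _match_scene(120.0, seed=1, protocol=protocol)
    assert np.array_equal(pred, truth)


def test_radius_zero_gives_no_matches(protocol):
    cfg = SceneConfig()
    scene = make_scene(cfg, 1)
    ds = simulate_spikes(scene, protocol, 1, epoch_kinds=("spont_pre", "spont_cno"))
    changes = activity_table(ds)
    blobs = BlobSet.from_points_um(scene.soma_xy[scene.is_dreadd])
    cents = np.array([u.centroid_um for u in ds.units])
    _, nearest = pairwise_unit_blob_distances(cents, blobs)
    table = classify_matches(changes, nearest, radius_um=0.0)
    assert table.is_match.sum() == 0


# ----------------------------------------------------------------------
# distance/change profile

def test_profile_peaks_at_small_distance_for_dreadd_rich_scene(protocol):
    """With many planted DREADD units (AIS ~ Exp(15 µm)), the distance
    distribution of supra-threshold points peaks below 30 µm."""
    cfg = SceneConfig(dreadd_frac=0.2, confound_ratio=0.0)
    scene = make_scene(cfg, 3)
    ds = simulate_spikes(scene, protocol, 3, epoch_kinds=("spont_pre", "spont_cno"))
    changes = activity_table(ds)
    blobs = BlobSet.from_points_um(scene.soma_xy[scene.is_dreadd])
    cents = np.array([u.centroid_um for u in ds.units])
    prof = distance_change_profile(changes, cents, blobs)
    assert prof.supra_distance_peak_um < 30.0
    assert prof.change_peak_pct < 20.0  # bulk of units unaffected


def test_profile_requires_blobs():
    with pytest.raises(ConfigurationError):
        distance_change_profile(_changes([1.0]), np.array([[0.0, 0.0]]),
                                BlobSet.from_points_um(np.empty((0, 2))))


# ----------------------------------------------------------------------
# density maps

def test_density_map_empty_is_zero():
    grid = density_map(np.empty((0, 2)), extent_um=600.0)
    assert grid.shape == (10, 10)
    assert np.all(grid == 0.0)


def test_single_point_unsmoothed_density():
    grid = density_map(np.array([[90.0, 90.0]]), extent_um=600.0, smooth_sigma_bins=0.0)
    assert grid.max() == pytest.approx((1000.0 / 60.0) ** 2)
    assert np.count_nonzero(grid) == 1


def test_uniform_density_preserved_after_smoothing():
    rng = np.random.default_rng(2)
    extent = 2688.0
    target = 50.0  # cells / mm^2
    n = int(target * (extent / 1000.0) ** 2)
    pts = rng.uniform(0, extent, (n, 2))
    grid = density_map(pts, extent_um=extent)
    interior = grid[5:-5, 5:-5]
    assert abs(interior.mean() - target) / target < 0.1
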