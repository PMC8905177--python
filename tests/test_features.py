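import numpy as np
import pandas as pd
import pytest

from rgcpipe.errors import ConfigurationError
from rgcpipe.features import (bias_index, direction_tuning, pre_sort, psth,
                              quality_filter, response_duration, response_quality)


# ----------------------------------------------------------------------
# PSTH

def test_psth_no_spikes_is_zero():
    grid, rate = psth([np.empty(0)], (0.0, 1.0))
    assert np.all(rate == 0.0)


def test_psth_single_spike_peak_is_kernel_maximum():
    grid, rate = psth([np.array([0.5])], (0.0, 1.0))
    expected = 1.0 / (np.sqrt(2 * np.pi) * 0.025)
    assert rate.max() == pytest.approx(expected, rel=1e-6)
    assert grid[np.argmax(rate)] == pytest.approx(0.5)


def test_psth_mass_conservation():
    """Kernel integrates to 1: integral ~ mean spike count per trial."""
    rng = np.random.default_rng(0)
    trains = [np.sort(rng.uniform(0.5, 9.5, 40)) for _ in range(4)]  # >= 4 sd from edges
    grid, rate = psth(trains, (0.0, 10.0))
    integral = np.trapezoid(rate, grid)
    mean_count = np.mean([len(t) for t in trains])
    assert abs(integral - mean_count) / mean_count < 0.01


def test_psth_trial_averaging():
    g1, r1 = psth([np.array([0.3])], (0.0, 1.0))
    g2, r2 = psth([np.array([0.3]), np.empty(0)], (0.0, 1.0))
    np.testing.assert_allclose(r2, r1 / 2.0)


def test_psth_empty_window_rejected():
    with pytest.raises(ConfigurationError):
        psth([np.array([0.1])], (1.0, 1.0))


# ----------------------------------------------------------------------
# bias index

def test_bias_index_polarities():
    grid = np.linspace(0.0, 8.0, 8001)
    on_only = np.where((grid >= 2.0) & (grid < 3.0), 10.0, 0.0)
    assert bias_index(grid, on_only, (2.0, 3.0), (5.0, 6.0)) == 1.0
    off_only = np.where((grid >= 5.0) & (grid < 6.0), 10.0, 0.0)
    assert bias_index(grid, off_only, (2.0, 3.0), (5.0, 6.0)) == -1.0
    assert bias_index(grid, np.zeros_like(grid), (2.0, 3.0), (5.0, 6.0)) == 0.0


def test_bias_index_arithmetic_and_sign_flip():
    grid = np.linspace(0.0, 8.0, 8001)
    rate = np.where((grid >= 2.0) & (grid < 3.0), 6.0,
                    np.where((grid >= 5.0) & (grid < 6.0), 4.0, 0.0))
    bi = bias_index(grid, rate, (2.0, 3.0), (5.0, 6.0))
    assert bi == pytest.approx(0.2, abs=1e-3)
    flipped = bias_index(grid, rate, (5.0, 6.0), (2.0, 3.0))
    assert flipped == pytest.approx(-bi, abs=1e-9)


# ----------------------------------------------------------------------
# response duration

def test_sustained_response_capped_at_window_end():
    grid = np.linspace(0.0, 3.0, 3001)
    rate = np.where(grid >= 2.0, 20.0, 0.0)
    dur, flagged = response_duration(grid, rate, 2.0, 0.0, window_end=3.0)
    assert dur == pytest.approx(1.0, abs=2e-3)
    assert not flagged


def test_exponential_decay_crosses_quarter_peak_at_tau_ln4():
    tau = 0.05
    grid = np.linspace(0.0, 2.0, 20001)
    rate = np.where(grid >= 1.0, 100.0 * np.exp(-np.clip(grid - 1.0, 0, None) / tau), 0.0)
    dur, flagged = response_duration(grid, rate, 1.0, 0.0)
    assert dur == pytest.approx(tau * np.log(4.0), abs=2e-3)
    assert not flagged


def test_zero_response_flagged():
    grid = np.linspace(0.0, 2.0, 2001)
    dur, flagged = response_duration(grid, np.zeros_like(grid), 1.0, 0.0)
    assert dur == 0.0 and flagged


# ----------------------------------------------------------------------
# direction tuning

def test_single_direction_response_is_fully_selective():
    responses = {d: 0.0 for d in range(0, 360, 30)}
    responses[90] = 5.0
    dsi, osi, pref = direction_tuning(responses)
    assert dsi == pytest.approx(1.0)
    assert pref == pytest.approx(90.0)


def test_uniform_responses_are_unselective():
    dsi, osi, _ = direction_tuning({d: 3.0 for d in range(0, 360, 30)})
    assert dsi == pytest.approx(0.0, abs=1e-12)
    assert osi == pytest.approx(0.0, abs=1e-12)


def test_cosine_tuning_closed_form():
    """r = 1 + cos(theta - 30 deg) over 12 directions: dsi 0.5, osi 0."""
    responses = {d: 1.0 + np.cos(np.deg2rad(d - 30.0)) for d in range(0, 360, 30)}
    dsi, osi, pref = direction_tuning(responses)
    assert dsi == pytest.approx(0.5, abs=1e-12)
    assert osi == pytest.approx(0.0, abs=1e-12)
    assert pref == pytest.approx(30.0, abs=1e-9)


def test_tuning_scale_invariance_and_mirror_symmetry():
    responses = {d: 1.0 + np.cos(np.deg2rad(d - 30.0)) for d in range(0, 360, 30)}
    dsi1, osi1, _ = direction_tuning(responses)
    dsi2, osi2, _ = direction_tuning({d: 7.3 * r for d, r in responses.items()})
    assert (dsi1, osi1) == pytest.approx((dsi2, osi2))
    mirror = {d: 1.0 + abs(np.cos(np.deg2rad(d))) for d in range(0, 360, 30)}
    dsi_m, _, _ = direction_tuning(mirror)
    assert dsi_m == pytest.approx(0.0, abs=1e-12)


def test_tuning_input_validation():
    with pytest.raises(ConfigurationError):
        direction_tuning({0.0: 1.0, 90.0: 1.0})
    with pytest.raises(ConfigurationError):
        direction_tuning({d: -1.0 for d in range(0, 360, 90)})
    assert direction_tuning({d: 0.0 for d in range(0, 360, 90)}) == (0.0, 0.0, 0.0)


# ----------------------------------------------------------------------
# response quality

def test_identical_trials_perfectly_reliable():
    curve = np.sin(np.linspace(0, 6, 200)) + 2
    snr, rel = response_quality(np.vstack([curve, curve, curve]))
    assert rel == 1.0
    assert snr == np.inf


def test_noise_only_trials_unreliable():
    rng = np.random.default_rng(0)
    curves = rng.normal(size=(20, 10_000))
    snr, rel = response_quality(curves)
    assert abs(rel) < 0.1
    assert snr < 0.2


def test_anticorrelated_pair():
    base = np.sin(np.linspace(0, 6, 100))
    snr, rel = response_quality(np.vstack([base, -base]))
    assert rel == pytest.approx(-1.0)


def test_constant_trial_contributes_zero_correlation():
    curve = np.sin(np.linspace(0, 6, 100))
    snr, rel = response_quality(np.vstack([curve, np.zeros(100)]))
    assert rel == 0.0


def test_single_trial_rejected():
    with pytest.raises(ConfigurationError):
        response_quality(np.ones((1, 10)))


# ----------------------------------------------------------------------
# pre-sort and quality filter

@pytest.mark.parametrize("dsi,osi,expected", [
    (0.5, 0.1, "non-stationary"),
    (0.32, 0.32, "stationary"),
    (0.33, 0.0, "non-stationary"),  # boundary: >= cutoff
    (0.0, 0.34, "non-stationary"),
])
def test_pre_sort_cutoff(dsi, osi, expected):
    assert pre_sort(dsi, osi) == expected


def test_quality_filter_percentile_definition():
    """Metrics 1..100: values strictly below the 25.75 percentile point drop."""
    df = pd.DataFrame({
        "snr": np.arange(1.0, 101.0),
        "reliability": np.ones(100),
        "motion_class": ["stationary"] * 100,
    })
    out = quality_filter(df, percentile=25.0)
    dropped = (~out["passes_quality"]).sum()
    assert dropped == 25
    assert out.loc[out["snr"] >= 25.75, "passes_quality"].all()


def test_quality_filter_identical_metrics_drop_nothing():
    df = pd.DataFrame({
        "snr": np.ones(10), "reliability": np.ones(10),
        "motion_class": ["stationary"] * 10,
    })
    out = quality_filter(df)
    assert out["passes_quality"].all()


def test_quality_filter_small_pool_skipped_with_warning():
    df = pd.DataFrame({
        "snr": [1.0, 2.0, 3.0], "reliability": [1.0, 2.0, 3.0],
        "motion_class": ["stationary"] * 3,
    })
    with pytest.warns(UserWarning):
        out = quality_filter(df)
    assert out["passes_quality"].all()


def test_quality_filter_pools_are_independent():
    df = pd.DataFrame({
        "snr": np.concatenate([np.arange(1.0, 9.0), 100 + np.arange(1.0, 9.0)]),
        "reliability": np.ones(16),
        "motion_class": ["stationary"] * 8 + ["non-stationary"] * 8,
    })
    out = quality_filter(df, percentile=25.0)
    # each pool loses its own bottom quarter, not a shared one
    assert (~out.loc[df.motion_class == "stationary", "passes_quality"]).sum() == 2
    assert (~out.loc[df.motion_class == "non-stationary", "passes_quality"]).sum() == 2


def test_planted_noise_units_are_dropped(protocol):
    """Units of the silent class (spontaneous noise only) fail the filter."""
    from rgcpipe.features import feature_table
    from rgcpipe.synthetic import SceneConfig, make_dataset

    cfg = SceneConfig(class_counts={"on_sustained": 8, "off_transient": 8,
                                    "on_weak": 8, "silent": 6},
                      dreadd_frac=0.0)
    _, ds = make_dataset(cfg, protocol, seed=21)
    feats, _, _ = feature_table(ds)
    merged = feats.join(ds.truth["cell_class"])
    silent = merged[merged.cell_class == "silent"]
    assert not silent["passes_quality"].any()
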