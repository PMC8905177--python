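"""Trial-resolved response features.

PSTHs are kernel firing-rate estimates: every trial's spike train is
convolved with a unit-mass Gaussian (default sd 25 ms) evaluated exactly on
a fixed time grid, then averaged over trials.  From the chirp PSTH we take
the bias index (ON-OFF polarity), the response duration (transient vs
sustained decay) and the baseline rate; from the moving-bar trials the
direction (DSI) and orientation (OSI) selectivity indices via circular
vector sums.  Units are pre-sorted into stationary vs non-stationary pools
(max(DSI, OSI) against a 0.33 cutoff) and each pool is quality-filtered at
its own 25th percentile of SNR and trial-to-trial reliability.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .protocol import StimulusProtocol
from .synthetic import SpikeDataset

__all__ = [
    "psth",
    "bias_index",
    "response_duration",
    "direction_tuning",
    "response_quality",
    "pre_sort",
    "quality_filter",
    "feature_table",
    "chirp_psths",
]

KERNEL_TRUNCATION_SD = 6.0


def psth(trains: list[np.ndarray], window: tuple[float, float],
         sd_ms: float = 25.0, dt_ms: float = 1.0) -> tuple[np.ndarray, np.ndarray]:
    """Trial-averaged Gaussian-kernel rate estimate.

    Returns ``(time_grid_s, rate_hz)``.  The kernel is evaluated exactly at
    the grid points (no binning), truncated at 6 sd.
    """
    t0, t1 = window
    if t1 <= t0:
        raise ConfigurationError("empty PSTH window")
    if len(trains) == 0:
        raise ConfigurationError("psth needs at least one trial")
    sd = sd_ms / 1000.0
    dt = dt_ms / 1000.0
    grid = np.arange(t0, t1 + dt / 2.0, dt)
    rate = np.zeros_like(grid)
    norm = 1.0 / (np.sqrt(2.0 * np.pi) * sd)
    half = KERNEL_TRUNCATION_SD * sd
    for train in trains:
        for spike in np.asarray(train, dtype=float):
            i0 = int(np.searchsorted(grid, spike - half))
            i1 = int(np.searchsorted(grid, spike + half))
            if i1 > i0:
                seg = grid[i0:i1] - spike
                rate[i0:i1] += norm * np.exp(-0.5 * (seg / sd) ** 2)
    return grid, rate / len(trains)


def _window_mean(grid: np.ndarray, rate: np.ndarray, window: tuple[float, float]) -> float:
    sel = (grid >= window[0]) & (grid < window[1])
    return float(rate[sel].mean()) if np.any(sel) else 0.0


def bias_index(grid: np.ndarray, rate: np.ndarray,
               on_window: tuple[float, float], off_window: tuple[float, float]) -> float:
    """(R_on - R_off) / (R_on + R_off); 0 when both responses vanish."""
    r_on = _window_mean(grid, rate, on_window)
    r_off = _window_mean(grid, rate, off_window)
    if r_on + r_off == 0.0:
        return 0.0
    return (r_on - r_off) / (r_on + r_off)


def response_duration(grid: np.ndarray, rate: np.ndarray, onset_time: float,
                      baseline_hz: float, decay_frac: float = 0.25,
                      window_end: float | None = None) -> tuple[float, bool]:
    """Time from the post-onset peak until the rate decays toward baseline.

    The response ends when the curve first falls below
    ``baseline + decay_frac * (peak - baseline)``; capped at ``window_end``.
    Returns ``(duration_s, low_response_flag)``.
    """
    if window_end is None:
        window_end = float(grid[-1])
    sel = (grid >= onset_time) & (grid <= window_end)
    if not np.any(sel):
        raise ConfigurationError("onset outside the PSTH window")
    seg_t, seg_r = grid[sel], rate[sel]
    ipk = int(np.argmax(seg_r))
    peak = float(seg_r[ipk])
    if peak <= baseline_hz:
        return 0.0, True
    thresh = baseline_hz + decay_frac * (peak - baseline_hz)
    after = seg_r[ipk:]
    below = np.flatnonzero(after < thresh)
    if len(below) == 0:
        return float(window_end - seg_t[ipk]), False
    return float(seg_t[ipk + below[0]] - seg_t[ipk]), False


def direction_tuning(responses: dict[float, float]) -> tuple[float, float, float]:
    """DSI, OSI and preferred direction from per-direction mean responses.

    dsi = |sum r e^{i theta}| / sum r,  osi = |sum r e^{2 i theta}| / sum r;
    the preferred direction is the argument of the first sum (deg mod 360).
    """
    if len(responses) < 4:
        raise ConfigurationError("direction tuning needs >= 4 distinct directions")
    thetas = np.deg2rad(np.array(list(responses.keys()), dtype=float))
    r = np.array(list(responses.values()), dtype=float)
    if np.any(r < 0):
        raise ConfigurationError("negative tuning responses")
    total = r.sum()
    if total == 0.0:
        return 0.0, 0.0, 0.0
    v1 = np.sum(r * np.exp(1j * thetas))
    v2 = np.sum(r * np.exp(2j * thetas))
    pref = float(np.rad2deg(np.angle(v1)) % 360.0)
    return float(np.abs(v1) / total), float(np.abs(v2) / total), pref


def response_quality(trial_curves: np.ndarray) -> tuple[float, float]:
    """(snr, reliability) from single-trial rate curves (n_trials x n_time).

    snr is the variance over time of the trial-mean curve divided by the
    time-averaged across-trial variance (infinite when trials are identical
    and non-constant); reliability is the mean pairwise Pearson correlation
    between trials, with 0 substituted for constant trials.
    """
    curves = np.asarray(trial_curves, dtype=float)
    if curves.ndim != 2 or curves.shape[0] < 2:
        raise ConfigurationError("response_quality needs >= 2 trials")
    mean_curve = curves.mean(axis=0)
    signal = float(mean_curve.var())
    noise = float(curves.var(axis=0, ddof=0).mean())
    if noise <= signal * 1e-12:  # identical trials up to rounding
        snr = np.inf if signal > 0 else 0.0
    else:
        snr = signal / noise
    n = curves.shape[0]
    sds = curves.std(axis=1)
    cors = []
    for i in range(n):
        for j in range(i + 1, n):
            if sds[i] == 0.0 or sds[j] == 0.0:
                cors.append(0.0)
            else:
                cors.append(float(np.corrcoef(curves[i], curves[j])[0, 1]))
    return float(snr), float(np.mean(cors))


def pre_sort(dsi: float, osi: float, cutoff: float = 0.33) -> str:
    """"non-stationary" iff max(dsi, osi) >= cutoff, else "stationary"."""
    return "non-stationary" if max(dsi, osi) >= cutoff else "stationary"


def quality_filter(features: pd.DataFrame, percentile: float = 25.0,
                   pool_column: str = "motion_class") -> pd.DataFrame:
    """Drop units whose SNR or reliability is below the pool percentile.

    Percentiles (linear interpolation) are computed separately within each
    motion-class pool; a unit is dropped when *either* metric falls strictly
    below its pool's threshold.  Pools with fewer than 4 units are passed
    through with a warning.  Returns the table with a boolean
    ``passes_quality`` column filled in.
    """
    out = features.copy()
    out["passes_quality"] = True
    for pool, sub in features.groupby(pool_column):
        if len(sub) < 4:
            warnings.warn(f"pool {pool!r} has {len(sub)} units; quality filter skipped",
                          stacklevel=2)
            continue
        snr_vals = sub["snr"].replace(np.inf, np.finfo(float).max)
        q_snr = float(np.percentile(snr_vals, percentile))
        q_rel = float(np.percentile(sub["reliability"], percentile))
        drop = (snr_vals < q_snr) | (sub["reliability"] < q_rel)
        out.loc[sub.index[drop], "passes_quality"] = False
    return out


# ----------------------------------------------------------------------
# dataset-level drivers

def chirp_psths(ds: SpikeDataset, sd_ms: float = 25.0, dt_ms: float = 1.0
                ) -> tuple[np.ndarray, dict[int, np.ndarray], dict[int, np.ndarray]]:
    """Per-unit trial-averaged chirp PSTH plus single-trial curves.

    Returns ``(time_grid, mean_psth_by_unit, trial_curves_by_unit)``.
    """
    window = (0.0, ds.protocol.chirp_duration_s)
    grid = None
    means: dict[int, np.ndarray] = {}
    trials_out: dict[int, np.ndarray] = {}
    for unit in ds.units:
        trials = unit.trial_times(ds.protocol, "chirp")
        curves = []
        for train in trials:
            g, r = psth([train], window, sd_ms, dt_ms)
            curves.append(r)
            grid = g
        curves = np.asarray(curves)
        trials_out[unit.unit_id] = curves
        means[unit.unit_id] = curves.mean(axis=0)
    return grid, means, trials_out


def feature_table(ds: SpikeDataset, sd_ms: float = 25.0, dt_ms: float = 1.0,
                  dsi_osi_cutoff: float = 0.33, quality_percentile: float = 25.0,
                  on_off_window_s: float = 1.0) -> tuple[pd.DataFrame, np.ndarray, dict[int, np.ndarray]]:
    """Full per-unit feature table for a dataset.

    Returns ``(features indexed by unit_id, psth_time_grid, psth_by_unit)``.
    Bar responses are summarized as the mean spike count per direction over
    trials; baseline is the mean rate during the chirp pre-stimulus segment.
    """
    protocol = ds.protocol
    grid, means, trial_curves = chirp_psths(ds, sd_ms, dt_ms)
    t_on, _ = protocol.segment("step_on")
    t_off, off_end = protocol.segment("step_off")
    base_win = protocol.segment("baseline")
    rows = []
    for unit in ds.units:
        rate = means[unit.unit_id]
        baseline = _window_mean(grid, rate, base_win)
        bi = bias_index(grid, rate, (t_on, t_on + on_off_window_s),
                        (t_off, t_off + on_off_window_s))
        dur, low_resp = response_duration(grid, rate, t_on, baseline,
                                          window_end=off_end)
        counts: dict[float, list[int]] = {d: [] for d in protocol.bar_directions}
        for ep in protocol.epochs(("bar",)):
            counts[ep.direction_deg].append(len(unit.times(ep.epoch_id)))
        mean_counts = {d: float(np.mean(c)) if c else 0.0 for d, c in counts.items()}
        if len(mean_counts) >= 4:
            dsi, osi, pref = direction_tuning(mean_counts)
        else:
            dsi = osi = pref = 0.0
        snr, rel = response_quality(trial_curves[unit.unit_id])
        rows.append({
            "unit_id": unit.unit_id, "bias_index": bi, "response_duration_s": dur,
            "low_response": low_resp, "baseline_hz": baseline,
            "dsi": dsi, "osi": osi, "pref_direction_deg": pref,
            "snr": snr, "reliability": rel,
            "motion_class": pre_sort(dsi, osi, dsi_osi_cutoff),
        })
    table = pd.DataFrame(rows).set_index("unit_id")
    table = quality_filter(table, quality_percentile)
    return table, grid, means
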