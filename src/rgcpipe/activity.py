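"""Spontaneous-activity metrics and their CNO-induced changes.

A unit's *activity change* is the larger of its percent change in mean
firing rate and in burst index between the spontaneous epoch before CNO and
the spontaneous epoch in CNO.  The burst index is the fraction of spikes
that belong to bursts, a burst being a maximal run of at least
``min_spikes`` spikes whose consecutive inter-spike intervals are all below
``isi_max``.  Units recruited from silence (zero pre-CNO rate) receive an
infinite percent change, so they pass any increase threshold.

The full-width-at-half-maximum (FWHM) helper characterizes empirical
distributions (of activity changes, or of unit-to-soma distances) via a
Gaussian kernel density estimate; the threshold-justification diagnostics in
:mod:`rgcpipe.matching` are built on it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.stats import gaussian_kde

from .errors import ConfigurationError
from .protocol import StimulusProtocol
from .synthetic import SpikeDataset, UnitRecord

__all__ = [
    "ActivityChange",
    "mean_firing_rate",
    "burst_index",
    "percent_change",
    "activity_change",
    "activity_table",
    "fwhm",
]


@dataclass(frozen=True)
class ActivityChange:
    unit_id: int
    mfr_pre: float
    mfr_cno: float
    burst_pre: float
    burst_cno: float
    d_mfr_pct: float
    d_burst_pct: float

    @property
    def change_pct(self) -> float:
        """The more prominent of the two percent changes."""
        return max(self.d_mfr_pct, self.d_burst_pct)


def mean_firing_rate(times: np.ndarray, interval: tuple[float, float]) -> float:
    """Spike count in [t0, t1) divided by the interval length, in Hz."""
    t0, t1 = interval
    if t1 <= t0:
        raise ConfigurationError("empty interval for mean firing rate")
    times = np.asarray(times, dtype=float)
    count = int(np.count_nonzero((times >= t0) & (times < t1)))
    return count / (t1 - t0)


def burst_index(times: np.ndarray, isi_max: float = 0.1, min_spikes: int = 3) -> float:
    """Fraction of spikes belonging to bursts (ISI < ``isi_max`` runs)."""
    times = np.asarray(times, dtype=float)
    if len(times) < min_spikes:
        return 0.0
    if np.any(np.diff(times) < 0):
        raise ConfigurationError("spike times must be sorted")
    fast = np.diff(times) < isi_max  # fast[i]: spikes i, i+1 joined
    in_burst = 0
    run = 0  # length of the current fast-ISI run, in ISIs
    for joined in np.append(fast, False):
        if joined:
            run += 1
        else:
            if run + 1 >= min_spikes:
                in_burst += run + 1
            run = 0
    return in_burst / len(times)


def percent_change(pre: float, post: float) -> float:
    """100 * (post - pre) / pre with the degenerate-zero conventions."""
    if pre < 0 or post < 0:
        raise ConfigurationError("percent_change requires nonnegative inputs")
    if pre == 0.0:
        return float("inf") if post > 0 else 0.0
    return 100.0 * (post - pre) / pre


def activity_change(unit: UnitRecord, protocol: StimulusProtocol,
                    isi_max: float = 0.1, min_spikes: int = 3,
                    burst_change_min_count: int = 300) -> ActivityChange:
    """Per-unit CNO activity change from the two spontaneous epochs.

    A percent change of the burst index is only meaningful when the index
    rests on enough events: unless at least one epoch contains
    ``burst_change_min_count`` burst spikes (roughly 80 bursts in a 5-minute
    epoch, putting the percent-change sampling error below ~15%), the burst
    change is reported as 0, so that sampling noise on sparse trains cannot
    dominate ``change_pct``.
    """
    epochs = {e.kind: e for e in protocol.epochs()}
    for kind in ("spont_pre", "spont_cno"):
        if kind not in epochs:
            raise ConfigurationError(f"protocol lacks a {kind} epoch")
        dur = epochs[kind].duration_s
        if dur < 60.0:
            raise ConfigurationError(f"{kind} epoch shorter than 60 s")
        if dur < 300.0:
            warnings.warn(f"{kind} epoch shorter than the recommended 300 s", stacklevel=2)
    pre = unit.times(epochs["spont_pre"].epoch_id)
    cno = unit.times(epochs["spont_cno"].epoch_id)
    mfr_pre = mean_firing_rate(pre, (0.0, epochs["spont_pre"].duration_s))
    mfr_cno = mean_firing_rate(cno, (0.0, epochs["spont_cno"].duration_s))
    b_pre = burst_index(pre, isi_max, min_spikes)
    b_cno = burst_index(cno, isi_max, min_spikes)
    if max(b_pre * len(pre), b_cno * len(cno)) < burst_change_min_count:
        d_burst = 0.0
    else:
        d_burst = percent_change(b_pre, b_cno)
    return ActivityChange(
        unit_id=unit.unit_id, mfr_pre=mfr_pre, mfr_cno=mfr_cno,
        burst_pre=b_pre, burst_cno=b_cno,
        d_mfr_pct=percent_change(mfr_pre, mfr_cno),
        d_burst_pct=d_burst,
    )


def activity_table(ds: SpikeDataset, isi_max: float = 0.1, min_spikes: int = 3,
                   burst_change_min_count: int = 300):
    """Activity changes for a whole dataset as a pandas DataFrame."""
    import pandas as pd

    rows = []
    for unit in ds.units:
        ac = activity_change(unit, ds.protocol, isi_max, min_spikes, burst_change_min_count)
        rows.append({
            "unit_id": ac.unit_id, "mfr_pre": ac.mfr_pre, "mfr_cno": ac.mfr_cno,
            "burst_pre": ac.burst_pre, "burst_cno": ac.burst_cno,
            "d_mfr_pct": ac.d_mfr_pct, "d_burst_pct": ac.d_burst_pct,
            "change_pct": ac.change_pct,
        })
    return pd.DataFrame(rows)


def fwhm(samples: np.ndarray, n_grid: int = 512,
         bw_method: str | float = "silverman") -> tuple[float, float]:
    """Peak location and full width at half maximum of a KDE.

    A Gaussian kernel density estimate (Silverman bandwidth by default) is
    evaluated on ``n_grid`` points spanning the sample range; the width is
    the distance between the outermost half-maximum crossings bracketing the
    global peak.
    """
    samples = np.asarray(samples, dtype=float)
    samples = samples[np.isfinite(samples)]
    if len(samples) < 10:
        raise ConfigurationError("fwhm needs at least 10 finite samples")
    if np.ptp(samples) == 0.0:
        raise ConfigurationError("degenerate density: all samples identical")
    kde = gaussian_kde(samples, bw_method=bw_method)
    grid = np.linspace(samples.min(), samples.max(), n_grid)
    dens = kde(grid)
    ipk = int(np.argmax(dens))
    half = dens[ipk] / 2.0

    def _cross(i_lo: int, i_hi: int) -> float:
        # linear interpolation of the half-max crossing between grid points
        x0, x1 = grid[i_lo], grid[i_hi]
        y0, y1 = dens[i_lo], dens[i_hi]
        if y1 == y0:
            return x0
        return x0 + (half - y0) * (x1 - x0) / (y1 - y0)

    above = np.flatnonzero(dens >= half)  # nonempty: contains the peak
    i_first, i_last = int(above[0]), int(above[-1])
    left = _cross(i_first - 1, i_first) if i_first > 0 else grid[0]
    right = _cross(i_last, i_last + 1) if i_last < n_grid - 1 else grid[-1]
    return float(grid[ipk]), float(right - left)
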