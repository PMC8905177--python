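"""Time-resolved SPIKE dissimilarity between spike trains.

For two trains observed on an interval [t0, t1] (auxiliary spikes are added
at both interval edges), the instantaneous dissimilarity profile is

    S(t) = ( S1(t) * x2(t) + S2(t) * x1(t) ) / ( 2 * <x>(t)^2 ),

where for train k, ``x_k(t)`` is the current inter-spike interval,
``<x> = (x1 + x2)/2`` and

    S_k(t) = ( dP_k * (tF_k - t) + dF_k * (t - tP_k) ) / x_k(t),

with ``tP_k``/``tF_k`` the preceding/following spike of train k and
``dP_k``/``dF_k`` their distances to the nearest spike of the other train.
Between consecutive spikes (of either train) the profile is linear in t, so
its time average over [t0, t1] is computed exactly segment by segment.  The
value is symmetric, zero for identical trains, and lies in [0, 1).
"""

from __future__ import annotations

import numpy as np

from .errors import ConfigurationError

__all__ = ["spike_distance", "spike_profile_at"]


def _augment(train: np.ndarray, t0: float, t1: float) -> np.ndarray:
    t = np.asarray(train, dtype=float)
    t = t[(t >= t0) & (t <= t1)]
    t = np.unique(np.concatenate([[t0], t, [t1]]))
    # merge spikes separated by less than 1e-12 of the interval: such ISIs
    # are physically coincident and their squares underflow
    eps = 1e-12 * (t1 - t0)
    if len(t) > 2:
        keep = np.concatenate([[True], np.diff(t) > eps])
        t = t[keep]
        if t[-1] != t1:  # the end auxiliary spike was merged leftward
            t[-1] = t1
    return t


def _nearest_dist(x: np.ndarray, other: np.ndarray) -> np.ndarray:
    """Distance from each element of x to the nearest element of other."""
    idx = np.searchsorted(other, x)
    left = np.abs(x - other[np.clip(idx - 1, 0, len(other) - 1)])
    right = np.abs(other[np.clip(idx, 0, len(other) - 1)] - x)
    return np.minimum(left, right)


def _segment_quantities(train: np.ndarray, other: np.ndarray, u: np.ndarray,
                        v: np.ndarray):
    """Per-segment preceding/following spikes of ``train`` and their
    nearest-neighbour distances to ``other`` (segments are (u, v) pairs with
    no spike of either train strictly inside)."""
    i_prev = np.searchsorted(train, u, side="right") - 1
    i_next = np.searchsorted(train, v, side="left")
    t_p = train[i_prev]
    t_f = train[i_next]
    d_p = _nearest_dist(t_p, other)
    d_f = _nearest_dist(t_f, other)
    return t_p, t_f, d_p, d_f


def spike_distance(train_a: np.ndarray, train_b: np.ndarray,
                   interval: tuple[float, float]) -> float:
    """Time-averaged SPIKE dissimilarity of two trains over ``interval``."""
    t0, t1 = float(interval[0]), float(interval[1])
    if t1 <= t0:
        raise ConfigurationError("spike_distance interval must have t1 > t0")
    a = _augment(train_a, t0, t1)
    b = _augment(train_b, t0, t1)
    events = np.union1d(a, b)
    u, v = events[:-1], events[1:]
    keep = v > u
    u, v = u[keep], v[keep]
    if len(u) == 0:
        return 0.0

    tpa, tfa, dpa, dfa = _segment_quantities(a, b, u, v)
    tpb, tfb, dpb, dfb = _segment_quantities(b, a, u, v)
    xa = tfa - tpa
    xb = tfb - tpb

    def profile(t: np.ndarray) -> np.ndarray:
        s_a = (dpa * (tfa - t) + dfa * (t - tpa)) / xa
        s_b = (dpb * (tfb - t) + dfb * (t - tpb)) / xb
        mean_isi = 0.5 * (xa + xb)
        return (s_a * xb + s_b * xa) / (2.0 * mean_isi**2)

    s_u = profile(u)
    s_v = profile(v)
    integral = float(np.sum(0.5 * (s_u + s_v) * (v - u)))
    return integral / (t1 - t0)


def spike_profile_at(train_a: np.ndarray, train_b: np.ndarray,
                     interval: tuple[float, float], t: np.ndarray) -> np.ndarray:
    """Evaluate the dissimilarity profile S(t) at arbitrary times.

    At spike times (profile discontinuities) the left limit is returned.
    Provided for inspection and plotting; :func:`spike_distance` integrates
    the profile exactly and does not go through this function.
    """
    t0, t1 = float(interval[0]), float(interval[1])
    a = _augment(train_a, t0, t1)
    b = _augment(train_b, t0, t1)
    t = np.atleast_1d(np.asarray(t, dtype=float))
    out = np.empty_like(t)
    for i, ti in enumerate(t):
        tpa = a[np.searchsorted(a, ti, side="left") - 1] if ti > t0 else t0
        tfa = a[np.searchsorted(a, ti, side="left")] if ti < t1 else t1
        tpb = b[np.searchsorted(b, ti, side="left") - 1] if ti > t0 else t0
        tfb = b[np.searchsorted(b, ti, side="left")] if ti < t1 else t1
        dpa = np.min(np.abs(b - tpa))
        dfa = np.min(np.abs(b - tfa))
        dpb = np.min(np.abs(a - tpb))
        dfb = np.min(np.abs(a - tfb))
        xa, xb = tfa - tpa, tfb - tpb
        s_a = (dpa * (tfa - ti) + dfa * (ti - tpa)) / xa
        s_b = (dpb * (tfb - ti) + dfb * (ti - tpb)) / xb
        out[i] = (s_a * xb + s_b * xa) / (2.0 * (0.5 * (xa + xb)) ** 2)
    return out
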