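"""Independent brute-force oracles used to validate the implementations.

These deliberately re-derive each quantity from its definition by direct
enumeration or dense numerical integration, sharing no code with the
package internals they check.
"""

from __future__ import annotations

import math
from collections import deque

import numpy as np


def spike_distance_oracle(train_a, train_b, interval, dt=1e-5):
    """Dense-grid numerical integration of the SPIKE dissimilarity profile.

    The profile is sampled at spacing ``dt`` inside every inter-event
    segment (it is smooth there) and integrated with the trapezoid rule;
    the pointwise values come from a direct transliteration of the
    definition.
    """
    t0, t1 = interval
    a = np.unique(np.concatenate([[t0], np.asarray(train_a, float), [t1]]))
    b = np.unique(np.concatenate([[t0], np.asarray(train_b, float), [t1]]))
    a = a[(a >= t0) & (a <= t1)]
    b = b[(b >= t0) & (b <= t1)]
    events = np.union1d(a, b)

    def value(ts, u, v):
        tpa = a[a <= u].max()
        tfa = a[a >= v].min()
        tpb = b[b <= u].max()
        tfb = b[b >= v].min()
        dpa = np.abs(b - tpa).min()
        dfa = np.abs(b - tfa).min()
        dpb = np.abs(a - tpb).min()
        dfb = np.abs(a - tfb).min()
        xa, xb = tfa - tpa, tfb - tpb
        sa = (dpa * (tfa - ts) + dfa * (ts - tpa)) / xa
        sb = (dpb * (tfb - ts) + dfb * (ts - tpb)) / xb
        return (sa * xb + sb * xa) / (2.0 * (0.5 * (xa + xb)) ** 2)

    total = 0.0
    for u, v in zip(events[:-1], events[1:]):
        if v <= u:
            continue
        n = max(int(math.ceil((v - u) / dt)), 2)
        ts = np.linspace(u, v, n)
        total += np.trapezoid(value(ts, u, v), ts)
    return total / (t1 - t0)


def kapur_threshold_oracle(image):
    """Exhaustive 256-level maximum-entropy search, plain loops."""
    image = np.asarray(image, dtype=float)
    lo, hi = image.min(), image.max()
    hist, edges = np.histogram(image.ravel(), bins=256, range=(lo, hi))
    p = hist / hist.sum()
    best_t, best_h = None, -np.inf
    for t in range(255):
        pb = sum(p[: t + 1])
        pf = 1.0 - pb
        if pb <= 0 or pf <= 0:
            continue
        hb = -sum(q / pb * math.log(q / pb) for q in p[: t + 1] if q > 0)
        hf = -sum(q / pf * math.log(q / pf) for q in p[t + 1:] if q > 0)
        if hb + hf > best_h + 1e-12:
            best_h, best_t = hb + hf, t
    return float(edges[best_t + 1])


def fill_and_clean_oracle(mask, min_size=50):
    """BFS flood-fill of holes (4-conn background) + small-object removal
    (8-conn foreground), written directly from the definitions."""
    mask = np.asarray(mask, dtype=bool).copy()
    h, w = mask.shape
    # background pixels reachable from the border with 4-connectivity
    reach = np.zeros_like(mask)
    dq = deque()
    for i in range(h):
        for j in (0, w - 1):
            if not mask[i, j] and not reach[i, j]:
                reach[i, j] = True
                dq.append((i, j))
    for j in range(w):
        for i in (0, h - 1):
            if not mask[i, j] and not reach[i, j]:
                reach[i, j] = True
                dq.append((i, j))
    while dq:
        i, j = dq.popleft()
        for di, dj in ((1, 0), (-1, 0), (0, 1), (0, -1)):
            ni, nj = i + di, j + dj
            if 0 <= ni < h and 0 <= nj < w and not mask[ni, nj] and not reach[ni, nj]:
                reach[ni, nj] = True
                dq.append((ni, nj))
    filled = mask | ~reach
    # 8-connected components
    seen = np.zeros_like(filled)
    out = filled.copy()
    for i in range(h):
        for j in range(w):
            if filled[i, j] and not seen[i, j]:
                comp = [(i, j)]
                seen[i, j] = True
                dq = deque(comp)
                while dq:
                    ci, cj = dq.popleft()
                    for di in (-1, 0, 1):
                        for dj in (-1, 0, 1):
                            ni, nj = ci + di, cj + dj
                            if 0 <= ni < h and 0 <= nj < w and filled[ni, nj] \
                                    and not seen[ni, nj]:
                                seen[ni, nj] = True
                                comp.append((ni, nj))
                                dq.append((ni, nj))
                if len(comp) < min_size:
                    for ci, cj in comp:
                        out[ci, cj] = False
    return out
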