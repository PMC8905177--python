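"""Parametric firing-rate templates for archetypal RGC response classes.

Each archetype is described by a small set of physiological parameters
(baseline rate, ON/OFF polarity, transient amplitude and decay constant,
sustained plateau, sweep-following gains, and an optional direction- or
orientation-selective bar modulation).  Templates return nonnegative
instantaneous rates in Hz; spikes are drawn from them by an inhomogeneous
Poisson process in :mod:`rgcpipe.synthetic`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import GenerationError
from .protocol import StimulusProtocol


@dataclass(frozen=True)
class CellClassParams:
    """Rate-template parameters of one response archetype.

    polarity: "on", "off" or "onoff" — which contrast-step edge drives the
    cell and how sweep stimuli are rectified.
    modulation: None, "ds" or "os" — bar-response modulation
    ``1 + depth*cos(theta - theta0)`` (ds) or ``1 + depth*cos 2(theta -
    theta0)`` (os).
    """

    name: str
    baseline_hz: float = 2.0
    polarity: str = "on"
    transient_amp_hz: float = 20.0
    transient_tau_s: float = 0.1
    sustained_amp_hz: float = 0.0
    sweep_amp_hz: float = 10.0
    contrast_amp_hz: float = 8.0
    suppression: float = 0.8  # fractional baseline suppression on the null step
    freq_cutoff_hz: float = np.inf  # low-pass corner of sweep following
    freq_low_hz: float = 0.0  # high-pass corner (band-pass sweep tuning)
    contrast_threshold: float = 0.0  # fraction of the contrast ramp before responding
    lock_sharpness: float = 1.0  # exponent on rectified carriers: >1 gives
    # narrow phase-locked spike packets at the cycle peaks
    response_lag_s: float = 0.0  # latency of stimulus-driven responses
    sweep_polarity: str | None = None  # carrier phase during the frequency sweep
    contrast_polarity: str | None = None  # carrier phase during the contrast sweep
    max_rate_hz: float = 250.0  # physiological ceiling on the instantaneous rate
    spont_hz: float | None = None  # dark spontaneous rate; defaults to baseline_hz
    modulation: str | None = None
    modulation_depth: float = 0.0
    pref_direction_deg: float = 0.0
    bar_amp_hz: float = 25.0

    def __post_init__(self) -> None:
        if self.baseline_hz < 0 or self.transient_amp_hz < 0 or self.sustained_amp_hz < 0:
            raise GenerationError(f"negative template rate parameter in class {self.name!r}")
        if self.polarity not in ("on", "off", "onoff"):
            raise GenerationError(f"unknown polarity {self.polarity!r}")
        if self.modulation not in (None, "ds", "os"):
            raise GenerationError(f"unknown modulation {self.modulation!r}")

    # ------------------------------------------------------------------
    def _rectify(self, drive: np.ndarray, polarity: str | None = None) -> np.ndarray:
        polarity = polarity or self.polarity
        if polarity == "on":
            out = np.maximum(drive, 0.0)
        elif polarity == "off":
            out = np.maximum(-drive, 0.0)
        else:
            out = np.abs(drive)
        if self.lock_sharpness != 1.0:
            out = out**self.lock_sharpness
        return out

    def _step_response(self, t_rel: np.ndarray, edge: str) -> np.ndarray:
        """Rate added during a contrast step starting at ``t_rel = 0``.

        ``edge`` is "on" or "off"; preferred edges get transient + sustained
        response, null edges get baseline suppression.
        """
        preferred = self.polarity == "onoff" or self.polarity == edge
        resp = np.zeros_like(t_rel)
        if preferred:
            resp += self.transient_amp_hz * np.exp(-t_rel / self.transient_tau_s)
            resp += self.sustained_amp_hz
        else:
            resp -= self.suppression * self.baseline_hz
        return resp

    def chirp_rate(self, t: np.ndarray, protocol: StimulusProtocol) -> np.ndarray:
        """Instantaneous rate (Hz) at chirp-relative times ``t``.

        Sweep responses are phase-locked packets: the rectified carrier is
        raised to ``lock_sharpness`` and its amplitude grows proportionally
        with the instantaneous frequency (constant expected spike count per
        cycle) up to ``max_rate_hz``.
        """
        t = np.asarray(t, dtype=float)
        rate = np.full_like(t, self.baseline_hz)
        lag = self.response_lag_s
        for label, start, end in protocol.chirp_segments:
            sel = (t >= start) & (t < end)
            if not np.any(sel):
                continue
            u = np.clip(t[sel] - start - lag, 0.0, None)
            active = t[sel] - start >= lag
            if label == "step_on":
                rate[sel] += active * self._step_response(u, "on")
            elif label == "step_off":
                rate[sel] += active * self._step_response(u, "off")
            elif label == "freq_sweep":
                length = end - start
                f0, f1 = 1.0, 15.0
                phase = f0 * u + (f1 - f0) / (2.0 * length) * u**2
                freq = f0 + (f1 - f0) * u / length
                env = 1.0 / (1.0 + (freq / self.freq_cutoff_hz) ** 4)
                if self.freq_low_hz > 0:
                    env = env / (1.0 + (self.freq_low_hz / freq) ** 4)
                amp = np.minimum(self.sweep_amp_hz * freq, self.max_rate_hz)
                carrier = self._rectify(np.sin(2 * np.pi * phase), self.sweep_polarity)
                rate[sel] += active * amp * env * carrier
            elif label == "contrast_sweep":
                length = end - start
                ramp = np.clip(t[sel] - start, 0.0, None) / length
                env = np.clip(ramp - self.contrast_threshold, 0.0, None)
                env = env / max(1.0 - self.contrast_threshold, 1e-9)
                pol = self.contrast_polarity or self.sweep_polarity
                carrier = self._rectify(np.sin(2 * np.pi * 2.0 * u), pol)
                rate[sel] += active * self.contrast_amp_hz * env * carrier
        return np.maximum(rate, 0.0)

    def bar_tuning(self, direction_deg: float) -> float:
        """Multiplicative tuning factor for a bar moving in ``direction_deg``."""
        if self.modulation is None or self.modulation_depth == 0.0:
            return 1.0
        delta = np.deg2rad(direction_deg - self.pref_direction_deg)
        mult = 2.0 if self.modulation == "os" else 1.0
        return float(1.0 + self.modulation_depth * np.cos(mult * delta))

    def bar_rate(self, t: np.ndarray, direction_deg: float, duration_s: float) -> np.ndarray:
        """Rate during one bar sweep: Gaussian response bump at mid-epoch."""
        t = np.asarray(t, dtype=float)
        bump = np.exp(-0.5 * ((t - duration_s / 2.0) / 0.15) ** 2)
        rate = self.baseline_hz + self.bar_amp_hz * self.bar_tuning(direction_deg) * bump
        return np.maximum(rate, 0.0)

    def spont_rate(self, cno_gain: float = 1.0) -> float:
        base = self.baseline_hz if self.spont_hz is None else self.spont_hz
        return base * cno_gain


def _lib(*classes: CellClassParams) -> dict[str, CellClassParams]:
    return {c.name: c for c in classes}


#: Archetype library: three stationary and five motion-selective classes plus
#: a silent control class.  Classes differ primarily in response *timing* —
#: ON/OFF polarity, transient decay, sweep frequency band, carrier phase and
#: contrast-sensitivity onset — which is what a spike-timing dissimilarity
#: resolves; firing during stimulation is organized in phase-locked packets
#: (instantaneous rates up to a 250 Hz ceiling) with near-silent interludes,
#: as in light-driven RGC recordings.  Amplitudes are balanced so that the
#: archetypes have comparable single-trial SNR and reliability: the quality
#: filter is meant to remove noisy units, not whole response classes.
#: Spontaneous (dark) rates are set independently of the light-adapted
#: chirp baseline and span 1-8 Hz across classes.
CLASS_LIBRARY: dict[str, CellClassParams] = _lib(
    CellClassParams("on_sustained", baseline_hz=0.1, spont_hz=8.0, polarity="on",
                    transient_amp_hz=118.8, transient_tau_s=0.08, sustained_amp_hz=33.0,
                    sweep_amp_hz=37.0, contrast_amp_hz=66.0, freq_cutoff_hz=5.7,
                    contrast_threshold=0.0, lock_sharpness=4.0, suppression=1.0),
    CellClassParams("off_transient", baseline_hz=0.05, spont_hz=2.0, polarity="off",
                    transient_amp_hz=118.8, transient_tau_s=0.05, sustained_amp_hz=0.0,
                    sweep_amp_hz=27.7, contrast_amp_hz=54.5, freq_cutoff_hz=15.0,
                    freq_low_hz=5.7, contrast_threshold=0.5, lock_sharpness=4.0,
                    suppression=1.0),
    CellClassParams("on_weak", baseline_hz=0.05, spont_hz=4.0, polarity="on",
                    transient_amp_hz=31.2, transient_tau_s=0.15, sustained_amp_hz=0.0,
                    sweep_amp_hz=21.8, contrast_amp_hz=31.2, freq_cutoff_hz=15.0,
                    contrast_threshold=0.75, response_lag_s=0.15, lock_sharpness=4.0,
                    suppression=1.0),
    CellClassParams("onoff_ds", baseline_hz=0.05, spont_hz=2.0, polarity="onoff",
                    transient_amp_hz=157.3, transient_tau_s=0.06, sweep_amp_hz=39.3,
                    contrast_amp_hz=59.0, freq_cutoff_hz=4.0, contrast_threshold=0.3,
                    lock_sharpness=4.0, suppression=1.0,
                    modulation="ds", modulation_depth=1.0, pref_direction_deg=0.0),
    CellClassParams("on_trans_ds", baseline_hz=0.05, spont_hz=1.0, polarity="on",
                    transient_amp_hz=66.3, transient_tau_s=0.05, sweep_amp_hz=30.4,
                    contrast_amp_hz=30.4, freq_cutoff_hz=8.0, contrast_threshold=0.0,
                    response_lag_s=0.15, lock_sharpness=4.0, suppression=1.0,
                    modulation="ds", modulation_depth=1.0, pref_direction_deg=90.0),
    CellClassParams("onoff_os", baseline_hz=0.05, spont_hz=6.0, polarity="onoff",
                    transient_amp_hz=56.9, transient_tau_s=0.12, sweep_amp_hz=13.4,
                    contrast_amp_hz=48.8, freq_cutoff_hz=15.0, freq_low_hz=5.0,
                    response_lag_s=0.25, contrast_polarity="on", contrast_threshold=0.55,
                    lock_sharpness=4.0, suppression=1.0,
                    modulation="os", modulation_depth=1.0, pref_direction_deg=45.0),
    CellClassParams("on_trans_os", baseline_hz=0.05, spont_hz=3.0, polarity="on",
                    transient_amp_hz=100.0, transient_tau_s=0.09, sweep_amp_hz=51.4,
                    contrast_amp_hz=85.7, freq_cutoff_hz=15.0, freq_low_hz=8.0,
                    response_lag_s=0.08, contrast_polarity="off", contrast_threshold=0.55,
                    lock_sharpness=4.0, suppression=1.0,
                    modulation="os", modulation_depth=1.0, pref_direction_deg=135.0),
    CellClassParams("on_sust_ds", baseline_hz=0.3, spont_hz=8.0, polarity="on",
                    sweep_polarity="off", transient_amp_hz=27.8, transient_tau_s=0.3,
                    sustained_amp_hz=16.5, sweep_amp_hz=37.8, contrast_amp_hz=52.1,
                    freq_cutoff_hz=8.0, contrast_threshold=0.0, lock_sharpness=4.0,
                    suppression=1.0,
                    modulation="ds", modulation_depth=1.0, pref_direction_deg=180.0),
    CellClassParams("silent", baseline_hz=0.0, transient_amp_hz=0.0,
                    sustained_amp_hz=0.0, sweep_amp_hz=0.0, contrast_amp_hz=0.0,
                    bar_amp_hz=0.0, suppression=0.0),
)

STATIONARY_CLASSES: tuple[str, ...] = ("on_sustained", "off_transient", "on_weak")
NONSTATIONARY_CLASSES: tuple[str, ...] = (
    "onoff_ds", "on_trans_ds", "onoff_os", "on_trans_os", "on_sust_ds")
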