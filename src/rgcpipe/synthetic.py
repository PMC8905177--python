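"""Seeded synthetic experiments: scenes, spike trains and ground truth.

A *scene* places somata on the MEA, assigns each a response archetype, marks
a small DREADD-expressing subset (these receive a CNO rate gain and a GFP
soma in the rendered micrograph), and marks a larger *confound* subset of
non-DREADD cells whose firing is also raised by CNO — emulating cells driven
indirectly through DREADD-expressing amacrine cells.  Confounds carry no GFP
label; rejecting them is the job of the spatial matching stage.  Spike
centroids are displaced from somata by an axon-initial-segment offset drawn
from a truncated exponential length distribution.

Spikes are drawn from inhomogeneous Poisson processes whose rate templates
come from :mod:`rgcpipe.templates`; the CNO gain multiplies the spontaneous
rate during the CNO epoch only.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .errors import ConfigurationError, GenerationError
from .protocol import Epoch, StimulusProtocol
from .registration import Calibration
from .templates import CLASS_LIBRARY, CellClassParams, NONSTATIONARY_CLASSES, STATIONARY_CLASSES

ARRAY_EXTENT_UM = 64 * 42.0  # 2.688 mm square array

DEFAULT_CLASS_COUNTS: dict[str, int] = {
    "on_sustained": 25, "off_transient": 25, "on_weak": 25,
    "onoff_ds": 15, "on_trans_ds": 15, "onoff_os": 15, "on_trans_os": 15,
    "on_sust_ds": 15,
}


@dataclass(frozen=True)
class WarpConfig:
    """Magnitude of the ground-truth fixed->moving image warp."""

    rotation_deg: float = 1.5
    scale_jitter: float = 0.01
    translation_px: float = 8.0
    sine_amp_px: float = 5.0
    sine_period_px: float = 3000.0  # sub-cycle, field-scale distortion


@dataclass(frozen=True)
class ImageConfig:
    um_per_px: float = 1.4
    soma_diameter_um: float = 18.0
    n_vessels: int = 14
    vessel_width_px: int = 2
    gfp_snr: float = 8.0
    gfp_amplitude: float = 12000.0
    background_frac: float = 0.15
    n_landmarks: int = 120
    landmark_jitter_px: float = 0.5
    landmark_margin_px: float = 20.0


@dataclass(frozen=True)
class SceneConfig:
    """Parameters of one synthetic experiment.

    Either ``class_counts`` (archetype -> soma count) or ``n_somata``
    (distributed over the default archetype mix) defines the population.
    ``confound_ratio`` sets the confound:DREADD count ratio; confounds are
    kept at least ``confound_clearance_um`` away from every DREADD soma
    unless that is None (fully uniform placement).
    """

    n_somata: int | None = None
    class_counts: dict[str, int] | None = None
    dreadd_frac: float = 0.02  # 3 DREADD somata per default 150-soma scene,
    # a 1:10-scale version of the per-retina proportions the rule targets
    confound_ratio: float = 10.0
    confound_clearance_um: float | None = 120.0
    ac_fraction: float = 0.0
    gain_range: tuple[float, float] = (1.8, 2.2)
    min_dreadd_gain: float = 1.5
    ais_mean_um: float = 15.0
    ais_max_um: float | None = 30.0
    centroid_jitter_um: float = 2.0
    extent_um: float = ARRAY_EXTENT_UM
    margin_um: float = 30.0
    burst_doublet_prob: float = 0.0
    doublet_dt_s: float = 0.004
    sim_dt_s: float = 0.001
    warp: WarpConfig = field(default_factory=WarpConfig)
    image: ImageConfig = field(default_factory=ImageConfig)

    def __post_init__(self) -> None:
        if not 0.0 <= self.dreadd_frac <= 1.0:
            raise ConfigurationError("dreadd_frac must be in [0, 1]")
        if self.n_somata is not None and self.n_somata < 0:
            raise ConfigurationError("n_somata must be nonnegative")
        if self.class_counts is not None:
            for name, count in self.class_counts.items():
                if count < 0:
                    raise ConfigurationError(f"negative count for class {name!r}")
                if name not in CLASS_LIBRARY:
                    raise ConfigurationError(f"unknown cell class {name!r}")
        if self.confound_ratio < 0 or not 0.0 <= self.ac_fraction <= 1.0:
            raise ConfigurationError("invalid confound_ratio or ac_fraction")
        if self.gain_range[0] > self.gain_range[1] or self.gain_range[0] < 1.0:
            raise ConfigurationError("gain_range must satisfy 1 <= low <= high")

    def resolved_class_counts(self) -> dict[str, int]:
        if self.class_counts is not None:
            return dict(self.class_counts)
        if self.n_somata is None:
            return dict(DEFAULT_CLASS_COUNTS)
        total_default = sum(DEFAULT_CLASS_COUNTS.values())
        names = list(DEFAULT_CLASS_COUNTS)
        counts = {n: (self.n_somata * c) // total_default for n, c in DEFAULT_CLASS_COUNTS.items()}
        # distribute the remainder deterministically
        short = self.n_somata - sum(counts.values())
        for name in names[:short]:
            counts[name] += 1
        return counts


@dataclass(frozen=True)
class WarpParams:
    """Smooth ground-truth warp, fixed-frame pixels -> moving-frame pixels.

    Similarity part (rotation about the image centre, isotropic scale,
    translation) plus a low-frequency sinusoidal displacement field.
    """

    rotation_deg: float
    scale: float
    translation_px: tuple[float, float]
    sine_amp_px: tuple[float, float]
    sine_period_px: float
    phase: tuple[float, float]
    center_px: tuple[float, float]

    def __call__(self, points_px: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points_px, dtype=float))
        c = np.asarray(self.center_px)
        th = math.radians(self.rotation_deg)
        rot = np.array([[math.cos(th), -math.sin(th)], [math.sin(th), math.cos(th)]])
        out = (pts - c) @ (self.scale * rot).T + c + np.asarray(self.translation_px)
        if self.sine_amp_px != (0.0, 0.0):
            k = 2 * np.pi / self.sine_period_px
            out = out + np.column_stack([
                self.sine_amp_px[0] * np.sin(k * pts[:, 1] + self.phase[0]),
                self.sine_amp_px[1] * np.sin(k * pts[:, 0] + self.phase[1]),
            ])
        return out

    @staticmethod
    def identity(center_px: tuple[float, float] = (0.0, 0.0)) -> "WarpParams":
        return WarpParams(0.0, 1.0, (0.0, 0.0), (0.0, 0.0), 1.0, (0.0, 0.0), center_px)


@dataclass
class GroundTruthScene:
    config: SceneConfig
    rng_seed: int
    soma_xy: np.ndarray  # (n, 2) µm, MEA frame
    cell_class: np.ndarray  # (n,) str
    is_rgc: np.ndarray  # (n,) bool
    is_dreadd: np.ndarray  # (n,) bool
    is_confound: np.ndarray  # (n,) bool
    cno_gain: np.ndarray  # (n,) float
    ais_offset_xy: np.ndarray  # (n, 2) µm
    warp: WarpParams
    calibration: Calibration

    @property
    def n_somata(self) -> int:
        return len(self.soma_xy)

    def class_params(self, i: int) -> CellClassParams:
        return CLASS_LIBRARY[str(self.cell_class[i])]


@dataclass
class UnitRecord:
    """One sorted unit: per-epoch spike times + spike-cluster centroid (µm)."""

    unit_id: int
    centroid_um: np.ndarray
    times_by_epoch: dict[int, np.ndarray]

    def times(self, epoch_id: int) -> np.ndarray:
        return self.times_by_epoch.get(epoch_id, np.empty(0))

    def trial_times(self, protocol: StimulusProtocol, kind: str) -> list[np.ndarray]:
        return [self.times(e.epoch_id) for e in protocol.epochs() if e.kind == kind]


@dataclass
class SpikeDataset:
    units: list[UnitRecord]
    protocol: StimulusProtocol
    calibration: Calibration
    truth: "object | None" = None  # pandas DataFrame indexed by unit_id, or None (blind)

    @property
    def unit_ids(self) -> list[int]:
        return [u.unit_id for u in self.units]


# ----------------------------------------------------------------------
# scene construction

def make_scene(config: SceneConfig, seed: int) -> GroundTruthScene:
    """Build a ground-truth scene; deterministic for a fixed (config, seed)."""
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0x5CE17E]))
    counts = config.resolved_class_counts()
    classes: list[str] = []
    for name, count in counts.items():
        classes.extend([name] * count)
    n = len(classes)
    cell_class = np.array(classes, dtype=object)
    rng.shuffle(cell_class)

    lo = config.margin_um
    hi = config.extent_um - config.margin_um
    soma_xy = rng.uniform(lo, hi, size=(n, 2)) if n else np.empty((0, 2))

    is_rgc = np.ones(n, dtype=bool)
    n_ac = int(math.floor(config.ac_fraction * n))
    if n_ac:
        is_rgc[rng.choice(n, size=n_ac, replace=False)] = False

    is_dreadd = np.zeros(n, dtype=bool)
    n_dreadd = int(math.floor(config.dreadd_frac * n))
    if n_dreadd:
        is_dreadd[rng.choice(n, size=n_dreadd, replace=False)] = True

    cno_gain = np.ones(n, dtype=float)
    cno_gain[is_dreadd] = rng.uniform(*config.gain_range, size=n_dreadd)
    if np.any(is_dreadd) and np.any(cno_gain[is_dreadd] < config.min_dreadd_gain):
        raise GenerationError("drawn DREADD gain below configured minimum")

    is_confound = np.zeros(n, dtype=bool)
    n_conf_wanted = int(round(config.confound_ratio * n_dreadd))
    candidates = np.flatnonzero(~is_dreadd)
    if config.confound_clearance_um is not None and n_dreadd:
        d = np.linalg.norm(
            soma_xy[candidates, None, :] - soma_xy[None, is_dreadd, :], axis=2)
        candidates = candidates[d.min(axis=1) >= config.confound_clearance_um]
    n_conf = min(n_conf_wanted, len(candidates))
    if n_conf:
        is_confound[rng.choice(candidates, size=n_conf, replace=False)] = True
        # amacrine-driven confounds mimic the DREADD gain distribution
        cno_gain[is_confound] = rng.uniform(*config.gain_range, size=n_conf)

    # truncated-exponential AIS offset lengths, uniform direction
    if n:
        u = rng.uniform(size=n)
        if config.ais_max_um is not None:
            cap = 1.0 - math.exp(-config.ais_max_um / config.ais_mean_um)
            lengths = -config.ais_mean_um * np.log1p(-u * cap)
        else:
            lengths = -config.ais_mean_um * np.log1p(-u)
        angles = rng.uniform(0.0, 2 * np.pi, size=n)
        ais = np.column_stack([lengths * np.cos(angles), lengths * np.sin(angles)])
    else:
        ais = np.empty((0, 2))

    img = config.image
    side_px = config.extent_um / img.um_per_px
    wc = config.warp
    warp = WarpParams(
        rotation_deg=rng.uniform(-wc.rotation_deg, wc.rotation_deg),
        scale=1.0 + rng.uniform(-wc.scale_jitter, wc.scale_jitter),
        translation_px=tuple(rng.uniform(-wc.translation_px, wc.translation_px, size=2)),
        sine_amp_px=tuple(rng.uniform(0.3, 1.0, size=2) * wc.sine_amp_px),
        sine_period_px=wc.sine_period_px,
        phase=tuple(rng.uniform(0.0, 2 * np.pi, size=2)),
        center_px=(side_px / 2.0, side_px / 2.0),
    )
    cal = Calibration(um_per_px=img.um_per_px, origin_offset_um=(0.0, 0.0))
    return GroundTruthScene(
        config=config, rng_seed=int(seed), soma_xy=soma_xy, cell_class=cell_class,
        is_rgc=is_rgc, is_dreadd=is_dreadd, is_confound=is_confound,
        cno_gain=cno_gain, ais_offset_xy=ais, warp=warp, calibration=cal)


# ----------------------------------------------------------------------
# spike simulation

def poisson_train(rate_fn, duration: float, rng: np.random.Generator,
                  dt: float = 0.001) -> np.ndarray:
    """Inhomogeneous Poisson spikes on [0, duration) by thinning.

    ``rate_fn`` maps a time array to nonnegative rates in Hz (or is a
    scalar constant rate).
    """
    if np.isscalar(rate_fn):
        const = float(rate_fn)
        if const < 0:
            raise GenerationError("negative template rate")
        rate_fn = lambda t, c=const: np.full_like(np.asarray(t, float), c)  # noqa: E731
    grid = np.arange(0.0, duration + dt, dt)
    rates = np.asarray(rate_fn(grid), dtype=float)
    if np.any(rates < 0):
        raise GenerationError("negative template rate")
    rmax = float(rates.max(initial=0.0))
    if rmax == 0.0:
        return np.empty(0)
    n = rng.poisson(rmax * duration)
    cand = np.sort(rng.uniform(0.0, duration, size=n))
    keep = rng.uniform(0.0, rmax, size=n) < np.interp(cand, grid, rates)
    return cand[keep]


def _insert_doublets(times: np.ndarray, prob: float, dt: float,
                     duration: float, rng: np.random.Generator) -> np.ndarray:
    if prob <= 0 or len(times) == 0:
        return times
    extra = times[rng.uniform(size=len(times)) < prob] + dt
    extra = extra[extra < duration]
    return np.sort(np.concatenate([times, extra]))


def simulate_spikes(scene: GroundTruthScene, protocol: StimulusProtocol, seed: int,
                    epoch_kinds: tuple[str, ...] | None = None) -> SpikeDataset:
    """Draw spike trains for every RGC soma of the scene.

    ``epoch_kinds`` restricts simulation to a subset of epoch kinds (e.g.
    only the spontaneous epochs for activity-change studies).
    """
    import pandas as pd

    cfg = scene.config
    epochs = protocol.epochs(epoch_kinds)
    rgc_idx = np.flatnonzero(scene.is_rgc)
    ss = np.random.SeedSequence([int(seed), scene.rng_seed, 0x51D])
    unit_seeds = ss.spawn(len(rgc_idx))
    units: list[UnitRecord] = []
    rows = []
    for uid, (soma_i, useed) in enumerate(zip(rgc_idx, unit_seeds)):
        rng = np.random.default_rng(useed)
        params = scene.class_params(soma_i)
        gain = float(scene.cno_gain[soma_i])
        jitter = rng.normal(0.0, cfg.centroid_jitter_um, size=2)
        centroid = scene.soma_xy[soma_i] + scene.ais_offset_xy[soma_i] + jitter
        times_by_epoch: dict[int, np.ndarray] = {}
        for ep in epochs:
            times_by_epoch[ep.epoch_id] = _simulate_epoch(params, ep, gain, cfg, protocol, rng)
        units.append(UnitRecord(uid, centroid, times_by_epoch))
        rows.append({
            "unit_id": uid, "soma_id": int(soma_i),
            "soma_x_um": scene.soma_xy[soma_i, 0], "soma_y_um": scene.soma_xy[soma_i, 1],
            "cell_class": str(scene.cell_class[soma_i]),
            "is_dreadd": bool(scene.is_dreadd[soma_i]),
            "is_confound": bool(scene.is_confound[soma_i]),
            "cno_gain": gain,
            "ais_offset_um": float(np.linalg.norm(scene.ais_offset_xy[soma_i])),
        })
    truth = pd.DataFrame(rows).set_index("unit_id") if rows else None
    return SpikeDataset(units=units, protocol=protocol,
                        calibration=scene.calibration, truth=truth)


def _simulate_epoch(params: CellClassParams, ep: Epoch, gain: float,
                    cfg: SceneConfig, protocol: StimulusProtocol,
                    rng: np.random.Generator) -> np.ndarray:
    if ep.kind == "spont_pre":
        return poisson_train(params.spont_rate(), ep.duration_s, rng, cfg.sim_dt_s)
    if ep.kind == "spont_cno":
        t = poisson_train(params.spont_rate(gain), ep.duration_s, rng, cfg.sim_dt_s)
        if gain > 1.0:
            t = _insert_doublets(t, cfg.burst_doublet_prob, cfg.doublet_dt_s,
                                 ep.duration_s, rng)
        return t
    if ep.kind == "chirp":
        return poisson_train(lambda t: params.chirp_rate(t, protocol),
                             ep.duration_s, rng, cfg.sim_dt_s)
    if ep.kind == "bar":
        return poisson_train(
            lambda t: params.bar_rate(t, ep.direction_deg, ep.duration_s),
            ep.duration_s, rng, cfg.sim_dt_s)
    raise GenerationError(f"unknown epoch kind {ep.kind!r}")


def make_dataset(config: SceneConfig, protocol: StimulusProtocol, seed: int,
                 epoch_kinds: tuple[str, ...] | None = None
                 ) -> tuple[GroundTruthScene, SpikeDataset]:
    """Convenience: scene + spikes from a single seed."""
    scene = make_scene(config, seed)
    return scene, simulate_spikes(scene, protocol, seed, epoch_kinds)
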