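"""File formats and pipeline configuration.

Spike datasets are stored in HDF5 as ``/units/<id>/{times, epoch_ids,
centroid}`` with the protocol under ``/protocol``, the pixel calibration
under ``/calibration`` and (unless exported blind) the ground truth under
``/truth``.  Spike times are relative to their epoch onset; the epoch table
derived from the protocol maps epoch ids to kinds, trials and bar
directions.  Configuration is a single YAML document; its SHA-256 hash is
stamped into every artefact so that stages refuse to mix outputs from
different configurations.
"""

from __future__ import annotations

import dataclasses
import hashlib
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import yaml

from .errors import SchemaError
from .protocol import StimulusProtocol
from .registration import Calibration, LandmarkPairs
from .synthetic import ImageConfig, SceneConfig, SpikeDataset, UnitRecord, WarpConfig

__all__ = [
    "PipelineConfig",
    "write_spike_hdf5",
    "read_spike_hdf5",
    "write_landmarks_csv",
    "read_landmarks_csv",
    "load_config",
    "save_config",
    "config_hash",
]


@dataclass
class PipelineConfig:
    """All thresholds and inputs of one pipeline run."""

    scene: SceneConfig = field(default_factory=SceneConfig)
    protocol: StimulusProtocol = field(default_factory=StimulusProtocol)
    seed: int = 0
    change_thresh_pct: float = 50.0
    radius_um: float = 60.0
    radius_probe_um: float = 200.0
    dsi_osi_cutoff: float = 0.33
    quality_percentile: float = 25.0
    blob_min_size_px: int = 50
    psth_sd_ms: float = 25.0
    psth_dt_ms: float = 1.0
    lwm_neighbors: int = 50
    k_max: int = 8
    gap_B: int = 50
    linkage_method: str = "average"
    cluster_scope: str = "all"  # "all" or "matched"
    nearest_only: bool = False
    density_bin_um: float = 60.0
    density_sigma_bins: float = 3.0


def _to_plain(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _to_plain(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, dict):
        return {k: _to_plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_to_plain(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


def config_to_dict(cfg: PipelineConfig) -> dict:
    return _to_plain(cfg)


def config_from_dict(data: dict) -> PipelineConfig:
    data = dict(data)
    scene = data.pop("scene", {})
    warp = WarpConfig(**scene.pop("warp", {}))
    image = ImageConfig(**scene.pop("image", {}))
    if scene.get("gain_range") is not None:
        scene["gain_range"] = tuple(scene["gain_range"])
    scene_cfg = SceneConfig(warp=warp, image=image, **scene)
    proto = data.pop("protocol", {})
    if "chirp_segments" in proto:
        proto["chirp_segments"] = tuple(
            (str(label), float(a), float(b)) for label, a, b in proto["chirp_segments"])
    if "bar_directions" in proto:
        proto["bar_directions"] = tuple(float(d) for d in proto["bar_directions"])
    protocol = StimulusProtocol(**proto)
    return PipelineConfig(scene=scene_cfg, protocol=protocol, **data)


def save_config(cfg: PipelineConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(config_to_dict(cfg), sort_keys=True))


def load_config(path: str | Path) -> PipelineConfig:
    return config_from_dict(yaml.safe_load(Path(path).read_text()))


def config_hash(cfg: PipelineConfig) -> str:
    canonical = yaml.safe_dump(config_to_dict(cfg), sort_keys=True)
    return hashlib.sha256(canonical.encode()).hexdigest()[:16]


# ----------------------------------------------------------------------
# spike HDF5

def write_spike_hdf5(ds: SpikeDataset, path: str | Path, blind: bool = False) -> None:
    """Write a spike dataset; ``blind=True`` omits the ground truth."""
    with h5py.File(path, "w") as f:
        units = f.create_group("units")
        for unit in ds.units:
            g = units.create_group(str(unit.unit_id))
            eids = sorted(unit.times_by_epoch)
            times = [np.asarray(unit.times_by_epoch[e], dtype=float) for e in eids]
            flat = np.concatenate(times) if times else np.empty(0)
            ids = np.concatenate([np.full(len(t), e, dtype=np.int32)
                                  for e, t in zip(eids, times)]) if times else np.empty(0, np.int32)
            g.create_dataset("times", data=flat)
            g.create_dataset("epoch_ids", data=ids)
            g.create_dataset("centroid", data=np.asarray(unit.centroid_um, dtype=float))
        proto = f.create_group("protocol")
        p = ds.protocol
        proto.attrs.update({
            "n_chirp_trials": p.n_chirp_trials, "n_bar_trials": p.n_bar_trials,
            "bar_epoch_duration_s": p.bar_epoch_duration_s,
            "spont_pre_duration_s": p.spont_pre_duration_s,
            "spont_cno_duration_s": p.spont_cno_duration_s,
        })
        proto.create_dataset("chirp_segment_labels",
                             data=np.array([s[0] for s in p.chirp_segments], dtype="S32"))
        proto.create_dataset("chirp_segment_start",
                             data=np.array([s[1] for s in p.chirp_segments]))
        proto.create_dataset("chirp_segment_end",
                             data=np.array([s[2] for s in p.chirp_segments]))
        proto.create_dataset("bar_directions", data=np.asarray(p.bar_directions, dtype=float))
        cal = f.create_group("calibration")
        cal.attrs.update({
            "um_per_px": ds.calibration.um_per_px,
            "origin_x_um": ds.calibration.origin_offset_um[0],
            "origin_y_um": ds.calibration.origin_offset_um[1],
            "flip_x": ds.calibration.axis_flip[0],
            "flip_y": ds.calibration.axis_flip[1],
        })
        if not blind and ds.truth is not None:
            truth = f.create_group("truth")
            truth.attrs["columns"] = np.array(list(ds.truth.columns), dtype="S32")
            truth.create_dataset("unit_id", data=ds.truth.index.to_numpy(dtype=np.int64))
            for col in ds.truth.columns:
                vals = ds.truth[col].to_numpy()
                if vals.dtype == object:
                    vals = vals.astype("S32")
                truth.create_dataset(col, data=vals)


def read_spike_hdf5(path: str | Path) -> SpikeDataset:
    """Read a spike dataset; raises SchemaError naming any missing group."""
    with h5py.File(path, "r") as f:
        for group in ("units", "protocol", "calibration"):
            if group not in f:
                raise SchemaError(f"missing group /{group} in {path}")
        proto = f["protocol"]
        try:
            labels = [s.decode() for s in proto["chirp_segment_labels"][()]]
            starts = proto["chirp_segment_start"][()]
            ends = proto["chirp_segment_end"][()]
            protocol = StimulusProtocol(
                chirp_segments=tuple(zip(labels, starts.tolist(), ends.tolist())),
                n_chirp_trials=int(proto.attrs["n_chirp_trials"]),
                bar_directions=tuple(proto["bar_directions"][()].tolist()),
                n_bar_trials=int(proto.attrs["n_bar_trials"]),
                bar_epoch_duration_s=float(proto.attrs["bar_epoch_duration_s"]),
                spont_pre_duration_s=float(proto.attrs["spont_pre_duration_s"]),
                spont_cno_duration_s=float(proto.attrs["spont_cno_duration_s"]),
            )
        except KeyError as exc:
            raise SchemaError(f"incomplete /protocol group in {path}: {exc}") from exc
        cal_g = f["calibration"]
        cal = Calibration(
            um_per_px=float(cal_g.attrs["um_per_px"]),
            origin_offset_um=(float(cal_g.attrs["origin_x_um"]),
                              float(cal_g.attrs["origin_y_um"])),
            axis_flip=(int(cal_g.attrs["flip_x"]), int(cal_g.attrs["flip_y"])),
        )
        units = []
        for name in sorted(f["units"], key=int):
            g = f["units"][name]
            for dset in ("times", "epoch_ids", "centroid"):
                if dset not in g:
                    raise SchemaError(f"missing /units/{name}/{dset} in {path}")
            times = g["times"][()]
            eids = g["epoch_ids"][()]
            by_epoch = {int(e): times[eids == e] for e in np.unique(eids)}
            units.append(UnitRecord(int(name), g["centroid"][()], by_epoch))
        truth = None
        if "truth" in f:
            tg = f["truth"]
            data = {}
            for col in tg:
                vals = tg[col][()]
                if vals.dtype.kind == "S":
                    vals = np.array([v.decode() for v in vals], dtype=object)
                data[col] = vals
            truth = pd.DataFrame(data).set_index("unit_id")
            if "columns" in tg.attrs:
                order = [c.decode() for c in tg.attrs["columns"]]
                truth = truth[order]
    return SpikeDataset(units=units, protocol=protocol, calibration=cal, truth=truth)


def write_landmarks_csv(landmarks: LandmarkPairs, path: str | Path) -> None:
    pd.DataFrame({
        "fixed_x": landmarks.fixed_xy[:, 0], "fixed_y": landmarks.fixed_xy[:, 1],
        "moving_x": landmarks.moving_xy[:, 0], "moving_y": landmarks.moving_xy[:, 1],
    }).to_csv(path, index=False)


def read_landmarks_csv(path: str | Path) -> LandmarkPairs:
    df = pd.read_csv(path)
    required = {"fixed_x", "fixed_y", "moving_x", "moving_y"}
    if not required.issubset(df.columns):
        raise SchemaError(f"landmark CSV {path} lacks columns {sorted(required - set(df.columns))}")
    return LandmarkPairs(df[["fixed_x", "fixed_y"]].to_numpy(),
                         df[["moving_x", "moving_y"]].to_numpy())
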