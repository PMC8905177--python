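"""End-to-end pipeline: simulate -> activity -> register -> blobs -> match
-> features -> cluster, with every intermediate table written to disk.

Each stage writes its artefacts into the output directory together with the
configuration hash; stages that consume artefacts verify the hash and abort
on mixtures from different configurations.  The final ``summary.json``
records category counts and the chosen cluster number per motion pool.
"""

from __future__ import annotations

import json
from pathlib import Path

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd
import tifffile

from . import __version__
from .activity import activity_table
from .blobs import detect_blobs
from .clustering import cluster_report, gap_statistic, hierarchical_cluster, unit_distance_matrix
from .errors import ConfigurationError, SchemaError
from .features import feature_table
from .io import (PipelineConfig, config_hash, read_landmarks_csv, read_spike_hdf5,
                 save_config, write_landmarks_csv, write_spike_hdf5)
from .matching import (classify_matches, density_map, distance_change_profile,
                       match_counts, pairwise_unit_blob_distances)
from .registration import fit_lwm, warp_image
from .rendering import render_scene_images
from .synthetic import make_scene, simulate_spikes

__all__ = ["run_pipeline", "simulate_stage"]


def _stamp(out: Path, cfg: PipelineConfig) -> None:
    stamp_path = out / "config_hash.txt"
    h = config_hash(cfg)
    if stamp_path.exists() and stamp_path.read_text().strip() != h:
        raise SchemaError(f"artefact directory {out} carries a different config hash")
    stamp_path.write_text(h + "\n")


def simulate_stage(cfg: PipelineConfig, out: Path, render: bool = True):
    """Generate the synthetic experiment and write all raw inputs."""
    out.mkdir(parents=True, exist_ok=True)
    _stamp(out, cfg)
    save_config(cfg, out / "config.yaml")
    scene = make_scene(cfg.scene, cfg.seed)
    ds = simulate_spikes(scene, cfg.protocol, cfg.seed)
    write_spike_hdf5(ds, out / "spikes.h5")
    if render:
        images = render_scene_images(scene)
        tifffile.imwrite(out / "fixed_vessels.tif", images.fixed_vessels)
        tifffile.imwrite(out / "moving_vessels.tif", images.moving_vessels)
        tifffile.imwrite(out / "gfp_moving.tif", images.gfp_moving)
        write_landmarks_csv(images.landmarks, out / "landmarks.csv")
    return scene, ds


def run_pipeline(cfg: PipelineConfig, out_dir: str | Path) -> dict:
    """Run every stage on a synthetic scene; returns the summary dict."""
    out = Path(out_dir)
    stage = "simulate"
    try:
        scene, ds = simulate_stage(cfg, out)

        stage = "activity"
        ds = read_spike_hdf5(out / "spikes.h5")
        changes = activity_table(ds)
        changes.to_csv(out / "activity.csv", index=False)

        stage = "registration"
        landmarks = read_landmarks_csv(out / "landmarks.csv")
        model = fit_lwm(landmarks, n_neighbors=cfg.lwm_neighbors)
        gfp = tifffile.imread(out / "gfp_moving.tif")
        warped, valid = warp_image(model, gfp)
        tifffile.imwrite(out / "gfp_warped.tif",
                         np.clip(warped, 0, 65535).astype(np.uint16))

        stage = "blobs"
        blobs = detect_blobs(warped, ds.calibration, min_size=cfg.blob_min_size_px)
        blobs.to_csv(out / "blobs.csv")

        stage = "matching"
        centroids = np.array([u.centroid_um for u in ds.units])
        _, nearest = pairwise_unit_blob_distances(centroids, blobs)
        matches = classify_matches(changes, nearest, cfg.radius_um,
                                   cfg.change_thresh_pct, cfg.nearest_only)
        matches.to_csv(out / "match.csv", index=False)
        counts = match_counts(matches)
        profile = None
        if len(blobs):
            profile = distance_change_profile(changes, centroids, blobs,
                                              cfg.radius_probe_um, cfg.change_thresh_pct)
            _plot_profile(profile, cfg, out / "distance_change.png")
        dmap = density_map(centroids, cfg.scene.extent_um,
                           cfg.density_bin_um, cfg.density_sigma_bins)
        np.savetxt(out / "density_map.csv", dmap, delimiter=",")
        tifffile.imwrite(out / "density_map.tif", dmap.astype(np.float32))

        stage = "features"
        feats, grid, psths = feature_table(
            ds, cfg.psth_sd_ms, cfg.psth_dt_ms, cfg.dsi_osi_cutoff, cfg.quality_percentile)
        feats_out = feats.join(matches.set_index("unit_id")[["is_match", "category"]])
        feats_out.to_csv(out / "features.csv")

        stage = "clustering"
        matched_ids = set(matches.loc[matches["is_match"], "unit_id"])
        cluster_summaries = {}
        labels_rows = []
        for pool in ("stationary", "non-stationary"):
            pool_feats = feats[(feats["motion_class"] == pool) & feats["passes_quality"]]
            if cfg.cluster_scope == "matched":
                pool_feats = pool_feats[pool_feats.index.isin(matched_ids)]
            uids = list(pool_feats.index)
            if len(uids) < max(4, 3):
                cluster_summaries[pool] = {"n_units": len(uids), "chosen_k": None}
                continue
            trials = {u.unit_id: u.trial_times(ds.protocol, "chirp")
                      for u in ds.units if u.unit_id in set(uids)}
            dm = unit_distance_matrix(trials, (0.0, ds.protocol.chirp_duration_s))
            k_max = min(cfg.k_max, len(uids) - 1)
            gap = gap_statistic(dm, k_max, cfg.gap_B, cfg.seed, cfg.linkage_method)
            labels, Z = hierarchical_cluster(dm, gap.chosen_k, cfg.linkage_method)
            act_cols = changes.set_index("unit_id").loc[uids, ["d_mfr_pct", "d_burst_pct"]]
            report = cluster_report(dm.unit_ids, labels,
                                    features=pool_feats.join(act_cols),
                                    psths=psths, psth_time=grid, linkage=Z, gap_curve=gap)
            tag = pool.replace("-", "")
            import h5py
            with h5py.File(out / f"distance_{tag}.h5", "w") as f:
                f.create_dataset("D", data=dm.D)
                f.create_dataset("unit_ids", data=np.asarray(dm.unit_ids, dtype=np.int64))
            pd.DataFrame({"unit_id": dm.unit_ids, "cluster": labels}).to_csv(
                out / f"labels_{tag}.csv", index=False)
            pd.DataFrame({"k": gap.k_values, "gap": gap.gap, "s": gap.s,
                          "log_w": gap.log_w}).to_csv(out / f"gap_{tag}.csv", index=False)
            if report.feature_summary is not None:
                report.feature_summary.to_csv(out / f"clusters_{tag}.csv", index=False)
            _plot_clusters(report, out / f"clusters_{tag}.png")
            labels_rows.append(pd.DataFrame({
                "unit_id": dm.unit_ids, "pool": pool, "cluster": labels}))
            cluster_summaries[pool] = {"n_units": len(uids),
                                       "chosen_k": int(gap.chosen_k),
                                       "gap_converged": bool(gap.converged)}
        if labels_rows:
            pd.concat(labels_rows).to_csv(out / "labels.csv", index=False)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    summary = {
        "config_hash": config_hash(cfg),
        "seed": cfg.seed,
        "version": __version__,
        "n_units": len(ds.units),
        "n_blobs": int(len(blobs)),
        "counts": counts,
        "clusters": cluster_summaries,
    }
    if profile is not None and not profile.is_empty:
        summary["change_fwhm_pct"] = _round(profile.change_fwhm_pct)
        summary["supra_distance_fwhm_um"] = _round(profile.supra_distance_fwhm_um)
    (out / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
    return summary


def _round(x: float, nd: int = 6):
    return None if x is None or not np.isfinite(x) else round(float(x), nd)


def _plot_profile(profile, cfg: PipelineConfig, path: Path) -> None:
    fig, ax = plt.subplots(figsize=(5, 4))
    finite = np.isfinite(profile.changes_pct)
    supra = profile.changes_pct > cfg.change_thresh_pct
    ax.scatter(profile.changes_pct[finite & ~supra], profile.distances_um[finite & ~supra],
               s=8, c="tab:blue", label="below threshold")
    ax.scatter(profile.changes_pct[finite & supra], profile.distances_um[finite & supra],
               s=8, c="tab:red", label="above threshold")
    ax.axvline(cfg.change_thresh_pct, ls="--", c="k", lw=0.8)
    ax.axhline(cfg.radius_um, ls=":", c="k", lw=0.8)
    ax.set_xlabel("activity change (%)")
    ax.set_ylabel("distance to GFP soma (µm)")
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def _plot_clusters(report, path: Path) -> None:
    fig, axes = plt.subplots(1, 2, figsize=(9, 3.5))
    for lab, curve in sorted(report.cluster_psth.items()):
        axes[0].plot(report.psth_time, curve, lw=0.9, label=f"#{lab}")
    axes[0].set_xlabel("time (s)")
    axes[0].set_ylabel("rate (Hz)")
    axes[0].legend(fontsize=6)
    if report.gap_curve is not None:
        g = report.gap_curve
        axes[1].errorbar(g.k_values, g.gap, yerr=g.s, marker="o", ms=3, lw=0.9)
        axes[1].axvline(g.chosen_k, ls="--", c="k", lw=0.8)
        axes[1].set_xlabel("k")
        axes[1].set_ylabel("gap")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
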