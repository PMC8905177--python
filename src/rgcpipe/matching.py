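"""Two-factor identification of DREADD-expressing units.

A unit is registered as a DREADD RGC ("match") when its CNO activity change
exceeds the change threshold (default 50%, increases only) AND its spike
centroid lies within the radius (default 60 µm) of a GFP soma centroid.
Units above threshold but with no soma in radius are the amacrine-driven
confound population ("confound"); units below threshold are "quiet".
Several units may match the same soma (somatic and axonal signals can both
fall in radius); a nearest-only mode restricts each soma to its closest
qualifying unit.

Diagnostics mirror the threshold-justification analysis: for every soma all
units within a 200 µm probe radius contribute (distance, change) points,
from which the activity-change marginal (peaked near 0% for unaffected
populations) and the distance distribution of supra-threshold points (peaked
at the AIS offset scale for genuine DREADD units) are summarized by their
FWHM.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter
from scipy.spatial.distance import cdist

from .activity import fwhm
from .blobs import BlobSet
from .errors import ConfigurationError

__all__ = [
    "pairwise_unit_blob_distances",
    "classify_matches",
    "match_counts",
    "distance_change_profile",
    "density_map",
]


def pairwise_unit_blob_distances(unit_xy_um: np.ndarray, blobs: BlobSet
                                 ) -> tuple[np.ndarray, pd.DataFrame]:
    """Euclidean distances for all unit x blob pairs, plus nearest-blob table.

    With an empty blob set the matrix has zero columns and nearest distances
    are NaN (categories then fall to quiet/confound downstream).
    """
    units = np.atleast_2d(np.asarray(unit_xy_um, dtype=float))
    centroids = blobs.centroids_um
    if len(centroids) == 0:
        dmat = np.empty((len(units), 0))
        nearest = pd.DataFrame({
            "nearest_blob_id": np.full(len(units), -1, dtype=int),
            "distance_um": np.full(len(units), np.nan),
        })
        return dmat, nearest
    dmat = cdist(units, centroids)
    idx = np.argmin(dmat, axis=1)
    blob_ids = blobs.table["blob_id"].to_numpy()
    nearest = pd.DataFrame({
        "nearest_blob_id": blob_ids[idx],
        "distance_um": dmat[np.arange(len(units)), idx],
    })
    return dmat, nearest


def classify_matches(changes: pd.DataFrame, nearest: pd.DataFrame,
                     radius_um: float = 60.0, change_thresh_pct: float = 50.0,
                     nearest_only: bool = False) -> pd.DataFrame:
    """Apply the two-factor match rule.

    ``changes`` needs columns ``unit_id`` and ``change_pct``; ``nearest``
    (aligned row-wise) needs ``nearest_blob_id`` and ``distance_um``.
    Returns the MatchTable with ``is_match`` and ``category`` in
    {match, confound, quiet}.
    """
    if len(changes) != len(nearest):
        raise ConfigurationError("changes and nearest tables must align row-wise")
    table = pd.DataFrame({
        "unit_id": changes["unit_id"].to_numpy(),
        "change_pct": changes["change_pct"].to_numpy(dtype=float),
        "nearest_blob_id": nearest["nearest_blob_id"].to_numpy(),
        "distance_um": nearest["distance_um"].to_numpy(dtype=float),
    })
    active = table["change_pct"] > change_thresh_pct
    in_radius = table["distance_um"] <= radius_um  # NaN -> False
    table["is_match"] = active & in_radius
    if nearest_only:
        keep = np.zeros(len(table), dtype=bool)
        cand = table[table["is_match"]]
        for _, grp in cand.groupby("nearest_blob_id"):
            keep[grp["distance_um"].idxmin()] = True
        table["is_match"] = table["is_match"] & keep
    table["category"] = np.where(
        table["is_match"], "match", np.where(active, "confound", "quiet"))
    return table


def match_counts(match_table: pd.DataFrame) -> dict[str, int]:
    counts = match_table["category"].value_counts().to_dict()
    return {cat: int(counts.get(cat, 0)) for cat in ("match", "confound", "quiet")}


@dataclass
class DistanceChangeProfile:
    """Scatter of (distance, change) points around somata + FWHM summaries."""

    distances_um: np.ndarray
    changes_pct: np.ndarray
    change_peak_pct: float
    change_fwhm_pct: float
    supra_distance_peak_um: float
    supra_distance_fwhm_um: float

    @property
    def is_empty(self) -> bool:
        return len(self.distances_um) == 0


def distance_change_profile(changes: pd.DataFrame, unit_xy_um: np.ndarray,
                            blobs: BlobSet, radius_probe_um: float = 200.0,
                            change_thresh_pct: float = 50.0) -> DistanceChangeProfile:
    """Pooled (distance, activity change) points within the probe radius.

    Every unit contributes one point per soma within 200 µm.  The marginal
    change distribution (all points) and the distance distribution of
    supra-threshold points are summarized by KDE peak and FWHM; summaries
    are NaN when fewer than 10 finite samples are available.
    """
    if len(blobs) == 0:
        raise ConfigurationError("distance_change_profile needs at least one blob")
    dmat, _ = pairwise_unit_blob_distances(unit_xy_um, blobs)
    change = changes["change_pct"].to_numpy(dtype=float)
    rows_d, rows_c = [], []
    for j in range(dmat.shape[1]):
        sel = dmat[:, j] <= radius_probe_um
        rows_d.append(dmat[sel, j])
        rows_c.append(change[sel])
    dists = np.concatenate(rows_d) if rows_d else np.empty(0)
    chngs = np.concatenate(rows_c) if rows_c else np.empty(0)

    def _summary(samples: np.ndarray) -> tuple[float, float]:
        finite = samples[np.isfinite(samples)]
        if len(finite) < 10 or np.ptp(finite) == 0:
            return np.nan, np.nan
        return fwhm(finite)

    change_peak, change_width = _summary(chngs)
    supra = dists[chngs > change_thresh_pct]
    supra_peak, supra_width = _summary(supra)
    return DistanceChangeProfile(
        distances_um=dists, changes_pct=chngs,
        change_peak_pct=change_peak, change_fwhm_pct=change_width,
        supra_distance_peak_um=supra_peak, supra_distance_fwhm_um=supra_width)


def density_map(points_um: np.ndarray, extent_um: float,
                bin_um: float = 60.0, smooth_sigma_bins: float = 3.0) -> np.ndarray:
    """Smoothed cell-density map in cells/mm².

    Counts in ``bin_um`` square bins are converted to cells/mm² and
    Gaussian-smoothed with ``smooth_sigma_bins`` (0 disables smoothing).
    """
    pts = np.atleast_2d(np.asarray(points_um, dtype=float))
    edges = np.arange(0.0, extent_um + bin_um, bin_um)
    if pts.size == 0:
        grid = np.zeros((len(edges) - 1, len(edges) - 1))
    else:
        grid, _, _ = np.histogram2d(pts[:, 0], pts[:, 1], bins=(edges, edges))
    grid = grid * (1000.0 / bin_um) ** 2
    if smooth_sigma_bins > 0:
        grid = gaussian_filter(grid, sigma=smooth_sigma_bins, mode="nearest")
    return grid
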