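"""Landmark-based local weighted mean (LWM) registration.

The live blood-vessel image acquired on the MEA is the *fixed* frame; the
post-fixation vessel image (and the GFP image co-registered with it) is the
*moving* frame.  Paired control points picked on vessels define a local
weighted mean transform: around every control point a second-order bivariate
polynomial is fitted to its ``n_neighbors`` nearest control points, and an
arbitrary point is mapped by a weighted average of the local polynomial
predictions, with the cubic falloff weight

    w(R) = 1 - 3 R^2 + 2 R^3,   R = distance / radius_i,  0 for R >= 1,

where ``radius_i`` is the distance from control point ``i`` to its n-th
nearest neighbour.  Points outside every local support are extrapolated with
the nearest control point's polynomial and flagged.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

from .errors import ConfigurationError

__all__ = [
    "Calibration",
    "LandmarkPairs",
    "TransformModel",
    "fit_lwm",
    "apply_transform",
    "warp_image",
    "pixel_to_mea",
]

ELECTRODE_PITCH_UM = 42.0  # 64 x 64 electrode grid -> 2.67 x 2.67 mm array


@dataclass(frozen=True)
class Calibration:
    """Mapping from image pixel indices (0-based, x = column) to MEA µm.

    ``um = origin_offset_um + um_per_px * flip * pixel`` per axis; electrode
    (i, j) sits at (42 i, 42 j) µm.
    """

    um_per_px: float = 1.4
    origin_offset_um: tuple[float, float] = (0.0, 0.0)
    axis_flip: tuple[int, int] = (1, 1)

    def __post_init__(self) -> None:
        if self.um_per_px <= 0:
            raise ConfigurationError("um_per_px must be positive")
        if any(f not in (-1, 1) for f in self.axis_flip):
            raise ConfigurationError("axis_flip entries must be +1 or -1")


def pixel_to_mea(points_px: np.ndarray, cal: Calibration) -> np.ndarray:
    """Convert (x, y) pixel coordinates to µm in the MEA frame."""
    pts = np.atleast_2d(np.asarray(points_px, dtype=float))
    flip = np.asarray(cal.axis_flip, dtype=float)
    out = np.asarray(cal.origin_offset_um, dtype=float) + cal.um_per_px * flip * pts
    return out


def mea_to_pixel(points_um: np.ndarray, cal: Calibration) -> np.ndarray:
    pts = np.atleast_2d(np.asarray(points_um, dtype=float))
    flip = np.asarray(cal.axis_flip, dtype=float)
    return (pts - np.asarray(cal.origin_offset_um, dtype=float)) / cal.um_per_px * flip


@dataclass
class LandmarkPairs:
    """Paired control points: ``fixed_xy[i] <-> moving_xy[i]`` (pixels)."""

    fixed_xy: np.ndarray
    moving_xy: np.ndarray

    def __post_init__(self) -> None:
        self.fixed_xy = np.asarray(self.fixed_xy, dtype=float).reshape(-1, 2)
        self.moving_xy = np.asarray(self.moving_xy, dtype=float).reshape(-1, 2)
        if len(self.fixed_xy) != len(self.moving_xy):
            raise ConfigurationError("fixed and moving landmark lists differ in length")
        if len(np.unique(self.fixed_xy, axis=0)) != len(self.fixed_xy):
            raise ConfigurationError("duplicated fixed landmark positions")

    def __len__(self) -> int:
        return len(self.fixed_xy)

    def swapped(self) -> "LandmarkPairs":
        return LandmarkPairs(self.moving_xy.copy(), self.fixed_xy.copy())


def _design_matrix(xy: np.ndarray, degree: int) -> np.ndarray:
    x, y = xy[:, 0], xy[:, 1]
    cols = [np.ones_like(x)]
    for total in range(1, degree + 1):
        for j in range(total + 1):
            cols.append(x ** (total - j) * y**j)
    return np.column_stack(cols)


@dataclass
class TransformModel:
    """Fitted LWM transform mapping source-frame points to target-frame points.

    For registration use the source frame is the moving (post-fixation)
    image and the target frame is the fixed (MEA) image.
    """

    source_points: np.ndarray  # (n, 2) control points, source frame
    target_points: np.ndarray  # (n, 2) control points, target frame
    coeffs: np.ndarray  # (n, n_terms, 2) local polynomial coefficients
    radii: np.ndarray  # (n,) support radius per control point
    n_neighbors: int
    degree: int
    _tree: cKDTree = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self._tree = cKDTree(self.source_points)

    def transform(self, points: np.ndarray, return_flags: bool = False):
        """Map source-frame points to the target frame.

        Returns the warped points, plus (optionally) a boolean array
        flagging points that fell outside all local supports and were
        extrapolated from the nearest control point.
        """
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        preds = self._local_predictions(pts)  # (m, n, 2)
        dists = np.linalg.norm(pts[:, None, :] - self.source_points[None, :, :], axis=2)
        r = dists / self.radii[None, :]
        w = np.where(r < 1.0, 1.0 - 3.0 * r**2 + 2.0 * r**3, 0.0)
        wsum = w.sum(axis=1)
        extrapolated = wsum <= 0.0
        out = np.empty_like(pts)
        ok = ~extrapolated
        if np.any(ok):
            out[ok] = (w[ok, :, None] * preds[ok]).sum(axis=1) / wsum[ok, None]
        if np.any(extrapolated):
            nearest = np.argmin(dists[extrapolated], axis=1)
            out[extrapolated] = preds[extrapolated, nearest]
        if return_flags:
            return out, extrapolated
        return out

    def _local_predictions(self, pts: np.ndarray) -> np.ndarray:
        design = _design_matrix(pts, self.degree)  # (m, n_terms)
        # (m, n_terms) @ (n_terms, n*2) -> (m, n, 2)
        n = len(self.source_points)
        flat = self.coeffs.reshape(n, -1, 2).transpose(1, 0, 2).reshape(design.shape[1], -1)
        return (design @ flat).reshape(len(pts), n, 2)

    def __call__(self, points: np.ndarray) -> np.ndarray:
        return self.transform(points)


def fit_lwm(landmarks: LandmarkPairs, n_neighbors: int = 50, degree: int = 2) -> TransformModel:
    """Fit the LWM transform mapping moving-frame points to the fixed frame."""
    n_terms = (degree + 1) * (degree + 2) // 2
    n = len(landmarks)
    if n_neighbors < n_terms:
        raise ConfigurationError(
            f"n_neighbors={n_neighbors} below the {n_terms} terms of a degree-{degree} fit")
    if n < n_neighbors:
        raise ConfigurationError(
            f"{n} landmarks provided but n_neighbors={n_neighbors} required")
    source = landmarks.moving_xy
    target = landmarks.fixed_xy
    tree = cKDTree(source)
    dists, idx = tree.query(source, k=n_neighbors)
    radii = dists[:, -1].astype(float)
    if np.any(radii <= 0):
        raise ConfigurationError("duplicated source landmark positions (zero support radius)")
    coeffs = np.empty((n, n_terms, 2))
    for i in range(n):
        nb = idx[i]
        A = _design_matrix(source[nb], degree)
        sol, _, rank, _ = np.linalg.lstsq(A, target[nb], rcond=None)
        if rank < n_terms:
            raise ConfigurationError(
                f"rank-deficient local polynomial fit at control point {i} "
                f"(source position {tuple(source[i])})")
        coeffs[i] = sol
    return TransformModel(source.copy(), target.copy(), coeffs, radii, n_neighbors, degree)


def apply_transform(model: TransformModel, points: np.ndarray,
                    return_flags: bool = False):
    """Map moving-frame points into the fixed frame (thin wrapper)."""
    return model.transform(points, return_flags=return_flags)


def warp_image(model: TransformModel, image: np.ndarray,
               output_shape: tuple[int, int] | None = None,
               grid_step: int = 4):
    """Resample a moving-frame image onto the fixed-frame pixel grid.

    The fixed grid is traversed and mapped back into the moving frame with
    an LWM model fitted in the opposite direction from the same control
    points; the smooth inverse map is evaluated on a ``grid_step``-spaced
    lattice and bilinearly interpolated to full resolution.  Sampling is
    bilinear; pixels falling outside the moving image are set to 0 and
    flagged in the returned validity mask.
    """
    if output_shape is None:
        output_shape = image.shape
    inverse = fit_lwm(
        LandmarkPairs(model.source_points, model.target_points),
        n_neighbors=model.n_neighbors, degree=model.degree)
    h, w = output_shape
    gy = np.arange(0, h + grid_step, grid_step, dtype=float)
    gx = np.arange(0, w + grid_step, grid_step, dtype=float)
    lat = np.column_stack([np.tile(gx, len(gy)), np.repeat(gy, len(gx))])
    coarse = inverse.transform(lat).reshape(len(gy), len(gx), 2)
    yy, xx = np.mgrid[0:h, 0:w]
    # bilinear interpolation of the displacement lattice to every pixel
    mapped = np.empty((h * w, 2))
    for dim in range(2):
        mapped[:, dim] = ndimage.map_coordinates(
            coarse[:, :, dim], [yy.ravel() / grid_step, xx.ravel() / grid_step], order=1)
    mx, my = mapped[:, 0], mapped[:, 1]
    inside = (mx >= 0) & (mx <= image.shape[1] - 1) & (my >= 0) & (my <= image.shape[0] - 1)
    sampled = ndimage.map_coordinates(
        image.astype(float), [my, mx], order=1, mode="constant", cval=0.0)
    sampled[~inside] = 0.0
    warped = sampled.reshape(output_shape)
    valid = inside.reshape(output_shape)
    return warped, valid
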