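"""Rendering of synthetic micrographs: blood vessels, GFP somata, landmarks.

The fixed (live-on-MEA) vessel image is rendered from random smooth curves;
the moving (post-fixation) image re-renders the same curves after applying
the scene's ground-truth warp to the curve points, so landmark pairs sampled
on the curves satisfy ``moving = warp(fixed) + jitter`` exactly by
construction.  The GFP image lives in the moving frame and shows a bright
disk at every warped DREADD soma position on a noisy background with a
smooth gradient.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .errors import GenerationError
from .registration import LandmarkPairs, mea_to_pixel
from .synthetic import GroundTruthScene, WarpParams


@dataclass
class SceneImages:
    fixed_vessels: np.ndarray  # uint16, fixed frame
    moving_vessels: np.ndarray  # uint16, moving frame
    gfp_moving: np.ndarray  # uint16, moving frame
    landmarks: LandmarkPairs  # pixel units


def _vessel_curves(side_px: float, n_vessels: int,
                   rng: np.random.Generator) -> list[np.ndarray]:
    """Random smooth curves crossing the field of view."""
    curves = []
    for _ in range(n_vessels):
        horizontal = rng.uniform() < 0.5
        offset = rng.uniform(0.05, 0.95) * side_px
        u = np.linspace(0.0, side_px, 1500)
        wobble = np.zeros_like(u)
        for _harm in range(3):
            period = rng.uniform(0.3, 1.2) * side_px
            amp = rng.uniform(0.01, 0.05) * side_px
            wobble += amp * np.sin(2 * np.pi * u / period + rng.uniform(0, 2 * np.pi))
        drift = rng.uniform(-0.25, 0.25) * (u - side_px / 2.0)
        other = offset + wobble + drift
        xy = np.column_stack([u, other] if horizontal else [other, u])
        curves.append(xy)
    return curves


def _rasterize(curves: list[np.ndarray], side: int, width_px: int) -> np.ndarray:
    img = np.zeros((side, side), dtype=float)
    for xy in curves:
        cols = np.clip(np.round(xy[:, 0]).astype(int), 0, side - 1)
        rows = np.clip(np.round(xy[:, 1]).astype(int), 0, side - 1)
        inside = (xy[:, 0] >= -0.5) & (xy[:, 0] < side - 0.5) & \
                 (xy[:, 1] >= -0.5) & (xy[:, 1] < side - 0.5)
        img[rows[inside], cols[inside]] = 1.0
    if width_px > 0:
        img = ndimage.grey_dilation(img, size=(width_px * 2 + 1, width_px * 2 + 1))
    return ndimage.gaussian_filter(img, 1.2)


def _to_uint16(img: np.ndarray, peak: float = 40000.0) -> np.ndarray:
    top = img.max()
    if top > 0:
        img = img / top
    return np.clip(img * peak, 0, 65535).astype(np.uint16)


def _check_invertible(warp: WarpParams, side_px: float) -> None:
    """Reject warps that fold the field of view (non-invertible)."""
    k = 2 * np.pi / warp.sine_period_px
    max_grad = max(abs(warp.sine_amp_px[0]), abs(warp.sine_amp_px[1])) * k
    if warp.scale - max_grad <= 0.1:
        raise GenerationError("ground-truth warp is not invertible on the field of view")


def render_scene_images(scene: GroundTruthScene, seed: int | None = None) -> SceneImages:
    """Render fixed/moving vessel images, the moving GFP image and landmarks."""
    cfg = scene.config
    img_cfg = cfg.image
    side = int(round(cfg.extent_um / img_cfg.um_per_px))
    rng = np.random.default_rng(np.random.SeedSequence(
        [scene.rng_seed if seed is None else int(seed), 0x1A6E]))
    _check_invertible(scene.warp, side)

    curves = _vessel_curves(side, img_cfg.n_vessels, rng)
    fixed = _rasterize(curves, side, img_cfg.vessel_width_px)
    moving = _rasterize([scene.warp(c) for c in curves], side, img_cfg.vessel_width_px)

    landmarks = sample_landmarks(curves, scene.warp, img_cfg.n_landmarks,
                                 img_cfg.landmark_jitter_px, side,
                                 img_cfg.landmark_margin_px, rng)
    gfp = render_gfp_image(scene, rng)
    return SceneImages(
        fixed_vessels=_to_uint16(fixed),
        moving_vessels=_to_uint16(moving),
        gfp_moving=gfp,
        landmarks=landmarks,
    )


def sample_landmarks(curves: list[np.ndarray], warp: WarpParams, n_landmarks: int,
                     jitter_px: float, side: int, margin_px: float,
                     rng: np.random.Generator) -> LandmarkPairs:
    """Sample control points on the vessel curves; pairs obey the warp exactly
    (plus the configured picking jitter on the moving side)."""
    pts = np.concatenate(curves, axis=0)
    inside = np.all((pts >= margin_px) & (pts <= side - 1 - margin_px), axis=1)
    pts = pts[inside]
    if len(pts) < n_landmarks:
        raise GenerationError("not enough vessel points inside the margin for landmarks")
    # greedy spaced subsample for spatial coverage
    order = rng.permutation(len(pts))
    chosen: list[int] = []
    min_sep = side / np.sqrt(n_landmarks) / 2.0
    for i in order:
        if len(chosen) == n_landmarks:
            break
        if all(np.hypot(*(pts[i] - pts[j])) >= min_sep for j in chosen):
            chosen.append(i)
    if len(chosen) < n_landmarks:  # relax separation if coverage was too sparse
        extra = [i for i in order if i not in chosen]
        chosen.extend(extra[: n_landmarks - len(chosen)])
    fixed = pts[np.array(chosen)]
    moving = warp(fixed) + rng.normal(0.0, jitter_px, size=(len(fixed), 2))
    return LandmarkPairs(fixed_xy=fixed, moving_xy=moving)


def render_gfp_image(scene: GroundTruthScene, rng: np.random.Generator) -> np.ndarray:
    """GFP image (moving frame): disks at warped DREADD soma positions."""
    cfg = scene.config
    img_cfg = cfg.image
    side = int(round(cfg.extent_um / img_cfg.um_per_px))
    radius_px = img_cfg.soma_diameter_um / img_cfg.um_per_px / 2.0
    amp = img_cfg.gfp_amplitude
    img = np.zeros((side, side), dtype=float)

    soma_px = mea_to_pixel(scene.soma_xy, scene.calibration) if scene.n_somata else np.empty((0, 2))
    dreadd_px = scene.warp(soma_px[scene.is_dreadd]) if scene.n_somata else np.empty((0, 2))
    yy, xx = np.mgrid[0:side, 0:side]
    for cx, cy in dreadd_px:
        if not (0 <= cx < side and 0 <= cy < side):
            continue
        x0, x1 = int(max(cx - radius_px - 3, 0)), int(min(cx + radius_px + 4, side))
        y0, y1 = int(max(cy - radius_px - 3, 0)), int(min(cy + radius_px + 4, side))
        d = np.hypot(xx[y0:y1, x0:x1] - cx, yy[y0:y1, x0:x1] - cy)
        # soft-edged disk (half-pixel antialiasing ramp)
        img[y0:y1, x0:x1] += amp * np.clip(radius_px - d + 0.5, 0.0, 1.0)

    gx = np.linspace(0.0, 1.0, side)
    background = img_cfg.background_frac * amp * np.outer(
        0.5 + 0.5 * gx, 0.3 + 0.7 * gx)
    noise = rng.normal(0.0, amp / img_cfg.gfp_snr, size=img.shape)
    out = np.clip(img + background + noise, 0, 65535)
    return out.astype(np.uint16)
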