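"""Seeded generator of paired conventional/CEUS-like ultrasound phantoms.

Each pair shares one elliptical region of interest (the "perfused"
tissue).  The conventional image is a grayscale speckle phantom: a dim
background plus a brighter ROI, multiplied by gamma-distributed speckle of
mean 1, replicated across the three channels.  The CEUS counterpart uses a
stronger ROI gain (contrast agent pools in perfused tissue) and a
per-channel tint emulating the colormap of contrast-mode display.  Ground
truth masks accompany every pair, so segmentation-format export and
contrast checks need no external data.

The generator reproduces the statistical structure the decomposition
pipeline relies on — a coherent bright region, multiplicative speckle,
cross-channel intensity ratios — not ultrasound physics: there is no wave
propagation, attenuation, or perfusion time dynamics.

Every draw is a pure function of ``(params.seed, pair_index)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["SyntheticParams", "SyntheticDataset", "generate_pair", "generate_dataset", "mask_to_polygon"]


@dataclass
class SyntheticParams:
    """Phantom geometry and noise parameters.

    ROI geometry is sampled per pair: the ellipse center is jittered
    uniformly within ``center_jitter`` pixels of the frame center, the
    semi-axes uniformly within ``semi_axis_range`` (pixels), the rotation
    uniformly within ``rotation_range`` (radians).  ``speckle_shape`` is
    the gamma shape of the multiplicative noise (mean 1, variance
    1/shape); larger is cleaner.  With ``shared_speckle`` both modalities
    reuse one speckle field (useful for degenerate-equality checks).
    """

    height: int = 64
    width: int = 64
    n_pairs: int = 16
    center_jitter: float = 6.0
    semi_axis_range: tuple[float, float] = (8.0, 16.0)
    rotation_range: tuple[float, float] = (0.0, np.pi)
    background_level: float = 0.15
    roi_gain_conv: float = 0.35
    roi_gain_ceus: float = 0.5
    ceus_tint: tuple[float, float, float] = (1.0, 0.8, 0.45)
    speckle_shape: float = 30.0
    shared_speckle: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.height < 8 or self.width < 8:
            raise ValueError("frame must be at least 8x8")
        if self.n_pairs < 1:
            raise ValueError("n_pairs must be >= 1")
        if self.background_level <= 0 or self.roi_gain_conv <= 0 or self.roi_gain_ceus <= 0:
            raise ValueError("background and ROI gains must be > 0")
        if any(g <= 0 for g in self.ceus_tint):
            raise ValueError("ceus_tint gains must be > 0")
        if self.speckle_shape <= 0:
            raise ValueError("speckle_shape must be > 0")
        lo, hi = self.semi_axis_range
        if not 0 < lo <= hi:
            raise ValueError("semi_axis_range must satisfy 0 < lo <= hi")
        half = min(self.height, self.width) / 2.0
        if self.center_jitter + hi > half:
            raise ValueError(
                f"ellipse ranges exceed frame: center_jitter {self.center_jitter} + "
                f"max semi-axis {hi} > half frame {half}"
            )


@dataclass
class SyntheticDataset:
    """Paired stacks with ground-truth masks and the geometry manifest."""

    conv: np.ndarray  # (N, H, W, 3)
    ceus: np.ndarray  # (N, H, W, 3)
    masks: np.ndarray  # (N, H, W) uint8
    manifest: list[dict] = field(default_factory=list)


def _pair_rng(params: SyntheticParams, index: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([params.seed, index]))


def _ellipse_mask(
    h: int, w: int, cy: float, cx: float, a: float, b: float, theta: float
) -> np.ndarray:
    yy, xx = np.mgrid[0:h, 0:w]
    dy, dx = yy - cy, xx - cx
    ct, st = np.cos(theta), np.sin(theta)
    u = dx * ct + dy * st
    v = -dx * st + dy * ct
    return ((u / a) ** 2 + (v / b) ** 2 <= 1.0).astype(np.uint8)


def generate_pair(
    params: SyntheticParams, index: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray, dict]:
    """One (conventional, CEUS, mask, geometry) phantom tuple.

    Deterministic in (params.seed, index).
    """
    rng = _pair_rng(params, index)
    h, w = params.height, params.width
    lo, hi = params.semi_axis_range
    cy = h / 2.0 + rng.uniform(-params.center_jitter, params.center_jitter)
    cx = w / 2.0 + rng.uniform(-params.center_jitter, params.center_jitter)
    a = rng.uniform(lo, hi)
    b = rng.uniform(lo, hi)
    theta = rng.uniform(*params.rotation_range)
    mask = _ellipse_mask(h, w, cy, cx, a, b, theta)

    shape = params.speckle_shape
    speckle_conv = rng.gamma(shape, 1.0 / shape, size=(h, w))
    speckle_ceus = (
        speckle_conv if params.shared_speckle else rng.gamma(shape, 1.0 / shape, size=(h, w))
    )

    conv_template = params.background_level + params.roi_gain_conv * mask
    conv = np.clip(conv_template * speckle_conv, 0.0, 1.0)
    conv = np.repeat(conv[:, :, np.newaxis], 3, axis=2)

    ceus_template = params.background_level + params.roi_gain_ceus * mask
    ceus_gray = ceus_template * speckle_ceus
    tint = np.asarray(params.ceus_tint)
    ceus = np.clip(ceus_gray[:, :, np.newaxis] * tint, 0.0, 1.0)

    geometry = {
        "index": index,
        "center": [round(cy, 4), round(cx, 4)],
        "semi_axes": [round(a, 4), round(b, 4)],
        "rotation": round(theta, 6),
    }
    return conv, ceus, mask, geometry


def generate_dataset(params: SyntheticParams) -> SyntheticDataset:
    """Paired stacks of ``n_pairs`` phantoms with per-pair masks and manifest."""
    conv_list, ceus_list, mask_list, manifest = [], [], [], []
    for i in range(params.n_pairs):
        conv, ceus, mask, geometry = generate_pair(params, i)
        conv_list.append(conv)
        ceus_list.append(ceus)
        mask_list.append(mask)
        manifest.append(geometry)
    return SyntheticDataset(
        conv=np.stack(conv_list),
        ceus=np.stack(ceus_list),
        masks=np.stack(mask_list),
        manifest=manifest,
    )


def mask_to_polygon(mask: np.ndarray, max_points: int = 64) -> list[tuple[float, float]]:
    """Trace the largest contour of a binary mask as normalized (x, y) points.

    Suitable for YOLO segmentation label lines (class followed by
    alternating normalized x y coordinates).  Returns [] for empty masks.
    """
    from skimage import measure

    mask = np.asarray(mask)
    if mask.max() == 0:
        return []
    contours = measure.find_contours(mask.astype(float), 0.5)
    contour = max(contours, key=len)
    if len(contour) > max_points:
        idx = np.linspace(0, len(contour) - 1, max_points).astype(int)
        contour = contour[idx]
    h, w = mask.shape
    return [(float(c / w), float(r / h)) for r, c in contour]
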