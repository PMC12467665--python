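"""Per-channel two-dimensional PCA (2DPCA) on RGB image stacks.

Classical 2DPCA operates on grayscale image matrices directly: the W x W
column scatter matrix of the training set is eigendecomposed, and its
leading eigenvectors serve as projection axes.  Here the decomposition is
applied independently to each of the three color channels of an image
stack, which preserves spectral differences between tissue types (and, for
contrast-enhanced ultrasound, between perfusion phases) that a grayscale
reduction would discard.

Conventions used throughout the package:

* an image is a float array of shape ``(H, W, 3)`` with intensities in
  ``[0, 1]`` after loading;
* a stack is an array of shape ``(N, H, W, 3)``;
* the channel axis is always last, so per-channel matrices (covariance,
  eigenvectors, projections) have shape ``(..., 3)``;
* a selection mask is a ``(d, 3)`` binary array, ``d`` being the image
  width ``W`` (the number of projection axes per channel).

The projection step multiplies the *raw* image by the eigenvector basis
(``Y = O W``) and reconstruction sums outer products ``Y_j W_j^T`` without
re-adding a mean term.  That is the literal form of the method as used for
feature selection; the conventional centered variant (project ``O - mean``,
add the mean back on reconstruction) is available via
``centered_reconstruction=True`` on the helpers that take it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np

logger = logging.getLogger("flfsi")

#: file extensions accepted by the directory reader, lexicographic order
IMAGE_EXTENSIONS = (".png", ".jpg", ".jpeg", ".tif", ".tiff")

_SYMMETRY_TOL = 1e-9
_PSD_TOL = 1e-8


class ShapeError(ValueError):
    """Raised when array shapes violate an operation's contract."""


# ---------------------------------------------------------------------------
# validation helpers
# ---------------------------------------------------------------------------

def as_image(pixels: np.ndarray) -> np.ndarray:
    """Validate and return an (H, W, 3) float image."""
    arr = np.asarray(pixels, dtype=np.float64)
    if arr.ndim != 3 or arr.shape[2] != 3:
        raise ShapeError(f"image must have shape (H, W, 3), got {arr.shape}")
    if arr.shape[0] < 2 or arr.shape[1] < 2:
        raise ShapeError(f"image must be at least 2x2, got {arr.shape[:2]}")
    if not np.all(np.isfinite(arr)):
        raise ValueError("image contains non-finite intensities")
    if np.any(arr < 0):
        raise ValueError("image contains negative intensities")
    return arr


def as_stack(images) -> np.ndarray:
    """Validate a sequence of same-shape images and return an (N, H, W, 3) array."""
    if isinstance(images, np.ndarray) and images.ndim == 4:
        images = list(images)
    images = list(images)
    if len(images) == 0:
        raise ShapeError("empty stack")
    first = as_image(images[0])
    out = np.empty((len(images),) + first.shape, dtype=np.float64)
    out[0] = first
    for i, img in enumerate(images[1:], start=1):
        arr = as_image(img)
        if arr.shape != first.shape:
            raise ShapeError(
                f"stack image {i} has shape {arr.shape}, expected {first.shape}"
            )
        out[i] = arr
    return out


@dataclass(frozen=True)
class ProjectionBasis:
    """Per-channel eigenvector basis of the channel covariance matrices.

    Attributes
    ----------
    vectors : ndarray, shape (W, W, 3)
        ``vectors[:, j, c]`` is the j-th projection axis of channel ``c``.
        Columns are orthonormal; eigenvalue order is non-increasing.
    values : ndarray, shape (W, 3)
        Eigenvalues matching the column order.
    """

    vectors: np.ndarray
    values: np.ndarray

    @property
    def dim(self) -> int:
        return self.vectors.shape[0]


# ---------------------------------------------------------------------------
# decomposition
# ---------------------------------------------------------------------------

def compute_mean_image(stack: np.ndarray) -> np.ndarray:
    """Elementwise mean image of the training stack, shape (H, W, 3)."""
    stack = as_stack(stack)
    return stack.mean(axis=0)


def compute_covariance(stack: np.ndarray, mean: np.ndarray | None = None) -> np.ndarray:
    """Per-channel column scatter matrices, shape (W, W, 3).

    For each channel c the scatter is (1/N) sum_i (O_i^c - mean^c)^T
    (O_i^c - mean^c): a W x W symmetric positive semi-definite matrix.
    The 1/N normalization (not 1/(N-1)) is deliberate.
    """
    stack = as_stack(stack)
    if mean is None:
        mean = stack.mean(axis=0)
    mean = np.asarray(mean, dtype=np.float64)
    if mean.shape != stack.shape[1:]:
        raise ShapeError(
            f"mean shape {mean.shape} does not match stack images {stack.shape[1:]}"
        )
    centered = stack - mean  # (N, H, W, 3)
    # sum over images and rows of X^T X per channel
    cov = np.einsum("nhjc,nhkc->jkc", centered, centered) / stack.shape[0]
    cov = 0.5 * (cov + cov.transpose(1, 0, 2))  # enforce exact symmetry
    return cov


def eigendecompose(cov: np.ndarray) -> ProjectionBasis:
    """Full eigendecomposition of each channel's covariance matrix.

    Eigenvalues are returned in non-increasing order.  Each eigenvector's
    sign is fixed so that its first nonzero entry is non-negative, making
    the basis reproducible across platforms and LAPACK builds.
    """
    cov = np.asarray(cov, dtype=np.float64)
    if cov.ndim != 3 or cov.shape[0] != cov.shape[1] or cov.shape[2] != 3:
        raise ShapeError(f"covariance set must have shape (W, W, 3), got {cov.shape}")
    asym = np.max(np.abs(cov - cov.transpose(1, 0, 2)))
    if asym > _SYMMETRY_TOL:
        raise ValueError(f"covariance not symmetric (max asymmetry {asym:.3e})")
    w = cov.shape[0]
    vectors = np.empty((w, w, 3))
    values = np.empty((w, 3))
    for c in range(3):
        lam, vec = np.linalg.eigh(cov[:, :, c])
        order = np.argsort(lam)[::-1]
        lam, vec = lam[order], vec[:, order]
        vec = _fix_signs(vec)
        values[:, c] = lam
        vectors[:, :, c] = vec
    return ProjectionBasis(vectors=vectors, values=values)


def _fix_signs(vec: np.ndarray) -> np.ndarray:
    """Flip columns so the first entry of magnitude > 1e-12 is positive."""
    vec = vec.copy()
    for j in range(vec.shape[1]):
        col = vec[:, j]
        nz = np.nonzero(np.abs(col) > 1e-12)[0]
        if nz.size and col[nz[0]] < 0:
            vec[:, j] = -col
    return vec


def fit_basis(stack: np.ndarray) -> ProjectionBasis:
    """Convenience: mean -> covariance -> eigendecomposition in one call."""
    stack = as_stack(stack)
    return eigendecompose(compute_covariance(stack))


# ---------------------------------------------------------------------------
# projection / reconstruction
# ---------------------------------------------------------------------------

def project(image: np.ndarray, basis: ProjectionBasis) -> np.ndarray:
    """Project an image onto the basis: Y^c = O^c W^c, shape (H, W, 3).

    Column ``j`` of channel ``c`` (``Y[:, j, c]``) is the projected feature
    vector for axis ``j``.  The raw image is projected, not the centered one.
    """
    image = np.asarray(image, dtype=np.float64)
    if image.ndim != 3 or image.shape[2] != 3:
        raise ShapeError(f"image must have shape (H, W, 3), got {image.shape}")
    if image.shape[1] != basis.dim:
        raise ShapeError(
            f"image width {image.shape[1]} does not match basis dimension {basis.dim}"
        )
    return np.einsum("hwc,wjc->hjc", image, basis.vectors)


def reconstruct(
    projection: np.ndarray, basis: ProjectionBasis, mask: np.ndarray
) -> np.ndarray:
    """Partial reconstruction sum_{j: mask[j,c]=1} Y_j^c (W_j^c)^T.

    Output is not clipped; clipping to [0, 1] happens only at export.
    """
    projection = np.asarray(projection, dtype=np.float64)
    mask = validate_mask(mask, basis.dim)
    if projection.ndim != 3 or projection.shape[1] != basis.dim:
        raise ShapeError(
            f"projection shape {projection.shape} incompatible with basis dim {basis.dim}"
        )
    masked = projection * mask[np.newaxis, :, :]
    return np.einsum("hjc,wjc->hwc", masked, basis.vectors)


def validate_mask(mask: np.ndarray, d: int | None = None) -> np.ndarray:
    """Check a (d, 3) binary selection mask and return it as uint8."""
    mask = np.asarray(mask)
    if mask.ndim != 2 or mask.shape[1] != 3:
        raise ShapeError(f"selection mask must have shape (d, 3), got {mask.shape}")
    if d is not None and mask.shape[0] != d:
        raise ShapeError(f"selection mask has d={mask.shape[0]}, expected {d}")
    if not np.isin(mask, (0, 1)).all():
        raise ValueError("selection mask entries must be 0 or 1")
    return mask.astype(np.uint8)


def frobenius_error(x: np.ndarray, xhat: np.ndarray) -> tuple[np.ndarray, float]:
    """Per-channel Frobenius distortion ||X^c - Xhat^c||_F and their sum."""
    x = np.asarray(x, dtype=np.float64)
    xhat = np.asarray(xhat, dtype=np.float64)
    if x.shape != xhat.shape:
        raise ShapeError(f"shape mismatch: {x.shape} vs {xhat.shape}")
    diff = x - xhat
    per_channel = np.sqrt(np.einsum("hwc,hwc->c", diff, diff))
    return per_channel, float(per_channel.sum())


def topk_mask(d: int, k: int) -> np.ndarray:
    """Mask selecting the first k (largest-eigenvalue) components on all channels."""
    if not 1 <= k <= d:
        raise ValueError(f"k must be in [1, {d}], got {k}")
    mask = np.zeros((d, 3), dtype=np.uint8)
    mask[:k, :] = 1
    return mask


def reconstruct_image(
    image: np.ndarray,
    basis: ProjectionBasis,
    mask: np.ndarray,
    *,
    centered_reconstruction: bool = False,
    mean: np.ndarray | None = None,
) -> np.ndarray:
    """Project then partially reconstruct one image.

    With ``centered_reconstruction`` the mean image is removed before
    projection and added back afterwards (the conventional PCA variant);
    the default projects and reconstructs the raw image.
    """
    if centered_reconstruction:
        if mean is None:
            raise ValueError("centered_reconstruction requires the stack mean")
        return reconstruct(project(image - mean, basis), basis, mask) + mean
    return reconstruct(project(image, basis), basis, mask)


# ---------------------------------------------------------------------------
# image I/O
# ---------------------------------------------------------------------------

def load_image(path: str | Path) -> np.ndarray:
    """Load one image file as an (H, W, 3) float array in [0, 1].

    8-bit and 16-bit integer images are rescaled by their type maximum.
    Grayscale inputs are replicated across the three channels (logged);
    an alpha channel, if present, is dropped.
    """
    import imageio.v3 as iio

    raw = iio.imread(Path(path))
    arr = np.asarray(raw)
    if np.issubdtype(arr.dtype, np.integer):
        arr = arr.astype(np.float64) / np.iinfo(raw.dtype).max
    else:
        arr = arr.astype(np.float64)
    if arr.ndim == 2:
        logger.warning("grayscale image %s replicated to 3 channels", path)
        arr = np.repeat(arr[:, :, np.newaxis], 3, axis=2)
    elif arr.shape[2] == 4:
        arr = arr[:, :, :3]
    return as_image(np.clip(arr, 0.0, None))


def load_stack(directory: str | Path) -> tuple[np.ndarray, list[str]]:
    """Load all images in a directory (lexicographic order defines stack order)."""
    directory = Path(directory)
    if not directory.is_dir():
        raise FileNotFoundError(f"image directory not found: {directory}")
    paths = sorted(
        p for p in directory.iterdir() if p.suffix.lower() in IMAGE_EXTENSIONS
    )
    if not paths:
        raise FileNotFoundError(f"no images ({'/'.join(IMAGE_EXTENSIONS)}) in {directory}")
    return as_stack([load_image(p) for p in paths]), [p.name for p in paths]


def save_image(path: str | Path, image: np.ndarray) -> None:
    """Write an image: 8-bit PNG (clipped to [0,1], scaled) or float32 TIFF (unclipped)."""
    path = Path(path)
    image = np.asarray(image, dtype=np.float64)
    if path.suffix.lower() in (".tif", ".tiff"):
        import tifffile

        tifffile.imwrite(path, image.astype(np.float32), photometric="rgb")
    else:
        import imageio.v3 as iio

        out = np.clip(image, 0.0, 1.0)
        iio.imwrite(path, np.round(out * 255).astype(np.uint8))
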