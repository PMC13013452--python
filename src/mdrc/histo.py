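"""Histology-side statistics: patch-wise structure-tensor coherency and
optical density of stained sections.

The structure tensor of a grayscale image is the local average of the outer
product of its smoothed intensity gradients.  Its eigenvalues per patch give
the coherency

    C = (lambda_max - lambda_min) / (lambda_max + lambda_min),

1 for perfectly parallel structures (coherent fiber bundles), 0 for
isotropic texture or flat patches (convention: C = 0 where both eigenvalues
vanish).  Patches tile the image without overlap; the default patch is
70 um to match an in-plane MRI voxel.

Optical density per pixel is OD = max(0, -ln(I / I_background)) with a
manually chosen background threshold, patch-averaged and normalized to
[0, 1] by the image's maximum per-pixel OD.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage


def patch_size_px(patch_um: float = 70.0, pixel_um: float = 1.0) -> int:
    n = int(round(patch_um / pixel_um))
    if n < 1:
        raise ValueError("patch smaller than one pixel")
    return n


def _patch_view(arr: np.ndarray, patch_px: int) -> np.ndarray:
    """Crop to full patches and reshape to (py, px, patch, patch)."""
    ny = arr.shape[0] // patch_px
    nx = arr.shape[1] // patch_px
    if ny < 1 or nx < 1:
        raise ValueError("image smaller than one patch")
    crop = arr[: ny * patch_px, : nx * patch_px]
    return crop.reshape(ny, patch_px, nx, patch_px).swapaxes(1, 2)


def structure_tensor_coherency(image: np.ndarray, patch_px: int,
                               sigma: float = 2.0) -> np.ndarray:
    """Per-patch coherency of a 2D grayscale image.

    Gradients are estimated with Gaussian-derivative filters of width
    ``sigma`` (pixels); the structure tensor is averaged over the pixels of
    each non-overlapping patch.
    """
    image = np.asarray(image, dtype=float)
    if image.ndim != 2:
        raise ValueError("image must be 2D grayscale")
    gy = ndimage.gaussian_filter(image, sigma, order=(1, 0))
    gx = ndimage.gaussian_filter(image, sigma, order=(0, 1))
    jxx = _patch_view(gx * gx, patch_px).mean(axis=(2, 3))
    jyy = _patch_view(gy * gy, patch_px).mean(axis=(2, 3))
    jxy = _patch_view(gx * gy, patch_px).mean(axis=(2, 3))
    trace = jxx + jyy
    disc = np.sqrt(((jxx - jyy) / 2.0) ** 2 + jxy ** 2)
    with np.errstate(invalid="ignore", divide="ignore"):
        coh = np.where(trace > 0, 2.0 * disc / trace, 0.0)
    return np.clip(coh, 0.0, 1.0)


def optical_density(image: np.ndarray, background_threshold: float,
                    patch_px: int | None = None
                    ) -> tuple[np.ndarray, np.ndarray | None]:
    """(per-pixel OD, per-patch OD or None), both normalized to [0, 1]."""
    image = np.asarray(image, dtype=float)
    if image.ndim != 2:
        raise ValueError("image must be 2D grayscale")
    if background_threshold <= 0:
        raise ValueError("background_threshold must be > 0")
    with np.errstate(divide="ignore"):
        od = np.maximum(0.0, -np.log(np.maximum(image, 1e-300)
                                     / background_threshold))
    od_max = od.max()
    if od_max > 0:
        od_norm = od / od_max
    else:
        od_norm = od
    if patch_px is None:
        return od_norm, None
    patches = _patch_view(od, patch_px).mean(axis=(2, 3))
    if od_max > 0:
        patches = patches / od_max
    return od_norm, patches
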