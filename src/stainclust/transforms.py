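"""Random affine augmentations for the consistency penalty.

Each patch receives one randomly sampled rotation + translation +
scaling, applied identically to all of its stain channels so the
co-registration of the stack is preserved. The transformed copy is what
the affine KL penalty compares against the original.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

__all__ = ["AffineRanges", "apply_affine", "random_affine"]


@dataclass(frozen=True)
class AffineRanges:
    """Sampling ranges for the augmentation, mild enough to keep class identity."""

    angle_deg: tuple[float, float] = (-30.0, 30.0)
    shift_frac: tuple[float, float] = (-0.1, 0.1)
    scale: tuple[float, float] = (0.9, 1.1)

    def __post_init__(self):
        if self.scale[0] <= 0 or self.scale[1] <= 0:
            raise ValueError("scale range must be positive")
        for lo, hi in (self.angle_deg, self.shift_frac, self.scale):
            if hi < lo:
                raise ValueError("range bounds must be ordered (lo, hi)")


def apply_affine(
    patch: np.ndarray,
    angle_deg: float,
    shift_frac: tuple[float, float],
    scale: float,
) -> np.ndarray:
    """Rotate/scale about the center then translate one (C, H, W) patch.

    Bilinear interpolation with reflected borders; all channels share
    the transform. Values are clipped back to [0, 1].
    """
    if scale <= 0:
        raise ValueError("scale must be positive")
    c, h, w = patch.shape
    theta = np.deg2rad(angle_deg)
    cos_t, sin_t = np.cos(theta), np.sin(theta)
    # Output->input mapping: inverse rotation and inverse scale about the center,
    # then subtract the translation (rows = y axis, cols = x axis).
    rot = np.array([[cos_t, -sin_t], [sin_t, cos_t]]) / scale
    center = np.array([(h - 1) / 2.0, (w - 1) / 2.0])
    shift = np.array([shift_frac[0] * h, shift_frac[1] * w])
    offset = center - rot @ (center + shift)
    matrix = np.zeros((3, 3))
    matrix[0, 0] = 1.0
    matrix[1:, 1:] = rot
    full_offset = np.array([0.0, offset[0], offset[1]])
    out = ndimage.affine_transform(
        patch, matrix, offset=full_offset, order=1, mode="reflect", prefilter=False
    )
    return np.clip(out, 0.0, 1.0).astype(patch.dtype)


def _batch_affine(
    patches: np.ndarray,
    angles: np.ndarray,
    shifts: np.ndarray,
    scales: np.ndarray,
) -> np.ndarray:
    """Batched bilinear warp of (N, C, H, W) with one transform per patch.

    Matches :func:`apply_affine` (rotation and scaling about the center,
    then translation; reflected borders) but runs as one batched kernel.
    """
    from .nn._kernels import warp_bilinear

    n, c, h, w = patches.shape
    theta = np.deg2rad(angles)
    cos_t, sin_t = np.cos(theta), np.sin(theta)
    # Per-patch output->input 2x2 maps (rows = y axis, cols = x axis).
    rot = np.empty((n, 2, 2))
    rot[:, 0, 0] = cos_t
    rot[:, 0, 1] = -sin_t
    rot[:, 1, 0] = sin_t
    rot[:, 1, 1] = cos_t
    rot /= scales[:, None, None]
    center = np.array([(h - 1) / 2.0, (w - 1) / 2.0])
    shift_px = shifts * np.array([h, w])
    offset = center[None, :] - np.einsum("nij,nj->ni", rot, center[None, :] + shift_px)
    return warp_bilinear(patches, rot, offset)


def random_affine(
    patches: np.ndarray,
    ranges: AffineRanges = AffineRanges(),
    seed: int = 0,
) -> np.ndarray:
    """Apply an independently sampled affine map to each patch in (N, C, H, W).

    Every channel of a patch receives the same transform; the sampling
    stream is fixed by `seed`.
    """
    patches = np.asarray(patches)
    if patches.ndim != 4:
        raise ValueError("expected an (N, C, H, W) patch batch")
    n = len(patches)
    if n == 0:
        return patches.copy()
    rng = np.random.default_rng(seed)
    params = rng.uniform(size=(n, 4))
    angles = ranges.angle_deg[0] + params[:, 0] * (ranges.angle_deg[1] - ranges.angle_deg[0])
    shifts = ranges.shift_frac[0] + params[:, 1:3] * (
        ranges.shift_frac[1] - ranges.shift_frac[0]
    )
    scales = ranges.scale[0] + params[:, 3] * (ranges.scale[1] - ranges.scale[0])
    return _batch_affine(patches, angles, shifts, scales)
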