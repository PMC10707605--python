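"""Reading stain stacks, cutting patches, tiling and normalization.

A whole-slide image (WSI) arrives as five co-registered RGB renditions
of the same tissue, one per stain, stacked channel-wise into a single
(C, H, W) array with C = 3 x n_stains. Patches are cut either at random
anchors (training sets) or as a sequential non-overlapping grid
(whole-slide cluster maps); in both cases the same anchor is applied to
every stain channel so patches stay co-registered.

Coordinates are 0-based and row-major; tiles are half-open
``[r*t, (r+1)*t) x [c*t, (c+1)*t)`` squares, and remainder strips that
do not fit a full tile are discarded.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile

__all__ = [
    "STAIN_ORDER",
    "MultiStainPatchSet",
    "TileGrid",
    "tile_grid",
    "cut_tiles",
    "sample_random_patches",
    "effective_resolution",
    "normalize_image",
    "save_patchset",
    "load_patchset",
    "load_stain_stack",
]

#: Default stacking order of the stain panel (config-overridable).
STAIN_ORDER = ("HE", "MT", "CD31", "CK19", "Ki67")


@dataclass
class MultiStainPatchSet:
    """N patches x C channels x H x W in [0, 1], with optional anchors."""

    data: np.ndarray
    positions: np.ndarray | None = None
    source_id: str | None = None

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 4:
            raise ValueError("patch data must be (N, C, H, W)")
        if self.data.size and (self.data.min() < 0 or self.data.max() > 1):
            raise ValueError("patch values must lie in [0, 1]")
        if self.positions is not None:
            self.positions = np.asarray(self.positions)
            if len(self.positions) != len(self.data):
                raise ValueError("positions and data lengths differ")

    def __len__(self) -> int:
        return len(self.data)

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def patch_size(self) -> int:
        return self.data.shape[2]


@dataclass(frozen=True)
class TileGrid:
    """Row-major non-overlapping tiling of an image; remainders discarded."""

    height_px: int
    width_px: int
    tile_size: int

    def __post_init__(self):
        if self.tile_size <= 0:
            raise ValueError("tile_size must be positive")
        if self.height_px <= 0 or self.width_px <= 0:
            raise ValueError("image dimensions must be positive")

    @property
    def n_rows(self) -> int:
        return self.height_px // self.tile_size

    @property
    def n_cols(self) -> int:
        return self.width_px // self.tile_size

    @property
    def count(self) -> int:
        return self.n_rows * self.n_cols

    def anchors(self) -> np.ndarray:
        """(count, 2) array of (row_px, col_px) top-left corners, row-major."""
        t = self.tile_size
        rr, cc = np.meshgrid(
            np.arange(self.n_rows) * t, np.arange(self.n_cols) * t, indexing="ij"
        )
        return np.stack([rr.ravel(), cc.ravel()], axis=1)


def tile_grid(height_px: int, width_px: int, tile_size: int) -> TileGrid:
    """Plan a sequential non-overlapping tiling of a height x width image."""
    return TileGrid(height_px, width_px, tile_size)


def cut_tiles(stack: np.ndarray, tile_size: int) -> MultiStainPatchSet:
    """Cut a (C, H, W) stain stack into its full sequential tile grid."""
    c, h, w = stack.shape
    grid = tile_grid(h, w, tile_size)
    anchors = grid.anchors()
    patches = np.empty((grid.count, c, tile_size, tile_size), dtype=stack.dtype)
    for i, (r, col) in enumerate(anchors):
        patches[i] = stack[:, r : r + tile_size, col : col + tile_size]
    return MultiStainPatchSet(patches, positions=anchors)


def sample_random_patches(
    stack: np.ndarray, n: int, size: int, seed: int = 0
) -> MultiStainPatchSet:
    """Cut `n` patches at uniform random anchors (with replacement).

    The same anchor is applied to every stain channel of the stack.
    """
    c, h, w = stack.shape
    if size > min(h, w):
        raise ValueError(f"patch size {size} exceeds image extent {h}x{w}")
    rng = np.random.default_rng(seed)
    rows = rng.integers(0, h - size + 1, size=n)
    cols = rng.integers(0, w - size + 1, size=n)
    patches = np.empty((n, c, size, size), dtype=stack.dtype)
    for i, (r, col) in enumerate(zip(rows, cols)):
        patches[i] = stack[:, r : r + size, col : col + size]
    return MultiStainPatchSet(patches, positions=np.stack([rows, cols], axis=1))


def effective_resolution(base_um_per_px: float, linear_scale: float) -> float:
    """Micrometres per pixel after resizing an image by `linear_scale`.

    Shrinking the image (scale < 1) makes each remaining pixel cover more
    tissue, so the resolution coarsens to ``base / scale``: e.g. a
    0.22 um/px scan resized to 70% of its linear size is 0.31 um/px.
    """
    if base_um_per_px <= 0 or linear_scale <= 0:
        raise ValueError("resolution and scale must be positive")
    if linear_scale > 1:
        raise ValueError("linear_scale must be in (0, 1]")
    return base_um_per_px / linear_scale


def normalize_image(img: np.ndarray) -> np.ndarray:
    """Map an integer image to float32 in [0, 1] by its dtype maximum."""
    if np.issubdtype(img.dtype, np.integer):
        return (img / np.iinfo(img.dtype).max).astype(np.float32)
    img = img.astype(np.float32)
    if img.size and (img.min() < 0 or img.max() > 1):
        raise ValueError("float images must already lie in [0, 1]")
    return img


# ------------------------------------------------------------------------ IO
def save_patchset(
    path: str | Path, patches: MultiStainPatchSet, labels: np.ndarray | None = None
) -> None:
    """Write a patch set as a multi-channel TIFF plus an optional label CSV."""
    path = Path(path)
    tifffile.imwrite(path, patches.data.astype(np.float32))
    if labels is not None:
        np.savetxt(path.with_suffix(".labels.csv"), labels, fmt="%d")


def load_patchset(path: str | Path) -> tuple[MultiStainPatchSet, np.ndarray | None]:
    path = Path(path)
    data = tifffile.imread(path)
    labels_path = path.with_suffix(".labels.csv")
    labels = None
    if labels_path.exists():
        labels = np.loadtxt(labels_path, dtype=int)
    return MultiStainPatchSet(np.asarray(data)), labels


def _read_image(path: str | Path) -> np.ndarray:
    if str(path).lower().endswith((".png", ".jpg", ".jpeg")):
        from PIL import Image

        return np.asarray(Image.open(path))
    return tifffile.imread(path)


def load_stain_stack(paths: list[str | Path] | str | Path) -> np.ndarray:
    """Load a stain stack as (C, H, W) float32 in [0, 1].

    Accepts either one multi-channel TIFF (C, H, W) or a list of
    per-stain RGB images (TIFF or PNG, each (H, W, 3)) stacked in the
    given order.
    """
    if isinstance(paths, (str, Path)):
        arr = tifffile.imread(paths)
        if arr.ndim != 3:
            raise ValueError("expected a (C, H, W) stack")
        return normalize_image(arr)
    planes = []
    shape = None
    for p in paths:
        img = _read_image(p)
        if img.ndim == 2:
            img = np.stack([img] * 3, axis=-1)
        if img.ndim != 3 or img.shape[-1] != 3:
            raise ValueError(f"{p}: expected an RGB image")
        if shape is None:
            shape = img.shape
        elif img.shape != shape:
            raise ValueError("stain images must share dimensions (co-registered)")
        planes.append(normalize_image(img).transpose(2, 0, 1))
    return np.concatenate(planes, axis=0)
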