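"""Synthetic multi-stain patch datasets with known class structure.

Real inputs are co-registered five-stain renditions of the same tissue:
every stain shows the same geometry but a different color chemistry.
The generator emulates exactly that: each latent tissue class is a
parameterized texture field (stripe frequency/orientation plus blobs),
and one field realization is rendered into ``n_stains`` RGB triplets
through stain-specific color transfer, so all 3 x n_stains channels of a
patch share one geometry.

``separation`` controls how far class-specific colors and texture
parameters sit from the common base: at 0 all classes are statistically
indistinguishable, and class distinguishability grows monotonically with
it. ``noise_sd`` adds iid Gaussian pixel noise before clipping to [0, 1].
Class labels are assigned round-robin and then shuffled, so cluster
sizes are near-uniform — the regime the marginal-entropy term of the
clustering objective assumes.

No attempt is made at histologically realistic nuclei or stroma; the
point is a controllable testbed with ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io_patches import MultiStainPatchSet

__all__ = ["SynthSpec", "SynthWSISpec", "generate_patch_dataset", "generate_synthetic_wsi"]

# Light backgrounds and stain-like foreground bases (HE, MT, CD31, CK19, Ki67);
# cycled if more stains are requested.
_BACKGROUNDS = np.array(
    [
        [0.92, 0.88, 0.93],
        [0.90, 0.91, 0.95],
        [0.93, 0.91, 0.88],
        [0.92, 0.90, 0.87],
        [0.91, 0.89, 0.90],
    ]
)
_FOREGROUNDS = np.array(
    [
        [0.45, 0.30, 0.55],  # haematoxylin purple
        [0.30, 0.35, 0.65],  # trichrome blue
        [0.55, 0.38, 0.22],  # DAB brown
        [0.50, 0.33, 0.20],
        [0.48, 0.30, 0.25],
    ]
)


@dataclass(frozen=True)
class SynthSpec:
    """Parameters of the synthetic patch generator."""

    n_classes: int = 4
    n_patches: int = 600
    patch_size: int = 32
    n_stains: int = 5
    separation: float = 3.0
    noise_sd: float = 0.05
    seed: int = 0

    def __post_init__(self):
        if self.n_classes < 1:
            raise ValueError("n_classes must be >= 1")
        if self.n_patches < 0:
            raise ValueError("n_patches must be >= 0")
        if self.patch_size < 8:
            raise ValueError("patch_size must be >= 8")
        if self.n_stains < 1:
            raise ValueError("n_stains must be >= 1")
        if self.separation < 0 or self.noise_sd < 0:
            raise ValueError("separation and noise_sd must be non-negative")

    @property
    def n_channels(self) -> int:
        return 3 * self.n_stains


@dataclass(frozen=True)
class SynthWSISpec:
    """Layout of a synthetic tiled whole-slide image."""

    height_px: int
    width_px: int
    tile_size: int
    class_map: tuple[tuple[int, ...], ...]

    def __post_init__(self):
        if self.tile_size > min(self.height_px, self.width_px):
            raise ValueError("tile_size exceeds image dimensions")
        cmap = np.asarray(self.class_map)
        expected = (self.height_px // self.tile_size, self.width_px // self.tile_size)
        if cmap.shape != expected:
            raise ValueError(
                f"class_map shape {cmap.shape} must equal floor-division grid {expected}"
            )

    @property
    def class_map_array(self) -> np.ndarray:
        return np.asarray(self.class_map, dtype=int)


class _ClassModel:
    """Per-class texture parameters and per-(class, stain) foreground colors."""

    def __init__(self, spec: SynthSpec, rng: np.random.Generator):
        k, s = spec.n_classes, spec.n_stains
        # Bounded texture modulation: identical across classes at separation 0.
        g = spec.separation / (1.0 + spec.separation)
        self.freq = 2.0 + 3.0 * g * rng.uniform(0.0, 1.0, size=k)
        self.theta = g * rng.uniform(0.0, np.pi, size=k)
        self.n_blobs = np.round(3.0 * g * rng.uniform(0.0, 1.0, size=k)).astype(int)
        bg = np.stack([_BACKGROUNDS[i % len(_BACKGROUNDS)] for i in range(s)])
        fg = np.stack([_FOREGROUNDS[i % len(_FOREGROUNDS)] for i in range(s)])
        # Class color offsets: pairwise-equidistant directions in the 3*S-dim
        # color space (orthonormalized random draws), scaled linearly by
        # `separation` so inter-class distance is controlled, not left to
        # chance. Falls back to normalized random rows when K > 3*S.
        dim = 3 * s
        raw = rng.normal(size=(max(k, 1), dim))
        if k <= dim:
            q, _ = np.linalg.qr(raw.T)
            dirs = q.T[:k]
        else:
            dirs = raw / np.linalg.norm(raw, axis=1, keepdims=True)
        offsets = (0.35 * spec.separation * dirs).reshape(k, s, 3)
        self.background = bg  # (S, 3)
        self.foreground = np.clip(fg[None, :, :] + offsets, 0.0, 1.0)  # (K, S, 3)

    def render(self, cls: int, size: int, rng: np.random.Generator, noise_sd: float) -> np.ndarray:
        yy, xx = np.mgrid[0:size, 0:size] / size
        phase = rng.uniform(0.0, 2.0 * np.pi)
        theta = self.theta[cls]
        field = 0.5 + 0.35 * np.sin(
            2.0 * np.pi * self.freq[cls] * (xx * np.cos(theta) + yy * np.sin(theta)) + phase
        )
        for _ in range(self.n_blobs[cls]):
            cy, cx = rng.uniform(0.1, 0.9, size=2)
            field += 0.4 * np.exp(-(((yy - cy) ** 2 + (xx - cx) ** 2) / (2 * 0.15**2)))
        field = np.clip(field, 0.0, 1.0)
        chans = (
            self.background[:, :, None, None]
            + field[None, None]
            * (self.foreground[cls][:, :, None, None] - self.background[:, :, None, None])
        )  # (S, 3, H, W)
        patch = chans.reshape(-1, size, size)
        if noise_sd > 0:
            patch = patch + rng.normal(0.0, noise_sd, size=patch.shape)
        return np.clip(patch, 0.0, 1.0).astype(np.float32)


def generate_patch_dataset(spec: SynthSpec) -> tuple[MultiStainPatchSet, np.ndarray]:
    """Generate a labeled multi-stain patch dataset.

    Returns a patch set of shape (n_patches, 3*n_stains, size, size) in
    [0, 1] and the true class label of every patch. Identical specs
    (including the seed) produce bit-identical output.
    """
    rng = np.random.default_rng(spec.seed)
    model = _ClassModel(spec, rng)
    labels = np.arange(spec.n_patches) % spec.n_classes
    rng.shuffle(labels)
    data = np.empty(
        (spec.n_patches, spec.n_channels, spec.patch_size, spec.patch_size),
        dtype=np.float32,
    )
    for i, cls in enumerate(labels):
        data[i] = model.render(int(cls), spec.patch_size, rng, spec.noise_sd)
    return MultiStainPatchSet(data, source_id="synthetic"), labels


def generate_synthetic_wsi(
    wsi_spec: SynthWSISpec, synth: SynthSpec
) -> tuple[np.ndarray, np.ndarray]:
    """Render a tiled synthetic whole-slide stain stack with a known class map.

    Each tile of the (3*n_stains, H, W) output is one patch drawn from
    the class of its ``class_map`` entry; remainder strips that fit no
    full tile are filled with the stain backgrounds. Re-cutting the
    image sequentially recovers the generated tiles pixel-exactly.
    """
    rng = np.random.default_rng(synth.seed)
    model = _ClassModel(synth, rng)
    cmap = wsi_spec.class_map_array
    if cmap.size and (cmap.min() < 0 or cmap.max() >= synth.n_classes):
        raise ValueError("class_map entries must be valid class ids")
    t = wsi_spec.tile_size
    c = synth.n_channels
    stack = np.empty((c, wsi_spec.height_px, wsi_spec.width_px), dtype=np.float32)
    bg = model.background.reshape(-1)  # (S*3,)
    stack[:] = bg[: c][:, None, None]
    for r in range(cmap.shape[0]):
        for col in range(cmap.shape[1]):
            tile = model.render(int(cmap[r, col]), t, rng, synth.noise_sd)
            stack[:, r * t : (r + 1) * t, col * t : (col + 1) * t] = tile
    return stack, cmap
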