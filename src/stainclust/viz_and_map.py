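"""2-D embedding export and whole-slide cluster maps.

After training, each tile of a slide gets a cluster ID; painting every
tile with its cluster's color yields a patch-level anomaly map of the
slide, and the histogram of IDs summarizes its composition. Upper-latent
embeddings can additionally be projected to 2-D with UMAP for visual
inspection of the cluster structure.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import matplotlib
import numpy as np

matplotlib.use("Agg")

from .io_patches import TileGrid

__all__ = ["default_palette", "ClusterMap", "embed_2d", "build_cluster_map", "save_scatter"]


def default_palette(n: int = 20) -> np.ndarray:
    """A fixed categorical palette (tab20), (n, 3) floats in [0, 1]."""
    from matplotlib import colormaps

    tab = colormaps["tab20"]
    return np.array([tab(i % 20)[:3] for i in range(n)])


@dataclass
class ClusterMap:
    """Per-tile cluster IDs of a slide plus palette and tile histogram."""

    grid: np.ndarray  # (n_rows, n_cols) int cluster ids
    palette: np.ndarray  # (n_colors, 3) floats in [0, 1]
    histogram: dict[int, int] = field(init=False)

    def __post_init__(self):
        self.grid = np.asarray(self.grid, dtype=int)
        if self.grid.ndim != 2:
            raise ValueError("grid must be 2-D")
        if self.grid.size and self.grid.max() >= len(self.palette):
            raise ValueError("cluster id outside palette")
        if self.grid.size and self.grid.min() < 0:
            raise ValueError("cluster ids must be non-negative")
        ids, counts = np.unique(self.grid, return_counts=True)
        self.histogram = {int(i): int(c) for i, c in zip(ids, counts)}

    def render(self, tile_px: int = 1) -> np.ndarray:
        """RGB image with one solid tile_px-square per tile, float in [0, 1]."""
        if tile_px < 1:
            raise ValueError("tile_px must be >= 1")
        img = self.palette[self.grid]  # (rows, cols, 3)
        if tile_px > 1:
            img = np.repeat(np.repeat(img, tile_px, axis=0), tile_px, axis=1)
        return img

    def save_png(self, path: str | Path, tile_px: int = 8) -> None:
        from PIL import Image

        arr = (self.render(tile_px) * 255).round().astype(np.uint8)
        Image.fromarray(arr).save(path)

    def save_histogram_csv(self, path: str | Path) -> None:
        import pandas as pd

        pd.Series(self.histogram, name="n_tiles").rename_axis("cluster").to_csv(path)


def embed_2d(features: np.ndarray, seed: int = 0, n_neighbors: int = 15) -> np.ndarray:
    """Project (N, D) features to 2-D with UMAP; row order preserved.

    The neighborhood size is capped at N - 1; at least 10 points are
    required to form a meaningful neighbor graph.
    """
    features = np.asarray(features)
    n = len(features)
    if n < 10:
        raise ValueError("need at least 10 points for a 2-D embedding")
    import umap

    reducer = umap.UMAP(
        n_components=2,
        n_neighbors=min(n_neighbors, n - 1),
        random_state=seed,
    )
    return np.asarray(reducer.fit_transform(features), dtype=float)


def build_cluster_map(
    grid: TileGrid, labels: np.ndarray, palette: np.ndarray | None = None
) -> ClusterMap:
    """Fill a tile grid row-major with per-tile cluster labels."""
    labels = np.asarray(labels, dtype=int)
    if len(labels) != grid.count:
        raise ValueError(f"expected {grid.count} labels, got {len(labels)}")
    if palette is None:
        palette = default_palette(max(20, labels.max() + 1 if labels.size else 1))
    return ClusterMap(labels.reshape(grid.n_rows, grid.n_cols), np.asarray(palette))


def save_scatter(
    coords: np.ndarray, labels: np.ndarray, path: str | Path, palette: np.ndarray | None = None
) -> None:
    """Save a 2-D embedding scatter colored by cluster label."""
    import matplotlib.pyplot as plt

    coords = np.asarray(coords)
    labels = np.asarray(labels, dtype=int)
    if palette is None:
        palette = default_palette(max(20, labels.max() + 1))
    fig, ax = plt.subplots(figsize=(6, 6))
    for k in np.unique(labels):
        m = labels == k
        ax.scatter(coords[m, 0], coords[m, 1], s=6, color=palette[k], label=str(k))
    ax.set_xlabel("UMAP 1")
    ax.set_ylabel("UMAP 2")
    ax.legend(markerscale=2, fontsize=8, title="cluster")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
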