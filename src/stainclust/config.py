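"""Pipeline configuration (YAML) and end-to-end orchestration.

One config object covers every stage: synthetic data generation,
model architecture profile, training hyperparameters, the cluster-count
sweep, and visualization. Defaults follow the published hyperparameter
table; :func:`desk_profile` returns a configuration sized for a single
CPU (reduced model, 300 epochs, sweep over a few cluster counts).

``run_pipeline`` orders the full workflow — generate, train per
candidate cluster count, assign, validate, select by vote, embed and
map — and writes every artifact plus a manifest into one directory.
"""

from __future__ import annotations

import dataclasses
import json
import platform
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .clustering_eval import ValidityTable, select_optimal, validity_scores, vote
from .io_patches import save_patchset, tile_grid
from .losses import LossWeights
from .model import ModelConfig, reduced_config
from .synthdata import SynthSpec, SynthWSISpec, generate_patch_dataset, generate_synthetic_wsi
from .training import TrainConfig, assign_clusters, train
from .transforms import AffineRanges

__all__ = ["PipelineConfig", "desk_profile", "run_pipeline"]


@dataclass(frozen=True)
class PipelineConfig:
    """Everything needed for one end-to-end run."""

    seed: int = 0
    synth: SynthSpec = field(default_factory=SynthSpec)
    sweep: tuple[int, ...] = tuple(range(8, 19))
    epochs: int = 4000
    batch_size: int = 100
    learning_rate: float = 0.003
    weights: LossWeights = field(default_factory=LossWeights)
    affine: AffineRanges = field(default_factory=AffineRanges)
    model_profile: str = "full"  # "full" | "reduced"
    make_scatter: bool = True
    make_wsi_map: bool = True
    wsi_tiles: tuple[int, int] = (6, 8)

    def __post_init__(self):
        if self.model_profile not in ("full", "reduced"):
            raise ValueError("model_profile must be 'full' or 'reduced'")
        if any(k < 2 for k in self.sweep):
            raise ValueError("sweep cluster counts must be >= 2")

    # ------------------------------------------------------------------ YAML
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["sweep"] = list(self.sweep)
        d["wsi_tiles"] = list(self.wsi_tiles)
        for k in ("affine",):
            d[k] = {kk: list(vv) if isinstance(vv, tuple) else vv for kk, vv in d[k].items()}
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        known = {f.name for f in dataclasses.fields(cls)}
        for key in d:
            if key not in known:
                raise ValueError(f"unknown config key: {key!r}")
        if "synth" in d:
            cls._check_keys(SynthSpec, d["synth"], "synth")
            d["synth"] = SynthSpec(**d["synth"])
        if "weights" in d:
            cls._check_keys(LossWeights, d["weights"], "weights")
            d["weights"] = LossWeights(**d["weights"])
        if "affine" in d:
            cls._check_keys(AffineRanges, d["affine"], "affine")
            d["affine"] = AffineRanges(
                **{k: tuple(v) if isinstance(v, list) else v for k, v in d["affine"].items()}
            )
        for k in ("sweep", "wsi_tiles"):
            if k in d:
                d[k] = tuple(d[k])
        return cls(**d)

    @staticmethod
    def _check_keys(klass, sub: dict, path: str) -> None:
        known = {f.name for f in dataclasses.fields(klass)}
        for key in sub:
            if key not in known:
                raise ValueError(f"unknown config key: {path}.{key!r}")

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    # --------------------------------------------------------------- helpers
    def model_config(self, n_clusters: int) -> ModelConfig:
        if self.model_profile == "reduced":
            return reduced_config(
                n_clusters,
                seed=self.seed,
                in_channels=self.synth.n_channels,
                input_size=self.synth.patch_size,
            )
        rescale = 64 if self.synth.patch_size > 64 else None
        return ModelConfig(
            in_channels=self.synth.n_channels,
            input_size=self.synth.patch_size,
            input_rescale=rescale,
            n_clusters=n_clusters,
            seed=self.seed,
        )

    def train_config(self, n_clusters: int) -> TrainConfig:
        return TrainConfig(
            epochs=self.epochs,
            batch_size=self.batch_size,
            learning_rate=self.learning_rate,
            weights=self.weights,
            affine=self.affine,
            seed=self.seed,
            n_clusters=n_clusters,
        )


def desk_profile(seed: int = 0, sweep: tuple[int, ...] = (3, 4, 5)) -> PipelineConfig:
    """A single-CPU configuration: reduced model, 300 epochs, small sweep."""
    return PipelineConfig(
        seed=seed,
        synth=SynthSpec(seed=seed),
        sweep=sweep,
        epochs=300,
        batch_size=25,
        learning_rate=5.0,
        model_profile="reduced",
    )


def run_pipeline(config: PipelineConfig, out_dir: str | Path) -> Path:
    """Generate data, sweep cluster counts, validate, select, embed, map.

    Returns the artifact directory. Candidate cluster counts whose
    clustering leaves a cluster empty cannot be scored by the validity
    indices and are recorded as missing.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    patches, labels = generate_patch_dataset(config.synth)
    save_patchset(out / "dataset.tiff", patches, labels)

    scores: dict[int, dict[str, float]] = {}
    per_k: dict[int, dict] = {}
    for nc in config.sweep:
        model, history = train(
            patches.data, config.train_config(nc), config.model_config(nc)
        )
        model.save(out / f"model_k{nc}.npz")
        history.to_csv(out / f"history_k{nc}.csv", index=False)
        hard, soft = assign_clusters(model, patches.data)
        emb = model.encode(patches.data)
        np.savetxt(out / f"assignments_k{nc}.csv", hard, fmt="%d")
        np.save(out / f"embeddings_k{nc}.npy", emb)
        per_k[nc] = {"model": model, "labels": hard, "soft": soft, "embeddings": emb}
        try:
            scores[nc] = validity_scores(emb, hard, soft)
        except ValueError as err:
            scores[nc] = {}
            (out / f"validity_skipped_k{nc}.txt").write_text(str(err) + "\n")

    table = ValidityTable.from_scores({k: v for k, v in scores.items() if v})
    table.to_csv(out / "validity_table.csv")
    optima = select_optimal(table)
    optima.to_csv(out / "selection.csv")
    chosen, histogram = vote(optima)

    report = {
        "chosen_n_clusters": chosen,
        "votes": histogram,
        "sweep": list(config.sweep),
    }
    best = per_k[chosen]

    if config.make_scatter and len(best["embeddings"]) >= 10:
        from .viz_and_map import embed_2d, save_scatter

        coords = embed_2d(best["embeddings"], seed=config.seed)
        np.savetxt(out / "embedding_2d.csv", coords, delimiter=",")
        save_scatter(coords, best["labels"], out / "embedding_2d.png")

    if config.make_wsi_map:
        from .training import assign_clusters as _assign
        from .viz_and_map import build_cluster_map

        rows, cols = config.wsi_tiles
        t = config.synth.patch_size
        rng = np.random.default_rng(config.seed)
        class_map = tuple(
            tuple(int(v) for v in row)
            for row in rng.integers(0, config.synth.n_classes, size=(rows, cols))
        )
        wsi_spec = SynthWSISpec(rows * t, cols * t, t, class_map)
        stack, truth_map = generate_synthetic_wsi(wsi_spec, config.synth)
        from .io_patches import cut_tiles

        tiles = cut_tiles(stack, t)
        tile_labels, _ = _assign(best["model"], tiles.data)
        cmap = build_cluster_map(tile_grid(stack.shape[1], stack.shape[2], t), tile_labels)
        cmap.save_png(out / "wsi_cluster_map.png")
        cmap.save_histogram_csv(out / "wsi_histogram.csv")
        np.savetxt(out / "wsi_true_class_map.csv", truth_map, fmt="%d", delimiter=",")

    manifest = {
        "config": config.to_dict(),
        "report": report,
        "versions": {
            "python": platform.python_version(),
            "numpy": np.__version__,
        },
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    (out / "selection_report.json").write_text(json.dumps(report, indent=2) + "\n")
    return out
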