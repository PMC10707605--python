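"""The three-part convolutional autoencoder.

The network embeds co-registered multi-stain patches (3 RGB channels per
stain, 15 channels for the default 5-stain panel) into a shared latent
space:

* **encoder** — strided convolutions compress a patch to the *upper
  latent space*, a D-dimensional feature vector (D = 196 by default);
* **classifier** — a small dense head maps the upper latent vector to
  the *lower latent space*, a softmax distribution over ``n_clusters``
  (the soft cluster assignment);
* **decoder** — reconstructs the input from the concatenation of upper
  and lower latent features through transposed convolutions, ending in a
  sigmoid so outputs live in (0, 1) like the normalized inputs.

Large patches can be bilinearly downscaled before the encoder
(``input_rescale``) so one architecture depth serves several patch
sizes; the reconstruction target is then the rescaled input.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from . import nn
from .nn import Tensor

__all__ = [
    "ModelConfig",
    "AutoencoderClusterer",
    "build_model",
    "load_model",
    "reduced_config",
]


@dataclass(frozen=True)
class ModelConfig:
    """Architectural hyperparameters.

    Defaults follow the published configuration: 15 input channels,
    conv stages widening through (15, 45, 128), a 196-dimensional upper
    latent space, leaky-rectifier activations and a sigmoid output.
    """

    in_channels: int = 15
    input_size: int = 64
    input_rescale: int | None = None
    channel_plan: tuple[int, ...] = (15, 45, 128)
    upper_dim: int = 196
    n_clusters: int = 14
    classifier_hidden: tuple[int, ...] = (128, 64)
    leaky_slope: float = 0.1
    double_convs: bool = True
    seed: int = 0

    def __post_init__(self):
        if self.n_clusters < 2:
            raise ValueError("n_clusters must be at least 2")
        if self.upper_dim < self.n_clusters:
            raise ValueError("upper_dim must be >= n_clusters")
        side = self.input_rescale or self.input_size
        if side % (2 ** len(self.channel_plan)) != 0:
            raise ValueError(
                f"encoder side {side} not divisible by 2^{len(self.channel_plan)}"
            )

    @property
    def encoder_side(self) -> int:
        return self.input_rescale or self.input_size

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["channel_plan"] = list(self.channel_plan)
        d["classifier_hidden"] = list(self.classifier_hidden)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        d = dict(d)
        d["channel_plan"] = tuple(d["channel_plan"])
        d["classifier_hidden"] = tuple(d["classifier_hidden"])
        return cls(**d)


def reduced_config(n_clusters: int, seed: int = 0, in_channels: int = 15,
                   input_size: int = 32) -> ModelConfig:
    """A small configuration for desk-scale experiments on 32-pixel patches."""
    return ModelConfig(
        in_channels=in_channels,
        input_size=input_size,
        input_rescale=16,
        channel_plan=(16, 32),
        upper_dim=32,
        n_clusters=n_clusters,
        classifier_hidden=(64,),
        double_convs=False,
        seed=seed,
    )


def _downscale(x: np.ndarray, side: int) -> np.ndarray:
    """Downscale (N, C, H, W) to (N, C, side, side)."""
    n, c, h, w = x.shape
    if h == side and w == side:
        return x
    if h % side == 0 and w % side == 0:
        fh, fw = h // side, w // side
        return x.reshape(n, c, side, fh, side, fw).mean(axis=(3, 5))
    from skimage.transform import resize

    out = resize(
        x.transpose(0, 2, 3, 1), (n, side, side), order=1, anti_aliasing=False,
        preserve_range=True,
    )
    return out.transpose(0, 3, 1, 2).astype(x.dtype)


class AutoencoderClusterer:
    """Encoder + classifier + decoder with persistable state."""

    def __init__(self, config: ModelConfig):
        self.config = config
        rng = np.random.default_rng(config.seed)
        slope = config.leaky_slope
        plan = config.channel_plan
        side = config.encoder_side

        enc: list[nn.Module] = []
        prev = config.in_channels
        for ch in plan:
            enc += [nn.Conv2d(prev, ch, 4, rng, stride=2, padding=1), nn.LeakyReLU(slope)]
            if config.double_convs:
                enc += [nn.Conv2d(ch, ch, 3, rng, stride=1, padding=1), nn.LeakyReLU(slope)]
            prev = ch
            side //= 2
        enc += [nn.Flatten(), nn.Linear(prev * side * side, config.upper_dim, rng)]
        self.encoder = nn.Sequential(*enc)

        cls: list[nn.Module] = []
        dims = (config.upper_dim,) + config.classifier_hidden
        for a, b in zip(dims[:-1], dims[1:]):
            cls += [nn.Linear(a, b, rng), nn.LeakyReLU(slope)]
        cls += [nn.Linear(dims[-1], config.n_clusters, rng), nn.Softmax(axis=1)]
        self.classifier = nn.Sequential(*cls)

        dec: list[nn.Module] = [
            nn.Linear(config.upper_dim + config.n_clusters, prev * side * side, rng),
            nn.LeakyReLU(slope),
            nn.Reshape(prev, side, side),
        ]
        for i in range(len(plan) - 1, 0, -1):
            dec += [nn.ConvTranspose2d(plan[i], plan[i - 1], 4, rng, stride=2, padding=1),
                    nn.LeakyReLU(slope)]
            if config.double_convs:
                dec += [nn.Conv2d(plan[i - 1], plan[i - 1], 3, rng, stride=1, padding=1),
                        nn.LeakyReLU(slope)]
        dec += [nn.ConvTranspose2d(plan[0], config.in_channels, 4, rng, stride=2, padding=1),
                nn.Sigmoid()]
        self.decoder = nn.Sequential(*dec)

    # --------------------------------------------------------------- plumbing
    def parameters(self) -> list[Tensor]:
        return (
            self.encoder.parameters()
            + self.classifier.parameters()
            + self.decoder.parameters()
        )

    def prepare_input(self, patches: np.ndarray) -> np.ndarray:
        """Validate channel count and apply the configured downscale."""
        patches = np.asarray(patches, dtype=np.float32)
        if patches.ndim != 4 or patches.shape[1] != self.config.in_channels:
            raise ValueError(
                f"expected (N, {self.config.in_channels}, H, W) input, got {patches.shape}"
            )
        if self.config.input_rescale is not None:
            patches = _downscale(patches, self.config.input_rescale)
        return patches

    # ------------------------------------------------------ tensor-mode paths
    def encode_t(self, x: Tensor) -> Tensor:
        return self.encoder(x)

    def classify_t(self, upper: Tensor) -> Tensor:
        return self.classifier(upper)

    def decode_t(self, upper: Tensor, lower: Tensor) -> Tensor:
        if upper.shape[0] != lower.shape[0]:
            raise ValueError("upper and lower latent batches differ in length")
        return self.decoder(nn.concat([upper, lower], axis=1))

    # ------------------------------------------------------- numpy-mode paths
    def encode(self, patches: np.ndarray, batch_size: int = 256) -> np.ndarray:
        """Map patches to the upper latent space: (N, D) array."""
        x = self.prepare_input(patches)
        out = [
            self.encode_t(Tensor(x[i : i + batch_size])).data
            for i in range(0, len(x), batch_size)
        ]
        if not out:
            return np.zeros((0, self.config.upper_dim), dtype=np.float32)
        return np.concatenate(out, axis=0)

    def classify(self, upper: np.ndarray) -> np.ndarray:
        """Soft cluster assignments (N, n_clusters), rows on the simplex."""
        upper = np.asarray(upper, dtype=np.float32)
        if upper.ndim != 2 or upper.shape[1] != self.config.upper_dim:
            raise ValueError(
                f"expected (N, {self.config.upper_dim}) embedding, got {upper.shape}"
            )
        return self.classify_t(Tensor(upper)).data

    def decode(self, upper: np.ndarray, lower: np.ndarray) -> np.ndarray:
        """Reconstructions (N, C, side, side) in (0, 1)."""
        return self.decode_t(
            Tensor(np.asarray(upper, dtype=np.float32)),
            Tensor(np.asarray(lower, dtype=np.float32)),
        ).data

    # ------------------------------------------------------------ persistence
    def save(self, path: str | Path) -> None:
        """Persist parameters and config to an ``.npz`` checkpoint."""
        arrays = {f"p{i}": p.data for i, p in enumerate(self.parameters())}
        arrays["config_json"] = np.frombuffer(
            json.dumps(self.config.to_dict()).encode(), dtype=np.uint8
        )
        np.savez(path, **arrays)

    def load_parameters(self, arrays: dict[str, np.ndarray]) -> None:
        for i, p in enumerate(self.parameters()):
            a = arrays[f"p{i}"]
            if a.shape != p.data.shape:
                raise ValueError(f"parameter {i} shape mismatch: {a.shape} vs {p.data.shape}")
            p.data = a.astype(np.float32)


def build_model(config: ModelConfig) -> AutoencoderClusterer:
    return AutoencoderClusterer(config)


def load_model(path: str | Path) -> AutoencoderClusterer:
    with np.load(path) as z:
        cfg = ModelConfig.from_dict(json.loads(bytes(z["config_json"]).decode()))
        model = AutoencoderClusterer(cfg)
        model.load_parameters({k: z[k] for k in z.files if k != "config_json"})
    return model
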