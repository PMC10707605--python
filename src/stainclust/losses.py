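"""Training objectives: entropies, mutual information, MSE, affine KL.

The clustering objective is regularized information maximization: train
the classifier head to maximize the mutual information

    I(X; Y) = H(Y) - H(Y|X)

between inputs and soft cluster assignments, where H(Y) is the entropy
of the batch-mean assignment (rewarding balanced cluster usage) and
H(Y|X) the mean per-sample assignment entropy (rewarding confident
assignments). The full objective to minimize is

    L = L_recon - (lambda_ME * H(Y) - lambda_CE * H(Y|X)) + lambda_AF * L_AF

with a mean-squared-error reconstruction term and an affine-consistency
penalty L_AF, the mean KL divergence between the assignments of each
patch and of its randomly affine-transformed copy.

All entropies are in nats. Every public function accepts plain NumPy
arrays and returns floats; the ``*_t`` variants operate on autodiff
tensors and are used inside the training loop.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .nn import Tensor

__all__ = [
    "EPS",
    "LossWeights",
    "LossBreakdown",
    "entropy",
    "conditional_entropy",
    "marginal_entropy",
    "mutual_information",
    "reconstruction_mse",
    "affine_kl",
    "total_loss",
]

#: Floor applied inside logarithms; treats 0*log(0) as 0.
EPS = 1e-12


@dataclass(frozen=True)
class LossWeights:
    """Trade-off weights for the combined objective (published defaults)."""

    lambda_me: float = 0.1
    lambda_ce: float = 0.03
    lambda_af: float = 0.03

    def __post_init__(self):
        if min(self.lambda_me, self.lambda_ce, self.lambda_af) < 0:
            raise ValueError("loss weights must be non-negative")


@dataclass(frozen=True)
class LossBreakdown:
    recon: float
    marginal_entropy: float
    conditional_entropy: float
    affine_kl: float
    total: float

    @property
    def mutual_information(self) -> float:
        return self.marginal_entropy - self.conditional_entropy


def _check_rows(p: np.ndarray, atol: float = 1e-5) -> np.ndarray:
    p = np.asarray(p, dtype=np.float64)
    if p.size == 0:
        raise ValueError("empty assignment matrix")
    if (p < -atol).any():
        raise ValueError("probabilities must be non-negative")
    sums = p.sum(axis=-1)
    if not np.allclose(sums, 1.0, atol=1e-4):
        raise ValueError("probability rows must sum to 1")
    return p


# -------------------------------------------------------------- tensor forms
def entropy_t(p: Tensor) -> Tensor:
    """Shannon entropy h(p) = -sum p log p of the last axis, in nats."""
    return -(p * p.clip_min(EPS).log()).sum(axis=-1)


def conditional_entropy_t(assignments: Tensor) -> Tensor:
    return entropy_t(assignments).mean()


def marginal_entropy_t(assignments: Tensor) -> Tensor:
    return entropy_t(assignments.mean(axis=0))


def reconstruction_mse_t(original: Tensor, reconstructed: Tensor) -> Tensor:
    return ((original - reconstructed) ** 2.0).mean()


def affine_kl_t(p_original: Tensor, p_transformed: Tensor) -> Tensor:
    logp = p_original.clip_min(EPS).log()
    logq = p_transformed.clip_min(EPS).log()
    return (p_original * (logp - logq)).sum(axis=-1).mean()


# --------------------------------------------------------------- numpy forms
def entropy(p: np.ndarray) -> float:
    """Shannon entropy of a probability vector, in nats (0*log 0 = 0)."""
    p = _check_rows(p)
    if p.ndim != 1:
        raise ValueError("entropy expects a single probability vector")
    return float(entropy_t(Tensor(p)).item())


def conditional_entropy(assignments: np.ndarray) -> float:
    """H(Y|X): mean entropy of the per-sample assignment rows."""
    p = _check_rows(assignments)
    if p.ndim != 2:
        raise ValueError("expected an (N, K) assignment matrix")
    return float(conditional_entropy_t(Tensor(p)).item())


def marginal_entropy(assignments: np.ndarray) -> float:
    """H(Y): entropy of the column-mean assignment distribution."""
    p = _check_rows(assignments)
    if p.ndim != 2:
        raise ValueError("expected an (N, K) assignment matrix")
    return float(marginal_entropy_t(Tensor(p)).item())


def mutual_information(assignments: np.ndarray) -> float:
    """Plug-in mutual information H(Y) - H(Y|X); non-negative by concavity."""
    return marginal_entropy(assignments) - conditional_entropy(assignments)


def reconstruction_mse(original: np.ndarray, reconstructed: np.ndarray) -> float:
    """Mean of squared element-wise differences over all elements."""
    a = np.asarray(original, dtype=np.float64)
    b = np.asarray(reconstructed, dtype=np.float64)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    return float(np.mean((a - b) ** 2))


def affine_kl(p_original: np.ndarray, p_transformed: np.ndarray) -> float:
    """Mean over rows of KL(P_row || Q_row), with epsilon-floored logs.

    P is the assignment of the original patches (the reference), Q that
    of their affine-transformed copies.
    """
    p = _check_rows(p_original)
    q = _check_rows(p_transformed)
    if p.shape != q.shape:
        raise ValueError(f"shape mismatch: {p.shape} vs {q.shape}")
    return float(affine_kl_t(Tensor(p), Tensor(q)).item())


def total_loss(
    recon: float,
    marginal: float,
    conditional: float,
    affine: float,
    weights: LossWeights = LossWeights(),
) -> LossBreakdown:
    """Assemble the combined objective from its components."""
    if recon < 0:
        raise ValueError("reconstruction loss must be non-negative")
    if affine < 0:
        raise ValueError("affine KL penalty must be non-negative")
    for v in (recon, marginal, conditional, affine):
        if not np.isfinite(v):
            raise ValueError("loss components must be finite")
    total = (
        recon
        - (weights.lambda_me * marginal - weights.lambda_ce * conditional)
        + weights.lambda_af * affine
    )
    return LossBreakdown(
        recon=float(recon),
        marginal_entropy=float(marginal),
        conditional_entropy=float(conditional),
        affine_kl=float(affine),
        total=float(total),
    )
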