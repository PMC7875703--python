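"""The three self-supervised pretraining objectives and their combination.

* Deep-InfoMax noise-contrastive (NCE) term: a discriminator scores
  (embedding, input-tokens) pairs; matched pairs (same visit) are labeled 1,
  mismatched pairs 0, and the binary cross-entropy over all pairs is
  minimized jointly by the discriminator and the encoder. Maximizing the
  discriminability of matched pairs maximizes a lower bound on the mutual
  information between inputs and embeddings.
* Adversarial prior matching: a linear domain discriminator separates
  embeddings from i.i.d. Uniform[-1,1]^d draws; the encoder is trained
  (non-saturating GAN objective) to fool it, pushing the embedding
  distribution toward the uniform prior. The uniform prior is the minimizer
  of Σ p log p over distributions on a bounded support — see
  :func:`negative_entropy_grid_minimum` for the numerical check of that
  convexity argument.
* SimCLR / NT-Xent: two augmented views of each visit are positives, all
  other batch members negatives, with temperature-scaled cosine similarity.

Total encoder loss = DIM NCE + γ·(prior generator term) + SimCLR, with the
discriminator terms optimized in the alternating adversarial step.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .nn import Linear, Module, Tensor, as_tensor, concat

__all__ = [
    "PretrainLossParts",
    "LinearDomainDiscriminator",
    "dim_nce_loss",
    "prior_adversarial_losses",
    "simclr_loss",
    "nt_xent_value",
    "total_pretrain_loss",
    "negative_entropy_grid_minimum",
]


@dataclass
class PretrainLossParts:
    """Scalar loss components of one pretraining step.

    ``total = dim_nce + gamma * prior_gen + simclr``; the discriminator-side
    prior loss is optimized in the alternating step and never enters total.
    """

    dim_nce: float
    prior_gen: float
    prior_disc: float
    simclr: float
    gamma: float = 0.1

    @property
    def total(self) -> float:
        return self.dim_nce + self.gamma * self.prior_gen + self.simclr


def _bce(p: Tensor, targets: np.ndarray) -> Tensor:
    t = Tensor(np.asarray(targets, dtype=float))
    return -(t * p.log() + (1.0 - t) * (1.0 - p).log()).mean()


def dim_nce_loss(scores) -> Tensor:
    """Mean binary cross-entropy over a B×B matrix of discriminator
    probabilities, target 1 on the diagonal (matched embedding/input pairs)
    and 0 off-diagonal, all B² pairs weighted equally."""
    scores = as_tensor(scores)
    if scores.ndim != 2 or scores.shape[0] != scores.shape[1]:
        raise ValueError("scores must be a square B×B matrix")
    if scores.shape[0] < 2:
        raise ValueError("need batch size B >= 2")
    if not ((scores.data > 0) & (scores.data < 1)).all():
        raise ValueError("scores must lie strictly inside (0, 1)")
    return _bce(scores, np.eye(scores.shape[0]))


class LinearDomainDiscriminator(Module):
    """Single linear layer + sigmoid over a d_hidden input: probability that
    the input comes from the prior domain."""

    def __init__(self, d_hidden: int, rng: np.random.Generator):
        self.linear = Linear(d_hidden, 1, rng)

    def __call__(self, z: Tensor) -> Tensor:
        return self.linear(z).sigmoid().reshape(-1)


def prior_adversarial_losses(eps_batch: Tensor, prior_batch: np.ndarray,
                             discriminator: LinearDomainDiscriminator
                             ) -> tuple[Tensor, Tensor]:
    """Adversarial uniform-prior matching losses.

    ``disc_loss`` — BCE labeling prior draws 1 and (detached) embeddings 0;
    its gradient reaches only the discriminator. ``gen_loss`` — the
    non-saturating generator objective −log D(ε) on the live embeddings,
    computed with detached discriminator weights conceptually: step only
    encoder parameters with it. At the GAN equilibrium (embedding
    distribution equal to the prior, discriminator at chance 0.5) disc_loss
    is ln 2.
    """
    eps_batch = as_tensor(eps_batch)
    prior_batch = np.asarray(prior_batch, dtype=float)
    if prior_batch.shape != eps_batch.shape:
        raise ValueError("prior and embedding batches must share a shape")
    d_prior = discriminator(Tensor(prior_batch))
    d_eps_detached = discriminator(eps_batch.detach())
    disc_loss = 0.5 * (_bce(d_prior, np.ones(len(d_prior.data)))
                       + _bce(d_eps_detached, np.zeros(len(d_eps_detached.data))))
    d_eps = discriminator(eps_batch)
    gen_loss = -(d_eps.log()).mean()
    return disc_loss, gen_loss


def _nt_xent(z: Tensor, z_prime: Tensor, temperature: float) -> Tensor:
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    b = z.shape[0]
    if b < 2 or z_prime.shape[0] != b:
        raise ValueError("NEED_NEGATIVES: need two equal batches with B >= 2")
    all_z = concat([z, z_prime], axis=0)  # (2B, d)
    norms_sq = (all_z * all_z).sum(axis=1, keepdims=True)
    if (norms_sq.data <= 0).any():
        raise ValueError("ZERO_VECTOR: zero-norm embedding in contrastive batch")
    normed = all_z / norms_sq**0.5
    sim = normed @ normed.transpose() * (1.0 / temperature)  # (2B, 2B)
    # exclude self-similarity from every anchor's softmax
    sim = sim + Tensor(np.diag(np.full(2 * b, -1e9)))
    pos_idx = np.concatenate([np.arange(b, 2 * b), np.arange(0, b)])
    log_norm = sim.logsumexp(axis=-1, keepdims=True).reshape(-1)
    pos_logit = sim[np.arange(2 * b), pos_idx]
    return (log_norm - pos_logit).mean()


def simclr_loss(z, z_prime, temperature: float = 0.5) -> Tensor:
    """NT-Xent over 2B embeddings: each anchor's positive is its other
    augmented view; the remaining 2B−2 embeddings are negatives; similarity
    is cosine / temperature; averaged over all 2B anchors."""
    return _nt_xent(as_tensor(z), as_tensor(z_prime), temperature)


def nt_xent_value(z: np.ndarray, z_prime: np.ndarray, temperature: float = 0.5) -> float:
    """Plain-number NT-Xent for non-trainable feature batches (e.g. the
    chief-complaint / present-illness text-pair objective)."""
    return simclr_loss(Tensor(z), Tensor(z_prime), temperature).item()


def total_pretrain_loss(parts: PretrainLossParts) -> float:
    """Combined encoder objective: DIM NCE + γ·prior generator term +
    SimCLR. The discriminator-side prior loss is excluded by construction."""
    return parts.total


def negative_entropy_grid_minimum(n: int = 4, step: float = 0.01) -> tuple[np.ndarray, float]:
    """Brute-force minimizer of F(p) = Σ p_i log p_i over the n-simplex grid.

    Enumerates all probability vectors with entries on a `step` lattice and
    returns (argmin, min). Because F is convex and symmetric the minimum
    sits at the uniform vector — this function is the numerical check of
    that claim (used to justify the Uniform[-1,1]^d prior).
    """
    m = int(round(1.0 / step))
    grids = np.meshgrid(*[np.arange(m + 1)] * (n - 1), indexing="ij")
    head = np.stack([g.ravel() for g in grids], axis=1)  # lattice heads
    tail = m - head.sum(axis=1)
    valid = tail >= 0
    counts = np.column_stack([head[valid], tail[valid]])
    p = counts / float(m)
    with np.errstate(divide="ignore", invalid="ignore"):
        values = np.where(p > 0, p * np.log(p), 0.0).sum(axis=1)
    i = int(np.argmin(values))
    return p[i], float(values[i])
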