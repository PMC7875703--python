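"""The disease-concept embedding model.

A visit is fused into a 4-token sequence — a learned [CLS] token, the
projected structural vector M_S, the projected chief-complaint feature
M_CC, and the projected mean-history feature M_Hx — with additive position
and segment embeddings, BERT-style. A Transformer encoder pools the
sequence through the [CLS] row, and an elementwise tanh bounds every
coordinate of the resulting disease embedding ε to [-1, 1], which makes the
uniform-prior matching on [-1,1]^d well-posed.

The attention mask zeroes the history slot whenever the patient has no past
records, so the padding feature's content can never reach ε. The same
machinery backs the Deep-InfoMax discriminator, which reads the 6-token
sequence [CLS], ε, [SEP], M_S, M_CC, M_Hx with segment level 0 on [CLS]/ε
and level 1 on the rest, and scores how likely ε belongs to that visit.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from .nn import MLP, Linear, Module, Tensor, TransformerEncoder, concat

__all__ = [
    "ModelConfig",
    "AssembledInput",
    "DiseaseEncoder",
    "DimDiscriminator",
    "augment",
]


@dataclass
class ModelConfig:
    """Architecture hyperparameters.

    Defaults follow the full-scale configuration (12 layers, 12 heads,
    hidden size 96, 768-d text features); :meth:`small_preset` is the
    desk-scale configuration used throughout the tests.
    """

    d_hidden: int = 96
    n_layers: int = 12
    n_heads: int = 12
    d_text: int = 768
    d_struct: int = 15
    history_mask_prob: float = 0.5
    noise_fraction: float = 0.1
    # segment level is settable for future multi-segment extensions; the
    # base model keeps every input token at level 0.
    n_segments: int = 2
    struct_mlp_width: int = 64
    text_mlp_width: int = 256

    def __post_init__(self):
        if self.d_hidden % self.n_heads:
            raise ValueError("d_hidden must be divisible by n_heads")

    @classmethod
    def small_preset(cls, **overrides) -> "ModelConfig":
        kwargs = dict(d_hidden=32, n_layers=2, n_heads=4, d_text=96)
        kwargs.update(overrides)
        return cls(**kwargs)

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class AssembledInput:
    """A batch of assembled 4-token input sequences.

    ``tokens`` already contains token + position + segment embeddings
    summed; ``mask`` row pattern is (1, 1, 1, hx_valid).
    """

    tokens: Tensor  # (B, 4, d_hidden)
    mask: np.ndarray  # (B, 4) of {0,1}
    segment_ids: np.ndarray = field(default=None)
    position_ids: np.ndarray = field(default=None)


class DiseaseEncoder(Module):
    """Projection heads + input assembly + Transformer encoder -> ε."""

    def __init__(self, config: ModelConfig, rng: np.random.Generator):
        self.config = config
        d = config.d_hidden
        self.l_s = MLP([config.d_struct, config.struct_mlp_width, d], rng)
        self.l_b = MLP([config.d_text, config.text_mlp_width, d], rng)
        self.cls_token = Tensor(rng.normal(0, 0.02, size=d), requires_grad=True)
        self.position_table = Tensor(rng.normal(0, 0.02, size=(4, d)), requires_grad=True)
        self.segment_table = Tensor(rng.normal(0, 0.02, size=(config.n_segments, d)),
                                    requires_grad=True)
        self.encoder = TransformerEncoder(d, config.n_layers, config.n_heads, rng)

    # -- projections -------------------------------------------------------
    def project_structural(self, s) -> Tensor:
        """L_S: the (imputed, standardized) 15-vector S -> M_S in R^d."""
        s = s if isinstance(s, Tensor) else Tensor(np.atleast_2d(np.asarray(s, dtype=float)))
        if s.shape[-1] != self.config.d_struct:
            raise ValueError(f"expected {self.config.d_struct} structural fields, got {s.shape[-1]}")
        return self.l_s(s)

    def project_text(self, f) -> Tensor:
        """L_B: a d_text feature (CC or mean history) -> R^d. One shared
        network serves both text slots."""
        f = f if isinstance(f, Tensor) else Tensor(np.atleast_2d(np.asarray(f, dtype=float)))
        if f.shape[-1] != self.config.d_text:
            raise ValueError(f"expected d_text={self.config.d_text}, got {f.shape[-1]}")
        return self.l_b(f)

    # -- assembly ----------------------------------------------------------
    def assemble_input(self, m_s: Tensor, m_cc: Tensor, m_hx: Tensor,
                       hx_valid) -> AssembledInput:
        """Stack [CLS], M_S, M_CC, M_Hx; add position embeddings (ids 0..3)
        and segment embeddings (all level 0); mask = (1,1,1,hx_valid)."""
        b, d = m_s.shape
        if m_cc.shape != (b, d) or m_hx.shape != (b, d):
            raise ValueError("M_S, M_CC, M_Hx must share shape (B, d_hidden)")
        hx_valid = np.atleast_1d(np.asarray(hx_valid, dtype=int))
        cls_row = (self.cls_token.reshape(1, 1, -1)
                   * Tensor(np.ones((b, 1, 1))))  # broadcast learned [CLS] over batch
        tokens = concat(
            [cls_row, m_s.reshape(b, 1, d), m_cc.reshape(b, 1, d), m_hx.reshape(b, 1, d)],
            axis=1,
        )
        position_ids = np.tile(np.arange(4), (b, 1))
        segment_ids = np.zeros((b, 4), dtype=int)
        tokens = tokens + self.position_table.reshape(1, 4, d) \
                        + self.segment_table[segment_ids]
        mask = np.column_stack([np.ones((b, 3), dtype=int), hx_valid])
        return AssembledInput(tokens=tokens, mask=mask,
                              segment_ids=segment_ids, position_ids=position_ids)

    # -- encoding ----------------------------------------------------------
    def embed(self, assembled: AssembledInput) -> Tensor:
        """ε = tanh([CLS] row of the Transformer output): every coordinate
        in [-1, 1]."""
        if not assembled.mask.any(axis=-1).all():
            raise ValueError("EMPTY_INPUT: all positions masked")
        out = self.encoder(assembled.tokens, assembled.mask)
        return out[:, 0, :].tanh()

    def forward(self, s, cc_feat, hx_feat, hx_valid) -> Tensor:
        m_s = self.project_structural(s)
        m_cc = self.project_text(cc_feat)
        m_hx = self.project_text(hx_feat)
        return self.embed(self.assemble_input(m_s, m_cc, m_hx, hx_valid))

    __call__ = forward


class DimDiscriminator(Module):
    """β_D: Transformer scorer of (ε, visit-tokens) pairs.

    Shares the encoder architecture; input sequence [CLS], ε, [SEP], M_S,
    M_CC, M_Hx with segment ids (0,0,1,1,1,1); the score is
    sigmoid(w·[CLS] row), an estimate of p(ε | m).
    """

    SEQ_LEN = 6

    def __init__(self, config: ModelConfig, rng: np.random.Generator):
        self.config = config
        d = config.d_hidden
        self.cls_token = Tensor(rng.normal(0, 0.02, size=d), requires_grad=True)
        self.sep_token = Tensor(rng.normal(0, 0.02, size=d), requires_grad=True)
        self.position_table = Tensor(rng.normal(0, 0.02, size=(self.SEQ_LEN, d)),
                                     requires_grad=True)
        self.segment_table = Tensor(rng.normal(0, 0.02, size=(2, d)), requires_grad=True)
        self.encoder = TransformerEncoder(d, config.n_layers, config.n_heads, rng)
        self.readout = Linear(d, 1, rng)

    def score(self, eps: Tensor, m_s: Tensor, m_cc: Tensor, m_hx: Tensor,
              hx_valid) -> Tensor:
        b, d = eps.shape
        hx_valid = np.atleast_1d(np.asarray(hx_valid, dtype=int))
        ones = Tensor(np.ones((b, 1, 1)))
        tokens = concat(
            [self.cls_token.reshape(1, 1, -1) * ones,
             eps.reshape(b, 1, d),
             self.sep_token.reshape(1, 1, -1) * ones,
             m_s.reshape(b, 1, d), m_cc.reshape(b, 1, d), m_hx.reshape(b, 1, d)],
            axis=1,
        )
        segment_ids = np.tile(np.array([0, 0, 1, 1, 1, 1]), (b, 1))
        tokens = tokens + self.position_table.reshape(1, self.SEQ_LEN, d) \
                        + self.segment_table[segment_ids]
        mask = np.column_stack([np.ones((b, 5), dtype=int), hx_valid])
        out = self.encoder(tokens, mask)
        return self.readout(out[:, 0, :]).sigmoid().reshape(-1)

    __call__ = score


def augment(s_batch: np.ndarray, hx_valid: np.ndarray, sd_vector: np.ndarray,
            config: ModelConfig, rng: np.random.Generator,
            gender_index: int = 1) -> tuple[np.ndarray, np.ndarray]:
    """One stochastic view of a batch for contrastive pretraining.

    (a) adds zero-mean Gaussian noise to each structural element with scale
    ``noise_fraction`` × that field's training SD (gender excluded: noise
    must not cross the category boundary), and (b) independently drops the
    history slot (hx_valid -> 0) with probability ``history_mask_prob``.
    Two calls with independent rng draws give a SimCLR positive pair.
    """
    s_batch = np.asarray(s_batch, dtype=float)
    hx_valid = np.asarray(hx_valid, dtype=int)
    s_out = s_batch.copy()
    if config.noise_fraction > 0:
        noise = rng.normal(0.0, 1.0, size=s_batch.shape) * config.noise_fraction * sd_vector
        noise[..., gender_index] = 0.0
        s_out = s_out + noise
    hx_out = hx_valid.copy()
    if config.history_mask_prob > 0:
        drop = rng.random(size=hx_valid.shape) < config.history_mask_prob
        hx_out = np.where(drop, 0, hx_out)
    return s_out, hx_out
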