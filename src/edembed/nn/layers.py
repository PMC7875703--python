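"""Neural-network building blocks: Linear, LayerNorm, MLP, and a BERT-style
post-norm Transformer encoder with additive key masking."""

from __future__ import annotations

import numpy as np

from .tensor import Tensor, concat

__all__ = [
    "Module",
    "Linear",
    "MLP",
    "LayerNorm",
    "TransformerLayer",
    "TransformerEncoder",
]

_MASK_NEG = -1e9  # additive logit for masked keys; exp(-1e9) underflows to exactly 0


class Module:
    """Parameter container with recursive traversal and (de)serialization."""

    def parameters(self) -> list[Tensor]:
        params: list[Tensor] = []
        for value in vars(self).values():
            if isinstance(value, Tensor) and value.requires_grad:
                params.append(value)
            elif isinstance(value, Module):
                params.extend(value.parameters())
            elif isinstance(value, (list, tuple)):
                for item in value:
                    if isinstance(item, Module):
                        params.extend(item.parameters())
        return params

    def named_parameters(self, prefix: str = "") -> dict[str, Tensor]:
        out: dict[str, Tensor] = {}
        for name, value in vars(self).items():
            key = f"{prefix}{name}"
            if isinstance(value, Tensor) and value.requires_grad:
                out[key] = value
            elif isinstance(value, Module):
                out.update(value.named_parameters(f"{key}."))
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, Module):
                        out.update(item.named_parameters(f"{key}.{i}."))
        return out

    def state_dict(self) -> dict[str, np.ndarray]:
        return {k: v.data.copy() for k, v in self.named_parameters().items()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        params = self.named_parameters()
        missing = set(params) - set(state)
        if missing:
            raise KeyError(f"state dict missing parameters: {sorted(missing)}")
        for key, param in params.items():
            arr = np.asarray(state[key], dtype=np.float64)
            if arr.shape != param.data.shape:
                raise ValueError(f"shape mismatch for {key}: {arr.shape} vs {param.data.shape}")
            param.data = arr.copy()

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.zero_grad()


def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    scale = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-scale, scale, size=(fan_in, fan_out))


class Linear(Module):
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator):
        self.weight = Tensor(_glorot(rng, d_in, d_out), requires_grad=True)
        self.bias = Tensor(np.zeros(d_out), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.weight + self.bias


class MLP(Module):
    """Feed-forward stack with GELU between layers, linear output."""

    def __init__(self, widths: list[int], rng: np.random.Generator):
        self.layers = [Linear(a, b, rng) for a, b in zip(widths[:-1], widths[1:])]

    def __call__(self, x: Tensor) -> Tensor:
        for i, layer in enumerate(self.layers):
            x = layer(x)
            if i < len(self.layers) - 1:
                x = x.gelu()
        return x


class LayerNorm(Module):
    def __init__(self, d: int, eps: float = 1e-5):
        self.gain = Tensor(np.ones(d), requires_grad=True)
        self.shift = Tensor(np.zeros(d), requires_grad=True)
        self.eps = eps

    def __call__(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        centered = x - mu
        var = (centered * centered).mean(axis=-1, keepdims=True)
        return centered / (var + self.eps) ** 0.5 * self.gain + self.shift


class TransformerLayer(Module):
    """Post-norm (BERT-style) block: self-attention then feed-forward,
    each wrapped in residual + LayerNorm."""

    def __init__(self, d_model: int, n_heads: int, d_ff: int, rng: np.random.Generator):
        if d_model % n_heads:
            raise ValueError("d_model must be divisible by n_heads")
        self.n_heads = n_heads
        self.d_head = d_model // n_heads
        self.wq = Linear(d_model, d_model, rng)
        self.wk = Linear(d_model, d_model, rng)
        self.wv = Linear(d_model, d_model, rng)
        self.wo = Linear(d_model, d_model, rng)
        self.ff1 = Linear(d_model, d_ff, rng)
        self.ff2 = Linear(d_ff, d_model, rng)
        self.norm1 = LayerNorm(d_model)
        self.norm2 = LayerNorm(d_model)

    def _attention(self, x: Tensor, key_mask: np.ndarray) -> Tensor:
        b, t, d = x.shape
        h, dh = self.n_heads, self.d_head

        def split(v: Tensor) -> Tensor:  # (B,T,D) -> (B,H,T,dh)
            return v.reshape(b, t, h, dh).transpose(0, 2, 1, 3)

        q, k, v = split(self.wq(x)), split(self.wk(x)), split(self.wv(x))
        scores = q @ k.swapaxes(-1, -2) * (1.0 / np.sqrt(dh))  # (B,H,T,T)
        bias = np.where(key_mask[:, None, None, :] > 0, 0.0, _MASK_NEG)
        attn = (scores + Tensor(bias)).softmax(axis=-1)
        out = (attn @ v).transpose(0, 2, 1, 3).reshape(b, t, d)
        return self.wo(out)

    def __call__(self, x: Tensor, key_mask: np.ndarray) -> Tensor:
        x = self.norm1(x + self._attention(x, key_mask))
        x = self.norm2(x + self.ff2(self.ff1(x).gelu()))
        return x


class TransformerEncoder(Module):
    """Stack of post-norm Transformer layers sharing one key mask.

    `key_mask` is a {0,1} array of shape (batch, seq); positions with 0 are
    invisible to every attention query in every layer, so their content can
    never reach any other position's output.
    """

    def __init__(self, d_model: int, n_layers: int, n_heads: int,
                 rng: np.random.Generator, d_ff: int | None = None):
        d_ff = d_ff or 4 * d_model
        self.layers = [TransformerLayer(d_model, n_heads, d_ff, rng) for _ in range(n_layers)]

    def __call__(self, x: Tensor, key_mask: np.ndarray) -> Tensor:
        key_mask = np.asarray(key_mask)
        if key_mask.ndim == 1:
            key_mask = key_mask[None, :]
        if not key_mask.any(axis=-1).all():
            raise ValueError("EMPTY_INPUT: attention mask is all-zero for some row")
        for layer in self.layers:
            x = layer(x, key_mask)
        return x
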