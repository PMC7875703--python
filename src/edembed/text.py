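"""Text features for chief complaints and past-history entries.

A text encoder is any object satisfying :class:`TextEncoder`: it maps a
free-text span to a fixed-width dense feature, deterministically. The
package ships :class:`HashingTextEncoder`, a seeded signed hashing
bag-of-words encoder: lightweight, deterministic, and order-insensitive, so
the full pipeline is testable without a large pretrained language model.
Any frozen sentence encoder with the same ``encode`` / ``d_text`` surface
can be dropped in.

Variable-length history lists are averaged into a single feature; an empty
history yields the padding feature with a validity bit of 0, which the
embedding model masks out downstream.
"""

from __future__ import annotations

import hashlib
import re
from dataclasses import dataclass
from typing import Protocol, runtime_checkable

import numpy as np

from .losses import nt_xent_value

__all__ = [
    "TextFeature",
    "TextEncoder",
    "HashingTextEncoder",
    "hash_encode",
    "padding_feature",
    "history_mean",
    "text_pair_contrastive_loss",
]

_TOKEN_RE = re.compile(r"[a-z0-9]+")


@dataclass
class TextFeature:
    """Dense feature of one free-text span.

    ``kind`` records the span's role: CC (chief complaint), PI (present
    illness), HX (past history), or PAD (the padding feature standing in
    for an absent span).
    """

    vector: np.ndarray
    kind: str = "CC"

    @property
    def d_text(self) -> int:
        return self.vector.shape[0]


@runtime_checkable
class TextEncoder(Protocol):
    d_text: int

    def encode(self, text: str, kind: str = "CC") -> TextFeature: ...


def _token_bucket(token: str, d_text: int, seed: int) -> tuple[int, float]:
    digest = hashlib.blake2b(token.encode(), digest_size=8,
                             key=str(seed).encode()).digest()
    value = int.from_bytes(digest, "big")
    return value % d_text, 1.0 if (value >> 63) & 1 else -1.0


def hash_encode(text: str, d_text: int = 768, seed: int = 0, kind: str = "CC") -> TextFeature:
    """Signed hashing bag-of-words feature, L2-normalized.

    Tokenizes on lowercase alphanumeric runs; each token adds ±1 to a
    hashed bucket. Equal bags of tokens give equal features regardless of
    word order; the empty text gives the zero PAD feature. The blake2b hash
    is keyed by ``seed``, so features are stable across processes.
    """
    if d_text < 8:
        raise ValueError("d_text must be at least 8")
    vec = np.zeros(d_text)
    tokens = _TOKEN_RE.findall(text.lower())
    if not tokens:
        return TextFeature(vector=vec, kind="PAD")
    for token in tokens:
        bucket, sign = _token_bucket(token, d_text, seed)
        vec[bucket] += sign
    norm = np.linalg.norm(vec)
    if norm > 0:
        vec = vec / norm
    return TextFeature(vector=vec, kind=kind)


class HashingTextEncoder:
    """Reference :class:`TextEncoder` built on :func:`hash_encode`."""

    def __init__(self, d_text: int = 768, seed: int = 0):
        self.d_text = d_text
        self.seed = seed

    def encode(self, text: str, kind: str = "CC") -> TextFeature:
        return hash_encode(text, d_text=self.d_text, seed=self.seed, kind=kind)


def padding_feature(d_text: int) -> TextFeature:
    """The fixed padding feature: all zeros. Its content is masked out by
    the embedding model, and zeros make that mask contract easy to test."""
    return TextFeature(vector=np.zeros(d_text), kind="PAD")


def history_mean(features: list[TextFeature],
                 padding: TextFeature | None = None) -> tuple[TextFeature, int]:
    """Element-wise mean of a patient's history features.

    Averaging happens on the raw text features, before any projection.
    An empty history returns ``(padding, valid=0)``.
    """
    if not features:
        if padding is None:
            raise ValueError("empty history requires an explicit padding feature")
        return padding, 0
    d = features[0].d_text
    for f in features:
        if f.d_text != d:
            raise ValueError(f"DIM_MISMATCH: {f.d_text} != {d}")
    mean = np.mean([f.vector for f in features], axis=0)
    return TextFeature(vector=mean, kind="HX"), 1


def save_feature_cache(path, features: dict[str, TextFeature]) -> None:
    """Persist per-visit text features as an .npz archive with a JSON
    sidecar schema (visit_id -> span kind, plus d_text)."""
    import json
    from pathlib import Path

    path = Path(path)
    np.savez(path, **{vid: f.vector for vid, f in features.items()})
    sidecar = {"d_text": next(iter(features.values())).d_text if features else 0,
               "kinds": {vid: f.kind for vid, f in features.items()}}
    Path(str(path) + ".json").write_text(json.dumps(sidecar))


def load_feature_cache(path) -> dict[str, TextFeature]:
    import json
    from pathlib import Path

    path = Path(path)
    sidecar = json.loads(Path(str(path) + ".json").read_text())
    with np.load(path if path.suffix == ".npz" else str(path) + ".npz") as archive:
        return {vid: TextFeature(archive[vid].copy(), sidecar["kinds"][vid])
                for vid in archive.files}


def text_pair_contrastive_loss(anchor_feats: np.ndarray, positive_feats: np.ndarray,
                               temperature: float = 0.5) -> float:
    """NT-Xent loss over B text-feature pairs.

    Row i of the two arrays is a positive pair — the chief complaint and
    present illness of the same patient, or two history subsets of the same
    patient — and every other pairing in the 2B batch is a negative. Shares
    the NT-Xent implementation used for the embedding-level contrastive
    loss.
    """
    anchor_feats = np.asarray(anchor_feats, dtype=float)
    positive_feats = np.asarray(positive_feats, dtype=float)
    if anchor_feats.shape != positive_feats.shape:
        raise ValueError("anchor and positive batches must have equal shapes")
    if anchor_feats.shape[0] < 2:
        raise ValueError("NEED_NEGATIVES: batch size must be at least 2")
    return nt_xent_value(anchor_feats, positive_feats, temperature)
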