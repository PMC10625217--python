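"""Text encoders and batch-level inter-sample attention.

Two text backends produce a d-dimensional embedding per article field
(title or abstract) from the final-layer classification-token state:

* ``toy`` — a deterministic, dependency-free encoder: each normalized
  token is hashed into one of d buckets, the bucket-indicator vectors
  (including a reserved ``[CLS]`` token) are mean-pooled, and the pooled
  vector is passed through a fixed random projection drawn once from the
  configured seed.  All tests and desk-scale experiments run on this
  backend.
* ``pretrained`` — a biomedical transformer via HuggingFace, returning the
  final-layer [CLS] embedding.  Requires the optional ``torch`` and
  ``transformers`` dependencies.

Inter-sample attention operates across the *samples of a batch*, not the
tokens of a text: the batch matrix r (s×d) is projected with trainable
square matrices W^Q, W^K, W^V, each sample's weight vector is the softmax
of its query against all keys in the batch, and its output representation
is the corresponding mixture of value rows.  No 1/sqrt(d) scaling is
applied by default; ``scaled=True`` enables the conventional variant.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from typing import Optional, Protocol

import numpy as np

from .corpus import normalize_tokens

__all__ = [
    "TextEncoder",
    "ToyTextEncoder",
    "PretrainedTextEncoder",
    "get_encoder",
    "AttentionParams",
    "AttentionOutput",
    "init_attention_params",
    "intersample_attention",
    "attention_backward",
]

CLS_TOKEN = "[CLS]"


class TextEncoder(Protocol):
    dim: int

    def encode(self, text: str) -> np.ndarray: ...

    def encode_batch(self, texts: list[str]) -> np.ndarray: ...


def _bucket(token: str, dim: int) -> int:
    digest = hashlib.blake2b(token.encode("utf-8"), digest_size=8).digest()
    return int.from_bytes(digest, "big") % dim


class ToyTextEncoder:
    """Deterministic hash–pool–project text encoder.

    Recipe: prepend the reserved classification token, truncate to
    ``max_len`` tokens, hash each token into one of ``dim`` buckets
    (blake2b mod dim), mean-pool the bucket indicator vectors, and apply a
    fixed ``dim x dim`` Gaussian projection (scaled by 1/sqrt(dim)) drawn
    from ``seed``.  Empty text encodes the classification token alone.
    """

    kind = "toy"

    def __init__(self, dim: int = 64, max_len: int = 512, seed: int = 0) -> None:
        if dim < 1 or max_len < 1:
            raise ValueError("dim and max_len must be positive")
        self.dim = dim
        self.max_len = max_len
        self.seed = seed
        rng = np.random.default_rng(seed)
        self.projection = rng.standard_normal((dim, dim)) / np.sqrt(dim)

    def encode(self, text: str) -> np.ndarray:
        tokens = [CLS_TOKEN] + normalize_tokens(text)
        tokens = tokens[: self.max_len]
        pooled = np.zeros(self.dim)
        for tok in tokens:
            pooled[_bucket(tok, self.dim)] += 1.0
        pooled /= len(tokens)
        return pooled @ self.projection

    def encode_batch(self, texts: list[str]) -> np.ndarray:
        return np.stack([self.encode(t) for t in texts]) if texts else np.zeros((0, self.dim))

    def config(self) -> dict:
        return {"kind": "toy", "dim": self.dim, "max_len": self.max_len, "seed": self.seed}


class PretrainedTextEncoder:
    """Final-layer [CLS] embeddings from a pretrained biomedical transformer.

    Uses the model's own tokenizer with tail truncation at ``max_len``.
    Deterministic in evaluation mode.  Needs the optional ``pretrained``
    extra (torch + transformers).
    """

    kind = "pretrained"

    def __init__(
        self,
        name: str = "microsoft/BiomedNLP-PubMedBERT-base-uncased-abstract-fulltext",
        max_len: int = 512,
    ) -> None:
        try:
            import torch  # noqa: F401
            from transformers import AutoModel, AutoTokenizer
        except ImportError as exc:  # pragma: no cover - optional dependency
            raise ImportError(
                "the pretrained text backend requires the optional 'torch' and "
                "'transformers' dependencies (pip install litscreen[pretrained]); "
                "use the 'toy' backend otherwise"
            ) from exc
        self._torch = __import__("torch")
        self.tokenizer = AutoTokenizer.from_pretrained(name)
        self.model = AutoModel.from_pretrained(name)
        self.model.eval()
        self.name = name
        self.max_len = max_len
        self.dim = int(self.model.config.hidden_size)

    def encode(self, text: str) -> np.ndarray:  # pragma: no cover - optional dependency
        return self.encode_batch([text])[0]

    def encode_batch(self, texts: list[str]) -> np.ndarray:  # pragma: no cover
        torch = self._torch
        enc = self.tokenizer(
            texts, padding=True, truncation=True, max_length=self.max_len, return_tensors="pt"
        )
        with torch.no_grad():
            out = self.model(**enc)
        return out.last_hidden_state[:, 0, :].numpy()

    def config(self) -> dict:  # pragma: no cover
        return {"kind": "pretrained", "name": self.name, "max_len": self.max_len}


def get_encoder(config: dict) -> TextEncoder:
    """Build a text encoder from ``{kind: toy|pretrained, ...}`` config."""
    kind = config.get("kind", "toy")
    if kind == "toy":
        return ToyTextEncoder(
            dim=config.get("dim", 64),
            max_len=config.get("max_len", 512),
            seed=config.get("seed", 0),
        )
    if kind == "pretrained":
        return PretrainedTextEncoder(
            name=config.get("name", "microsoft/BiomedNLP-PubMedBERT-base-uncased-abstract-fulltext"),
            max_len=config.get("max_len", 512),
        )
    raise ValueError(f"unknown encoder kind {kind!r}")


@dataclass
class AttentionParams:
    """Trainable square projections (no bias) for one attention stream."""

    wq: np.ndarray
    wk: np.ndarray
    wv: np.ndarray

    def __post_init__(self) -> None:
        d = self.wq.shape[0]
        for name in ("wq", "wk", "wv"):
            m = getattr(self, name)
            if m.shape != (d, d):
                raise ValueError(f"{name} must be square of dimension {d}, got {m.shape}")


@dataclass
class AttentionOutput:
    """Per-sample attention weights (s×s, rows sum to 1) and outputs (s×d)."""

    weights: np.ndarray
    output: np.ndarray
    _cache: Optional[dict] = None


def init_attention_params(d: int, rng: np.random.Generator, scale: float = 0.2) -> AttentionParams:
    return AttentionParams(
        wq=scale * rng.standard_normal((d, d)),
        wk=scale * rng.standard_normal((d, d)),
        wv=scale * rng.standard_normal((d, d)),
    )


def _softmax_rows(scores: np.ndarray) -> np.ndarray:
    shifted = scores - scores.max(axis=1, keepdims=True)
    e = np.exp(shifted)
    return e / e.sum(axis=1, keepdims=True)


def intersample_attention(
    r: np.ndarray, params: AttentionParams, scaled: bool = False, keep_cache: bool = False
) -> AttentionOutput:
    """Weight each sample's embedding by its batch-mates.

    Q = r W^Q, K = r W^K, V = r W^V; row i of the weight matrix is
    softmax(q_i K^T) (divided by sqrt(d) first when ``scaled``); the output
    row is that weight vector applied to V.
    """
    if r.ndim != 2 or r.shape[0] < 1:
        raise ValueError("batch matrix must be 2-D with at least one row")
    d = r.shape[1]
    if params.wq.shape[0] != d:
        raise ValueError(f"attention dimension mismatch: batch d={d}, params d={params.wq.shape[0]}")
    q = r @ params.wq
    k = r @ params.wk
    v = r @ params.wv
    scores = q @ k.T
    if scaled:
        scores = scores / np.sqrt(d)
    weights = _softmax_rows(scores)
    output = weights @ v
    cache = {"r": r, "q": q, "k": k, "v": v, "weights": weights, "scaled": scaled} if keep_cache else None
    return AttentionOutput(weights=weights, output=output, _cache=cache)


def attention_backward(
    out: AttentionOutput, d_output: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Gradients of a scalar loss w.r.t. (W^Q, W^K, W^V), given the gradient
    w.r.t. the attention output.  The batch matrix r is treated as constant
    (the toy encoder has no trainable parameters)."""
    if out._cache is None:
        raise ValueError("attention output was computed without keep_cache=True")
    c = out._cache
    r, q, k, v, a = c["r"], c["q"], c["k"], c["v"], c["weights"]
    d_v = a.T @ d_output
    d_a = d_output @ v.T
    # softmax backward, row-wise
    d_scores = a * (d_a - (d_a * a).sum(axis=1, keepdims=True))
    if c["scaled"]:
        d_scores = d_scores / np.sqrt(r.shape[1])
    d_q = d_scores @ k
    d_k = d_scores.T @ q
    return r.T @ d_q, r.T @ d_k, r.T @ d_v
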