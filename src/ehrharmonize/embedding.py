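"""Text preprocessing and the pluggable text -> vector embedding contract.

Preprocessing lowercases, optionally strips configured note sections (e.g.
physical exam, discharge instructions), and truncates on whitespace tokens.
Two truncation sides are exposed because extraction pipelines commonly keep
the *first* N words of a note while encoder input limits keep the *last* N
tokens; both conventions appear in practice, so neither is hard-coded.

The embedding contract is a simple protocol: ``embed(text) -> (d,) vector``,
deterministic per text.  The bundled reference implementation is a hashed
bag-of-words projected through a seeded fixed Gaussian matrix and
L2-normalised — a fast, dependency-free, fully deterministic stand-in for a
pretrained clinical encoder.  An adapter wrapping a real transformer encoder
can be registered under the same contract.
"""

from __future__ import annotations

import hashlib
import re
from dataclasses import dataclass, field
from typing import Callable, Protocol

import numpy as np


class EmbeddingError(RuntimeError):
    """Raised when an embedding provider fails."""


@dataclass(frozen=True)
class EmbeddingConfig:
    dim: int = 768
    token_limit: int = 512
    truncation_side: str = "last_tokens"  # or "first_words"
    lowercase: bool = True
    strip_sections: tuple[str, ...] = ()
    hash_buckets: int = 4096
    seed: int = 0

    def __post_init__(self) -> None:
        if self.dim < 2:
            raise ValueError("dim must be >= 2")
        if self.token_limit < 1:
            raise ValueError("token_limit must be >= 1")
        if self.truncation_side not in ("first_words", "last_tokens"):
            raise ValueError(f"unknown truncation_side {self.truncation_side!r}")


_HEADER_LINE = re.compile(r"^\s*[A-Za-z][A-Za-z /]*:")


def strip_section(text: str, header: str) -> str:
    """Remove a note section: from its header line up to (excluding) the
    next header-like line (``Title:`` style) or the end of the text."""
    out, skipping = [], False
    header_lc = header.lower()
    for line in text.splitlines(keepends=True):
        if skipping and _HEADER_LINE.match(line):
            skipping = False
        if line.lstrip().lower().startswith(header_lc):
            skipping = True
        if not skipping:
            out.append(line)
    return "".join(out)


def preprocess(text: str, config: EmbeddingConfig) -> str:
    """Lowercase, strip configured sections, truncate on whitespace tokens."""
    if not text:
        return ""
    for header in config.strip_sections:
        text = strip_section(text, header)
    if config.lowercase:
        text = text.lower()
    tokens = text.split()
    if len(tokens) > config.token_limit:
        if config.truncation_side == "first_words":
            tokens = tokens[: config.token_limit]
        else:
            tokens = tokens[-config.token_limit :]
    return " ".join(tokens)


class EmbeddingProvider(Protocol):
    """Contract: deterministic text -> d-vector."""

    dim: int

    def embed(self, text: str) -> np.ndarray: ...


def _token_hash(token: str, buckets: int) -> int:
    digest = hashlib.blake2b(token.encode("utf-8"), digest_size=8).digest()
    return int.from_bytes(digest, "little") % buckets


@dataclass
class HashingEmbedder:
    """Hashed bag-of-words -> fixed random projection -> L2 normalisation.

    Deterministic (token hashing is seed-free; the projection matrix is drawn
    once from ``config.seed``).  Bag-of-words by construction, so token order
    does not matter.  Empty text maps to the zero vector.
    """

    config: EmbeddingConfig = field(default_factory=EmbeddingConfig)

    def __post_init__(self) -> None:
        rng = np.random.default_rng(self.config.seed)
        self._projection = rng.normal(
            0.0, 1.0, size=(self.config.hash_buckets, self.config.dim)
        ) / np.sqrt(self.config.dim)
        self.dim = self.config.dim

    def embed(self, text: str) -> np.ndarray:
        tokens = text.split()
        if not tokens:
            return np.zeros(self.dim)
        counts = np.zeros(self.config.hash_buckets)
        for tok in tokens:
            counts[_token_hash(tok, self.config.hash_buckets)] += 1.0
        vec = counts @ self._projection
        norm = np.linalg.norm(vec)
        return vec / norm if norm > 0 else vec


_PROVIDERS: dict[str, Callable[[EmbeddingConfig], EmbeddingProvider]] = {
    "hashing": HashingEmbedder,
}


def register_provider(
    name: str, factory: Callable[[EmbeddingConfig], EmbeddingProvider]
) -> None:
    _PROVIDERS[name] = factory


def get_provider(name: str, config: EmbeddingConfig) -> EmbeddingProvider:
    try:
        factory = _PROVIDERS[name]
    except KeyError:
        raise EmbeddingError(
            f"unknown embedding provider {name!r}; registered: {sorted(_PROVIDERS)}"
        ) from None
    return factory(config)
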