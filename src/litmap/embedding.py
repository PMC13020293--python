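"""Joint document–word embeddings and vector arithmetic.

The topic pipeline only assumes an :class:`Embedder`: something that
maps documents, vocabulary terms and free phrases into one shared
d-dimensional space, where cosine similarity expresses semantic
association. Production systems plug in a pretrained sentence encoder;
the package itself ships :class:`HashingEmbedder`, a deterministic
bag-of-tokens embedder that hashes tokens into ``dim`` buckets with
term-frequency weighting and L2 normalisation. Its word vectors are the
one-hot hashed token vectors, so documents and words genuinely live in
one space — enough for clustering and nearest-word extraction on
corpora whose topics differ in vocabulary, and fully reproducible
(seeded hashing, no model download, bit-identical across runs).
"""

from __future__ import annotations

import hashlib
import re
from typing import Protocol, Sequence, runtime_checkable

import numpy as np

from .records import PublicationRecord

_TOKEN_RE = re.compile(r"[^0-9a-z]+")


def tokenize(text: str, min_len: int = 2) -> list[str]:
    """Lowercase, split on non-alphanumerics, drop tokens shorter than 2.

    The same tokeniser backs the hashing embedder, the class-based
    topic-word extraction and the coherence windows, so word
    probabilities and word vectors refer to the same vocabulary.
    """
    return [t for t in _TOKEN_RE.split(text.lower()) if len(t) >= min_len]


@runtime_checkable
class Embedder(Protocol):
    """Behavioural contract for a joint document–word embedding."""

    dim: int

    def embed_documents(self, texts: Sequence[str]) -> np.ndarray: ...

    def embed_terms(self, vocabulary: Sequence[str]) -> np.ndarray: ...

    def embed_phrase(self, text: str) -> np.ndarray: ...


class HashingEmbedder:
    """Deterministic seeded bag-of-tokens embedder.

    Each token hashes to a bucket index and a sign via blake2b keyed by
    the seed; a document vector is the signed TF-weighted sum of its
    token vectors, L2-normalised. Semantic similarity is purely lexical
    overlap — appropriate for synthetic corpora with planted topic
    vocabularies, not for real prose.
    """

    def __init__(self, dim: int = 256, seed: int = 0):
        if dim < 2:
            raise ValueError("embedding dimension must be >= 2")
        self.dim = dim
        self.seed = seed

    def _bucket(self, token: str) -> tuple[int, float]:
        digest = hashlib.blake2b(
            token.encode("utf-8"), key=str(self.seed).encode(), digest_size=8
        ).digest()
        value = int.from_bytes(digest, "big")
        return value % self.dim, 1.0 if (value >> 63) & 1 else -1.0

    def embed_phrase(self, text: str) -> np.ndarray:
        vec = np.zeros(self.dim)
        for token in tokenize(text):
            idx, sign = self._bucket(token)
            vec[idx] += sign
        norm = np.linalg.norm(vec)
        return vec / norm if norm > 0 else vec

    def embed_documents(self, texts: Sequence[str]) -> np.ndarray:
        return np.vstack([self.embed_phrase(t) for t in texts])

    def embed_terms(self, vocabulary: Sequence[str]) -> np.ndarray:
        out = np.zeros((len(vocabulary), self.dim))
        for i, term in enumerate(vocabulary):
            idx, sign = self._bucket(term.lower())
            out[i, idx] = sign
        return out


def cosine_similarity(u: np.ndarray, v: np.ndarray) -> float:
    """Cosine of the angle between two vectors, in [-1, 1]."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if u.shape != v.shape:
        raise ValueError(f"dimension mismatch: {u.shape} vs {v.shape}")
    nu = np.linalg.norm(u)
    nv = np.linalg.norm(v)
    if nu == 0.0 or nv == 0.0:
        raise ValueError("cosine similarity is undefined for a zero vector")
    return float(np.clip(np.dot(u, v) / (nu * nv), -1.0, 1.0))


def embed_corpus(
    records: Sequence[PublicationRecord], embedder: Embedder
) -> tuple[np.ndarray, list[str]]:
    """Embed title + body of each record; row i corresponds to record i.

    Returns the document-vector matrix and the aligned pub_id index.
    """
    if not records:
        raise ValueError("cannot embed an empty corpus")
    matrix = embedder.embed_documents([rec.text for rec in records])
    return matrix, [rec.pub_id for rec in records]
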