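"""Sentence-embedding backends and the shared TF-IDF vectorizer.

Two embedding backends sit behind one contract:

``offline-hash``
    A deterministic, dependency-free feature-hashing embedder: lowercase
    whitespace tokens are hashed into signed buckets, the bag vector is
    projected through a seed-fixed random Gaussian matrix and L2-normalized.
    It preserves bag-of-words geometry (shared tokens -> higher cosine),
    which is all the recommendation pipeline relies on, and keeps every test
    and simulation fully offline and reproducible.

``pretrained``
    An optional adapter around ``sentence-transformers`` models (default
    ``sentence-transformers/all-MiniLM-L6-v2``); never required by the core
    pipeline or the tests.

The TF-IDF model here is shared by the profile builder's author
discriminator and the TF-IDF+LR ranking baseline, so both operate in a
single feature space fitted once on the full abstract collection.  Dialect:
lowercase unigrams, no stop list, smoothed idf = ln((1+N)/(1+df)) + 1,
L2-normalized output.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from functools import lru_cache
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import scipy.sparse as sp
from sklearn.feature_extraction.text import CountVectorizer, TfidfVectorizer
from sklearn.preprocessing import normalize as _sk_normalize

from .errors import ConfigurationError, TrainingError

__all__ = [
    "EmbedderSpec",
    "SentenceEmbedding",
    "hash_embed",
    "embed_sentences",
    "register_backend",
    "TfidfModel",
    "fit_tfidf",
    "tfidf_transform",
]

SentenceEmbedding = np.ndarray  # 1-D float64 vector of length `dim`

DEFAULT_DIM = 384  # dimensionality of the MiniLM sentence encoder
_N_BUCKETS = 4096


@dataclass(frozen=True)
class EmbedderSpec:
    """Resolvable description of an embedding backend.

    ``seed`` only matters for the offline-hash backend, where it fixes the
    random projection; ``model_id`` only for the pretrained adapter.
    """

    backend: str = "offline-hash"
    dim: int = DEFAULT_DIM
    seed: int = 0
    model_id: str = "sentence-transformers/all-MiniLM-L6-v2"


def _token_hash(token: str) -> int:
    # blake2b rather than hash(): stable across processes and runs
    return int.from_bytes(
        hashlib.blake2b(token.encode("utf-8"), digest_size=8).digest(), "big"
    )


@lru_cache(maxsize=8)
def _projection(n_buckets: int, dim: int, seed: int) -> np.ndarray:
    rng = np.random.default_rng(seed)
    return rng.standard_normal((n_buckets, dim)) / np.sqrt(dim)


def hash_embed(text: str, dim: int = DEFAULT_DIM, seed: int = 0) -> SentenceEmbedding:
    """Deterministic offline sentence embedding.

    Empty or token-free text maps to the all-zero vector.  Only the bag of
    lowercase whitespace tokens matters; token order is irrelevant.
    """
    if dim < 2:
        raise ConfigurationError("hash_embed requires dim >= 2")
    tokens = text.lower().split()
    if not tokens:
        return np.zeros(dim)
    bag = np.zeros(_N_BUCKETS)
    for tok in tokens:
        h = _token_hash(tok)
        sign = 1.0 if (h >> 63) & 1 == 0 else -1.0
        bag[h % _N_BUCKETS] += sign
    vec = bag @ _projection(_N_BUCKETS, dim, seed)
    norm = np.linalg.norm(vec)
    if norm > 0:
        vec = vec / norm
    return vec


def _offline_hash_backend(texts: Sequence[str], spec: EmbedderSpec) -> list[np.ndarray]:
    return [hash_embed(t, dim=spec.dim, seed=spec.seed) for t in texts]


def _pretrained_backend(texts: Sequence[str], spec: EmbedderSpec) -> list[np.ndarray]:
    try:
        from sentence_transformers import SentenceTransformer
    except ImportError as exc:  # pragma: no cover - optional dependency
        raise ConfigurationError(
            "the 'pretrained' backend requires the sentence-transformers "
            "package (pip install recsoi[pretrained])"
        ) from exc
    model = SentenceTransformer(spec.model_id)  # pragma: no cover
    return [np.asarray(v, dtype=float) for v in model.encode(list(texts))]


_BACKENDS: dict[str, Callable[[Sequence[str], EmbedderSpec], list[np.ndarray]]] = {
    "offline-hash": _offline_hash_backend,
    "pretrained": _pretrained_backend,
}


def register_backend(
    name: str, fn: Callable[[Sequence[str], EmbedderSpec], list[np.ndarray]]
) -> None:
    """Register a custom embedding backend under ``name``."""
    _BACKENDS[name] = fn


def embed_sentences(
    texts: Sequence[str], spec: EmbedderSpec | None = None
) -> list[SentenceEmbedding]:
    """Embed each text; one vector of length ``spec.dim`` per input.

    Identical texts map to identical vectors within a run (determinism
    contract of the recommender).
    """
    spec = spec or EmbedderSpec()
    try:
        backend = _BACKENDS[spec.backend]
    except KeyError:
        raise ConfigurationError(
            f"unknown embedding backend {spec.backend!r}; "
            f"registered: {sorted(_BACKENDS)}"
        ) from None
    out = backend(texts, spec)
    for v in out:
        if v.shape != (spec.dim,) and spec.backend == "offline-hash":
            raise ConfigurationError("backend returned wrong dimension")
    return out


# ---------------------------------------------------------------------------
# TF-IDF
# ---------------------------------------------------------------------------


@dataclass
class TfidfModel:
    """A fitted TF-IDF vectorizer (fixed dialect, JSON-serializable).

    The dialect flags are stored so that a serialized model documents its own
    preprocessing choices.
    """

    vocabulary: dict[str, int]
    idf: np.ndarray
    fit_corpus_size: int
    dialect: dict = field(
        default_factory=lambda: {
            "lowercase": True,
            "ngram_range": [1, 1],
            "smooth_idf": True,
            "sublinear_tf": False,
            "norm": "l2",
            "stop_words": None,
            "token_pattern": r"(?u)\b\w\w+\b",
        }
    )

    def __post_init__(self):
        vals = sorted(self.vocabulary.values())
        if vals != list(range(len(self.vocabulary))):
            raise ConfigurationError("vocabulary indices must be a bijection onto 0..V-1")
        self.idf = np.asarray(self.idf, dtype=float)
        if len(self.idf) != len(self.vocabulary):
            raise ConfigurationError("idf length must equal vocabulary size")

    @property
    def n_features(self) -> int:
        return len(self.vocabulary)

    def _counter(self) -> CountVectorizer:
        return CountVectorizer(
            vocabulary=self.vocabulary,
            lowercase=self.dialect["lowercase"],
            token_pattern=self.dialect["token_pattern"],
        )

    def transform(self, texts: Sequence[str]) -> sp.csr_matrix:
        """tf*idf rows, each L2-normalized (zero rows stay zero)."""
        counts = self._counter().transform(texts)
        tfidf = counts.multiply(self.idf).tocsr()
        return _sk_normalize(tfidf, norm="l2", copy=False)

    # -- persistence -------------------------------------------------------
    def to_json(self) -> str:
        return json.dumps(
            {
                "vocabulary": self.vocabulary,
                "idf": self.idf.tolist(),
                "fit_corpus_size": self.fit_corpus_size,
                "dialect": self.dialect,
            },
            sort_keys=True,
        )

    def save(self, path: str | Path) -> None:
        Path(path).write_text(self.to_json(), encoding="utf-8")

    @classmethod
    def from_json(cls, payload: str) -> "TfidfModel":
        obj = json.loads(payload)
        return cls(
            vocabulary=obj["vocabulary"],
            idf=np.asarray(obj["idf"]),
            fit_corpus_size=obj["fit_corpus_size"],
            dialect=obj["dialect"],
        )

    @classmethod
    def load(cls, path: str | Path) -> "TfidfModel":
        return cls.from_json(Path(path).read_text(encoding="utf-8"))


def fit_tfidf(documents: Sequence[str]) -> TfidfModel:
    """Fit the shared TF-IDF space on a document collection.

    idf(t) = ln((1+N)/(1+df(t))) + 1 (smoothed); transform output is
    L2-normalized.  Raises :class:`TrainingError` on an empty or all-empty
    corpus.
    """
    documents = list(documents)
    if not documents or all(not d.strip() for d in documents):
        raise TrainingError("fit_tfidf requires at least one non-empty document")
    vec = TfidfVectorizer(
        lowercase=True, norm="l2", smooth_idf=True, sublinear_tf=False
    )
    try:
        vec.fit(documents)
    except ValueError as exc:
        raise TrainingError(f"TF-IDF fit failed: {exc}") from exc
    vocab = {t: int(i) for t, i in vec.vocabulary_.items()}
    return TfidfModel(
        vocabulary=vocab, idf=vec.idf_.copy(), fit_corpus_size=len(documents)
    )


def tfidf_transform(model: TfidfModel, text: str) -> sp.csr_matrix:
    """Transform one text into a 1 x V sparse tf-idf row (L2 norm 0 or 1)."""
    return model.transform([text])
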