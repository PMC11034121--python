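"""Ranking of SOI candidates for one author.

Four methods share one output contract (:class:`RankedList`):

* ``recsoi`` — ascending minimum Euclidean distance between the candidate's
  sentence embedding and any vector of the author's profile;
* ``baseline_sbert`` — ascending Euclidean distance to a single author
  vector (mean over abstracts of the mean sentence embedding);
* ``baseline_tfidf_lr`` — descending authorship probability from the
  author's TF-IDF discriminator;
* ``random`` — uniform draw without replacement.

All four are deterministic given their inputs (and seed for ``random``);
score ties are broken by lexicographic soi_id so that rankings are stable
and independent of candidate input order.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp

from .corpus import AbstractDoc, Corpus, SOIRecord, filter_recommendable_sois
from .embeddings import EmbedderSpec, TfidfModel, embed_sentences
from .errors import ConfigurationError
from .profiles import AuthorDiscriminator, ProfileEmbedding

__all__ = [
    "SOICandidate",
    "RankedList",
    "make_candidates",
    "candidate_score_recsoi",
    "rank_recsoi",
    "rank_baseline_sbert",
    "rank_baseline_tfidf_lr",
    "rank_random",
]

METHODS = ("recsoi", "baseline_sbert", "baseline_tfidf_lr", "random")


@dataclass
class SOICandidate:
    """A recommendable SOI, vectorized for ranking."""

    soi_id: str
    embedding: np.ndarray
    tfidf_vector: sp.csr_matrix | None = None
    concepts: frozenset[str] = frozenset()


@dataclass
class RankedList:
    """Top-k recommendation list for one author under one method."""

    author_id: str
    method: str
    items: list[tuple[str, float]]  # (soi_id, score), already ordered
    k: int

    def __post_init__(self):
        if self.method not in METHODS:
            raise ConfigurationError(f"unknown method {self.method!r}")
        ids = [i for i, _ in self.items]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate soi_ids in ranked list")

    @property
    def soi_ids(self) -> list[str]:
        return [i for i, _ in self.items]

    def top(self, k: int) -> list[str]:
        """Re-cut the list at any k <= requested k."""
        if k > self.k:
            raise ValueError(f"cannot re-cut at k={k} > requested k={self.k}")
        return self.soi_ids[:k]


def make_candidates(
    corpus: Corpus,
    spec: EmbedderSpec | None = None,
    tfidf: TfidfModel | None = None,
    sois: list[SOIRecord] | None = None,
) -> list[SOICandidate]:
    """Vectorize the recommendable SOIs of a corpus into candidates."""
    sois = filter_recommendable_sois(corpus) if sois is None else sois
    texts = [s.text for s in sois]
    embs = embed_sentences(texts, spec) if sois else []
    tf = tfidf.transform(texts).tocsr() if (tfidf is not None and sois) else None
    return [
        SOICandidate(
            soi_id=s.soi_id,
            embedding=e,
            tfidf_vector=tf[i] if tf is not None else None,
            concepts=s.concepts,
        )
        for i, (s, e) in enumerate(zip(sois, embs))
    ]


def candidate_score_recsoi(
    profile: ProfileEmbedding, candidate: SOICandidate
) -> float:
    """Minimum Euclidean distance from the candidate to any profile vector."""
    emb = np.asarray(candidate.embedding, dtype=float)
    if emb.shape[0] != profile.dim:
        raise ConfigurationError(
            f"dimension mismatch: candidate {emb.shape[0]} vs profile {profile.dim}"
        )
    return float(np.min(np.linalg.norm(profile.vectors - emb[None, :], axis=1)))


def _cut(
    author_id: str,
    method: str,
    scored: list[tuple[str, float]],
    k: int,
    descending: bool = False,
) -> RankedList:
    if k <= 0:
        raise ConfigurationError("k must be positive")
    key = (lambda t: (-t[1], t[0])) if descending else (lambda t: (t[1], t[0]))
    ordered = sorted(scored, key=key)[:k]
    return RankedList(author_id=author_id, method=method, items=ordered, k=k)


def rank_recsoi(
    profile: ProfileEmbedding, candidates: list[SOICandidate], k: int
) -> RankedList:
    """Rank candidates by ascending min-distance to the profile."""
    if not candidates:
        raise ConfigurationError("rank_recsoi requires at least one candidate")
    # vectorized pairwise distances: (n_candidates, n_profile)
    embs = np.stack([np.asarray(c.embedding, dtype=float) for c in candidates])
    if embs.shape[1] != profile.dim:
        raise ConfigurationError("dimension mismatch between candidates and profile")
    d2 = (
        (embs**2).sum(axis=1)[:, None]
        - 2.0 * embs @ profile.vectors.T
        + (profile.vectors**2).sum(axis=1)[None, :]
    )
    scores = np.sqrt(np.maximum(d2, 0.0)).min(axis=1)
    scored = [(c.soi_id, float(s)) for c, s in zip(candidates, scores)]
    return _cut(profile.author_id, "recsoi", scored, k)


def rank_baseline_sbert(
    author_abstracts: list[AbstractDoc],
    candidates: list[SOICandidate],
    k: int,
    spec: EmbedderSpec | None = None,
) -> RankedList:
    """Mean-of-means baseline: one author vector, ascending distance.

    The author vector is the average over abstracts of the average of the
    abstract's sentence embeddings (no weighting).
    """
    if not author_abstracts:
        raise ConfigurationError("rank_baseline_sbert requires >= 1 abstract")
    per_abstract = []
    for ab in author_abstracts:
        embs = embed_sentences([s.text for s in ab.sentences], spec)
        per_abstract.append(np.stack(embs).mean(axis=0))
    author_vec = np.stack(per_abstract).mean(axis=0)
    scored = [
        (c.soi_id, float(np.linalg.norm(np.asarray(c.embedding) - author_vec)))
        for c in candidates
    ]
    return _cut(author_abstracts[0].author_id, "baseline_sbert", scored, k)


def rank_baseline_tfidf_lr(
    model: AuthorDiscriminator, candidates: list[SOICandidate], k: int
) -> RankedList:
    """TF-IDF+LR baseline: descending authorship probability."""
    scored = []
    for c in candidates:
        if c.tfidf_vector is None:
            raise ConfigurationError(
                f"candidate {c.soi_id} lacks a tfidf_vector; build candidates "
                "with a fitted TfidfModel"
            )
        scored.append((c.soi_id, float(model.predict_proba(c.tfidf_vector)[0])))
    return _cut(model.author_id, "baseline_tfidf_lr", scored, k, descending=True)


def rank_random(
    candidates: list[SOICandidate], k: int, seed: int, author_id: str = ""
) -> RankedList:
    """Uniform draw of min(k, n) candidates without replacement."""
    if k <= 0:
        raise ConfigurationError("k must be positive")
    rng = np.random.default_rng(seed)
    ids = sorted(c.soi_id for c in candidates)  # input-order independence
    perm = rng.permutation(len(ids))
    picked = [ids[i] for i in perm[:k]]
    return RankedList(
        author_id=author_id,
        method="random",
        items=[(soi_id, float(rank)) for rank, soi_id in enumerate(picked)],
        k=k,
    )
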