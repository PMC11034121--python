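"""Researcher profile construction.

A profile is a list of one vector per prior abstract (at most five in
experiment mode).  Each abstract vector is a weighted mean of its sentence
embeddings, in the spirit of Rocchio relevance feedback: a per-author
logistic-regression discriminator, trained on TF-IDF vectors of abstracts
(label 1 iff the author is first author), scores each sentence with the
probability p that the author wrote it, and the sentence weight is

    weight(p) = -(2*(0.5 - p))  if p < 0.5,   2*(p - 0.5)  otherwise

(algebraically 2p - 1 on all of [0, 1], signed so that sentences the
discriminator attributes to the author pull the abstract vector toward them
and atypical sentences push it away).  The abstract embedding is

    embedding(a) = sum_i weight(s_i) * e_i / sum_i |weight(s_i)|,

with e_i the sentence embeddings.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
from scipy.special import expit
from sklearn.linear_model import LogisticRegression

from .corpus import Corpus, SentenceUnit, select_profile_abstracts
from .embeddings import EmbedderSpec, TfidfModel, embed_sentences, fit_tfidf
from .errors import TrainingError

__all__ = [
    "AuthorDiscriminator",
    "WeightedSentence",
    "ProfileEmbedding",
    "train_discriminator",
    "predict_sentence_prob",
    "sentence_weight",
    "abstract_embedding",
    "build_profile",
]


@dataclass
class AuthorDiscriminator:
    """Per-author binary LR over the shared TF-IDF space.

    Ridge (L2) penalty with C=1, the setting of the TF-IDF+LR ranking
    baseline, reused for the profile weighting.  Classes are reweighted to
    balance: one author's abstracts are a tiny fraction of the collection,
    and the 0.5 threshold in the sentence-weight formula only means "more
    the author's than not" against an even prior — with the raw prior every
    probability sits far below 0.5, every weight turns negative, and the
    profile degenerates to the negated mean of the author's own sentences.
    """

    author_id: str
    coefficients: np.ndarray
    intercept: float
    regularization: str = "l2:C=1.0:balanced"

    def decision(self, x: sp.spmatrix | np.ndarray) -> np.ndarray:
        return np.asarray(x @ self.coefficients).ravel() + self.intercept

    def predict_proba(self, x: sp.spmatrix | np.ndarray) -> np.ndarray:
        return expit(self.decision(x))


@dataclass
class WeightedSentence:
    sentence: SentenceUnit
    prob: float
    weight: float
    embedding: np.ndarray


@dataclass
class ProfileEmbedding:
    """Author profile: one embedding vector per selected prior abstract."""

    author_id: str
    abstract_ids: list[str]
    vectors: np.ndarray  # shape (n_abstracts, dim)

    def __post_init__(self):
        self.vectors = np.atleast_2d(np.asarray(self.vectors, dtype=float))
        if len(self.abstract_ids) != self.vectors.shape[0]:
            raise ValueError("one vector per abstract_id required")

    def __len__(self) -> int:
        return self.vectors.shape[0]

    @property
    def dim(self) -> int:
        return self.vectors.shape[1]


def train_discriminator(
    abstract_vectors: sp.spmatrix | np.ndarray,
    labels: np.ndarray,
    author: str,
) -> AuthorDiscriminator:
    """Fit the author-vs-rest logistic regression on abstract TF-IDF rows."""
    labels = np.asarray(labels).astype(int)
    classes = set(labels.tolist())
    if classes != {0, 1}:
        missing = sorted({0, 1} - classes) or "both"
        raise TrainingError(
            f"discriminator for {author!r} needs positive and negative "
            f"examples; missing class: {missing}"
        )
    lr = LogisticRegression(
        C=1.0, solver="lbfgs", max_iter=1000, class_weight="balanced"
    )
    lr.fit(abstract_vectors, labels)
    return AuthorDiscriminator(
        author_id=author,
        coefficients=lr.coef_.ravel().copy(),
        intercept=float(lr.intercept_[0]),
    )


def predict_sentence_prob(
    model: AuthorDiscriminator,
    tfidf: TfidfModel,
    sentence: SentenceUnit | str,
) -> float:
    """Probability that the author wrote this sentence.

    The sentence is vectorized in the same TF-IDF space the discriminator
    was trained in (training is abstract-level, application sentence-level).
    """
    text = sentence.text if isinstance(sentence, SentenceUnit) else sentence
    x = tfidf.transform([text])
    return float(model.predict_proba(x)[0])


def sentence_weight(prob: float) -> float:
    """Signed relevance weight of a sentence given its authorship probability."""
    if not 0.0 <= prob <= 1.0:
        raise ValueError(f"prob must lie in [0, 1], got {prob}")
    if prob < 0.5:
        return -(2.0 * (0.5 - prob))
    return 2.0 * (prob - 0.5)


def abstract_embedding(weighted: list[WeightedSentence]) -> np.ndarray:
    """Aggregate weighted sentence embeddings into one abstract vector.

    If the weights' absolute sum underflows (all probabilities ~0.5, i.e. an
    uninformative discriminator) the unweighted mean is used instead and a
    warning is emitted.
    """
    if not weighted:
        raise ValueError("abstract_embedding requires at least one sentence")
    embs = np.stack([w.embedding for w in weighted])
    weights = np.array([w.weight for w in weighted], dtype=float)
    denom = np.abs(weights).sum()
    if denom < 1e-12:
        warnings.warn(
            "all sentence weights ~0: falling back to unweighted mean",
            RuntimeWarning,
            stacklevel=2,
        )
        return embs.mean(axis=0)
    return (weights[:, None] * embs).sum(axis=0) / denom


def build_profile(
    corpus: Corpus,
    author: str,
    spec: EmbedderSpec | None = None,
    seed: int = 0,
    cap: int = 5,
    tfidf: TfidfModel | None = None,
    discriminator: AuthorDiscriminator | None = None,
) -> ProfileEmbedding:
    """Full profile pipeline: select -> train -> weight -> aggregate.

    Deterministic given (corpus, seed, spec).  ``tfidf`` and
    ``discriminator`` may be passed to reuse models fitted once for a whole
    author batch; otherwise they are fitted here (TF-IDF on all abstracts in
    the corpus, as all authors share one feature space).
    """
    spec = spec or EmbedderSpec()
    selected = select_profile_abstracts(corpus, author, cap=cap, seed=seed)
    if tfidf is None:
        tfidf = fit_tfidf([a.text for a in corpus.abstracts])
    if discriminator is None:
        texts = [a.text for a in corpus.abstracts]
        labels = np.array(
            [1 if a.author_id == author else 0 for a in corpus.abstracts]
        )
        discriminator = train_discriminator(tfidf.transform(texts), labels, author)

    vectors = []
    for ab in selected:
        sent_texts = [s.text for s in ab.sentences]
        embs = embed_sentences(sent_texts, spec)
        probs = discriminator.predict_proba(tfidf.transform(sent_texts))
        weighted = [
            WeightedSentence(sentence=s, prob=float(p),
                             weight=sentence_weight(float(p)), embedding=e)
            for s, p, e in zip(ab.sentences, probs, embs)
        ]
        vectors.append(abstract_embedding(weighted))
    return ProfileEmbedding(
        author_id=author,
        abstract_ids=[a.abstract_id for a in selected],
        vectors=np.stack(vectors),
    )
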