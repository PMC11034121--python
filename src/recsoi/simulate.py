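"""Synthetic corpus generator with ground-truth relevance.

Real inputs to the recommender are abstracts and SOI-bearing papers with
three statistical features the method relies on: (1) authors cluster into
topics with topic-specific vocabularies; (2) each author additionally has a
personal writing signature (idiosyncratic terms recurring across their own
abstracts and papers) — the very signal the first-author relevance
heuristic rewards; (3) a fraction of SOIs are *generic*: phrased without
any topical concept ("results remain inconclusive"), which is the known
failure mode of profile matching.  The generator reifies all three as
knobs, emulates the empirical 1-to-5 abstracts-per-author profile-length
distribution, samples co-author links within topics, tags concepts, and
enforces the temporal split (all abstracts strictly precede the author's
paper).

Everything is driven by a single seed; replicate r of an experiment uses
seed + r.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .categories import RECOMMENDABLE_CATEGORIES
from .corpus import (
    AbstractDoc,
    AuthorRef,
    Corpus,
    PaperDoc,
    SentenceUnit,
    SOIRecord,
)
from .errors import ConfigurationError

__all__ = [
    "TopicSpec",
    "SimConfig",
    "SimulatedCorpus",
    "simulate_corpus",
    "ground_truth",
    "recovery_experiment",
]

#: Empirical distribution of profile lengths (authors with 1..5 abstracts).
ABSTRACT_COUNT_WEIGHTS = (72, 57, 38, 42, 291)

#: Generic ignorance phrasings carrying no topical concept.  These emulate
#: the form of real generic SOIs without borrowing any corpus text.
GENERIC_TEMPLATES = (
    "further studies are needed to clarify this finding",
    "however the available results remain inconclusive",
    "additional large scale investigations are warranted",
    "the long term consequences remain to be tested in future research",
    "it is urgent to explore effective ways to address this open problem",
    "more work is required before firm conclusions can be drawn",
)

#: Ignorance wrappers for topical SOIs; {terms} receives topic/concept words.
TOPICAL_TEMPLATES = (
    "it remains unknown how {terms} interact in this setting",
    "whether {terms} can be modulated is an open question",
    "a key complication is the measurement of {terms}",
    "future work should examine {terms} in larger cohorts",
    "we predict that {terms} will become increasingly relevant",
)

_RECOMMENDABLE = tuple(sorted(RECOMMENDABLE_CATEGORIES))


@dataclass(frozen=True)
class TopicSpec:
    """One topic: a Zipf-shaped term distribution and its concept pool."""

    topic_id: str
    terms: tuple[str, ...]
    probabilities: tuple[float, ...]
    concept_pool: frozenset[str]

    def __post_init__(self):
        if abs(sum(self.probabilities) - 1.0) > 1e-9:
            raise ConfigurationError("topic term probabilities must sum to 1")
        if not self.concept_pool <= set(self.terms):
            raise ConfigurationError("concept_pool must be supported by terms")


@dataclass(frozen=True)
class SimConfig:
    """Knobs of the generator, defaulting to the study conditions.

    ``topic_overlap`` mixes each author's sentences with a shared background
    vocabulary (0 = fully disjoint topics, 1 = indistinguishable);
    ``generic_soi_fraction`` is the probability that a paper's SOI is
    phrased generically, with no concept token at all.
    """

    n_authors: int = 50
    n_topics: int = 5
    abstracts_per_author_weights: tuple[int, ...] = ABSTRACT_COUNT_WEIGHTS
    sentences_per_abstract: tuple[int, int] = (4, 8)
    sois_per_paper: tuple[int, int] = (3, 6)
    generic_soi_fraction: float = 0.0
    topic_overlap: float = 0.0
    topic_vocab_size: int = 200
    background_vocab_size: int = 500
    signature_vocab_size: int = 15
    concepts_per_topic: int = 30
    seed: int = 0

    def __post_init__(self):
        if self.n_authors < 1 or self.n_topics < 1:
            raise ConfigurationError("n_authors and n_topics must be positive")
        if not 0.0 <= self.generic_soi_fraction <= 1.0:
            raise ConfigurationError("generic_soi_fraction must lie in [0, 1]")
        if not 0.0 <= self.topic_overlap <= 1.0:
            raise ConfigurationError("topic_overlap must lie in [0, 1]")
        for lo, hi in (self.sentences_per_abstract, self.sois_per_paper):
            if lo < 1 or hi < lo:
                raise ConfigurationError("ranges must satisfy 1 <= lo <= hi")


@dataclass
class SimulatedCorpus:
    corpus: Corpus
    #: heuristic name -> author_id -> set of relevant soi_ids (by construction)
    truth: dict[str, dict[str, set[str]]]
    config: SimConfig


def _zipf_probs(n: int, exponent: float = 1.1) -> np.ndarray:
    w = 1.0 / np.arange(1, n + 1) ** exponent
    return w / w.sum()


def _make_topics(config: SimConfig) -> list[TopicSpec]:
    probs = tuple(_zipf_probs(config.topic_vocab_size).tolist())
    topics = []
    for t in range(config.n_topics):
        terms = tuple(f"t{t}w{j}" for j in range(config.topic_vocab_size))
        topics.append(
            TopicSpec(
                topic_id=f"topic{t}",
                terms=terms,
                probabilities=probs,
                concept_pool=frozenset(terms[: config.concepts_per_topic]),
            )
        )
    return topics


def _topical_sentence(
    rng: np.random.Generator,
    topic: TopicSpec,
    background: tuple[str, ...],
    signature: tuple[str, ...],
    config: SimConfig,
    n_topic_tokens: int = 6,
    n_signature_tokens: int = 4,
) -> list[str]:
    """Sample the token bag of one sentence of an author's text.

    ``topic_overlap`` replaces any content token (topic *or* signature) with
    a shared background token: at 1.0 all authors write indistinguishable
    text and profile matching collapses to chance.
    """
    tokens: list[str] = []
    p = np.asarray(topic.probabilities)
    for _ in range(n_topic_tokens):
        if background and rng.random() < config.topic_overlap:
            tokens.append(background[rng.integers(len(background))])
        else:
            tokens.append(topic.terms[rng.choice(len(topic.terms), p=p)])
    for _ in range(n_signature_tokens):
        if background and rng.random() < config.topic_overlap:
            tokens.append(background[rng.integers(len(background))])
        else:
            tokens.append(signature[rng.integers(len(signature))])
    return tokens


def _concepts_in(tokens: list[str], topic: TopicSpec) -> frozenset[str]:
    return frozenset(t for t in tokens if t in topic.concept_pool)


def simulate_corpus(config: SimConfig) -> SimulatedCorpus:
    """Generate a validated corpus plus per-heuristic ground truth.

    Each author gets a home topic (round-robin), 1-5 prior abstracts drawn
    from the empirical profile-length distribution, and exactly one
    first-authored paper whose SOIs are ignorance-wrapped topic sentences
    (or concept-free generic statements with probability
    ``generic_soi_fraction``).  Co-authors are sampled within the author's
    topic; abstracts are strictly older than the paper by construction.
    """
    rng = np.random.default_rng(config.seed)
    topics = _make_topics(config)
    background = tuple(f"bg{j}" for j in range(config.background_vocab_size))

    authors: list[AuthorRef] = []
    abstracts: list[AbstractDoc] = []
    papers: list[PaperDoc] = []
    sois: list[SOIRecord] = []

    home_topic: dict[str, TopicSpec] = {}
    signatures: dict[str, tuple[str, ...]] = {}
    weights = np.asarray(config.abstracts_per_author_weights, dtype=float)
    weights = weights / weights.sum()

    author_ids = [f"auth{i:03d}" for i in range(config.n_authors)]
    for i, aid in enumerate(author_ids):
        authors.append(AuthorRef(author_id=aid, display_name=f"Author {i}"))
        home_topic[aid] = topics[i % config.n_topics]
        signatures[aid] = tuple(
            f"{aid}s{j}" for j in range(config.signature_vocab_size)
        )

    # prior abstracts (time_rank 0..): the profile-building material
    for aid in author_ids:
        n_abs = int(rng.choice(len(weights), p=weights)) + 1
        topic = home_topic[aid]
        for j in range(n_abs):
            lo, hi = config.sentences_per_abstract
            n_sent = int(rng.integers(lo, hi + 1))
            sentences = []
            for si in range(n_sent):
                tokens = _topical_sentence(rng, topic, background,
                                           signatures[aid], config)
                sentences.append(
                    SentenceUnit(
                        text=" ".join(tokens),
                        paragraph_index=0,
                        sentence_index=si,
                        concepts=_concepts_in(tokens, topic),
                    )
                )
            abstracts.append(
                AbstractDoc(
                    abstract_id=f"{aid}-abs{j}",
                    author_id=aid,
                    sentences=tuple(sentences),
                    time_rank=j,
                )
            )

    # papers with SOIs (time_rank far above every abstract)
    by_topic: dict[str, list[str]] = {}
    for aid in author_ids:
        by_topic.setdefault(home_topic[aid].topic_id, []).append(aid)

    for pi, aid in enumerate(author_ids):
        topic = home_topic[aid]
        peers = [a for a in by_topic[topic.topic_id] if a != aid]
        n_co = int(rng.integers(1, min(3, len(peers)) + 1)) if peers else 0
        co = tuple(
            peers[i] for i in sorted(rng.choice(len(peers), n_co, replace=False))
        ) if n_co else ()

        sentences: list[SentenceUnit] = []
        paper_id = f"paper-{aid}"
        lo, hi = config.sois_per_paper
        n_sois = int(rng.integers(lo, hi + 1))
        si = 0
        # a couple of ordinary narrative sentences first
        for _ in range(2):
            tokens = _topical_sentence(rng, topic, background, signatures[aid],
                                       config)
            sentences.append(
                SentenceUnit(text=" ".join(tokens), paragraph_index=0,
                             sentence_index=si,
                             concepts=_concepts_in(tokens, topic))
            )
            si += 1
        for s in range(n_sois):
            category = _RECOMMENDABLE[rng.integers(len(_RECOMMENDABLE))]
            if rng.random() < config.generic_soi_fraction:
                text = GENERIC_TEMPLATES[rng.integers(len(GENERIC_TEMPLATES))]
                concepts: frozenset[str] = frozenset()
            else:
                tokens = _topical_sentence(rng, topic, background,
                                           signatures[aid], config)
                template = TOPICAL_TEMPLATES[rng.integers(len(TOPICAL_TEMPLATES))]
                text = template.format(terms=" ".join(tokens))
                concepts = _concepts_in(tokens, topic)
            unit = SentenceUnit(
                text=text, paragraph_index=0, sentence_index=si, is_soi=True,
                soi_category=category, concepts=concepts,
            )
            sentences.append(unit)
            sois.append(
                SOIRecord(
                    soi_id=f"soi-{aid}-{s}",
                    paper_id=paper_id,
                    sentence=unit,
                    category=category,
                    concepts=concepts,
                )
            )
            si += 1
        # one non-recommendable SOI to exercise category filtering
        if rng.random() < config.generic_soi_fraction:
            nr_text = GENERIC_TEMPLATES[rng.integers(len(GENERIC_TEMPLATES))]
            nr_concepts: frozenset[str] = frozenset()
        else:
            tokens = _topical_sentence(rng, topic, background, signatures[aid],
                                       config)
            nr_text = "this question is answered by " + " ".join(tokens)
            nr_concepts = _concepts_in(tokens, topic)
        unit = SentenceUnit(
            text=nr_text,
            paragraph_index=0, sentence_index=si, is_soi=True,
            soi_category="question answered by this work",
            concepts=nr_concepts,
        )
        sentences.append(unit)
        sois.append(
            SOIRecord(
                soi_id=f"soi-{aid}-nr",
                paper_id=paper_id,
                sentence=unit,
                category="question answered by this work",
                concepts=nr_concepts,
            )
        )
        papers.append(
            PaperDoc(
                paper_id=paper_id,
                first_author=aid,
                co_authors=co,
                sentences=tuple(sentences),
                time_rank=10_000 + pi,
            )
        )

    corpus = Corpus(authors=authors, papers=papers, abstracts=abstracts, sois=sois)
    corpus.validate()

    truth = _build_truth(corpus)
    return SimulatedCorpus(corpus=corpus, truth=truth, config=config)


def _build_truth(corpus: Corpus) -> dict[str, dict[str, set[str]]]:
    """Relevant soi_ids per author, by direct construction joins.

    Computed only over recommendable SOIs, independently of the evaluation
    module's predicates (which must agree with these sets).
    """
    from .corpus import filter_recommendable_sois

    sois = filter_recommendable_sois(corpus)
    first_author: dict[str, set[str]] = {}
    co_authors: dict[str, set[str]] = {}
    concepts: dict[str, set[str]] = {}

    paper_author = {p.paper_id: p.first_author for p in corpus.papers}
    coauthor_of: dict[str, set[str]] = {a.author_id: set() for a in corpus.authors}
    for p in corpus.papers:
        coauthor_of[p.first_author] |= set(p.co_authors)
    abstract_concepts: dict[str, set[str]] = {a.author_id: set() for a in corpus.authors}
    for ab in corpus.abstracts:
        for s in ab.sentences:
            abstract_concepts[ab.author_id] |= s.concepts

    for a in corpus.authors:
        aid = a.author_id
        first_author[aid] = {s.soi_id for s in sois if paper_author[s.paper_id] == aid}
        co_authors[aid] = {
            s.soi_id
            for s in sois
            if paper_author[s.paper_id] != aid
            and paper_author[s.paper_id] in coauthor_of[aid]
        }
        concepts[aid] = {
            s.soi_id for s in sois if s.concepts & abstract_concepts[aid]
        }
    return {
        "first_author": first_author,
        "co_authors": co_authors,
        "concepts": concepts,
    }


def ground_truth(sim: SimulatedCorpus, heuristic: str):
    """Relevance predicate (author_id, soi_id) -> bool for one heuristic."""
    if heuristic not in sim.truth:
        raise ConfigurationError(f"unknown heuristic {heuristic!r}")
    table = sim.truth[heuristic]

    def judge(author: str, soi_id: str) -> bool:
        return soi_id in table.get(author, set())

    return judge


def recovery_experiment(
    config: SimConfig,
    methods=("recsoi", "random"),
    ks=(5,),
    n_replicates: int = 10,
    seed: int = 0,
    heuristics=("first_author",),
    spec=None,
) -> pd.DataFrame:
    """Desk-scale recovery study: simulate -> profile -> rank -> score.

    Replicate r uses config seed ``seed + r``.  Returns mean MAP_existence@k
    with binomial halfwidths per (method, heuristic, k).
    """
    from .embeddings import EmbedderSpec, fit_tfidf
    from .evaluation import map_exists_at_k, wald_halfwidth
    from .profiles import build_profile, train_discriminator
    from .ranking import (
        make_candidates,
        rank_baseline_sbert,
        rank_baseline_tfidf_lr,
        rank_random,
        rank_recsoi,
    )
    from .corpus import filter_recommendable_sois, select_profile_abstracts

    spec = spec or EmbedderSpec()
    kmax = max(ks)
    per_rep: dict[tuple[str, str, int], list[float]] = {}
    authors_counted = 0
    for r in range(n_replicates):
        sim = simulate_corpus(replace(config, seed=seed + r))
        corpus = sim.corpus
        sois = filter_recommendable_sois(corpus)
        tfidf = fit_tfidf([a.text for a in corpus.abstracts])
        candidates = make_candidates(corpus, spec=spec, tfidf=tfidf, sois=sois)
        abstract_matrix = tfidf.transform([a.text for a in corpus.abstracts])
        labels_by_author = {
            aid: np.array([1 if a.author_id == aid else 0 for a in corpus.abstracts])
            for aid in (a.author_id for a in corpus.authors)
        }
        ranked: dict[str, dict[str, object]] = {m: {} for m in methods}
        for i, a in enumerate(corpus.authors):
            aid = a.author_id
            if "recsoi" in methods or "baseline_tfidf_lr" in methods:
                disc = train_discriminator(abstract_matrix, labels_by_author[aid], aid)
            if "recsoi" in methods:
                profile = build_profile(
                    corpus, aid, spec=spec, seed=seed + r, tfidf=tfidf,
                    discriminator=disc,
                )
                ranked["recsoi"][aid] = rank_recsoi(profile, candidates, kmax)
            if "baseline_sbert" in methods:
                selected = select_profile_abstracts(corpus, aid, seed=seed + r)
                ranked["baseline_sbert"][aid] = rank_baseline_sbert(
                    selected, candidates, kmax, spec=spec
                )
            if "baseline_tfidf_lr" in methods:
                ranked["baseline_tfidf_lr"][aid] = rank_baseline_tfidf_lr(
                    disc, candidates, kmax
                )
            if "random" in methods:
                ranked["random"][aid] = rank_random(
                    candidates, kmax, seed=seed + r * config.n_authors + i,
                    author_id=aid,
                )
        authors_counted = len(corpus.authors)
        for heuristic in heuristics:
            judge = ground_truth(sim, heuristic)
            for m in methods:
                for k in ks:
                    per_rep.setdefault((m, heuristic, k), []).append(
                        map_exists_at_k(ranked[m], judge, k)
                    )

    rows = []
    for (m, heuristic, k), vals in sorted(per_rep.items()):
        mean = float(np.mean(vals))
        rows.append(
            {
                "method": m,
                "heuristic": heuristic,
                "k": k,
                "map_exists_mean": mean,
                "ci_halfwidth": wald_halfwidth(
                    min(max(mean, 0.0), 1.0), authors_counted * n_replicates
                ),
                "n_replicates": n_replicates,
                "n_authors": authors_counted,
            }
        )
    return pd.DataFrame(rows)
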