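"""Evaluation of recommendation quality.

Ground truth for "is this SOI relevant to researcher r?" is approximated by
three heuristics:

* ``first_author`` — the SOI comes from a paper whose first author is r;
* ``co_authors`` — the SOI's paper's first author is a co-author of r on
  some paper where r is first author;
* ``concepts`` — the SOI shares at least one concept with r's abstracts
  (authors sharing no concept with any candidate are excluded from this
  heuristic's denominator).

The headline metric is MAP_existence@k: the fraction of evaluated authors
with at least one relevant item in their top-k list.  Because each author
contributes a Bernoulli trial, the reported confidence halfwidth is the
normal-approximation (Wald) binomial interval.  The analytic random
baseline follows the hypergeometric expectation k*(n_R/n): drawing k SOIs
uniformly without replacement from a pool of n of which n_R are relevant.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from scipy.stats import norm

from .corpus import Corpus, SOIRecord, select_profile_abstracts
from .errors import ConfigurationError, IntegrityError

__all__ = [
    "HEURISTICS",
    "DatasetStats",
    "EvaluationReport",
    "relevant_first_author",
    "relevant_co_author",
    "relevant_concepts",
    "concepts_eligible",
    "author_concepts",
    "map_exists_at_k",
    "map_at_k",
    "wald_halfwidth",
    "wilson_halfwidth",
    "expected_random_relevant",
    "random_success_percentage",
    "evaluate_all",
]

HEURISTICS = ("first_author", "co_authors", "concepts")


# ---------------------------------------------------------------------------
# Relevance heuristics
# ---------------------------------------------------------------------------


def relevant_first_author(soi: SOIRecord, author: str, corpus: Corpus) -> bool:
    """True iff the SOI's paper was first-authored by ``author``."""
    return corpus.paper(soi.paper_id).first_author == author


def relevant_co_author(soi: SOIRecord, author: str, corpus: Corpus) -> bool:
    """True iff the SOI's paper's first author co-authored with ``author``.

    "Co-author of r" ranges over all papers in the corpus where r is first
    author.  r is never their own co-author (that case belongs to the
    first-author heuristic).
    """
    writer = corpus.paper(soi.paper_id).first_author
    if writer == author:
        return False
    for p in corpus.papers_of(author):
        if writer in p.co_authors:
            return True
    return False


def author_concepts(corpus: Corpus, author: str) -> frozenset[str]:
    """Union of concepts across all sentences of the author's abstracts."""
    out: set[str] = set()
    for ab in corpus.abstracts_of(author):
        for s in ab.sentences:
            out |= s.concepts
    return frozenset(out)


def relevant_concepts(soi: SOIRecord, author: str, corpus: Corpus) -> bool:
    """True iff the SOI shares >= 1 concept with the author's abstracts."""
    return bool(soi.concepts & author_concepts(corpus, author))


def concepts_eligible(
    author: str, candidates: list[SOIRecord], corpus: Corpus
) -> bool:
    """False iff no candidate shares any concept with the author.

    Ineligible authors cannot be scored under the concepts heuristic and are
    dropped from its denominator only; per-author outcomes of other authors
    are unaffected.
    """
    mine = author_concepts(corpus, author)
    if not mine:
        return False
    return any(s.concepts & mine for s in candidates)


# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------


def map_exists_at_k(ranked: dict, judge, k: int) -> float:
    """Fraction of authors with >= 1 relevant item among their top k.

    ``ranked`` maps author_id -> RankedList; ``judge(author_id, soi_id)``
    returns relevance.
    """
    if not ranked:
        raise ConfigurationError("map_exists_at_k requires >= 1 author")
    hits = 0
    for author, rl in ranked.items():
        if any(judge(author, soi_id) for soi_id in rl.top(min(k, len(rl.items)))):
            hits += 1
    return hits / len(ranked)


def map_at_k(ranked: dict, judge, k: int) -> float:
    """Mean over authors of (relevant count in top k) / k."""
    if not ranked:
        raise ConfigurationError("map_at_k requires >= 1 author")
    total = 0.0
    for author, rl in ranked.items():
        top = rl.top(min(k, len(rl.items)))
        total += sum(1 for soi_id in top if judge(author, soi_id)) / k
    return total / len(ranked)


def wald_halfwidth(p: float, n: int, confidence: float = 0.95) -> float:
    """Normal-approximation halfwidth z * sqrt(p(1-p)/n) for a proportion."""
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"p must lie in [0, 1], got {p}")
    if n < 1:
        raise ValueError("n must be >= 1")
    z = float(norm.ppf(0.5 + confidence / 2.0))
    return z * (p * (1.0 - p) / n) ** 0.5


def wilson_halfwidth(p: float, n: int, confidence: float = 0.95) -> float:
    """Wilson score-interval halfwidth for a binomial proportion.

    z*sqrt(p(1-p)/n + z^2/(4n^2)) / (1 + z^2/n).  Unlike the Wald width it
    is strictly positive at p = 0 or 1, and it reproduces every published
    interval of the reference evaluation (including the 0% random rows) to
    the printed decimal; the Wald width matches all cells except those at
    extreme proportions.
    """
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"p must lie in [0, 1], got {p}")
    if n < 1:
        raise ValueError("n must be >= 1")
    z = float(norm.ppf(0.5 + confidence / 2.0))
    return (
        z * (p * (1.0 - p) / n + z**2 / (4.0 * n**2)) ** 0.5 / (1.0 + z**2 / n)
    )


def expected_random_relevant(k: int, n_r: int, n: int) -> float:
    """Hypergeometric expectation k * n_R / n of relevant items in k draws."""
    if n < 1 or k < 1:
        raise ValueError("k and n must be positive")
    if not 0 <= n_r <= n:
        raise ValueError(f"need 0 <= n_R <= n, got n_R={n_r}, n={n}")
    if k > n:
        raise ValueError(f"cannot draw k={k} from a pool of n={n}")
    return k * n_r / n


@dataclass
class DatasetStats:
    """Pool size and per-author relevant counts under one heuristic."""

    n_sois: int
    per_author_relevant: dict[str, int]

    def __post_init__(self):
        if self.n_sois < 1:
            raise ValueError("n_sois must be positive")
        for a, n_r in self.per_author_relevant.items():
            if not 0 <= n_r <= self.n_sois:
                raise IntegrityError(
                    f"author {a!r}: n_R={n_r} outside [0, {self.n_sois}]"
                )


def random_success_percentage(k: int, stats: DatasetStats) -> float:
    """Percent of authors whose expected random draw yields >= 1 relevant SOI."""
    if not stats.per_author_relevant:
        return 0.0
    ok = sum(
        1
        for n_r in stats.per_author_relevant.values()
        if expected_random_relevant(k, n_r, stats.n_sois) >= 1.0
    )
    return 100.0 * ok / len(stats.per_author_relevant)


# ---------------------------------------------------------------------------
# Full report
# ---------------------------------------------------------------------------


@dataclass
class EvaluationReport:
    """MAP_existence@k per (method, heuristic, k), plus the analytic random row.

    ``cells`` maps (method, heuristic, k) -> dict with keys ``proportion``,
    ``authors_evaluated`` and ``ci_halfwidth``; ``random_row`` maps
    (heuristic, k) -> percentage of authors for which k*(n_R/n) >= 1.
    """

    cells: dict[tuple[str, str, int], dict] = field(default_factory=dict)
    random_row: dict[tuple[str, int], float] = field(default_factory=dict)
    ks: tuple[int, ...] = (5, 10, 20)

    def proportion(self, method: str, heuristic: str, k: int) -> float:
        return self.cells[(method, heuristic, k)]["proportion"]

    def to_table(self):
        """Flatten to a pandas DataFrame mirroring the published layout."""
        import pandas as pd

        rows = []
        for (method, heuristic, k), cell in sorted(self.cells.items()):
            rows.append(
                {
                    "method": method,
                    "heuristic": heuristic,
                    "k": k,
                    "map_exists_pct": round(100.0 * cell["proportion"], 1),
                    "ci_halfwidth_pct": round(100.0 * cell["ci_halfwidth"], 1),
                    "authors_evaluated": cell["authors_evaluated"],
                }
            )
        for (heuristic, k), pct in sorted(self.random_row.items()):
            rows.append(
                {
                    "method": "random_analytic",
                    "heuristic": heuristic,
                    "k": k,
                    "map_exists_pct": round(pct, 1),
                    "ci_halfwidth_pct": float("nan"),
                    "authors_evaluated": len(self.cells) and next(
                        iter(self.cells.values())
                    )["authors_evaluated"],
                }
            )
        return pd.DataFrame(rows)


def _judge_for(heuristic: str, corpus: Corpus, soi_by_id: dict[str, SOIRecord]):
    fn = {
        "first_author": relevant_first_author,
        "co_authors": relevant_co_author,
        "concepts": relevant_concepts,
    }[heuristic]

    def judge(author: str, soi_id: str) -> bool:
        return fn(soi_by_id[soi_id], author, corpus)

    return judge


def evaluate_all(
    corpus: Corpus,
    methods=("recsoi", "baseline_sbert", "baseline_tfidf_lr", "random"),
    heuristics=HEURISTICS,
    ks=(5, 10, 20),
    seed: int = 0,
    spec=None,
    cap: int = 5,
) -> EvaluationReport:
    """Run the full evaluation cross of methods x heuristics x ks.

    Authors with at least one prior abstract are evaluated; under the
    concepts heuristic, authors sharing no concept with any candidate are
    additionally excluded from the denominator.  Deterministic per seed.
    """
    from .corpus import filter_recommendable_sois
    from .embeddings import EmbedderSpec, fit_tfidf
    from .profiles import build_profile, train_discriminator
    from .ranking import (
        make_candidates,
        rank_baseline_sbert,
        rank_baseline_tfidf_lr,
        rank_random,
        rank_recsoi,
    )
    import numpy as np

    spec = spec or EmbedderSpec()
    sois = filter_recommendable_sois(corpus)
    if not sois:
        raise ConfigurationError("corpus has no recommendable SOIs")
    soi_by_id = {s.soi_id: s for s in sois}
    tfidf = fit_tfidf([a.text for a in corpus.abstracts])
    candidates = make_candidates(corpus, spec=spec, tfidf=tfidf, sois=sois)
    authors = [a.author_id for a in corpus.authors if corpus.abstracts_of(a.author_id)]
    if not authors:
        raise ConfigurationError("no author has prior abstracts")
    kmax = max(ks)

    abstract_texts = [a.text for a in corpus.abstracts]
    abstract_matrix = tfidf.transform(abstract_texts)

    ranked: dict[str, dict[str, "object"]] = {m: {} for m in methods}
    for i, author in enumerate(sorted(authors)):
        selected = select_profile_abstracts(corpus, author, cap=cap, seed=seed)
        if "recsoi" in methods:
            labels = np.array(
                [1 if a.author_id == author else 0 for a in corpus.abstracts]
            )
            disc = train_discriminator(abstract_matrix, labels, author)
            profile = build_profile(
                corpus, author, spec=spec, seed=seed, cap=cap,
                tfidf=tfidf, discriminator=disc,
            )
            ranked["recsoi"][author] = rank_recsoi(profile, candidates, kmax)
        if "baseline_sbert" in methods:
            ranked["baseline_sbert"][author] = rank_baseline_sbert(
                selected, candidates, kmax, spec=spec
            )
        if "baseline_tfidf_lr" in methods:
            labels = np.array(
                [1 if a.author_id == author else 0 for a in corpus.abstracts]
            )
            disc = train_discriminator(abstract_matrix, labels, author)
            ranked["baseline_tfidf_lr"][author] = rank_baseline_tfidf_lr(
                disc, candidates, kmax
            )
        if "random" in methods:
            ranked["random"][author] = rank_random(
                candidates, kmax, seed=seed + i, author_id=author
            )

    report = EvaluationReport(ks=tuple(ks))
    for heuristic in heuristics:
        judge = _judge_for(heuristic, corpus, soi_by_id)
        if heuristic == "concepts":
            eligible = [a for a in authors if concepts_eligible(a, sois, corpus)]
        else:
            eligible = list(authors)
        if not eligible:
            continue
        # analytic random row
        stats = DatasetStats(
            n_sois=len(sois),
            per_author_relevant={
                a: sum(1 for s in sois if judge(a, s.soi_id)) for a in eligible
            },
        )
        for k in ks:
            report.random_row[(heuristic, k)] = random_success_percentage(k, stats)
        for method in methods:
            sub = {a: rl for a, rl in ranked[method].items() if a in set(eligible)}
            for k in ks:
                p = map_exists_at_k(sub, judge, k)
                report.cells[(method, heuristic, k)] = {
                    "proportion": p,
                    "authors_evaluated": len(sub),
                    "ci_halfwidth": wald_halfwidth(p, len(sub)),
                }
    return report
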