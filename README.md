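# recsoi

Rank *statements of ignorance* (SOIs) — sentences in scientific papers that
express open questions, unknowns, problems or future work — against a
researcher's profile, so that each researcher sees the research directions
most relevant to their own work.

The package is aimed at researchers and tool builders in literature mining
who consume pre-annotated SOI corpora (sentence-segmented papers with a
13-way ignorance-category label per SOI sentence) and want to turn them
into personalized research-direction recommendations, evaluate those
recommendations, and present each recommendation with useful paragraph
context.

## The method

For a researcher *r* with prior first-author abstracts *a₁…aₘ* (at most 5
in experiment mode):

1. every sentence *sᵢ* of an abstract is embedded (*eᵢ*) by a sentence
   encoder, and a per-author **discriminator** — an L2-penalized logistic
   regression (C = 1, class-balanced) over TF-IDF vectors, trained with
   label 1 iff the abstract's first author is *r* — scores the probability
   *p = LR(sᵢ)* that *r* wrote the sentence;
2. each sentence gets the signed weight
   `weight(sᵢ) = −(2·(0.5 − p))` if *p* < 0.5 else `2·(p − 0.5)`
   (≡ 2p − 1), so author-typical sentences attract the abstract vector and
   atypical ones repel it, in the spirit of Rocchio relevance feedback;
3. the abstract embedding is `Σ weight(sᵢ)·eᵢ / Σ |weight(sᵢ)|`, and the
   profile of *r* is the list of its abstract embeddings;
4. each candidate SOI is embedded the same way and scored by the **minimum
   Euclidean distance** to any vector of the profile; the top-k closest
   SOIs are recommended.  Ties break by lexicographic SOI id, so rankings
   are fully deterministic.

Two published baselines are included (mean-of-means sentence-embedding
distance, and ranking by the discriminator's own probability on each SOI),
plus a uniform-random baseline.  Evaluation uses
`MAP_∃@k` — the fraction of researchers with ≥ 1 relevant SOI in their
top k — under three relevance heuristics (first-author, co-authors,
concepts), with binomial confidence halfwidths and the analytic
hypergeometric random row `k·n_R/n`.

The default embedding backend (`offline-hash`) is a deterministic
feature-hashing encoder (signed token buckets → seed-fixed Gaussian
projection → L2 normalization); a `pretrained` adapter for
sentence-transformers models can be enabled with the `pretrained` extra.

## Worked example

Generate a small synthetic corpus (8 authors in 2 topics, each with 1–5
prior abstracts and one SOI-bearing paper), validate it, and rank SOIs for
one author:

```bash
recsoi simulate --n-authors 8 --n-topics 2 --seed 5 --out corpus.jsonl
recsoi validate corpus.jsonl
recsoi rank --corpus corpus.jsonl --author auth000 --method recsoi --k 5 \
    --out ranked.jsonl
```

`ranked.jsonl` then contains (scores are Euclidean distances, ascending —
smaller is closer to the author's profile):

```json
{"rank": 0, "soi_id": "soi-auth002-1", "score": 0.8242073754781405, "method": "recsoi"}
{"rank": 1, "soi_id": "soi-auth006-0", "score": 0.8784769741086531, "method": "recsoi"}
{"rank": 2, "soi_id": "soi-auth004-3", "score": 0.9092591599208684, "method": "recsoi"}
{"rank": 3, "soi_id": "soi-auth000-0", "score": 0.9494008207938086, "method": "recsoi"}
{"rank": 4, "soi_id": "soi-auth002-5", "score": 0.966438265127998, "method": "recsoi"}
```

auth000 and its same-topic peers (auth002/004/006 share topic 0) dominate
the top of the list: the recommender has recovered the author's topical
neighborhood, including one of the author's own statements.  The other
commands — `recsoi profile`, `recsoi evaluate`, `recsoi context`,
`recsoi study plan|analyze` — cover profile inspection, the full
evaluation cross, paragraph-context extraction with highlight validation,
and the usefulness-study tooling; `--help` documents each.

In Python the same pipeline is three calls:

```python
from recsoi import (SimConfig, simulate_corpus, build_profile,
                    make_candidates, rank_recsoi, fit_tfidf)

sim = simulate_corpus(SimConfig(n_authors=8, n_topics=2, seed=5))
tfidf = fit_tfidf([a.text for a in sim.corpus.abstracts])
profile = build_profile(sim.corpus, "auth000", tfidf=tfidf)
top5 = rank_recsoi(profile, make_candidates(sim.corpus, tfidf=tfidf), k=5)
```

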