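"""Ranking methods against exhaustive oracles and determinism contracts."""

import numpy as np
import pytest
from scipy.stats import chisquare

from recsoi.embeddings import fit_tfidf
from recsoi.errors import ConfigurationError
from recsoi.profiles import AuthorDiscriminator, ProfileEmbedding
from recsoi.ranking import (
    SOICandidate,
    candidate_score_recsoi,
    rank_baseline_sbert,
    rank_baseline_tfidf_lr,
    rank_random,
    rank_recsoi,
)


def _profile(vectors, author="a"):
    vectors = np.asarray(vectors, dtype=float)
    return ProfileEmbedding(
        author_id=author,
        abstract_ids=[f"ab{i}" for i in range(vectors.shape[0])],
        vectors=vectors,
    )


def _cands(embs, prefix="s"):
    return [
        SOICandidate(soi_id=f"{prefix}{i:03d}", embedding=np.asarray(e, float))
        for i, e in enumerate(embs)
    ]


class TestRecsoiScore:
    def test_min_over_profile_vectors(self):
        prof = _profile([[0.0, 0.0], [10.0, 10.0]])
        cand = SOICandidate("x", np.array([1.0, 0.0]))
        assert candidate_score_recsoi(prof, cand) == pytest.approx(1.0)

    def test_candidate_on_profile_vector_scores_zero(self):
        prof = _profile([[0.3, -0.2, 0.5]])
        cand = SOICandidate("x", np.array([0.3, -0.2, 0.5]))
        assert candidate_score_recsoi(prof, cand) == pytest.approx(0.0)

    def test_dim_mismatch_rejected(self):
        prof = _profile([[0.0, 0.0]])
        with pytest.raises(ConfigurationError):
            candidate_score_recsoi(prof, SOICandidate("x", np.zeros(3)))

    def test_matches_brute_force_distance_matrix(self):
        rng = np.random.default_rng(0)
        prof = _profile(rng.standard_normal((5, 16)))
        cands = _cands(rng.standard_normal((50, 16)))
        for c in cands:
            brute = min(
                np.linalg.norm(v - c.embedding) for v in prof.vectors
            )
            assert candidate_score_recsoi(prof, c) == pytest.approx(brute)


class TestRankRecsoi:
    def test_ascending_distance_order(self):
        prof = _profile([[0.0]])
        cands = [
            SOICandidate("a", np.array([3.0])),
            SOICandidate("b", np.array([1.0])),
            SOICandidate("c", np.array([2.0])),
        ]
        rl = rank_recsoi(prof, cands, 3)
        assert rl.soi_ids == ["b", "c", "a"]

    def test_ties_broken_by_soi_id(self):
        prof = _profile([[0.0, 0.0]])
        cands = [
            SOICandidate("zzz", np.array([1.0, 0.0])),
            SOICandidate("aaa", np.array([0.0, 1.0])),
        ]
        assert rank_recsoi(prof, cands, 2).soi_ids == ["aaa", "zzz"]

    def test_matches_oracle_stable_sort_on_200_candidates(self):
        rng = np.random.default_rng(1)
        prof = _profile(rng.standard_normal((5, 12)))
        cands = _cands(rng.standard_normal((200, 12)))
        rl = rank_recsoi(prof, cands, 200)
        oracle = sorted(
            (
                (min(np.linalg.norm(v - c.embedding) for v in prof.vectors),
                 c.soi_id)
                for c in cands
            )
        )
        assert rl.soi_ids == [soi_id for _, soi_id in oracle]
        np.testing.assert_allclose(
            [s for _, s in rl.items], [d for d, _ in oracle], atol=1e-9
        )

    def test_input_order_invariance(self):
        rng = np.random.default_rng(2)
        prof = _profile(rng.standard_normal((3, 8)))
        cands = _cands(rng.standard_normal((40, 8)))
        a = rank_recsoi(prof, cands, 10).soi_ids
        shuffled = [cands[i] for i in rng.permutation(len(cands))]
        b = rank_recsoi(prof, shuffled, 10).soi_ids
        assert a == b

    def test_adding_profile_vector_never_increases_scores(self):
        rng = np.random.default_rng(3)
        base = rng.standard_normal((2, 8))
        prof_small = _profile(base)
        prof_big = _profile(np.vstack([base, rng.standard_normal((1, 8))]))
        for c in _cands(rng.standard_normal((30, 8))):
            assert (
                candidate_score_recsoi(prof_big, c)
                <= candidate_score_recsoi(prof_small, c) + 1e-12
            )

    def test_k_must_be_positive(self):
        prof = _profile([[0.0]])
        with pytest.raises(ConfigurationError):
            rank_recsoi(prof, [SOICandidate("a", np.zeros(1))], 0)


class TestBaselines:
    def test_sbert_single_sentence_author_vector(self, tiny_corpus):
        from recsoi.embeddings import EmbedderSpec, hash_embed

        spec = EmbedderSpec(dim=32)
        ab = tiny_corpus.abstracts_of("carol")  # one abstract, one sentence
        target = hash_embed(ab[0].sentences[0].text, dim=32)
        cands = [SOICandidate("hit", target), SOICandidate("far", -target)]
        rl = rank_baseline_sbert(ab, cands, 2, spec=spec)
        assert rl.soi_ids[0] == "hit"
        assert rl.items[0][1] == pytest.approx(0.0, abs=1e-12)

    def test_sbert_matches_mean_of_means_oracle(self):
        from recsoi.corpus import AbstractDoc, SentenceUnit
        from recsoi.embeddings import EmbedderSpec, hash_embed

        rng = np.random.default_rng(4)
        vocab = [f"w{i}" for i in range(40)]
        abstracts = []
        for j in range(5):
            sents = tuple(
                SentenceUnit(" ".join(rng.choice(vocab, 5)), 0, i)
                for i in range(3)
            )
            abstracts.append(AbstractDoc(f"ab{j}", "a", sents, time_rank=j))
        spec = EmbedderSpec(dim=24)
        cands = _cands(rng.standard_normal((20, 24)))
        rl = rank_baseline_sbert(abstracts, cands, 20, spec=spec)
        author_vec = np.mean(
            [
                np.mean([hash_embed(s.text, dim=24) for s in ab.sentences],
                        axis=0)
                for ab in abstracts
            ],
            axis=0,
        )
        oracle = sorted(
            (float(np.linalg.norm(c.embedding - author_vec)), c.soi_id)
            for c in cands
        )
        assert rl.soi_ids == [s for _, s in oracle]

    def test_tfidf_lr_prefers_signature_tokens(self):
        docs = ["zebrafish study one", "zebrafish study two",
                "fibrosis assay one", "fibrosis assay two"]
        tfidf = fit_tfidf(docs)
        from recsoi.profiles import train_discriminator

        disc = train_discriminator(
            tfidf.transform(docs), np.array([1, 1, 0, 0]), "a"
        )
        cands = [
            SOICandidate("own", np.zeros(2),
                         tfidf_vector=tfidf.transform(["zebrafish zebrafish"])),
            SOICandidate("other", np.zeros(2),
                         tfidf_vector=tfidf.transform(["fibrosis assay"])),
        ]
        rl = rank_baseline_tfidf_lr(disc, cands, 2)
        assert rl.soi_ids[0] == "own"

    def test_tfidf_lr_zero_model_falls_back_to_id_order(self):
        tfidf = fit_tfidf(["alpha beta", "beta gamma"])
        disc = AuthorDiscriminator("a", np.zeros(tfidf.n_features), 0.0)
        cands = [
            SOICandidate(sid, np.zeros(2), tfidf_vector=tfidf.transform(["alpha"]))
            for sid in ["m", "a", "z"]
        ]
        assert rank_baseline_tfidf_lr(disc, cands, 3).soi_ids == ["a", "m", "z"]

    def test_tfidf_lr_matches_probability_oracle(self):
        rng = np.random.default_rng(5)
        docs = [" ".join(rng.choice([f"w{i}" for i in range(30)], 6))
                for _ in range(10)]
        tfidf = fit_tfidf(docs)
        from recsoi.profiles import train_discriminator

        disc = train_discriminator(
            tfidf.transform(docs), np.array([1] * 5 + [0] * 5), "a"
        )
        texts = [" ".join(rng.choice([f"w{i}" for i in range(30)], 6))
                 for _ in range(100)]
        cands = [
            SOICandidate(f"c{i:03d}", np.zeros(2),
                         tfidf_vector=tfidf.transform([t]))
            for i, t in enumerate(texts)
        ]
        rl = rank_baseline_tfidf_lr(disc, cands, 100)
        from scipy.special import expit

        oracle = sorted(
            (
                -float(expit(
                    (c.tfidf_vector @ disc.coefficients)[0] + disc.intercept
                )),
                c.soi_id,
            )
            for c in cands
        )
        assert rl.soi_ids == [s for _, s in oracle]


class TestRandom:
    def test_k_at_least_n_is_permutation(self):
        cands = _cands(np.zeros((6, 2)))
        rl = rank_random(cands, 10, seed=0)
        assert sorted(rl.soi_ids) == sorted(c.soi_id for c in cands)

    def test_same_seed_same_list(self):
        cands = _cands(np.zeros((20, 2)))
        assert rank_random(cands, 5, seed=9).soi_ids == rank_random(
            cands, 5, seed=9
        ).soi_ids

    def test_top1_frequency_is_uniform(self):
        cands = _cands(np.zeros((8, 2)))
        counts = {c.soi_id: 0 for c in cands}
        for seed in range(10_000):
            counts[rank_random(cands, 1, seed=seed).soi_ids[0]] += 1
        _, p = chisquare(list(counts.values()))
        assert p > 1e-3


def test_all_methods_return_min_k_n_distinct_items(tiny_corpus):
    from recsoi.embeddings import EmbedderSpec
    from recsoi.profiles import build_profile
    from recsoi.ranking import make_candidates

    spec = EmbedderSpec(dim=16)
    tfidf = fit_tfidf([a.text for a in tiny_corpus.abstracts])
    cands = make_candidates(tiny_corpus, spec=spec, tfidf=tfidf)
    n = len(cands)  # 3 recommendable SOIs
    prof = build_profile(tiny_corpus, "alice", spec=spec, tfidf=tfidf)
    from recsoi.profiles import train_discriminator

    labels = np.array(
        [1 if a.author_id == "alice" else 0 for a in tiny_corpus.abstracts]
    )
    disc = train_discriminator(
        tfidf.transform([a.text for a in tiny_corpus.abstracts]), labels, "alice"
    )
    lists = [
        rank_recsoi(prof, cands, 10),
        rank_baseline_sbert(tiny_corpus.abstracts_of("alice"), cands, 10, spec),
        rank_baseline_tfidf_lr(disc, cands, 10),
        rank_random(cands, 10, seed=1, author_id="alice"),
    ]
    for rl in lists:
        assert len(rl.items) == min(10, n)
        assert len(set(rl.soi_ids)) == len(rl.soi_ids)
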