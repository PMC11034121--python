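"""Relevance heuristics, MAP metrics, intervals and the random baseline."""

import numpy as np
import pytest

from recsoi.errors import ConfigurationError
from recsoi.evaluation import (
    DatasetStats,
    concepts_eligible,
    evaluate_all,
    expected_random_relevant,
    map_at_k,
    map_exists_at_k,
    random_success_percentage,
    relevant_co_author,
    relevant_concepts,
    relevant_first_author,
    wald_halfwidth,
)
from recsoi.ranking import RankedList


def _rl(author, ids, method="recsoi"):
    return RankedList(
        author_id=author,
        method=method,
        items=[(i, float(r)) for r, i in enumerate(ids)],
        k=len(ids),
    )


class TestHeuristics:
    def test_first_author(self, tiny_corpus):
        soi = tiny_corpus.sois[0]  # from alice's paper
        assert relevant_first_author(soi, "alice", tiny_corpus)
        assert not relevant_first_author(soi, "bob", tiny_corpus)

    def test_co_author_true_for_listed_coauthor(self, tiny_corpus):
        # bob co-authors alice's paper -> bob's SOIs are co-author-relevant
        # for alice
        soi_bob = next(s for s in tiny_corpus.sois if s.paper_id == "p-bob")
        assert relevant_co_author(soi_bob, "alice", tiny_corpus)

    def test_co_author_false_for_self(self, tiny_corpus):
        soi_alice = tiny_corpus.sois[0]
        assert not relevant_co_author(soi_alice, "alice", tiny_corpus)

    def test_co_author_false_without_link(self, tiny_corpus):
        soi_alice = tiny_corpus.sois[0]
        # alice is not a co-author on any of bob's first-authored papers
        assert not relevant_co_author(soi_alice, "bob", tiny_corpus)

    def test_concepts_shared_and_empty(self, tiny_corpus):
        soi = next(s for s in tiny_corpus.sois if s.soi_id == "soi-2")
        assert relevant_concepts(soi, "alice", tiny_corpus)  # zebrafish
        assert not relevant_concepts(soi, "carol", tiny_corpus)  # folate only
        bare = next(s for s in tiny_corpus.sois if s.soi_id == "soi-3")
        assert not relevant_concepts(bare, "alice", tiny_corpus)

    def test_heuristics_agree_with_brute_force_join(self, small_sim):
        corpus = small_sim.corpus
        sois = corpus.sois
        coauthors = {
            a.author_id: {
                co for p in corpus.papers_of(a.author_id) for co in p.co_authors
            }
            for a in corpus.authors
        }
        for author in (a.author_id for a in corpus.authors):
            for s in sois:
                writer = corpus.paper(s.paper_id).first_author
                assert relevant_first_author(s, author, corpus) == (
                    writer == author
                )
                assert relevant_co_author(s, author, corpus) == (
                    writer != author and writer in coauthors[author]
                )

    def test_concepts_eligibility(self, tiny_corpus):
        from recsoi.corpus import filter_recommendable_sois

        cands = filter_recommendable_sois(tiny_corpus)
        assert concepts_eligible("alice", cands, tiny_corpus)
        assert not concepts_eligible("carol", cands, tiny_corpus)  # folate only


class TestMapMetrics:
    def test_all_and_none_satisfied(self):
        ranked = {f"a{i}": _rl(f"a{i}", ["x", "y"]) for i in range(4)}
        assert map_exists_at_k(ranked, lambda a, s: True, 2) == 1.0
        assert map_exists_at_k(ranked, lambda a, s: False, 2) == 0.0

    def test_one_of_three_authors(self):
        ranked = {a: _rl(a, ["x", "y"]) for a in ["a", "b", "c"]}
        judge = lambda author, soi: author == "a" and soi == "y"
        assert map_exists_at_k(ranked, judge, 2) == pytest.approx(1 / 3)

    def test_map_at_k_counts_fraction(self):
        ranked = {"a": _rl("a", ["1", "2", "3", "4", "5"])}
        judge = lambda author, soi: soi in {"2", "4"}
        assert map_at_k(ranked, judge, 5) == pytest.approx(0.4)

    def test_empty_author_set_rejected(self):
        with pytest.raises(ConfigurationError):
            map_exists_at_k({}, lambda a, s: True, 5)

    def test_map_dominance_and_monotonicity_on_random_patterns(self):
        rng = np.random.default_rng(0)
        for _ in range(1000):
            n_authors = int(rng.integers(1, 6))
            pattern = rng.random((n_authors, 20)) < rng.random()
            ranked = {
                f"a{i}": _rl(f"a{i}", [f"s{i}_{j}" for j in range(20)])
                for i in range(n_authors)
            }
            rel = {
                f"s{i}_{j}"
                for i in range(n_authors)
                for j in range(20)
                if pattern[i, j]
            }
            judge = lambda a, s: s in rel
            prev = 0.0
            for k in (5, 10, 20):
                m = map_at_k(ranked, judge, k)
                me = map_exists_at_k(ranked, judge, k)
                assert 0.0 <= m <= me <= 1.0
                assert me >= prev - 1e-12  # monotone in k
                prev = me


class TestWaldHalfwidth:
    @pytest.mark.parametrize(
        "p,n,printed",
        [
            (0.23, 500, 0.037),
            (0.346, 500, 0.042),
            (0.282, 500, 0.039),
        ],
    )
    def test_reproduces_published_interval_widths(self, p, n, printed):
        assert wald_halfwidth(p, n) == pytest.approx(printed, abs=5e-4)

    @pytest.mark.parametrize(
        "p,n,printed_pct",
        [
            # the full published set, incl. the extreme-proportion cells the
            # normal approximation misses (0% rows, 13.6% and 23.7% at n=59)
            (0.0, 500, 0.4),
            (0.0, 59, 3.1),
            (0.136, 59, 8.8),
            (0.237, 59, 10.6),
            (0.23, 500, 3.7),
            (0.282, 500, 3.9),
            (0.346, 500, 4.2),
            (0.653, 496, 4.2),
            (0.909, 496, 2.5),
        ],
    )
    def test_wilson_reproduces_all_published_widths(self, p, n, printed_pct):
        from recsoi.evaluation import wilson_halfwidth

        assert round(100 * wilson_halfwidth(p, n), 1) == printed_pct

    def test_zero_proportion_gives_zero_width(self):
        assert wald_halfwidth(0.0, 100) == 0.0

    def test_maximal_at_half_and_root_n_scaling(self):
        n = 200
        widths = [wald_halfwidth(p, n) for p in np.linspace(0.01, 0.99, 99)]
        assert max(widths) == pytest.approx(wald_halfwidth(0.5, n))
        assert wald_halfwidth(0.3, 400) == pytest.approx(
            wald_halfwidth(0.3, 100) / 2
        )

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            wald_halfwidth(1.2, 10)
        with pytest.raises(ValueError):
            wald_halfwidth(0.5, 0)


class TestRandomBaseline:
    def test_published_median_author_expectations(self):
        assert expected_random_relevant(5, 99, 61_511) == pytest.approx(
            0.008, abs=5e-4
        )
        assert expected_random_relevant(20, 99, 61_511) == pytest.approx(
            0.032, abs=5e-4
        )

    def test_zero_relevant_gives_zero(self):
        assert expected_random_relevant(7, 0, 100) == 0.0

    def test_linearity_in_k_and_n_r(self):
        assert expected_random_relevant(10, 30, 300) == pytest.approx(
            2 * expected_random_relevant(5, 30, 300)
        )
        assert expected_random_relevant(5, 60, 300) == pytest.approx(
            2 * expected_random_relevant(5, 30, 300)
        )

    def test_bounds_enforced(self):
        with pytest.raises(ValueError):
            expected_random_relevant(5, 101, 100)
        with pytest.raises(ValueError):
            expected_random_relevant(101, 5, 100)

    def test_matches_hypergeometric_sampling(self):
        # 1e5 draws without replacement vs k*n_R/n, within 3 standard errors
        rng = np.random.default_rng(42)
        k, n_r, n = 10, 37, 500
        draws = rng.hypergeometric(n_r, n - n_r, k, size=100_000)
        expected = expected_random_relevant(k, n_r, n)
        se = draws.std(ddof=1) / np.sqrt(len(draws))
        assert abs(draws.mean() - expected) < 3 * se

    def test_success_percentage_extremes_and_brute_force(self):
        all_in = DatasetStats(10, {f"a{i}": 10 for i in range(4)})
        none_in = DatasetStats(10, {f"a{i}": 0 for i in range(4)})
        assert random_success_percentage(5, all_in) == 100.0
        assert random_success_percentage(5, none_in) == 0.0
        mixed = DatasetStats(100, {"a": 99, "b": 10, "c": 50})
        # brute force: k*n_R/n >= 1 per author
        k = 5
        expected = 100 * sum(
            1 for v in (99, 10, 50) if k * v / 100 >= 1
        ) / 3
        assert random_success_percentage(k, mixed) == pytest.approx(expected)


class TestEvaluateAll:
    @pytest.fixture
    def report(self, small_sim):
        return evaluate_all(small_sim.corpus, ks=(2, 5), seed=0)

    def test_report_shape(self, report):
        methods = {m for m, _, _ in report.cells}
        heuristics = {h for _, h, _ in report.cells}
        assert methods == {
            "recsoi", "baseline_sbert", "baseline_tfidf_lr", "random"
        }
        assert heuristics <= {"first_author", "co_authors", "concepts"}
        for cell in report.cells.values():
            assert 0.0 <= cell["proportion"] <= 1.0
            assert cell["ci_halfwidth"] >= 0.0

    def test_map_exists_monotone_in_k(self, report):
        for (m, h, k), cell in report.cells.items():
            if k == 2:
                assert (
                    report.cells[(m, h, 5)]["proportion"]
                    >= cell["proportion"] - 1e-12
                )

    def test_random_row_present_per_heuristic_and_k(self, report):
        heuristics = {h for _, h, _ in report.cells}
        for h in heuristics:
            for k in (2, 5):
                assert (h, k) in report.random_row
                assert 0.0 <= report.random_row[(h, k)] <= 100.0

    def test_recsoi_beats_analytic_random_on_separated_corpus(self, report):
        # disjoint topics, no generic SOIs: first-author recovery is strong
        p = report.cells[("recsoi", "first_author", 5)]["proportion"]
        assert p - report.random_row[("first_author", 5)] / 100.0 >= 0.5
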