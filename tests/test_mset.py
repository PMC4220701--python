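"""MSET randomization test: oracle agreement, calibration, invariances."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import msetkit as mk
from msetkit.errors import InvalidInputError

from conftest import make_collection


def brute_force_upper_tail(x, B, K, n):
    """Exhaustive hypergeometric tail by binomial-coefficient enumeration."""
    total = math.comb(B, n)
    return sum(
        math.comb(K, i) * math.comb(B - K, n - i)
        for i in range(x, min(n, K) + 1)
    ) / total


class TestCountMatches:
    def test_hand_enumeration(self):
        db = mk.GeneSet("db", frozenset(["PER1", "GRM3"]))
        assert mk.count_matches({"PER1", "PER2"}, db) == 1

    def test_disjoint_and_containment(self):
        db = mk.GeneSet("db", frozenset(["A", "B", "C"]))
        assert mk.count_matches({"X", "Y"}, db) == 0
        assert mk.count_matches({"a", "b"}, db) == 2  # case-insensitive


class TestHypergeomOracle:
    def test_zero_matches_total_mass(self):
        assert mk.hypergeom_upper_tail(0, 100, 10, 5) == 1.0

    def test_hand_enumerated_values(self):
        assert mk.hypergeom_upper_tail(3, 10, 4, 3) == pytest.approx(4 / 120)
        assert mk.hypergeom_upper_tail(3, 20, 5, 5) == pytest.approx(1126 / 15504)

    def test_inconsistent_counts_rejected(self):
        with pytest.raises(InvalidInputError):
            mk.hypergeom_upper_tail(6, 10, 5, 5)
        with pytest.raises(InvalidInputError):
            mk.hypergeom_upper_tail(1, 10, 11, 5)

    @given(
        B=st.integers(5, 40),
        K=st.integers(0, 40),
        n=st.integers(0, 40),
        x=st.integers(0, 40),
    )
    @settings(max_examples=100, deadline=None)
    def test_matches_brute_force_enumeration(self, B, K, n, x):
        K, n = min(K, B), min(n, B)
        x = min(x, min(n, K))
        assert mk.hypergeom_upper_tail(x, B, K, n) == pytest.approx(
            brute_force_upper_tail(x, B, K, n), rel=1e-10
        )


class TestMsetTest:
    def setup_method(self):
        self.background = [f"G{i}" for i in range(20)]
        self.db = mk.GeneSet("db", frozenset(self.background[:5]))  # K=5

    def test_saturated_database(self):
        db_all = mk.GeneSet("all", frozenset(self.background))
        res = mk.mset_test(
            self.background[:5], db_all, self.background,
            mk.MsetConfig(n_randomizations=200, seed=1),
        )
        assert res.observed_matches == 5
        assert res.empirical_p == 1.0

    def test_zero_matches_floor(self):
        sig = self.background[10:15]
        db = mk.GeneSet("db", frozenset(self.background[:5]))
        res = mk.mset_test(sig, db, self.background, mk.MsetConfig(n_randomizations=200, seed=2))
        assert res.observed_matches == 0
        assert res.empirical_p == 1.0

    def test_empirical_agrees_with_exact_tail(self):
        """B=20, K=5, n=5, x=3: empirical p within Monte-Carlo error of
        the exhaustive tail 1126/15504."""
        sig = self.background[:3] + self.background[10:12]  # 3 matches
        R = 100_000
        res = mk.mset_test(sig, self.db, self.background, mk.MsetConfig(n_randomizations=R, seed=3))
        p = 1126 / 15504
        assert res.observed_matches == 3
        assert res.oracle_p == pytest.approx(p, rel=1e-9)
        assert abs(res.empirical_p - p) < 3 * np.sqrt(p * (1 - p) / R) + 2 / R

    def test_literal_p_rule_available(self):
        sig = self.background[:3] + self.background[10:12]
        res = mk.mset_test(
            sig, self.db, self.background,
            mk.MsetConfig(n_randomizations=1000, seed=3, pseudocount_correction=False),
        )
        hist = res.null_match_counts
        expected = sum(hist[3:]) / 1000
        assert res.empirical_p == pytest.approx(expected)

    def test_histogram_mass_and_support(self):
        res = mk.mset_test(
            self.background[:5], self.db, self.background,
            mk.MsetConfig(n_randomizations=500, seed=4),
        )
        assert res.null_match_counts.sum() == 500
        assert len(res.null_match_counts) == min(res.significant_size, res.restricted_db_size) + 1

    def test_null_mean_matches_hypergeometric(self):
        res = mk.mset_test(
            self.background[:5], self.db, self.background,
            mk.MsetConfig(n_randomizations=20_000, seed=5),
        )
        expected = 5 * 5 / 20  # n*K/B
        var = expected * (1 - 5 / 20) * (20 - 5) / (20 - 1)
        assert abs(res.null_mean - expected) < 3 * np.sqrt(var / 20_000)

    def test_empty_restricted_database_refused(self):
        db = mk.GeneSet("off", frozenset(["ZZZ"]))
        with pytest.warns(UserWarning):
            with pytest.raises(InvalidInputError, match="refusing"):
                mk.mset_test(self.background[:3], db, self.background,
                             mk.MsetConfig(n_randomizations=200, seed=6))

    def test_significant_genes_outside_background_dropped(self):
        sig = self.background[:3] + ["NOT_THERE"]
        with pytest.warns(UserWarning, match="dropped"):
            res = mk.mset_test(sig, self.db, self.background,
                               mk.MsetConfig(n_randomizations=200, seed=7))
        assert res.significant_size == 3

    def test_monotone_in_observed_matches(self):
        """Same background, database, n and seed: p non-increasing in x."""
        ps = []
        for x in range(6):
            sig = self.background[:x] + self.background[10 : 10 + (5 - x)]
            res = mk.mset_test(sig, self.db, self.background,
                               mk.MsetConfig(n_randomizations=2000, seed=8))
            assert res.observed_matches == x
            ps.append(res.empirical_p)
        assert all(a >= b for a, b in zip(ps, ps[1:]))

    def test_removing_one_nonmatching_gene_barely_moves_p(self):
        """Dropping one non-matching gene from a 1000-gene list shifts the
        p-value by less than the Monte-Carlo error bound."""
        u = mk.simulate_universe(mk.UniverseSpec(n_genes=5000, seed=9))
        syms = list(u.symbols)
        db = mk.GeneSet("db", frozenset(syms[:400]))
        sig = syms[:60] + syms[1000:1940]  # 1000 genes, 60 matches
        R = 20_000
        cfg = mk.MsetConfig(n_randomizations=R, seed=10)
        p_full = mk.mset_test(sig, db, syms, cfg).empirical_p
        p_drop = mk.mset_test(sig[:-1], db, syms, cfg).empirical_p
        bound = 4 * np.sqrt(max(p_full, 1e-4) * (1 - p_full) / R) + 2 / R
        assert abs(p_full - p_drop) < max(bound, 0.01)

    def test_deterministic_given_seed(self):
        cfg = mk.MsetConfig(n_randomizations=500, seed=11)
        a = mk.mset_test(self.background[:5], self.db, self.background, cfg)
        b = mk.mset_test(self.background[:5], self.db, self.background, cfg)
        assert a.empirical_p == b.empirical_p
        assert np.array_equal(a.null_match_counts, b.null_match_counts)


class TestMsetBatch:
    def test_empty_collection_gives_empty_table(self):
        table, results = mk.mset_batch(
            ["G1"], mk.DatabaseCollection([]), ["G1", "G2", "G3"],
            mk.MsetConfig(n_randomizations=200, seed=1),
        )
        assert table.empty and not results

    def test_results_independent_of_database_order(self):
        bg = [f"G{i}" for i in range(100)]
        coll_ab = make_collection(("a", bg[:20]), ("b", bg[30:60]))
        coll_ba = make_collection(("b", bg[30:60]), ("a", bg[:20]))
        cfg = mk.MsetConfig(n_randomizations=1000, seed=2)
        t1, _ = mk.mset_batch(bg[:10], coll_ab, bg, cfg)
        t2, _ = mk.mset_batch(bg[:10], coll_ba, bg, cfg)
        p1 = t1.set_index("database")["empirical_p"]
        p2 = t2.set_index("database")["empirical_p"]
        assert p1["a"] == p2["a"] and p1["b"] == p2["b"]

    def test_failed_database_flagged_not_aborting(self):
        bg = [f"G{i}" for i in range(50)]
        coll = make_collection(("ok", bg[:10]), ("off_background", ["ZZZ"]))
        with pytest.warns(UserWarning):
            table, results = mk.mset_batch(
                bg[:5], coll, bg, mk.MsetConfig(n_randomizations=200, seed=3)
            )
        assert "ok" in results and "off_background" not in results
        flagged = table.set_index("database")["error"]
        assert flagged["off_background"] != ""


class TestMatchReport:
    def test_no_membership_gives_empty(self):
        coll = make_collection(("a", ["X"]))
        report = mk.match_report(["G1", "G2"], coll)
        assert report.empty

    def test_membership_counts(self):
        coll = make_collection(*((f"db{i}", ["HUB", f"U{i}"]) for i in range(5)))
        report = mk.match_report(["HUB", "U0", "ABSENT"], coll)
        assert report.loc["HUB", "n_databases"] == 5
        assert report.loc["U0", "n_databases"] == 1
        assert "ABSENT" not in report.index

    def test_report_matches_generator_truth(self, small_universe, de_study):
        _, truth = de_study
        coll = mk.simulate_genesets(
            small_universe, truth,
            mk.GenesetSpec(sizes=[80, 90], names=["d1", "d2"], enrichment_fraction=0.5, seed=13),
        )
        sig = list(truth.gene)
        report = mk.match_report(sig, coll)
        for g in report.index:
            for db in coll:
                assert report.loc[g, db.name] == (g in db.genes)
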