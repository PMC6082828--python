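"""Direction-aware overlap, coverage percentages and hypergeometric enrichment."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from smokesig.overlap import (
    coverage_percent,
    enrichment_fisher,
    enrichment_matrix,
    geneset_enrichment,
    overlap_directional,
    overlap_three_way,
)
from helpers import hypergeom_tail_bruteforce, make_signature


class TestOverlapDirectional:
    def test_mixed_direction_classification(self):
        a = make_signature(["g1", "g3"], ["g2"])
        b = make_signature(["g1", "g2"], ["g4"])
        res = overlap_directional(a, b)
        assert set(res.table["gene"]) == {"g1", "g2"}
        assert res.counts == (1, 0, 1)

    def test_disjoint_signatures_empty(self):
        res = overlap_directional(make_signature(["a"], []), make_signature(["b"], []))
        assert res.n_shared == 0
        assert res.counts == (0, 0, 0)

    def test_self_overlap_all_concordant(self):
        sig = make_signature(["g1", "g2"], ["g3"])
        res = overlap_directional(sig, sig)
        assert res.discordant == 0
        assert res.n_shared == 3

    def test_species_mismatch_rejected(self):
        a = make_signature(["g1"], [], species="human")
        b = make_signature(["g1"], [], species="mouse")
        with pytest.raises(ValueError, match="namespaces"):
            overlap_directional(a, b)

    @settings(deadline=None, derandomize=True, max_examples=100)
    @given(st.integers(0, 2**32 - 1))
    def test_partition_identity_on_random_signatures(self, seed):
        # concordant-up + concordant-down + discordant always equals |shared|
        rng = np.random.default_rng(seed)
        genes = [f"g{i}" for i in range(30)]
        def rand_sig():
            chosen = rng.choice(genes, size=rng.integers(1, 20), replace=False)
            dirs = rng.choice([1, -1], size=len(chosen))
            return make_signature(
                [g for g, d in zip(chosen, dirs) if d == 1],
                [g for g, d in zip(chosen, dirs) if d == -1],
                universe=genes,
            )
        a, b = rand_sig(), rand_sig()
        res = overlap_directional(a, b)
        assert sum(res.counts) == res.n_shared == len(a.genes & b.genes)


class TestOverlapThreeWay:
    def test_identical_signatures_all_concordant(self):
        sig = make_signature(["g1"], ["g2", "g3"])
        res = overlap_three_way(sig, sig, sig)
        assert res.counts == (1, 2, 0)

    def test_any_direction_flip_is_discordant(self):
        a = make_signature(["g1"], [])
        b = make_signature(["g1"], [])
        c = make_signature([], ["g1"])
        assert overlap_three_way(a, b, c).counts == (0, 0, 1)

    def test_constructed_partition(self):
        up = [f"u{i}" for i in range(5)]
        down = [f"d{i}" for i in range(2)]
        mixed = [f"x{i}" for i in range(3)]
        a = make_signature(up + mixed, down)
        b = make_signature(up, down + mixed)
        c = make_signature(up + mixed, down)
        res = overlap_three_way(a, b, c)
        assert res.counts == (5, 2, 3)
        assert res.n_shared == 10


class TestCoveragePercent:
    @pytest.mark.parametrize(
        "k, denom, expected",
        [(184, 386, 48), (1958, 3687, 53), (1003, 3687, 27), (116, 386, 30),
         (168, 386, 44), (914, 4071, 22), (60, 139, 43), (0, 100, 0)],
    )
    def test_rounding_half_away_from_zero(self, k, denom, expected):
        assert coverage_percent(k, denom) == expected

    def test_monotone_in_overlap_count(self):
        values = [coverage_percent(k, 37) for k in range(38)]
        assert values == sorted(values)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            coverage_percent(1, 0)
        with pytest.raises(ValueError):
            coverage_percent(5, 4)


class TestEnrichmentFisher:
    def test_independence_expectation_fold_one(self):
        # k = |A|*|B|/N exactly -> fold 1.0
        universe = [f"g{i}" for i in range(20)]
        a = set(universe[:10])
        b = set(universe[5:15])  # k = 5 = 10*10/20
        res = enrichment_fisher(a, b, set(universe))
        assert res.fold == pytest.approx(1.0)

    def test_small_example_exhaustive_enumeration(self):
        universe = [f"g{i}" for i in range(10)]
        a = set(universe[:5])
        b = set(universe[:4])
        res = enrichment_fisher(a, b, set(universe))
        assert res.k == 4
        assert res.fold == pytest.approx(2.0)
        assert res.p_value == pytest.approx(5 / 210)

    @settings(deadline=None, derandomize=True, max_examples=100)
    @given(st.integers(0, 2**32 - 1))
    def test_matches_bruteforce_tail_small_universes(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 200))
        universe = [f"g{i}" for i in range(n)]
        a = set(rng.choice(universe, size=rng.integers(1, n), replace=False))
        b = set(rng.choice(universe, size=rng.integers(1, n), replace=False))
        res = enrichment_fisher(a, b, set(universe))
        expected = hypergeom_tail_bruteforce(res.k, n, len(a), len(b))
        assert res.p_value == pytest.approx(expected, rel=1e-9)

    def test_fold_formula_inversion_round_trip(self):
        # published fold 3.8 for k=184, |A|=386, |B|=3687 implies N ~ 29,392;
        # recomputing the fold at that N returns 3.8
        k, size_a, size_b, fold = 184, 386, 3687, 3.8
        n = round(fold * size_a * size_b / k)
        assert n == pytest.approx(29392, abs=1)
        assert round(k * n / (size_a * size_b), 1) == fold

    def test_entries_outside_universe_dropped_with_warning(self):
        universe = {"g1", "g2", "g3"}
        with pytest.warns(UserWarning, match="outside the universe"):
            res = enrichment_fisher({"g1", "gX"}, {"g1"}, universe)
        assert res.size_a == 1 and res.k == 1

    def test_empty_universe_rejected(self):
        with pytest.raises(ValueError, match="universe"):
            enrichment_fisher({"a"}, {"a"}, set())

    def test_independent_signatures_calibrated(self, rng):
        # random sets in a fixed universe: mean fold ~ 1, p approximately uniform
        universe = [f"g{i}" for i in range(400)]
        folds, ps = [], []
        for _ in range(500):
            a = set(rng.choice(universe, size=60, replace=False))
            b = set(rng.choice(universe, size=60, replace=False))
            res = enrichment_fisher(a, b, set(universe))
            folds.append(res.fold)
            ps.append(res.p_value)
        assert 0.9 <= np.mean(folds) <= 1.1
        # discrete k makes p slightly conservative; KS against uniform is loose
        assert stats.kstest(ps, "uniform").pvalue > 1e-4 or np.mean(ps) > 0.4


class TestEnrichmentMatrix:
    def _three_sigs(self):
        universe = [f"g{i}" for i in range(100)]
        a = make_signature(universe[:20], [], universe=universe)
        b = make_signature(universe[10:35], [], universe=universe)
        c = make_signature(universe[30:40], [], universe=universe)
        return {"A": a, "B": b, "C": c}

    def test_folds_match_hand_computed(self):
        sigs = self._three_sigs()
        table = enrichment_matrix(sigs)
        row = table.set_index(["signature_a", "signature_b"])
        assert row.loc[("A", "B"), "k"] == 10
        assert row.loc[("A", "B"), "fold"] == pytest.approx(10 * 100 / (20 * 25))
        assert row.loc[("A", "C"), "k"] == 0

    def test_symmetric_under_shared_universe(self):
        table = enrichment_matrix(self._three_sigs())
        idx = table.set_index(["signature_a", "signature_b"])
        for a, b in [("A", "B"), ("A", "C"), ("B", "C")]:
            assert idx.loc[(a, b), "fold"] == pytest.approx(idx.loc[(b, a), "fold"])
            assert idx.loc[(a, b), "p_value"] == pytest.approx(idx.loc[(b, a), "p_value"])

    def test_diagonal_omitted(self):
        table = enrichment_matrix(self._three_sigs())
        assert not (table["signature_a"] == table["signature_b"]).any()

    def test_self_enrichment_fold_is_n_over_s(self):
        universe = [f"g{i}" for i in range(50)]
        a = make_signature(universe[:10], [], universe=universe)
        b = make_signature(universe[:10], [], universe=universe)
        res = enrichment_fisher(a, b)
        assert res.fold == pytest.approx(50 / 10)


class TestGenesetEnrichment:
    def test_exact_query_set_ranks_first(self):
        universe = [f"g{i}" for i in range(60)]
        annotation = {
            "target": set(universe[:10]),
            "other1": set(universe[20:35]),
            "other2": set(universe[40:55]),
        }
        table = geneset_enrichment(set(universe[:10]), annotation, set(universe))
        assert table["set_name"].iloc[0] == "target"
        assert table["fold"].iloc[0] == max(table["fold"])

    def test_random_query_null_behavior(self, rng):
        universe = [f"g{i}" for i in range(300)]
        annotation = {f"s{i}": set(rng.choice(universe, size=30, replace=False))
                      for i in range(20)}
        query = set(rng.choice(universe, size=40, replace=False))
        table = geneset_enrichment(query, annotation, set(universe))
        assert table["fdr"].min() > 0.05

    def test_counts_match_enumeration_oracle(self):
        universe = [f"g{i}" for i in range(30)]
        annotation = {
            "setA": set(universe[:10]),
            "setB": set(universe[10:18]),
            "setC": set(universe[25:30]),
        }
        query = set(universe[5:15])
        table = geneset_enrichment(query, annotation, set(universe)).set_index("set_name")
        for name, members in annotation.items():
            k = len(query & members)
            assert table.loc[name, "k"] == k
            expected_p = hypergeom_tail_bruteforce(k, 30, len(query), len(members))
            assert table.loc[name, "p_value"] == pytest.approx(expected_p)

    def test_empty_universe_set_skipped(self):
        universe = {"g1", "g2"}
        annotation = {"ok": {"g1"}, "empty": {"zz"}}
        with pytest.warns(UserWarning, match="skipped"):
            table = geneset_enrichment({"g1"}, annotation, universe)
        assert list(table["set_name"]) == ["ok"]
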