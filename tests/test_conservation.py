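"""Profile r^2 conservation and the paired signed-rank test."""

import itertools
import math

import numpy as np
import pytest
import scipy.stats
from hypothesis import given
from hypothesis import strategies as st

import monodi as m
from monodi.conservation import (_exact_two_sided_p, _normal_two_sided_p,
                                 wilcoxon_signed_rank)
from monodi.coverage import Region

from conftest import random_fragments


class TestProfileR2:
    def test_identical_profiles_give_one(self):
        x = np.array([1, 5, 2, 7])
        assert m.profile_r2(x, x) == pytest.approx(1.0)

    def test_hand_computed_example(self):
        # Pearson r of these vectors is 0.8
        assert m.profile_r2(np.array([1, 2, 3, 4]),
                            np.array([1, 3, 2, 4])) == pytest.approx(0.64)

    def test_zero_variance_is_undefined(self):
        assert math.isnan(m.profile_r2(np.array([2, 2, 2]), np.array([1, 2, 3])))

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            m.profile_r2(np.arange(4), np.arange(5))

    @given(st.lists(st.integers(0, 50), min_size=4, max_size=20),
           st.integers(1, 9), st.integers(-20, 20))
    def test_symmetric_and_affine_invariant(self, values, scale, shift):
        x = np.array(values, dtype=float)
        y = np.roll(x, 1) + np.arange(len(x))  # some second profile
        r2 = m.profile_r2(x, y)
        if math.isnan(r2):
            return
        assert m.profile_r2(y, x) == pytest.approx(r2)
        assert m.profile_r2(scale * x + shift, y) == pytest.approx(r2)


def brute_force_two_sided_p(d):
    """Literal enumeration of every sign assignment."""
    d = np.asarray(d, dtype=float)
    d = d[d != 0]
    ranks = scipy.stats.rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    ws = [np.sum(ranks[list(signs)]) for signs in
          itertools.product([False, True], repeat=len(d))]
    ws = np.array([sum(r for r, s in zip(ranks, signs) if s)
                   for signs in itertools.product([0, 1], repeat=len(d))])
    p_le = np.mean(ws <= w_obs + 1e-9)
    p_ge = np.mean(ws >= w_obs - 1e-9)
    return w_obs, min(1.0, 2 * min(p_le, p_ge))


class TestSignedRank:
    def test_three_positive_differences(self):
        res = wilcoxon_signed_rank([1, 2, 3])
        assert res.w == 6 and res.p == pytest.approx(0.25)
        assert res.method == "exact"

    def test_tied_magnitudes_use_midranks(self):
        res = wilcoxon_signed_rank([1, -1])
        assert res.w == 1.5 and res.p == pytest.approx(1.0)

    def test_single_pair(self):
        res = wilcoxon_signed_rank([0.7])
        assert res.w == 1 and res.p == pytest.approx(1.0)

    def test_all_zero_differences_degenerate(self):
        res = wilcoxon_signed_rank([0.0, 0.0])
        assert res.method == "degenerate"
        assert res.p == 1.0 and res.n_used == 0 and res.n_zero == 2

    def test_zero_differences_dropped(self):
        res = wilcoxon_signed_rank([0, 1, 2, 3])
        assert res.n_zero == 1 and res.n_used == 3
        assert res.p == pytest.approx(0.25)

    def test_matches_enumeration_oracle(self, rng):
        """Exact p agrees with literal 2^n enumeration, ties included."""
        for _ in range(40):
            n = int(rng.integers(1, 13))
            d = np.round(rng.normal(size=n) * 2, 1)  # rounding induces ties
            d = d[d != 0]
            if len(d) == 0:
                continue
            w_oracle, p_oracle = brute_force_two_sided_p(d)
            res = wilcoxon_signed_rank(d)
            assert res.w == pytest.approx(w_oracle)
            assert res.p == pytest.approx(p_oracle)

    def test_matches_scipy_exact_without_ties(self, rng):
        for _ in range(20):
            n = int(rng.integers(4, 16))
            d = rng.normal(size=n)
            res = wilcoxon_signed_rank(d)
            ref = scipy.stats.wilcoxon(d, alternative="two-sided", method="exact")
            assert res.p == pytest.approx(ref.pvalue)

    def test_normal_approximation_close_to_exact_at_n20(self, rng):
        for _ in range(10):
            d = rng.normal(size=20)
            ranks = scipy.stats.rankdata(np.abs(d))
            w = float(ranks[d > 0].sum())
            exact = _exact_two_sided_p(np.round(2 * ranks).astype(np.int64), 2 * w)
            approx = _normal_two_sided_p(ranks, w)
            assert abs(exact - approx) <= 0.02


class TestRegionR2Table:
    def genes_with_tss(self, model):
        genes = []
        for g in model.genes:
            gene = m.Gene(g.gene_id, g.chrom, g.cds_start, g.cds_end,
                          g.strand, tss=g.tss)
            genes.append(gene)
        return genes

    def test_identical_conditions_give_r2_one(self, small_model):
        ps = m.deduplicate(m.simulate_fragments(small_model, "untreated_mono",
                                                20_000, seed=3))
        rows = m.region_r2_table(self.genes_with_tss(small_model), ps, ps,
                                 chrom_lengths=small_model.chrom_lengths)
        defined = [r for r in rows if r.defined]
        assert defined and all(r.r2 == pytest.approx(1.0) for r in defined)

    def test_empty_condition_all_undefined(self, small_model):
        ps = m.deduplicate(m.simulate_fragments(small_model, "untreated_mono",
                                                5_000, seed=3))
        empty = m.deduplicate(m.FragmentSet.empty("mono"))
        rows = m.region_r2_table(self.genes_with_tss(small_model), ps, empty,
                                 chrom_lengths=small_model.chrom_lengths)
        assert rows and all(not r.defined for r in rows)

    def test_genes_without_tss_skipped(self, small_model):
        genes = self.genes_with_tss(small_model)
        genes[0].tss = None
        ps = m.deduplicate(m.simulate_fragments(small_model, "untreated_mono",
                                                5_000, seed=3))
        rows = m.region_r2_table(genes, ps, ps,
                                 chrom_lengths=small_model.chrom_lengths)
        assert len(rows) == 2 * (len(genes) - 1)


class TestTssWindows:
    def test_identical_conditions_give_one(self, small_model):
        genes = TestRegionR2Table().genes_with_tss(small_model)
        ps = m.deduplicate(m.simulate_fragments(small_model, "untreated_mono",
                                                20_000, seed=4))
        rows = m.tss_window_r2(genes, ps, ps,
                               chrom_lengths=small_model.chrom_lengths)
        assert {r.label for r in rows} == {"tss_down", "tss_up"}
        for r in rows:
            if r.defined:
                assert r.r2 == pytest.approx(1.0)

    def test_window_clipped_at_chromosome_edge(self):
        gene = m.Gene("g", "c1", 400, 1600, "+", tss=200)
        ps = m.PositionSet(np.array(["c1"], dtype=object), np.array([100]),
                           np.array([260]), np.array([1]))
        rows = m.tss_window_r2([gene], ps, ps, half_window=300,
                               chrom_lengths={"c1": 2000})
        up = [r for r in rows if r.label == "tss_up"][0]
        assert up.length == 200  # [0, 200) instead of 300 nt


class TestMedianByClass:
    def test_small_cell(self):
        rows = [m.RegionR2("a", "body", 0.2, 10),
                m.RegionR2("b", "body", 0.6, 10),
                m.RegionR2("c", "body", 1.0, 10)]
        table = m.median_by_class(rows, {"a": "x", "b": "x", "c": "x"})
        assert table.loc[0, "median"] == pytest.approx(0.6)

    def test_single_value_cell_and_undefined_counting(self):
        rows = [m.RegionR2("a", "body", 0.7, 10),
                m.RegionR2("b", "body", math.nan, 10)]
        table = m.median_by_class(rows, {"a": "x", "b": "x"})
        row = table.iloc[0]
        assert row["median"] == pytest.approx(0.7)
        assert row["n_defined"] == 1 and row["n_undefined"] == 1

    def test_matches_sort_oracle_on_random_rows(self, rng):
        classes, labels = ["p", "q", "r"], ["body", "promoter"]
        rows, truth = [], {}
        for i in range(500):
            cls = classes[int(rng.integers(3))]
            lab = labels[int(rng.integers(2))]
            val = float(rng.random())
            rows.append(m.RegionR2(f"g{i}", lab, val, 10))
            truth[f"g{i}"] = cls
        table = m.median_by_class(rows, truth).set_index(["class", "label"])
        for cls in classes:
            for lab in labels:
                pool = sorted(r.r2 for r in rows
                              if truth[r.gene_id] == cls and r.label == lab)
                mid = len(pool) // 2
                expected = (pool[mid] if len(pool) % 2
                            else 0.5 * (pool[mid - 1] + pool[mid]))
                assert table.loc[(cls, lab), "median"] == pytest.approx(expected)
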