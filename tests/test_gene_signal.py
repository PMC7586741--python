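"""Gene-level calls, FPKB arithmetic, fold calls, set algebra, paired t."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from crunmark.fragments import FragmentSet
from crunmark.gene_signal import (
    GeneSignal,
    assign_enriched_genes,
    extend_gene_regions,
    intersection_counts,
    paired_t_signal,
    pairwise_fold_calls,
    quantify_fpkb,
    set_difference_marked,
)


def _regions(rows):
    return pd.DataFrame(
        rows, columns=["gene_id", "contig", "start_ext", "end_ext", "length_ext"]
    )


def _peaks(rows):
    return pd.DataFrame(rows, columns=["contig", "start", "end"])


class TestAssignEnriched:
    def test_abutting_peak_not_enriched(self):
        regions = _regions([("g1", "c", 1000, 4000, 3000)])
        peaks = _peaks([("c", 4000, 4500)])
        assert assign_enriched_genes(peaks, regions) == set()

    def test_one_bp_overlap_enriched(self):
        regions = _regions([("g1", "c", 1000, 4000, 3000)])
        peaks = _peaks([("c", 3999, 4500)])
        assert assign_enriched_genes(peaks, regions) == {"g1"}

    def test_matches_allpairs_oracle(self):
        rng = np.random.default_rng(0)
        regions = _regions(
            [
                (f"g{i}", f"c{rng.integers(3)}", s, s + 3000, 3000)
                for i, s in enumerate(rng.integers(0, 50_000, 200))
            ]
        )
        peaks = _peaks(
            [
                (f"c{rng.integers(3)}", s, s + rng.integers(500, 3000))
                for s in rng.integers(0, 50_000, 40)
            ]
        )
        got = assign_enriched_genes(peaks, regions)
        oracle = {
            r.gene_id
            for r in regions.itertuples(index=False)
            for p in peaks.itertuples(index=False)
            if r.contig == p.contig and p.start < r.end_ext and p.end > r.start_ext
        }
        assert got == oracle


class TestFPKB:
    def test_closed_form(self):
        # 30 fragments over a 3000 bp extended region, N = 1e7 -> 1000 FPKB
        frags = pd.DataFrame(
            {"contig": ["c"] * 30, "start": range(1000, 1300, 10), "end": range(1100, 1400, 10)}
        )
        fs = FragmentSet("s", frags)
        regions = _regions([("g1", "c", 500, 3500, 3000)])
        k = quantify_fpkb(fs, regions)
        manual = 30 / (3000 / 1000) / (30 / 1e9)
        assert k["g1"] == pytest.approx(manual)
        # closed-form with N = 1e7 via direct formula
        assert 30 / 3 / (1e7 / 1e9) == pytest.approx(1000.0)

    def test_zero_overlap_zero_fpkb(self):
        fs = FragmentSet(
            "s", pd.DataFrame({"contig": ["c"], "start": [0], "end": [100]})
        )
        regions = _regions([("g1", "c", 5000, 8000, 3000)])
        assert quantify_fpkb(fs, regions)["g1"] == 0.0

    def test_empty_fragment_set_warns(self):
        fs = FragmentSet("s", pd.DataFrame(columns=["contig", "start", "end"]))
        regions = _regions([("g1", "c", 0, 3000, 3000)])
        with pytest.warns(UserWarning):
            vals = quantify_fpkb(fs, regions)
        assert (vals == 0).all()

    def test_matches_bruteforce_recomputation(self, toy_genome, toy_annotation):
        rng = np.random.default_rng(1)
        ids = [c for c, _ in toy_genome.contigs]
        lens = np.array([L for _, L in toy_genome.contigs])
        ci = rng.integers(0, len(ids), 3000)
        starts = (rng.random(3000) * (lens[ci] - 100)).astype(int)
        fs = FragmentSet(
            "s",
            pd.DataFrame(
                {
                    "contig": np.array(ids)[ci],
                    "start": starts,
                    "end": np.minimum(starts + rng.integers(50, 700, 3000), lens[ci]),
                }
            ),
        )
        regions = extend_gene_regions(toy_annotation, toy_genome)
        got = quantify_fpkb(fs, regions)
        for row in regions.itertuples(index=False):
            block = fs.fragments[fs.fragments["contig"] == row.contig]
            k = int(((block["start"] < row.end_ext) & (block["end"] > row.start_ext)).sum())
            expected = k / (row.length_ext / 1000) / (3000 / 1e9)
            assert got[row.gene_id] == pytest.approx(expected, rel=1e-9)

    def test_scale_invariance(self):
        # doubling both counts and N leaves FPKB unchanged
        frags = pd.DataFrame(
            {"contig": ["c"] * 10, "start": range(0, 1000, 100), "end": range(50, 1050, 100)}
        )
        regions = _regions([("g1", "c", 0, 2000, 2000)])
        single = quantify_fpkb(FragmentSet("s", frags), regions)
        double = quantify_fpkb(
            FragmentSet("s", pd.concat([frags, frags], ignore_index=True)), regions
        )
        assert single["g1"] == pytest.approx(double["g1"])


def _sig(sample, fpkb: dict, enriched=None, total=10_000):
    enriched = enriched if enriched is not None else set(fpkb)
    table = pd.DataFrame(
        {"enriched": [g in enriched for g in fpkb], "fpkb": list(fpkb.values())},
        index=pd.Index(list(fpkb), name="gene_id"),
    )
    return GeneSignal(sample, table, total)


class TestFoldCalls:
    def test_ratio_exactly_two_is_gained(self):
        # (11 + 1) / (5 + 1) == 2 exactly: "twice or more" is inclusive
        res = pairwise_fold_calls(
            _sig("a", {"g": 5.0}), _sig("b", {"g": 11.0}), pseudo=1.0
        )
        assert res.gained == {"g"}

    def test_ratio_below_two_not_gained(self):
        res = pairwise_fold_calls(
            _sig("a", {"g": 5.1}), _sig("b", {"g": 10.0}), pseudo=1e-6
        )
        assert res.gained == set()

    def test_pseudocount_makes_zero_finite(self):
        res = pairwise_fold_calls(
            _sig("a", {"g": 0.0}), _sig("b", {"g": 10.0}), pseudo=0.1
        )
        assert res.gained == {"g"}
        assert res.table.loc["g", "ratio_b_over_a"] == pytest.approx(10.1 / 0.1)

    def test_gained_lost_disjoint(self):
        rng = np.random.default_rng(2)
        genes = {f"g{i}": float(v) for i, v in enumerate(rng.gamma(2, 50, 200))}
        other = {g: float(v) for g, v in zip(genes, rng.gamma(2, 50, 200))}
        res = pairwise_fold_calls(_sig("a", genes), _sig("b", other))
        assert not (res.gained & res.lost)


class TestSetAlgebra:
    def test_identical_and_disjoint(self):
        a = {"x", "y"}
        assert set_difference_marked(a, set(a)) == (set(), set(), a)
        only_a, only_b, both = set_difference_marked({"x"}, {"y"})
        assert (only_a, only_b, both) == ({"x"}, {"y"}, set())

    def test_counts_match_enumeration(self):
        rng = np.random.default_rng(3)
        universe = [f"g{i}" for i in range(500)]
        a = {g for g in universe if rng.random() < 0.4}
        b = {g for g in universe if rng.random() < 0.4}
        a_only, b_only, both = set_difference_marked(a, b)
        for g in universe:
            assert (g in a_only) == (g in a and g not in b)
            assert (g in b_only) == (g in b and g not in a)
            assert (g in both) == (g in a and g in b)


class TestIntersectionCounts:
    def test_identical_sets_single_core_cell(self):
        s = {f"g{i}" for i in range(10)}
        res = intersection_counts({f"t{j}": set(s) for j in range(5)})
        assert res.cells == {tuple(sorted(f"t{j}" for j in range(5))): 10}
        assert res.core_size == 10

    def test_disjoint_sets_two_singleton_cells(self):
        res = intersection_counts({"a": {"x"}, "b": {"y"}})
        assert res.cells == {("a",): 1, ("b",): 1}

    def test_matches_bitmask_oracle(self):
        rng = np.random.default_rng(4)
        universe = [f"g{i}" for i in range(1000)]
        sets = {
            name: {g for g in universe if rng.random() < p}
            for name, p in zip("abcde", [0.3, 0.5, 0.2, 0.4, 0.1])
        }
        res = intersection_counts(sets)
        # brute-force 2^5 membership enumeration
        names = sorted(sets)
        oracle: dict[tuple, int] = {}
        for g in set().union(*sets.values()):
            key = tuple(n for n in names if g in sets[n])
            oracle[key] = oracle.get(key, 0) + 1
        assert res.cells == oracle
        assert sum(res.cells.values()) == res.union_size


class TestPairedT:
    def test_identical_vectors_convention(self):
        res = paired_t_signal([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert (res.t, res.p) == (0.0, 1.0)

    def test_matches_hand_formula(self):
        a = np.zeros(4)
        b = np.array([1.0, 2.0, 3.0, 4.0])
        res = paired_t_signal(a, b)
        d = b - a
        t_oracle = d.mean() / (d.std(ddof=1) / math.sqrt(len(d)))
        assert res.t == pytest.approx(t_oracle, abs=1e-12)

    def test_constant_shift_degenerate(self):
        a = np.array([1.0, 2.0, 3.0])
        res = paired_t_signal(a, a + 5.0)
        assert res.degenerate
        assert res.p == 0.0 and math.isinf(res.t)

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError):
            paired_t_signal([1.0], [2.0])
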