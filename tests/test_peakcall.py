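"""Binning, per-bin binomial testing, BH adjustment, peak merging."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.special import gammaln

from crunmark.fragments import FragmentSet
from crunmark.peakcall import (
    adjust_bh,
    bin_genome,
    binomial_test_bins,
    call_peaks,
    call_peaks_from_fragments,
    count_per_bin,
)
from crunmark.synthetic_data import ToyGenome


def binom_tail_oracle(k, n, p):
    """Direct log-space summation of P(X >= k) — independent of scipy.stats."""
    if k <= 0:
        return 1.0
    js = np.arange(k, n + 1)
    logs = (
        gammaln(n + 1)
        - gammaln(js + 1)
        - gammaln(n - js + 1)
        + js * np.log(p)
        + (n - js) * np.log1p(-p)
    )
    m = logs.max()
    return float(np.exp(m) * np.exp(logs - m).sum())


class TestBinGrid:
    @pytest.mark.parametrize(
        "length,expected",
        [
            (1250, [(0, 500), (500, 1000), (1000, 1250)]),
            (500, [(0, 500)]),
            (499, [(0, 499)]),
        ],
    )
    def test_tiling_examples(self, length, expected):
        g = ToyGenome(contigs=(("c", length),))
        grid = bin_genome(g)
        got = list(zip(grid.bins["start"], grid.bins["end"]))
        assert got == expected

    def test_widths_sum_to_contig_lengths(self, toy_genome):
        grid = bin_genome(toy_genome, 500)
        per_contig = (
            pd.DataFrame({"contig": grid.bins["contig"], "w": grid.widths})
            .groupby("contig")["w"]
            .sum()
        )
        for cid, length in toy_genome.contigs:
            assert per_contig[cid] == length


class TestCounting:
    def test_boundary_spanning_fragment_counts_twice(self):
        g = ToyGenome(contigs=(("c", 1000),))
        grid = bin_genome(g)
        fs = FragmentSet(
            "s", pd.DataFrame({"contig": ["c"], "start": [490], "end": [510]})
        )
        counts = count_per_bin(fs, grid)
        assert counts.tolist() == [1, 1]

    def test_no_fragments_all_zero(self, toy_genome):
        grid = bin_genome(toy_genome)
        fs = FragmentSet("s", pd.DataFrame(columns=["contig", "start", "end"]))
        assert count_per_bin(fs, grid).sum() == 0

    def test_unknown_contig_warned_and_skipped(self):
        g = ToyGenome(contigs=(("c", 1000),))
        grid = bin_genome(g)
        fs = FragmentSet(
            "s",
            pd.DataFrame({"contig": ["c", "zzz"], "start": [0, 0], "end": [10, 10]}),
        )
        with pytest.warns(UserWarning, match="skipped"):
            counts = count_per_bin(fs, grid)
        assert counts.sum() == 1

    def test_matches_bruteforce_overlap_oracle(self):
        rng = np.random.default_rng(2)
        g = ToyGenome(contigs=(("c", 100_000),))
        grid = bin_genome(g)
        starts = rng.integers(0, 99_000, 1000)
        ends = starts + rng.integers(50, 900, 1000)
        ends = np.minimum(ends, 100_000)
        fs = FragmentSet("s", pd.DataFrame({"contig": "c", "start": starts, "end": ends}))
        counts = count_per_bin(fs, grid)
        oracle = np.array(
            [
                int(((starts < be) & (ends > bs)).sum())
                for bs, be in zip(grid.bins["start"], grid.bins["end"])
            ]
        )
        np.testing.assert_array_equal(counts, oracle)


class TestBinomialTest:
    def test_zero_count_gives_one(self):
        p = binomial_test_bins(np.array([0]), 100, np.array([500]), 10_000)
        assert p[0] == 1.0

    def test_all_successes_single_term(self):
        n, p0 = 7, 500 / 10_000
        p = binomial_test_bins(np.array([n]), n, np.array([500]), 10_000)
        assert p[0] == pytest.approx(p0**n, rel=1e-12)

    def test_matches_direct_summation(self):
        n, k = 10_000, 20
        p = binomial_test_bins(np.array([k]), n, np.array([500]), 1_000_000)
        assert p[0] == pytest.approx(binom_tail_oracle(k, n, 5e-4), rel=1e-9)

    def test_no_fragments_warns_all_one(self):
        with pytest.warns(UserWarning, match="no fragments"):
            p = binomial_test_bins(np.array([0, 0]), 0, np.array([500, 500]), 10_000)
        assert (p == 1).all()


class TestBH:
    def test_all_equal(self):
        q = adjust_bh([0.2] * 5)
        np.testing.assert_allclose(q, 0.2)

    def test_stepup_arithmetic(self):
        np.testing.assert_allclose(adjust_bh([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])

    def test_matches_reference_implementation(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(3)
        p = rng.uniform(size=1000)
        q = adjust_bh(p)
        ref = multipletests(p, method="fdr_bh")[1]
        np.testing.assert_allclose(q, ref, atol=1e-12)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.lists(st.floats(min_value=0, max_value=1), min_size=1, max_size=200))
    def test_bounds_and_order_preservation(self, p):
        q = adjust_bh(p)
        assert ((q >= np.asarray(p) - 1e-15) & (q <= 1.0)).all()
        # ordering by p implies ordering by q
        order = np.argsort(p, kind="mergesort")
        assert (np.diff(q[order]) >= -1e-15).all()


class TestCallPeaks:
    @staticmethod
    def _bins(rows):
        return pd.DataFrame(rows, columns=["contig", "start", "end", "q"])

    def test_adjacent_bins_merge(self):
        bins = self._bins([("c", 0, 500, 1e-30), ("c", 500, 1000, 1e-28)])
        peaks = call_peaks(bins)
        assert len(peaks) == 1
        assert (peaks.iloc[0]["start"], peaks.iloc[0]["end"]) == (0, 1000)
        assert peaks.iloc[0]["min_q"] == 1e-30

    def test_gap_of_one_bin_splits(self):
        bins = self._bins(
            [("c", 0, 500, 1e-30), ("c", 500, 1000, 0.5), ("c", 1000, 1500, 1e-30)]
        )
        peaks = call_peaks(bins)
        assert len(peaks) == 2

    def test_merge_idempotent(self):
        rng = np.random.default_rng(4)
        qs = np.where(rng.random(50) < 0.3, 1e-30, 0.9)
        bins = self._bins(
            [("c", 500 * i, 500 * (i + 1), q) for i, q in enumerate(qs)]
        )
        peaks = call_peaks(bins)
        again = call_peaks(
            peaks.rename(columns={"min_q": "q"})[["contig", "start", "end", "q"]]
        )
        pd.testing.assert_frame_equal(
            peaks[["contig", "start", "end"]], again[["contig", "start", "end"]]
        )

    def test_threshold_monotonicity(self):
        rng = np.random.default_rng(5)
        qs = 10.0 ** rng.uniform(-40, 0, 200)
        bins = self._bins([("c", 500 * i, 500 * (i + 1), q) for i, q in enumerate(qs)])
        previous = -1
        for thr in (1e-30, 1e-25, 1e-10, 0.05, 1.0):
            n_sig = int((qs <= thr).sum())
            assert n_sig >= previous
            previous = n_sig

    def test_planted_loci_recovered_exactly(self):
        from crunmark.evaluate import peak_recovery_run

        rec = peak_recovery_run(seed=0, enrichment_fold=10.0)
        assert rec.exact


def test_full_call_matches_bruteforce_on_small_instance(toy_genome):
    """End-to-end bins: counts exact, p-values to 1e-9 vs direct summation."""
    rng = np.random.default_rng(6)
    ids = [c for c, _ in toy_genome.contigs]
    lens = np.array([L for _, L in toy_genome.contigs])
    ci = rng.integers(0, len(ids), 2000)
    starts = (rng.random(2000) * (lens[ci] - 200)).astype(int)
    fs = FragmentSet(
        "s",
        pd.DataFrame(
            {
                "contig": np.array(ids)[ci],
                "start": starts,
                "end": np.minimum(starts + 170, lens[ci]),
            }
        ).sort_values(["contig", "start"]).reset_index(drop=True),
    )
    bins, _ = call_peaks_from_fragments(fs, toy_genome)
    g = toy_genome.total_length
    sub = bins.sample(40, random_state=0)
    for row in sub.itertuples(index=False):
        block = fs.fragments[fs.fragments["contig"] == row.contig]
        k = int(((block["start"] < row.end) & (block["end"] > row.start)).sum())
        assert k == row.k
        expected = binom_tail_oracle(k, 2000, (row.end - row.start) / g)
        assert row.p == pytest.approx(expected, rel=1e-9)
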