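"""Binned binomial peak calling for sparse CUT&RUN coverage.

The genome is tiled with fixed-width bins (default 500 bp; the terminal
bin of each contig is truncated).  For each bin the number of fragments
overlapping it by at least 1 bp is counted and tested against a uniform
null: with N total fragments and a bin of width w on an effective genome
of length G, the count is Binomial(N, w/G) under the null, and the
one-sided upper-tail probability P(X >= k) is the bin's p-value.  P-values
are Benjamini-Hochberg adjusted genome-wide (all bins, one family,
zero-count bins included) and bins at FDR <= 1e-25 are kept; surviving
bins closer than 100 bp are merged transitively into peaks.

The uniform null is the simplest model consistent with per-bin binomial
testing on a genome without a control track; the effective genome length
defaults to the sum of contig lengths and can be overridden (e.g. for a
mappability-corrected length).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

DEFAULT_BIN_SIZE = 500
DEFAULT_FDR = 1e-25
DEFAULT_MERGE_GAP = 100

__all__ = [
    "BinGrid",
    "bin_genome",
    "count_per_bin",
    "binomial_test_bins",
    "adjust_bh",
    "call_peaks",
    "merge_intervals",
    "call_peaks_from_fragments",
]


@dataclass(frozen=True)
class BinGrid:
    """Fixed-width bins tiling every contig exactly (no gaps, no overlaps)."""

    bins: pd.DataFrame  # columns: contig, start, end
    bin_size: int

    @property
    def widths(self) -> np.ndarray:
        return (self.bins["end"] - self.bins["start"]).to_numpy()

    def __len__(self) -> int:
        return len(self.bins)


def bin_genome(genome, bin_size: int = DEFAULT_BIN_SIZE) -> BinGrid:
    """Tile each contig with ceil(L / bin_size) bins, last bin truncated."""
    if bin_size < 1:
        raise ValueError("bin_size must be >= 1")
    contigs, starts, ends = [], [], []
    for cid, length in genome.contigs:
        edges = np.arange(0, length + bin_size, bin_size)
        edges[-1] = min(edges[-1], length)
        if edges[-1] == edges[-2]:
            edges = edges[:-1]
        contigs.extend([cid] * (len(edges) - 1))
        starts.append(edges[:-1])
        ends.append(edges[1:])
    df = pd.DataFrame(
        {
            "contig": contigs,
            "start": np.concatenate(starts).astype(np.int64),
            "end": np.concatenate(ends).astype(np.int64),
        }
    )
    return BinGrid(bins=df, bin_size=bin_size)


def count_per_bin(fs, grid: BinGrid) -> np.ndarray:
    """Count fragments overlapping each bin by >= 1 bp.

    A fragment spanning a bin boundary is counted in every bin it
    overlaps, so bin counts may sum to more than the fragment total.
    """
    bins = grid.bins
    counts = np.zeros(len(bins), dtype=np.int64)
    # first row index of each contig's bin block
    offsets: dict[str, tuple[int, int]] = {}
    for cid, block in bins.groupby("contig", sort=False):
        offsets[cid] = (int(block.index[0]), len(block))

    frags = fs.fragments
    unknown = ~frags["contig"].isin(offsets.keys())
    if unknown.any():
        warnings.warn(
            f"{int(unknown.sum())} fragments on contigs absent from the grid "
            "were skipped",
            stacklevel=2,
        )
        frags = frags.loc[~unknown]

    bs = grid.bin_size
    for cid, block in frags.groupby("contig", sort=False):
        off, nb = offsets[cid]
        first = (block["start"].to_numpy() // bs).clip(0, nb - 1)
        last = ((block["end"].to_numpy() - 1) // bs).clip(0, nb - 1)
        # difference array over the bin range [first, last]
        diff = np.zeros(nb + 1, dtype=np.int64)
        np.add.at(diff, first, 1)
        np.add.at(diff, last + 1, -1)
        counts[off : off + nb] += np.cumsum(diff[:-1])
    return counts


def binomial_test_bins(
    counts: np.ndarray,
    n_total: int,
    widths: np.ndarray,
    effective_genome_length: int,
) -> np.ndarray:
    """Upper-tail exact binomial p-value per bin under the uniform null.

    p0 = bin_width / effective_genome_length; p = P(X >= k | N, p0).
    Bins with zero count get p = 1.  If ``n_total`` is 0 every p is 1.
    """
    counts = np.asarray(counts)
    widths = np.asarray(widths)
    if effective_genome_length < widths.max(initial=1):
        raise ValueError("effective_genome_length must be >= the largest bin width")
    if n_total == 0:
        warnings.warn("no fragments: all bin p-values set to 1", stacklevel=2)
        return np.ones_like(counts, dtype=float)
    p0 = widths / effective_genome_length
    # sf(k-1) = P(X >= k); exact at k=0 (sf(-1) = 1)
    return stats.binom.sf(counts - 1, n_total, p0)


def adjust_bh(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values).

    q_(i) = min over j >= i of p_(j) * m / j, in sorted order, capped at 1;
    output order matches input order.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise ValueError("p_values must be one-dimensional")
    if len(p) == 0:
        return p.copy()
    if (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def merge_intervals(df: pd.DataFrame, merge_gap: int) -> list[tuple[str, int, int, int, float]]:
    """Transitively merge intervals on a contig whose gap is < merge_gap.

    ``df`` columns: contig, start, end, and optionally q (per-seed minimum
    q carried into ``min_q``).  Returns (contig, start, end, n_seeds, min_q).
    """
    merged: list[tuple[str, int, int, int, float]] = []
    has_q = "q" in df.columns
    for cid, block in df.groupby("contig", sort=False):
        block = block.sort_values("start", kind="mergesort")
        cur = None
        for row in block.itertuples(index=False):
            q = float(row.q) if has_q else float("nan")
            if cur is None:
                cur = [cid, row.start, row.end, 1, q]
            elif row.start - cur[2] < merge_gap:
                cur[2] = max(cur[2], row.end)
                cur[3] += 1
                cur[4] = min(cur[4], q) if has_q else cur[4]
            else:
                merged.append(tuple(cur))
                cur = [cid, row.start, row.end, 1, q]
        if cur is not None:
            merged.append(tuple(cur))
    return merged


def call_peaks(
    bins: pd.DataFrame,
    fdr_threshold: float = DEFAULT_FDR,
    merge_gap: int = DEFAULT_MERGE_GAP,
) -> pd.DataFrame:
    """Select bins at q <= fdr_threshold and merge gaps strictly < merge_gap.

    ``bins`` columns: contig, start, end, q.  Returns a peak table with
    columns contig, start, end, n_bins, min_q, sorted by (contig, start).
    """
    if "q" not in bins.columns:
        raise ValueError("bins table must carry a 'q' column")
    sig = bins.loc[bins["q"] <= fdr_threshold, ["contig", "start", "end", "q"]]
    merged = merge_intervals(sig, merge_gap)
    peaks = pd.DataFrame(
        merged, columns=["contig", "start", "end", "n_bins", "min_q"]
    )
    return peaks.sort_values(["contig", "start"], kind="mergesort").reset_index(
        drop=True
    )


def call_peaks_from_fragments(
    fs,
    genome,
    bin_size: int = DEFAULT_BIN_SIZE,
    fdr_threshold: float = DEFAULT_FDR,
    merge_gap: int = DEFAULT_MERGE_GAP,
    effective_genome_length: int | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Full per-sample peak call: bin, count, test, adjust, select, merge.

    Returns ``(bin_table, peak_table)``; the bin table has columns contig,
    start, end, k, p, q.
    """
    grid = bin_genome(genome, bin_size)
    counts = count_per_bin(fs, grid)
    egl = effective_genome_length or genome.total_length
    p = binomial_test_bins(counts, fs.total_count, grid.widths, egl)
    q = adjust_bh(p)
    bins = grid.bins.copy()
    bins["k"] = counts
    bins["p"] = p
    bins["q"] = q
    peaks = call_peaks(bins, fdr_threshold, merge_gap)
    logger.info(
        "%s: %d significant bins -> %d peaks (FDR <= %g)",
        getattr(fs, "sample_id", "?"),
        int((q <= fdr_threshold).sum()),
        len(peaks),
        fdr_threshold,
    )
    return bins, peaks
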