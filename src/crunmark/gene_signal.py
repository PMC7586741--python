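"""Gene-level H3K27me3 calls and intensities.

A gene is called H3K27me3-enriched when its body, extended by 500 bp
upstream and downstream (clipped to contig bounds), overlaps at least one
called peak by >= 1 bp.  Signal intensity per gene is FPKB — fragments per
kilobase of the extended region per billion mapped fragments:

    fpkb = k / (length_ext / 1000) / (N / 1e9)

where k counts fragments overlapping the extended region and N is the
post-filter fragment total of the sample.  A fragment may count toward
several overlapping gene regions.

The module also provides pairwise >= 2-fold comparisons between samples,
set differences of marked-gene sets, exclusive (UpSet-style) intersection
counts over many samples, and a paired t-test on shared-gene intensities.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

DEFAULT_EXTENSION = 500

__all__ = [
    "GeneSignal",
    "extend_gene_regions",
    "assign_enriched_genes",
    "quantify_fpkb",
    "build_gene_signal",
    "pairwise_fold_calls",
    "FoldCallResult",
    "set_difference_marked",
    "intersection_counts",
    "IntersectionResult",
    "paired_t_signal",
    "PairedTResult",
]


def extend_gene_regions(
    annotation, genome, extension: int = DEFAULT_EXTENSION
) -> pd.DataFrame:
    """Gene bodies extended ``extension`` bp both ways, clipped to contigs.

    Returns columns gene_id, contig, start_ext, end_ext, length_ext.
    """
    lengths = genome.lengths
    g = annotation.genes
    start_ext = (g["start"] - extension).clip(lower=0)
    end_ext = np.minimum(
        g["end"] + extension, g["contig"].map(lengths).to_numpy()
    )
    return pd.DataFrame(
        {
            "gene_id": g["gene_id"],
            "contig": g["contig"],
            "start_ext": start_ext.astype(np.int64),
            "end_ext": end_ext.astype(np.int64),
            "length_ext": (end_ext - start_ext).astype(np.int64),
        }
    ).reset_index(drop=True)


def assign_enriched_genes(peaks: pd.DataFrame, regions: pd.DataFrame) -> set[str]:
    """Genes whose extended region overlaps any peak by >= 1 bp (half-open)."""
    enriched: set[str] = set()
    if len(peaks) == 0 or len(regions) == 0:
        return enriched
    for cid, pk in peaks.groupby("contig", sort=False):
        reg = regions.loc[regions["contig"] == cid]
        if len(reg) == 0:
            continue
        ps = pk["start"].to_numpy()
        pe = pk["end"].to_numpy()
        for row in reg.itertuples(index=False):
            if ((ps < row.end_ext) & (pe > row.start_ext)).any():
                enriched.add(row.gene_id)
    return enriched


def _count_overlaps(fs, regions: pd.DataFrame) -> np.ndarray:
    """Fragments overlapping each region by >= 1 bp, via sorted endpoints."""
    k = np.zeros(len(regions), dtype=np.int64)
    frag_by_contig = {
        cid: (
            np.sort(block["start"].to_numpy()),
            np.sort(block["end"].to_numpy()),
        )
        for cid, block in fs.fragments.groupby("contig", sort=False)
    }
    for i, row in enumerate(regions.itertuples(index=False)):
        entry = frag_by_contig.get(row.contig)
        if entry is None:
            continue
        starts, ends = entry
        n = len(starts)
        # overlap iff start < end_ext and end > start_ext
        n_start_ok = np.searchsorted(starts, row.end_ext, side="left")
        n_end_bad = np.searchsorted(ends, row.start_ext, side="right")
        k[i] = n_start_ok - n_end_bad if n else 0
    return k


def quantify_fpkb(fs, regions: pd.DataFrame) -> pd.Series:
    """FPKB per extended gene region.

    fpkb = k / (length_ext/1000) / (N/1e9).  With N = 0 all values are 0
    and a warning is emitted.
    """
    k = _count_overlaps(fs, regions)
    n = fs.total_count
    if n == 0:
        warnings.warn("empty fragment set: all FPKB values are 0", stacklevel=2)
        vals = np.zeros(len(regions))
    else:
        vals = k / (regions["length_ext"].to_numpy() / 1000.0) / (n / 1e9)
    return pd.Series(vals, index=pd.Index(regions["gene_id"], name="gene_id"))


@dataclass
class GeneSignal:
    """Per-gene enrichment flag and FPKB intensity for one sample."""

    sample_id: str
    table: pd.DataFrame  # index gene_id; columns: enriched (bool), fpkb (float)
    total_fragments: int

    @property
    def enriched_genes(self) -> set[str]:
        return set(self.table.index[self.table["enriched"]])

    @property
    def fpkb(self) -> pd.Series:
        return self.table["fpkb"]


def build_gene_signal(fs, peaks: pd.DataFrame, regions: pd.DataFrame) -> GeneSignal:
    """Combine peak-overlap calls and FPKB quantification for one sample."""
    enriched = assign_enriched_genes(peaks, regions)
    fpkb = quantify_fpkb(fs, regions)
    table = pd.DataFrame(
        {
            "enriched": [g in enriched for g in fpkb.index],
            "fpkb": fpkb.to_numpy(),
        },
        index=fpkb.index,
    )
    return GeneSignal(
        sample_id=fs.sample_id, table=table, total_fragments=fs.total_count
    )


@dataclass
class FoldCallResult:
    gained: set[str]  # higher in B by >= fold
    lost: set[str]  # higher in A by >= fold
    table: pd.DataFrame  # gene_id index; fpkb_a, fpkb_b, ratio_b_over_a


def pairwise_fold_calls(
    sig_a: GeneSignal,
    sig_b: GeneSignal,
    fold: float = 2.0,
    pseudo: float | None = None,
    universe: set[str] | None = None,
) -> FoldCallResult:
    """Genes whose intensity differs by ``fold`` or more between samples.

    gained: (fpkb_b + pseudo) / (fpkb_a + pseudo) >= fold; lost symmetric.
    The default pseudocount is the FPKB of a single fragment on a 1 kb
    region given each sample's own fragment total (1e9 / N), which keeps
    ratios finite and unit-consistent; a scalar ``pseudo`` applies the
    same value to both samples.  The comparison universe defaults to the
    union of the two samples' enriched-gene sets.
    """
    if fold <= 1:
        raise ValueError("fold must be > 1")
    if universe is None:
        universe = sig_a.enriched_genes | sig_b.enriched_genes
    genes = sorted(universe)
    a = sig_a.fpkb.reindex(genes).fillna(0.0).to_numpy()
    b = sig_b.fpkb.reindex(genes).fillna(0.0).to_numpy()
    if pseudo is None:
        pa = 1e9 / sig_a.total_fragments if sig_a.total_fragments else 1.0
        pb = 1e9 / sig_b.total_fragments if sig_b.total_fragments else 1.0
    else:
        if pseudo <= 0:
            raise ValueError("pseudo must be > 0")
        pa = pb = pseudo
    ratio = (b + pb) / (a + pa)
    table = pd.DataFrame(
        {"fpkb_a": a, "fpkb_b": b, "ratio_b_over_a": ratio},
        index=pd.Index(genes, name="gene_id"),
    )
    gained = set(table.index[ratio >= fold])
    lost = set(table.index[ratio <= 1.0 / fold])
    return FoldCallResult(gained=gained, lost=lost, table=table)


def set_difference_marked(
    set_a: set[str], set_b: set[str]
) -> tuple[set[str], set[str], set[str]]:
    """(A only, B only, both) for two enriched-gene sets."""
    return set_a - set_b, set_b - set_a, set_a & set_b


@dataclass
class IntersectionResult:
    """Exclusive intersection cells over named gene sets (UpSet-style)."""

    cells: dict[tuple[str, ...], int]  # sorted member-set names -> count
    set_sizes: dict[str, int]
    union_size: int
    core_size: int  # genes in every set

    def as_records(self) -> pd.DataFrame:
        rows = [
            ("&".join(names), len(names), count)
            for names, count in sorted(
                self.cells.items(), key=lambda kv: (-len(kv[0]), kv[0])
            )
        ]
        return pd.DataFrame(rows, columns=["cell", "degree", "count"])


def intersection_counts(sets: dict[str, set[str]]) -> IntersectionResult:
    """Assign each gene of the union to its exclusive membership cell."""
    if len(sets) < 2:
        raise ValueError("need at least 2 sets")
    names = sorted(sets)
    union: set[str] = set()
    for s in sets.values():
        union |= s
    cells: dict[tuple[str, ...], int] = {}
    for gene in union:
        key = tuple(n for n in names if gene in sets[n])
        cells[key] = cells.get(key, 0) + 1
    all_key = tuple(names)
    return IntersectionResult(
        cells=cells,
        set_sizes={n: len(sets[n]) for n in names},
        union_size=len(union),
        core_size=cells.get(all_key, 0),
    )


@dataclass
class PairedTResult:
    t: float
    p: float
    n: int
    degenerate: bool  # constant nonzero difference: infinite t, p -> 0


def paired_t_signal(values_a, values_b) -> PairedTResult:
    """Paired two-sided Student's t-test on per-gene intensity differences.

    All-zero differences give t = 0, p = 1 by convention; a constant
    nonzero difference (zero variance) is reported as the p -> 0 limit
    with a degeneracy flag.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired vectors must have equal length")
    n = len(a)
    if n < 2:
        raise ValueError("paired t-test needs at least 2 observations")
    d = b - a
    if np.all(d == 0):
        return PairedTResult(t=0.0, p=1.0, n=n, degenerate=False)
    sd = d.std(ddof=1)
    if sd == 0:
        t = math.inf if d.mean() > 0 else -math.inf
        return PairedTResult(t=t, p=0.0, n=n, degenerate=True)
    res = stats.ttest_rel(b, a)
    return PairedTResult(t=float(res.statistic), p=float(res.pvalue), n=n, degenerate=False)
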