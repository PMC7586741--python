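"""Ground-truth recovery experiments on synthetic studies.

These routines measure how well the peak caller and the gene-level calls
recover planted enrichment under stated simulation conditions, averaging
over independent seeds.  They power both the test suite and the
reproduction script.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .fragments import filter_by_length
from .gene_signal import assign_enriched_genes, extend_gene_regions
from .peakcall import call_peaks_from_fragments
from .synthetic_data import (
    GroundTruth,
    generate_annotation,
    generate_fragments,
    generate_toy_genome,
)

__all__ = ["PeakRecovery", "peak_recovery_run", "GeneRecovery", "gene_recovery_run"]


@dataclass
class PeakRecovery:
    n_peaks: int
    n_loci_recovered: int  # planted loci overlapped by >= 1 peak
    n_false_peaks: int  # peaks overlapping no planted locus
    exact: bool  # one peak per planted locus, none elsewhere


def _planted_windows(annotation, truth_genes, genome, extension=500):
    regions = extend_gene_regions(annotation, genome, extension)
    return regions.loc[regions["gene_id"].isin(truth_genes)]


def peak_recovery_run(
    seed: int,
    n_contigs: int = 50,
    mean_contig_len: int = 20_000,
    n_genes: int = 30,
    n_marked: int = 3,
    enrichment_fold: float = 10.0,
    background_rate: float = 0.01,
    fdr: float = 1e-25,
) -> PeakRecovery:
    """Plant ``n_marked`` enriched loci, call peaks, score recovery.

    Default conditions: ~1 Mbp genome over 50 contigs, background 0.01
    fragments/bp (so a 500 bp bin expects 5 background and ~50 enriched
    fragments at fold 10).
    """
    genome = generate_toy_genome(n_contigs, mean_contig_len, seed)
    annotation = generate_annotation(genome, n_genes, seed=seed)
    rng = np.random.default_rng(seed)
    marked = set(rng.choice(annotation.gene_ids, size=n_marked, replace=False))
    truth = GroundTruth(
        marked_genes={"s": marked},
        enrichment_fold=enrichment_fold,
        background_rate=background_rate,
    )
    n_bg = int(round(background_rate * genome.total_length))
    fs = generate_fragments(genome, annotation, truth, n_bg, seed=seed)["s"]
    fs = filter_by_length(fs)
    _, peaks = call_peaks_from_fragments(fs, genome, fdr_threshold=fdr)

    windows = _planted_windows(annotation, marked, genome)
    loci_hit = 0
    peak_hits = np.zeros(len(peaks), dtype=bool)
    for w in windows.itertuples(index=False):
        ov = (
            (peaks["contig"] == w.contig)
            & (peaks["start"] < w.end_ext)
            & (peaks["end"] > w.start_ext)
        ).to_numpy()
        if ov.any():
            loci_hit += 1
        peak_hits |= ov
    n_false = int((~peak_hits).sum())
    return PeakRecovery(
        n_peaks=len(peaks),
        n_loci_recovered=loci_hit,
        n_false_peaks=n_false,
        exact=(len(peaks) == n_marked and loci_hit == n_marked and n_false == 0),
    )


@dataclass
class GeneRecovery:
    sensitivity: float
    false_positive_rate: float
    n_marked: int
    n_unmarked: int


def gene_recovery_run(
    seed: int,
    n_contigs: int = 50,
    mean_contig_len: int = 40_000,
    n_genes: int = 100,
    n_marked: int = 20,
    enrichment_fold: float = 8.0,
    background_rate: float = 0.01,
    fdr: float = 1e-25,
) -> GeneRecovery:
    """Planted marked-gene recovery through peak calling + gene assignment."""
    genome = generate_toy_genome(n_contigs, mean_contig_len, seed)
    annotation = generate_annotation(genome, n_genes, seed=seed)
    rng = np.random.default_rng(seed)
    marked = set(rng.choice(annotation.gene_ids, size=n_marked, replace=False))
    truth = GroundTruth(
        marked_genes={"s": marked},
        enrichment_fold=enrichment_fold,
        background_rate=background_rate,
    )
    n_bg = int(round(background_rate * genome.total_length))
    fs = generate_fragments(genome, annotation, truth, n_bg, seed=seed)["s"]
    fs = filter_by_length(fs)
    _, peaks = call_peaks_from_fragments(fs, genome, fdr_threshold=fdr)
    regions = extend_gene_regions(annotation, genome)
    called = assign_enriched_genes(peaks, regions)
    unmarked = set(annotation.gene_ids) - marked
    tp = len(called & marked)
    fp = len(called & unmarked)
    return GeneRecovery(
        sensitivity=tp / len(marked),
        false_positive_rate=fp / len(unmarked),
        n_marked=len(marked),
        n_unmarked=len(unmarked),
    )
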