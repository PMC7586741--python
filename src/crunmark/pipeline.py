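"""End-to-end orchestration over synthetic or user-supplied inputs.

``simulate_study`` materializes a full toy study (genome, annotation,
fragments per sample, expression, functional maps) with ground truth;
``run_pipeline`` executes size filtering, peak calling, gene-level calls
and intensities, pairwise comparisons, entropy contrast, GO enrichment,
conservation contrast and motif-region extraction, writing plain-text
artifacts plus a JSON manifest of every parameter and input.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as cio
from ._rng import child_rng
from .config import PipelineConfig
from .enrichment import conservation_contrast, hypergeom_go
from .fragments import FragmentSet, filter_by_length
from .gene_signal import (
    build_gene_signal,
    extend_gene_regions,
    intersection_counts,
    paired_t_signal,
    pairwise_fold_calls,
    set_difference_marked,
)
from .motif_regions import (
    build_coverage,
    export_region_fasta,
    sample_matched_background,
    select_signal_regions,
)
from .peakcall import call_peaks_from_fragments
from .specificity import entropy_contrast, entropy_per_gene
from .synthetic_data import (
    GroundTruth,
    generate_annotation,
    generate_expression,
    generate_fragments,
    generate_functional_maps,
    generate_toy_genome,
)

logger = logging.getLogger(__name__)

__all__ = ["StudyData", "simulate_study", "run_pipeline", "write_study"]


@dataclass
class StudyData:
    genome: object
    annotation: object
    truth: GroundTruth
    fragment_sets: dict[str, FragmentSet]
    expression: pd.DataFrame
    maps: object


def simulate_study(config: PipelineConfig, with_sequences: bool = True) -> StudyData:
    """Generate a complete toy study from the simulation config."""
    sim = config.simulation
    seed = config.seed
    genome = generate_toy_genome(
        sim.n_contigs, sim.mean_contig_len, seed, with_sequences=with_sequences
    )
    annotation = generate_annotation(
        genome, sim.n_genes, gene_len=sim.gene_len, te_fraction=sim.te_fraction,
        seed=seed,
    )
    gene_ids = annotation.gene_ids
    rng = child_rng(seed, "truth")
    marked = {
        s: set(
            rng.choice(gene_ids, size=min(sim.marked_per_sample, len(gene_ids)),
                       replace=False)
        )
        for s in sim.samples
    }
    shuffled = list(rng.permutation(gene_ids))
    truth = GroundTruth(
        marked_genes=marked,
        enrichment_fold=sim.enrichment_fold,
        background_rate=sim.background_rate,
        specific_genes=set(shuffled[: sim.n_specific]),
        broad_genes=set(shuffled[sim.n_specific : sim.n_specific + sim.n_broad]),
        planted_go_terms={
            f"GO:{9000000 + i:07d}" for i in range(1, sim.n_planted_terms + 1)
        },
    )
    n_fragments = int(round(sim.background_rate * genome.total_length))
    fragment_sets = generate_fragments(
        genome, annotation, truth, n_fragments,
        frag_len_mean=sim.frag_len_mean, long_frac=sim.long_frac, seed=seed,
    )
    expression = generate_expression(annotation, sim.n_tissues, truth, seed=seed)
    maps = generate_functional_maps(
        annotation, sim.n_go_terms, truth, seed=seed,
        orphan_fraction=sim.orphan_fraction, planted_odds=sim.planted_odds,
    )
    return StudyData(
        genome=genome, annotation=annotation, truth=truth,
        fragment_sets=fragment_sets, expression=expression, maps=maps,
    )


def write_study(study: StudyData, outdir) -> dict[str, str]:
    """Write every study input as a text artifact; returns path map."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, str] = {}

    def _reg(key: str, name: str) -> Path:
        paths[key] = name
        return outdir / name

    if study.genome.sequences is not None:
        cio.write_genome_fasta(study.genome, _reg("genome_fasta", "genome.fa"))
    cio.write_contig_lengths(study.genome, _reg("contig_lengths", "contigs.tsv"))
    cio.write_gff3(study.annotation, _reg("annotation", "annotation.gff3"))
    for sample, fs in study.fragment_sets.items():
        cio.write_fragments_bed(fs, _reg(f"fragments_{sample}", f"{sample}.fragments.bed"))
    cio.write_expression_tsv(study.expression, _reg("expression", "expression.tsv"))
    cio.write_maps_tsv(
        study.maps, _reg("go_map", "go_map.tsv"), _reg("homology", "homology.tsv")
    )
    cio.write_truth_json(study.truth, _reg("truth", "truth.json"))
    return paths


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(
    config: PipelineConfig,
    outdir,
    study: StudyData | None = None,
) -> dict:
    """Run every analysis stage and write artifacts + manifest.

    When ``study`` is None a synthetic study is simulated from the config
    (the one-shot demo mode).  Returns the manifest dictionary.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if study is None:
        study = simulate_study(config)
    input_paths = write_study(study, outdir / "inputs")

    samples = sorted(study.fragment_sets)
    filtered: dict[str, FragmentSet] = {}
    signals = {}
    regions = extend_gene_regions(study.annotation, study.genome, config.extension)
    for sample in samples:
        fs = filter_by_length(study.fragment_sets[sample], config.max_fragment)
        filtered[sample] = fs
        bins, peaks = call_peaks_from_fragments(
            fs, study.genome,
            bin_size=config.bin_size, fdr_threshold=config.fdr,
            merge_gap=config.merge_gap,
            effective_genome_length=config.effective_genome_length,
        )
        bins.to_csv(outdir / f"{sample}.bins.tsv", sep="\t", index=False,
                    float_format="%.6g")
        cio.write_peaks_bed(peaks, outdir / f"{sample}.peaks.bed")
        sig = build_gene_signal(fs, peaks, regions)
        signals[sample] = sig
        sig.table.to_csv(outdir / f"{sample}.genes.tsv", sep="\t",
                         float_format="%.6g")

    summary: dict = {"samples": {}}
    for sample in samples:
        summary["samples"][sample] = {
            "n_fragments": filtered[sample].total_count,
            "n_enriched_genes": len(signals[sample].enriched_genes),
        }

    # multi-sample set structure
    if len(samples) >= 2:
        inter = intersection_counts({s: signals[s].enriched_genes for s in samples})
        inter.as_records().to_csv(outdir / "intersection_cells.tsv", sep="\t",
                                  index=False)
        summary["intersection"] = {
            "union": inter.union_size,
            "core": inter.core_size,
            "set_sizes": inter.set_sizes,
        }
        a, b = samples[0], samples[1]
        a_only, b_only, both = set_difference_marked(
            signals[a].enriched_genes, signals[b].enriched_genes
        )
        fold_res = pairwise_fold_calls(signals[a], signals[b], fold=config.fold)
        fold_res.table.to_csv(outdir / f"{a}_vs_{b}.ratios.tsv", sep="\t",
                              float_format="%.6g")
        common = sorted(signals[a].enriched_genes & signals[b].enriched_genes)
        summary["pairwise"] = {
            "pair": [a, b],
            "a_only": len(a_only),
            "b_only": len(b_only),
            "both": len(both),
            "gained": len(fold_res.gained),
            "lost": len(fold_res.lost),
        }
        if len(common) >= 2:
            tt = paired_t_signal(
                signals[a].fpkb.reindex(common), signals[b].fpkb.reindex(common)
            )
            summary["pairwise"]["paired_t"] = {"t": tt.t, "p": tt.p, "n": tt.n}

        # entropy contrast and GO enrichment for the first sample's calls
        marked = signals[a].enriched_genes
        if marked and len(marked) < len(study.expression):
            ec = entropy_contrast(marked, study.expression, base=config.entropy_base)
            per_gene, _ = entropy_per_gene(study.expression, base=config.entropy_base)
            per_gene.to_frame().to_csv(outdir / "entropy.tsv", sep="\t",
                                       float_format="%.6g")
            summary["entropy"] = {
                "sample": a,
                "median_target": ec.median_target,
                "median_nontarget": ec.median_nontarget,
                "p_value": ec.p_value,
                "targets_more_specific": ec.targets_more_specific,
                "test": ec.test,
            }
        universe = set(study.annotation.gene_ids)
        go_table = hypergeom_go(marked & universe, universe, study.maps)
        go_table.to_csv(outdir / f"{a}.go_enrichment.tsv", sep="\t", index=False,
                        float_format="%.6g")
        cons = conservation_contrast(marked, study.maps, universe)
        summary["conservation"] = {
            "frac_marked_of_ref_marked": cons.frac_marked_of_ref_marked,
            "frac_marked_of_ref_unmarked": cons.frac_marked_of_ref_unmarked,
            "frac_marked_of_orphans": cons.frac_marked_of_orphans,
            "p_value": cons.p_value,
        }

    # motif regions for the first sample
    first = filtered[samples[0]]
    if first.total_count:
        cov = build_coverage(first, study.genome)
        (outdir / f"{samples[0]}.coverage.bedgraph").write_text(cov.to_bedgraph())
        sig_regions = select_signal_regions(
            cov, threshold=config.motif_threshold, merge_gap=config.motif_merge
        )
        sig_regions.to_csv(outdir / "motif_query.bed", sep="\t", header=False,
                           index=False)
        summary["motif"] = {"n_query_regions": len(sig_regions)}
        if len(sig_regions) and study.genome.sequences is not None:
            try:
                bg = sample_matched_background(sig_regions, study.genome, config.seed)
                summary["motif"]["background_avoids_queries"] = True
            except (RuntimeError, ValueError):
                # signal regions cover too much of the genome to avoid;
                # fall back to unconstrained placement
                bg = sample_matched_background(
                    sig_regions, study.genome, config.seed, avoid_regions=False
                )
                summary["motif"]["background_avoids_queries"] = False
            bg.to_csv(outdir / "motif_background.bed", sep="\t", header=False,
                      index=False)
            export_region_fasta(sig_regions, study.genome, outdir / "motif_query.fa")
            export_region_fasta(bg, study.genome, outdir / "motif_background.fa")

    manifest = {
        "parameters": config.to_dict(),
        "inputs": {
            key: {"path": name, "sha256": _sha256(outdir / "inputs" / name)}
            for key, name in input_paths.items()
        },
        "summary": summary,
    }
    (outdir / "manifest.json").write_text(
        json.dumps(manifest, indent=1, sort_keys=True, default=_json_default) + "\n"
    )
    return manifest


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, set):
        return sorted(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")
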