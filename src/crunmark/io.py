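"""Readers and writers for the pipeline's on-disk formats.

Conventions: BED/BEDPE and the internal fragment tables are 0-based,
half-open; GFF3 is converted at the boundary (1-based, closed).  All
tables are plain TSV so every artifact stays text and diffable.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .fragments import FragmentSet
from .synthetic_data import GroundTruth, ToyAnnotation, ToyGenome

__all__ = [
    "write_genome_fasta",
    "read_genome_fasta",
    "write_contig_lengths",
    "read_contig_lengths",
    "write_gff3",
    "read_gff3",
    "write_fragments_bed",
    "read_fragments_bed",
    "read_bedpe",
    "write_expression_tsv",
    "read_expression_tsv",
    "write_maps_tsv",
    "read_maps_tsv",
    "write_truth_json",
    "read_truth_json",
    "write_peaks_bed",
]


def write_genome_fasta(genome: ToyGenome, path) -> None:
    if genome.sequences is None:
        raise ValueError("genome has no sequences to write")
    records = [
        SeqRecord(Seq(genome.sequences[cid]), id=cid, description="")
        for cid, _ in genome.contigs
    ]
    SeqIO.write(records, path, "fasta")


def read_genome_fasta(path) -> ToyGenome:
    records = list(SeqIO.parse(str(path), "fasta"))
    contigs = tuple((r.id, len(r.seq)) for r in records)
    sequences = {r.id: str(r.seq).upper() for r in records}
    return ToyGenome(contigs=contigs, sequences=sequences)


def write_contig_lengths(genome: ToyGenome, path) -> None:
    pd.DataFrame(genome.contigs, columns=["contig", "length"]).to_csv(
        path, sep="\t", index=False
    )


def read_contig_lengths(path) -> ToyGenome:
    df = pd.read_csv(path, sep="\t")
    return ToyGenome(contigs=tuple(zip(df["contig"], df["length"].astype(int))))


def write_gff3(annotation: ToyAnnotation, path) -> None:
    """GFF3 with gene and repeat_region features (1-based, closed)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for row in annotation.genes.itertuples(index=False):
            fh.write(
                f"{row.contig}\tcrunmark\tgene\t{row.start + 1}\t{row.end}\t.\t.\t.\t"
                f"ID={row.gene_id}\n"
            )
        for row in annotation.transposable_elements.itertuples(index=False):
            fh.write(
                f"{row.contig}\tcrunmark\trepeat_region\t{row.start + 1}\t{row.end}"
                f"\t.\t.\t.\tID={row.te_id}\n"
            )


def read_gff3(path) -> ToyAnnotation:
    genes, tes = [], []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 9:
                continue
            contig, _src, ftype, start, end, _s, _st, _f, attrs = fields[:9]
            ident = dict(
                kv.split("=", 1) for kv in attrs.split(";") if "=" in kv
            ).get("ID", "")
            rec = (ident, contig, int(start) - 1, int(end))
            if ftype == "gene":
                genes.append(rec)
            elif ftype in ("repeat_region", "transposable_element"):
                tes.append(rec)
    return ToyAnnotation(
        genes=pd.DataFrame(genes, columns=["gene_id", "contig", "start", "end"]),
        transposable_elements=pd.DataFrame(
            tes, columns=["te_id", "contig", "start", "end"]
        ),
    )


def write_fragments_bed(fs: FragmentSet, path) -> None:
    fs.fragments[["contig", "start", "end"]].to_csv(
        path, sep="\t", header=False, index=False
    )


def read_fragments_bed(path, sample_id: str) -> FragmentSet:
    df = pd.read_csv(
        path,
        sep="\t",
        header=None,
        usecols=[0, 1, 2],
        names=["contig", "start", "end"],
        dtype={"contig": str, "start": np.int64, "end": np.int64},
    )
    return FragmentSet(sample_id=sample_id, fragments=df)


def read_bedpe(path) -> pd.DataFrame:
    """BEDPE -> pair table (pair_id, contig/start/end per mate)."""
    df = pd.read_csv(
        path,
        sep="\t",
        header=None,
        usecols=list(range(7)),
        names=["contig1", "start1", "end1", "contig2", "start2", "end2", "pair_id"],
    )
    # '.' marks an unmapped mate in BEDPE
    for col in ("contig1", "contig2"):
        df[col] = df[col].replace(".", np.nan)
    return df[["pair_id", "contig1", "start1", "end1", "contig2", "start2", "end2"]]


def write_expression_tsv(matrix: pd.DataFrame, path) -> None:
    matrix.to_csv(path, sep="\t", index=True, float_format="%.6g")


def read_expression_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def write_maps_tsv(maps, go_path, homology_path) -> None:
    maps.go.to_csv(go_path, sep="\t", index=False)
    maps.homology.to_csv(homology_path, sep="\t", index=False)


def read_maps_tsv(go_path, homology_path, term_names: dict[str, str] | None = None):
    from .enrichment import AnnotationMaps

    go = pd.read_csv(go_path, sep="\t")
    homology = pd.read_csv(homology_path, sep="\t")
    if term_names is None:
        term_names = {t: t for t in go["go_id"].unique()}
    return AnnotationMaps(homology=homology, go=go, term_names=term_names)


def write_truth_json(truth: GroundTruth, path) -> None:
    payload = {
        "marked_genes": {s: sorted(g) for s, g in truth.marked_genes.items()},
        "enrichment_fold": truth.enrichment_fold,
        "background_rate": truth.background_rate,
        "specific_genes": sorted(truth.specific_genes),
        "broad_genes": sorted(truth.broad_genes),
        "planted_go_terms": sorted(truth.planted_go_terms),
    }
    Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True) + "\n")


def read_truth_json(path) -> GroundTruth:
    payload = json.loads(Path(path).read_text())
    return GroundTruth(
        marked_genes={s: set(g) for s, g in payload["marked_genes"].items()},
        enrichment_fold=payload["enrichment_fold"],
        background_rate=payload["background_rate"],
        specific_genes=set(payload["specific_genes"]),
        broad_genes=set(payload["broad_genes"]),
        planted_go_terms=set(payload["planted_go_terms"]),
    )


def write_peaks_bed(peaks: pd.DataFrame, path, score_cap: float = 1000.0) -> None:
    """Peaks BED with score = -log10(min_q), capped."""
    with np.errstate(divide="ignore"):
        score = np.minimum(-np.log10(peaks["min_q"].to_numpy()), score_cap)
    out = peaks[["contig", "start", "end"]].copy()
    out["name"] = [f"peak_{i + 1}" for i in range(len(peaks))]
    out["score"] = np.round(score, 3)
    out.to_csv(path, sep="\t", header=False, index=False)
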