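"""Synthetic genomes, annotations, fragment sets, expression and GO maps.

This module emulates the study system — a very large conifer genome split
across many short contigs, sparsely covered by CUT&RUN fragments — at desk
scale, with known ground truth so that every downstream stage (peak calling,
gene-level quantification, specificity, GO enrichment) can be validated
against planted signal.

Design notes
------------
* Contig lengths are geometric around ``mean_len`` with a floor of 500 bp,
  mimicking a fragmented draft assembly.
* A "marked" gene carries fragment enrichment over its body extended by
  500 bp on both sides — the same window downstream quantification uses —
  so truth and measurement windows coincide.
* Fragment lengths follow a truncated normal (floor 50 bp); an optional
  fraction of "long contaminants" is drawn uniformly in (700, 2000] bp to
  exercise the 700 bp size filter.
* All randomness flows from a single seed through named child streams.
"""

from __future__ import annotations

import string
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._rng import child_rng
from .fragments import FragmentSet

__all__ = [
    "ToyGenome",
    "ToyAnnotation",
    "GroundTruth",
    "generate_toy_genome",
    "generate_annotation",
    "generate_fragments",
    "generate_expression",
    "generate_functional_maps",
]

_DNA = np.array(list("ACGT"))


@dataclass(frozen=True)
class ToyGenome:
    """A toy assembly: ordered contigs with lengths and optional sequence."""

    contigs: tuple[tuple[str, int], ...]
    sequences: dict[str, str] | None = None

    def __post_init__(self):
        ids = [c for c, _ in self.contigs]
        if len(set(ids)) != len(ids):
            raise ValueError("contig ids must be unique")
        for cid, length in self.contigs:
            if length < 1:
                raise ValueError(f"contig {cid} has non-positive length")
        if self.sequences is not None:
            for cid, length in self.contigs:
                seq = self.sequences.get(cid)
                if seq is None or len(seq) != length:
                    raise ValueError(f"sequence of {cid} does not match declared length")

    @property
    def lengths(self) -> dict[str, int]:
        return dict(self.contigs)

    @property
    def total_length(self) -> int:
        return sum(length for _, length in self.contigs)


@dataclass(frozen=True)
class ToyAnnotation:
    """Gene and transposable-element intervals (0-based, half-open)."""

    genes: pd.DataFrame  # columns: gene_id, contig, start, end
    transposable_elements: pd.DataFrame  # columns: te_id, contig, start, end

    def __post_init__(self):
        if self.genes["gene_id"].duplicated().any():
            raise ValueError("gene ids must be unique")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.genes["gene_id"])


@dataclass
class GroundTruth:
    """Planted truth labels used by recovery tests.

    ``marked_genes`` maps sample id to the set of genes designed to carry
    H3K27me3-like fragment enrichment in that sample.
    """

    marked_genes: dict[str, set[str]]
    enrichment_fold: float = 8.0
    background_rate: float = 0.01  # fragments per bp, genome-wide
    specific_genes: set[str] = field(default_factory=set)
    broad_genes: set[str] = field(default_factory=set)
    planted_go_terms: set[str] = field(default_factory=set)

    def __post_init__(self):
        if self.enrichment_fold <= 1:
            raise ValueError("enrichment_fold must be > 1")

    @property
    def all_marked(self) -> set[str]:
        out: set[str] = set()
        for genes in self.marked_genes.values():
            out |= genes
        return out

    def validate_against(self, annotation: ToyAnnotation) -> None:
        known = set(annotation.gene_ids)
        unknown = self.all_marked - known
        if unknown:
            raise ValueError(f"marked genes absent from annotation: {sorted(unknown)[:5]}")


def generate_toy_genome(
    n_contigs: int,
    mean_len: int,
    seed: int,
    with_sequences: bool = False,
) -> ToyGenome:
    """Draw a fragmented toy assembly.

    Contig lengths are 499 + Geometric(1/(mean_len-499)), i.e. geometric
    around ``mean_len`` with floor 500 bp.
    """
    if n_contigs < 1:
        raise ValueError("n_contigs must be >= 1")
    if mean_len < 500:
        raise ValueError("mean_len must be >= 500")
    rng = child_rng(seed, "genome")
    p = 1.0 / (mean_len - 499)
    lengths = 499 + rng.geometric(p, size=n_contigs)
    contigs = tuple(
        (f"contig_{i:05d}", int(L)) for i, L in enumerate(lengths, start=1)
    )
    sequences = None
    if with_sequences:
        sequences = {
            cid: "".join(_DNA[rng.integers(0, 4, size=L)]) for cid, L in contigs
        }
    return ToyGenome(contigs=contigs, sequences=sequences)


def _place_nonoverlapping(
    rng: np.random.Generator,
    contigs: list[tuple[str, int]],
    n: int,
    length_of: "callable",
    occupied: dict[str, list[tuple[int, int]]],
    min_gap: int,
    max_tries_per_item: int = 500,
) -> list[tuple[str, int, int]]:
    """Rejection-sample ``n`` intervals that avoid ``occupied`` (+min_gap)."""
    ids = [c for c, _ in contigs]
    lens = np.array([L for _, L in contigs], dtype=float)
    weights = lens / lens.sum()
    placed: list[tuple[str, int, int]] = []
    for _ in range(n):
        item_len = length_of()
        ok = False
        for _try in range(max_tries_per_item):
            ci = rng.choice(len(ids), p=weights)
            cid, clen = ids[ci], int(lens[ci])
            if clen < item_len:
                continue
            start = int(rng.integers(0, clen - item_len + 1))
            end = start + item_len
            clash = any(
                start - min_gap < e and end + min_gap > s
                for s, e in occupied.get(cid, [])
            )
            if not clash:
                occupied.setdefault(cid, []).append((start, end))
                placed.append((cid, start, end))
                ok = True
                break
        if not ok:
            raise RuntimeError(
                f"could not place interval of length {item_len}: "
                "genome too crowded for the requested annotation"
            )
    return placed


def generate_annotation(
    genome: ToyGenome,
    n_genes: int,
    gene_len: int = 2000,
    te_fraction: float = 0.0,
    seed: int = 0,
    min_gap: int = 1200,
) -> ToyAnnotation:
    """Place non-overlapping genes and TE intervals on the genome.

    ``min_gap`` keeps gene bodies well separated (default 1200 bp > two
    500 bp quantification extensions), so planted enrichment windows of
    different genes never overlap and per-gene truth stays unambiguous.
    TE intervals cover approximately ``te_fraction`` of non-genic sequence.
    """
    if not 0 <= te_fraction < 1:
        raise ValueError("te_fraction must be in [0, 1)")
    if n_genes < 0:
        raise ValueError("n_genes must be >= 0")
    rng = child_rng(seed, "annotation")
    contigs = list(genome.contigs)
    occupied: dict[str, list[tuple[int, int]]] = {}
    gene_iv = _place_nonoverlapping(
        rng, contigs, n_genes, lambda: gene_len, occupied, min_gap
    )
    genes = pd.DataFrame(
        [
            (f"gene_{i:05d}", cid, s, e)
            for i, (cid, s, e) in enumerate(sorted(gene_iv), start=1)
        ],
        columns=["gene_id", "contig", "start", "end"],
    )

    te_rows: list[tuple[str, str, int, int]] = []
    if te_fraction > 0:
        nongenic = genome.total_length - n_genes * gene_len
        target = te_fraction * nongenic
        covered = 0.0
        i = 0
        while covered < target:
            te_len = int(rng.integers(500, 5001))
            try:
                (cid, s, e), = _place_nonoverlapping(
                    rng, contigs, 1, lambda: te_len, occupied, 0
                )
            except RuntimeError:
                break  # genome saturated; report what fits
            i += 1
            te_rows.append((f"te_{i:05d}", cid, s, e))
            covered += te_len
    tes = pd.DataFrame(
        sorted(te_rows, key=lambda r: (r[1], r[2])),
        columns=["te_id", "contig", "start", "end"],
    )
    return ToyAnnotation(genes=genes, transposable_elements=tes)


def _draw_lengths(
    rng: np.random.Generator,
    n: int,
    frag_len_mean: int,
    long_frac: float,
    frag_len_sd: float = 50.0,
) -> np.ndarray:
    """Truncated-normal fragment lengths with a long-contaminant mixture."""
    lengths = np.maximum(
        50, np.rint(rng.normal(frag_len_mean, frag_len_sd, size=n))
    ).astype(np.int64)
    if long_frac > 0:
        is_long = rng.random(n) < long_frac
        n_long = int(is_long.sum())
        if n_long:
            lengths[is_long] = rng.integers(701, 2001, size=n_long)
    return lengths


def generate_fragments(
    genome: ToyGenome,
    annotation: ToyAnnotation,
    truth: GroundTruth,
    n_fragments: int,
    frag_len_mean: int = 170,
    long_frac: float = 0.0,
    seed: int = 0,
    extension: int = 500,
) -> dict[str, FragmentSet]:
    """Simulate one fragment table per sample in ``truth.marked_genes``.

    ``n_fragments`` background fragments are placed uniformly genome-wide
    (start uniform, length truncated normal around ``frag_len_mean``).  Over
    each marked gene body ±``extension`` an extra Poisson number of
    fragments is added so that local density is ``enrichment_fold`` times
    the genome-wide background rate ``n_fragments / total_length``.
    """
    if n_fragments < 0:
        raise ValueError("n_fragments must be >= 0")
    if not 0 <= long_frac < 1:
        raise ValueError("long_frac must be in [0, 1)")
    truth.validate_against(annotation)

    ids = [c for c, _ in genome.contigs]
    clens = np.array([L for _, L in genome.contigs], dtype=np.int64)
    weights = clens / clens.sum()
    clen_of = genome.lengths
    bg_rate = n_fragments / genome.total_length if genome.total_length else 0.0
    gene_lookup = annotation.genes.set_index("gene_id")

    out: dict[str, FragmentSet] = {}
    for sample_id, marked in truth.marked_genes.items():
        rng = child_rng(seed, "fragments", sample_id)
        # background
        ci = rng.choice(len(ids), size=n_fragments, p=weights)
        starts = (rng.random(n_fragments) * clens[ci]).astype(np.int64)
        lengths = _draw_lengths(rng, n_fragments, frag_len_mean, long_frac)
        rows = [
            pd.DataFrame(
                {
                    "contig": np.array(ids, dtype=object)[ci],
                    "start": starts,
                    "end": np.minimum(starts + lengths, clens[ci]),
                }
            )
        ]
        # planted enrichment over marked gene windows
        for gid in sorted(marked):
            g = gene_lookup.loc[gid]
            clen = clen_of[g["contig"]]
            r0 = max(0, int(g["start"]) - extension)
            r1 = min(clen, int(g["end"]) + extension)
            lam = (truth.enrichment_fold - 1.0) * bg_rate * (r1 - r0)
            n_extra = int(rng.poisson(lam))
            if n_extra == 0:
                continue
            s = r0 + (rng.random(n_extra) * (r1 - r0)).astype(np.int64)
            ln = _draw_lengths(rng, n_extra, frag_len_mean, long_frac)
            rows.append(
                pd.DataFrame(
                    {
                        "contig": g["contig"],
                        "start": s,
                        "end": np.minimum(s + ln, clen),
                    }
                )
            )
        df = pd.concat(rows, ignore_index=True)
        df = df.sort_values(["contig", "start", "end"], kind="mergesort").reset_index(
            drop=True
        )
        out[sample_id] = FragmentSet(sample_id=sample_id, fragments=df)
    return out


def generate_expression(
    annotation: ToyAnnotation,
    n_tissues: int,
    truth: GroundTruth,
    seed: int = 0,
    base: float = 100.0,
    noise: float = 0.1,
    leakage: float = 0.02,
) -> pd.DataFrame:
    """Genes × tissues expression with designed specificity structure.

    ``truth.specific_genes`` are expressed predominantly in one tissue
    (off-tissue level = ``leakage * base``); ``truth.broad_genes`` are
    near-uniform.  Remaining genes get an intermediate random profile.
    ``noise`` is a multiplicative log-normal dispersion; at ``noise=0``
    broad genes are exactly uniform and at ``leakage=0`` specific genes
    have a single nonzero tissue.
    """
    if n_tissues < 2:
        raise ValueError("n_tissues must be >= 2")
    rng = child_rng(seed, "expression")
    genes = annotation.gene_ids
    tissues = [f"tissue_{t:02d}" for t in range(1, n_tissues + 1)]

    def jitter(shape):
        if noise == 0:
            return np.ones(shape)
        return np.exp(rng.normal(0.0, noise, size=shape))

    mat = np.empty((len(genes), n_tissues))
    for i, gid in enumerate(genes):
        if gid in truth.specific_genes:
            home = rng.integers(0, n_tissues)
            row = leakage * base * jitter(n_tissues)
            row[home] = base * jitter(1)[0]
        elif gid in truth.broad_genes:
            row = base * jitter(n_tissues)
        else:
            # intermediate: a random half of tissues at full level
            on = rng.random(n_tissues) < 0.5
            if not on.any():
                on[rng.integers(0, n_tissues)] = True
            row = np.where(on, base, 0.2 * base) * jitter(n_tissues)
        mat[i] = row
    return pd.DataFrame(mat, index=pd.Index(genes, name="gene_id"), columns=tissues)


def generate_functional_maps(
    annotation: ToyAnnotation,
    n_terms: int,
    truth: GroundTruth,
    seed: int = 0,
    orphan_fraction: float = 0.2,
    base_term_prob: float = 0.05,
    planted_odds: float = 8.0,
    ref_marked_given_marked: float = 0.7,
    ref_marked_given_unmarked: float = 0.1,
):
    """Homology and GO maps with planted term enrichment.

    Each non-orphan spruce gene gets a unique reference-species homologue
    (one-to-one best hit) carrying a marked/unmarked flag correlated with
    the spruce truth labels.  Each GO term annotates reference genes
    independently with probability ``base_term_prob``; for terms in
    ``truth.planted_go_terms`` the odds of annotating a homologue of a
    marked spruce gene are multiplied by ``planted_odds``.

    Returns an :class:`~crunmark.enrichment.AnnotationMaps`.
    """
    from .enrichment import AnnotationMaps  # local import to avoid cycle

    if n_terms < 1:
        raise ValueError("n_terms must be >= 1")
    if not 0 <= orphan_fraction <= 1:
        raise ValueError("orphan_fraction must be in [0, 1]")
    rng = child_rng(seed, "functional_maps")
    genes = annotation.gene_ids
    marked = truth.all_marked

    is_orphan = rng.random(len(genes)) < orphan_fraction
    hom_rows = []
    for i, gid in enumerate(genes):
        if is_orphan[i]:
            continue
        ref_id = f"REF_{gid}"
        p_marked = (
            ref_marked_given_marked if gid in marked else ref_marked_given_unmarked
        )
        hom_rows.append((gid, ref_id, int(rng.random() < p_marked)))
    homology = pd.DataFrame(
        hom_rows, columns=["gene_id", "ref_gene_id", "ref_marked"]
    )

    planted = sorted(truth.planted_go_terms)
    term_ids = list(planted)
    t = 0
    while len(term_ids) < n_terms:
        t += 1
        tid = f"GO:{7000000 + t:07d}"
        if tid not in truth.planted_go_terms:
            term_ids.append(tid)
    base_odds = base_term_prob / (1.0 - base_term_prob)
    p_planted = (planted_odds * base_odds) / (1.0 + planted_odds * base_odds)

    go_rows = []
    hom_by_gene = dict(zip(homology["gene_id"], homology["ref_gene_id"]))
    for gid, ref_id in hom_by_gene.items():
        target = gid in marked
        for tid in term_ids:
            p = (
                p_planted
                if (tid in truth.planted_go_terms and target)
                else base_term_prob
            )
            if rng.random() < p:
                go_rows.append((ref_id, tid))
    go = pd.DataFrame(go_rows, columns=["ref_gene_id", "go_id"])
    letters = string.ascii_uppercase
    term_names = {
        tid: f"synthetic process {letters[i % 26]}{i // 26 + 1}"
        for i, tid in enumerate(term_ids)
    }
    return AnnotationMaps(homology=homology, go=go, term_names=term_names)
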