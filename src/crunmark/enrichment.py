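"""Homology-mediated hypergeometric GO enrichment and conservation contrast.

GO terms are carried by reference-species (e.g. Arabidopsis) genes; a
spruce gene inherits the terms of its single best-hit homologue.  Both the
gene set of interest and the background are restricted to genes with a
homologue before testing.  For a term annotating K of N background genes
and k of n sample genes, the enrichment p-value is the upper-tail
hypergeometric probability P(X >= k), and the enrichment ratio is
(k/n) / (K/N).

The conservation contrast asks whether spruce-marked genes are
over-represented among homologues of reference-marked genes, again with an
upper-tail hypergeometric test on the 2x2 margin.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import nan

import pandas as pd
from scipy import stats

from .peakcall import adjust_bh

__all__ = [
    "AnnotationMaps",
    "hypergeom_go",
    "conservation_contrast",
    "ConservationResult",
]


@dataclass
class AnnotationMaps:
    """Homology and GO maps.

    homology: columns gene_id, ref_gene_id, ref_marked (0/1); one row per
    spruce gene (best hit).  go: columns ref_gene_id, go_id.  term_names:
    go_id -> label.
    """

    homology: pd.DataFrame
    go: pd.DataFrame
    term_names: dict[str, str]

    def __post_init__(self):
        if self.homology["gene_id"].duplicated().any():
            # keep the first listed (best) hit per gene
            self.homology = self.homology.drop_duplicates("gene_id", keep="first")

    @property
    def mapped_genes(self) -> set[str]:
        return set(self.homology["gene_id"])

    def terms_of(self, gene_id: str) -> set[str]:
        row = self.homology.loc[self.homology["gene_id"] == gene_id]
        if row.empty:
            return set()
        ref = row.iloc[0]["ref_gene_id"]
        return set(self.go.loc[self.go["ref_gene_id"] == ref, "go_id"])

    def gene_term_table(self, genes: set[str]) -> pd.DataFrame:
        """(gene_id, go_id) rows for the given spruce genes via homology."""
        hom = self.homology.loc[self.homology["gene_id"].isin(genes)]
        merged = hom.merge(self.go, on="ref_gene_id", how="inner")
        return merged[["gene_id", "go_id"]]


def hypergeom_go(
    sample_genes: set[str],
    background_genes: set[str],
    maps: AnnotationMaps,
    with_bh: bool = False,
) -> pd.DataFrame:
    """Per-term upper-tail hypergeometric enrichment of a gene set.

    Returns a table with columns go_id, label, freq_sample,
    freq_background, n_sample, n_background, enrichment, p_value (plus
    q_value when ``with_bh``), sorted by enrichment (descending) then
    p-value.  Terms with no background annotation are skipped; raw
    p-values are the primary output.
    """
    if not sample_genes <= background_genes:
        raise ValueError("sample genes must be a subset of the background")
    mapped = maps.mapped_genes
    bg = background_genes & mapped
    smp = sample_genes & mapped
    n_bg, n_smp = len(bg), len(smp)

    bg_terms = maps.gene_term_table(bg)
    smp_terms = maps.gene_term_table(smp)
    freq_bg = bg_terms.groupby("go_id")["gene_id"].nunique()
    freq_smp = smp_terms.groupby("go_id")["gene_id"].nunique()

    rows = []
    for go_id, K in freq_bg.items():
        k = int(freq_smp.get(go_id, 0))
        p = float(stats.hypergeom.sf(k - 1, n_bg, int(K), n_smp))
        enr = (k / n_smp) / (K / n_bg) if n_smp and K else 0.0
        rows.append(
            (
                go_id,
                maps.term_names.get(go_id, go_id),
                k,
                int(K),
                n_smp,
                n_bg,
                enr,
                min(p, 1.0),
            )
        )
    out = pd.DataFrame(
        rows,
        columns=[
            "go_id",
            "label",
            "freq_sample",
            "freq_background",
            "n_sample",
            "n_background",
            "enrichment",
            "p_value",
        ],
    )
    if with_bh and len(out):
        out["q_value"] = adjust_bh(out["p_value"].to_numpy())
    return out.sort_values(
        ["enrichment", "p_value"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)


@dataclass
class ConservationResult:
    frac_marked_of_ref_marked: float  # spruce-marked fraction, ref-marked homologues
    frac_marked_of_ref_unmarked: float
    frac_marked_of_orphans: float
    p_value: float
    n_ref_marked: int
    n_ref_unmarked: int
    n_orphans: int


def conservation_contrast(
    spruce_marked: set[str],
    maps: AnnotationMaps,
    universe: set[str],
) -> ConservationResult:
    """Cross-species conservation of the repressive mark.

    Splits ``universe`` into homologues of reference-marked genes,
    homologues of reference-unmarked genes, and orphans (no homologue),
    reports the spruce-marked fraction of each, and an upper-tail
    hypergeometric p-value for over-representation of spruce-marked genes
    among the homologues of reference-marked genes (population: all genes
    with a homologue).  Empty categories yield NaN fractions.
    """
    hom = maps.homology.loc[maps.homology["gene_id"].isin(universe)]
    ref_marked = set(hom.loc[hom["ref_marked"] == 1, "gene_id"])
    ref_unmarked = set(hom.loc[hom["ref_marked"] != 1, "gene_id"])
    orphans = universe - set(hom["gene_id"])

    def frac(group: set[str]) -> float:
        return len(group & spruce_marked) / len(group) if group else nan

    n_pop = len(ref_marked) + len(ref_unmarked)
    K = len((ref_marked | ref_unmarked) & spruce_marked)
    n_draw = len(ref_marked)
    k = len(ref_marked & spruce_marked)
    p = float(stats.hypergeom.sf(k - 1, n_pop, K, n_draw)) if n_pop else nan
    return ConservationResult(
        frac_marked_of_ref_marked=frac(ref_marked),
        frac_marked_of_ref_unmarked=frac(ref_unmarked),
        frac_marked_of_orphans=frac(orphans),
        p_value=p,
        n_ref_marked=len(ref_marked),
        n_ref_unmarked=len(ref_unmarked),
        n_orphans=len(orphans),
    )
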