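# Methods

## Model and assumptions

`crunmark` treats a CUT&RUN library as a set of mapped DNA fragments on a
multi-contig assembly. The peak-calling null model is uniform fragment
placement: for a bin of width *w* on an effective genome of length *G*,
the number of fragments overlapping the bin among *N* total fragments is
Binomial(*N*, *w*/*G*), and a bin's p-value is the one-sided upper tail
P(X ≥ k). This is deliberately the simplest null compatible with per-bin
binomial testing on an assembly where no control (IgG/input) track is
available; it ignores local coverage biases (mappability, GC,
accessibility), so the stringent genome-wide FDR cutoff (1e-25) does the
work of suppressing false calls. *G* defaults to the sum of contig
lengths and can be overridden with a mappability-corrected value.

Two known approximations in the null are worth stating. First, overlap
counting (a fragment counts in every bin it touches) inflates counts
relative to the point-process null by roughly a factor
(w + L̄ − 1)/w for mean fragment length L̄; with 500 bp bins and
~170 bp fragments this is ~1.3×, uniformly across bins, and is absorbed
by the extreme FDR threshold. Second, BH is applied to all bins in one
family, including zero-count bins, which is conservative.

## Parameters

| parameter | default | meaning |
|---|---|---|
| `bin_size` | 500 bp | genome tiling width |
| `max_fragment` | 700 bp | strict upper size bound; longer fragments are non-nucleosomal contaminants |
| `fdr` | 1e-25 | BH-adjusted per-bin selection threshold |
| `merge_gap` | 100 bp | significant bins closer than this merge into one peak |
| `extension` | 500 bp | gene-body extension for both enrichment calls and FPKB |
| `fold` | 2 | pairwise differential-marking ratio threshold (inclusive) |
| `motif_threshold` | 8.0e-7 | per-bp coverage / total reads cutoff (strict >) |
| `motif_merge` | 101 bp | motif regions closer than this merge |
| `entropy_base` | e | natural-log entropy; configurable |

All defaults are exposed in `PipelineConfig` and on the CLI.

FPKB (fragments per kilobase per billion mapped fragments) uses the
extended gene region length and the post-filter fragment total, so values
are invariant under uniform subsampling. The pairwise pseudocount
defaults to the FPKB of a single fragment on a 1 kb region given each
sample's own total (1e9/N), which makes zero-signal ratios finite without
changing units. The comparison universe defaults to the union of the two
samples' enriched sets (configurable to all genes).

## Statistical tests

* Per-bin enrichment: exact binomial upper tail (enrichment only;
  two-sided testing would also flag depleted bins, which is not the goal).
* Multiple testing: Benjamini–Hochberg step-up, implemented directly and
  validated against an independent reference implementation.
* Paired intensity shift: paired Student's t on per-gene FPKB over shared
  enriched genes. All-zero differences return t = 0, p = 1; a constant
  nonzero difference is reported as the p → 0 limit with a degeneracy
  flag.
* Specificity contrast: two-sided Wilcoxon rank-sum on Shannon entropies.
  The choice of test is this package's own (the contrast needs no
  normality assumption) and is labelled in the output metadata.
* GO enrichment and conservation: upper-tail hypergeometric. GO terms are
  inherited from the single best-hit homologue; no GO-graph propagation
  is performed, and raw p-values are the primary output (BH column
  optional, off by default).

## Synthetic data: what it does and does not emulate

The generator emulates the features the pipeline is sensitive to: a
fragmented assembly (geometric contig lengths, floor 500 bp), sparse
uniform background coverage, planted fold-enrichment over marked gene
bodies ±500 bp (the same window quantification uses, so truth and
measurement coincide), a truncated-normal fragment-length mixture with
>700 bp contaminants, designed tissue-specific vs broad expression
profiles, and GO/homology maps with planted over-represented terms and
orphan genes.

It does not emulate read-level artifacts (sequencing error, mapping
ambiguity, duplicates), non-uniform background (chromatin accessibility,
GC bias), spike-in sequence content, or correlated replicate structure.
Passing recovery tests therefore demonstrates the pipeline's correctness
and statistical behaviour under its stated model, not robustness to
real-data biases — on real libraries the uniform null makes the effective
FDR less interpretable, which is why the threshold is so stringent.

Default simulation conditions: 50 contigs of mean 20 kb (~1 Mbp), genes
of 2 kb placed with ≥1.2 kb separation (so 500 bp extension windows of
neighbouring genes never overlap and per-gene truth stays unambiguous),
background 0.01 fragments/bp, enrichment fold 8–10 (≥40 expected
fragments per marked 500 bp bin), fragment length 170 ± 50 bp (mono- to
di-nucleosome scale), 5% long contaminants. The recovery experiments
average 20 independent seeds; these sizes keep a full run in seconds
while leaving the planted signal comfortably above the detection
threshold — the same regime, scaled down, as a deeply sequenced CUT&RUN
library on a gigabase genome.

## Numerical and design choices

* Coordinates are 0-based half-open internally and in BED; GFF3 is
  converted at the boundary (1-based closed). One internal convention
  avoids off-by-one drift.
* Strand is ignored throughout; duplicates are kept (no deduplication
  stage exists in the pipeline definition).
* Boundary semantics are literal: fragment length exactly 700 is kept
  (> is strict); peak merging requires gap < 100 strictly; motif coverage
  must exceed 8.0e-7 strictly and motif merging requires gap < 101
  strictly; the fold threshold is inclusive ("twice or more").
* The binomial tail is computed via the regularized incomplete beta
  function (scipy); tests validate it against direct log-space summation
  to 1e-9 relative.
* Determinism: all randomness derives from one seed through named child
  streams (CRC32 of the stream name), so regenerating one artifact never
  shifts another, and a full pipeline re-run is byte-identical.
* Matched background sampling excludes query regions by default — a
  deliberate addition beyond plain random picking, to keep the motif
  control set uncontaminated. When signal regions cover so much of the
  genome that exclusion is infeasible (tiny, shallow demo libraries where
  nearly every covered base exceeds the read-fraction threshold), the
  pipeline falls back to unconstrained placement and records the fact in
  the run summary.
* GO enrichment rows are ordered by enrichment ratio then p-value; ties
  are broken stably.

## Known limitations

* No control-track or local-background (λ-local) correction; the uniform
  null is anti-conservative in high-coverage-bias regions of real data.
* Peak boundaries are bin-quantized; no summit estimation.
* One homologue per gene; paralogous GO signal is not aggregated.
* The expression unit fed to the entropy computation is taken as given;
  entropies are scale-invariant per gene but not invariant to
  between-condition normalization choices.
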