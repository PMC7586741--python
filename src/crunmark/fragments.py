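"""Fragment preprocessing: mate merging, the 700 bp size filter, spike-in QC.

Mapped paired-end mates on the same contig are merged into a single
fragment spanning both; cross-contig or unpaired mates are discarded.
Fragments longer than 700 bp (strictly) are then removed — they exceed the
tri-nucleosome range a CUT&RUN H3K27me3 library should contain.  The
post-filter fragment count N is the normalizer for all downstream
per-billion quantities.

Coordinates are 0-based, half-open throughout; strand is ignored.
Duplicate fragments are kept.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

DEFAULT_MAX_FRAGMENT = 700

__all__ = [
    "FragmentSet",
    "MergeSummary",
    "SpikeInQC",
    "merge_read_pairs",
    "filter_by_length",
    "spikein_correlation",
]


@dataclass
class FragmentSet:
    """A sample's mapped fragments; ``total_count`` is the normalizer N."""

    sample_id: str
    fragments: pd.DataFrame  # columns: contig, start, end

    def __post_init__(self):
        df = self.fragments
        required = {"contig", "start", "end"}
        if not required.issubset(df.columns):
            raise ValueError(f"fragment table needs columns {sorted(required)}")
        if len(df) and not (df["start"] < df["end"]).all():
            raise ValueError("all fragments must satisfy start < end")

    @property
    def total_count(self) -> int:
        return len(self.fragments)

    @property
    def lengths(self) -> np.ndarray:
        return (self.fragments["end"] - self.fragments["start"]).to_numpy()


@dataclass
class MergeSummary:
    n_pairs: int = 0
    n_merged: int = 0
    n_cross_contig: int = 0
    n_malformed: int = 0

    def as_dict(self) -> dict:
        return dict(self.__dict__)


def merge_read_pairs(
    pairs: pd.DataFrame, sample_id: str = "sample"
) -> tuple[FragmentSet, MergeSummary]:
    """Merge mate intervals mapped on the same contig into fragments.

    ``pairs`` columns: pair_id, contig1, start1, end1, contig2, start2,
    end2.  A missing mate (NaN contig) counts as unpaired and is discarded
    along with cross-contig pairs; records with a malformed interval
    (start >= end) are rejected with a warning.  The fragment spans
    min(start) .. max(end) of the two mates.
    """
    summary = MergeSummary(n_pairs=len(pairs))
    if len(pairs) == 0:
        fs = FragmentSet(sample_id, pd.DataFrame(columns=["contig", "start", "end"]))
        return fs, summary

    df = pairs.copy()
    bad = (df["start1"] >= df["end1"]) | (df["start2"] >= df["end2"])
    bad = bad.fillna(True)
    malformed = bad & df["contig1"].notna() & df["contig2"].notna()
    summary.n_malformed = int(malformed.sum())
    if summary.n_malformed:
        logger.warning("%d pairs with malformed intervals rejected", summary.n_malformed)

    unpaired = df["contig1"].isna() | df["contig2"].isna()
    cross = (~unpaired) & (df["contig1"] != df["contig2"])
    summary.n_cross_contig = int((cross | unpaired).sum())

    keep = (~malformed) & (~cross) & (~unpaired)
    kept = df.loc[keep]
    frags = pd.DataFrame(
        {
            "contig": kept["contig1"].to_numpy(),
            "start": np.minimum(kept["start1"], kept["start2"]).astype(np.int64),
            "end": np.maximum(kept["end1"], kept["end2"]).astype(np.int64),
        }
    )
    frags = frags.sort_values(["contig", "start", "end"], kind="mergesort").reset_index(
        drop=True
    )
    summary.n_merged = len(frags)
    logger.info(
        "merged %d/%d pairs (%d cross-contig/unpaired, %d malformed)",
        summary.n_merged,
        summary.n_pairs,
        summary.n_cross_contig,
        summary.n_malformed,
    )
    return FragmentSet(sample_id, frags), summary


def filter_by_length(fs: FragmentSet, max_len: int = DEFAULT_MAX_FRAGMENT) -> FragmentSet:
    """Drop fragments strictly longer than ``max_len`` bp.

    A fragment of exactly ``max_len`` is retained.  Idempotent.
    """
    if max_len <= 0:
        raise ValueError("max_len must be positive")
    lengths = fs.fragments["end"] - fs.fragments["start"]
    keep = lengths <= max_len
    n_removed = int((~keep).sum())
    if n_removed:
        logger.info(
            "%s: removed %d fragments longer than %d bp", fs.sample_id, n_removed, max_len
        )
    return FragmentSet(fs.sample_id, fs.fragments.loc[keep].reset_index(drop=True))


@dataclass
class SpikeInQC:
    """Spike-in vs total read-count correlation check."""

    r: float  # Pearson r, NaN if undefined
    threshold: float
    defined: bool
    passed: bool
    n_samples: int = 0

    def as_dict(self) -> dict:
        return dict(self.__dict__)


def spikein_correlation(
    samples: pd.DataFrame | list[tuple[str, int, int]],
    threshold: float = 0.8,
) -> SpikeInQC:
    """Pearson correlation of spike-in read counts vs total read counts.

    The same amount of exogenous spike-in DNA is added to every sample, so
    spike-in reads should track total sequencing depth; a strong positive
    correlation (r >= ``threshold``) passes QC.  Zero variance in either
    vector makes the correlation undefined and fails QC.
    """
    if not isinstance(samples, pd.DataFrame):
        samples = pd.DataFrame(
            samples, columns=["sample_id", "spikein_read_count", "total_read_count"]
        )
    if len(samples) < 3:
        raise ValueError("spike-in QC needs at least 3 samples")
    x = samples["spikein_read_count"].to_numpy(dtype=float)
    y = samples["total_read_count"].to_numpy(dtype=float)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        logger.warning("spike-in correlation undefined: zero variance")
        return SpikeInQC(
            r=math.nan, threshold=threshold, defined=False, passed=False,
            n_samples=len(samples),
        )
    r = float(np.corrcoef(x, y)[0, 1])
    return SpikeInQC(
        r=r, threshold=threshold, defined=True, passed=bool(r >= threshold),
        n_samples=len(samples),
    )
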