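"""High-signal region selection and matched background for motif discovery.

Per-base-pair fragment coverage is normalized by the total fragment count
(units: fraction of total reads per bp).  Maximal runs with normalized
coverage strictly above 8.0e-7 are signal regions; adjacent regions on a
contig closer than 101 bp are merged.  For each query region one
background interval of identical length is sampled uniformly from the
genome; by default backgrounds must not overlap any query region, a
constraint this package adds to keep the control set clean (it can be
switched off).  Query and background sequences are exported as FASTA for
external motif discovery.
"""

from __future__ import annotations

from dataclasses import dataclass
from io import StringIO

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from ._rng import child_rng

DEFAULT_THRESHOLD = 8.0e-7
DEFAULT_MERGE_GAP = 101

__all__ = [
    "CoverageTrack",
    "build_coverage",
    "select_signal_regions",
    "sample_matched_background",
    "export_region_fasta",
]


@dataclass
class CoverageTrack:
    """Per-bp fragment coverage divided by total fragment count."""

    values: dict[str, np.ndarray]  # contig -> float array over every bp
    total_count: int

    def to_bedgraph(self) -> str:
        """Run-length-encoded BedGraph text (zero runs included)."""
        out = StringIO()
        for cid, vals in self.values.items():
            if len(vals) == 0:
                continue
            change = np.flatnonzero(np.diff(vals)) + 1
            starts = np.concatenate(([0], change))
            ends = np.concatenate((change, [len(vals)]))
            for s, e in zip(starts, ends):
                out.write(f"{cid}\t{s}\t{e}\t{vals[s]:.10g}\n")
        return out.getvalue()


def build_coverage(fs, genome) -> CoverageTrack:
    """coverage(b) = (#fragments overlapping bp b) / total fragment count."""
    if fs.total_count == 0:
        raise ValueError("cannot build coverage from an empty fragment set")
    n = fs.total_count
    values = {
        cid: np.zeros(length, dtype=np.float64) for cid, length in genome.contigs
    }
    for cid, block in fs.fragments.groupby("contig", sort=False):
        if cid not in values:
            continue
        length = len(values[cid])
        diff = np.zeros(length + 1, dtype=np.int64)
        s = block["start"].to_numpy().clip(0, length)
        e = block["end"].to_numpy().clip(0, length)
        np.add.at(diff, s, 1)
        np.add.at(diff, e, -1)
        values[cid] = np.cumsum(diff[:-1]) / n
    return CoverageTrack(values=values, total_count=n)


def select_signal_regions(
    cov: CoverageTrack,
    threshold: float = DEFAULT_THRESHOLD,
    merge_gap: int = DEFAULT_MERGE_GAP,
) -> pd.DataFrame:
    """Maximal runs with coverage strictly > threshold, gaps < merge_gap merged.

    Returns columns contig, start, end; per contig the output intervals are
    disjoint, sorted, and separated by >= merge_gap.
    """
    if threshold <= 0:
        raise ValueError("threshold must be > 0")
    rows: list[tuple[str, int, int]] = []
    for cid, vals in cov.values.items():
        above = vals > threshold
        if not above.any():
            continue
        # run boundaries: starts where False->True, ends where True->False
        d = np.diff(np.concatenate(([0], above.astype(np.int8), [0])))
        run_starts = np.flatnonzero(d == 1)
        run_ends = np.flatnonzero(d == -1)
        cur_s, cur_e = int(run_starts[0]), int(run_ends[0])
        for s, e in zip(run_starts[1:], run_ends[1:]):
            if s - cur_e < merge_gap:
                cur_e = int(e)
            else:
                rows.append((cid, cur_s, cur_e))
                cur_s, cur_e = int(s), int(e)
        rows.append((cid, cur_s, cur_e))
    return pd.DataFrame(rows, columns=["contig", "start", "end"])


def sample_matched_background(
    regions: pd.DataFrame,
    genome,
    seed: int,
    avoid_regions: bool = True,
    max_tries: int = 1000,
) -> pd.DataFrame:
    """One random background interval per query, with identical length.

    Placement is uniform over contigs long enough to hold the interval
    (contigs weighted by length); with ``avoid_regions`` a candidate
    overlapping any query region is rejected and redrawn.  Deterministic
    for a given seed.  Raises when a length cannot be placed within
    ``max_tries`` draws.
    """
    rng = child_rng(seed, "matched_background")
    ids = [c for c, _ in genome.contigs]
    lens = np.array([L for _, L in genome.contigs], dtype=np.int64)
    query_by_contig: dict[str, list[tuple[int, int]]] = {}
    for row in regions.itertuples(index=False):
        query_by_contig.setdefault(row.contig, []).append((row.start, row.end))

    rows = []
    for row in regions.itertuples(index=False):
        L = row.end - row.start
        eligible = lens >= L
        if not eligible.any():
            raise ValueError(f"no contig can hold a background of length {L}")
        w = np.where(eligible, lens, 0).astype(float)
        w /= w.sum()
        placed = False
        for _ in range(max_tries):
            ci = rng.choice(len(ids), p=w)
            start = int(rng.integers(0, lens[ci] - L + 1))
            end = start + L
            cid = ids[ci]
            if avoid_regions and any(
                start < qe and end > qs for qs, qe in query_by_contig.get(cid, [])
            ):
                continue
            rows.append((cid, start, end))
            placed = True
            break
        if not placed:
            raise RuntimeError(
                f"failed to place a background interval of length {L} "
                f"after {max_tries} tries"
            )
    return pd.DataFrame(rows, columns=["contig", "start", "end"])


def export_region_fasta(
    regions: pd.DataFrame, genome, path=None
) -> list[SeqRecord]:
    """One FASTA record per region, header ``contig:start-end``, uppercase."""
    if genome.sequences is None:
        raise ValueError("genome carries no sequences")
    records = []
    for row in regions.itertuples(index=False):
        seq = genome.sequences[row.contig]
        if row.end > len(seq) or row.start < 0:
            raise ValueError(
                f"region {row.contig}:{row.start}-{row.end} exceeds sequence bounds"
            )
        records.append(
            SeqRecord(
                Seq(seq[row.start : row.end].upper()),
                id=f"{row.contig}:{row.start}-{row.end}",
                description="",
            )
        )
    if path is not None:
        SeqIO.write(records, path, "fasta")
    return records
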