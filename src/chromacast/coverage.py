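"""Per-base coverage tracks from alignment records.

ATAC-seq reads are shifted +4 bp on the plus strand and −5 bp on the minus
strand before pileup, so read starts mark the centre of the Tn5 transposase
binding site. Coverage is the per-base count of read-covered positions
("reads per bp"), replicate samples are averaged into one track per dataset
kind, and — because the libraries are PCR-amplified and effectively
unstranded — the same coverage is attached to both strands of each chunk.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from chromacast.errors import DataError
from chromacast.genome import EncodedChunk

#: ATAC-seq read start shift, by strand (Tn5 dimer footprint correction).
ATAC_SHIFT = {"+": 4, "-": -5}

#: Sentinel stored at padded positions of per-chunk target arrays; always
#: excluded through the chunk's pad mask before any loss or metric.
PAD_SENTINEL = -1.0


@dataclass(frozen=True)
class ReadInterval:
    """One mapped read as a 0-based half-open genomic interval."""

    seq_id: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if not 0 <= self.start < self.end:
            raise DataError(
                f"invalid read interval [{self.start}, {self.end}) on {self.seq_id}"
            )


@dataclass
class CoverageTrack:
    """Per-base non-negative read coverage for one sequence and dataset kind."""

    seq_id: str
    kind: str
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 1:
            raise DataError("coverage values must be one-dimensional")
        if not np.all(np.isfinite(self.values)) or np.any(self.values < 0):
            raise DataError(
                f"coverage for {self.seq_id} contains negative or non-finite values"
            )


def shift_atac(read: ReadInterval) -> ReadInterval:
    """Apply the Tn5 shift: +4 bp on the plus strand, −5 bp on the minus strand.

    The whole interval moves, so read length is preserved; intervals shifted
    below zero are clipped at zero.
    """
    delta = ATAC_SHIFT.get(read.strand)
    if delta is None:
        raise DataError(f"read strand must be '+' or '-', got {read.strand!r}")
    length = read.end - read.start
    start = read.start + delta
    if start < 0:
        start = 0
    return replace(read, start=start, end=start + length)


def pileup(reads: Iterable[ReadInterval], seq_length: int) -> CoverageTrack:
    """Count, per base, how many read intervals cover it.

    Intervals are clipped to ``[0, seq_length)``. Implemented as a difference
    array + cumulative sum.
    """
    if seq_length <= 0:
        raise DataError(f"sequence length must be positive, got {seq_length}")
    diff = np.zeros(seq_length + 1, dtype=np.float64)
    seq_id = ""
    for read in reads:
        if seq_id and read.seq_id != seq_id:
            raise DataError(
                f"pileup mixes sequences {seq_id!r} and {read.seq_id!r}"
            )
        seq_id = read.seq_id
        start = max(read.start, 0)
        end = min(read.end, seq_length)
        if start < end:
            diff[start] += 1.0
            diff[end] -= 1.0
    return CoverageTrack(seq_id, "unknown", np.cumsum(diff[:-1]))


def average_samples(tracks: Sequence[CoverageTrack]) -> CoverageTrack:
    """Element-wise mean of replicate sample tracks, kept as float.

    All tracks must share sequence, kind and length; the result is the one
    coverage track per dataset kind used everywhere downstream.
    """
    if not tracks:
        raise DataError("average_samples requires at least one track")
    first = tracks[0]
    for t in tracks[1:]:
        if t.seq_id != first.seq_id or t.kind != first.kind:
            raise DataError(
                f"cannot average tracks of ({t.seq_id}, {t.kind}) with "
                f"({first.seq_id}, {first.kind})"
            )
        if t.values.shape != first.values.shape:
            raise DataError("cannot average tracks of different lengths")
    mean = np.mean(np.stack([t.values for t in tracks]), axis=0)
    return CoverageTrack(first.seq_id, first.kind, mean)


def track_to_chunks(track: CoverageTrack, chunks: Sequence[EncodedChunk]) -> np.ndarray:
    """Align a coverage track with encoded chunks, producing target arrays.

    Plus-strand chunks receive ``values[start:end]``; minus-strand chunks the
    same window reversed (coverage applies to both strands). Padded positions
    carry :data:`PAD_SENTINEL` and must be excluded via the pad mask.
    """
    n = len(track.values)
    out = np.full((len(chunks), chunks[0].matrix.shape[0] if chunks else 0),
                  PAD_SENTINEL, dtype=np.float64)
    for i, chunk in enumerate(chunks):
        if chunk.seq_id != track.seq_id:
            raise DataError(
                f"chunk sequence {chunk.seq_id!r} does not match track {track.seq_id!r}"
            )
        if chunk.end > n:
            raise DataError(
                f"chunk [{chunk.start}, {chunk.end}) exceeds track length {n}"
            )
        window = track.values[chunk.start:chunk.end]
        if chunk.strand == "+":
            out[i, : len(window)] = window
        else:
            out[i, out.shape[1] - len(window):] = window[::-1]
    return out


# ---------------------------------------------------------------------------
# Readers for the public alignment/track formats


def reads_from_bam(path: str | Path, seq_id: str) -> list[ReadInterval]:
    """Extract primary, mapped reads for one sequence from an indexed BAM.

    Upstream filtering (duplicates, QC fails) is assumed done; flags are still
    checked defensively so secondary/supplementary or unmapped records never
    reach the pileup.
    """
    import pysam

    intervals: list[ReadInterval] = []
    with pysam.AlignmentFile(str(path), "rb") as bam:
        for rec in bam.fetch(seq_id):
            if rec.is_unmapped or rec.is_secondary or rec.is_supplementary:
                continue
            intervals.append(
                ReadInterval(
                    seq_id,
                    rec.reference_start,
                    rec.reference_end,
                    "-" if rec.is_reverse else "+",
                )
            )
    return intervals


def read_bedgraph(path: str | Path, seq_lengths: dict[str, int],
                  kind: str = "unknown") -> dict[str, CoverageTrack]:
    """Read a bedGraph file into one dense per-base track per sequence.

    Positions not covered by any interval get value 0.
    """
    import io

    with open(path) as handle:
        body = "".join(
            line for line in handle
            if line.strip() and not line.startswith(("track", "browser", "#"))
        )
    try:
        df = pd.read_csv(
            io.StringIO(body), sep="\t", header=None,
            names=["seq_id", "start", "end", "value"],
            dtype={"seq_id": str, "start": np.int64, "end": np.int64, "value": np.float64},
        )
    except (ValueError, pd.errors.ParserError) as exc:
        raise DataError(f"cannot parse bedGraph {path}: {exc}") from exc
    if df.empty:
        return {}
    tracks: dict[str, CoverageTrack] = {}
    for seq_id, sub in df.groupby("seq_id", sort=False):
        if seq_id not in seq_lengths:
            raise DataError(f"bedGraph sequence {seq_id!r} has no known length")
        values = np.zeros(seq_lengths[seq_id], dtype=np.float64)
        for start, end, value in zip(sub["start"], sub["end"], sub["value"]):
            values[start:end] = value
        tracks[seq_id] = CoverageTrack(seq_id, kind, values)
    return tracks
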