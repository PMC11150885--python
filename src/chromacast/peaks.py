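"""Post-processing of per-base signal tracks: rolling-mean smoothing and a
bedGraph-level threshold peak caller (cutoff, minimum length, maximum gap).

The caller mirrors threshold-based calling on a per-base track: positions with
value ≥ cutoff form candidate runs, runs separated by at most ``max_gap``
sub-threshold positions are merged, and merged regions shorter than
``min_length`` are discarded. Merging happens before the length filter.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from chromacast.errors import DataError


@dataclass(frozen=True)
class PeakCallParams:
    """Threshold peak-calling parameters.

    ``min_length`` and ``max_gap`` correspond to the expected fragment size of
    the underlying library (e.g. 149/149 with cutoff 5 for *A. thaliana*
    ATAC-seq); the cutoff is the minimum read coverage to call a peak.
    """

    cutoff: float
    min_length: int
    max_gap: int

    def __post_init__(self) -> None:
        if self.min_length < 1:
            raise DataError(f"min_length must be ≥ 1, got {self.min_length}")
        if self.max_gap < 0:
            raise DataError(f"max_gap must be ≥ 0, got {self.max_gap}")


@dataclass(frozen=True)
class Peak:
    """A called interval (0-based half-open) with its maximum track value."""

    seq_id: str
    start: int
    end: int
    score: float


def rolling_mean(track: np.ndarray, window: int) -> np.ndarray:
    """Centred rolling mean; near the edges the mean is over the truncated
    window. Output length equals input length."""
    if window < 1:
        raise DataError(f"rolling-mean window must be ≥ 1, got {window}")
    values = np.asarray(track, dtype=np.float64)
    if window == 1:
        return values.copy()
    return (
        pd.Series(values)
        .rolling(window, center=True, min_periods=1)
        .mean()
        .to_numpy()
    )


def threshold_runs(values: np.ndarray, cutoff: float) -> list[tuple[int, int]]:
    """Maximal runs of positions with value ≥ cutoff, as half-open intervals."""
    above = np.asarray(values) >= cutoff
    if not above.any():
        return []
    padded = np.concatenate(([False], above, [False]))
    edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
    return list(zip(edges[::2], edges[1::2]))


def merge_runs(runs: list[tuple[int, int]], max_gap: int) -> list[tuple[int, int]]:
    """Merge consecutive runs separated by ≤ ``max_gap`` sub-threshold bases."""
    if not runs:
        return []
    merged = [list(runs[0])]
    for start, end in runs[1:]:
        if start - merged[-1][1] <= max_gap:
            merged[-1][1] = end
        else:
            merged.append([start, end])
    return [(s, e) for s, e in merged]


def call_peaks(
    track: np.ndarray, params: PeakCallParams, seq_id: str = ""
) -> list[Peak]:
    """Threshold peak calling: runs ≥ cutoff, gap merging, length filtering.

    Ties at exactly the cutoff are included. Returned peaks are sorted and
    non-overlapping; a peak's score is the maximum track value inside it.
    """
    values = np.asarray(track, dtype=np.float64)
    if not np.all(np.isfinite(values)):
        raise DataError("cannot call peaks on a track with non-finite values")
    runs = merge_runs(threshold_runs(values, params.cutoff), params.max_gap)
    return [
        Peak(seq_id, start, end, float(values[start:end].max()))
        for start, end in runs
        if end - start >= params.min_length
    ]


def peaks_to_mask(peaks: list[Peak], seq_length: int) -> np.ndarray:
    """Boolean track that is True exactly inside peak intervals."""
    mask = np.zeros(seq_length, dtype=bool)
    for peak in peaks:
        if peak.start < 0 or peak.end > seq_length:
            raise DataError(
                f"peak [{peak.start}, {peak.end}) outside sequence of length {seq_length}"
            )
        if mask[peak.start:peak.end].any():
            raise DataError("overlapping peaks passed to peaks_to_mask")
        mask[peak.start:peak.end] = True
    return mask


def mask_to_peaks(mask: np.ndarray, seq_id: str = "") -> list[Peak]:
    """Inverse of :func:`peaks_to_mask` (scores set to 1)."""
    return [Peak(seq_id, s, e, 1.0) for s, e in threshold_runs(mask.astype(float), 0.5)]
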