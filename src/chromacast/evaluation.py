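"""Evaluation stack: masked Pearson correlation, base-wise peak
precision/recall/F1, precision-recall curves with the fraction-of-positives
baseline, TSS meta-profiles and the 2.5× enrichment quality check.

All base-wise metrics honour a validity mask so that padded positions and
flagged (blacklisted) sequences never enter any computation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from chromacast.errors import DataError
from chromacast.peaks import PeakCallParams, call_peaks, peaks_to_mask

#: Guard added to the Pearson denominator to avoid division by zero.
PEARSON_EPS = 1e-8

#: Enrichment ratio a TSS meta-profile must reach to pass coverage QC.
QC_ENRICHMENT_RATIO = 2.5


@dataclass
class MetricsReport:
    """Summary of one model/dataset evaluation."""

    pearson_r: float
    tp: int
    fp: int
    fn: int
    precision: float
    recall: float
    f1: float
    prc: list[tuple[float, float, float]] = field(default_factory=list)
    auprc: float = float("nan")
    baseline: float = float("nan")
    poisson_loss: float = float("nan")

    def to_dict(self) -> dict:
        return {
            "pearson_r": self.pearson_r,
            "tp": self.tp, "fp": self.fp, "fn": self.fn,
            "precision": self.precision, "recall": self.recall, "f1": self.f1,
            "prc": [list(p) for p in self.prc],
            "auprc": self.auprc, "baseline": self.baseline,
            "poisson_loss": self.poisson_loss,
        }


@dataclass
class MetaProfile:
    """Mean coverage as a function of offset from a set of anchors (e.g. TSS)."""

    offsets: np.ndarray
    mean_coverage: np.ndarray


def pearson_r(x: np.ndarray, y: np.ndarray, mask: np.ndarray | None = None) -> float:
    """Pearson correlation over unmasked positions with an ε-guarded denominator.

        r = Σ(x−x̄)(y−ȳ) / (√(Σ(x−x̄)² · Σ(y−ȳ)²) + ε),   ε = 1e-8

    The guard makes the result 0 (not NaN) when either input is constant.
    """
    x = np.asarray(x, dtype=np.float64).ravel()
    y = np.asarray(y, dtype=np.float64).ravel()
    if x.shape != y.shape:
        raise DataError(f"shape mismatch: {x.shape} vs {y.shape}")
    if mask is not None:
        mask = np.asarray(mask, dtype=bool).ravel()
        x, y = x[mask], y[mask]
    if x.size < 2:
        raise DataError(f"need at least 2 unmasked positions, got {x.size}")
    dx = x - x.mean()
    dy = y - y.mean()
    return float(np.dot(dx, dy) / (np.sqrt(np.dot(dx, dx) * np.dot(dy, dy)) + PEARSON_EPS))


def base_confusion(
    pred_mask: np.ndarray, exp_mask: np.ndarray, valid_mask: np.ndarray | None = None
) -> tuple[int, int, int]:
    """Base-wise confusion counts (TP, FP, FN) between peak masks.

    Only positions where ``valid_mask`` is True are counted, so flagged
    sequences and padding are excluded.
    """
    pred = np.asarray(pred_mask, dtype=bool).ravel()
    exp = np.asarray(exp_mask, dtype=bool).ravel()
    if pred.shape != exp.shape:
        raise DataError(f"shape mismatch: {pred.shape} vs {exp.shape}")
    if valid_mask is None:
        valid = np.ones_like(pred)
    else:
        valid = np.asarray(valid_mask, dtype=bool).ravel()
        if valid.shape != pred.shape:
            raise DataError("valid_mask shape mismatch")
    tp = int(np.sum(pred & exp & valid))
    fp = int(np.sum(pred & ~exp & valid))
    fn = int(np.sum(~pred & exp & valid))
    return tp, fp, fn


def prf1(tp: int, fp: int, fn: int) -> tuple[float, float, float]:
    """Precision, recall and F1 from confusion counts; 0 on zero denominators."""
    if min(tp, fp, fn) < 0:
        raise DataError("confusion counts must be non-negative")
    precision = tp / (tp + fp) if tp + fp > 0 else 0.0
    recall = tp / (tp + fn) if tp + fn > 0 else 0.0
    f1 = (
        2.0 * precision * recall / (precision + recall)
        if precision + recall > 0
        else 0.0
    )
    return precision, recall, f1


def pr_curve(
    rate_track: np.ndarray,
    exp_mask: np.ndarray,
    cutoffs: np.ndarray,
    peak_params: PeakCallParams,
    valid_mask: np.ndarray | None = None,
) -> tuple[list[tuple[float, float, float]], float]:
    """Precision-recall curve from a cutoff sweep of the threshold peak caller.

    For every cutoff, peaks are called with the given ``min_length``/``max_gap``
    and compared base-wise to the experimental peak mask. Returns the list of
    ``(recall, precision, cutoff)`` points (cutoffs strictly increasing) and
    the AUPRC, integrated with the trapezoid rule over recall-sorted points.
    """
    cutoffs = np.asarray(cutoffs, dtype=np.float64)
    if cutoffs.size == 0:
        raise DataError("cutoff grid is empty")
    if np.any(np.diff(cutoffs) <= 0):
        raise DataError("cutoffs must be strictly increasing")
    track = np.asarray(rate_track, dtype=np.float64)
    points: list[tuple[float, float, float]] = []
    for cutoff in cutoffs:
        params = PeakCallParams(float(cutoff), peak_params.min_length, peak_params.max_gap)
        mask = peaks_to_mask(call_peaks(track, params), len(track))
        precision, recall, _ = prf1(*base_confusion(mask, exp_mask, valid_mask))
        points.append((recall, precision, float(cutoff)))
    recalls = np.array([p[0] for p in points])
    precisions = np.array([p[1] for p in points])
    order = np.argsort(recalls, kind="stable")
    auprc = float(np.trapezoid(precisions[order], recalls[order]))
    return points, auprc


def baseline_auprc(exp_mask: np.ndarray, valid_mask: np.ndarray | None = None) -> float:
    """Fraction of positive (peak) bases among valid positions.

    This is the expected AUPRC of an uninformative predictor and the reference
    any model must beat.
    """
    exp = np.asarray(exp_mask, dtype=bool).ravel()
    valid = (
        np.ones_like(exp) if valid_mask is None
        else np.asarray(valid_mask, dtype=bool).ravel()
    )
    n_valid = int(valid.sum())
    if n_valid == 0:
        raise DataError("no valid positions for baseline AUPRC")
    return float(np.sum(exp & valid) / n_valid)


def meta_profile(
    track: np.ndarray,
    anchors,
    W: int = 3000,
) -> MetaProfile:
    """Mean coverage at each offset in ``[−W, +W]`` around a set of anchors.

    ``anchors`` is a sequence of positions or ``(position, strand)`` pairs;
    minus-strand anchors read their window right-to-left so that positive
    offsets always point downstream. Windows truncated by sequence ends
    contribute only their available positions.
    """
    values = np.asarray(track, dtype=np.float64)
    pairs = [(a, "+") if np.isscalar(a) else (int(a[0]), a[1]) for a in anchors]
    if not pairs:
        raise DataError("meta_profile requires at least one anchor")
    width = 2 * W + 1
    acc = np.zeros(width)
    count = np.zeros(width)
    n = len(values)
    for pos, strand in pairs:
        lo, hi = pos - W, pos + W + 1
        src_lo, src_hi = max(lo, 0), min(hi, n)
        if src_lo >= src_hi:
            continue
        window = np.full(width, np.nan)
        window[src_lo - lo: src_hi - lo] = values[src_lo:src_hi]
        if strand == "-":
            window = window[::-1]
        ok = ~np.isnan(window)
        acc[ok] += window[ok]
        count[ok] += 1
    if not count.any():
        raise DataError("no anchor window overlaps the track")
    mean = np.full(width, np.nan)
    mean[count > 0] = acc[count > 0] / count[count > 0]
    return MetaProfile(np.arange(-W, W + 1), mean)


def qc_enrichment(profile: MetaProfile) -> tuple[float, bool]:
    """TSS enrichment QC: peak-to-background ratio of a meta-profile.

    Background is the median over the two outermost 25% flanks of the window;
    the check passes when ``max(profile) / background ≥ 2.5``. A zero
    background yields an infinite ratio (pass).
    """
    cov = np.asarray(profile.mean_coverage, dtype=np.float64)
    cov = cov[~np.isnan(cov)]
    if cov.size == 0:
        raise DataError("empty meta-profile")
    quarter = max(1, cov.size // 4)
    background = float(np.median(np.concatenate([cov[:quarter], cov[-quarter:]])))
    peak = float(np.max(cov))
    if background == 0.0:
        return float("inf"), True
    ratio = peak / background
    return ratio, ratio >= QC_ENRICHMENT_RATIO


def make_report(
    rates: np.ndarray,
    target: np.ndarray,
    exp_mask: np.ndarray,
    peak_params: PeakCallParams,
    cutoffs: np.ndarray | None = None,
    valid_mask: np.ndarray | None = None,
) -> MetricsReport:
    """Assemble the full metrics report for one predicted track."""
    from chromacast.training import poisson_loss

    pred_mask = peaks_to_mask(call_peaks(np.asarray(rates, float), peak_params), len(rates))
    tp, fp, fn = base_confusion(pred_mask, exp_mask, valid_mask)
    precision, recall, f1 = prf1(tp, fp, fn)
    valid = (
        np.ones(len(rates), dtype=bool) if valid_mask is None
        else np.asarray(valid_mask, dtype=bool)
    )
    report = MetricsReport(
        pearson_r=pearson_r(rates, target, valid),
        tp=tp, fp=fp, fn=fn,
        precision=precision, recall=recall, f1=f1,
    )
    with np.errstate(divide="ignore"):
        log_rates = np.log(np.clip(np.asarray(rates, float), 1e-12, None))
    report.poisson_loss = poisson_loss(log_rates, np.asarray(target, float), valid)
    report.baseline = baseline_auprc(exp_mask, valid_mask)
    if cutoffs is not None:
        report.prc, report.auprc = pr_curve(
            rates, exp_mask, cutoffs, peak_params, valid_mask
        )
    return report
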