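"""Validation machinery: coverage tracks, correlations, Poisson site
calling, precision-recall, false-negative rates and meta-profiles.

Experimental ChIP-seq coverage (extended-read pile-up) is the reference
the sequence-based occupation probabilities are judged against; all
statistics respect the mappability mask of the tracks involved.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .genome_io import MappedRead, Region, RegionSet, TrackArray
from .specificity import extend_read

logger = logging.getLogger(__name__)

DEFAULT_CUTOFFS = tuple(np.round(np.arange(0.1, 1.0, 0.1), 10))


@dataclass
class PRCurve:
    """Base-pair-resolution precision/recall at a set of probability cutoffs."""

    cutoffs: np.ndarray
    precision: np.ndarray  # NaN where no bases were predicted
    recall: np.ndarray
    n_positive_bases: int

    def __post_init__(self) -> None:
        self.cutoffs = np.asarray(self.cutoffs, dtype=float)
        self.precision = np.asarray(self.precision, dtype=float)
        self.recall = np.asarray(self.recall, dtype=float)

    def at(self, cutoff: float) -> tuple[float, float]:
        i = int(np.argmin(np.abs(self.cutoffs - cutoff)))
        return float(self.precision[i]), float(self.recall[i])


def coverage_track(
    reads: Sequence[MappedRead], chrom: str, chrom_len: int, ext: int = 151
) -> TrackArray:
    """Extended-read pile-up: values[t] = number of extended reads covering t."""
    diff = np.zeros(chrom_len + 1)
    for r in reads:
        if r.chrom != chrom:
            continue
        s, e = extend_read(r, chrom_len, ext)
        if s < e:
            diff[s] += 1
            diff[e] -= 1
    return TrackArray(chrom, np.cumsum(diff[:-1]))


def track_correlation(a: TrackArray, b: TrackArray) -> float:
    """Pearson correlation over jointly unmasked bases."""
    if len(a) != len(b):
        raise ValueError("tracks must have equal length")
    ok = a.mask & b.mask
    if ok.sum() < 2:
        raise ValueError("fewer than 2 jointly unmasked bases")
    x, y = a.values[ok], b.values[ok]
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance in a track")
    return float(np.corrcoef(x, y)[0, 1])


def call_enriched_sites(
    coverage: TrackArray,
    p_threshold: float = 1e-5,
    min_len: int = 1,
) -> RegionSet:
    """Poisson enrichment calling against the genome-wide mean rate.

    lambda is the mean coverage over unmasked bases; a base is enriched
    when the upper-tail probability P(X >= observed; lambda) falls below
    ``p_threshold``. Maximal enriched runs of at least ``min_len`` bases
    become regions.
    """
    ok = coverage.mask
    if not ok.any():
        raise ValueError("all bases masked")
    lam = float(coverage.values[ok].mean())
    # P(X >= x) = sf(x - 1); non-integer coverage is conservatively floored
    x = np.floor(coverage.values).astype(np.int64)
    pvals = stats.poisson.sf(x - 1, lam)
    enriched = (pvals < p_threshold) & ok
    recs = []
    for s, e in _runs(enriched):
        if e - s >= min_len:
            recs.append(Region(coverage.chrom, s, e, ".", "enriched"))
    return RegionSet(recs)


def _runs(flags: np.ndarray) -> list[tuple[int, int]]:
    padded = np.concatenate(([False], flags, [False])).astype(np.int8)
    d = np.diff(padded)
    return list(zip(np.flatnonzero(d == 1).tolist(), np.flatnonzero(d == -1).tolist()))


def precision_recall(
    prob: TrackArray,
    truth: RegionSet,
    cutoffs: Sequence[float] = DEFAULT_CUTOFFS,
    resolution: str = "base",
) -> PRCurve:
    """Precision/recall of thresholded probability against a truth region set.

    ``resolution='base'`` counts individual unmasked bases (the finest
    reading of per-bp tracks); ``'region'`` counts called regions
    (a predicted run is a TP if it overlaps truth, a truth region is
    recalled if overlapped by any prediction).
    """
    cutoffs = np.asarray(cutoffs, dtype=float)
    truth_mask = truth.to_mask(prob.chrom, len(prob))
    ok = prob.mask
    n_pos = int((truth_mask & ok).sum())
    precision = np.full(cutoffs.size, np.nan)
    recall = np.zeros(cutoffs.size)
    any_pred = False
    for i, c in enumerate(cutoffs):
        pred = (prob.values >= c) & ok
        if resolution == "base":
            tp = int((pred & truth_mask).sum())
            npred = int(pred.sum())
            if npred > 0:
                any_pred = True
                precision[i] = tp / npred
            recall[i] = tp / n_pos if n_pos else 0.0
        elif resolution == "region":
            pred_runs = _runs(pred)
            if pred_runs:
                any_pred = True
                hits = sum(1 for s, e in pred_runs if truth_mask[s:e].any())
                precision[i] = hits / len(pred_runs)
            recalled = sum(
                1
                for r in truth.for_chrom(prob.chrom)
                if pred[max(0, r.start) : r.end].any()
            )
            n_truth = len(truth.for_chrom(prob.chrom))
            recall[i] = recalled / n_truth if n_truth else 0.0
        else:
            raise ValueError(f"unknown resolution {resolution!r}")
    if n_pos == 0 and not any_pred:
        raise ValueError("empty truth and no predictions at any cutoff")
    return PRCurve(cutoffs, precision, recall, n_pos)


def false_negative_rate(
    prob: TrackArray,
    coverage: TrackArray,
    elements: RegionSet,
    low_prob: float = 1e-5,
    top_frac: float = 0.001,
    window: int = 200,
) -> dict[str, float]:
    """Per-element-class rate of high experimental occupancy at low predicted
    probability.

    Each element span is tiled into ``window``-bp windows. A window is
    low-probability if its mean predicted probability is below
    ``low_prob`` and high-occupancy if its mean coverage exceeds the
    genome-wide ``top_frac`` upper coverage quantile (ties included).
    The rate per label is |high-occ AND low-prob| / |low-prob|; labels
    with no low-prob window report NaN with a warning.
    """
    if len(elements) == 0:
        raise ValueError("empty element set")
    ok = coverage.mask
    if not ok.any():
        raise ValueError("all bases masked")
    thresh = float(np.quantile(coverage.values[ok], 1.0 - top_frac))
    out: dict[str, float] = {}
    for label in elements.labels():
        n_low = 0
        n_low_high = 0
        for r in elements:
            if r.label != label or r.chrom != prob.chrom:
                continue
            for s in range(r.start, r.end, window):
                e = min(s + window, r.end, len(prob))
                if s >= e:
                    continue
                m = prob.mask[s:e] & coverage.mask[s:e]
                if not m.any():
                    continue
                if float(prob.values[s:e][m].mean()) < low_prob:
                    n_low += 1
                    if float(coverage.values[s:e][m].mean()) >= thresh:
                        n_low_high += 1
        if n_low == 0:
            logger.warning("no low-probability windows for element label %r", label)
            out[label] = float("nan")
        else:
            out[label] = n_low_high / n_low
    return out


def meta_profile(
    track: TrackArray, anchors: RegionSet, flank: int
) -> tuple[np.ndarray, np.ndarray, float]:
    """Mean track value at each offset in [-flank, +flank] across anchors.

    Anchors are collapsed to their start positions ('+'/'.') or end-1
    ('-'); '-' anchors contribute with the offset axis flipped. Masked
    bases drop out per offset. Returns (offsets, mean profile, genome-wide
    mean over unmasked bases).
    """
    n_off = 2 * flank + 1
    acc = np.zeros(n_off)
    cnt = np.zeros(n_off)
    used = 0
    for r in anchors.for_chrom(track.chrom):
        if r.strand == "-":
            center = r.end - 1
        else:
            center = r.start
        lo, hi = center - flank, center + flank + 1
        s, e = max(0, lo), min(len(track), hi)
        if s >= e:
            continue
        used += 1
        vals = track.values[s:e]
        m = track.mask[s:e]
        idx = np.arange(s - lo, s - lo + (e - s))
        if r.strand == "-":
            idx = n_off - 1 - idx
        acc[idx[m]] += vals[m]
        cnt[idx[m]] += 1
    if used == 0:
        raise ValueError("all anchors out of range")
    mean = np.divide(acc, cnt, out=np.full(n_off, np.nan), where=cnt > 0)
    genome_mean = float(track.values[track.mask].mean())
    return np.arange(-flank, flank + 1), mean, genome_mean
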