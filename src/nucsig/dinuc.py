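"""Position-specific dinucleotide profiles around nucleosome centers.

Nucleosomal DNA shows an ~10-bp periodicity of certain dinucleotides
(the helical repeat): AA/TT-type steps favor the rotational setting of
DNA bent around the histone octamer. These profiles quantify that
periodicity per dinucleotide and compare states (e.g. H3K4me3 vs H3)
with a paired t-test over positions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

from ._kmers import encode_bases, kmer_to_index, revcomp, window_codes
from .genome_io import GenomeSequence, RegionSet

logger = logging.getLogger(__name__)

# The ten pooled panel labels: reverse-complement pairs pooled, the four
# self-complementary dimers kept alone.
POOLED_LABELS = ["AA/TT", "CC/GG", "AG/CT", "AC/GT", "CA/TG", "GA/TC", "AT", "TA", "CG", "GC"]
ALL_DINUCS = [a + b for a in "ACGT" for b in "ACGT"]


def _pool_members(label: str) -> list[str]:
    return label.split("/")


@dataclass
class PositionalProfile:
    """Frequency of one dinucleotide (or pooled pair) per offset from center."""

    dinucleotide: str
    positions: np.ndarray  # offsets -H..+H
    values: np.ndarray  # frequency per offset, in [0, 1]
    window: int
    denominators: np.ndarray | None = None  # dinucleotide totals per offset

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=int)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.size != self.positions.size:
            raise ValueError("positions/values length mismatch")


def positional_dinuc_profile(
    genomes: list[GenomeSequence],
    centers: RegionSet,
    halfwidth: int = 73,
    window: int = 3,
    pool_revcomp: bool = True,
) -> list[PositionalProfile]:
    """Dinucleotide frequency at each offset from site centers, in w-bp windows.

    The midpoint of each region is the center; '-'-strand sites are read
    on the reverse-complement strand (offset axis flipped, dimers
    complemented). At offset p, the frequency of dimer X is the count of
    X-dimers starting inside the length-``window`` window centered at p,
    summed over sites, divided by all valid dimers in those windows.
    Dimers containing N are excluded from numerator and denominator; sites
    too close to a chromosome edge are skipped (count logged).
    """
    if halfwidth < window:
        raise ValueError("halfwidth must be >= window")
    if len(centers) == 0:
        raise ValueError("no center sites given")
    seqs = {g.name: g.seq for g in genomes}
    H = halfwidth
    n_off = 2 * H + 1
    counts2d = np.zeros((16, n_off))  # dimer code x offset
    skipped = 0
    # dimer-start offsets contributing to offset p: window centered at p
    wlo = -(window // 2)
    whi = window - 1 + wlo  # inclusive
    off_idx = np.arange(n_off)
    for r in centers:
        seq = seqs.get(r.chrom)
        if seq is None:
            skipped += 1
            continue
        mid = (r.start + r.end) // 2
        lo = mid - H + wlo
        hi = mid + H + whi + 2  # dimer at the last start needs one extra base
        if lo < 0 or hi > len(seq):
            skipped += 1
            continue
        sub = seq[lo:hi]
        if r.strand == "-":
            sub = revcomp(sub)
        codes = window_codes(encode_bases(sub), 2)  # -1 where the dimer has N
        for dw in range(window):
            sl = codes[dw : dw + n_off]
            ok = sl >= 0
            np.add.at(counts2d, (sl[ok], off_idx[ok]), 1)
    if skipped:
        logger.warning("%d sites skipped (edge-adjacent or unknown chromosome)", skipped)
    totals = counts2d.sum(axis=0)
    if totals.max() == 0:
        raise ValueError("all sites skipped; no dinucleotides counted")
    positions = np.arange(-H, H + 1)
    safe = np.where(totals > 0, totals, 1.0)
    out = []
    labels = POOLED_LABELS if pool_revcomp else ALL_DINUCS
    for label in labels:
        num = sum(counts2d[kmer_to_index(m)] for m in _pool_members(label))
        out.append(
            PositionalProfile(label, positions, num / safe, window, denominators=totals)
        )
    return out


def periodicity_power(profile: PositionalProfile, period: float = 10.0) -> float:
    """Fraction of detrended profile variance at the given period.

    The profile is mean- and linear-trend-removed, then the squared DFT
    amplitude in the frequency bin nearest 1/period is divided by the
    total squared amplitude over all nonzero frequencies.
    """
    x = np.asarray(profile.values, dtype=float)
    n = x.size
    if n < 2 * period:
        raise ValueError("profile too short for the requested period")
    t = np.arange(n)
    coef = np.polyfit(t, x, 1)
    x = x - np.polyval(coef, t)
    if np.allclose(x, 0):
        return 0.0
    spec = np.abs(np.fft.rfft(x)) ** 2
    spec[0] = 0.0
    freqs = np.fft.rfftfreq(n)
    k = int(np.argmin(np.abs(freqs - 1.0 / period)))
    total = spec.sum()
    return float(spec[k] / total) if total > 0 else 0.0


def compare_profiles_paired(
    a: PositionalProfile, b: PositionalProfile
) -> tuple[float, float]:
    """Paired t-test of a.values - b.values over offsets -> (t, two-sided p).

    Zero-variance differences are handled explicitly: identical profiles
    give (0, 1); a constant nonzero shift gives (+/-inf, 0).
    """
    if a.values.size != b.values.size or not np.array_equal(a.positions, b.positions):
        raise ValueError("profiles must share offsets")
    if a.values.size < 3:
        raise ValueError("need at least 3 offsets")
    diff = a.values - b.values
    if np.ptp(diff) == 0:
        if diff[0] == 0:
            return 0.0, 1.0
        return (math_inf if diff[0] > 0 else -math_inf), 0.0
    t, p = stats.ttest_rel(a.values, b.values)
    return float(t), float(p)


math_inf = float("inf")
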