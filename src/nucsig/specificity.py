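"""State-specific k-mer sequence specificities and HMM emission tables.

ChIP-seq reads are extended to nucleosome-sized intervals (151 bp by
default), the k-mer content of those intervals is counted, and the
resulting frequencies are normalized by the genome's own k-mer composition
to give per-state enrichments. 6-mer counts are also converted into
conditional base-given-5-mer-context emission tables for the occupancy
HMM.

Overlapping read intervals are counted per read, never merged: pile-up
depth is the enrichment signal. Windows containing N are skipped entirely.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from ._kmers import (
    all_kmers,
    encode_bases,
    index_to_kmer,
    kmer_to_index,
    revcomp_permutation,
    window_codes,
)
from .genome_io import GenomeSequence, MappedRead, Region, RegionSet

N_CONTEXTS = 4**5  # 1024 five-base contexts of the order-5 emission model


@dataclass
class KmerCounts:
    """Dense counts over all 4^k k-mers."""

    k: int
    counts: np.ndarray

    def __post_init__(self) -> None:
        if not 1 <= self.k <= 6:
            raise ValueError(f"k must be in [1, 6], got {self.k}")
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.shape != (4**self.k,):
            raise ValueError(f"counts must have 4^{self.k} entries")

    @property
    def total(self) -> float:
        return float(self.counts.sum())

    def __getitem__(self, kmer: str) -> float:
        return float(self.counts[kmer_to_index(kmer)])

    def __add__(self, other: "KmerCounts") -> "KmerCounts":
        if self.k != other.k:
            raise ValueError("mismatched k")
        return KmerCounts(self.k, self.counts + other.counts)

    def as_dict(self) -> dict[str, float]:
        return {index_to_kmer(i, self.k): float(c) for i, c in enumerate(self.counts)}


@dataclass
class KmerSpecificity:
    """Read-derived k-mer frequency divided by genome frequency, per state."""

    state: str
    k: int
    enrichment: np.ndarray
    pseudocount: float
    genome_freq: np.ndarray

    def __post_init__(self) -> None:
        self.enrichment = np.asarray(self.enrichment, dtype=float)
        self.genome_freq = np.asarray(self.genome_freq, dtype=float)
        if not np.all(np.isfinite(self.enrichment)) or np.any(self.enrichment <= 0):
            raise ValueError("enrichment values must be finite and positive")

    def __getitem__(self, kmer: str) -> float:
        return float(self.enrichment[kmer_to_index(kmer)])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "kmer": all_kmers(self.k),
                "genome_freq": self.genome_freq,
                "enrichment": self.enrichment,
            }
        )


@dataclass
class EmissionModel:
    """Fifth-order emission table: P(next base | preceding 5-mer context).

    ``table[c, b]`` is the probability that base ``b`` follows context
    ``c`` (contexts encoded as base-4 integers, most significant first).
    ``context_weights`` carries the empirical 5-mer context counts when the
    model was estimated from data; they weight the marginalization used to
    build the truncated lower-order tables applied at the first bases of a
    run, where fewer than five preceding bases exist.
    """

    state: str
    table: np.ndarray
    context_weights: np.ndarray | None = None
    order: int = 5
    _lower: list[np.ndarray] | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.table = np.asarray(self.table, dtype=float)
        if self.table.shape != (N_CONTEXTS, 4):
            raise ValueError("emission table must be (1024, 4)")
        rows = self.table.sum(axis=1)
        if not np.allclose(rows, 1.0, atol=1e-9):
            raise ValueError("every context row must sum to 1")
        if self.context_weights is not None:
            self.context_weights = np.asarray(self.context_weights, dtype=float)

    def lower_order_tables(self) -> list[np.ndarray]:
        """Tables for context orders 0..5 (order-o table has shape (4^o, 4)).

        Order o < 5 marginalizes the full table over all contexts whose last
        o bases match, weighted by ``context_weights`` (uniform if absent).
        """
        if self._lower is None:
            w = self.context_weights
            if w is None:
                w = np.ones(N_CONTEXTS)
            w = w + 1e-12  # guard all-zero weights
            tables: list[np.ndarray] = []
            joint = self.table * w[:, None]  # unnormalized P(context, base)
            for o in range(6):
                if o == 5:
                    tables.append(self.table)
                    continue
                # contexts sharing the last o bases share (code mod 4^o)
                sub = joint.reshape(4 ** (5 - o), 4**o, 4).sum(axis=0)
                tables.append(sub / sub.sum(axis=1, keepdims=True))
            self._lower = tables
        return self._lower

    def prob(self, context: str, base: str) -> float:
        """Emission probability for an explicit (possibly short) context."""
        o = len(context)
        if o > 5:
            context = context[-5:]
            o = 5
        t = self.lower_order_tables()[o]
        ci = kmer_to_index(context) if o else 0
        return float(t[ci, kmer_to_index(base)])

    def to_frame(self) -> pd.DataFrame:
        ctx = np.repeat(all_kmers(5), 4)
        base = list("ACGT") * N_CONTEXTS
        return pd.DataFrame(
            {"context": ctx, "base": base, "probability": self.table.ravel()}
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame, state: str = "unknown") -> "EmissionModel":
        table = np.zeros((N_CONTEXTS, 4))
        ci = df["context"].map(kmer_to_index).to_numpy()
        bi = df["base"].map(kmer_to_index).to_numpy()
        table[ci, bi] = df["probability"].to_numpy()
        return cls(state, table)


def write_emission_tsv(model: EmissionModel, path: str | Path) -> None:
    model.to_frame().to_csv(path, sep="\t", index=False)


def read_emission_tsv(path: str | Path, state: str = "unknown") -> EmissionModel:
    return EmissionModel.from_frame(pd.read_csv(path, sep="\t"), state=state)


# ---------------------------------------------------------------------------
# read extension and counting


def extend_read(read: MappedRead, chrom_len: int, ext: int = 151) -> tuple[int, int]:
    """Interval covered by extending the read toward its 3' end to ``ext`` bp.

    '+' strand: [pos5, pos5+ext); '-' strand: [pos5-ext+1, pos5+1);
    clipped to the chromosome.
    """
    if ext < 1:
        raise ValueError("ext must be >= 1")
    if read.strand == "+":
        start, end = read.pos5, read.pos5 + ext
    else:
        start, end = read.pos5 - ext + 1, read.pos5 + 1
    return max(0, start), min(chrom_len, end)


def _interval_weights(
    length: int, intervals: Iterable[tuple[int, int]], k: int
) -> np.ndarray:
    """How many intervals fully contain the k-window starting at each position."""
    n_win = length - k + 1
    if n_win <= 0:
        return np.empty(0)
    diff = np.zeros(n_win + 1)
    for s, e in intervals:
        lo, hi = max(0, s), min(n_win, e - k + 1)
        if lo < hi:
            diff[lo] += 1
            diff[hi] -= 1
    return np.cumsum(diff[:-1])


def count_kmers(
    genome: GenomeSequence,
    k: int,
    intervals: RegionSet | Sequence[tuple[int, int]] | None = None,
    both_strands: bool = True,
) -> KmerCounts:
    """Count k-mers in windows fully contained in the given intervals.

    ``intervals=None`` counts the whole sequence once. Overlapping
    intervals each contribute independently (read-depth semantics);
    windows containing N never count. With ``both_strands`` every window
    also contributes its reverse complement.
    """
    if not 1 <= k <= 6:
        raise ValueError(f"k must be in [1, 6], got {k}")
    codes = window_codes(encode_bases(genome.seq), k)
    if intervals is None:
        ivs: list[tuple[int, int]] = [(0, genome.length)]
    elif isinstance(intervals, RegionSet):
        ivs = [(r.start, r.end) for r in intervals.for_chrom(genome.name)]
    else:
        ivs = [(s, e) for s, e in intervals]
    w = _interval_weights(genome.length, ivs, k)
    counts = np.zeros(4**k)
    valid = codes >= 0
    if codes.size:
        np.add.at(counts, codes[valid], w[valid])
    if both_strands:
        counts = counts + counts[revcomp_permutation(k)]
    return KmerCounts(k, counts)


def count_read_kmers(
    genomes: Sequence[GenomeSequence],
    reads: Sequence[MappedRead],
    k: int = 6,
    ext: int = 151,
    both_strands: bool = True,
    restrict: RegionSet | None = None,
    exclude: bool = False,
) -> KmerCounts:
    """Extend each read and count k-mers over the extended intervals.

    ``restrict`` intersects each read interval with a region set before
    counting (or excludes the region set when ``exclude`` is True),
    supporting region-stratified specificity estimates.
    """
    total = KmerCounts(k, np.zeros(4**k))
    by_chrom: dict[str, list[MappedRead]] = {}
    for r in reads:
        by_chrom.setdefault(r.chrom, []).append(r)
    for g in genomes:
        rs = by_chrom.get(g.name, [])
        ivs = [extend_read(r, g.length, ext) for r in rs]
        ivs = [(s, e) for s, e in ivs if s < e]
        if restrict is not None:
            region_mask = restrict.to_mask(g.name, g.length)
            if exclude:
                region_mask = ~region_mask
            ivs = _clip_to_mask(ivs, region_mask)
        total = total + count_kmers(g, k, ivs, both_strands=both_strands)
    return total


def _clip_to_mask(
    ivs: Sequence[tuple[int, int]], mask: np.ndarray
) -> list[tuple[int, int]]:
    """Intersect intervals with True runs of a boolean mask."""
    out: list[tuple[int, int]] = []
    for s, e in ivs:
        t = s
        while t < e:
            if mask[t]:
                u = t
                while u < e and mask[u]:
                    u += 1
                out.append((t, u))
                t = u
            else:
                t += 1
    return out


# ---------------------------------------------------------------------------
# specificity and emissions


def kmer_specificity(
    state_counts: KmerCounts,
    genome_counts: KmerCounts,
    pseudocount: float = 0.5,
    state: str = "state",
) -> KmerSpecificity:
    """Per-k-mer enrichment: pseudocounted state frequency / genome frequency.

    The result is rescaled so that the genome-frequency-weighted mean
    enrichment is exactly 1.
    """
    if state_counts.k != genome_counts.k:
        raise ValueError("mismatched k between state and genome counts")
    if genome_counts.total <= 0:
        raise ValueError("genome counts are empty")
    k = state_counts.k
    nk = 4**k
    sf = (state_counts.counts + pseudocount) / (state_counts.total + pseudocount * nk)
    gf = (genome_counts.counts + pseudocount) / (genome_counts.total + pseudocount * nk)
    enr = sf / gf
    enr = enr / float(np.dot(gf, enr))  # exact weighted-mean-1 normalization
    return KmerSpecificity(state, k, enr, pseudocount, gf)


def emission_from_counts(
    state_counts: KmerCounts, pseudocount: float = 0.5, state: str = "state"
) -> EmissionModel:
    """Conditional base-given-context probabilities from 6-mer counts."""
    if state_counts.k != 6:
        raise ValueError("emission tables require 6-mer counts")
    joint = state_counts.counts.reshape(N_CONTEXTS, 4) + pseudocount
    table = joint / joint.sum(axis=1, keepdims=True)
    ctx_weights = state_counts.counts.reshape(N_CONTEXTS, 4).sum(axis=1)
    return EmissionModel(state, table, context_weights=ctx_weights)


def background_emission(
    genomes: Sequence[GenomeSequence],
    pseudocount: float = 0.5,
    both_strands: bool = True,
) -> EmissionModel:
    """Whole-genome emission model: the nucleosome-free state's sequence model."""
    if not genomes:
        raise ValueError("empty genome")
    total = KmerCounts(6, np.zeros(4**6))
    for g in genomes:
        total = total + count_kmers(g, 6, both_strands=both_strands)
    if total.total <= 0:
        raise ValueError("genome contains fewer than 6 consecutive valid bases")
    return emission_from_counts(total, pseudocount, state="background")


def specificity_correlation(a: KmerSpecificity, b: KmerSpecificity) -> float:
    """Pearson correlation of two enrichment vectors over all 4^k k-mers."""
    if a.k != b.k:
        raise ValueError("mismatched k")
    if np.std(a.enrichment) == 0 or np.std(b.enrichment) == 0:
        raise ValueError("degenerate specificity: zero variance")
    return float(np.corrcoef(a.enrichment, b.enrichment)[0, 1])


def positional_kmer_specificity(
    genomes: Sequence[GenomeSequence],
    reads: Sequence[MappedRead],
    genome_counts: KmerCounts,
    regions: RegionSet,
    k: int = 6,
    ext: int = 151,
    pseudocount: float = 0.5,
    exclude: bool = False,
    state: str = "state",
) -> KmerSpecificity:
    """Specificity restricted to (or excluding) a region set.

    Read intervals are intersected with the regions before counting; used
    to compare, e.g., promoter vs non-promoter sequence preferences.
    """
    if len(regions) == 0:
        raise ValueError("empty region set")
    counts = count_read_kmers(
        genomes, reads, k=k, ext=ext, restrict=regions, exclude=exclude
    )
    if counts.total == 0:
        raise ValueError("no read sequence intersects the region set")
    return kmer_specificity(counts, genome_counts, pseudocount, state=state)


def write_specificity_tsv(
    spec: KmerSpecificity,
    state_counts: KmerCounts,
    genome_counts: KmerCounts,
    path: str | Path,
) -> None:
    df = pd.DataFrame(
        {
            "kmer": all_kmers(spec.k),
            "state_count": state_counts.counts,
            "genome_count": genome_counts.counts,
            "enrichment": spec.enrichment,
        }
    )
    df.to_csv(path, sep="\t", index=False)
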