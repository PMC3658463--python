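"""I/O for the standard formats the tool touches: FASTA, BED6, bedGraph, TSV.

All coordinates are 0-based, half-open, everywhere. BED and bedGraph are
native to that convention; no 1-based arithmetic appears outside log
messages.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, NamedTuple

import numpy as np
from Bio import SeqIO

logger = logging.getLogger(__name__)

_ALLOWED = set("ACGTN")


@dataclass
class GenomeSequence:
    """A named chromosome sequence over the alphabet {A,C,G,T,N}."""

    name: str
    seq: str

    def __post_init__(self) -> None:
        bad = set(self.seq) - _ALLOWED
        if bad:
            raise ValueError(f"invalid characters in {self.name}: {sorted(bad)}")

    @property
    def length(self) -> int:
        return len(self.seq)

    def __len__(self) -> int:
        return len(self.seq)


class MappedRead(NamedTuple):
    """A uniquely mapped ChIP-seq read: 5' end position and strand."""

    chrom: str
    pos5: int
    strand: str


class Region(NamedTuple):
    chrom: str
    start: int
    end: int
    strand: str
    label: str


@dataclass
class RegionSet:
    """Strand-aware genomic intervals (anchors, truth sets, masks).

    Records are normalized to sorted order by (chrom, start, end) on
    construction. Coordinates are 0-based half-open; strand is one of
    ``+``, ``-``, ``.``.
    """

    records: list[Region] = field(default_factory=list)

    def __post_init__(self) -> None:
        recs = []
        for r in self.records:
            r = Region(*r)
            if r.start >= r.end:
                raise ValueError(f"empty/inverted region {r.chrom}:{r.start}-{r.end}")
            if r.strand not in "+-.":
                raise ValueError(f"bad strand {r.strand!r}")
            recs.append(r)
        self.records = sorted(recs, key=lambda r: (r.chrom, r.start, r.end))

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[Region]:
        return iter(self.records)

    def for_chrom(self, chrom: str) -> list[Region]:
        return [r for r in self.records if r.chrom == chrom]

    def labels(self) -> list[str]:
        seen: dict[str, None] = {}
        for r in self.records:
            seen.setdefault(r.label, None)
        return list(seen)

    def to_mask(self, chrom: str, length: int) -> np.ndarray:
        """Boolean array, True inside any record on ``chrom``."""
        mask = np.zeros(length, dtype=bool)
        for r in self.for_chrom(chrom):
            mask[max(0, r.start) : min(length, r.end)] = True
        return mask


@dataclass
class TrackArray:
    """A per-base real-valued track with a mappability mask.

    ``mask[t]`` is True where the base is valid (mappable); masked-out
    bases are excluded from every statistic computed on the track.
    """

    chrom: str
    values: np.ndarray
    mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.mask is None:
            self.mask = np.ones(self.values.size, dtype=bool)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.size != self.values.size:
            raise ValueError("values and mask must have equal length")

    def __len__(self) -> int:
        return self.values.size


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: str | Path) -> list[GenomeSequence]:
    """Load a multi-record FASTA; uppercase, non-ACGTN folded to N.

    The number of substituted characters is logged as a warning so silently
    dirty references are visible.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    out: list[GenomeSequence] = []
    names: set[str] = set()
    n_subst = 0
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in names:
            raise ValueError(f"duplicate sequence name {rec.id!r} in {path}")
        names.add(rec.id)
        seq = str(rec.seq).upper()
        cleaned = "".join(c if c in _ALLOWED else "N" for c in seq)
        n_subst += sum(1 for a, b in zip(seq, cleaned) if a != b)
        out.append(GenomeSequence(rec.id, cleaned))
    if not out:
        raise ValueError(f"no FASTA records in {path}")
    if n_subst:
        logger.warning("%d non-ACGTN characters replaced by N in %s", n_subst, path)
    return out


def write_fasta(genomes: Iterable[GenomeSequence], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for g in genomes:
            fh.write(f">{g.name}\n")
            for i in range(0, g.length, width):
                fh.write(g.seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# BED


def read_reads_bed(path: str | Path) -> list[MappedRead]:
    """Parse reads from BED6. pos5 = start for '+', end - 1 for '-'."""
    reads: list[MappedRead] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split()
            if len(parts) < 6:
                raise ValueError(f"{path}:{lineno}: strand required (BED6 expected)")
            chrom, start, end, _name, _score, strand = parts[:6]
            try:
                s, e = int(start), int(end)
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: malformed coordinates") from exc
            if s >= e:
                raise ValueError(f"{path}:{lineno}: start >= end")
            if strand not in "+-":
                raise ValueError(f"{path}:{lineno}: strand must be + or -, got {strand!r}")
            reads.append(MappedRead(chrom, s if strand == "+" else e - 1, strand))
    return reads


def write_reads_bed(
    reads: Iterable[MappedRead], path: str | Path, read_len: int = 36
) -> None:
    """Write reads as BED6, reconstructing [start, end) from pos5 and strand."""
    with open(path, "w") as fh:
        for i, r in enumerate(reads):
            if r.strand == "+":
                s, e = r.pos5, r.pos5 + read_len
            else:
                s, e = r.pos5 - read_len + 1, r.pos5 + 1
            fh.write(f"{r.chrom}\t{s}\t{e}\tr{i}\t0\t{r.strand}\n")


def read_regions_bed(path: str | Path) -> RegionSet:
    """Parse a BED file into a RegionSet (3+ columns; strand defaults to '.')."""
    recs: list[Region] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split()
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: need at least chrom/start/end")
            chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            if start >= end:
                raise ValueError(f"{path}:{lineno}: start >= end")
            label = parts[3] if len(parts) > 3 else "."
            strand = parts[5] if len(parts) > 5 else "."
            recs.append(Region(chrom, start, end, strand, label))
    return RegionSet(recs)


def write_regions_bed(rs: RegionSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in rs:
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{r.label}\t0\t{r.strand}\n")


# ---------------------------------------------------------------------------
# bedGraph


def write_bedgraph(
    track: TrackArray,
    path: str | Path,
    precision: int = 6,
    header: bool = False,
    name: str = "track",
    mode: str = "w",
) -> None:
    """Run-length-merged bedGraph; masked bases are omitted entirely."""
    with open(path, mode) as fh:
        if header:
            fh.write(f'track type=bedGraph name="{name}"\n')
        vals = np.round(track.values, precision)
        run_start = None
        run_val = 0.0
        for t in range(len(track) + 1):
            cur = None
            if t < len(track) and track.mask[t]:
                cur = vals[t]
            if run_start is not None and (cur is None or cur != run_val):
                fh.write(f"{track.chrom}\t{run_start}\t{t}\t{run_val:.{precision}g}\n")
                run_start = None
            if cur is not None and run_start is None:
                run_start = t
                run_val = cur


def read_bedgraph(path: str | Path, chrom: str, length: int) -> TrackArray:
    """Load one chromosome of a bedGraph into a dense masked track."""
    values = np.zeros(length)
    mask = np.zeros(length, dtype=bool)
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            c, s, e, v = line.split()[:4]
            if c != chrom:
                continue
            s_i, e_i = int(s), int(e)
            values[s_i:e_i] = float(v)
            mask[s_i:e_i] = True
    return TrackArray(chrom, values, mask)
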