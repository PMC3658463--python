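"""High-level modelling interface.

`NucleosomeOccupancyModel` bundles the full pipeline the way a
statistical model object would: it is constructed from a genome plus
per-state ChIP-seq reads, `fit()` estimates the state emission tables
from the extended reads, calibrates the transition parameters from the
target genome proportions, and runs posterior decoding; the returned
`OccupancyResults` carries the per-base probability tracks, the
log-likelihood, the estimated specificities, and a text `summary()`.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from . import evaluation, hmm, specificity as spc
from .genome_io import (
    GenomeSequence,
    MappedRead,
    RegionSet,
    read_fasta,
    read_reads_bed,
    write_bedgraph,
)


class NucleosomeOccupancyModel:
    """Sequence-based H3K4me3/H3 nucleosome occupancy model.

    Parameters
    ----------
    genomes : chromosomes to decode.
    reads_me3, reads_h3 : uniquely-mapped ChIP-seq read 5' positions for
        the H3K4me3 and bulk-H3 experiments; used only to estimate the
        6-mer emission tables.
    L : nucleosome footprint (bp).
    pi_nuc, pi_me3 : target genome fractions of nucleosome-bound and
        H3K4me3-bound bases; calibrate the depletion parameter d and the
        class ratio rho in closed form.
    ext : read extension length toward the 3' end (bp).
    pseudocount : added to every 6-mer count before normalization.
    mask : optional mappability region set; bases outside are ignored.
    """

    def __init__(
        self,
        genomes: Sequence[GenomeSequence],
        reads_me3: Sequence[MappedRead],
        reads_h3: Sequence[MappedRead],
        L: int = 147,
        pi_nuc: float = 0.80,
        pi_me3: float = 0.05,
        ext: int = 151,
        pseudocount: float = 0.5,
        mask: RegionSet | None = None,
    ):
        if not genomes:
            raise ValueError("empty genome")
        self.genomes = list(genomes)
        self.reads_me3 = list(reads_me3)
        self.reads_h3 = list(reads_h3)
        self.L = L
        self.pi_nuc = pi_nuc
        self.pi_me3 = pi_me3
        self.ext = ext
        self.pseudocount = pseudocount
        self.mask = mask

    @classmethod
    def from_files(
        cls, genome_fasta: str | Path, reads_me3_bed: str | Path,
        reads_h3_bed: str | Path, **kwargs,
    ) -> "NucleosomeOccupancyModel":
        return cls(
            read_fasta(genome_fasta),
            read_reads_bed(reads_me3_bed),
            read_reads_bed(reads_h3_bed),
            **kwargs,
        )

    def fit(self) -> "OccupancyResults":
        """Estimate emissions, calibrate transitions, decode the genome."""
        genome_counts = spc.KmerCounts(6, np.zeros(4**6))
        for g in self.genomes:
            genome_counts = genome_counts + spc.count_kmers(g, 6)
        counts_me3 = spc.count_read_kmers(self.genomes, self.reads_me3, ext=self.ext)
        counts_h3 = spc.count_read_kmers(self.genomes, self.reads_h3, ext=self.ext)
        emissions = {
            "me3": spc.emission_from_counts(counts_me3, self.pseudocount, "H3K4me3"),
            "h3": spc.emission_from_counts(counts_h3, self.pseudocount, "H3"),
            "background": spc.emission_from_counts(
                genome_counts, self.pseudocount, "background"
            ),
        }
        params = hmm.calibrate_transitions(
            self.pi_nuc, self.pi_me3, L=self.L, emissions=emissions
        )
        posteriors = hmm.run_genome(self.genomes, params, mask=self.mask)
        specs = {
            "me3": spc.kmer_specificity(
                counts_me3, genome_counts, self.pseudocount, state="H3K4me3"
            ),
            "h3": spc.kmer_specificity(
                counts_h3, genome_counts, self.pseudocount, state="H3"
            ),
        }
        return OccupancyResults(self, params, posteriors, specs)


@dataclass
class OccupancyResults:
    """Fitted occupancy model: parameters, tracks, specificities."""

    model: NucleosomeOccupancyModel
    params: hmm.HmmParams
    posteriors: list[hmm.PosteriorResult]
    specificities: dict[str, spc.KmerSpecificity]

    @property
    def loglik(self) -> float:
        return sum(p.loglik for p in self.posteriors)

    def track(self, which: str = "me3", chrom: str | None = None):
        for p in self.posteriors:
            if chrom is None or p.chrom == chrom:
                return getattr(p, f"track_{which}")
        raise KeyError(chrom)

    def mean_occupancy(self, which: str = "me3") -> float:
        """Genome-average posterior occupancy over unmasked bases."""
        num = 0.0
        den = 0
        for p in self.posteriors:
            tr = getattr(p, f"track_{which}")
            num += float(tr.values[tr.mask].sum())
            den += int(tr.mask.sum())
        return num / den if den else float("nan")

    def correlation_with(self, coverage, which: str = "me3") -> float:
        """Pearson r between the decoded track and an in vivo coverage track."""
        return evaluation.track_correlation(self.track(which, coverage.chrom), coverage)

    def to_bedgraph(self, prefix: str | Path, precision: int = 6) -> list[Path]:
        paths = []
        for which in ("me3", "h3", "free"):
            path = Path(f"{prefix}.{which}.bedgraph")
            for i, p in enumerate(self.posteriors):
                write_bedgraph(
                    getattr(p, f"track_{which}"),
                    path,
                    precision=precision,
                    mode="w" if i == 0 else "a",
                )
            paths.append(path)
        return paths

    def summary(self) -> str:
        lines = [
            "Nucleosome occupancy model (fifth-order emission HMM)",
            "=" * 56,
            f"chromosomes:        {len(self.posteriors)}",
            f"L (nucleosome bp):  {self.params.L}",
            f"d (depletion):      {self.params.d:.6f}",
            f"rho (P me3|nuc):    {self.params.rho:.6f}",
            f"pi_nuc target:      {self.params.pi_nuc:.4f}",
            f"pi_me3 target:      {self.params.pi_me3:.4f}",
            f"log-likelihood:     {self.loglik:.2f}",
            f"mean P(H3K4me3):    {self.mean_occupancy('me3'):.6f}",
            f"mean P(H3):         {self.mean_occupancy('h3'):.6f}",
            f"mean P(free):       {self.mean_occupancy('free'):.6f}",
        ]
        return "\n".join(lines)

    def plot_track(self, chrom: str | None = None, start: int = 0, end: int | None = None, ax=None):
        """Plot the three posterior tracks over a window (needs matplotlib)."""
        import matplotlib.pyplot as plt

        tr_m = self.track("me3", chrom)
        end = len(tr_m) if end is None else end
        if ax is None:
            _, ax = plt.subplots(figsize=(10, 3))
        x = np.arange(start, end)
        for which, color in (("me3", "tab:red"), ("h3", "tab:blue"), ("free", "0.6")):
            tr = self.track(which, chrom)
            ax.plot(x, tr.values[start:end], color=color, lw=0.8, label=f"P({which})")
        ax.set_xlabel(f"{tr_m.chrom} position (bp)")
        ax.set_ylabel("posterior probability")
        ax.set_ylim(0, 1)
        ax.legend(loc="upper right", fontsize=8)
        return ax
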