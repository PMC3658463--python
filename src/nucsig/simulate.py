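"""Generative counterpart of the occupancy model: synthetic genomes,
planted nucleosome arrangements, and ChIP-seq-like reads.

The simulator samples the same renewal chain the decoder assumes (free
base with probability d, else a whole L-bp nucleosome, H3K4me3-marked
with probability rho) and emits each base from the active state's
fifth-order table given the running sequence context — so the synthetic
genome is exactly distributed according to the model, and every other
module can be tested against known ground truth without any downloads.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from ._kmers import BASES
from .genome_io import (
    GenomeSequence,
    MappedRead,
    Region,
    RegionSet,
    TrackArray,
    write_fasta,
    write_reads_bed,
    write_regions_bed,
)
from .hmm import HmmParams, calibrate_transitions
from .specificity import EmissionModel, N_CONTEXTS

_CHUNK = 65536


class _UniformStream:
    """Pre-drawn uniforms in chunks; cheaper than per-base Generator calls."""

    def __init__(self, rng: np.random.Generator):
        self.rng = rng
        self.buf: list[float] = []
        self.i = 0

    def next(self) -> float:
        if self.i >= len(self.buf):
            self.buf = self.rng.random(_CHUNK).tolist()
            self.i = 0
        v = self.buf[self.i]
        self.i += 1
        return v


@dataclass
class SyntheticTruth:
    """A simulated genome with its hidden nucleosome arrangement."""

    genome: GenomeSequence
    nucleosomes: RegionSet  # labels 'H3K4me3' / 'H3', each exactly L bp
    occupancy_me3: TrackArray
    occupancy_h3: TrackArray
    params: HmmParams
    seed: int


def make_emission_tables(
    seed: int = 0, me3_cg_boost: float = 3.0, h3_bend_bias: float = 2.0
) -> dict[str, EmissionModel]:
    """Construct planted emission tables for the three states.

    Background is uniform. The H3K4me3 table multiplies C/G continuation
    probabilities by ``me3_cg_boost`` (CpG-island-like sequence
    signature); the H3 table favors A-after-A and T-after-T steps by
    ``h3_bend_bias`` (DNA-bending preference). Rows renormalized. Boosts
    of 1 give three identical uniform tables. The tables are
    deterministic functions of the boosts; ``seed`` is accepted for
    interface stability and unused.
    """
    del seed
    uniform = np.full((N_CONTEXTS, 4), 0.25)
    bg = EmissionModel("background", uniform.copy())

    me3 = uniform.copy()
    me3[:, 1] *= me3_cg_boost  # C
    me3[:, 2] *= me3_cg_boost  # G
    me3 /= me3.sum(axis=1, keepdims=True)

    h3 = uniform.copy()
    prev = np.arange(N_CONTEXTS) % 4  # last base of the 5-mer context
    h3[prev == 0, 0] *= h3_bend_bias  # A after A
    h3[prev == 3, 3] *= h3_bend_bias  # T after T
    h3 /= h3.sum(axis=1, keepdims=True)

    return {
        "me3": EmissionModel("H3K4me3", me3),
        "h3": EmissionModel("H3", h3),
        "background": bg,
    }


def simulate_arrangement(
    params: HmmParams, T: int, rng: np.random.Generator
) -> list[tuple[int, str]]:
    """Sample nucleosome starts from the renewal chain over [0, T).

    A nucleosome that would overrun T is rejected (the decision point is
    forced free), matching the decoder's no-partial-nucleosome boundary.
    """
    us = _UniformStream(rng)
    starts: list[tuple[int, str]] = []
    pos = 0
    d, rho, L = params.d, params.rho, params.L
    while pos < T:
        if us.next() < d or pos + L > T:
            pos += 1
        else:
            label = "H3K4me3" if us.next() < rho else "H3"
            starts.append((pos, label))
            pos += L
    return starts


def simulate_genome(params: HmmParams, T: int, seed: int) -> SyntheticTruth:
    """Sample a hidden arrangement and emit a genome from the state tables."""
    if params.L > T:
        raise ValueError("T must be >= L")
    emissions = params.emissions
    if emissions is None:
        raise ValueError("params.emissions required to emit sequence")
    rng = np.random.default_rng(seed)
    starts = simulate_arrangement(params, T, rng)

    state = np.zeros(T, dtype=np.int8)  # 0 free, 1 me3, 2 h3
    for s, label in starts:
        state[s : s + params.L] = 1 if label == "H3K4me3" else 2
    state_l = state.tolist()

    models = [emissions["background"], emissions["me3"], emissions["h3"]]
    lowers = [m.lower_order_tables() for m in models]
    # cumulative per-row probabilities for the order-5 tables, as lists
    cdf5 = [np.cumsum(m.table, axis=1)[:, :3].tolist() for m in models]

    us = _UniformStream(rng)
    bases: list[int] = []
    ctx = 0
    for t in range(T):
        st = state_l[t]
        u = us.next()
        if t < 5:
            row = np.cumsum(lowers[st][t][ctx])
            b = int(np.searchsorted(row, u, side="right"))
            b = min(b, 3)
        else:
            c = cdf5[st][ctx]
            if u < c[0]:
                b = 0
            elif u < c[1]:
                b = 1
            elif u < c[2]:
                b = 2
            else:
                b = 3
        bases.append(b)
        ctx = (ctx * 4 + b) % N_CONTEXTS if t >= 4 else ctx * 4 + b

    seq = "".join(BASES[b] for b in bases)
    genome = GenomeSequence("synth1", seq)
    recs = [Region("synth1", s, s + params.L, ".", lab) for s, lab in starts]
    occ_m = TrackArray("synth1", (state == 1).astype(float))
    occ_h = TrackArray("synth1", (state == 2).astype(float))
    return SyntheticTruth(
        genome=genome,
        nucleosomes=RegionSet(recs),
        occupancy_me3=occ_m,
        occupancy_h3=occ_h,
        params=params,
        seed=seed,
    )


def simulate_reads(
    truth: SyntheticTruth,
    state: str,
    n_reads: int,
    read_len: int = 36,
    jitter_sd: float = 10.0,
    seed: int = 0,
) -> list[MappedRead]:
    """Sample ChIP-seq-like reads off planted nucleosomes of one state.

    Each read picks a nucleosome of the state uniformly, tosses a fair
    strand coin, and places its 5' end at the strand-appropriate
    nucleosome boundary plus rounded Gaussian jitter, clipped in range.
    """
    nucs = [r for r in truth.nucleosomes if r.label == state]
    if not nucs:
        raise ValueError(f"no planted nucleosomes of state {state!r}")
    rng = np.random.default_rng(seed)
    T = truth.genome.length
    picks = rng.integers(0, len(nucs), size=n_reads)
    strands = rng.random(n_reads) < 0.5
    jit = np.rint(rng.normal(0.0, jitter_sd, size=n_reads)).astype(np.int64)
    reads = []
    for i in range(n_reads):
        r = nucs[picks[i]]
        if strands[i]:
            pos5 = int(np.clip(r.start + jit[i], 0, T - 1))
            reads.append(MappedRead(truth.genome.name, pos5, "+"))
        else:
            pos5 = int(np.clip(r.end - 1 + jit[i], 0, T - 1))
            reads.append(MappedRead(truth.genome.name, pos5, "-"))
    return reads


def end_to_end_fixture(
    seed: int,
    out_dir: str | Path | None = None,
    T: int = 2_000_000,
    L: int = 147,
    pi_nuc: float = 0.80,
    pi_me3: float = 0.05,
    me3_cg_boost: float = 3.0,
    h3_bend_bias: float = 2.0,
    n_reads: int = 200_000,
    read_len: int = 36,
    jitter_sd: float = 10.0,
) -> dict:
    """A complete deterministic test bundle: genome, truth and reads.

    Returns the in-memory objects and (when ``out_dir`` is given) writes
    genome FASTA, per-state read BEDs, truth BED and a params JSON. Same
    seed, byte-identical files.
    """
    ss = np.random.SeedSequence(seed)
    seeds = [int(s) % (2**31) for s in ss.generate_state(3)]
    emissions = make_emission_tables(
        me3_cg_boost=me3_cg_boost, h3_bend_bias=h3_bend_bias
    )
    params = calibrate_transitions(pi_nuc, pi_me3, L=L, emissions=emissions)
    truth = simulate_genome(params, T, seeds[0])
    reads_me3 = simulate_reads(
        truth, "H3K4me3", n_reads, read_len=read_len, jitter_sd=jitter_sd, seed=seeds[1]
    )
    reads_h3 = simulate_reads(
        truth, "H3", n_reads, read_len=read_len, jitter_sd=jitter_sd, seed=seeds[2]
    )
    bundle = {
        "truth": truth,
        "params": params,
        "reads_me3": reads_me3,
        "reads_h3": reads_h3,
    }
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_fasta([truth.genome], out / "genome.fa")
        write_reads_bed(reads_me3, out / "reads_me3.bed", read_len=read_len)
        write_reads_bed(reads_h3, out / "reads_h3.bed", read_len=read_len)
        write_regions_bed(truth.nucleosomes, out / "truth_nucleosomes.bed")
        with open(out / "params.json", "w") as fh:
            json.dump(
                {
                    "seed": seed,
                    "T": T,
                    "L": L,
                    "pi_nuc": pi_nuc,
                    "pi_me3": pi_me3,
                    "d": params.d,
                    "rho": params.rho,
                    "me3_cg_boost": me3_cg_boost,
                    "h3_bend_bias": h3_bend_bias,
                    "n_reads_per_state": n_reads,
                    "read_len": read_len,
                    "jitter_sd": jitter_sd,
                },
                fh,
                indent=2,
                sort_keys=True,
            )
        bundle["paths"] = {
            "genome": out / "genome.fa",
            "reads_me3": out / "reads_me3.bed",
            "reads_h3": out / "reads_h3.bed",
            "truth": out / "truth_nucleosomes.bed",
            "params": out / "params.json",
        }
    return bundle
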