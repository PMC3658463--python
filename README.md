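# nucsig

Sequence-based prediction of H3K4me3 and H3 nucleosome occupancy.

H3K4me3 (trimethylation of lysine 4 on histone H3) marks nucleosomes at
active promoters and other regulatory regions. `nucsig` asks how much of
that placement is encoded in the DNA sequence itself: it learns the
6-mer sequence preferences of H3K4me3-modified and unmodified (H3)
nucleosomes from ChIP-seq reads and then computes, for **every base pair
of a genome**, the posterior probability that the base is covered by an
H3K4me3 nucleosome, an H3 nucleosome, or no nucleosome — from sequence
alone. It is aimed at epigenomics researchers studying the sequence
determinants of chromatin state.

## The model

Hidden states are `free` plus position-within-nucleosome states
`M_1..M_L` (H3K4me3) and `N_1..N_L` (H3), with nucleosome footprint
`L = 147` bp. At each renewal point (a free base or a completed
nucleosome) the chain stays nucleosome-free with probability `d` or
starts a whole nucleosome with probability `1 − d`, which carries
H3K4me3 with probability `ρ`. Emissions are **fifth-order**: each base
is emitted conditional on the preceding five bases, with one 6-mer table
per state estimated from 151-bp-extended ChIP-seq reads (normalized by
genome composition) and a background table from the genome itself.
`(d, ρ)` are calibrated in closed form from target genome proportions:

```
d = L(1 − π_nuc) / (L(1 − π_nuc) + π_nuc),    ρ = π_me3 / π_nuc
```

so the stationary bound fraction `L(1−d) / (L(1−d) + d)` equals `π_nuc`
and the H3K4me3 base fraction equals `π_me3` (default 0.05: roughly 5 %
of a mammalian genome is H3K4me3-occupied). Scaled forward/backward
recursions — collapsed to an O(T) renewal recursion in production —
yield per-base posteriors `P_me3(t) = Σ_i P(state_t = M_i | S_1..S_T)`,
and similarly `P_h3`, `P_free`, with `P_me3 + P_h3 + P_free = 1`.

The package also implements the surrounding analysis toolkit:
position-specific dinucleotide profiles around nucleosome centers with
10-bp periodicity quantification and paired t-tests, extended-read
coverage tracks, Poisson enrichment calling, base-pair precision–recall,
false-negative rates at regulatory elements, and meta-profiles — plus a
generative simulator (the exact sampling dual of the HMM) so the whole
pipeline is testable against planted ground truth without any downloads.

## Worked example

```python
import nucsig as ns

# synthetic study: 2 Mb genome with planted nucleosomes, 2e5 reads/state
bundle = ns.end_to_end_fixture(seed=7, T=2_000_000, n_reads=200_000)
truth = bundle["truth"]

model = ns.NucleosomeOccupancyModel(
    [truth.genome], bundle["reads_me3"], bundle["reads_h3"],
    L=147, pi_nuc=0.80, pi_me3=0.05,
)
res = model.fit()
print(res.summary())
print("track r:", ns.track_correlation(res.track("me3"), truth.occupancy_me3))
```

prints

```
Nucleosome occupancy model (fifth-order emission HMM)
========================================================
chromosomes:        1
L (nucleosome bp):  147
d (depletion):      0.973510
rho (P me3|nuc):    0.062500
pi_nuc target:      0.8000
pi_me3 target:      0.0500
log-likelihood:     -2726318.03
mean P(H3K4me3):    0.049930
mean P(H3):         0.744062
mean P(free):       0.205993
track r: 0.9733143033346148
```

`d` is the calibrated depletion probability; the mean posteriors land on
the calibration targets (5 % H3K4me3, 80 % total nucleosome), and the
decoded `P(H3K4me3)` track correlates at r ≈ 0.97 with the hidden planted
occupancy. `res.to_bedgraph("out")` exports the three per-base tracks.

The same pipeline is available from the shell:

```bash
nucsig simulate --t 2000000 --seed 7 --out-dir sim/
nucsig specificity --genome sim/genome.fa --reads sim/reads_me3.bed \
    --state me3 --out-prefix me3
nucsig predict --genome sim/genome.fa --emissions-me3 me3.emissions.tsv \
    --emissions-h3 h3.emissions.tsv --emissions-bg bg.emissions.tsv \
    --out-prefix pred
nucsig evaluate --prob pred.me3.bedgraph --reads sim/reads_me3.bed \
    --genome-sizes sizes.tsv --truth sim/truth_nucleosomes.bed --out-prefix eval
```

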