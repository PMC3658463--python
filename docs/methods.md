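# Methods

## Model

`nucsig` models a genome as the output of a left-to-right renewal chain.
At every renewal point — a nucleosome-free base or the last base of a
nucleosome — the chain stays free with probability `d` (the depletion
parameter) and emits one base from the background sequence model, or
starts a whole nucleosome of `L` bases with probability `1 − d`. A new
nucleosome carries the H3K4me3 mark with probability `ρ` and is an
unmodified H3 nucleosome otherwise. Expanded to single-base hidden
states this is the chain `{free, M_1..M_L, N_1..N_L}`, where `M_i`/`N_i`
means "the i-th base of an H3K4me3/H3 nucleosome"; transitions
`M_i → M_{i+1}` (and `N` likewise) are deterministic, and `free`, `M_L`
and `N_L` all feed the next renewal decision.

Emissions are fifth-order: the probability of each base conditions on
the preceding five bases of the *observed* sequence (whatever hidden
state emitted them), one 1024×4 table per state class. The table is
position-independent within the nucleosome — one table per modification
class, estimated by pooling all extended-read sequence — not
position-specific; the dinucleotide-profile module measures positional
structure descriptively, but the decoder does not use it.

Boundary rule: a run (chromosome, or maximal N-free unmasked stretch)
begins in `{free, M_1, N_1}` with the renewal weights
`(d, (1−d)ρ, (1−d)(1−ρ))` and must end in `{free, M_L, N_L}` — no
partial nucleosomes at run boundaries. Runs shorter than `L` therefore
decode as entirely nucleosome-free. Likelihoods are normalized over all
legal arrangements, so the end-of-run constraint is handled by the
normalization rather than by truncated nucleosome states.

## Emission estimation

ChIP-seq read 5′ ends are extended toward the 3′ end to 151 bp
(immunoprecipitated fragments are ~150 bp; the value is configurable via
`ext`). 6-mer counts over the extended intervals are accumulated
per read — overlapping intervals each count, because pile-up depth is
the enrichment signal — on both strands, skipping any window containing
N. The emission table is the conditional frequency
`P(b | c) = (n(c·b) + ε) / Σ_b' (n(c·b') + ε)` with pseudocount
`ε = 0.5` (Jeffreys-style; guarantees strict positivity, which the
log-space decoder requires). The background table comes from
whole-genome 6-mer counts. Specificity tables (read frequency divided by
genome frequency, rescaled to genome-weighted mean 1) are reported for
inspection and cross-dataset correlation but are not themselves inputs
to the decoder.

At the first five positions of a run fewer than five context bases
exist; the decoder uses lower-order tables obtained by marginalizing the
order-5 table over the missing leading context bases, weighting contexts
by their empirical counts when the model was estimated from data and
uniformly otherwise. The same truncation is used by the generative
simulator and the enumeration oracle, so the convention is self-consistent
end to end.

## Decoding

Two mathematically identical decoders are implemented.

The *full state-space* scaled forward/backward pair (`forward`,
`backward`, `state_posteriors`) follows the textbook recursions over
`2L + 1` states with per-position scaling; it exposes per-state
quantities and exists as the transparent reference implementation.

The *production* decoder (`posterior`, `run_genome`) exploits the
deterministic within-nucleosome transitions: an entire nucleosome
contributes `log(entry weight) + Σ emissions`, so the recursion only
needs the log-probability `G(t)` of reaching a renewal point after base
`t` (lag-`L` recurrence) and its suffix mirror `B(t)`. Per-base coverage
probabilities are sliding-window sums of per-start posteriors
`exp(G(s−1) + log entry + emission sum + B(s+L−1) − loglik)`. This is
O(T) time and memory with a working set independent of `L`.

Numerics: the renewal recursion runs in log space. All per-position log
emissions are tilted by the mean background log-probability before the
recursion — every arrangement shifts by the same `T·μ`, which cancels in
the posteriors — so `G`, `B` and the emission prefix sums stay
`O(√T)` in magnitude and double precision preserves the conservation
identity `P_me3 + P_h3 + P_free = 1` to better than 1e-9 on megabase
runs. `P_free` is computed independently (not as one minus the rest), so
conservation is a genuine cross-check of the implementation. The
enumeration oracle (`brute_force_oracle`) sums over every legal tiling
exactly and bounds the instance size it accepts.

`segment_probability` classifies a single ≤ `L` segment by comparing its
likelihood under the three emission models with priors
`(π_me3, π_nuc − π_me3, 1 − π_nuc)`; segments shorter than 6 bases have
no full context and are rejected.

## Parameters

| parameter | default | meaning |
|---|---|---|
| `L` | 147 bp | nucleosome footprint |
| `π_nuc` | 0.80 | target genome fraction covered by any nucleosome |
| `π_me3` | 0.05 | target genome fraction covered by H3K4me3 nucleosomes (~5 % of a mammalian genome) |
| `d` | derived | `L(1−π_nuc) / (L(1−π_nuc) + π_nuc)` |
| `ρ` | derived | `π_me3 / π_nuc` |
| `ext` | 151 bp | read extension toward 3′ |
| `pseudocount` | 0.5 | 6-mer count smoothing |

`π_me3 = 0.05` reflects the ~5 % H3K4me3 genome occupancy typical of
human T cells; `π_nuc = 0.80` is a standard bulk-nucleosome coverage
figure for eukaryotic genomes. Both are required, exposed configuration —
the decoder's output scales directly with them. The calibration is
validated by simulation: sampling the chain at `T = 10⁶` reproduces the
target bound fraction within 0.02.

Linker lengths are geometric by construction (each free base is an
independent `d` event); heavier-tailed linker distributions are out of
scope.

## Dinucleotide profiles

Profiles are computed around region midpoints over offsets ±`halfwidth`
(default 73 ≈ L/2): at offset p, the frequency of a dinucleotide is the
count of that dimer starting within a `window`-bp window (default 3 bp)
centered at p across sites, divided by all valid dimers in those
windows. Sites on the '−' strand are read 5′→3′ on their own strand:
the offset axis is flipped and the dimer reverse-complemented.
Reverse-complement pairs are pooled into the ten standard labels
(AA/TT, CC/GG, AG/CT, AC/GT, CA/TG, GA/TC, and the self-complementary
AT, TA, CG, GC). Periodicity power is the fraction of detrended profile
variance in the DFT bin nearest 1/period (default 10 bp); it is
invariant to constant offsets and linear ramps by construction. Paired
t-tests between state profiles handle zero-variance differences
explicitly (identical → t = 0, p = 1; exactly constant shift → ±∞, 0).

## Evaluation machinery

In vivo coverage is the extended-read pile-up. Correlations are Pearson
over jointly unmasked bases. Enriched-site calling is Poisson: the rate
λ is the mean coverage over unmasked bases and a base is called when
`P(X ≥ observed; λ)` falls below `p_threshold` (default 1e-5; exposed,
as is the low-probability cutoff 1e-5 of the false-negative-rate
statistic). Precision/recall is computed at base-pair resolution by
default — the finest reading consistent with per-bp tracks — with a
region-level mode behind a flag; precision with no predicted bases is
reported as missing, never zero. False-negative rates tile each element
into 200-bp windows and use window *means* against the genome-wide top
0.1 % coverage quantile (ties included above the threshold).

## Synthetic data

The simulator is the exact generative dual of the decoder: it samples
the renewal chain (rejecting nucleosome starts that would overrun the
sequence end, mirroring the decoder's boundary rule) and emits each base
from the active state's table given the running 5-base context. Planted
emission tables are uniform background, a C/G-continuation boost for
H3K4me3 (default 3, a CpG-island-like signature), and an A-after-A /
T-after-T bias for H3 (default 2, a bending-type preference). Reads are
36 bp (inside the 30–50 bp range of typical early ChIP-seq), with 5′
ends at nucleosome boundaries plus rounded Gaussian jitter (sd 10 bp)
modeling fragment-end variability.

What the simulator does *not* emulate — and hence what passing tests do
not show about real data: mappability gaps, PCR duplicates, GC bias,
sequencing error, cell-type mixtures, positional (rotational) sequence
structure within nucleosomes, and any placement signal not carried by
6-mer composition. Recovery statistics on synthetic data (specificity
r > 0.95, track r > 0.7, ≥ 5× precision enrichment over the 5 % base
rate) validate the machinery, not the biological accuracy of the model
on a real genome.

## Problem sizes and determinism

The standard synthetic study uses a 2 Mb genome with 2×10⁵ reads per
state — large enough for stable 6-mer estimates (≈ 3×10⁷ extended-read
bases over 4096 6-mers) while a full fit-and-decode completes in well
under a minute. All stochastic components take explicit integer seeds
through `numpy.random.default_rng`; same-seed runs are byte-identical,
including written files. The decoder itself is deterministic.

## Known limitations

- Reverse-complement symmetry of the decoded tracks is *not* asserted or
  expected: fifth-order emission is directional, so decoding the reverse
  complement gives a (slightly) different track.
- One emission table per state: no position-within-nucleosome structure.
- Two nucleosome classes only; no Viterbi segmentation; no Baum–Welch
  re-estimation from sequence alone.
- The closed-form calibration targets stationary proportions; very short
  runs (comparable to `L`) are dominated by boundary effects and decode
  mostly free.
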