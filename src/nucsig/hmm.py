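"""Posterior decoding of nucleosome occupancy from genome sequence.

The hidden chain walks the genome left to right. At every renewal point
(a nucleosome-free base or the last base of a nucleosome) it either stays
nucleosome-free with probability ``d`` (the depletion parameter, emitting
one base from the background model) or starts a whole L-bp nucleosome
with probability 1-d, which is H3K4me3-marked with probability ``rho``
and unmarked H3 otherwise. Expanded to single-base states this is the
chain {free, M_1..M_L, N_1..N_L} with deterministic M_i -> M_{i+1}
transitions; emissions condition on the preceding five bases (6-mer
context), truncated to shorter contexts at the first bases of a run.
Runs begin and end only in {free, M_1/N_1} / {free, M_L/N_L}: no partial
nucleosomes at run boundaries.

Two equivalent decoders are provided. ``forward``/``backward`` implement
the scaled full-state recursions and expose per-state quantities; the
production path (`posterior`, `run_genome`) collapses the deterministic
within-nucleosome transitions into an O(T)-time, O(T)-memory renewal
recursion over log-space prefix sums, which is what makes genome-scale
decoding cheap. `brute_force_oracle` enumerates every legal nucleosome
arrangement exactly and exists to pin both decoders down on small
instances.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from ._kmers import encode_bases
from .genome_io import GenomeSequence, RegionSet, TrackArray
from .specificity import EmissionModel

NEG_INF = float("-inf")


@dataclass
class HmmParams:
    """Parameters of the occupancy chain.

    L : nucleosome footprint in bp.
    d : probability of staying nucleosome-free at a renewal point.
    rho : probability a newly started nucleosome carries H3K4me3.
    pi_free/pi_nuc/pi_me3 : the genome proportions the (d, rho) pair was
        calibrated to (free, any-nucleosome, H3K4me3-nucleosome bases).
    emissions : dict with keys 'me3', 'h3', 'background'.
    """

    L: int
    d: float
    rho: float
    pi_nuc: float
    pi_me3: float
    emissions: dict[str, EmissionModel] | None = None

    def __post_init__(self) -> None:
        if self.L < 2:
            raise ValueError("L must be >= 2")
        if not 0 < self.d < 1:
            raise ValueError("d must be in (0, 1)")
        if not 0 <= self.rho <= 1:
            raise ValueError("rho must be in [0, 1]")
        if not 0 < self.pi_nuc < 1 or not 0 <= self.pi_me3 <= self.pi_nuc:
            raise ValueError("need 0 < pi_nuc < 1 and 0 <= pi_me3 <= pi_nuc")

    @property
    def pi_free(self) -> float:
        return 1.0 - self.pi_nuc


def calibrate_transitions(
    pi_nuc: float,
    pi_me3: float,
    L: int = 147,
    emissions: dict[str, EmissionModel] | None = None,
) -> HmmParams:
    """Solve (d, rho) so the chain's stationary base fractions hit the targets.

    One renewal cycle emits 1 free base with probability d or L nucleosome
    bases with probability 1-d, so the stationary bound fraction is
    L(1-d) / (L(1-d) + d); inverting gives the closed form
    d = L(1-pi_nuc) / (L(1-pi_nuc) + pi_nuc), and rho = pi_me3/pi_nuc.
    """
    if not 0 < pi_nuc < 1:
        raise ValueError("pi_nuc must be strictly inside (0, 1)")
    if not 0 <= pi_me3 <= pi_nuc:
        raise ValueError("need 0 <= pi_me3 <= pi_nuc")
    d = L * (1 - pi_nuc) / (L * (1 - pi_nuc) + pi_nuc)
    rho = pi_me3 / pi_nuc
    return HmmParams(L=L, d=d, rho=rho, pi_nuc=pi_nuc, pi_me3=pi_me3, emissions=emissions)


# ---------------------------------------------------------------------------
# emissions along a run


def _require_emissions(params: HmmParams) -> dict[str, EmissionModel]:
    if params.emissions is None:
        raise ValueError("params.emissions must be set for decoding")
    for key in ("me3", "h3", "background"):
        if key not in params.emissions:
            raise ValueError(f"missing emission model {key!r}")
    return params.emissions


def log_emission_arrays(seq: str, params: HmmParams) -> dict[str, np.ndarray]:
    """Per-position log emission probability for each state class.

    Position t uses context order min(5, t): the preceding bases within
    the run, truncated via the model's marginal lower-order tables.
    """
    emissions = _require_emissions(params)
    codes = encode_bases(seq)
    if np.any(codes < 0):
        raise ValueError("sequence contains N; split runs before decoding")
    T = codes.size
    out: dict[str, np.ndarray] = {}
    # 5-mer context codes for positions >= 5
    n5 = max(T - 5, 0)
    ctx = np.zeros(n5, dtype=np.int64)
    if n5:
        for j in range(5):
            ctx = ctx * 4 + codes[j : n5 + j]
    for key, model in emissions.items():
        tables = model.lower_order_tables()
        logp = np.empty(T)
        for t in range(min(5, T)):
            o = t
            ci = 0
            for j in range(t - o, t):
                ci = ci * 4 + int(codes[j])
            logp[t] = math.log(tables[o][ci, codes[t]])
        if T > 5:
            logp[5:] = np.log(tables[5][ctx, codes[5:]])
        out[key] = logp
    return out


# ---------------------------------------------------------------------------
# full-state scaled forward/backward (states: 0=free, 1..L=M, L+1..2L=N)


@dataclass
class ForwardBackwardState:
    """Scaled forward/backward quantities for one N-free run."""

    alpha: np.ndarray | None = None  # (T, 2L+1), rows sum to 1
    beta: np.ndarray | None = None  # (T, 2L+1), scaled by forward constants
    scale: np.ndarray | None = None  # (T,) per-position scaling constants
    loglik: float = 0.0


def _entry_probs(params: HmmParams) -> tuple[float, float, float]:
    d, rho = params.d, params.rho
    return d, (1 - d) * rho, (1 - d) * (1 - rho)


def forward(seq: str, params: HmmParams) -> ForwardBackwardState:
    """Scaled forward pass over the full state space.

    At t=0 only {free, M_1, N_1} have mass, weighted by the renewal
    distribution; termination sums final mass over {free, M_L, N_L}.
    """
    L = params.L
    logE = log_emission_arrays(seq, params)
    e_b, e_m, e_n = (np.exp(logE[k]) for k in ("background", "me3", "h3"))
    T = e_b.size
    p_free, p_m, p_n = _entry_probs(params)
    S = 2 * L + 1
    alpha = np.zeros((T, S))
    scale = np.empty(T)
    cur = np.zeros(S)
    cur[0] = p_free * e_b[0]
    cur[1] = p_m * e_m[0]
    cur[L + 1] = p_n * e_n[0]
    scale[0] = cur.sum()
    cur /= scale[0]
    alpha[0] = cur
    for t in range(1, T):
        nxt = np.zeros(S)
        entry = cur[0] + cur[L] + cur[2 * L]
        nxt[0] = entry * p_free * e_b[t]
        nxt[1] = entry * p_m * e_m[t]
        nxt[L + 1] = entry * p_n * e_n[t]
        nxt[2 : L + 1] += cur[1:L] * e_m[t]
        nxt[L + 2 : 2 * L + 1] += cur[L + 1 : 2 * L] * e_n[t]
        scale[t] = nxt.sum()
        nxt /= scale[t]
        alpha[t] = nxt
        cur = nxt
    final_mass = cur[0] + cur[L] + cur[2 * L]
    loglik = float(np.log(scale).sum() + math.log(final_mass))
    return ForwardBackwardState(alpha=alpha, scale=scale, loglik=loglik)


def backward(
    seq: str, params: HmmParams, fwd: ForwardBackwardState | None = None
) -> ForwardBackwardState:
    """Scaled backward pass; reuses (or computes) the forward scaling constants.

    The independently accumulated backward log-likelihood is stored in
    ``loglik`` and must match the forward value.
    """
    if fwd is None:
        fwd = forward(seq, params)
    L = params.L
    logE = log_emission_arrays(seq, params)
    e_b, e_m, e_n = (np.exp(logE[k]) for k in ("background", "me3", "h3"))
    T = e_b.size
    p_free, p_m, p_n = _entry_probs(params)
    S = 2 * L + 1
    beta = np.zeros((T, S))
    cur = np.zeros(S)
    cur[[0, L, 2 * L]] = 1.0  # terminal states: free, M_L, N_L
    beta[T - 1] = cur
    for t in range(T - 2, -1, -1):
        prv = np.zeros(S)
        exit_val = p_free * e_b[t + 1] * cur[0] + p_m * e_m[t + 1] * cur[1]
        exit_val += p_n * e_n[t + 1] * cur[L + 1]
        prv[0] = exit_val
        prv[L] = exit_val
        prv[2 * L] = exit_val
        prv[1:L] += e_m[t + 1] * cur[2 : L + 1]
        prv[L + 1 : 2 * L] += e_n[t + 1] * cur[L + 2 : 2 * L + 1]
        prv /= fwd.scale[t + 1]
        beta[t] = prv
        cur = prv
    init = p_free * e_b[0] * cur[0] + p_m * e_m[0] * cur[1] + p_n * e_n[0] * cur[L + 1]
    loglik = float(math.log(init) + np.log(fwd.scale[1:]).sum())
    return ForwardBackwardState(beta=beta, scale=fwd.scale, loglik=loglik)


def state_posteriors(seq: str, params: HmmParams) -> np.ndarray:
    """(T, 2L+1) per-state posteriors from the full forward/backward pair."""
    fwd = forward(seq, params)
    bwd = backward(seq, params, fwd)
    gamma = fwd.alpha * bwd.beta
    gamma /= gamma.sum(axis=1, keepdims=True)
    return gamma


# ---------------------------------------------------------------------------
# production decoder: renewal recursion in log space


@dataclass
class PosteriorResult:
    """Per-base occupation probabilities for one chromosome (or run)."""

    track_me3: TrackArray
    track_h3: TrackArray
    track_free: TrackArray
    loglik: float

    @property
    def chrom(self) -> str:
        return self.track_me3.chrom


def _logaddexp3(a: float, b: float, c: float) -> float:
    m = a if a >= b else b
    if c > m:
        m = c
    if m == NEG_INF:
        return NEG_INF
    return m + math.log(math.exp(a - m) + math.exp(b - m) + math.exp(c - m))


def _renewal_posterior(
    seq: str, params: HmmParams
) -> tuple[np.ndarray, np.ndarray, np.ndarray, float]:
    """Per-base (P_me3, P_h3, P_free) and loglik for one N-free run.

    G[t] = log P(S_1..S_t, renewal point after t); B[t] is the mirrored
    quantity for the suffix. A nucleosome spanning [s, s+L) contributes
    G[s] + log(entry) + sum of its emissions + B[s+L]; per-base coverage
    probabilities are sliding-window sums of these start posteriors.
    """
    L = params.L
    logE = log_emission_arrays(seq, params)
    lb, lm, ln = logE["background"], logE["me3"], logE["h3"]
    T = lb.size
    d, pm, pn = _entry_probs(params)
    log_d = math.log(d)
    log_pm = math.log(pm) if pm > 0 else NEG_INF
    log_pn = math.log(pn) if pn > 0 else NEG_INF
    # Tilt all emissions by the mean background log-probability: every
    # arrangement's weight shifts by the same T*mu, which cancels in the
    # posteriors but keeps G/B and the prefix sums O(sqrt(T)) instead of
    # O(T), so double precision holds the 1e-9 conservation contract.
    mu = float(lb.mean())
    lb = lb - mu
    lm = lm - mu
    ln = ln - mu
    # prefix sums of nucleosome-state emissions: C[t] = sum of logE[0..t-1]
    C_m = np.concatenate(([0.0], np.cumsum(lm)))
    C_n = np.concatenate(([0.0], np.cumsum(ln)))
    lb_l = lb.tolist()
    C_m_l, C_n_l = C_m.tolist(), C_n.tolist()

    G = [0.0] * (T + 1)
    for t in range(1, T + 1):
        x = G[t - 1] + log_d + lb_l[t - 1]
        if t >= L:
            g0 = G[t - L]
            a = g0 + log_pm + C_m_l[t] - C_m_l[t - L] if log_pm > NEG_INF else NEG_INF
            b = g0 + log_pn + C_n_l[t] - C_n_l[t - L] if log_pn > NEG_INF else NEG_INF
            x = _logaddexp3(x, a, b)
        G[t] = x
    loglik = G[T]

    B = [0.0] * (T + 1)
    for t in range(T - 1, -1, -1):
        x = log_d + lb_l[t] + B[t + 1]
        if t + L <= T:
            bL = B[t + L]
            a = log_pm + C_m_l[t + L] - C_m_l[t] + bL if log_pm > NEG_INF else NEG_INF
            b = log_pn + C_n_l[t + L] - C_n_l[t] + bL if log_pn > NEG_INF else NEG_INF
            x = _logaddexp3(x, a, b)
        B[t] = x

    G_a = np.asarray(G)
    B_a = np.asarray(B)
    # posterior that a free base sits at t (0-based)
    p_free = np.exp(G_a[:T] + log_d + lb - loglik + B_a[1:])
    # posterior that a nucleosome of each class starts at s (s + L <= T)
    n_starts = T - L + 1
    if n_starts > 0:
        g_s = G_a[:n_starts]
        b_e = B_a[L:]
        lp_m = g_s + log_pm + (C_m[L:] - C_m[:n_starts]) + b_e - loglik
        lp_n = g_s + log_pn + (C_n[L:] - C_n[:n_starts]) + b_e - loglik
        start_m = np.exp(lp_m)
        start_n = np.exp(lp_n)
        p_me3 = _coverage_from_starts(start_m, T, L)
        p_h3 = _coverage_from_starts(start_n, T, L)
    else:
        p_me3 = np.zeros(T)
        p_h3 = np.zeros(T)
    return p_me3, p_h3, p_free, float(loglik + T * mu)  # undo the tilt


def _coverage_from_starts(starts: np.ndarray, T: int, L: int) -> np.ndarray:
    """P(base covered) = sum of start posteriors within L bases upstream."""
    diff = np.zeros(T + 1)
    diff[: starts.size] += starts
    ends = np.arange(starts.size) + L
    np.add.at(diff, ends, -starts)
    return np.cumsum(diff)[:T]


def posterior(seq: str, params: HmmParams, chrom: str = "run") -> PosteriorResult:
    """Per-base posterior occupation probabilities for an N-free sequence."""
    p_me3, p_h3, p_free, loglik = _renewal_posterior(seq, params)
    return PosteriorResult(
        track_me3=TrackArray(chrom, p_me3),
        track_h3=TrackArray(chrom, p_h3),
        track_free=TrackArray(chrom, p_free),
        loglik=loglik,
    )


def segment_probability(seq: str, params: HmmParams) -> tuple[float, float]:
    """Posterior class probabilities for one whole segment of <= L bases.

    The segment likelihood under each state's emission model (contexts
    truncated at the segment start) is combined with the class priors
    (pi_me3, pi_nuc - pi_me3, pi_free); returns (P_me3, P_h3).
    """
    if len(seq) < 6:
        raise ValueError("segment must be at least 6 bases")
    if len(seq) > params.L:
        raise ValueError(f"segment longer than L={params.L}")
    logE = log_emission_arrays(seq, params)  # raises on N
    ll = {k: float(v.sum()) for k, v in logE.items()}
    priors = {
        "me3": params.pi_me3,
        "h3": params.pi_nuc - params.pi_me3,
        "background": params.pi_free,
    }
    logpost = {k: math.log(priors[k]) + ll[k] if priors[k] > 0 else NEG_INF for k in ll}
    m = max(logpost.values())
    w = {k: math.exp(v - m) for k, v in logpost.items()}
    z = sum(w.values())
    return w["me3"] / z, w["h3"] / z


def run_genome(
    genomes: Sequence[GenomeSequence],
    params: HmmParams,
    mask: RegionSet | None = None,
) -> list[PosteriorResult]:
    """Decode whole chromosomes: split on N / masked-out bases, stitch tracks.

    Each maximal N-free, unmasked run is decoded independently (no
    nucleosome crosses a run boundary); bases outside runs are flagged
    unmappable in all three tracks.
    """
    if not genomes:
        raise ValueError("empty genome")
    results = []
    for g in genomes:
        valid = encode_bases(g.seq) >= 0
        if mask is not None:
            valid &= mask.to_mask(g.name, g.length)
        vals_m = np.zeros(g.length)
        vals_h = np.zeros(g.length)
        vals_f = np.zeros(g.length)
        total_ll = 0.0
        for s, e in _true_runs(valid):
            p_me3, p_h3, p_free, ll = _renewal_posterior(g.seq[s:e], params)
            vals_m[s:e] = p_me3
            vals_h[s:e] = p_h3
            vals_f[s:e] = p_free
            total_ll += ll
        results.append(
            PosteriorResult(
                track_me3=TrackArray(g.name, vals_m, valid.copy()),
                track_h3=TrackArray(g.name, vals_h, valid.copy()),
                track_free=TrackArray(g.name, vals_f, valid.copy()),
                loglik=total_ll,
            )
        )
    return results


def _true_runs(valid: np.ndarray) -> list[tuple[int, int]]:
    if valid.size == 0:
        return []
    padded = np.concatenate(([False], valid, [False])).astype(np.int8)
    d = np.diff(padded)
    starts = np.flatnonzero(d == 1)
    ends = np.flatnonzero(d == -1)
    return list(zip(starts.tolist(), ends.tolist()))


# ---------------------------------------------------------------------------
# exact enumeration oracle


def brute_force_oracle(seq: str, params: HmmParams, chrom: str = "run") -> PosteriorResult:
    """Enumerate every legal arrangement of whole nucleosomes and free bases.

    Exact posterior by summation over arrangements; exponential in T, so
    guarded to tiny instances. This is the independent reference the fast
    decoders are tested against.
    """
    T = len(seq)
    L = params.L
    if T > 20 or L > 6:
        raise ValueError("instance too large for exhaustive enumeration")
    logE = log_emission_arrays(seq, params)
    lb, lm, ln = logE["background"], logE["me3"], logE["h3"]
    d, pm, pn = _entry_probs(params)

    weights: list[float] = []
    covers: list[tuple[str, int]] = []  # flattened (kind, pos) per arrangement
    arrangement_cover: list[list[tuple[str, int, int]]] = []

    def recurse(t: int, logw: float, segs: list[tuple[str, int, int]]) -> None:
        if t == T:
            weights.append(logw)
            arrangement_cover.append(list(segs))
            return
        # free base
        recurse(t + 1, logw + math.log(d) + lb[t], segs + [("free", t, t + 1)])
        if t + L <= T:
            if pm > 0:
                w = logw + math.log(pm) + float(lm[t : t + L].sum())
                recurse(t + L, w, segs + [("me3", t, t + L)])
            if pn > 0:
                w = logw + math.log(pn) + float(ln[t : t + L].sum())
                recurse(t + L, w, segs + [("h3", t, t + L)])

    recurse(0, 0.0, [])
    w = np.asarray(weights)
    m = w.max()
    lin = np.exp(w - m)
    z = lin.sum()
    loglik = float(m + math.log(z))
    post = lin / z
    p_me3 = np.zeros(T)
    p_h3 = np.zeros(T)
    p_free = np.zeros(T)
    for p, segs in zip(post, arrangement_cover):
        for kind, s, e in segs:
            if kind == "me3":
                p_me3[s:e] += p
            elif kind == "h3":
                p_h3[s:e] += p
            else:
                p_free[s:e] += p
    return PosteriorResult(
        track_me3=TrackArray(chrom, p_me3),
        track_h3=TrackArray(chrom, p_h3),
        track_free=TrackArray(chrom, p_free),
        loglik=loglik,
    )
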