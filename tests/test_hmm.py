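import math

import numpy as np
import pytest

import nucsig as ns
from nucsig.hmm import log_emission_arrays, state_posteriors

from conftest import random_emissions, random_seq, random_toy_params


def uniform_emissions():
    t = np.full((1024, 4), 0.25)
    return {k: ns.EmissionModel(k, t.copy()) for k in ("me3", "h3", "background")}


def identical_emissions(seed=0):
    rng = np.random.default_rng(seed)
    table = rng.dirichlet([1.0] * 4, size=1024)
    return {k: ns.EmissionModel(k, table.copy()) for k in ("me3", "h3", "background")}


class TestCalibration:
    def test_closed_form_and_round_trip(self):
        p = ns.calibrate_transitions(0.5, 0.25, L=147)
        assert p.d == pytest.approx(147 / 148)
        # plugging d back into the stationary bound fraction returns pi_nuc
        bound = 147 * (1 - p.d) / (147 * (1 - p.d) + p.d)
        assert bound == pytest.approx(0.5)

    def test_rho_is_me3_share_of_nucleosomes(self):
        p = ns.calibrate_transitions(0.80, 0.05, L=147)
        assert p.rho == pytest.approx(0.0625)

    def test_no_nucleosome_limit(self):
        assert ns.calibrate_transitions(1e-9, 0.0).d == pytest.approx(1.0, abs=1e-6)

    def test_degenerate_proportions_rejected(self):
        for bad in (0.0, 1.0):
            with pytest.raises(ValueError):
                ns.calibrate_transitions(bad, 0.0)


class TestForwardBackward:
    def test_single_base_loglik_is_prior_mixture(self):
        em = identical_emissions()
        p = ns.HmmParams(L=3, d=0.7, rho=0.4, pi_nuc=0.5, pi_me3=0.2, emissions=em)
        f = ns.forward("A", p)
        # only the free path can terminate a length-1 run
        expect = math.log(p.d * em["background"].prob("", "A"))
        assert f.loglik == pytest.approx(expect, abs=1e-12)

    def test_identical_emissions_loglik_factorizes(self):
        # emissions cancel: loglik = background log-prob of the sequence plus
        # the log mass of legal tilings, enumerated here independently
        em = identical_emissions(1)
        p = ns.HmmParams(L=3, d=0.6, rho=0.3, pi_nuc=0.5, pi_me3=0.2, emissions=em)
        seq = "ACGTACGTACGT"
        logp_bg = float(log_emission_arrays(seq, p)["background"].sum())

        def tiling_mass(t):  # sum of transition weights over legal tilings
            if t == 0:
                return 1.0
            m = p.d * tiling_mass(t - 1)
            if t >= p.L:
                m += (1 - p.d) * tiling_mass(t - p.L)
            return m

        expect = logp_bg + math.log(tiling_mass(len(seq)))
        f = ns.forward(seq, p)
        assert f.loglik == pytest.approx(expect, rel=1e-12)

    def test_forward_and_backward_logliks_agree(self):
        rng = np.random.default_rng(2)
        for _ in range(10):
            p = random_toy_params(rng, L=int(rng.integers(2, 8)))
            seq = random_seq(rng, int(rng.integers(p.L, 60)))
            f = ns.forward(seq, p)
            b = ns.backward(seq, p, f)
            assert b.loglik == pytest.approx(f.loglik, rel=1e-9)

    def test_alpha_rows_are_normalized(self):
        rng = np.random.default_rng(3)
        p = random_toy_params(rng, L=4)
        f = ns.forward(random_seq(rng, 30), p)
        assert np.allclose(f.alpha.sum(axis=1), 1.0, atol=1e-12)

    def test_n_in_sequence_rejected(self):
        p = random_toy_params(np.random.default_rng(0), L=3)
        with pytest.raises(ValueError, match="N"):
            ns.forward("ACGNACGT", p)


class TestPosterior:
    def test_matches_oracle_and_state_space_on_random_toys(self):
        rng = np.random.default_rng(4)
        for _ in range(25):
            p = random_toy_params(rng)
            T = int(rng.integers(p.L, 15))
            seq = random_seq(rng, T)
            fast = ns.posterior(seq, p)
            oracle = ns.brute_force_oracle(seq, p)
            gamma = state_posteriors(seq, p)
            assert fast.loglik == pytest.approx(oracle.loglik, abs=1e-9)
            for which, sl in (
                ("me3", slice(1, p.L + 1)),
                ("h3", slice(p.L + 1, 2 * p.L + 1)),
            ):
                got = getattr(fast, f"track_{which}").values
                want = getattr(oracle, f"track_{which}").values
                assert np.max(np.abs(got - want)) < 1e-9
                assert np.max(np.abs(gamma[:, sl].sum(axis=1) - want)) < 1e-9

    def test_three_tracks_conserve_probability(self):
        rng = np.random.default_rng(5)
        p = random_toy_params(rng, L=5)
        res = ns.posterior(random_seq(rng, 500), p)
        total = res.track_me3.values + res.track_h3.values + res.track_free.values
        assert np.max(np.abs(total - 1.0)) < 1e-9

    def test_rho_zero_forbids_me3(self):
        rng = np.random.default_rng(6)
        em = random_emissions(rng)
        p = ns.HmmParams(L=4, d=0.8, rho=0.0, pi_nuc=0.5, pi_me3=0.0, emissions=em)
        res = ns.posterior(random_seq(rng, 200), p)
        assert np.all(res.track_me3.values == 0.0)

    def test_identical_emissions_interior_is_stationary(self):
        em = identical_emissions(7)
        p = ns.calibrate_transitions(0.6, 0.3, L=5, emissions=em)
        res = ns.posterior(random_seq(np.random.default_rng(7), 3000), p)
        interior = res.track_me3.values[500:-500]
        assert np.max(np.abs(interior - p.pi_me3)) < 1e-6
        assert np.ptp(interior) < 1e-9  # constant across the interior

    def test_me3_mean_monotone_in_rho(self):
        rng = np.random.default_rng(8)
        em = random_emissions(rng)
        seq = random_seq(rng, 400)
        means = []
        for rho in (0.0, 0.25, 0.5, 0.75, 1.0):
            p = ns.HmmParams(
                L=5, d=0.8, rho=rho, pi_nuc=0.5, pi_me3=0.5 * rho, emissions=em
            )
            means.append(res := ns.posterior(seq, p).track_me3.values.mean())
        assert all(b >= a - 1e-12 for a, b in zip(means, means[1:]))


class TestSegmentProbability:
    def test_identical_emissions_return_priors(self):
        em = identical_emissions(9)
        p = ns.HmmParams(L=147, d=0.9, rho=0.0625, pi_nuc=0.8, pi_me3=0.05, emissions=em)
        pm, ph = ns.segment_probability("ACGTACGTACGTACG", p)
        assert pm == pytest.approx(0.05, abs=1e-12)
        assert ph == pytest.approx(0.75, abs=1e-12)

    def test_cg_favoring_table_prefers_me3_on_cg_segment(self):
        em = ns.make_emission_tables(me3_cg_boost=4.0)
        p = ns.calibrate_transitions(0.8, 0.05, L=147, emissions=em)
        pm, ph = ns.segment_probability("CG" * 40, p)
        assert pm > ph

    def test_length_and_n_guards(self):
        em = uniform_emissions()
        p = ns.HmmParams(L=10, d=0.9, rho=0.5, pi_nuc=0.5, pi_me3=0.25, emissions=em)
        with pytest.raises(ValueError):
            ns.segment_probability("ACGTA", p)  # < 6 bases
        with pytest.raises(ValueError):
            ns.segment_probability("ACGTACGTACGTA", p)  # > L
        with pytest.raises(ValueError):
            ns.segment_probability("ACGTNCGTA", p)


class TestRunGenome:
    def test_all_n_chromosome_fully_masked(self):
        p = random_toy_params(np.random.default_rng(0), L=3)
        (res,) = ns.run_genome([ns.GenomeSequence("c", "N" * 100)], p)
        assert not res.track_me3.mask.any()

    def test_short_run_cannot_hold_a_nucleosome(self):
        rng = np.random.default_rng(1)
        p = random_toy_params(rng, L=4)
        (res,) = ns.run_genome([ns.GenomeSequence("c", "ACGNACNGT")], p)
        # every N-free run is shorter than L: only the free state is possible
        assert np.all(res.track_me3.values[res.track_me3.mask] == 0.0)
        assert np.all(res.track_h3.values[res.track_h3.mask] == 0.0)
        assert np.allclose(res.track_free.values[res.track_free.mask], 1.0)

    def test_n_break_equals_independent_runs(self):
        rng = np.random.default_rng(2)
        p = random_toy_params(rng, L=3)
        a, b = random_seq(rng, 40), random_seq(rng, 25)
        (joint,) = ns.run_genome([ns.GenomeSequence("c", a + "N" + b)], p)
        ra = ns.posterior(a, p)
        rb = ns.posterior(b, p)
        assert np.allclose(joint.track_me3.values[:40], ra.track_me3.values, atol=1e-12)
        assert np.allclose(joint.track_me3.values[41:], rb.track_me3.values, atol=1e-12)
        assert joint.loglik == pytest.approx(ra.loglik + rb.loglik)

    def test_mask_region_excluded(self):
        rng = np.random.default_rng(3)
        p = random_toy_params(rng, L=3)
        mask = ns.RegionSet([ns.Region("c", 10, 20, ".", "keep")])
        (res,) = ns.run_genome([ns.GenomeSequence("c", random_seq(rng, 30))], p, mask=mask)
        assert res.track_me3.mask.sum() == 10
        assert not res.track_me3.mask[:10].any()

    def test_empty_genome_rejected(self):
        with pytest.raises(ValueError):
            ns.run_genome([], random_toy_params(np.random.default_rng(0)))


class TestBruteForceOracle:
    def test_shorter_than_l_is_all_free(self):
        p = random_toy_params(np.random.default_rng(0), L=4)
        res = ns.brute_force_oracle("ACG", p)
        assert np.allclose(res.track_free.values, 1.0)

    def test_three_arrangement_hand_normalization(self):
        # T = L = 3 with uniform emissions: arrangements are all-free,
        # one me3 nucleosome, one h3 nucleosome
        em = uniform_emissions()
        d, rho = 0.6, 0.3
        p = ns.HmmParams(L=3, d=d, rho=rho, pi_nuc=0.5, pi_me3=0.15, emissions=em)
        res = ns.brute_force_oracle("ACG", p)
        e = 0.25**3  # emission product, common to all three arrangements
        w_free, w_m, w_h = d**3 * e, (1 - d) * rho * e, (1 - d) * (1 - rho) * e
        z = w_free + w_m + w_h
        assert np.allclose(res.track_me3.values, w_m / z)
        assert np.allclose(res.track_h3.values, w_h / z)
        assert np.allclose(res.track_free.values, w_free / z)
        assert res.loglik == pytest.approx(math.log(z))

    def test_large_instance_guard(self):
        p = random_toy_params(np.random.default_rng(0), L=3)
        with pytest.raises(ValueError):
            ns.brute_force_oracle("A" * 30, p)
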