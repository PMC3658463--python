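import numpy as np
import pytest

import nucsig as ns


def random_emissions(rng: np.random.Generator) -> dict[str, ns.EmissionModel]:
    """Three random, well-formed fifth-order emission tables."""
    return {
        key: ns.EmissionModel(key, rng.dirichlet([1.0] * 4, size=1024))
        for key in ("me3", "h3", "background")
    }


def random_toy_params(rng: np.random.Generator, L: int | None = None) -> ns.HmmParams:
    """Random small-L parameters with random emissions for oracle sweeps."""
    if L is None:
        L = int(rng.integers(2, 5))
    return ns.HmmParams(
        L=L,
        d=float(rng.uniform(0.05, 0.95)),
        rho=float(rng.uniform(0.0, 1.0)),
        pi_nuc=0.5,
        pi_me3=0.25,
        emissions=random_emissions(rng),
    )


def random_seq(rng: np.random.Generator, T: int) -> str:
    return "".join("ACGT"[i] for i in rng.integers(0, 4, size=T))


@pytest.fixture(scope="session")
def e2e_bundle():
    """The full-scale synthetic study: 2 Mb genome, 2e5 reads per state.

    Session-scoped because generation plus decoding is the most expensive
    step in the suite; every test reads, never mutates, the bundle.
    """
    return ns.end_to_end_fixture(7, T=2_000_000, n_reads=200_000)


@pytest.fixture(scope="session")
def e2e_fit(e2e_bundle):
    truth = e2e_bundle["truth"]
    model = ns.NucleosomeOccupancyModel(
        [truth.genome], e2e_bundle["reads_me3"], e2e_bundle["reads_h3"]
    )
    return model.fit()


@pytest.fixture(scope="session")
def small_bundle():
    """A light-weight pipeline fixture for I/O and CLI tests."""
    return ns.end_to_end_fixture(11, T=40_000, n_reads=4_000)
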