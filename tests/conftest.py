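import numpy as np
import pytest

from poolgs.genotyping import AlleleFrequencyMatrix, ReadCountMatrix
from poolgs.pipeline import prepare_from_simulation
from poolgs.simulate import SimulationConfig, simulate_program


@pytest.fixture(scope="session")
def small_config():
    """A 6-year miniature program used by most integration-style tests."""
    return SimulationConfig(
        n_years=6,
        populations_per_year=10,
        n_loci=300,
        n_founders_per_group=60,
        n_qtl_biomass=40,
        n_qtl_heading=6,
        group_b_start_year=4,
        seed=7,
    )


@pytest.fixture(scope="session")
def small_sim(small_config):
    return simulate_program(small_config)


@pytest.fixture(scope="session")
def small_pipeline(small_sim):
    return prepare_from_simulation(small_sim)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def make_rcm(ref, alt, populations=None, loci=None):
    ref = np.atleast_2d(np.asarray(ref))
    alt = np.atleast_2d(np.asarray(alt))
    n, m = ref.shape
    return ReadCountMatrix(
        populations=populations or [f"POP{i + 1}" for i in range(n)],
        loci=loci or [f"chr1:{100 * (j + 1)}:A:G" for j in range(m)],
        ref_depth=ref,
        alt_depth=alt,
    )


def make_afm(af, populations=None, loci=None):
    af = np.atleast_2d(np.asarray(af, dtype=float))
    n, m = af.shape
    return AlleleFrequencyMatrix(
        populations=populations or [f"POP{i + 1}" for i in range(n)],
        loci=loci or [f"chr1:{100 * (j + 1)}:A:G" for j in range(m)],
        af=af,
    )
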