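import numpy as np
import pytest

from ribokinetics import (
    CodonContext,
    RATE_NAMES,
    RateSet,
    SyntheticSpec,
    build_codon_contexts,
    generate_fixture,
)
from ribokinetics.fixtures import random_rate_set


def random_instance(seed: int, rate_span=(1e-2, 1e4), conc_span=(0.01, 100.0)):
    """A random rate set and codon context with log-uniform draws."""
    rng = np.random.default_rng(seed)
    values = {
        name: float(np.exp(rng.uniform(np.log(rate_span[0]), np.log(rate_span[1]))))
        for name in RATE_NAMES
    }
    conc = np.exp(rng.uniform(np.log(conc_span[0]), np.log(conc_span[1]), size=3))
    rates = RateSet(**values)
    ctx = CodonContext("AAA", float(conc[0]), float(conc[1]), float(conc[2]), usage=1.0)
    return rates, ctx


@pytest.fixture(scope="session")
def moderate_rates():
    """A physiologically scaled rate set (fast cycles, cheap to simulate)."""
    return random_rate_set(np.random.default_rng(11), label="moderate")


@pytest.fixture(scope="session")
def simple_context():
    return CodonContext("GCU", c_cog=2.0, c_nea=1.0, c_non=5.0, usage=1.0)


@pytest.fixture(scope="session")
def small_fixture():
    """Synthetic study conditions: 20 codons decoded by 10 tRNA species."""
    return generate_fixture(SyntheticSpec(seed=7, n_trnas=10, n_codons=20))


@pytest.fixture(scope="session")
def small_contexts(small_fixture):
    contexts = build_codon_contexts(
        small_fixture.matrix, small_fixture.concentrations, small_fixture.usage
    )
    return tuple(contexts.values())
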