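import numpy as np
import pytest

from aggsense.kinetics import InjectionProtocol
from aggsense.presets import default_aggregate, default_monomer, default_species
from aggsense.synthetic import NoiseModel, simulate_mixture


@pytest.fixture(scope="session")
def species():
    return default_species()


@pytest.fixture(scope="session")
def monomer():
    return default_monomer()


@pytest.fixture(scope="session")
def aggregate():
    return default_aggregate()


def make_protocol(ph=3.8, total=0.45, fraction=0.0, **kw) -> InjectionProtocol:
    return InjectionProtocol(
        ph=ph,
        concentrations={
            "monomer": total * (1.0 - fraction),
            "aggregate": total * fraction,
        },
        **kw,
    )


@pytest.fixture(scope="session")
def mixture_trace_factory(species):
    """Factory for mixture traces: (fraction, ph, sigma, seed) -> Sensorgram."""

    def factory(fraction, ph=3.8, sigma=0.0, seed=0, total=0.45, bulk_jump=0.0):
        noise = None
        if sigma > 0 or bulk_jump != 0:
            noise = NoiseModel(sigma=sigma, bulk_jump=bulk_jump, seed=seed)
        return simulate_mixture(make_protocol(ph, total, fraction), species, noise)

    return factory


@pytest.fixture(autouse=True)
def _seeded_numpy():
    np.random.seed(12345)
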