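import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from fftbor import (
    BasePairRule,
    GeneratorConfig,
    NussinovModel,
    ThermoConstants,
    enumerate_structures,
    random_rna,
)

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")

#: pairing rule admitting every nucleotide combination — lets structure-only
#: properties (distance, restriction, parsing) range over all non-crossing
#: pair sets via enumeration of a homopolymer
PERMISSIVE_RULE = BasePairRule(
    allowed=frozenset(
        (a, b) for a in "ACGU" for b in "ACGU"
    )
)


@pytest.fixture
def micro_model():
    """Per-pair model with RT = 1 and epsilon = -1: hand-checkable numbers."""
    return NussinovModel(epsilon=-1.0, thermo=ThermoConstants(R=1.0, T=1.0))


def all_structures(n, theta=3):
    """Every non-crossing structure on n positions (pairing rule ignored)."""
    seq = random_rna(GeneratorConfig(seed=0, length=n, composition=(1, 0, 0, 0)))
    return enumerate_structures(seq, theta=theta, rule=PERMISSIVE_RULE).structures


def sample_structures(rng, n, count, theta=3):
    """Uniform draws from the full non-crossing ensemble on n positions."""
    pool = all_structures(n, theta)
    idx = rng.integers(0, len(pool), size=count)
    return [pool[int(k)] for k in idx]
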