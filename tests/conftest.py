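import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import subtelcnv as sc

settings.register_profile(
    "suite", max_examples=30, deadline=None, derandomize=True,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("suite")


@pytest.fixture(scope="session")
def desk_genome():
    """Small cohort genome: one homozygous-amplified resistant individual,
    one heterozygote, one susceptible."""
    spec, cas = sc.desk_scale(seed=11, tandem_copies=4)
    cohort = [sc.IndividualDesign("R1", (4, 4)),
              sc.IndividualDesign("R2", (2, 0)),
              sc.IndividualDesign("S1", (0, 0))]
    return sc.build_genome(spec, cas, cohort)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)


def random_seq(rng, n):
    return sc.simulate.decode_seq(rng.integers(0, 4, n, dtype=np.uint8))
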