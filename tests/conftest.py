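import numpy as np
import pytest
from hypothesis import settings

from sipoolkit import (
    AssemblyConfig,
    assemble_templates,
    generate_target_mrna,
    select_sirnas,
)

settings.register_profile("suite", deadline=None, derandomize=True)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def target_1500():
    return generate_target_mrna(1500, 0.45, rng_seed=42)


@pytest.fixture(scope="session")
def duplexes_15(target_1500):
    return select_sirnas(target_1500, 15, rng_seed=1)


@pytest.fixture(scope="session")
def template_15(duplexes_15):
    return assemble_templates(duplexes_15, AssemblyConfig(rng_seed=7))


def random_rna(rng: np.random.Generator, length: int, gc: float = 0.5) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(rng.choice(np.array(list("ACGU")), size=length, p=p))
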