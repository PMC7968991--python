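import numpy as np
import pytest

from grnaswitch import (
    EngineParams,
    NucSeq,
    ReferenceEngine,
    SwitchArchitecture,
    make_fixtures,
)


@pytest.fixture(scope="session")
def engine():
    return ReferenceEngine(EngineParams())


@pytest.fixture(scope="session")
def default_guide():
    return NucSeq("guide", "ACGUACGUACGUACGUACGUACGU")


@pytest.fixture(scope="session")
def default_arch(default_guide):
    return SwitchArchitecture(guide=default_guide)


@pytest.fixture(scope="session")
def bundle():
    return make_fixtures(seed=1, n_switches=4)


def random_rna(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list("ACGU"), size=length))
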