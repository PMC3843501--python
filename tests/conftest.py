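import numpy as np
import pytest
from hypothesis import settings

from kclust.kmer_engine import KmerSpec, ScoringModel

settings.register_profile("kclust", derandomize=True, max_examples=50)
settings.load_profile("kclust")


@pytest.fixture(scope="session")
def scoring() -> ScoringModel:
    return ScoringModel.blosum62()


@pytest.fixture(scope="session")
def spec6() -> KmerSpec:
    return KmerSpec.spaced_6mer()


@pytest.fixture(scope="session")
def spec4() -> KmerSpec:
    return KmerSpec.spaced_4mer()


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)
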