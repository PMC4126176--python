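import numpy as np
import pytest

from butyragene import refdb, synthfix


@pytest.fixture(scope="session")
def small_cfg() -> synthfix.SynthConfig:
    """Two tiny samples per family; enough to exercise every stage."""
    return synthfix.SynthConfig(seed=11, n_samples=2, n_reads_per_sample=30)


@pytest.fixture(scope="session")
def families(small_cfg):
    return synthfix.make_reference_families(small_cfg)


@pytest.fixture(scope="session")
def but_family(families):
    return families["but"]


@pytest.fixture(scope="session")
def but_curation(but_family) -> refdb.CurationResult:
    return refdb.curate(list(but_family.refs))


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(20131)


def random_protein(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=length))
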