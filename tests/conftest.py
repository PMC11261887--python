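import numpy as np
import pytest

from cleanhalf.ani_classify import MinHashParams
from cleanhalf.report_cli import build_sketches
from cleanhalf.synthetic_data import ReferenceSet, SimConfig, build_reference_set


@pytest.fixture(scope="session")
def small_config() -> SimConfig:
    return SimConfig(
        seed=1,
        taxa_per_rank=(2, 1, 2, 2, 2, 2),
        genome_len=30_000,
        n_contigs=10,
        genes_per_kb=1.0,
        contamination_fraction=0.3,
        contamination_rank="f",
        assignment_error=0.05,
    )


@pytest.fixture(scope="session")
def refs(small_config) -> ReferenceSet:
    return build_reference_set(small_config)


@pytest.fixture(scope="session")
def ref_sketches(refs):
    return build_sketches(refs, MinHashParams())


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(7)
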