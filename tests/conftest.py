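import numpy as np
import pytest

from cycflex.predictor import LinearDinucModel
from cycflex.randomization import PositionalBaseModel
from cycflex.sequence_io import GenomeStore
from cycflex import synthetic_data as sd

BASES = np.array(list("ACGT"))


def random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(BASES[rng.integers(0, 4, length)])


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def toy_genome(rng):
    return GenomeStore({
        "chr1": random_seq(rng, 5000),
        "chr2": random_seq(rng, 3000),
    })


@pytest.fixture
def truth_model(rng):
    return LinearDinucModel.random_symmetric(rng, scale=0.15)


@pytest.fixture
def ta_model():
    return LinearDinucModel.from_dict({"TA": 1.0})


@pytest.fixture
def constant_model():
    return LinearDinucModel.from_dict({}, b=0.7)


@pytest.fixture(scope="session")
def planted_sim():
    """Small planted-promoter genome shared across profile tests."""
    spec = sd.SyntheticGenomeSpec(
        chrom_lengths=(120_000,),
        background_trans=sd.uniform_background_trans(),
        n_genes=120,
        promoter_model=sd.default_promoter_model(150),
        tata_fraction=0.0,
        seed=11,
    )
    return spec, sd.simulate_genome(spec)
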