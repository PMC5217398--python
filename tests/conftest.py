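import numpy as np
import pytest

from dgetag import (
    NoiseProfile,
    extract_virtual_tags,
    generate_transcriptome,
    make_de_scenario,
)


@pytest.fixture(scope="session")
def transcripts():
    """50 random transcripts, every one with >=1 valid CATG+17 site."""
    return generate_transcriptome(n_genes=50, length_range=(200, 400), seed=3)


@pytest.fixture(scope="session")
def index(transcripts):
    return extract_virtual_tags(transcripts)


@pytest.fixture(scope="session")
def scenario(transcripts):
    return make_de_scenario(transcripts, frac_de=0.1, log2fc_magnitude=2.0, seed=11)


@pytest.fixture()
def quiet_noise():
    return NoiseProfile(seed=5)


def random_tag(rng: np.random.Generator) -> str:
    return "CATG" + "".join(rng.choice(list("ACGT"), size=17))
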