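import numpy as np
import pytest

from chromacast.simulate import SyntheticSpec


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def tiny_spec():
    """A miniature synthetic dataset spec for fast I/O and pipeline tests."""
    return SyntheticSpec(
        n_sequences=6,
        seq_length=2048,
        n_sites=1,
        atac_peak_width=150,
        chip_peak_width=300,
        chip_offset=150,
        subseq_len=512,
        seed=11,
    )


@pytest.fixture(scope="session")
def tiny_dataset(tiny_spec, tmp_path_factory):
    """Tiny generated dataset on disk, shared across tests."""
    from chromacast.simulate import generate_dataset

    out = tmp_path_factory.mktemp("tiny_dataset")
    paths = generate_dataset(tiny_spec, out)
    return tiny_spec, paths
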