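import numpy as np
import pytest

from promoshift.io_formats import MotifClass, PSSM


@pytest.fixture
def rng():
    return np.random.default_rng(42)


def one_hot_pssm(consensus: str, motif_id: str = "m", motif_class=MotifClass.CORE_PROMOTER) -> PSSM:
    probs = np.zeros((len(consensus), 4))
    for i, b in enumerate(consensus):
        probs[i, "ACGT".index(b)] = 1.0
    return PSSM(motif_id, motif_class, probs)


@pytest.fixture
def tiny_dataset(tmp_path):
    """A 150-gene synthetic study on disk, shared within one test module."""
    from promoshift.synthetic_data import SyntheticConfig, generate_dataset

    cfg = SyntheticConfig(seed=11, n_genes=150)
    paths, truth = generate_dataset(cfg, tmp_path / "data")
    return cfg, paths, truth
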