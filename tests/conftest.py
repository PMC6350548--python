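import numpy as np
import pytest

import mammodense as md
from mammodense.mammo_io import preprocess


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def tiny_spec():
    return md.assemble_network(md.tiny_config())


def make_phantoms(n=4, contrast=0.25, seed=7, canvas=64, size_range=(10, 20),
                  noise_sd=0.03):
    """Desk-scale 64x64 phantoms with clinical-like class imbalance."""
    cfg = md.PhantomConfig(canvas_side=canvas, tumor_size_range=size_range,
                           tumor_contrast=contrast, noise_sd=noise_sd)
    phantoms, _ = md.generate_dataset(n, cfg, seed=seed)
    return phantoms


def as_training_pairs(phantoms, side=64):
    return [(preprocess(p.image, side=side), p.mask.astype(np.int64))
            for p in phantoms]


@pytest.fixture(scope="session")
def small_phantoms():
    return make_phantoms()


@pytest.fixture(scope="session")
def training_pairs(small_phantoms):
    return as_training_pairs(small_phantoms)
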