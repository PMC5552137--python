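import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from glycosite.peptide_windows import AMINO_ACIDS, SiteWindow
from glycosite.synthetic_data import SimConfig, generate_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def random_window(rng, length=41, pad_free=True):
    """A random SiteWindow; pad-free windows use only codes 1..20."""
    lo = 1 if pad_free else 0
    codes = rng.integers(lo, 21, size=length)
    return SiteWindow(codes)


@pytest.fixture
def random_windows(rng):
    return [random_window(rng) for _ in range(25)]


@pytest.fixture(scope="session")
def separable_dataset():
    """Small labeled window set with a strong sequon signal (fixed seed)."""
    cfg = SimConfig(n_pos=60, n_neg=60, sequon_prob_pos=0.95,
                    sequon_prob_neg=0.05, seed=7)
    return generate_dataset(cfg)


@pytest.fixture(scope="session")
def residue_alphabet():
    return AMINO_ACIDS
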