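import numpy as np
import pytest

from retfusion import generate_dataset
from retfusion.preprocess import PreprocessConfig, preprocess_dataset


@pytest.fixture(scope="session")
def phantom_pairs():
    """Twelve raw phantom report pairs on a 128 px canvas (seeded)."""
    return generate_dataset(12, seed=42, canvas_size=128)


@pytest.fixture(scope="session")
def samples32(phantom_pairs):
    """Phantom pairs pushed through the full pipeline at a 32 px canvas."""
    records = [(p.fa_report, p.oct_report, p.laterality, p.grade_label,
                f"{i:03d}") for i, p in enumerate(phantom_pairs)]
    samples, rows, manual = preprocess_dataset(
        records, PreprocessConfig(canvas_side=32))
    assert not manual
    return samples


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)


def random_rgb(rng, h=48, w=48):
    return rng.integers(0, 256, (h, w, 3), dtype=np.uint8)


def random_gray(rng, h=48, w=48):
    return rng.integers(0, 256, (h, w), dtype=np.uint8)
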