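import numpy as np
import pytest

from foundress import BroodRecord, CurveTruth, GeneratorDesign, generate_dataset


@pytest.fixture(scope="session")
def curve_dataset():
    """Default-shaped synthetic dataset from the logistic-curve truth."""
    return generate_dataset(GeneratorDesign(seed=42))


@pytest.fixture
def small_records():
    """A tiny hand-written brood list covering all kinship levels."""
    return [
        BroodRecord(1, "single", 1, 9),
        BroodRecord(1, "single", 2, 10),
        BroodRecord(2, "sisters", 2, 16),
        BroodRecord(2, "nonsisters", 7, 13),
        BroodRecord(4, "sisters", 5, 30),
        BroodRecord(4, "nonsisters", 14, 21),
    ]
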