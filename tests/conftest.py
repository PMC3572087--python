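import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for _oracles

from sglut.seqio import ALPHABET, POSITIVE, NEGATIVE, WindowSample


def random_peptide(rng: np.random.Generator, w: int = 15) -> str:
    mid = w // 2
    aas = rng.choice(list(ALPHABET), size=w)
    aas[mid] = "C"
    return "".join(aas)


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def random_windows(rng):
    def make(n: int, w: int = 15) -> list[WindowSample]:
        return [
            WindowSample(f"r{i}", w // 2 + 1, random_peptide(rng, w),
                         POSITIVE if i % 3 == 0 else NEGATIVE)
            for i in range(n)
        ]

    return make


@pytest.fixture(scope="session")
def worked_windows():
    from sglut.synth import worked_example_windows

    return worked_example_windows()


@pytest.fixture(scope="session")
def strong_dataset():
    """A default strong-signal synthetic dataset with its extracted windows."""
    from sglut.synth import SynthConfig, generate_dataset
    from sglut.seqio import extract_labeled_windows

    proteins, annotations = generate_dataset(SynthConfig(seed=7))
    windows, _ = extract_labeled_windows(proteins, annotations, 15)
    return proteins, annotations, windows
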