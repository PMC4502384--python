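import numpy as np
import pytest

from cochip.formats_io import GeneRecord, GenomeSequence, PWMRecord
from cochip.synthetic_data import SyntheticSpec, generate_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def simple_pwm():
    """An informative width-4 motif with continuous-valued rows."""
    mat = np.array([
        [0.70, 0.10, 0.15, 0.05],
        [0.05, 0.80, 0.05, 0.10],
        [0.10, 0.05, 0.70, 0.15],
        [0.15, 0.05, 0.10, 0.70],
    ])
    return PWMRecord("tf1", mat)


@pytest.fixture
def tiny_genome():
    rng = np.random.default_rng(5)
    seq = "".join("ACGT"[i] for i in rng.integers(0, 4, size=5000))
    return GenomeSequence({"chr1": seq})


@pytest.fixture
def plus_gene():
    return GeneRecord("gA", "chr1", "+", 2001, (2000, 3000))


@pytest.fixture
def minus_gene():
    return GeneRecord("gB", "chr1", "-", 3000, (2200, 3000))


@pytest.fixture(scope="session")
def default_dataset():
    """One default-condition synthetic dataset shared across tests."""
    return generate_dataset(SyntheticSpec(seed=42))


def random_genome(rng, n_chroms=3, min_len=50, max_len=400):
    chroms = {}
    for i in range(n_chroms):
        n = int(rng.integers(min_len, max_len))
        chroms[f"chr{i + 1}"] = "".join(
            "ACGTN"[j] for j in rng.choice(5, size=n, p=[0.24, 0.24, 0.24, 0.24, 0.04]))
    return GenomeSequence(chroms)
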