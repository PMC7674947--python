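import numpy as np
import pytest

from mam.demo import demo_genome
from mam.local_index import build_mam_index
from mam.simeval import RepeatFamily, SimParams, simulate_genome


@pytest.fixture(scope="session")
def demo_index():
    """MAM-index of the 140 bp worked-example reference at toy parameters."""
    return build_mam_index(demo_genome(), l_init=6, l_ext=4, k=2, max_depth=8)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def small_repeat_genome(seed: int, length: int = 2000, copies: int = 6,
                        unit: int = 60, divergence: float = 0.02):
    """A small genome with two planted repeat families, plus its params."""
    params = SimParams(
        genome_length=length,
        families=(
            RepeatFamily(copies=copies, unit_length=unit, divergence=divergence),
            RepeatFamily(copies=copies, unit_length=unit, divergence=divergence),
        ),
        seed=seed,
    )
    genome, _ = simulate_genome(params)
    return genome


def random_dna(rng: np.random.Generator, n: int) -> str:
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=n)])
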