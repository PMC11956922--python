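import numpy as np
import pytest

from sdparalog.synthetic_cohort import SimConfig, simulate_cohort, simulate_family

BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def random_seq(rng: np.random.Generator, n: int) -> str:
    return BASES[rng.integers(0, 4, n)].tobytes().decode()


def mutate_seq(seq: str, n_subs: int, rng: np.random.Generator) -> str:
    """Independent substitution helper for constructing test pairs."""
    arr = list(seq)
    for pos in rng.choice(len(seq), size=n_subs, replace=False):
        arr[pos] = "ACGT"[("ACGT".index(arr[pos]) + int(rng.integers(1, 4))) % 4]
    return "".join(arr)


@pytest.fixture
def rng():
    return np.random.default_rng(20250930)


@pytest.fixture(scope="session")
def family_panel():
    """One reference paralog family under the default study conditions."""
    return simulate_family(SimConfig(), np.random.default_rng(5))


@pytest.fixture(scope="session")
def small_cohort():
    """A 25-haplotype cohort with truth, plus its reference panel."""
    cfg = SimConfig(n_haplotypes=25)
    cohort, truth = simulate_cohort(cfg, np.random.default_rng(7))
    return cohort, truth
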