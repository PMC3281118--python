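import numpy as np
import pytest

from smartltr.io_formats import GenomeRecord
from smartltr.synthetic_data import SimConfig, simulate_genome

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def rand_dna(rng: np.random.Generator, n: int) -> str:
    """Uniform random DNA, fast enough for Mb-scale fixtures."""
    return _BASES[rng.integers(0, 4, n)].tobytes().decode("ascii")


def build_element(rng, ltr_len: int = 85, internal_len: int = 122):
    """A complete element with identical LTRs: TGT...ACA | internal | TGT...ACA."""
    ltr = "TGT" + rand_dna(rng, ltr_len - 6) + "ACA"
    internal = rand_dna(rng, internal_len)
    return ltr + internal + ltr, ltr, internal


def plant(background: str, pos: int, element: str, tsd: str = "GACTC"):
    """Insert an element with a duplicated target site at ``pos``.

    Returns (sequence, element_start, element_end) - the span excludes the
    TSD copies, matching the annotation convention.
    """
    seq = background[:pos] + tsd + element + tsd + background[pos:]
    start = pos + len(tsd)
    return seq, start, start + len(element)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


@pytest.fixture(scope="session")
def small_sim():
    """A modest simulated genome reused by read-only tests."""
    cfg = SimConfig(
        genome_length=150_000, n_complete=8, n_solo=3, n_fragment=4,
        n_genes=8, seed=11,
    )
    return cfg, simulate_genome(cfg)


@pytest.fixture(scope="session")
def young_sim():
    """All elements at age 0: identical LTR pairs and identical copies."""
    cfg = SimConfig(
        genome_length=200_000, n_complete=15, n_solo=0, n_fragment=0,
        n_genes=5, ages_mya=[0.0], seed=19,
    )
    return cfg, simulate_genome(cfg)


@pytest.fixture()
def null_genome(rng):
    return GenomeRecord("null", rand_dna(rng, 10_000))
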