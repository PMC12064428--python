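import numpy as np
import pytest

from oakintro.genotype_io import MISSING, GenotypeMatrix


def make_genotypes(calls, pop_ids, individual_ids=None, loci=None):
    """Small-fixture helper: calls is a nested list (n, L, 2)."""
    calls = np.asarray(calls, dtype=np.int64)
    n, L = calls.shape[:2]
    if individual_ids is None:
        individual_ids = [f"i{k + 1}" for k in range(n)]
    if loci is None:
        loci = [f"L{l + 1}" for l in range(L)]
    return GenotypeMatrix(individual_ids, [str(p) for p in pop_ids], loci, calls)


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def two_pop_fixture():
    """Hand-computable two-population, one-locus fixture.

    pop1: (A,A), (A,B) -> p = (0.75, 0.25), Ho = 0.5
    pop2: (B,B), (B,B) -> p = (0, 1), Ho = 0
    Closed forms (Nei & Chesser corrections, harmonic n = 2, k = 2):
    Hs = 0.25, Ht = 0.5, FST = 0.5, Jost D = 2/3.
    """
    A, B = 100, 102
    return make_genotypes(
        [[[A, A]], [[A, B]], [[B, B]], [[B, B]]],
        ["p1", "p1", "p2", "p2"],
    )


@pytest.fixture
def missing_sentinel():
    return MISSING
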