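import numpy as np
import pytest

from cropboost import geno, simpop
from cropboost.pedigree import Pedigree


def make_genotypes(calls, sample_ids=None, marker_ids=None):
    """GenotypeMatrix from a nested list of 2-char call strings."""
    calls = np.asarray(calls, dtype="<U2")
    n, m = calls.shape
    sample_ids = sample_ids or [f"s{i}" for i in range(n)]
    marker_ids = marker_ids or [f"snp{j}" for j in range(m)]
    chrom = np.array(["chr1"] * m, dtype=object)
    pos = np.arange(1, m + 1) * 1000
    return geno.GenotypeMatrix(sample_ids, marker_ids, chrom, pos, calls)


@pytest.fixture
def tiny_genotypes():
    """3 samples x 4 markers covering hom/het/missing calls."""
    return make_genotypes(
        [["AA", "AG", "CC", "TT"],
         ["AG", "GG", "CT", "NN"],
         ["AA", "AA", "TT", "TT"]])


@pytest.fixture(scope="session")
def small_pop():
    """Small NC-II population shared by read-only tests."""
    cfg = simpop.SimConfig(n_maternal=60, n_testers=5, n_markers=120,
                           n_qtl=8, h2=0.6, seed=11)
    return simpop.simulate_population(cfg)


@pytest.fixture
def factorial_pedigree():
    """4 mothers x 3 fathers full factorial."""
    mothers = [f"m{i}" for i in range(4)]
    fathers = [f"f{j}" for j in range(3)]
    return simpop.make_crosses(mothers, fathers)
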