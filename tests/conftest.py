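"""Shared fixtures: small genotype matrices with hand-checkable structure."""

import numpy as np
import pytest

from clinepop import GenotypeMatrix, PopulationMap
from clinepop.genotypes import MISSING


@pytest.fixture
def two_pop_matrix() -> tuple[GenotypeMatrix, PopulationMap]:
    """2 populations x 4 diploids x 3 loci, fully genotyped, hand-enumerable."""
    dosage = np.array([
        # L1 L2 L3
        [0, 1, 2],
        [1, 1, 2],
        [1, 1, 2],
        [2, 1, 2],
        [0, 1, 0],
        [0, 1, 0],
        [1, 1, 0],
        [1, 1, 0],
    ], dtype=np.int8)
    samples = [f"s{i}" for i in range(8)]
    pops = ["A"] * 4 + ["B"] * 4
    G = GenotypeMatrix(samples=samples, populations=pops,
                       loci=["L1", "L2", "L3"], dosage=dosage)
    pm = PopulationMap(populations={"A": samples[:4], "B": samples[4:]})
    return G, pm


@pytest.fixture
def missing_cell_matrix() -> tuple[GenotypeMatrix, PopulationMap]:
    dosage = np.array([[0, 1], [MISSING, 1], [2, MISSING]], dtype=np.int8)
    samples = ["x1", "x2", "x3"]
    G = GenotypeMatrix(samples=samples, populations=["A", "A", "A"],
                       loci=["L1", "L2"], dosage=dosage)
    pm = PopulationMap(populations={"A": samples})
    return G, pm


def make_qc_fixture():
    """30 individuals x 20 loci engineered so each QC stage removes a known set.

    With the default thresholds (call rate >= 0.75, individual missingness
    <= 0.20, MAF > 0.05, HWE alpha = 0.05 in >= 6 of 6 populations):

    * loci L01, L02 are missing in 10/30 individuals (call rate 2/3 < 0.75)
      -> fail stage 1; the affected individuals then carry 2/20 = 10%
      missing calls, so stage 2 removes nobody;
    * loci L03, L04, L05 carry a single heterozygote among 30 diploids
      (MAF = 1/60) -> fail stage 3;
    * locus L06 shows complete heterozygote deficit with dosages
      (0, 0, 0, 2, 2) in each of the 6 populations of 5 diploids: the exact
      test gives p = 1/21 = 0.0476 < 0.05 in all 6 -> fails stage 4;
    * 14 loci remain (20 - 2 - 3 - 1).
    """
    rng = np.random.default_rng(1234)
    n, m = 30, 20
    # benign polymorphic background for the surviving loci
    dosage = rng.binomial(2, 0.5, size=(n, m)).astype(np.int8)
    # L01, L02: missing for the first 10 individuals -> call rate 20/30
    dosage[:10, 0] = MISSING
    dosage[:10, 1] = MISSING
    # L03-L05: single heterozygote, everyone else homozygous reference
    for j in (2, 3, 4):
        dosage[:, j] = 0
        dosage[5, j] = 1
    samples = [f"i{i:02d}" for i in range(n)]
    pops = [f"P{i % 6}" for i in range(n)]  # 6 populations x 5 diploids
    # L06: (3 hom-ref, 0 het, 2 hom-alt) within every population
    for p in range(6):
        idx = [i for i in range(n) if i % 6 == p]
        dosage[idx[:3], 5] = 0
        dosage[idx[3:], 5] = 2
    loci = [f"L{j + 1:02d}" for j in range(m)]
    G = GenotypeMatrix(samples=samples, populations=pops, loci=loci, dosage=dosage)
    popmap = PopulationMap(populations={
        p: [s for s, sp in zip(samples, pops) if sp == p]
        for p in sorted(set(pops))})
    return G, popmap


@pytest.fixture
def qc_fixture():
    return make_qc_fixture()
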