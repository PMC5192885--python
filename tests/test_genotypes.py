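"""Genotype containers, I/O round-trips, allele statistics, HWE and QC."""

import itertools
from math import comb

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from clinepop import (GenotypeMatrix, PopulationMap, QCThresholds,
                      allele_statistics, apply_qc_filters, hwe_exact_test,
                      read_genotypes, write_genotypes)
from clinepop.genotypes import MISSING
from clinepop.io import read_popmap, write_popmap


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

VCF_TOY = """##fileformat=VCFv4.2
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##contig=<ID=1>
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\ts1\ts2\ts3
1\t100\tlocA\tA\tG\t.\t.\t.\tGT\t0/0\t0/1\t1/1
1\t200\tlocB\tC\tT\t.\t.\t.\tGT\t0/1\t./.\t0/0
"""


def test_vcf_dosages_and_missing(tmp_path):
    """Alternate-allele dosage encoding, with ./. preserved as missing."""
    path = tmp_path / "toy.vcf"
    path.write_text(VCF_TOY)
    pm = PopulationMap(populations={"X": ["s1", "s2", "s3"]})
    G = read_genotypes(path, "vcf", pm)
    assert G.samples == ["s1", "s2", "s3"]
    assert G.loci == ["locA", "locB"]
    assert list(G.dosage[:, 0]) == [0, 1, 2]
    assert G.dosage[1, 1] == MISSING
    assert G.dosage[0, 1] == 1 and G.dosage[2, 1] == 0


def test_vcf_rejects_multiallelic(tmp_path):
    text = VCF_TOY.replace("1\t200\tlocB\tC\tT", "1\t200\tlocB\tC\tT,G")
    path = tmp_path / "bad.vcf"
    path.write_text(text)
    with pytest.raises(ValueError, match="locB"):
        read_genotypes(path, "vcf")


def test_vcf_unknown_sample_named(tmp_path):
    path = tmp_path / "toy.vcf"
    path.write_text(VCF_TOY)
    pm = PopulationMap(populations={"X": ["s1", "s2"]})
    with pytest.raises(ValueError, match="s3"):
        read_genotypes(path, "vcf", pm)


@pytest.mark.parametrize("fmt", ["vcf", "plink-text"])
def test_roundtrip_identity(tmp_path, fmt, two_pop_matrix):
    """write_genotypes then read_genotypes reproduces the matrix exactly."""
    G, pm = two_pop_matrix
    G.dosage[0, 0] = MISSING  # include a missing call in the round trip
    path = tmp_path / ("g.vcf" if fmt == "vcf" else "g")
    write_genotypes(G, path, fmt)
    back = read_genotypes(path, fmt, pm)
    assert back == G


def test_popmap_roundtrip(tmp_path):
    pm = PopulationMap(populations={"A": ["s1", "s2"], "B": ["s3"]},
                       positions_km={"A": 0.0, "B": 120.5})
    write_popmap(pm, tmp_path / "pm.tsv", positions_path=tmp_path / "pos.tsv")
    back = read_popmap(tmp_path / "pm.tsv", positions_path=tmp_path / "pos.tsv")
    assert back.populations == pm.populations
    assert back.positions_km == pm.positions_km


# ---------------------------------------------------------------------------
# allele statistics
# ---------------------------------------------------------------------------

def test_allele_statistics_hand_counts():
    """Dosages (0,1,1,2) give p = 0.5 with n = 8 alleles; all-het pop gives
    p = 0.5, He = 0.5; a monomorphic locus gives MAF = He = 0."""
    dosage = np.array([[0, 1, 0], [1, 1, 0], [1, 1, 0], [2, 1, 0]], dtype=np.int8)
    samples = ["a", "b", "c", "d"]
    G = GenotypeMatrix(samples=samples, populations=["A"] * 4,
                       loci=["L1", "L2", "L3"], dosage=dosage)
    pm = PopulationMap(populations={"A": samples})
    stats = allele_statistics(G, pm)
    ft = stats.freqs
    assert ft.p[0, 0] == 0.5 and ft.n[0, 0] == 8
    assert ft.p[0, 1] == 0.5 and stats.expected_het[1] == 0.5
    assert stats.maf[2] == 0.0 and stats.expected_het[2] == 0.0


def test_empty_population_cell_flagged_not_zero(missing_cell_matrix):
    G, pm = missing_cell_matrix
    G2 = G.subset(sample_idx=[1], locus_idx=[0])  # only a missing call at L1
    stats = allele_statistics(G2, pm)
    assert np.isnan(stats.freqs.p[0, 0])
    assert stats.freqs.n[0, 0] == 0


@settings(max_examples=50, deadline=None, derandomize=True)
@given(st.integers(0, 2**31 - 1))
def test_allele_count_is_integer(seed):
    """p * n recovers an integer allele count for every (population, locus)."""
    rng = np.random.default_rng(seed)
    n, m = rng.integers(2, 12), rng.integers(1, 8)
    dosage = rng.choice([0, 1, 2, MISSING], size=(n, m)).astype(np.int8)
    samples = [f"s{i}" for i in range(n)]
    pops = ["A" if i < n // 2 else "B" for i in range(n)]
    G = GenotypeMatrix(samples=samples, populations=pops,
                       loci=[f"L{j}" for j in range(m)], dosage=dosage)
    pm = PopulationMap(populations={
        p: [s for s, sp in zip(samples, pops) if sp == p]
        for p in dict.fromkeys(pops)})
    ft = allele_statistics(G, pm).freqs
    counts = ft.p * ft.n
    ok = ~np.isnan(counts)
    assert np.allclose(counts[ok], np.round(counts[ok]), atol=1e-9)


# ---------------------------------------------------------------------------
# Hardy-Weinberg exact test
# ---------------------------------------------------------------------------

def hwe_oracle(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """Brute-force exact test: enumerate genotype configurations with the
    observed allele counts and sum Levene probabilities <= the observed one."""
    n = n_AA + n_Aa + n_aa
    nA = 2 * n_AA + n_Aa
    na = 2 * n - nA
    if nA == 0 or na == 0:
        return 1.0
    probs = {}
    for h in range(min(nA, na) + 1):
        if (nA - h) % 2 or h > nA or h > na:
            continue
        aa1, aa2 = (nA - h) // 2, (na - h) // 2
        if aa1 < 0 or aa2 < 0:
            continue
        # P = n! / (aa1! h! aa2!) * 2^h * nA! na! / (2n)!
        num = (comb(n, aa1) * comb(n - aa1, h) * 2**h)
        probs[h] = num
    tot = sum(probs.values())
    obs = probs[n_Aa]
    return sum(v for v in probs.values() if v <= obs) / tot


def test_hwe_matches_enumeration_small():
    for n_AA, n_Aa, n_aa in [(1, 0, 1), (5, 0, 0), (2, 3, 2), (0, 5, 0),
                             (3, 0, 2), (25, 50, 25)]:
        assert hwe_exact_test(n_AA, n_Aa, n_aa) == pytest.approx(
            hwe_oracle(n_AA, n_Aa, n_aa), abs=1e-12)


def test_hwe_trivial_cases():
    assert hwe_exact_test(5, 0, 0) == 1.0
    assert hwe_exact_test(0, 0, 7) == 1.0
    assert hwe_exact_test(1, 0, 1) == pytest.approx(1 / 3, abs=1e-12)
    assert hwe_exact_test(25, 50, 25) > 0.9
    with pytest.raises(ValueError):
        hwe_exact_test(0, 0, 0)


# ---------------------------------------------------------------------------
# QC chain
# ---------------------------------------------------------------------------

def test_qc_stage_counts_match_construction(qc_fixture):
    G, pm = qc_fixture
    G2, report = apply_qc_filters(G, pm, QCThresholds())
    frame = report.to_frame().set_index("stage")
    assert frame.loc["locus_call_rate", "n_loci_removed"] == 2
    assert frame.loc["individual_missingness", "n_samples_removed"] == 0
    assert frame.loc["maf", "n_loci_removed"] == 3
    assert frame.loc["hwe", "n_loci_removed"] == 1
    assert G2.n_loci == 14
    removed = set(report.stages[0].removed_loci)
    assert removed == {"L01", "L02"}
    assert set(report.stages[2].removed_loci) == {"L03", "L04", "L05"}
    assert set(report.stages[3].removed_loci) == {"L06"}


def test_qc_individual_missingness_removal():
    """An individual above the missing-call ceiling is dropped at stage 2."""
    rng = np.random.default_rng(0)
    dosage = rng.binomial(2, 0.5, size=(6, 10)).astype(np.int8)
    dosage[0, :5] = MISSING  # 50% missing
    samples = [f"s{i}" for i in range(6)]
    G = GenotypeMatrix(samples=samples, populations=["A"] * 6,
                       loci=[f"L{j}" for j in range(10)], dosage=dosage)
    pm = PopulationMap(populations={"A": samples})
    thr = QCThresholds(locus_call_rate_min=0.0, maf_min=0.0,
                       indiv_missing_max=0.20, hwe_alpha=0.0)
    G2, report = apply_qc_filters(G, pm, thr)
    assert report.stages[1].removed_samples == ["s0"]
    assert G2.n_samples == 5


def test_qc_noop_thresholds_identity(qc_fixture):
    G, pm = qc_fixture
    G2, _ = apply_qc_filters(G, pm, QCThresholds.none())
    assert G2 == G


def test_qc_idempotent(qc_fixture):
    G, pm = qc_fixture
    thr = QCThresholds()
    G1, _ = apply_qc_filters(G, pm, thr)
    G2, rep2 = apply_qc_filters(G1, pm, thr)
    assert G2 == G1
    assert all(len(s.removed_loci) == 0 and len(s.removed_samples) == 0
               for s in rep2.stages)


def test_qc_threshold_validation():
    with pytest.raises(ValueError):
        QCThresholds(maf_min=1.5)
    with pytest.raises(ValueError):
        QCThresholds(indiv_missing_max=-0.1)


def test_filter_report_counts_chain(qc_fixture):
    G, pm = qc_fixture
    _, report = apply_qc_filters(G, pm, QCThresholds())
    frame = report.to_frame()
    # non-increasing along the chain; removed + retained = input
    assert (frame["loci_after"] <= frame["loci_before"]).all()
    assert (frame["loci_before"] - frame["loci_after"] == frame["n_loci_removed"]).all()
    assert list(frame["loci_before"][1:]) == list(frame["loci_after"][:-1])
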