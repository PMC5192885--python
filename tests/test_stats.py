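"""Summary statistics against hand-computed and brute-force oracles."""

import itertools

import numpy as np
import pandas as pd
import pytest

from clinepop import (GenotypeMatrix, PopulationMap, allele_statistics, amova,
                      chord_distance, chord_distance_matrix, ld_r2, mantel_test,
                      nj_tree, pairwise_fst, pca_kmeans_bic, wc_fst)
from clinepop.genotypes import MISSING
from clinepop.simulate import SimulationConfig, sample_genotypes


def _matrix(dosage, pops):
    dosage = np.asarray(dosage, dtype=np.int8)
    samples = [f"s{i}" for i in range(dosage.shape[0])]
    G = GenotypeMatrix(samples=samples, populations=list(pops),
                       loci=[f"L{j}" for j in range(dosage.shape[1])],
                       dosage=dosage)
    pm = PopulationMap(populations={
        p: [s for s, sp in zip(samples, pops) if sp == p]
        for p in dict.fromkeys(pops)})
    return G, pm


# ---------------------------------------------------------------------------
# Weir-Cockerham F_ST
# ---------------------------------------------------------------------------

def wc_oracle_two_pops(n1, p1, h1, n2, p2, h2):
    """Weir & Cockerham (1984) components for two populations, written out
    in scalar arithmetic straight from the published formulas."""
    r = 2
    nbar = (n1 + n2) / r
    nc = (n1 + n2 - (n1**2 + n2**2) / (n1 + n2)) / (r - 1)
    pbar = (n1 * p1 + n2 * p2) / (n1 + n2)
    s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1) * nbar)
    hbar = (n1 * h1 + n2 * h2) / (n1 + n2)
    a = nbar / nc * (s2 - 1 / (nbar - 1) * (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4))
    b = nbar / (nbar - 1) * (pbar * (1 - pbar) - (r - 1) / r * s2 - (2 * nbar - 1) / (4 * nbar) * hbar)
    c = hbar / 2
    return a, b, c


def test_wc_fst_matches_hand_formula():
    """2 populations x 4 diploids toy table equals the published component
    arithmetic a / (a + b + c)."""
    dosage = [[0, 2], [1, 2], [1, 1], [2, 2],
              [0, 0], [0, 1], [1, 0], [1, 0]]
    G, pm = _matrix(dosage, ["A"] * 4 + ["B"] * 4)
    res = wc_fst(G, pm)
    # pop A: L0 freqs p=4/8? dosages (0,1,1,2): p=0.5, het=2/4
    a0, b0, c0 = wc_oracle_two_pops(4, 0.5, 0.5, 4, 0.25, 0.5)
    assert res.theta[0] == pytest.approx(a0 / (a0 + b0 + c0), abs=1e-12)
    a1, b1, c1 = wc_oracle_two_pops(4, 7 / 8, 1 / 4, 4, 1 / 8, 1 / 4)
    assert res.theta[1] == pytest.approx(a1 / (a1 + b1 + c1), abs=1e-12)
    assert res.multilocus == pytest.approx((a0 + a1) / (a0 + b0 + c0 + a1 + b1 + c1),
                                           abs=1e-12)


def test_wc_fst_identical_pops_near_zero():
    block = [[0, 1], [1, 1], [1, 2], [2, 0]]
    G, pm = _matrix(block + block, ["A"] * 4 + ["B"] * 4)
    res = wc_fst(G, pm)
    assert np.nanmax(np.abs(res.theta)) < 0.2
    assert res.multilocus < 0.05


def test_wc_fst_fixed_difference_is_one():
    G, pm = _matrix([[0], [0], [0], [2], [2], [2]], ["A"] * 3 + ["B"] * 3)
    assert wc_fst(G, pm).multilocus == pytest.approx(1.0)


def test_wc_fst_locus_single_population_excluded():
    dosage = [[1, MISSING], [0, MISSING], [2, 1], [1, 0]]
    G, pm = _matrix(dosage, ["A", "A", "B", "B"])
    res = wc_fst(G, pm)
    assert res.n_excluded == 1
    assert np.isnan(res.theta[1])


def test_pairwise_fst_symmetric_zero_diagonal():
    rng = np.random.default_rng(0)
    G, pm = _matrix(rng.binomial(2, 0.4, size=(12, 30)),
                    ["A"] * 4 + ["B"] * 4 + ["C"] * 4)
    pw = pairwise_fst(G, pm)
    assert np.allclose(pw, pw.T)
    assert np.all(np.diag(pw) == 0)
    assert (pw.to_numpy() > -1).all()


# ---------------------------------------------------------------------------
# LD r^2
# ---------------------------------------------------------------------------

def test_ld_r2_arithmetic_oracle():
    x = np.array([0, 1, 2, 0])
    y = np.array([0, 1, 1, 0])
    G, _ = _matrix(np.column_stack([x, y]), ["A"] * 4)
    res = ld_r2(G, pairs=[("L0", "L1")])
    expected = np.corrcoef(x, y)[0, 1] ** 2
    assert res.pairs["r2"].iloc[0] == pytest.approx(expected, abs=1e-12)


def test_ld_r2_copy_and_complement():
    x = np.array([0, 1, 2, 0, 1, 2])
    G, _ = _matrix(np.column_stack([x, x, 2 - x]), ["A"] * 6)
    res = ld_r2(G)
    assert np.allclose(res.pairs["r2"], 1.0)


def test_ld_r2_invariances():
    rng = np.random.default_rng(1)
    d = rng.binomial(2, 0.5, size=(20, 2)).astype(np.int8)
    G, _ = _matrix(d, ["A"] * 20)
    base = ld_r2(G, pairs=[("L0", "L1")]).pairs["r2"].iloc[0]
    flipped, _ = _matrix(np.column_stack([2 - d[:, 0], d[:, 1]]), ["A"] * 20)
    assert ld_r2(flipped, pairs=[("L0", "L1")]).pairs["r2"].iloc[0] == pytest.approx(base)
    perm = rng.permutation(20)
    reordered, _ = _matrix(d[perm], ["A"] * 20)
    assert ld_r2(reordered, pairs=[("L0", "L1")]).pairs["r2"].iloc[0] == pytest.approx(base)


def test_ld_r2_zero_variance_undefined():
    G, _ = _matrix(np.column_stack([[1, 1, 1, 1], [0, 1, 2, 0]]), ["A"] * 4)
    res = ld_r2(G)
    assert res.n_undefined == 1
    assert np.isnan(res.mean_r2)


def test_ld_r2_pairwise_complete_matches_loop():
    """The vectorized all-pairs path equals the per-pair masked computation."""
    rng = np.random.default_rng(2)
    d = rng.choice([0, 1, 2, MISSING], size=(30, 5), p=[0.3, 0.3, 0.3, 0.1])
    G, _ = _matrix(d, ["A"] * 30)
    allp = ld_r2(G).pairs.set_index(["locus_a", "locus_b"])
    pairs = list(itertools.combinations([f"L{j}" for j in range(5)], 2))
    loop = ld_r2(G, pairs=pairs).pairs.set_index(["locus_a", "locus_b"])
    for key in loop.index:
        a, b = allp.loc[key, "r2"], loop.loc[key, "r2"]
        assert (np.isnan(a) and np.isnan(b)) or a == pytest.approx(b, abs=1e-10)


# ---------------------------------------------------------------------------
# chord distance + NJ
# ---------------------------------------------------------------------------

def test_chord_distance_properties(two_pop_matrix):
    G, pm = two_pop_matrix
    ft = allele_statistics(G, pm).freqs
    assert chord_distance(ft, "A", "B") == pytest.approx(chord_distance(ft, "B", "A"))
    # identical frequency vectors -> 0
    G2, pm2 = two_pop_matrix
    G2.dosage[4:] = G2.dosage[:4]
    ft2 = allele_statistics(G2, pm2).freqs
    assert chord_distance(ft2, "A", "B") == pytest.approx(0.0, abs=1e-12)


def test_chord_distance_maximum_at_opposite_fixation():
    G, pm = _matrix([[0], [0], [2], [2]], ["A", "A", "B", "B"])
    ft = allele_statistics(G, pm).freqs
    assert chord_distance(ft, "A", "B") == pytest.approx(2 / np.pi * np.sqrt(2), abs=1e-12)


def test_nj_recovers_additive_topology():
    """Distances generated from tree ((A,B),(C,D)) with additive branch
    lengths are recovered exactly by neighbour joining."""
    # branch lengths: A=1, B=2, internal=3, C=4, D=5
    d = {("A", "B"): 3, ("A", "C"): 8, ("A", "D"): 9,
         ("B", "C"): 9, ("B", "D"): 10, ("C", "D"): 9}
    pops = ["A", "B", "C", "D"]
    m = np.zeros((4, 4))
    for (i, j), v in ((k, v) for k, v in d.items()):
        a, b = pops.index(i), pops.index(j)
        m[a, b] = m[b, a] = v
    tree = nj_tree(pd.DataFrame(m, index=pops, columns=pops))
    assert frozenset({"C", "D"}) in tree.bipartitions or \
        frozenset({"A", "B"}) in tree.bipartitions


def test_nj_degenerate_equal_distances_accepted():
    pops = ["A", "B", "C", "D"]
    m = np.ones((4, 4)) - np.eye(4)
    tree = nj_tree(pd.DataFrame(m, index=pops, columns=pops))
    assert tree.newick
    assert tree.supports is None


def test_nj_bootstrap_supports():
    rng = np.random.default_rng(3)
    freqs = np.array([[0.1] * 20, [0.15] * 20, [0.85] * 20, [0.9] * 20])
    cfg = SimulationConfig(seed=1, n_populations=4, diploids_per_population=15)
    G = sample_genotypes(freqs, cfg, rng)
    pm = PopulationMap(populations={
        p: [s for s, sp in zip(G.samples, G.populations) if sp == p]
        for p in dict.fromkeys(G.populations)})
    ft = allele_statistics(G, pm).freqs
    dc = chord_distance_matrix(ft)
    tree = nj_tree(dc, bootstrap=(G, pm, 30, 7))
    assert tree.supports is not None
    for v in tree.supports.values():
        assert 0 <= v <= 100
    # the deep 2-vs-2 split should be strongly supported
    split = frozenset({"P03", "P04"})
    assert tree.supports.get(split, 0) > 80


def test_nj_needs_three_populations():
    m = pd.DataFrame(np.zeros((2, 2)), index=["A", "B"], columns=["A", "B"])
    with pytest.raises(ValueError):
        nj_tree(m)


# ---------------------------------------------------------------------------
# AMOVA
# ---------------------------------------------------------------------------

def amova_oracle_balanced(dosage, pops_per_group, inds_per_pop):
    """Naive nested ANOVA on allele copies for a balanced complete design,
    written with explicit loops over groups/pops/individuals/copies."""
    n_groups = dosage.shape[0] // (pops_per_group * inds_per_pop)
    ss = dict(ag=0.0, ap=0.0, ai=0.0, wi=0.0)
    L = dosage.shape[1]
    for l in range(L):
        col = dosage[:, l]
        grand = col.sum() / (2.0 * len(col))
        idx = 0
        for g in range(n_groups):
            gvals = col[idx: idx + pops_per_group * inds_per_pop]
            g_mean = gvals.sum() / (2.0 * len(gvals))
            ss["ag"] += 2 * len(gvals) * (g_mean - grand) ** 2
            for p in range(pops_per_group):
                pvals = col[idx + p * inds_per_pop: idx + (p + 1) * inds_per_pop]
                p_mean = pvals.sum() / (2.0 * len(pvals))
                ss["ap"] += 2 * len(pvals) * (p_mean - g_mean) ** 2
                for d in pvals:
                    ss["ai"] += 2 * (d / 2.0 - p_mean) ** 2
                    ss["wi"] += 0.5 if d == 1 else 0.0
            idx += pops_per_group * inds_per_pop
    N = dosage.shape[0]
    P = n_groups * pops_per_group
    df = dict(ag=(n_groups - 1) * 1.0, ap=(P - n_groups) * 1.0,
              ai=(N - P) * 1.0, wi=N * 1.0)
    # multi-locus df: every locus complete, so df scale by L
    ms = {k: ss[k] / (df[k] * L) for k in ss}
    sigma_e = ms["wi"]
    sigma_i = (ms["ai"] - sigma_e) / 2
    copies_per_pop = 2 * inds_per_pop
    sigma_p = (ms["ap"] - sigma_e - 2 * sigma_i) / copies_per_pop
    copies_per_group = copies_per_pop * pops_per_group
    sigma_g = (ms["ag"] - sigma_e - 2 * sigma_i - copies_per_pop * sigma_p) / copies_per_group
    return sigma_g, sigma_p, sigma_i, sigma_e


def test_amova_matches_naive_oracle():
    """8-individual toy: components equal the hand-worked nested sums of
    squares (balanced design, complete data)."""
    rng = np.random.default_rng(4)
    dosage = rng.binomial(2, [[0.2], [0.8]][0], size=(8, 3)).astype(np.int8)
    dosage[4:] = rng.binomial(2, 0.8, size=(4, 3))
    pops = ["P1", "P1", "P2", "P2", "P3", "P3", "P4", "P4"]
    G, pm = _matrix(dosage, pops)
    grouping = {"P1": "N", "P2": "N", "P3": "S", "P4": "S"}
    res = amova(G, pm, grouping, n_perm=49, seed=0)
    got = res.table["variance"].to_numpy()
    want = amova_oracle_balanced(dosage.astype(float), pops_per_group=2,
                                 inds_per_pop=2)
    assert np.allclose(got, want, atol=1e-10)
    assert res.table["percent"].sum() == pytest.approx(100.0, abs=1e-6)


def test_amova_iid_groups_small_component():
    rng = np.random.default_rng(5)
    dosage = rng.binomial(2, 0.5, size=(40, 60)).astype(np.int8)
    pops = [f"P{i // 10}" for i in range(40)]
    G, pm = _matrix(dosage, pops)
    res = amova(G, pm, {"P0": "A", "P1": "A", "P2": "B", "P3": "B"},
                n_perm=99, seed=1)
    tab = res.table.set_index("stratum")
    assert abs(tab.loc["among_groups", "percent"]) < 3.0
    assert tab.loc["among_groups", "p_value"] > 0.05


def test_amova_saturated_among_groups():
    dosage = np.zeros((20, 10), dtype=np.int8)
    dosage[10:] = 2
    pops = [f"P{i // 5}" for i in range(20)]
    G, pm = _matrix(dosage, pops)
    res = amova(G, pm, {"P0": "A", "P1": "A", "P2": "B", "P3": "B"},
                n_perm=49, seed=2)
    tab = res.table.set_index("stratum")
    assert tab.loc["among_groups", "percent"] > 95.0


# ---------------------------------------------------------------------------
# PCA + k-means + BIC
# ---------------------------------------------------------------------------

def test_pca_kmeans_selects_two_separated_clusters():
    rng = np.random.default_rng(6)
    freqs = np.vstack([np.full((3, 80), 0.1), np.full((3, 80), 0.9)])
    cfg = SimulationConfig(seed=2, n_populations=6, diploids_per_population=10)
    G = sample_genotypes(freqs, cfg, rng)
    res = pca_kmeans_bic(G, max_k=5, seed=0)
    assert res.selected_k == 2
    assert 0.0 <= res.explained_variance_ratio[0] <= 1.0


def test_pca_kmeans_homogeneous_selects_one():
    rng = np.random.default_rng(7)
    cfg = SimulationConfig(seed=3, n_populations=4, diploids_per_population=10)
    G = sample_genotypes(np.full((4, 60), 0.5), cfg, rng)
    res = pca_kmeans_bic(G, max_k=5, seed=0)
    assert res.selected_k == 1


def test_pca_max_k_validation(two_pop_matrix):
    G, _ = two_pop_matrix
    with pytest.raises(ValueError):
        pca_kmeans_bic(G, max_k=G.n_samples)


# ---------------------------------------------------------------------------
# Mantel test
# ---------------------------------------------------------------------------

def mantel_oracle(A, B):
    """Exact enumeration over every relabeling of B (double loop, no rng)."""
    n = A.shape[0]
    iu = np.triu_indices(n, k=1)
    r_obs = np.corrcoef(A[iu], B[iu])[0, 1]
    hits = total = 0
    for perm in itertools.permutations(range(n)):
        Bp = B[np.ix_(perm, perm)]
        if np.corrcoef(A[iu], Bp[iu])[0, 1] >= r_obs - 1e-12:
            hits += 1
        total += 1
    return r_obs, hits / total


def test_mantel_exact_matches_enumeration():
    rng = np.random.default_rng(8)
    for n in (4, 5):
        A = rng.random((n, n)); A = (A + A.T) / 2; np.fill_diagonal(A, 0)
        B = rng.random((n, n)); B = (B + B.T) / 2; np.fill_diagonal(B, 0)
        res = mantel_test(A, B, n_perm=200_000, seed=0)
        r_o, p_o = mantel_oracle(A, B)
        assert res.exact
        assert res.r == pytest.approx(r_o, abs=1e-12)
        assert res.p == pytest.approx(p_o, abs=1e-12)


def test_mantel_identity_and_affine():
    x = np.linspace(0, 100, 8)
    D = np.abs(x[:, None] - x[None, :])
    res = mantel_test(D, D, n_perm=99, seed=0)
    assert res.r == pytest.approx(1.0)
    assert res.p == pytest.approx(1 / 100)
    res2 = mantel_test(D, 3.0 + 2.0 * D, n_perm=99, seed=0)
    assert res2.r == pytest.approx(1.0)


def test_mantel_constant_matrix_flagged():
    D = np.ones((5, 5)) - np.eye(5)
    res = mantel_test(D, D, n_perm=9, seed=0)
    assert np.isnan(res.r) and "undefined" in res.note
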