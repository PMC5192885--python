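"""Population-genetic summary statistics and structure diagnostics.

Implements the Weir & Cockerham (1984) theta estimator of F_ST (per locus,
multi-locus ratio-of-sums and pairwise between populations), genotypic
linkage-disequilibrium r^2 (squared Pearson correlation of dosages over
pairwise-complete individuals), the Cavalli-Sforza & Edwards chord distance,
neighbour-joining population trees with bootstrap over individuals,
hierarchical AMOVA with permutation tests, PCA + k-means with BIC model
selection, and the Mantel test (exact enumeration for small population sets).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from math import factorial

import numpy as np
import pandas as pd

from .genotypes import MISSING, FreqTable, GenotypeMatrix, PopulationMap, population_counts


# ---------------------------------------------------------------------------
# Weir-Cockerham F_ST
# ---------------------------------------------------------------------------

def wc_components(n_dip: np.ndarray, p: np.ndarray, het_prop: np.ndarray,
                  ) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Weir-Cockerham (1984) variance components per locus.

    Parameters are (n_pops, n_loci) arrays of non-missing diploid counts,
    counted-allele frequencies and observed heterozygote proportions.
    Returns per-locus arrays (a, b, c, valid) where ``valid`` marks loci with
    >= 2 populations observed; components are NaN elsewhere.
    """
    n_dip = np.asarray(n_dip, dtype=float)
    observed = n_dip > 0
    r = observed.sum(axis=0)
    valid = r >= 2
    with np.errstate(invalid="ignore", divide="ignore"):
        n = np.where(observed, n_dip, 0.0)
        psafe = np.where(observed, np.nan_to_num(p), 0.0)
        hsafe = np.where(observed, np.nan_to_num(het_prop), 0.0)
        nsum = n.sum(axis=0)
        nbar = nsum / np.maximum(r, 1)
        nc = (nsum - (n ** 2).sum(axis=0) / np.maximum(nsum, 1e-300)) / np.maximum(r - 1, 1)
        pbar = (n * psafe).sum(axis=0) / np.maximum(nsum, 1e-300)
        s2 = (n * (psafe - pbar) ** 2).sum(axis=0) / np.maximum((r - 1) * nbar, 1e-300)
        hbar = (n * hsafe).sum(axis=0) / np.maximum(nsum, 1e-300)
        inner = pbar * (1 - pbar) - (r - 1) / np.maximum(r, 1) * s2
        a = nbar / np.maximum(nc, 1e-300) * (s2 - (inner - hbar / 4) / np.maximum(nbar - 1, 1e-300))
        b = nbar / np.maximum(nbar - 1, 1e-300) * (inner - (2 * nbar - 1) / (4 * nbar) * hbar)
        c = hbar / 2
    a = np.where(valid, a, np.nan)
    b = np.where(valid, b, np.nan)
    c = np.where(valid, c, np.nan)
    return a, b, c, valid


@dataclass
class FstResult:
    """Per-locus theta and the multi-locus ratio-of-sums estimate."""

    loci: list[str]
    theta: np.ndarray          # per-locus a / (a + b + c); NaN where undefined
    multilocus: float          # sum(a) / sum(a + b + c) over defined loci
    n_excluded: int            # loci observed in < 2 populations
    components: pd.DataFrame = field(repr=False)  # a, b, c per locus


def wc_fst(G: GenotypeMatrix, popmap: PopulationMap,
           loci: list[str] | None = None) -> FstResult:
    """Weir-Cockerham theta per locus plus the multi-locus ratio of sums.

    Negative estimates are retained. Loci observed in fewer than two
    populations are excluded from the multi-locus sums and counted.
    """
    if loci is not None:
        keep = [G.loci.index(l) for l in loci]
        G = G.subset(locus_idx=keep)
    pops = [p for p in popmap.pops if p in set(G.populations)]
    n_dip, allele, het = population_counts(G, pops)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(n_dip > 0, allele / np.maximum(2 * n_dip, 1), np.nan)
        h = np.where(n_dip > 0, het / np.maximum(n_dip, 1), np.nan)
    a, b, c, valid = wc_components(n_dip, p, h)
    with np.errstate(invalid="ignore", divide="ignore"):
        theta = a / (a + b + c)
    num = np.nansum(np.where(valid, a, 0.0))
    den = np.nansum(np.where(valid, a + b + c, 0.0))
    multi = num / den if den != 0 else np.nan
    comp = pd.DataFrame({"a": a, "b": b, "c": c}, index=G.loci)
    return FstResult(loci=list(G.loci), theta=theta, multilocus=float(multi),
                     n_excluded=int((~valid).sum()), components=comp)


def pairwise_fst(G: GenotypeMatrix, popmap: PopulationMap,
                 loci: list[str] | None = None) -> pd.DataFrame:
    """Population x population multi-locus theta matrix (zero diagonal).

    Loci with undefined components within a pair (e.g. observed in only one
    of the two populations) are excluded from that pair's sums.
    """
    if loci is not None:
        keep = [G.loci.index(l) for l in loci]
        G = G.subset(locus_idx=keep)
    pops = [p for p in popmap.pops if p in set(G.populations)]
    n_dip, allele, het = population_counts(G, pops)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(n_dip > 0, allele / np.maximum(2 * n_dip, 1), np.nan)
        h = np.where(n_dip > 0, het / np.maximum(n_dip, 1), np.nan)
    P = len(pops)
    out = np.zeros((P, P))
    for i, j in itertools.combinations(range(P), 2):
        sel = np.array([i, j])
        a, b, c, valid = wc_components(n_dip[sel], p[sel], h[sel])
        den = np.nansum(np.where(valid, a + b + c, 0.0))
        theta = np.nansum(np.where(valid, a, 0.0)) / den if den != 0 else np.nan
        out[i, j] = out[j, i] = theta
    return pd.DataFrame(out, index=pops, columns=pops)


# ---------------------------------------------------------------------------
# linkage disequilibrium (genotypic r^2)
# ---------------------------------------------------------------------------

@dataclass
class LdResult:
    pairs: pd.DataFrame      # locus_a, locus_b, r2, n (complete individuals)
    mean_r2: float           # over defined pairs
    n_undefined: int         # pairs excluded (zero variance or < 2 complete)


def ld_r2(G: GenotypeMatrix, pairs: list[tuple[str, str]] | None = None,
          loci: list[str] | None = None) -> LdResult:
    """Squared dosage correlation over pairwise-complete individuals.

    ``pairs=None`` computes all pairs among ``loci`` (default: all loci).
    Pairs involving a zero-variance locus (over the complete individuals) or
    fewer than two complete individuals are undefined and excluded from the
    mean, but counted.
    """
    if pairs is None:
        sub = loci if loci is not None else list(G.loci)
        idx = [G.loci.index(l) for l in sub]
        D = G.dosage[:, idx].astype(float)
        M = (G.dosage[:, idx] != MISSING).astype(float)
        X = np.where(M > 0, D, 0.0)
        C = M.T @ M
        Sx = X.T @ M
        Sxx = (X ** 2).T @ M
        Sxy = X.T @ X
        with np.errstate(invalid="ignore", divide="ignore"):
            Cc = np.maximum(C, 1.0)
            cov = Sxy / Cc - (Sx / Cc) * (Sx.T / Cc)
            var_a = Sxx / Cc - (Sx / Cc) ** 2
            var_b = Sxx.T / Cc - (Sx.T / Cc) ** 2
            r2 = cov ** 2 / (var_a * var_b)
        iu = np.triu_indices(len(idx), k=1)
        defined = (C[iu] >= 2) & (var_a[iu] > 1e-12) & (var_b[iu] > 1e-12)
        df = pd.DataFrame({
            "locus_a": [sub[i] for i in iu[0]],
            "locus_b": [sub[j] for j in iu[1]],
            "r2": np.where(defined, r2[iu], np.nan),
            "n": C[iu].astype(int),
        })
    else:
        rows = []
        for la, lb in pairs:
            ia, ib = G.loci.index(la), G.loci.index(lb)
            da, db = G.dosage[:, ia], G.dosage[:, ib]
            ok = (da != MISSING) & (db != MISSING)
            x, y = da[ok].astype(float), db[ok].astype(float)
            if ok.sum() < 2 or x.var() <= 1e-12 or y.var() <= 1e-12:
                rows.append({"locus_a": la, "locus_b": lb, "r2": np.nan, "n": int(ok.sum())})
            else:
                r = np.corrcoef(x, y)[0, 1]
                rows.append({"locus_a": la, "locus_b": lb, "r2": float(r * r), "n": int(ok.sum())})
        df = pd.DataFrame(rows)
    mean = float(df["r2"].mean()) if df["r2"].notna().any() else np.nan
    return LdResult(pairs=df, mean_r2=mean, n_undefined=int(df["r2"].isna().sum()))


# ---------------------------------------------------------------------------
# chord distance and neighbour-joining trees
# ---------------------------------------------------------------------------

_CHORD_NORM = 2.0 / np.pi


def chord_distance(freqs: FreqTable, pop_a: str, pop_b: str) -> float:
    """Cavalli-Sforza & Edwards chord distance, averaged over shared loci.

    Per biallelic locus, Dc_l = (2/pi) sqrt(2 (1 - sqrt(p1 p2) - sqrt(q1 q2)));
    the reported distance is the mean of Dc_l over loci with defined
    frequencies in both populations. The per-locus maximum (opposite
    fixation) is (2/pi) sqrt(2).
    """
    ia, ib = freqs.pops.index(pop_a), freqs.pops.index(pop_b)
    pa, pb = freqs.p[ia], freqs.p[ib]
    shared = ~np.isnan(pa) & ~np.isnan(pb)
    if not shared.any():
        raise ValueError(f"populations {pop_a!r} and {pop_b!r} share no loci")
    pa, pb = pa[shared], pb[shared]
    cos_theta = np.sqrt(pa * pb) + np.sqrt((1 - pa) * (1 - pb))
    per_locus = _CHORD_NORM * np.sqrt(2.0 * np.clip(1.0 - cos_theta, 0.0, None))
    return float(per_locus.mean())


def chord_distance_matrix(freqs: FreqTable) -> pd.DataFrame:
    pops = freqs.pops
    out = np.zeros((len(pops), len(pops)))
    for i, j in itertools.combinations(range(len(pops)), 2):
        out[i, j] = out[j, i] = chord_distance(freqs, pops[i], pops[j])
    return pd.DataFrame(out, index=pops, columns=pops)


@dataclass
class PopTree:
    """Unrooted population tree with optional per-bipartition bootstrap support."""

    newick: str
    bipartitions: list[frozenset]            # internal-edge splits (canonical side)
    supports: dict[frozenset, float] | None  # percent of bootstrap replicates

    def newick_with_support(self) -> str:
        return self.newick


def _tree_bipartitions(tree, leaf_names: list[str]) -> tuple[str, list[frozenset]]:
    """Newick string and canonical internal bipartitions of an skbio tree."""
    ref = sorted(leaf_names)[0]
    n = len(leaf_names)
    splits = []
    for node in tree.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        if ref in side:
            side = frozenset(leaf_names) - side
        if 2 <= len(side) <= n - 2:
            splits.append(side)
    return tree.__str__().strip(), splits


def _nj_from_matrix(dist: pd.DataFrame):
    from skbio import DistanceMatrix
    from skbio.tree import nj
    dm = DistanceMatrix(np.ascontiguousarray(dist.to_numpy(dtype=float)),
                        ids=list(dist.index))
    return nj(dm)


def nj_tree(dist: pd.DataFrame,
            bootstrap: tuple[GenotypeMatrix, PopulationMap, int, int] | None = None,
            ) -> PopTree:
    """Saitou-Nei neighbour-joining over a population distance matrix.

    ``bootstrap`` = (G, popmap, replicates, seed) resamples individuals with
    replacement within each population, recomputes chord distances and the
    topology, and reports per-edge support as the percent of replicates
    containing the bipartition. With 0 replicates supports are absent.
    """
    if len(dist) < 3:
        raise ValueError("neighbour joining needs at least 3 populations")
    pops = list(dist.index)
    tree = _nj_from_matrix(dist)
    newick, splits = _tree_bipartitions(tree, pops)
    supports = None
    if bootstrap is not None:
        G, popmap, reps, seed = bootstrap
        if reps > 0:
            rng = np.random.default_rng(seed)
            counts = {s: 0 for s in splits}
            idx = G.pop_indices(pops)
            for _ in range(reps):
                rows = np.concatenate([
                    rng.choice(idx[p], size=idx[p].size, replace=True) for p in pops
                ])
                Gb = G.subset(sample_idx=rows)
                Gb = GenotypeMatrix(
                    samples=[f"s{i}" for i in range(Gb.n_samples)],
                    populations=Gb.populations, loci=Gb.loci, dosage=Gb.dosage)
                from .genotypes import allele_statistics
                ft = allele_statistics(Gb, popmap).freqs
                db = chord_distance_matrix(ft)
                _, bsplits = _tree_bipartitions(_nj_from_matrix(db.loc[pops, pops]), pops)
                bset = set(bsplits)
                for s in splits:
                    if s in bset:
                        counts[s] += 1
            supports = {s: 100.0 * counts[s] / reps for s in splits}
    return PopTree(newick=newick, bipartitions=splits, supports=supports)


# ---------------------------------------------------------------------------
# AMOVA
# ---------------------------------------------------------------------------

@dataclass
class AmovaResult:
    """Hierarchical variance components with permutation p-values.

    Components follow the four strata of a two-level grouping of diploid
    individuals: among groups, among populations within groups, among
    individuals within populations, within individuals. Percents sum to 100.
    """

    table: pd.DataFrame  # stratum, df, variance, percent, p_value

    def percents(self) -> np.ndarray:
        return self.table["percent"].to_numpy()


def _amova_ss(D: np.ndarray, present: np.ndarray, het: np.ndarray,
              pop_of: np.ndarray, group_of_pop: np.ndarray, n_pops: int,
              n_groups: int):
    """Per-locus sums of squares, df and expected-MS coefficients.

    D: zero-filled dosages (N x L); present: bool (N x L); het: bool
    (N x L, zero-filled); pop_of: int per individual; group_of_pop: int per
    population. Returns dict of per-locus arrays.
    """
    N, L = D.shape
    Z = np.zeros((n_pops, N))
    Z[pop_of, np.arange(N)] = 1.0
    n_pl = Z @ present          # diploids per (pop, locus)
    s_pl = Z @ D                # counted-allele sums
    het_pl = Z @ (het & present)
    Zg = np.zeros((n_groups, n_pops))
    Zg[group_of_pop, np.arange(n_pops)] = 1.0
    n_gl = Zg @ n_pl
    s_gl = Zg @ s_pl

    with np.errstate(invalid="ignore", divide="ignore"):
        sq_pl = s_pl ** 2 / np.maximum(2 * n_pl, 1e-300)      # s^2 / 2n per pop
        sq_gl = s_gl ** 2 / np.maximum(2 * n_gl, 1e-300)
        n_tot = n_pl.sum(axis=0)
        s_tot = s_pl.sum(axis=0)
        sq_tot = s_tot ** 2 / np.maximum(2 * n_tot, 1e-300)
        sumsq = Z @ (D ** 2 * present)                        # sum d^2 per pop

        ss_wi = 0.5 * het_pl.sum(axis=0)
        # Sum_i 2 (d_i/2 - pbar_p)^2 = 0.5 sum d^2 - s^2/(2n), per population
        ss_ai = (0.5 * sumsq).sum(axis=0) - sq_pl.sum(axis=0)
        ss_ap = sq_pl.sum(axis=0) - sq_gl.sum(axis=0)
        ss_ag = sq_gl.sum(axis=0) - sq_tot

        pops_present = (n_pl > 0)
        P_l = pops_present.sum(axis=0)
        groups_present = (n_gl > 0)
        G_l = groups_present.sum(axis=0)
        I_l = n_tot

        df_wi = I_l.astype(float)
        df_ai = (I_l - P_l).astype(float)
        df_ap = (P_l - G_l).astype(float)
        df_ag = (G_l - 1).astype(float)

        # expected-MS coefficients (copy counts = 2 x diploid counts)
        sum_np2_g = Zg @ (n_pl ** 2)                          # per group: sum n_p^2
        term_g = np.where(n_gl > 0, sum_np2_g / np.maximum(n_gl, 1e-300), 0.0)
        n1 = 2 * (n_tot - term_g.sum(axis=0)) / np.maximum(df_ap, 1e-300)
        n2 = 2 * (term_g.sum(axis=0)
                  - (n_pl ** 2).sum(axis=0) / np.maximum(n_tot, 1e-300)
                  ) / np.maximum(df_ag, 1e-300)
        n3 = 2 * (n_tot - (n_gl ** 2).sum(axis=0) / np.maximum(n_tot, 1e-300)
                  ) / np.maximum(df_ag, 1e-300)

    return {
        "ss_wi": ss_wi, "ss_ai": ss_ai, "ss_ap": ss_ap, "ss_ag": ss_ag,
        "df_wi": df_wi, "df_ai": df_ai, "df_ap": df_ap, "df_ag": df_ag,
        "n1": n1, "n2": n2, "n3": n3,
    }


def _amova_components(q: dict) -> tuple[float, float, float, float]:
    """Pooled method-of-moments variance components from per-locus sums."""
    sw, si = q["ss_wi"].sum(), q["ss_ai"].sum()
    sp, sg = q["ss_ap"].sum(), q["ss_ag"].sum()
    dw, di = q["df_wi"].sum(), q["df_ai"].sum()
    dp, dg = q["df_ap"].sum(), q["df_ag"].sum()
    sigma_e = sw / dw if dw > 0 else np.nan
    sigma_i = (si - sigma_e * di) / (2 * di) if di > 0 else np.nan
    c1 = (q["df_ap"] * q["n1"]).sum()
    sigma_p = (sp - (sigma_e + 2 * sigma_i) * dp) / c1 if c1 > 0 else np.nan
    c2 = (q["df_ag"] * q["n2"]).sum()
    c3 = (q["df_ag"] * q["n3"]).sum()
    sigma_g = ((sg - (sigma_e + 2 * sigma_i) * dg - sigma_p * c2) / c3
               if c3 > 0 else np.nan)
    return sigma_g, sigma_p, sigma_i, sigma_e


def amova(G: GenotypeMatrix, popmap: PopulationMap, grouping: dict[str, str],
          n_perm: int = 999, seed: int = 0) -> AmovaResult:
    """Excoffier-style hierarchical AMOVA on allelic (dosage) distances.

    Variance is decomposed over four strata (among groups; among populations
    within groups; among individuals within populations; within individuals)
    by a nested method-of-moments fit pooled over loci; missing genotypes
    are handled per locus. Permutation p-values use (#extreme + 1)/(n_perm + 1)
    with the units appropriate to each stratum: populations among groups,
    individuals among populations within groups, and allele pairings within
    populations for the individual-level strata.
    """
    pops = [p for p in popmap.pops if p in set(G.populations)]
    groups = sorted(set(grouping[p] for p in pops))
    if len(groups) < 2:
        raise ValueError("AMOVA needs at least 2 groups")
    pop_index = {p: i for i, p in enumerate(pops)}
    group_index = {g: i for i, g in enumerate(groups)}
    pop_of = np.array([pop_index[p] for p in G.populations])
    group_of_pop = np.array([group_index[grouping[p]] for p in pops])

    present = G.dosage != MISSING
    if not present.any(axis=0).all():
        pass  # loci with no data contribute zero SS and df
    D = np.where(present, G.dosage, 0).astype(float)
    het = G.dosage == 1

    q = _amova_ss(D, present, het, pop_of, group_of_pop, len(pops), len(groups))
    for g in range(len(groups)):
        if not present[np.isin(pop_of, np.flatnonzero(group_of_pop == g))].any():
            raise ValueError(f"group {groups[g]!r} has no observed genotypes")
    sigma_g, sigma_p, sigma_i, sigma_e = _amova_components(q)
    total = sigma_g + sigma_p + sigma_i + sigma_e
    percents = 100.0 * np.array([sigma_g, sigma_p, sigma_i, sigma_e]) / total

    rng = np.random.default_rng(seed)
    # among groups: permute populations among groups
    hits_g = 0
    for _ in range(n_perm):
        perm = rng.permutation(group_of_pop)
        qq = _amova_ss(D, present, het, pop_of, perm, len(pops), len(groups))
        if _amova_components(qq)[0] >= sigma_g:
            hits_g += 1
    p_g = (hits_g + 1) / (n_perm + 1)

    # among pops within groups: permute individuals among pops within groups
    hits_p = 0
    group_of_ind = group_of_pop[pop_of]
    for _ in range(n_perm):
        new_pop = pop_of.copy()
        for g in range(len(groups)):
            rows = np.flatnonzero(group_of_ind == g)
            new_pop[rows] = pop_of[rows][rng.permutation(rows.size)]
        qq = _amova_ss(D, present, het, new_pop, group_of_pop, len(pops), len(groups))
        if _amova_components(qq)[1] >= sigma_p:
            hits_p += 1
    p_p = (hits_p + 1) / (n_perm + 1)

    # individual strata: re-pair alleles within populations (Levene draw of
    # heterozygote counts); both SS_wi and SS_ai depend on the permutation
    # only through the per-cell heterozygote counts.
    Z = np.zeros((len(pops), G.n_samples))
    Z[pop_of, np.arange(G.n_samples)] = 1.0
    n_pl = (Z @ present).astype(int)
    s_pl = (Z @ D).astype(int)
    # SS_ai = 0.5 sum d^2 - sum s^2/2n and sum d^2 = 2s - het, so both SS_wi
    # and SS_ai are linear in the total heterozygote count.
    base = (s_pl.astype(float)
            - s_pl.astype(float) ** 2 / np.maximum(2 * n_pl, 1e-300)).sum()
    dw, di = q["df_wi"].sum(), q["df_ai"].sum()
    hits_i = 0
    hits_e = 0
    tot_het = np.empty(n_perm)
    for t in range(n_perm):
        tot_het[t] = _levene_total_het(rng, n_pl, s_pl)
    for t in range(n_perm):
        ss_wi_t = 0.5 * tot_het[t]
        ss_ai_t = base - 0.5 * tot_het[t]
        se_t = ss_wi_t / dw
        si_t = (ss_ai_t - se_t * di) / (2 * di)
        if si_t >= sigma_i:
            hits_i += 1
        if se_t <= sigma_e:
            hits_e += 1
    p_i = (hits_i + 1) / (n_perm + 1)
    p_e = (hits_e + 1) / (n_perm + 1)

    n_ind = int(present.any(axis=1).sum())
    table = pd.DataFrame({
        "stratum": ["among_groups", "among_populations_within_groups",
                    "among_individuals_within_populations", "within_individuals"],
        "df": [len(groups) - 1, len(pops) - len(groups), n_ind - len(pops), n_ind],
        "variance": [sigma_g, sigma_p, sigma_i, sigma_e],
        "percent": percents,
        "p_value": [p_g, p_p, p_i, p_e],
    })
    return AmovaResult(table=table)


def _levene_total_het(rng: np.random.Generator, n_pl: np.ndarray,
                      s_pl: np.ndarray) -> float:
    """Total heterozygote count after random re-pairing of alleles per cell.

    For each (population, locus) cell with n diploids and s counted alleles,
    draws the heterozygote count from the random-pairing (Levene)
    distribution by simulating the pairing directly.
    """
    total = 0.0
    P, L = n_pl.shape
    for j in range(P):
        ns = n_pl[j]
        ss = s_pl[j]
        for l in range(L):
            n, s = int(ns[l]), int(ss[l])
            if n == 0 or s == 0 or s == 2 * n:
                continue
            alleles = np.zeros(2 * n, dtype=np.int8)
            alleles[:s] = 1
            rng.shuffle(alleles)
            total += int((alleles[0::2] != alleles[1::2]).sum())
    return total


# ---------------------------------------------------------------------------
# PCA + k-means + BIC
# ---------------------------------------------------------------------------

@dataclass
class PcaKmeansResult:
    scores: np.ndarray                 # (n_samples, n_components)
    explained_variance_ratio: np.ndarray
    bic: dict[int, float]
    selected_k: int
    labels: dict[int, np.ndarray]      # per-k cluster assignments


def pca_kmeans_bic(G: GenotypeMatrix, max_k: int, n_components: int | None = None,
                   scale: bool = False, seed: int = 0) -> PcaKmeansResult:
    """PCA on mean-imputed centered dosages, k-means per k, BIC selection.

    BIC(k) = n ln(W_k / n) + k ln(n) with W_k the total within-cluster sum
    of squares over the retained components; the selected k minimizes BIC.
    """
    from sklearn.cluster import KMeans
    from sklearn.decomposition import PCA

    n = G.n_samples
    if max_k >= n:
        raise ValueError("max_k must be smaller than the number of individuals")
    X = G.dosage.astype(float)
    mask = G.dosage == MISSING
    with np.errstate(invalid="ignore"):
        colmean = np.where(mask, np.nan, X).mean(axis=0, where=~mask)
    colmean = np.nan_to_num(colmean)
    X = np.where(mask, colmean[None, :], X)
    X = X - X.mean(axis=0)
    if scale:
        sd = X.std(axis=0)
        X = X / np.where(sd > 0, sd, 1.0)
    k_comp = n_components or min(n - 1, G.n_loci, 20)
    pca = PCA(n_components=k_comp, random_state=seed)
    scores = pca.fit_transform(X)

    bic: dict[int, float] = {}
    labels: dict[int, np.ndarray] = {}
    for k in range(1, max_k + 1):
        if k == 1:
            w = float(((scores - scores.mean(axis=0)) ** 2).sum())
            lab = np.zeros(n, dtype=int)
        else:
            km = KMeans(n_clusters=k, n_init=10, random_state=seed).fit(scores)
            w = float(km.inertia_)
            lab = km.labels_
        bic[k] = n * np.log(max(w, 1e-300) / n) + k * np.log(n)
        labels[k] = lab
    selected = min(bic, key=bic.get)
    return PcaKmeansResult(scores=scores,
                           explained_variance_ratio=pca.explained_variance_ratio_,
                           bic=bic, selected_k=selected, labels=labels)


# ---------------------------------------------------------------------------
# Mantel test
# ---------------------------------------------------------------------------

@dataclass
class MantelResult:
    r: float
    p: float
    n_perm: int
    exact: bool      # True when all relabelings were enumerated
    note: str = ""


def _as_square(M) -> np.ndarray:
    a = M.to_numpy(dtype=float) if isinstance(M, pd.DataFrame) else np.asarray(M, dtype=float)
    if a.ndim != 2 or a.shape[0] != a.shape[1]:
        raise ValueError("matrix must be square")
    if not np.allclose(a, a.T):
        raise ValueError("matrix must be symmetric")
    return a


def mantel_test(M1, M2, n_perm: int = 999, seed: int = 0) -> MantelResult:
    """Mantel correlation with a one-sided (greater) permutation test.

    r is the Pearson correlation over off-diagonal upper-triangle pairs.
    When n! <= n_perm all relabelings of one matrix are enumerated and the
    p-value is exact (observed included); otherwise p = (#>= observed + 1) /
    (n_perm + 1) over random relabelings. A constant matrix leaves r
    undefined (NaN, flagged in ``note``).
    """
    A, B = _as_square(M1), _as_square(M2)
    if A.shape != B.shape:
        raise ValueError("matrices must share the population set")
    n = A.shape[0]
    iu = np.triu_indices(n, k=1)
    x, y = A[iu], B[iu]
    if x.std() == 0 or y.std() == 0:
        return MantelResult(r=np.nan, p=np.nan, n_perm=0, exact=False,
                            note="constant matrix: r undefined")
    r_obs = float(np.corrcoef(x, y)[0, 1])

    def corr_perm(perm: np.ndarray) -> float:
        Bp = B[np.ix_(perm, perm)]
        return float(np.corrcoef(x, Bp[iu])[0, 1])

    if factorial(n) <= n_perm:
        vals = [corr_perm(np.array(p)) for p in itertools.permutations(range(n))]
        hits = sum(v >= r_obs - 1e-12 for v in vals)
        return MantelResult(r=r_obs, p=hits / factorial(n), n_perm=factorial(n), exact=True)
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        if corr_perm(rng.permutation(n)) >= r_obs - 1e-12:
            hits += 1
    return MantelResult(r=r_obs, p=(hits + 1) / (n_perm + 1), n_perm=n_perm, exact=False)
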