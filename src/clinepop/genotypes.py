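"""Genotype containers, per-population allele statistics and the QC filter chain.

The substrate of every analysis stage is a diploid, biallelic dosage matrix:
``dosage[i, l]`` counts copies of the *counted* allele (VCF ALT or PLINK A1)
carried by individual ``i`` at locus ``l`` and is 0, 1, 2 or :data:`MISSING`.
All downstream statistics use pairwise-complete (non-missing) observations.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import lgamma, log

import numpy as np
import pandas as pd

#: Sentinel for a missing diploid genotype call, distinct from any dosage.
MISSING: int = -1


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class PopulationMap:
    """Sample -> population assignment with optional transect geometry.

    Parameters
    ----------
    populations : dict
        Population code -> ordered list of sample IDs. Populations must be
        non-empty and sample IDs unique across populations.
    positions_km : dict, optional
        Population code -> position (km) along the one-dimensional transect,
        measured from the transect origin (the northernmost site). Must be
        non-negative and finite when present.
    coordinates : dict, optional
        Population code -> (latitude, longitude).
    """

    populations: dict[str, list[str]]
    positions_km: dict[str, float] | None = None
    coordinates: dict[str, tuple[float, float]] | None = None

    def __post_init__(self) -> None:
        if not self.populations:
            raise ValueError("population map is empty")
        seen: set[str] = set()
        for pop, samples in self.populations.items():
            if not samples:
                raise ValueError(f"population {pop!r} has no samples")
            for s in samples:
                if s in seen:
                    raise ValueError(f"sample {s!r} assigned to more than one population")
                seen.add(s)
        if self.positions_km is not None:
            for pop, x in self.positions_km.items():
                if not np.isfinite(x) or x < 0:
                    raise ValueError(f"transect position for {pop!r} must be finite and >= 0, got {x}")

    @property
    def pops(self) -> list[str]:
        return list(self.populations)

    def sample_to_pop(self) -> dict[str, str]:
        return {s: p for p, samples in self.populations.items() for s in samples}

    def positions_for(self, pops: list[str]) -> np.ndarray:
        if self.positions_km is None:
            raise ValueError("population map carries no transect positions")
        return np.array([self.positions_km[p] for p in pops], dtype=float)


@dataclass
class GenotypeMatrix:
    """Individuals x loci diploid dosage matrix with sample/locus annotations."""

    samples: list[str]
    populations: list[str]
    loci: list[str]
    dosage: np.ndarray  # (n_samples, n_loci) int8, values in {0,1,2,MISSING}

    def __post_init__(self) -> None:
        self.dosage = np.asarray(self.dosage, dtype=np.int8)
        n, m = self.dosage.shape
        if n != len(self.samples) or m != len(self.loci):
            raise ValueError(
                f"dosage shape {self.dosage.shape} does not match "
                f"{len(self.samples)} samples x {len(self.loci)} loci"
            )
        if len(self.populations) != len(self.samples):
            raise ValueError("one population code per sample required")
        if len(set(self.loci)) != len(self.loci):
            dup = pd.Index(self.loci)
            raise ValueError(f"duplicate locus IDs: {sorted(dup[dup.duplicated()])[:5]}")
        bad = ~np.isin(self.dosage, (0, 1, 2, MISSING))
        if bad.any():
            raise ValueError("dosage values must be 0, 1, 2 or MISSING")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    def missing_mask(self) -> np.ndarray:
        return self.dosage == MISSING

    def subset(self, sample_idx: np.ndarray | list[int] | None = None,
               locus_idx: np.ndarray | list[int] | None = None) -> "GenotypeMatrix":
        si = np.arange(self.n_samples) if sample_idx is None else np.asarray(sample_idx)
        li = np.arange(self.n_loci) if locus_idx is None else np.asarray(locus_idx)
        return GenotypeMatrix(
            samples=[self.samples[i] for i in si],
            populations=[self.populations[i] for i in si],
            loci=[self.loci[j] for j in li],
            dosage=self.dosage[np.ix_(si, li)].copy(),
        )

    def pop_indices(self, pops: list[str] | None = None) -> dict[str, np.ndarray]:
        """Row indices per population, in the given (or first-seen) pop order."""
        codes = np.asarray(self.populations)
        if pops is None:
            pops = list(dict.fromkeys(self.populations))
        return {p: np.flatnonzero(codes == p) for p in pops}

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GenotypeMatrix):
            return NotImplemented
        return (self.samples == other.samples and self.populations == other.populations
                and self.loci == other.loci and np.array_equal(self.dosage, other.dosage))


@dataclass
class FreqTable:
    """Per (population, locus) counted-allele frequencies and allele sample sizes.

    ``p[j, l]`` is the counted-allele frequency in population ``j`` at locus
    ``l`` (NaN where no non-missing call exists), ``n[j, l]`` the allele sample
    size (2 x non-missing diploids) and ``het[j, l]`` the observed heterozygote
    count.
    """

    pops: list[str]
    loci: list[str]
    p: np.ndarray    # (n_pops, n_loci) float, NaN = undefined
    n: np.ndarray    # (n_pops, n_loci) int, allele counts (even)
    het: np.ndarray  # (n_pops, n_loci) int

    def __post_init__(self) -> None:
        self.p = np.asarray(self.p, dtype=float)
        self.n = np.asarray(self.n, dtype=int)
        self.het = np.asarray(self.het, dtype=int)
        shape = (len(self.pops), len(self.loci))
        for name, a in (("p", self.p), ("n", self.n), ("het", self.het)):
            if a.shape != shape:
                raise ValueError(f"{name} has shape {a.shape}, expected {shape}")
        with np.errstate(invalid="ignore"):
            if np.nanmin(self.p, initial=0.0) < 0 or np.nanmax(self.p, initial=0.0) > 1:
                raise ValueError("frequencies must lie in [0, 1]")
        if (self.n % 2).any() or (self.n < 0).any():
            raise ValueError("allele sample sizes must be even and >= 0")

    def pooled_p(self) -> np.ndarray:
        """Pooled (sample-size weighted) counted-allele frequency per locus."""
        counts = np.where(np.isnan(self.p), 0.0, self.p * self.n)
        tot = np.where(np.isnan(self.p), 0, self.n).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(tot > 0, counts.sum(axis=0) / tot, np.nan)

    def maf(self) -> np.ndarray:
        pbar = self.pooled_p()
        return np.minimum(pbar, 1.0 - pbar)

    def expected_het(self) -> np.ndarray:
        """He = 2 p̄ (1 − p̄) on the pooled frequency."""
        pbar = self.pooled_p()
        return 2.0 * pbar * (1.0 - pbar)

    def locus_data(self, locus: str) -> pd.DataFrame:
        """One locus as a (population, p, n, het) frame, defined pops only."""
        j = self.loci.index(locus)
        df = pd.DataFrame({
            "population": self.pops,
            "p": self.p[:, j],
            "n": self.n[:, j],
            "het": self.het[:, j],
        })
        return df[df["n"] > 0].reset_index(drop=True)


@dataclass
class FilterStage:
    name: str
    loci_before: int
    loci_after: int
    samples_before: int
    samples_after: int
    removed_loci: list[str] = field(default_factory=list)
    removed_samples: list[str] = field(default_factory=list)


@dataclass
class FilterReport:
    """Per-stage accounting of the QC filter chain."""

    stages: list[FilterStage] = field(default_factory=list)

    def add(self, stage: FilterStage) -> None:
        if self.stages:
            prev = self.stages[-1]
            if stage.loci_before != prev.loci_after or stage.samples_before != prev.samples_after:
                raise ValueError("filter stages must chain: before-counts must equal previous after-counts")
        if stage.loci_after > stage.loci_before or stage.samples_after > stage.samples_before:
            raise ValueError("filter counts must be non-increasing")
        if stage.loci_before - stage.loci_after != len(stage.removed_loci):
            raise ValueError("removed + retained loci must equal input")
        if stage.samples_before - stage.samples_after != len(stage.removed_samples):
            raise ValueError("removed + retained samples must equal input")
        self.stages.append(stage)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([
            {
                "stage": s.name,
                "loci_before": s.loci_before, "loci_after": s.loci_after,
                "samples_before": s.samples_before, "samples_after": s.samples_after,
                "n_loci_removed": len(s.removed_loci),
                "n_samples_removed": len(s.removed_samples),
            }
            for s in self.stages
        ])

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# allele statistics
# ---------------------------------------------------------------------------

@dataclass
class AlleleStats:
    """Bundle returned by :func:`allele_statistics`."""

    freqs: FreqTable
    maf: np.ndarray                 # per locus, pooled sample
    expected_het: np.ndarray        # per locus, 2 p̄ (1 − p̄)
    locus_missingness: np.ndarray   # per locus fraction of missing calls
    sample_missingness: np.ndarray  # per individual fraction of missing calls


def population_counts(G: GenotypeMatrix, pops: list[str]) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per (pop, locus) non-missing diploid count, counted-allele count, het count."""
    idx = G.pop_indices(pops)
    P, L = len(pops), G.n_loci
    n_dip = np.zeros((P, L), dtype=int)
    allele = np.zeros((P, L), dtype=int)
    het = np.zeros((P, L), dtype=int)
    for j, p in enumerate(pops):
        d = G.dosage[idx[p]]
        ok = d != MISSING
        n_dip[j] = ok.sum(axis=0)
        allele[j] = np.where(ok, d, 0).sum(axis=0)
        het[j] = (d == 1).sum(axis=0)
    return n_dip, allele, het


def allele_statistics(G: GenotypeMatrix, popmap: PopulationMap) -> AlleleStats:
    """Per-population allele frequencies plus pooled per-locus summaries.

    Frequencies are computed from non-missing calls only; a (population,
    locus) cell with zero non-missing calls gets frequency NaN (undefined,
    never 0). MAF and He use the pooled (all-population) frequency.
    """
    if G.n_samples == 0 or G.n_loci == 0:
        raise ValueError("genotype matrix is empty")
    pops = [p for p in popmap.pops if p in set(G.populations)]
    n_dip, allele, het = population_counts(G, pops)
    n = 2 * n_dip
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(n > 0, allele / np.maximum(n, 1), np.nan)
    freqs = FreqTable(pops=pops, loci=list(G.loci), p=p, n=n, het=het)
    miss = G.missing_mask()
    return AlleleStats(
        freqs=freqs,
        maf=freqs.maf(),
        expected_het=freqs.expected_het(),
        locus_missingness=miss.mean(axis=0),
        sample_missingness=miss.mean(axis=1),
    )


# ---------------------------------------------------------------------------
# Hardy-Weinberg exact test
# ---------------------------------------------------------------------------

def hwe_exact_test(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """Two-sided exact test for Hardy-Weinberg proportions (Levene/Haldane).

    Enumerates every heterozygote count compatible with the observed allele
    counts and sums the conditional probabilities of all configurations no
    more probable than the observed one. Monomorphic input returns p = 1.
    """
    if min(n_AA, n_Aa, n_aa) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_AA + n_Aa + n_aa
    if n == 0:
        raise ValueError("all genotype counts are zero")
    nA = 2 * n_AA + n_Aa
    na = 2 * n - nA
    if nA == 0 or na == 0:
        return 1.0
    rare = min(nA, na)
    # P(het = h | nA, na) ∝ n! / (nAA! nAa! naa!) * 2^h, h same parity as rare
    hets = range(rare % 2, rare + 1, 2)
    logprobs = {}
    for h in hets:
        aa_min = (min(nA, na) - h) // 2  # homozygotes of the rarer allele
        a_maj = (max(nA, na) - h) // 2
        logprobs[h] = (h * log(2.0) - lgamma(h + 1) - lgamma(aa_min + 1) - lgamma(a_maj + 1))
    mx = max(logprobs.values())
    probs = {h: np.exp(lp - mx) for h, lp in logprobs.items()}
    total = sum(probs.values())
    obs = probs[n_Aa]
    # sum over configurations with probability <= observed (tolerant to fp noise)
    pval = sum(pr for pr in probs.values() if pr <= obs * (1.0 + 1e-12)) / total
    return min(1.0, float(pval))


# ---------------------------------------------------------------------------
# QC filter chain
# ---------------------------------------------------------------------------

@dataclass
class QCThresholds:
    """Thresholds of the QC chain, defaulting to the study's values.

    ``locus_call_rate_min``
        minimum fraction of individuals genotyped at a locus (0 disables;
        preset 0.75, with 0.95 as the stricter alternative preset).
    ``maf_min``
        pooled minor-allele-frequency lower bound, strict (MAF > threshold;
        0 disables).
    ``indiv_missing_max``
        maximum per-individual missing fraction, inclusive (1 disables).
    ``hwe_alpha``
        per-population exact-test significance level, strict (p < alpha is
        out of HWE; 0 disables).
    ``hwe_pop_threshold``
        a locus is removed when out of HWE in at least this many populations.
    """

    locus_call_rate_min: float = 0.75
    maf_min: float = 0.05
    indiv_missing_max: float = 0.20
    hwe_alpha: float = 0.05
    hwe_pop_threshold: int = 6

    def __post_init__(self) -> None:
        for name in ("locus_call_rate_min", "maf_min", "indiv_missing_max", "hwe_alpha"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.hwe_pop_threshold < 1:
            raise ValueError("hwe_pop_threshold must be >= 1")

    @classmethod
    def none(cls) -> "QCThresholds":
        """No-op thresholds: every stage passes everything through."""
        return cls(locus_call_rate_min=0.0, maf_min=0.0, indiv_missing_max=1.0,
                   hwe_alpha=0.0, hwe_pop_threshold=1)


def apply_qc_filters(G: GenotypeMatrix, popmap: PopulationMap,
                     thresholds: QCThresholds | None = None) -> tuple[GenotypeMatrix, FilterReport]:
    """Apply the QC chain in fixed order and account for every removal.

    Order: (1) per-locus genotyping rate, (2) per-individual missingness,
    (3) pooled MAF on the retained individuals, (4) per-population HWE exact
    test (locus removed when out of HWE at alpha in >= the configured number
    of populations). The chain is idempotent for a fixed configuration.
    """
    thr = thresholds if thresholds is not None else QCThresholds()
    report = FilterReport()
    cur = G

    # (1) locus genotyping rate
    call_rate = 1.0 - cur.missing_mask().mean(axis=0)
    keep_l = np.flatnonzero(call_rate >= thr.locus_call_rate_min)
    removed = [cur.loci[j] for j in range(cur.n_loci) if j not in set(keep_l)]
    nxt = cur.subset(locus_idx=keep_l)
    report.add(FilterStage("locus_call_rate", cur.n_loci, nxt.n_loci,
                           cur.n_samples, nxt.n_samples, removed_loci=removed))
    cur = nxt

    # (2) individual missingness
    miss = cur.missing_mask().mean(axis=1)
    keep_s = np.flatnonzero(miss <= thr.indiv_missing_max)
    removed_s = [cur.samples[i] for i in range(cur.n_samples) if i not in set(keep_s)]
    nxt = cur.subset(sample_idx=keep_s)
    report.add(FilterStage("individual_missingness", cur.n_loci, nxt.n_loci,
                           cur.n_samples, nxt.n_samples, removed_samples=removed_s))
    cur = nxt

    # (3) MAF on retained individuals (strict >; threshold 0 disables)
    stats = allele_statistics(cur, popmap) if cur.n_samples and cur.n_loci else None
    if thr.maf_min > 0 and stats is not None:
        keep_l = np.flatnonzero(stats.maf > thr.maf_min)
    else:
        keep_l = np.arange(cur.n_loci)
    removed = [cur.loci[j] for j in range(cur.n_loci) if j not in set(keep_l)]
    nxt = cur.subset(locus_idx=keep_l)
    report.add(FilterStage("maf", cur.n_loci, nxt.n_loci,
                           cur.n_samples, nxt.n_samples, removed_loci=removed))
    cur = nxt

    # (4) per-population HWE
    if thr.hwe_alpha > 0 and cur.n_samples and cur.n_loci:
        pops = [p for p in popmap.pops if p in set(cur.populations)]
        idx = cur.pop_indices(pops)
        out_of_hwe = np.zeros(cur.n_loci, dtype=int)
        for p in pops:
            d = cur.dosage[idx[p]]
            for j in range(cur.n_loci):
                col = d[:, j]
                col = col[col != MISSING]
                if col.size == 0:
                    continue
                n_aa = int((col == 0).sum())
                n_het = int((col == 1).sum())
                n_AA = int((col == 2).sum())
                if hwe_exact_test(n_AA, n_het, n_aa) < thr.hwe_alpha:
                    out_of_hwe[j] += 1
        keep_l = np.flatnonzero(out_of_hwe < thr.hwe_pop_threshold)
    else:
        keep_l = np.arange(cur.n_loci)
    removed = [cur.loci[j] for j in range(cur.n_loci) if j not in set(keep_l)]
    nxt = cur.subset(locus_idx=keep_l)
    report.add(FilterStage("hwe", cur.n_loci, nxt.n_loci,
                           cur.n_samples, nxt.n_samples, removed_loci=removed))
    return nxt, report
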