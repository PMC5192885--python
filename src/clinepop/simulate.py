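"""Synthetic genotype datasets with known truth for every pipeline stage.

The generator emulates the statistical structure the analysis assumes: a
weak neutral divergence background (Balding–Nichols beta draws around an
ancestral frequency, with an explicit F_ST parameter), a minority of
high-divergence loci whose population frequencies follow a sigmoid cline
along a one-dimensional transect, optional linkage disequilibrium between
chosen locus pairs, and missing genotype calls. Everything is determined by
the seed.

The default configuration mirrors the study conditions the package targets:
12 populations along a ~4600 km transect, 20 diploids per population,
2000 neutral loci at F_ST = 0.005 and 32 clinal loci (~1.6% of the total)
sweeping from ~0.05 to ~0.95 in frequency across the transect.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genotypes import MISSING, GenotypeMatrix, PopulationMap


@dataclass
class ClineTruth:
    """True cline parameters of one simulated clinal locus."""

    center_km: float
    width_km: float
    p_min: float
    p_max: float

    def __post_init__(self) -> None:
        if self.width_km <= 0:
            raise ValueError("cline width must be > 0")
        if not (0.0 <= self.p_min < self.p_max <= 1.0):
            raise ValueError("require 0 <= p_min < p_max <= 1")


@dataclass
class SimulationConfig:
    """Knobs of the generator; defaults are the emulated study conditions."""

    seed: int = 0
    n_populations: int = 12
    diploids_per_population: int = 20
    transect_positions_km: list[float] | None = None  # default: even 0..4600
    transect_span_km: float = 4600.0
    n_neutral: int = 2000
    n_clinal: int = 32
    neutral_f: float = 0.005
    clinal_truths: list[ClineTruth] | None = None  # default: drawn per locus
    clinal_center_range_km: tuple[float, float] = (2000.0, 2600.0)
    clinal_width_range_km: tuple[float, float] = (300.0, 3000.0)  # log-uniform
    clinal_p_min: float = 0.05
    clinal_p_max: float = 0.95
    clinal_noise_f: float = 0.002
    ld_pairs: list[tuple[int, int]] | None = None  # clinal-locus index pairs
    n_ld_pairs: int = 8
    ld_target_r2: float = 0.2
    missingness: float = 0.05
    ancestral_law: tuple[float, float] = (0.05, 0.95)  # uniform support

    def __post_init__(self) -> None:
        if min(self.n_populations, self.diploids_per_population) <= 0:
            raise ValueError("population counts must be positive")
        if self.n_neutral < 0 or self.n_clinal < 0:
            raise ValueError("locus counts must be non-negative")
        if not (0.0 <= self.neutral_f < 1.0):
            raise ValueError("neutral F must lie in [0, 1)")
        if not (0.0 <= self.ld_target_r2 <= 1.0):
            raise ValueError("target r^2 must lie in [0, 1]")
        if not (0.0 <= self.missingness < 1.0):
            raise ValueError("missingness must lie in [0, 1)")

    def positions(self) -> np.ndarray:
        if self.transect_positions_km is not None:
            return np.asarray(self.transect_positions_km, dtype=float)
        return np.linspace(0.0, self.transect_span_km, self.n_populations)


def _balding_nichols(rng: np.random.Generator, p_anc: np.ndarray, f: float,
                     n_pops: int) -> np.ndarray:
    """Population frequencies ~ Beta with mean p and variance p(1-p)F."""
    p_anc = np.atleast_1d(np.asarray(p_anc, dtype=float))
    if f == 0.0:
        return np.tile(p_anc, (n_pops, 1))
    shape = (1.0 - f) / f
    a = np.clip(p_anc * shape, 1e-12, None)
    b = np.clip((1.0 - p_anc) * shape, 1e-12, None)
    return rng.beta(a[None, :], b[None, :], size=(n_pops, p_anc.size))


def simulate_neutral_loci(config: SimulationConfig,
                          rng: np.random.Generator | None = None) -> np.ndarray:
    """(n_populations, n_neutral) frequencies under the Balding–Nichols law.

    The ancestral frequency of each locus is uniform on the configured
    support; F = 0 degenerates to all populations sharing the ancestral
    frequency exactly.
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    lo, hi = config.ancestral_law
    p_anc = rng.uniform(lo, hi, size=config.n_neutral)
    return _balding_nichols(rng, p_anc, config.neutral_f, config.n_populations)


def sigmoid_cline(x: np.ndarray | float, center: float, width: float,
                  p_min: float, p_max: float) -> np.ndarray | float:
    """p(x) = p_min + (p_max - p_min) / (1 + exp(-4 (x - center) / width)).

    ``width`` is the inverse-maximum-slope width: the slope at the center is
    (p_max - p_min) / width.
    """
    return p_min + (p_max - p_min) / (1.0 + np.exp(-4.0 * (np.asarray(x, dtype=float) - center) / width))


def default_cline_truths(config: SimulationConfig,
                         rng: np.random.Generator) -> list[ClineTruth]:
    c_lo, c_hi = config.clinal_center_range_km
    w_lo, w_hi = config.clinal_width_range_km
    centers = rng.uniform(c_lo, c_hi, size=config.n_clinal)
    widths = np.exp(rng.uniform(np.log(w_lo), np.log(w_hi), size=config.n_clinal))
    return [ClineTruth(c, w, config.clinal_p_min, config.clinal_p_max)
            for c, w in zip(centers, widths)]


def simulate_clinal_loci(config: SimulationConfig,
                         rng: np.random.Generator | None = None,
                         truths: list[ClineTruth] | None = None,
                         ) -> tuple[np.ndarray, list[ClineTruth]]:
    """(n_populations, n_clinal) frequencies from sigmoid clines.

    Each locus's expected frequency is the tail-free sigmoid evaluated at
    the population transect positions, perturbed by Balding–Nichols noise
    with the (small) configured F.
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    if truths is None:
        truths = config.clinal_truths or default_cline_truths(config, rng)
    x = config.positions()
    cols = []
    for t in truths:
        mean = sigmoid_cline(x, t.center_km, t.width_km, t.p_min, t.p_max)
        if config.clinal_noise_f > 0:
            col = np.array([
                _balding_nichols(rng, m, config.clinal_noise_f, 1)[0, 0] for m in mean
            ])
        else:
            col = mean
        cols.append(col)
    freqs = (np.column_stack(cols) if cols
             else np.empty((config.n_populations, 0)))
    return freqs, truths


def sample_genotypes(freqs: np.ndarray, config: SimulationConfig,
                     rng: np.random.Generator | None = None,
                     locus_ids: list[str] | None = None) -> GenotypeMatrix:
    """Binomial(2, p) dosages, independent across individuals and loci."""
    rng = np.random.default_rng(config.seed) if rng is None else rng
    if np.nanmin(freqs, initial=0.0) < 0 or np.nanmax(freqs, initial=0.0) > 1:
        raise ValueError("frequencies must lie in [0, 1]")
    n_pops, n_loci = freqs.shape
    n_dip = config.diploids_per_population
    dosage = np.empty((n_pops * n_dip, n_loci), dtype=np.int8)
    for j in range(n_pops):
        dosage[j * n_dip:(j + 1) * n_dip] = rng.binomial(
            2, freqs[j][None, :], size=(n_dip, n_loci)).astype(np.int8)
    pops = [f"P{j + 1:02d}" for j in range(n_pops)]
    samples = [f"{p}_{i + 1:03d}" for p in pops for i in range(n_dip)]
    populations = [p for p in pops for _ in range(n_dip)]
    loci = locus_ids if locus_ids is not None else [f"L{j + 1:05d}" for j in range(n_loci)]
    return GenotypeMatrix(samples=samples, populations=populations, loci=loci, dosage=dosage)


def inject_ld_pairs(G: GenotypeMatrix, pairs: list[tuple[int, int]],
                    target_r2: float, seed: int) -> GenotypeMatrix:
    """Induce dosage correlation between locus pairs by mixture copying.

    For each (i, j) pair, each individual's dosage at locus j is replaced by
    its dosage at locus i with probability phi = sqrt(target_r2), else kept;
    for matched marginal frequencies the realized squared dosage correlation
    is approximately the target.
    """
    if not (0.0 <= target_r2 <= 1.0):
        raise ValueError("target r^2 must lie in [0, 1]")
    for i, j in pairs:
        if not (0 <= i < G.n_loci and 0 <= j < G.n_loci):
            raise ValueError(f"LD pair ({i}, {j}) references a missing locus")
    rng = np.random.default_rng(seed)
    dosage = G.dosage.copy()
    phi = np.sqrt(target_r2)
    for i, j in pairs:
        copy = rng.random(G.n_samples) < phi
        dosage[copy, j] = dosage[copy, i]
    return GenotypeMatrix(samples=list(G.samples), populations=list(G.populations),
                          loci=list(G.loci), dosage=dosage)


def inject_missingness(G: GenotypeMatrix, rate: float, seed: int) -> GenotypeMatrix:
    """Independently blank each cell with the given probability."""
    if not (0.0 <= rate < 1.0):
        raise ValueError("missingness rate must lie in [0, 1)")
    if rate == 0.0:
        return G
    rng = np.random.default_rng(seed)
    mask = rng.random(G.dosage.shape) < rate
    dosage = np.where(mask, np.int8(MISSING), G.dosage)
    return GenotypeMatrix(samples=list(G.samples), populations=list(G.populations),
                          loci=list(G.loci), dosage=dosage)


def simulate_dataset(config: SimulationConfig | None = None,
                     ) -> tuple[GenotypeMatrix, PopulationMap, pd.DataFrame]:
    """Compose the generator stages into one seeded dataset with truth.

    Returns the genotype matrix, a population map carrying the transect
    positions, and a truth table with one row per locus (class, true cline
    parameters for clinal loci, LD-pair membership).
    """
    config = config or SimulationConfig()
    rng = np.random.default_rng(config.seed)
    neutral = simulate_neutral_loci(config, rng)
    clinal, truths = simulate_clinal_loci(config, rng)
    freqs = np.hstack([neutral, clinal])
    n_neutral = config.n_neutral
    loci = ([f"N{j + 1:05d}" for j in range(n_neutral)]
            + [f"C{j + 1:05d}" for j in range(config.n_clinal)])
    G = sample_genotypes(freqs, config, rng, locus_ids=loci)

    pairs = config.ld_pairs
    if pairs is None and config.n_clinal >= 2 and config.n_ld_pairs > 0:
        # default: disjoint pairs among clinal loci, emulating multi-SNP tags
        k = min(config.n_ld_pairs, config.n_clinal // 2)
        perm = rng.permutation(config.n_clinal)[: 2 * k]
        pairs = [(n_neutral + int(perm[2 * t]), n_neutral + int(perm[2 * t + 1]))
                 for t in range(k)]
    pairs = pairs or []
    if pairs:
        G = inject_ld_pairs(G, pairs, config.ld_target_r2,
                            seed=int(rng.integers(2**31 - 1)))
    if config.missingness > 0:
        G = inject_missingness(G, config.missingness,
                               seed=int(rng.integers(2**31 - 1)))

    x = config.positions()
    pops = [f"P{j + 1:02d}" for j in range(config.n_populations)]
    popmap = PopulationMap(
        populations={p: [s for s, sp in zip(G.samples, G.populations) if sp == p]
                     for p in pops},
        positions_km={p: float(x[j]) for j, p in enumerate(pops)},
    )

    in_pair = {}
    for i, j in pairs:
        in_pair.setdefault(i, []).append((i, j))
        in_pair.setdefault(j, []).append((i, j))
    rows = []
    for idx, locus in enumerate(loci):
        clinal_idx = idx - n_neutral
        t = truths[clinal_idx] if clinal_idx >= 0 else None
        rows.append({
            "locus": locus,
            "class": "clinal" if t is not None else "neutral",
            "center_km": t.center_km if t else np.nan,
            "width_km": t.width_km if t else np.nan,
            "p_min": t.p_min if t else np.nan,
            "p_max": t.p_max if t else np.nan,
            "ld_pairs": ";".join(f"{loci[a]}|{loci[b]}" for a, b in in_pair.get(idx, [])),
        })
    truth = pd.DataFrame(rows)
    return G, popmap, truth


def transect_distance_matrix(popmap: PopulationMap) -> pd.DataFrame:
    """Pairwise |x_i - x_j| (km) from the transect positions."""
    pops = popmap.pops
    x = popmap.positions_for(pops)
    d = np.abs(x[:, None] - x[None, :])
    return pd.DataFrame(d, index=pops, columns=pops)
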