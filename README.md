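# clinepop

Population structure, selection scans and per-generation dispersal
estimation for range-wide SNP datasets sampled along a one-dimensional
transect — the analysis situation typical of broadcast-spawning marine
invertebrates (scallops, lobsters, urchins) genotyped by RADseq, where
neutral differentiation is weak (F_ST ~ 0.005), a small minority of loci
under directional selection show steep latitudinal allele-frequency clines,
and the scientific question is how far larvae effectively disperse per
generation.

The package takes a diploid biallelic genotype matrix (VCF or PLINK
ped/map text) plus a population map and transect positions, and provides:

* **Genotype QC** — the standard filter chain (per-locus genotyping rate,
  per-individual missingness, minor allele frequency, per-population exact
  Hardy–Weinberg tests) with a per-stage `FilterReport`.
* **Summary statistics** — Weir–Cockerham (1984) F_ST (per locus,
  multilocus ratio of sums, pairwise between populations), genotypic LD
  r² (squared dosage correlation over pairwise-complete individuals),
  Cavalli-Sforza & Edwards chord distances, neighbour-joining trees with
  bootstrap over individuals, hierarchical AMOVA with permutation tests,
  PCA + k-means with BIC cluster selection, and Mantel tests (exact
  enumeration for small population sets).
* **Outlier detection** — an FDIST-style scan comparing each locus's
  (He, F_ST) to a simulated hierarchical island-model null calibrated to
  the observed multilocus F_ST, with Benjamini–Hochberg FDR control.
* **Cline fitting** — per-locus MCMC fits of the hybrid-zone sigmoid

      p(x) = pMin + (pMax − pMin) / (1 + exp(−4 (x − c) / w)),

  where `c` is the cline center (km) and `w` the inverse-maximum-slope
  width, across a four-model family (fixed/free frequency scaling ×
  no/exponential tails) plus a flat null, selected by small-sample AICc
  and a log-likelihood significance cutoff.
* **Dispersal** — σ, the SD of parent–offspring distance (km/generation),
  via (a) Rousset's one-dimensional isolation-by-distance route,
  σ = √(1/(4 D b)) from the slope b of F_ST/(1−F_ST) on distance and
  effective density D, with a density sensitivity sweep; and (b) the
  cline × LD route, σᵢ = wᵢ √(R ρ) per locus with R the LD correlation
  and ρ the recombination rate.
* **Synthetic data** — a seeded generator (Balding–Nichols neutral
  background, sigmoid clinal loci, injected LD pairs, missingness) so the
  whole pipeline can be exercised against known truth without any
  download.

## Worked example

```python
import numpy as np
from clinepop import (SimulationConfig, simulate_dataset, apply_qc_filters,
                      QCThresholds, wc_fst, OutlierScan, NullConfig,
                      allele_statistics, fit_locus, cline_ld_sigma, ld_r2)

cfg = SimulationConfig(seed=42, n_neutral=800, n_clinal=12,
                       diploids_per_population=20, missingness=0.05,
                       clinal_width_range_km=(500.0, 1500.0))
G, popmap, truth = simulate_dataset(cfg)
G, report = apply_qc_filters(G, popmap, QCThresholds())
print(f"QC: {report.stages[0].loci_before} -> {G.n_loci} loci, "
      f"{G.n_samples} individuals retained")
fst = wc_fst(G, popmap)
print(f"multilocus Weir-Cockerham F_ST = {fst.multilocus:.4f}")
scan = OutlierScan(G, popmap, NullConfig(n_sims=60_000)).fit(alpha=0.05, seed=1)
print(scan.summary())

ft = allele_statistics(G, popmap).freqs
x = popmap.positions_for(ft.pops)
locus = scan.outlier_loci[0]
j = ft.loci.index(locus)
sel, _ = fit_locus(ft.p[:, j], ft.n[:, j], x, locus=locus,
                   iterations=20_000, burn_in=2_000, seed=7)
print(f"{locus}: best model {sel.best_model}, width = {sel.width_km:.0f} km, "
      f"center = {sel.center_km:.0f} km")

widths = []
for locus in scan.outlier_loci:
    j = ft.loci.index(locus)
    s, _ = fit_locus(ft.p[:, j], ft.n[:, j], x,
                     iterations=4000, burn_in=800, seed=7 + j)
    if s.significant:
        widths.append(s.width_km)
est = cline_ld_sigma(widths, ld_r2(G, loci=scan.outlier_loci).mean_r2)
print(est.summary())
```

prints (numbers from this exact seeded run):

```
QC: 812 -> 805 loci, 240 individuals retained
multilocus Weir-Cockerham F_ST = 0.0190
Outlier scan: 805 loci against island-model null (f = 0.01927); 12 outliers (1.5%) at q <= 0.05
C00001: best model free_notails, width = 1508 km, center = 2207 km
Dispersal (cline_ld): sigma = 749.5 ± 305.5 km/generation over 12 values
```

All 12 planted clinal loci are recovered as outliers (1.5% of the panel,
with zero false positives); the fitted width/center for the first outlier
(1508 km / 2207 km against a simulated truth of 1041 km / 2456 km) shows
the sampling + MCMC uncertainty expected from 12 populations of 40 alleles;
and the per-locus cline widths combine with the outlier-class mean r² into
a σ far below the ~1800 km mean pairwise population distance — the
restricted-dispersal signature the method is designed to expose.

The same stages run from the shell against a YAML config:

```bash
clinepop run-all --config config.yaml --out run/ --seed 5
```

producing a restartable run directory (`qc_genotypes.vcf`,
`pairwise_fst_*.tsv`, `outliers.tsv`, `clines.tsv`, `dispersal.tsv`,
`report.txt`, …) in which every TSV carries the config hash, and reruns
with the same config are byte-identical.

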