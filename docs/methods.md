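# Methods

This note documents the statistical models implemented in `clinepop`, the
assumptions behind them, the defaults and why they were chosen, what the
synthetic-data generator does and does not emulate, and the numerical
choices a user auditing results should know about.

## Data model

Everything operates on a diploid, biallelic dosage matrix: `dosage[i, l]`
counts copies of the *counted* allele (VCF ALT / PLINK A1) carried by
individual `i` at locus `l`, with a single missing sentinel distinct from
0/1/2. All statistics use pairwise-complete observations; a (population,
locus) cell with no calls has an *undefined* frequency (NaN), never 0.
Populations live on a one-dimensional transect with positions in km from
the origin (the northernmost site in the motivating design).

## QC filter chain

Filters run in a fixed order — (1) per-locus genotyping rate, (2)
per-individual missingness, (3) pooled MAF on the retained individuals,
(4) per-population exact Hardy–Weinberg tests — and a `FilterReport`
records every removal, so a different ordering would be visible in the
report rather than silent. Defaults: call rate ≥ 0.75 (0.95 is the natural
stricter preset for RADseq panels typed at high completeness), MAF > 0.05
(strict inequality; a threshold of 0 disables the filter), individual
missingness ≤ 0.20, HWE α = 0.05 with removal when a locus is out of HWE
in ≥ 6 populations. The HWE test is the full Levene/Haldane exact test
(enumeration of all heterozygote counts compatible with the observed
allele counts, summing configurations no more probable than the observed
one); no χ² approximation and no mid-p variant. The chain is idempotent.

A practical floor worth knowing: with n diploids the smallest attainable
two-sided exact p is bounded below (e.g. no configuration at n = 4 reaches
p < 0.0857), so very small per-population samples can never fail the HWE
stage at α = 0.05.

## Summary statistics

**F_ST.** The Weir & Cockerham (1984) θ estimator from the per-population
variance components (a, b, c) on genotype counts; the multilocus estimate
is the ratio of sums Σa / Σ(a+b+c). Negative estimates are retained —
truncation at 0 would bias the isolation-by-distance regression, whose
response is F_ST/(1−F_ST). Loci observed in fewer than two populations are
excluded from the sums and counted. Pairwise population matrices apply the
same estimator per pair; loci with undefined components within a pair are
dropped for that pair only.

**LD r².** The genotypic (dosage-correlation) r²: the squared Pearson
correlation of dosages over individuals complete at both loci. This is the
unphased-data convention of the standard PLINK workflow; haplotype-EM r²
is not implemented. Pairs involving a zero-variance locus are undefined,
excluded from class means and counted.

**Chord distance.** The Cavalli-Sforza & Edwards (1967) angular form with
the 2/π normalization, per biallelic locus
Dc = (2/π) √(2 (1 − √(p₁p₂) − √(q₁q₂))), averaged over shared loci; the
per-locus maximum at opposite fixation is (2/π)√2 ≈ 0.9003. The constant
is fixed so neighbour-joining topologies are reproducible across runs.

**Neighbour joining.** Saitou–Nei NJ (via scikit-bio) on the chord-distance
matrix. Bootstrap resamples *individuals with replacement within each
population* — not loci — recomputes frequencies, distances and the
topology, and reports per-internal-edge support as the percent of
replicates containing the bipartition.

**AMOVA.** A nested random-effects decomposition of allele-copy variance
over four strata (among groups; among populations within groups; among
individuals within populations; within individuals), estimated by a
method-of-moments fit with unbalanced-design coefficients, pooled over
loci (each locus contributes its sums of squares, degrees of freedom and
expected-mean-square coefficients computed from its own non-missing
sample structure). Percents sum to 100 by construction; components can be
negative, as in standard practice. Permutation p-values use
(#extreme + 1)/(n_perm + 1) with the unit appropriate to each stratum:
whole populations permuted among groups; individuals permuted among
populations within groups; and, for the two individual-level strata,
alleles re-paired at random within populations. The allele re-pairing
null is sampled exactly (the within- and among-individual sums of squares
are linear in the total heterozygote count, which is drawn from the
random-pairing distribution per population × locus). The within-individual
row is tested one-sided in the opposite direction of the among-individual
row (heterozygote deficit inflates one and deflates the other). Note the
estimand for the among-group component is the ddof = 1 variance of group
effects — with two groups at allele frequencies 0.3/0.7 the true
among-group component is 0.08, not the ddof = 0 value 0.04.

**PCA / k-means / BIC.** Dosages are mean-imputed per locus, centered
(scaling optional, default off), decomposed by PCA; k-means runs for
k = 1..max_k on the retained components and BIC(k) = n ln(W_k/n) + k ln(n)
(W_k the total within-cluster sum of squares) selects k at the minimum —
the find-clusters convention of the standard R workflow.

**Mantel test.** Pearson correlation over upper-triangle pairs with a
one-sided (greater) permutation test. When n! ≤ n_perm every relabeling is
enumerated and the p-value is exact (identity included); otherwise random
relabelings with the (#≥ + 1)/(n_perm + 1) convention.

## Island-model outlier scan

The null for "is this locus's F_ST too large for its heterozygosity?" is a
hierarchical island model: demes nested in groups (default 500 demes in 50
groups), with deme frequencies drawn from the drift–migration equilibrium —
Beta distributions around the group frequency, themselves Beta around an
ancestral frequency drawn uniformly subject to the expected-heterozygosity
cap (default 0.5). The two levels share a common divergence parameter f
split as f_ct = f_sc = 1 − √(1−f) so the composed deme-level divergence
equals f. Sampling mirrors the observed design: the same number of sampled
demes and diploids per deme, genotypes drawn under within-deme HWE, and
Weir–Cockerham F_ST computed per simulated locus exactly as for the data.

f is calibrated by geometric bisection so the simulated *multilocus
ratio-of-sums* F_ST matches the observed one (tolerance 5% relative /
0.001 absolute). Calibrating the simulated per-locus *median* to the
observed multilocus value was tried and rejected: the two estimators
differ systematically (median ≈ 0.0032 vs multilocus ≈ 0.005 at
f = 0.005), which leaves a visible uniformity bias in the p-values.
Matching like to like gives KS distances ≈ 0.02 at 2000 neutral loci. An
observed value at or below the Monte-Carlo noise floor of the calibration
is treated as panmixia.

Empirical p-values are computed within heterozygosity bins (20 quantile
bins of the null He by default): p = (#null ≥ observed + 1)/(bin + 1),
one-sided for directional selection; under-filled bins are widened
symmetrically and the affected loci flagged. The +1 convention avoids
zero p-values feeding the Benjamini–Hochberg step (via statsmodels) and
implies a *p-value floor* of 1/(bin count + 1): for BH at FDR α to be
attainable at all, the null cloud must satisfy
bin count ≳ m / (α · k_expected) — e.g. ~60,000 simulated loci for 2000
tested loci and ~30 expected discoveries. The default simulation size is
100,000. The exact deme/group arrangement of the original island-model
software is not published; the scheme here (sampled demes drawn without
replacement across all demes) is a documented, configurable choice.

## Cline models

The central sigmoid is parameterized so `w` is the inverse-maximum-slope
width — the slope at the center is (pMax − pMin)/w — the hybrid-zone
convention that makes widths comparable in km. Exponential tails
(Szymura–Barton form) replace the sigmoid beyond c ± δ on each side,
decaying at rate 4τ/w and continuous at the junction; tail parameter
ranges are uniform priors (δ over one span, τ over (0, 1]).

The likelihood is binomial on population allele counts, k = round(p̂·n),
with predicted frequencies clamped to [1e−9, 1−1e−9]; the binomial
coefficient constant is omitted, which affects no comparison between
models on the same data. Fitting is random-walk Metropolis over the free
parameters (width proposed on the log scale), priors: c uniform over
[−0.5, 1.5] × span, w log-uniform over [1 km, 10 × span], pMin/pMax
uniform with pMin < pMax enforced by rejection. Fixed scaling pins
pMin/pMax at the locus's observed extreme population frequencies. The
reported point estimate is the trace's maximum-lnL point (not the
posterior mean) so AICc = −2lnL + 2k + 2k(k+1)/(n − k − 1), with n the
number of populations with data, is well defined; models with
n − k − 1 ≤ 0 are dropped with a warning. Defaults are 100,000 iterations
after 10,000 burn-in; at 12 populations × 40 alleles this recovers a
w = 1000 km cline with ~18% median width error and ≥ 95% coverage of the
central trace interval (the package's acceptance suite runs exactly this
check at reduced locus counts).

**Significance cutoff.** A locus shows a significant cline when a
non-null model wins AICc *and* its log-likelihood clears a cutoff
(default −10). Three readings of the cutoff are implemented because the
convention is genuinely ambiguous:

* `saturated` (default): lnL relative to the saturated fit (one free
  frequency per population) — a deviance-scale goodness-of-fit that is 0
  for a perfect fit at any sample size, so a fixed −10 is meaningful
  whether populations contribute 24 or 400 alleles;
* `absolute`: the raw binomial lnL. At realistic allele counts even a
  perfect fit sits near −140 (≈ −n_pops · ln√(2πnp̂q̂) before the dropped
  constant), so this reading flags nothing at desk scale; it is retained
  because it is the literal published convention;
* `delta`: lnL relative to the flat null.

Neutral-locus cline screening uses a seeded random subset (default 500)
of the neutral class, mirroring common practice of screening a tractable
random subset rather than every neutral locus.

## Dispersal estimators

**IBD / Rousset.** OLS of F_ST/(1−F_ST) on pairwise distance over
population pairs (pairs with F_ST = 1 excluded and logged), Mantel
significance on the transformed matrix, and the one-dimensional lattice
conversion σ = √(1/(4 D b)). The 2-D log-distance variant is deliberately
not implemented: the motivating design is a linear coastal transect.
Effective density D (breeding adults per km) is a required input — census
densities from surveys are generally not effective densities — and the
first-class output includes a sensitivity sweep over density multipliers
(default 10⁻²…10²), since σ scales only as D^(−1/2).

**Cline × LD.** From the Barton–Gale relation R ≈ σ²/(ρ w₁ w₂) with
w₁ = w₂ = w, each locus's σᵢ = wᵢ √(R ρ). By default R = √(mean r²),
because the genotypic r² is the *squared* LD correlation; plugging mean
r² in directly (`ld_mode='direct'`) is available for audit since the
published convention is not explicit. ρ defaults to 0.5 (unlinked loci).
Per-locus σ uses each locus's own width with the class-level mean LD, so
the dispersion of σ across loci (mean ± SD) reflects the width
distribution. The class summary feeds a Welch two-sample comparison
(scipy, Satterthwaite df) between outlier-class and neutral-class σ.

## Synthetic data generator

The generator is first-class, tested code, and its defaults are the study
conditions the package targets: 12 populations evenly spaced over a
4600 km transect, 20 diploids per population, 2000 neutral loci under the
Balding–Nichols law at F = 0.005 (ancestral frequencies uniform on
[0.05, 0.95]), 32 clinal loci (~1.6%) sweeping 0.05→0.95 with centers
uniform on 2000–2600 km and widths log-uniform on 300–3000 km (bracketing
a geometric mean near 1000 km), 8 LD pairs among the clinal loci at
target r² = 0.2 (emulating multiple SNPs per sequencing tag), and 5%
missingness (the emulated panels carry little missing data after QC; up
to 20% is supported). LD is injected by dosage copying with probability
φ = √(target r²), the minimal mechanism that hits a *dosage-correlation*
target — which is exactly the r² the pipeline measures.

What the generator does **not** emulate, and hence what green tests do
not establish about real data: no coalescent ancestry or shared drift
(population frequencies are independent given the ancestral draw, so
there is no isolation-by-distance signal in the neutral background), no
demographic history or secondary contact, no recombination map (LD pairs
are exchangeable copies, not haplotype blocks), strictly one-dimensional
geometry, and missingness that is independent of genotype — real
RADseq missingness is not (allele dropout). One consequence worth noting:
loci sharing a cline are strongly correlated, so the realized mean r²
within the clinal class is far above the injected pairwise target; the
LD structure of the synthetic outlier class is more extreme than in the
motivating data.

## Numerical choices and degenerate inputs

* Missing dosage is a single sentinel (−1); every statistic goes through
  explicit masks, never through 0-filling visible to the result.
* Monomorphic input to the HWE test returns p = 1; a locus monomorphic
  within an LD pair leaves the pair undefined rather than 0 or 1.
* Degenerate (all-equal) distance matrices are accepted by NJ; the Mantel
  test flags constant matrices instead of dividing by zero.
* The Metropolis sampler clamps sigmoid exponents to ±700 to avoid
  overflow; proposals outside the prior box are rejected, not reflected.
* All randomness flows from explicit integer seeds through
  `numpy.random.default_rng`; the file pipeline derives per-stage seeds
  from the master seed by hashing the stage name, so runs are
  byte-reproducible and stages are independently rerunnable.
* Pipeline problem sizes are configurable; the shipped test and
  acceptance configurations use reduced locus counts and MCMC lengths
  (e.g. 3–4k iterations for screening-scale fits, 100k for the parameter
  recovery check), chosen as the smallest sizes at which the statistical
  behavior under test is stable.

## Known limitations

* The island-model null assumes the observed design samples demes
  exchangeably; spatially structured sampling (e.g. two clusters of
  demes) inflates the null calibration f and makes the scan conservative
  for loci differentiated *within* clusters.
* AMOVA assumes the two-level grouping is given; it does not search for
  the best grouping.
* Fixed-scaling cline fits pin pMin/pMax at observed extremes, which at
  small allele counts borrows noise from the data (visible as occasional
  AICc wins over the null on flat loci, at roughly the χ² tail rate).
* The Rousset route is reported even where the underlying stepping-stone
  assumption is questionable (a two-cluster system driven by one steep
  cline); judging its applicability is left to the analyst, as the
  sensitivity sweep makes its fragility explicit.
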