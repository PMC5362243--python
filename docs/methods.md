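# Methods

This note documents the models, the synthetic-data generator, the numerical
choices and the limits of what the test suite demonstrates.

## Pedigree and kinship

`simulate_pedigree` builds discrete-generation families: founder couples,
Poisson(`mean_offspring`) children per couple, and married-in spouses created
as new founders inside the same family, so families are self-contained
connected components and no inbreeding arises. `simulate_family_cohort`
produces the two-generation nuclear families (size capped, default 20) used
for the large block-diagonal cohorts.

Kinship follows the standard recursion — k_ii = ½(1 + k_fm), k_ij =
½(k_i,father(j) + k_i,mother(j)) — giving Φ with diagonal ½ and off-diagonal
k_ij, so 2Φ is the additive relationship matrix. A published piecewise form
with 2k_ij off the diagonal would make a parent-offspring covariance equal
the variance and destroys positive-definiteness in larger sibships; we use
the universal definition. Because families are independent, the recursion
runs per family and Φ is stored sparse above 4,000 individuals; consumers
work through `block_indices`/`dense_block`.

## Genotypes and LD

Founder haplotypes are drawn per LD block by a Markov chain across sites:
for each adjacent pair, the two-locus disequilibrium D = √(r²·p_A q_A p_B q_B)
is validated against the frequency bound D_max (an infeasible target r²
raises an error naming r²_max) and converted to conditional allele
probabilities. The declared block target therefore applies to adjacent
pairs; LD between non-adjacent block members decays geometrically, which is
adequate for the locus-zoom patterns the fine-mapping stage needs and keeps
every pairwise target achievable. Non-founders inherit by gene dropping
with crossover probability min(½, rate × distance) between adjacent sites;
phase is retained end to end so haplotype-level r²/D′ are exact.

## Phenotypes

Quantitative: y = α + Xγ + Σβ_v g_v + u + ε with u ~ N(0, h²·2Φ) and
ε ~ N(0, (1−h²)I), so the total residual variance is 1 in expectation and
`h2_family` is the family fraction. Full sibs then correlate at h²/2.
Binary: P(case) = logistic(logit(prevalence) + Σ log(OR_v)·g_v + Xγ).
Sex and age covariates are independent binary/uniform draws; their effect
sizes are caller inputs, since the real distributions are registry-specific.

Defaults for the headline simulations are the published study conditions:
allele frequency 0.65%, quantitative effect −0.21 SD per allele, protective
odds ratio 0.47, family variance fraction 0.2, cohorts of n = 20,000 in
families of at most 20 (50 replicates), and n = 500 with 2,000 null
redraws for calibration. These sizes were chosen once as the smallest
cohorts at which the published effects are comfortably estimable; they are
not tuned to outcomes.

## Phenotype preparation

Rank-based inverse-normal transform Φ⁻¹(rank/(n+1)) (Van der Waerden;
Blom's (r−⅜)/(n+¼) available), average ranks for ties — eosinophil counts
are heavily tied at laboratory resolution, so the tie rule matters — then
least-squares residualization on covariates, then optional restandardization
to unit SD. Standardize-then-adjust order is fixed; the transform is
idempotent and monotone.

## Mixed-model association

The fit decorrelates the data in the spectral basis of 2Φ, computed per
family block and assembled sparsely, so one likelihood evaluation is O(n).
The covariance is σ²[(1−c)I + c·2Φ]. A pure 2σ²Φ covariance (c = 1) is
available and is what a literal reading of the model statement implies, but
it is miscalibrated whenever the generating process includes independent
noise on top of the family effect — exactly what the generator above (and
real data) produce. We therefore estimate c by bounded one-dimensional ML
under the null model and hold it fixed for both models of the LRT, the
standard two-stage mixed-model GWAS scheme; σ² is profiled analytically as
RSS/n. Measured type-I error at α = 0.05 over 2,000 family-structured null
fits is ≈ 0.045. With 2Φ = I the fit collapses to OLS exactly.

The LRT statistic is n·log(RSS₀/RSS₁) on the whitened data (the log-det
terms cancel because c is shared); p-values come from the χ²₁ upper tail.
Monomorphic genotypes and non-positive-definite 2Φ raise specific errors.
Logistic fits (statsmodels) detect complete and quasi-complete separation
and refuse to emit estimates.

Genomic control divides χ² by the LD-score-regression intercept λ
(unweighted OLS of χ² on LD score; the published factors are 1.2844 for
eosinophil counts and 1.1120 for asthma and can be supplied directly).
λ ≤ 1 deliberately leaves p-values unchanged — the correction only ever
deflates significance.

Class-specific significance thresholds ship in
`config/class_thresholds.yaml`, following the five-tier weighted-Bonferroni
scheme in wide use for whole-genome variant scans (high-impact 2.6×10⁻⁷
down to 7.9×10⁻¹⁰ for remaining non-coding); the DNase-hypersensitivity
tier of that scheme has no counterpart among our variant classes, so
intronic/intergenic take the most stringent tier. A region-Bonferroni mode
(0.05/m) covers the secondary-signal criterion.

## Conditional fine-mapping

Forward selection with the conditioned dosages as covariates in both null
and alternative models. Ties break by smaller p, then larger |β|, then
position, making selection deterministic. Candidates whose r² with any
already-selected variant exceeds the independence cap (default 0.02) are
excluded; a target perfectly collinear with the conditioned set (residual
variance fraction < 10⁻¹⁰) is flagged, never fitted. r² uses phased
haplotypes when present, squared dosage correlation otherwise (D′ is then
unavailable). `explains_signal` reports the 2×2 of conditional p-values and
a verdict; both-collinear is "indistinguishable". Coordinates are 1-based
inclusive.

## Meta-analysis

Fixed-effect inverse-variance on the log-odds/SD scale; the model is
fixed-effect because combined estimates are reported alongside P_het/I²
and the published combined values are reproduced under it (recomputed from
the rounded printed CIs: OR 0.478 vs printed 0.47; P_het 0.248 vs 0.24;
I² 26.0 vs 26.8 — rounding noise in the CIs fully accounts for the gaps).
SEs are back-derived from 95% CIs with z = 1.959964. I² is clipped at 0.
DerSimonian–Laird random effects is provided as an option, never the
default.

## ASE and the transcript-fate model

Per sample, the wild-type chromosome emits exon reads at rate λ, the mutant
at s·λ; surviving mutant transcripts retain the intron with probability ρ,
contributing ρ·s·λ intron reads on top of a baseline intron/exon ratio
(default 0.67%, the non-carrier level) applied to all chromosomes. Reads
over the tagging SNP report chromosome of origin with mapping bias b (ALT
fraction in balanced non-carriers; default 0.5, exposed because observed
non-carrier means sit slightly below one half). Counts are Poisson by
default, negative binomial optionally — no noise model is prescribed by the
source analyses.

Group summaries use medians for expression and means for fractions; the
Wilcoxon rank-sum p is exact for groups ≤ 25 (full enumeration via
permutation when ties are present and the assignment count is ≤ 2×10⁵),
otherwise the normal approximation with tie and continuity corrections.
Intron/exon ratios are raw-count by default with optional per-base length
normalization, since "coverage" is ambiguous between the two conventions.
The fate fit prefers the allelic fraction for s (s = a(1−b)/(b(1−a))),
falls back to the expression ratio (s = 2r−1), derives ρ = share·(1+s)/s,
and flags — rather than rejects — inputs whose implied expression ratio
disagrees with the observed one beyond a tolerance (default 0.1). At s = 0
retention is unidentifiable and ρ is reported as 0 by convention when the
intron share is 0, otherwise left undefined.

Carriers are identified from genotype input, never inferred from allelic
fractions.

## What the synthetic data does and does not show

The generator reproduces the statistical structure the estimators assume:
exact pedigree covariance, exact phase, Hardy–Weinberg founders, Poisson
read counts, a correctly phased tagging SNP. It does not emulate genotyping
or imputation error, recombination hotspots, population stratification,
sequencing batch effects, or mapping artifacts beyond the single bias
parameter b. Passing tests therefore demonstrate correctness of the
statistical machinery under its own assumptions, not robustness to the
failure modes of real cohort data. Published single-cohort quantities that
require the original 100,000-person registry data (e.g. the discovery-scan
p-value) are out of reach at these problem sizes and are covered instead by
parameter-recovery and oracle-equivalence tests.

## Problem sizes

Simulation sizes used by the suite and the reproduction script — 50
replicates of n = 20,000 for effect recovery, 2,000 null fits at n = 500
for calibration, 50 + 50 samples at ~2,000 informative reads for the ASE
recovery, 10,000 founders for LD round-trips — were fixed as the smallest
designs that estimate each quantity with comfortable Monte-Carlo margin
(3 SE/SEM criteria throughout).
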