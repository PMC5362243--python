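# splicefate

Statistical machinery for dissecting a rare splice-acceptor loss-of-function
variant that lowers blood eosinophil counts and protects from asthma —
implemented as a tested, end-to-end pipeline that runs entirely on synthetic
family-structured cohorts and on published summary numbers.

The package is for statistical geneticists who want the full desk-scale
analysis chain behind such a discovery in one place: simulation with the
exact covariance structure the models assume, kinship-aware association
testing, conditional fine-mapping, multi-cohort meta-analysis, and an
allele-specific RNA analysis with an explicit transcript-fate model.

## The models

**Association.** Quantitative traits are standardized by rank-based
inverse-normal transformation, z = Φ⁻¹(rank/(n+1)), adjusted for covariates,
and tested under the mixed model

    y ~ N(α + βg + Xγ, σ²[(1−c)I + c·2Φ])

where g is the allele dosage, Φ the pedigree kinship matrix (diagonal ½,
off-diagonal the kinship coefficient k_ij) and c the variance-component
mixing ratio, estimated by maximum likelihood under the null; β is tested
with the likelihood-ratio χ²₁ statistic. Binary traits use logistic
regression with nuisance covariates. Residual inflation is removed by
dividing χ² statistics by the LD-score-regression intercept λ, and variants
are judged against functional-class-specific significance thresholds (or a
region-wide Bonferroni 0.05/m).

**Fine-mapping.** Within an 800 kb gene-centered window, forward stepwise
conditional analysis re-tests each variant with the selected variants'
dosages as covariates in both null and alternative models, selecting the
smallest conditional p that passes its threshold, with a pairwise r² < 0.02
independence cap. LD is computed from phased haplotypes: r² = D²/(p_A p_a
p_B p_b), D′ = |D|/D_max.

**Meta-analysis.** Fixed-effect inverse-variance combination on the
log-odds / SD scale, with SEs back-derived from printed 95% CIs; Cochran's
Q, P_het and I² = max(0, (Q−df)/Q)·100 quantify heterogeneity.

**Transcript fate.** In a heterozygous carrier, the mutant chromosome's
transcripts survive nonsense-mediated decay with probability s, and a
fraction ρ of survivors retain the last intron. With a phased transcribed
tagging SNP (ALT on the mutant chromosome), the three observables satisfy

    het/non expression ratio r = (1+s)/2
    carrier ALT-read fraction a = s/(1+s)
    carrier intron share        = ρs/(1+s)

`fit_fate_model` inverts these identities (with optional reference-mapping
bias b) to recover (s, ρ) from measured summaries.

## Worked example

```python
from splicefate.meta_analysis import fixed_effect_meta
from splicefate.study import published_cohorts, ase_fate_study

res = fixed_effect_meta(published_cohorts("asthma"))
print(f"combined OR = {res.estimate:.3f} ({res.ci_low:.3f}, {res.ci_high:.3f}), "
      f"P_het = {res.p_het:.3f}, I2 = {res.i2:.1f}%")

ase = ase_fate_study(seed=1)
print(f"carrier allelic fraction = {ase['carrier_alt_fraction']:.3f}, "
      f"s = {ase['fate_fit'].s_hat:.3f}")
```

prints

```
combined OR = 0.478 (0.322, 0.710), P_het = 0.248, I2 = 26.0%
carrier allelic fraction = 0.199, s = 0.249
```

The five published asthma cohorts (ORs 0.36–1.08 with their CIs) combine to
a protective odds ratio of about 0.48 with no significant heterogeneity, and
RNA counts simulated at NMD survival 0.25 put one fifth of carrier reads on
the mutant chromosome — the allelic share that, through r = (1+s)/2, implies
the observed ~38% expression reduction in heterozygotes.

The `analysis/` directory holds the narrative drivers, in order: cohort
simulation (`01`), the genomic-control-corrected association scan (`02`),
stepwise conditional fine-mapping with proxy adjudication (`03`), the
published-cohort meta-analysis (`04`) and the ASE transcript-fate analysis
(`05`). Each writes its tables under `results/`.

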