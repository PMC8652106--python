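# finepgs

Fast polygenic scores (PGS) from GWAS summary statistics, built on
fine-mapping posteriors. No individual-level training data and no external
test dataset are needed: per-variant weights are posterior probabilities of
causality with sensible genome-wide defaults, so there is nothing to tune.

## Who this is for

Statistical geneticists who have per-variant GWAS summary statistics
(effect estimate β̂ or log-OR, standard error, allele frequency, p-value,
sample sizes) and want genome-wide PGS weights in seconds to minutes, e.g.
for rapid screening across many traits before committing to a heavier
PGS method.

## The model

A PGS is the weighted dosage sum `Σᵢ wᵢ β̂ᵢ Gᵢ`. Treating weight choice as a
fine-mapping problem, `wᵢ` is the posterior probability that variant *i* is
causal, computed within approximately independent LD blocks (ldetect-style
intervals):

**Single-causal flavour** (`SingleCausalPGS`) — at most one causal variant
per block. With `Vᵢ = seᵢ²`, each variant gets a Wakefield approximate
Bayes factor

    BFᵢ = N(β̂ᵢ; 0, W + Vᵢ) / N(β̂ᵢ; 0, Vᵢ)

and the block posterior is

    PPᵢ = π BFᵢ / (π₀ + Σⱼ π BFⱼ),   π₀ = 1 − nπ,

with defaults π = 10⁻⁴ and W = 0.2² for case–control traits; for
quantitative traits W is estimated from the trait heritability as
`W = h² / (ν Σᵢ 1/(Nᵢ seᵢ²))`. No LD matrices are required, so this path
runs in seconds genome-wide.

**Multi-causal flavour** (`MultiCausalPGS`) — a per-block sum-of-single-
effects (SuSiE-style) variational fine-mapper on z-scores and an LD matrix
R (from a reference panel VCF or precomputed per-block files), producing
posterior inclusion probabilities `PIPᵢ = 1 − Πₗ (1 − αₗᵢ)` as weights. The
per-component prior effect variance can be fixed ("informed") or estimated
internally ("auto", recommended). Input SNPs are first thinned by p-value
(`alpha_block`, `alpha_snp`; defaults 10⁻³ and 0.1) — under the null only
~10% of SNPs have p < 0.1 and only ~10% of 1000-SNP null blocks reach
p < 10⁻⁴, so thinning removes mostly noise.

Also included: LDpred2-style summary-statistic QC (effective sample size,
SD_ss vs SD_val concordance rules), allele harmonization against a panel,
scoring from dosages, and evaluation — Mann–Whitney AUC with conversion to
liability-scale r² at prevalence K (Lee et al. 2012), or
covariate-residualized r² for quantitative traits, with bootstrap CIs.

## Worked example

Everything below runs offline on generated data:

```bash
finepgs simulate --out fixtures/ --seed 2 --trait cc --pi 0.01 --n-gwas 4000
finepgs single --sumstats fixtures/sumstats.tsv --blocks fixtures/blocks.bed \
               --trait cc --out single.tsv
finepgs multi  --sumstats fixtures/sumstats.tsv --blocks fixtures/blocks.bed \
               --trait cc --ld-panel fixtures/panel.vcf --out multi.tsv
finepgs score  --model multi.tsv --dosages fixtures/val_dosages.tsv --out scores.tsv
finepgs evaluate --scores scores.tsv --pheno fixtures/val_pheno.tsv \
                 --pheno-col trait --trait cc
```

The `multi` step prints a fit report like

```
MultiCausalPGS results
========================================
variants with weights : 158
prior pi              : 0.0001
sum of weights (PP)   : 35.6067
max weight_ppi        : 1.0000
top variants (chrom:pos  PP  final weight):
  1:3012701  1.0000  -0.73834
  1:1012901  1.0000  +0.81170
  1:1016401  0.9995  +0.65455
  1:2901  0.9862  +0.52028
  1:13401  0.9258  +0.38335
thinning              : 4/5 blocks, 158/1000 variants kept
block fits            : 4 fitted, 4 converged
```

`weight_ppi` is the posterior inclusion probability of each variant and
`weight = weight_ppi × beta` is its final score coefficient. The final
evaluation line,

```
AUC = 0.6088 (95% CI 0.5354-0.6925), K = 0.1000, liability r2 = 0.0367
```

reports the covariate-adjusted AUC of the score on the held-out cohort, the
case fraction used as prevalence, and the implied r² on the liability
scale. The same objects are available programmatically:

```python
from finepgs import MultiCausalPGS
model = MultiCausalPGS.from_files("sumstats.tsv", "blocks.bed", "panel.vcf")
res = model.fit()
print(res.summary())
res.save("weights.tsv")
scores = res.score(dosages)          # pandas DataFrame of dosages
```

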