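# Methods

This note documents the models, defaults, numerical choices and known
limitations of `finepgs`, in the order a dataset flows through the package.

## Input model and harmonization

Summary statistics are per-variant marginal effects: a log odds ratio for
case–control traits or a linear-regression slope for quantitative traits,
with its standard error, the effect-allele frequency, a two-sided p-value
and sample sizes. Only biallelic SNPs are accepted; indels, multi-allelic
records and rows failing basic validity (se ≤ 0, p ∉ (0,1], freq ∉ (0,1))
are dropped at read time and counted per reason. Duplicate
(chrom, pos, allele-pair) keys keep the first occurrence in file order — a
deterministic rule that makes reads reproducible.

Harmonization orients every row so the effect allele is the panel's
alternate allele: swapped-orientation rows have β negated, frequency
complemented and alleles exchanged (an involution — flipping twice is the
identity); reverse-complement matches are strand-corrected first.
Strand-ambiguous pairs (A/T, C/G) cannot be resolved from alleles alone, so
we use frequency agreement: the orientation whose summary-stat frequency is
closer to the panel frequency wins, and the variant is dropped when the two
distances differ by less than 0.05 (default) or when either frequency is
missing. This margin trades a few percent of usable ambiguous SNPs for
protection against silent sign flips, which corrupt scores far more than a
missing variant does.

Coordinates are 1-based (summary-stat/VCF convention); LD-block intervals
are BED convention (0-based, half-open), and block assignment tests
`start ≤ pos − 1 < end`. Variants outside every block are dropped with a
warning: the posterior model is defined only within blocks.

## Summary-statistic QC

Following the LDpred2 concordance check, we compare two estimates of the
per-SNP genotype SD: `SD_ss = 2/(√N_eff · SE)` with
`N_eff = 4/(1/N_controls + 1/N_cases)`, and `SD_val = √(2f(1−f))`. Variants
failing any of `SD_ss < 0.5·SD_val`, `SD_ss > SD_val + 0.1`, `SD_ss < 0.1`,
`SD_val < 0.05` are removed; a report keeps per-rule counts and the
(SD_ss, SD_val) pairs for the diagnostic scatter. The filter is idempotent.

Two documented caveats. First, the `2/(√N·SE)` form is exact for an
allele-count log-OR (where `se² ≈ 2/(N_eff·f(1−f))` makes SD_ss ≈ SD_val);
for a quantitative trait with a standardized phenotype, `1/(√N·SE)` already
estimates sd(G), so SD_ss sits near 2·SD_val and the filter would remove
nearly everything. We therefore apply the same four rules with
N_eff := per-SNP N but leave the filter opt-in (`--sd-filter`), and
recommend inspecting the scatter before enabling it on quantitative data.
Second, when the input lacks frequencies they are filled from the
harmonization panel before computing SD_val.

## Single-causal flavour

Within a block of n SNPs, at most one variant is causal and its true effect
is N(0, W). The Wakefield approximate Bayes factor for variant i is the
ratio of the two normal densities of β̂ᵢ under variance W+Vᵢ versus Vᵢ
(Vᵢ = seᵢ²); we evaluate its logarithm in the closed form
`0.5·[log(V/(V+W)) + z²·W/(V+W)]`, which is exact and stable for |z| far
beyond where linear-scale densities underflow. Block posteriors
`PPᵢ = πBFᵢ/(π₀ + Σ πBFⱼ)`, `π₀ = 1 − nπ`, are normalized by a log-sum-exp
that includes the log π₀ term, so `PP₀ + Σ PPᵢ = 1` holds to 1e−10 even
with log-BFs of several hundred. In real arithmetic every PP < 1; when the
null mass underflows relative to 1 in double precision we return
`1 − 1 ulp` rather than a rounded 1.0, keeping the strict inequality that
the weight contract (w ∈ [0,1)) requires. Blocks so large that nπ ≥ 1
rescale π to 0.9/n with a warning instead of crashing; the defaults never
reach this.

Defaults: π = 10⁻⁴ and W = 0.2² for case–control traits. For quantitative
traits W is estimated from heritability:
`W = h²/(ν · Σᵢ 1/(Nᵢ seᵢ²))` with ν = 10⁻⁴. The grouping follows from the
expected-heritability identity: for a standardized trait
`1/(Nᵢseᵢ²) ≈ var(Gᵢ)`, and setting the expected explained variance
`ν·W·Σ var(Gᵢ)` equal to h² gives the formula. The implied per-SNP prior
SD √W is logged at estimation time.

PP is computed on the post-QC block — removing variants changes n and
therefore π₀. The alternative (freezing n at the pre-QC count) would make
results depend on how many rows an upstream file happened to contain.

## Multi-causal flavour

Blocks are first thinned: a block is kept only if its minimum p-value
beats `alpha_block` (default 10⁻³), and within kept blocks only variants
with p < `alpha_snp` (default 0.1) are retained. Thinning is monotone and
removes ~90% of null SNPs at the defaults while keeping nearly every block
that contains signal.

Each surviving block is fitted with a sum-of-single-effects model on the z
scale: z ~ N(Rb, R) with `b = Σₗ bₗ`, each bₗ one-hot with effect
N(0, σ₀ₗ²). Coordinate ascent updates one component at a time: residual
z-scores are formed by subtracting R times the other components' posterior
means, the single-effect regression is solved in closed form (per-variant
Wakefield BF with unit observation variance, `α ∝ prior × BF`,
normal–normal shrinkage for the moments), and in "auto" mode σ₀ₗ² is first
re-optimized by maximizing the component's single-effect marginal
likelihood (1-D bounded search on log σ₀²; the optimum 0 — component
switched off — is taken whenever it is at least as good). "Informed" mode
fixes the prior: the effect-scale W is converted per variant to the z scale
as σ₀² = W/seᵢ², which makes the L = 1, identity-R fit reproduce the
single-flavour posteriors exactly (modulo the π₀ term).

The objective is the ELBO of the equivalent sufficient-statistic regression
(X'X = R, X'y = z, residual variance fixed at 1). The y'y constant is not
recoverable from z and R, so the reported trace is defined up to an
additive constant; convergence (default tol 10⁻³ on the objective change,
max 100 iterations with a flag to raise it) and monotonicity are
unaffected. Monotonicity requires R to be a valid covariance, hence the
PSD repair below. Non-convergence returns a partial fit flagged
`converged=False` — some LD blocks genuinely need many iterations.

Within-block prior over which variant a component selects: uniform by
default (standard sum-of-single-effects practice; the genome-wide per-SNP
π is not a normalized within-block prior), with optional user-supplied
per-SNP weights. The fitter is deterministic — all components initialize
at zero, so no seeds are involved.

Weights are `PIPᵢ = 1 − Πₗ (1 − αₗᵢ)`, computed over components whose prior
variance exceeds 10⁻⁹: a switched-off component's α row is the flat prior
and carries no inclusion evidence, and keeping it would inflate every PIP
by ~L/p. The final weight is PIP × β̂; the z-scale posterior-mean effect is
exposed as an extra `posterior_mean` column for users who prefer
posterior-expectation weighting. Variants thinned away or in skipped
blocks receive no entry (weight 0 by omission). Note that at
alpha_snp = 0.1 the retained null variants are a truncated (|z| ≳ 1.6)
sample, so auto-mode prior variances in signal-free kept blocks rarely
shrink fully to zero and small nonzero PIPs there are expected; their
contribution to the score is negligible because β̂ is also small.

## LD matrices

LD is the Pearson correlation of panel dosages, pairwise-complete when
genotypes are missing, with r set to 0 (and flagged) for pairs with fewer
than 30 complete observations or zero-variance columns. Sample correlation
matrices — especially pairwise-complete ones — can be indefinite, and the
variational fitter assumes a valid correlation matrix, so matrices are
repaired by clipping negative eigenvalues at 0 and renormalizing the
diagonal to 1; the repair is recorded and skipped for matrices already PSD
to 1e−8. Precomputed matrices are stored one compressed dense matrix per
block with an embedded variant index; on load the stored matrix is
re-ordered to the caller's variant order and variants absent from storage
are dropped from the block with a warning. Sparse or banded genome-wide
storage is out of scope — blocks are desk-scale.

## Scoring and evaluation

Scores sum `weight × dosage` over the intersection of model and genotyped
variants, re-using the harmonization rules: a dosage column keyed with the
swapped allele pair contributes through 2 − G. Missing dosage entries are
mean-imputed per variant (2f̂); model variants entirely absent from the
genotypes are skipped and counted.

Binary evaluation residualizes the score on covariates (OLS with
intercept) and computes the Mann–Whitney AUC of the residualized score
against case status. This residualize-then-rank adjustment is a deliberate
simplification of covariate-adjusted ROC regression: it has the same null
behavior and is testable at desk scale, but it is not identical to
covariate-specific ROC estimators. AUC converts to liability-scale r² at
prevalence K (taken as the observed case fraction) via
`t = Φ⁻¹(1−K)`, `m = φ(t)/K`, `m₂ = −mK/(1−K)`, `Q = Φ⁻¹(AUC)`,
`r² = 2Q²/((m₂−m)² + Q²m(m−t) + m₂(m₂−t))` — m is the truncated-normal
mean of case liabilities, the standard definition consistent with this
conversion's source. AUC = 0.5 maps to exactly 0; AUC < 0.5 is a hard
error suggesting an allele-orientation check. Quantitative evaluation
residualizes the trait on covariates and squares the Pearson correlation
with the score; rank-deficient covariates are a hard error naming the
collinear columns. All CIs are 95% bootstrap over individuals (1000
resamples, seeded, bit-for-bit reproducible).

## Synthetic data

The generator emulates exactly the generative model the methods assume.
Haplotypes within a block follow a Markov copying process on a shared
uniform: the latent uniform refreshes at each site with probability
1 − ld_decay, and the allele is the indicator u < fⱼ. Marginal frequencies
are exact, and for equal frequencies the allele correlation between sites
k apart is ld_decay^k; with heterogeneous frequencies adjacent correlations
fall somewhat below ld_decay. Blocks are independent. Architectures are
point-normal (causal mask Bernoulli(π), effects N(0, W), non-causal
effects exactly 0). Quantitative traits add normal noise (scaled to a
target h² when given, unit variance otherwise); binary traits threshold
the liability at the empirical 1 − K quantile. Summary statistics are
per-variant simple OLS (quantitative) or allele-count 2×2 log-ORs with
Haldane 0.5 correction (binary) — simple, deterministic and on the log-OR
scale the QC filter expects; per-variant logistic regression is not
implemented. Monomorphic variants in the GWAS sample are dropped with a
log entry. Everything is a pure function of (config, seed).

What the generator does not emulate: realistic human LD maps, imputation
error, population stratification or relatedness, case–control ascertainment
beyond simple thresholding. Passing tests demonstrate correctness of the
algorithms under their own assumptions, not performance on real cohorts.

Problem sizes: CI fixtures run at 5 blocks × 200 SNPs × 2000 individuals
(seconds end to end). The recovery experiment uses 20 replicates of
10 blocks × 250 SNPs with n_gwas = 5×10⁴, π = 10⁻³, W = 0.2², a 500-sample
panel for LD and 500 held-out individuals — large enough that
genome-wide-significant hits exist in most replicates, small enough for a
single CPU. Replicates whose realized architecture has zero causal
variants (probability ≈ e^−2.5) have an undefined truth correlation and
are excluded from the means.

## Known limitations

- No credible sets, colocalization, or variable per-SNP priors; no
  trans-ancestry modelling.
- The multi flavour's p-value thinning is an approximation adopted for
  speed; with all SNPs supplied the fit would be slower but possibly more
  accurate.
- The SD filter's quantitative-trait behavior assumes a standardized
  phenotype (see QC section).
- LD must come from a population matching the GWAS; the package does not
  detect mismatch.
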