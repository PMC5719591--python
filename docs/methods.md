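# Methods

## Model

Phenotypes are generated by the polygenic mixed model
`y = b₁ + b₂ s + g + e` with `g ~ N(0, σg² G)` and `e ~ N(0, σe² I)`.
`G` is the n×n matrix of pairwise relatedness coefficients
`G_ij = φ_ij/2 + δ_ij`, the probability-weighted count of alleles shared
identical by descent; its diagonal is 1 (non-inbred individuals).
Heritability is `R²h = σg²/(σg² + σe²)`. The analysis model is the
misspecified simple regression `y = β₁ + β₂ s + ε` fitted by OLS.

Exact consequences implemented here:

* `E(β̂₂) = b₂` — relatedness does not bias the slope.
* `V(β̂₂) = λ/(1 − R²h) · V_β` with `V_β = σe²/Σ(s−s̄)²` and the per-SNP
  inflation factor λ defined by the double sum over ordered pairs `j ≠ i`
  of `G_ij (s̄² − 2 s̄ s_i + s_i s_j)`, normalised by `Σ(s−s̄)²`. The
  implementation is the matrix identity
  `s̄²·ΣG₀ − 2 s̄ (r·s) + sᵀG₀s` (G₀ = off-diagonal part, r = row sums);
  a loop-based double-sum oracle is kept in the test suite and agreement is
  asserted to 1e−9. The quadratic-form identity
  `V(β̂₂) = scᵀ(σg²G + σe²I)sc / Sxx²` is used as an independent check.
* Averaging the numerator and denominator separately over genotype draws
  gives the allele-frequency-free approximation
  `λ′ = 1 + R²h (G₂ − (2/n)G_r)/(n − 1)`, valid for large n and mean
  relatedness Ḡ < 0.01. Violation of the Ḡ condition raises a warning,
  not an error: the bound is a quality advisory for an approximation, not a
  mathematical precondition.
* For `f;m;c` family designs (f fathers, m mothers each, c children per
  mother, all founders mutually unrelated and non-inbred) λ′ reduces to a
  ratio of polynomials in (f, m, c), evaluated in exact rational
  arithmetic (`fractions.Fraction`) to keep the grid-equivalence test at
  1e−9 honest. Special cases: trios
  `λ′ = 1 + R²h (f−1)/(3f−1)`; the (m=2, c=3) design
  `λ′ = 1 + R²h (243f−314)/(216f−24)`.
* Heritability transforms: for fixed relatedness structure, λ′−1 is
  proportional to R²h, so inflation at one heritability maps to another by
  `λ′t = 1 + (λ′−1) R²t/R²h` and inversely
  `R²t = (λ′t−1)/(λ′−1) · R²h`.

## Hypothesis testing

`T = β̂₂/S_β` with the conventional unbiased OLS variance estimator
(residual sum of squares / (n−2) / Sxx). Because the empirical variance
estimate is itself inflated by `1/(1 − R²h)`, that factor cancels in T and
`T ~ N(0, λ)` under the null, `T ~ N(μ, λ)` under the alternative with
`μ = √((n−1) R²s)`. Analytic consequences, with `z_{α/2}` the negative
lower-tail normal quantile:

* type I error `err = 2Φ(z_{α/2}/√λ)`;
* power `pwr = Φ((z_{α/2}−μ)/√λ) + 1 − Φ((−z_{α/2}−μ)/√λ)`;
* all power curves cross 50% at `α = 2Φ(−μ)` regardless of λ (at that
  level the upper cutoff sits at μ; the lower-tail contribution
  `Φ(−2μ/√λ)` is below 1e−9 for the μ of interest);
* genomic control `λ̂ = median(T²)/0.456` (the printed constant; the exact
  χ²₁ median 0.4549 is available via `constant=CHI2_1_MEDIAN`), corrected
  statistic `T/√λ̂ ~ N(μ/√λ̂, 1)`: level preserved, power reduced.

The residual degrees of freedom make T a t-like rather than exactly normal
statistic; at the sample sizes of the presets (n ≥ 129) the difference is
far below Monte-Carlo resolution, and the empirical slope-variance
deflation ν (mean S²β relative to `V_β/(1−R²h)`) is estimated from the
replicates rather than derived — its observed values are ≈ 0.99–1.00.

## Synthetic data generator

Genotypes: per SNP a population reference-allele frequency is drawn from
Beta(a=0.5, b=0.5) (a U-shaped spectrum heavy in rare variants); founder
haplotypes are Bernoulli draws at that frequency; each child inherits one
uniformly chosen allele from each parent (gene dropping over the two-
generation pedigree). SNPs are independent — no linkage disequilibrium,
mutation or genotyping error — and there are no missing genotypes. The
Beta draw is not truncated; monomorphic SNPs are removed by an explicit
filter instead, and the simulator oversamples (110,000 raw SNPs for
100,000 analysed, at full scale) so the analysis set reaches its target
size. MAF is computed from the realized in-sample p̂ over all samples
(founders and offspring). Consequently, passing tests demonstrate
correctness of the variance theory under idealised marker data; they say
nothing about LD structure, genotyping artefacts or population
stratification in real cohorts, none of which are modelled.

Phenotypes: multivariate normal replicates with covariance
`σg²G + σe²I`, drawn via a Cholesky factor of G computed once per study.
The variance scale is fixed to `σg² + σe² = 1` (σg² = R²h); every reported
quantity (λ, T, μ, ν) is invariant to this choice. Under the alternative
the SNP effect is calibrated so the SNP explains the fraction R²s of total
phenotypic variance, `b₂² Var(s) = R²s/(1−R²s) · (σg²+σe²)` with Var(s)
the sample variance (n−1 denominator). The implied mean statistic
`b₂√Sxx = √((n−1)R²s/(1−R²s))` exceeds the approximation μ by the factor
`1/√(1−R²s)` (≈ 1% at R²s = 0.02), which is inside the Monte-Carlo
tolerances used throughout.

## Relatedness estimation

The genotype-based estimator is a ratio-of-sums genomic-relationship
moment estimator: centred cross-products `(s_i − 2p̂)(s_j − 2p̂)` summed
over SNPs, divided by `Σ 2p̂(1−p̂)`, with in-sample allele frequencies
`p̂ = Σs/(2n)` and the diagonal pinned to 1. Pooling before normalising
keeps rare SNPs (abundant under the U-shaped spectrum) from dominating the
noise. In-sample frequencies introduce an O(1/n) downward bias in the
off-diagonals; with ≥ 50,000 SNPs the off-diagonal RMSD against the
pedigree matrix is ≲ 0.015 and λ′ from the estimated matrix lands within
0.05 of the closed form for all presets (the squared sampling noise adds a
small positive excess to G₂ that shrinks like 1/#SNPs). The estimator is a
plug-in surface: pedigree-derived matrices remain the exact reference for
all quantitative checks, and estimated matrices are an opt-in pathway in
the study runner. Estimated matrices may be slightly indefinite; negative
eigenvalues are clipped at zero (with a warning) before phenotype
factorisation.

## Numerical and design choices

* Sample ordering is fixed (father, mothers, each mother's children,
  families concatenated) purely for reproducibility; all statistics are
  permutation-invariant.
* Dense matrices with a memory guard at n = 20,000; the presets use
  n ≤ 999 where a full Cholesky is trivial.
* RNG: a single master seed feeds `numpy` `SeedSequence.spawn`, with one
  child stream per simulated SNP so per-SNP results do not depend on how
  many SNPs are run.
* λ summaries over SNPs report the sample SD (n−1); the over-replicate
  variance of T uses the same convention.
* `S²β = 0` (perfect fit) makes T undefined; it is returned as NaN and
  excluded from aggregates.
* Replicate grids: full scale is 1000 replicates × 1000 SNPs;
  `desk_scale()` uses 200 × 200 (and 2000 analysed SNPs), which resolves
  the mean null variance of T to about ±0.02 — an order of magnitude finer
  than the between-SNP spread it is compared against.
* The CSV dialects are sample-labelled square matrices for relatedness
  (−1 sentinel for non-estimable pairs, mapped to NaN on read) and a
  samples × SNPs table for genotypes (transposed orientation supported via
  a flag). VCF ingestion accepts complete bi-allelic diploid GT records
  only and codes the count of REF alleles.

## Known limitations

* No inbreeding, no X chromosome, no shared ancestry between founders, and
  no population stratification; the inflation studied here is purely
  relatedness-driven.
* The genotype-based estimator is a generic moment estimator, not a
  reimplementation of any specific published weighting scheme; for
  matrices with very different spectra the estimated-pathway λ′ inherits
  the estimator's noise-induced upward excess in G₂.
* The analytic T distributions are large-n approximations; at n well below
  ~100 the empirical variance of T visibly exceeds λ.
* Mixed-model fitting as a correction method is out of scope; the package
  quantifies the problem and the cost of genomic control, it does not fit
  the corrected model.
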