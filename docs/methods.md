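# Methods

## Model

For a quantitative trait measured on *n* samples and *m* biallelic
markers, each marker *j* is tested under the linear mixed model

    y = X_j β + u + ε,      u ~ N(0, σg² K),      ε ~ N(0, σe² I),

where `X_j ∈ R^{n×c}` stacks an intercept, optional covariates and the
dosage of marker *j* (so `c = 2 + #covariates`), and `K` is a genetic
similarity matrix correcting for population structure and relatedness.
The null hypothesis is that the marker coefficient is zero.

The variance components are estimated **once**, on the null model without
any marker, and reused for every marker's alternative model (the
EMMAX-style approximation).  With `V = σg² K + σe² I = C Cᵀ` (Cholesky),
pre-multiplying designs and phenotype by `C⁻¹` (triangular solves, never
an explicit inverse) reduces generalized least squares to ordinary least
squares.  Marker batches are then solved together: the batch of designs
is a `(b, n, c)` tensor, its Gram matrices and coefficient solves are
batched, and the marker test statistic is

    t_j = (n − c) (RSS₀ − RSS_j) / RSS_j,

compared against F(1, n − c).  Negative values arising from round-off
are clipped to zero (p = 1); a saturated fit (RSS = 0) is reported as an
infinite statistic.  Marker blocks whose design is rank-deficient
(condition number of the Gram matrix above 1e10 — e.g. monomorphic
markers) yield flagged missing results rather than errors, and flagged
entries are excluded from all downstream maxima and counts.

## Variance-component estimation

`K` is eigendecomposed once (`K = U S Uᵀ`, eigenvalues clipped at zero).
On the rotated data, β and the overall variance scale are profiled out
analytically, leaving a one-dimensional maximum-likelihood problem in
the ratio δ = σe²/σg².  δ is searched on a 100-point log₁₀ grid over
[1e−5, 1e5] followed by bounded Brent refinement between the grid
neighbours of the best point (tolerance 1e−6 in log δ).  ML is the
default criterion; REML is available through `method="reml"`.  When
`K = I` only σg² + σe² is identifiable; the profile is flat in δ and the
returned total equals the OLS ML residual variance, which is the correct
degenerate behaviour.

The eigendecomposition is shared across all per-permutation refits, so
each refit costs only the one-dimensional δ search.

## Permutation thresholds

The phenotype is permuted *q* times against fixed genotype, covariates
and kinship.  Covariates are deliberately **not** permuted (the
residual-permutation alternatives are out of scope).  For every
permutation the variance components are re-estimated, the data are
re-whitened with the permutation-specific Cholesky factor, and the full
scan is repeated; permutations are processed in groups whose whitened
designs form a (group × batch × n × c) tensor flattened onto the block
axis of the batched OLS kernel, so peak memory is
O(perm_batch · batch · n · c).

Per permutation *k* the maximal statistic `t_max^(k)` and minimal
p-value `p_min^(k)` are recorded.  The maxT threshold is the k-th
smallest of the `p_min^(k)` with k = max(1, ⌊αq⌋); for αq < 1 this
degrades conservatively to the smallest observed `p_min`.  Significance
is declared by strict inequality `p < δ*`.  Two adjusted p-values are
available: the maxT-adjusted value (fraction of permutations whose
maximum beats the observed statistic) and the pooled permutation p-value
that ranks an observed statistic within the entire q × m permuted null
distribution (optionally with add-one smoothing, default off; its
denominator is the count of non-flagged permuted statistics, i.e.
q · m_tested when nothing fails).  The Bonferroni baseline is α/m with m
the number of markers actually tested after filters.

Permutations are drawn up-front from one seeded PCG64 stream, so the
permutation set is a pure function of (n, q, seed) and results do not
depend on batch sizes.

## Kinship

The default similarity matrix is the VanRaden realized relationship
matrix `K = W Wᵀ / (2 Σ p_j(1 − p_j))` with `W` the dosage matrix
centred by twice the allele frequency, frequencies computed from the
analysis samples after alignment.  This choice keeps diag(K) ≈ 1 so
σg²/(σg² + σe²) reads as narrow-sense heritability; test statistics are
in any case invariant to joint rescaling of (σg², σe²).  Any other
square similarity matrix can be supplied from CSV/HDF5.  Before use the
matrix must admit a Cholesky factor; if it does not, the smallest ridge
from {1e−10, 1e−8, 1e−6, 1e−4} that makes the factorization succeed is
added to the diagonal and logged.

## Data handling conventions

* Dosages internally count copies of the **minor** allele; PLINK A1
  counting is flipped per marker on load.  Consequently a PLINK
  round-trip preserves dosages only for minor-allele-coded input.
* Missing genotype calls are mean-imputed per marker at load time.
* Replicate phenotype rows per sample are averaged, with a log entry.
* Positions are 1-based; windows are closed intervals.
* Canonical sample order after alignment is genotype-file order
  restricted to the usable intersection, so alignment is independent of
  the row order of the phenotype/kinship files.
* MAF/MAC filters drop markers below the thresholds; monomorphic
  markers are always dropped when maf_min > 0.  The filter is
  idempotent.
* HDF5 genotypes can be scanned chunk-wise against a precomputed
  kinship without loading the full matrix (`gwas_scan_hdf5`).

## Phenotype simulation

Each simulated trait samples 1001 markers at MAF ≥ 5% from the panel:
1000 polygenic background SNPs with effects drawn N(0, 0.1²) and one
causative SNP.  Noise is standard normal or mean-centred gamma (shape
0.1–4; smaller shape, more right-skew) and is rescaled so the background
explains exactly 70% of Var(background + noise) **in-sample** (the
scaling solves a quadratic in the noise multiplier, so the realized
fraction is exact to machine precision, not just in expectation).  The
causative effect is then sized so its term explains 20% of the
in-sample genetic variance.  The noise is scaled before the causative
term is added, and realized fractions are recorded with each trait.

A phenotype is **true positive** at a threshold if any marker with
p below it lies within a closed ±50 kbp window around the causative
marker on the same chromosome, and **false positive** if any such marker
lies outside the window; both can hold at once.  The phenotype-wise FDR
of a set is FP/(TP + FP) over phenotype counts, reported separately for
the Bonferroni and permutation thresholds and undefined (missing) when
no phenotype is TP or FP.

### Synthetic genotype panel

The default study panel is 200 samples × 1500 independent binomial(2, p)
markers on 5 chromosomes at 10 kb spacing, with per-marker allele
frequencies uniform on [0.01, 0.5].  The lower edge matters: rare
variants interacting with skewed residuals are the main source of the
spurious associations that a permutation threshold controls and a fixed
Bonferroni threshold does not, so a panel without rare alleles would
hide the contrast the study measures.  An optional AR(1) Gaussian-copula
parameter ρ correlates adjacent markers to emulate linkage; the default
is ρ = 0 (independent markers).

What the synthetic panel does **not** emulate: population structure and
cryptic relatedness (samples are exchangeable, so K ≈ I plus noise),
realistic LD decay, and MAF spectra skewed toward rare variants.
Passing the simulation-based tests therefore demonstrates the engine's
statistical calibration and the direction of the skewness effects, not
the magnitudes seen on real, structured data, where both the thresholds
and the FDR gap are far more extreme.

## Problem sizes and tolerances used by the validation suite

* Oracle equivalence: n = 100, m = 500 against a naive per-marker GLS
  solve (explicit V inverse); p-values to 1e−8 relative; batch size 1 vs
  m identical to 1e−12.
* Permutation engine: q = 3, n = 50, m = 20 against a loop of plain
  scans on each permuted phenotype (1e−8 relative); an identity
  permutation must reproduce the observed scan to 1e−12.
* FWER calibration: 200 replicates fully under the null (n = 100,
  m = 300, q = 100, α = 0.05); the empirical FWER at δ* must fall in the
  exact-binomial 99% band [0.01, 0.12].
* Heritability recovery: h² = 0.7 at n = 600, K from 2000 markers,
  median over 5 trait draws within ±0.15, cross-checked against a dense
  2-D likelihood grid.
* Skewness response and FDR ordering: 20 phenotypes per noise set
  (normal and gamma shapes 4, 2, 0.1) with q = 100 on the default panel;
  median δ* non-increasing with falling shape, median δ* ≥ α/m for
  normal noise, and FDR(permutation) ≤ FDR(Bonferroni) for shape 0.1.

These sizes are scaled-down versions of the full study (50 phenotypes
per set, six sets, dense real genotypes); the qualitative orderings are
stable at this scale while single-set FDR values retain visible Monte
Carlo noise (each is a ratio of counts ≤ 40).

## Numerical choices

* Whitening always via triangular forward-substitution.
* Batched Gram solves via LAPACK batched `solve`; marker standard
  errors from RSS/(n − c) times the marker diagonal of the Gram inverse
  (obtained by a solve, not an inverse).
* Cholesky of V retried with ridges {1e−10, 1e−8, 1e−6} before failing.
* Ties in the maxT order statistic resolve by plain sorting, so equal
  `p_min` values give the shared value.
* Degenerate inputs (constant phenotype, all-monomorphic genotype,
  empty marker set after filtering, rank-deficient covariates) raise
  `DataError` with a message naming the problem.

## Known limitations

* Single random effect only; no multi-kinship models, no
  leave-one-chromosome-out kinship.
* The EMMAX-style reuse of null variance components trades a small loss
  of per-marker exactness for speed, as in the standard fast LMM tools.
* Binary traits are not supported (the model is Gaussian).
* The permutation scheme permutes the phenotype only; when covariates
  are supplied, phenotype–covariate coupling is broken under
  permutation, which is conservative for covariates orthogonal to
  genotype but has no exactness guarantee otherwise.
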