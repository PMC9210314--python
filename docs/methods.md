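# Methods

This note documents the models behind each pipeline stage, the synthetic
data they are validated against, and the numerical choices that a user
changing defaults should know about. It states no empirical numbers beyond
what the test suite and `scripts/acceptance.py` compute at run time.

## Synthetic panel generator

The generator (`tritigs.simulate`) produces a diploid-coded SNP panel with
known ground truth for every downstream stage. Its defaults describe the
kind of panel the pipeline targets: 289 accessions in 5 subpopulations,
2000 biallelic SNPs on 21 chromosomes (7 per A/B/R sub-genome, split
19/25/56% to mirror a mapped triticale GBS marker set), 10% missing calls
before QC, and a yield trait controlled by 50 additive QTL.

**Allele frequencies.** Ancestral frequencies are Uniform(0.05, 0.5) per
marker; subpopulation frequencies follow the Balding–Nichols model,
Beta(p(1−F)/F, (1−p)(1−F)/F) with F = 0.1. This differentiation is what
makes the clustering and DAPC stages recoverable.

**Linkage disequilibrium.** Each subpopulation carries a pool of 100
founder haplotypes. Founders are generated by thresholding a latent AR(1)
Gaussian process along each chromosome (lag correlation exp(−c·d) for
distance d), so founder alleles at nearby sites are correlated; gametes
then copy along the founder pool, switching founders with per-bp
probability c (`recomb_rate`). Both layers decay exponentially, giving a
monotone r²–distance decline without an external coalescent simulator. A
copying chain over *independent-site* founders alone cannot produce
short-range r² above ~1/N_founders, which is why the founders themselves
carry distance-decaying correlation. The founder pool is large (100)
because a small pool adds founder-sampling drift that distorts observed
allele frequencies away from the generating ones. The default
c = 2×10⁻⁵/bp places the empirical r² = 0.1 crossing near 10 kb at the
default marker density; the decay scale in this engine is a property of
(c, founder correlation) jointly, not a coalescent ρ, so the fitted
Hill–Weir ρ̂ is a descriptive summary rather than an estimate of c.

**Trials.** Plot yield = μ + gᵢ + Eₑ + GEᵢₑ + f(row, col) + rowᵣ + col꜀ + ε.
The smooth surface f is a random low-frequency cosine mixture scaled to sd
`spatial_amplitude` (default 40 g·m⁻², against a genetic sd of 80 g·m⁻²
and grand mean 900 g·m⁻²); row/column effects have sd 15 g·m⁻²;
environment main effects sd 50 g·m⁻². GxE variance is
`ge_variance_ratio`·σ²_g (default 0.5). The residual variance is set from
the plot-level heritability target: h² = σ²_g/(σ²_g + σ²_ge + σ²_e), with
default h² = 0.45 — note this is *plot-level*; the entry-mean heritability
of a 2-replicate environment is correspondingly higher (~0.8), which is
the quantity the trial-analysis H² estimates. Layout is a resolvable
lattice: replicates occupy contiguous row bands, each field row within a
replicate is an incomplete block (a √n × √n lattice for the 289-line
default on a 34 × 17 grid).

**What the generator does not emulate.** Depth-dependent missingness and
genotype error, selfing/outcrossing structure, pedigree relatedness beyond
the founder pool, linked selection, multi-allelic sites, and any
sequence-level detail (reads, restriction sites). Passing tests therefore
demonstrate correctness of the *algorithms* under a clean additive world
with idealized uniform missingness — not robustness to depth artifacts or
model misspecification in real GBS data.

## Genotype QC

Filters run in the order biallelic → marker call rate ≥ 0.7 → accession
missingness ≤ 0.3 → MAF > 0.05, with MAF recomputed on the retained
accessions so frequencies are not distorted by dropped samples. The MAF
rule is strictly greater-than (a marker at exactly 0.05 is removed); the
sample rule removes strictly-greater-than 30% missing. Mean imputation
replaces each missing call with the marker's mean observed dosage, which
preserves allele frequencies exactly and is the standard preparation for
PCA on dosage data. Dosages are polarized to the minor allele; heterozygotes
are 1 regardless of phase, treating hexaploid lines as functionally diploid
at each biallelic GBS locus. "Coverage" is interpreted as per-marker call
rate across accessions — the only interpretation implementable from a
GT-only VCF.

## LD analysis

r² is the squared Pearson correlation of dosage vectors over accessions
observed at both markers (composite LD): deterministic, phase-free and
standard for unphased diploid data. Significance is the asymptotic
χ² = n·r² test on 1 df with strict p < α. All intra-chromosomal pairs
within 50 kb are used (a physical-distance window, not a marker-count
window). The decay summary reports (a) the left edge of the first
non-empty 500-bp bin whose mean r² falls below 0.1, and (b) the crossing
point of the fitted Hill–Weir curve, with ρ̂ minimizing the sum of squared
deviations over pairs. ρ is searched on a 40-point log grid over
[10⁻⁸, 1] per bp with bounded scalar refinement; ties and flat objectives
resolve to the smallest ρ, and a flat objective (every candidate fits
essentially perfectly, as happens when all pairs sit at the zero-distance
expectation) is flagged and returns the lower search bound. The sample-size
adjustment n defaults to the number of accessions; it is exposed as a
parameter because the same closed form is sometimes quoted with effective
population size instead.

## Population structure

PCA is a singular value decomposition of the column-centered (optionally
standardized) dosage matrix; eigenvalues are the covariance spectrum and
variance proportions are taken against total column variance.
Hierarchical clustering is Ward-D2 on Euclidean distances. k-means runs on
the leading PCs capturing 95% of variance (the same retention rule DAPC
uses), best of 20 k-means++ starts per k, and k is selected by
BIC(k) = n·ln(WSS_k/n) + k·ln(n). This BIC is dimensionality-sensitive: in
low dimension the n·ln(WSS/n) term rewards splitting pure noise, but at
panel-like retention (hundreds of PCs for ~300 accessions) the k·ln(n)
penalty dominates and structure-free data selects k = 1. DAPC is a linear
discriminant analysis on the retained PC scores with Gaussian
shared-covariance posteriors; marker loadings per discriminant axis are
the PCA eigenvectors composed with the discriminant coefficients, so they
live on the original dosage scale. Winter/spring growth-habit labels are
reported in cluster composition tables but never enter the clustering.

## Field-trial analysis

The lattice model is y = μ + replicate (fixed) + block-within-replicate
(random) + genotype + ε. The spatial model adds a tensor-product cubic
B-spline surface with second-order difference penalties in both
directions, plus independent random row and column effects. The penalty
P = D′D ⊗ I + I ⊗ D′D is eigen-reparametrized: its 4-dimensional null
space (bilinear in row and column) joins the fixed effects, and the
penalized remainder becomes a single isotropic random component whose
variance is the smoothing parameter. This is the written mixed-model form
of P-spline spatial adjustment; it does not reproduce any particular
package's PS-ANOVA decomposition, and the isotropic (single-variance)
spline is a deliberate simplification of anisotropic two-parameter
smoothing. Default knot spacing is one knot per 2 grid units, at least 4
per dimension. A practical consequence of isotropic smoothing is that very
high-frequency field trends (period ≲ 4 plots) are only partially
absorbed; recovery is strong for trends that are smooth at the block scale.

Variance components come from Schall's iterative REML on Henderson's
mixed-model equations: each σ²ⱼ updates as ûⱼ′ûⱼ over its effective
dimension, σ²_e from the residual sum of squares over residual df, to
relative tolerance 10⁻⁶ with a cap of 2000 iterations (convergence is
geometric but can need several hundred iterations when a small row/column
component creeps toward zero; each iteration is milliseconds). Components
are floored at 10⁻¹⁰·var(y) to keep the equations well-posed; a component
at the floor reads as zero. Convergence is judged against a variance scale
(10⁻⁴·var(y)) rather than each component's own magnitude, so a component
rattling at the floor cannot stall termination. Adjusted genotype means
come from a companion genotype-fixed generalized least squares pass at the
estimated variance components (genotype random for variance estimation,
fixed for means — the standard two-pass convention). Single-replicate
trials are degenerate and return raw means with a warning.

Efficiency of spatial over lattice is 100·(σ²_e,lat − σ²_e,sp)/σ²_e,lat —
the residual-variance reduction, which is scale-invariant. Heritability is
the entry-mean broad-sense formula H² = σ²_g/(σ²_g + σ²_e/r) with r the
environment's replicate count; within a single environment GxE is
inseparable from the genotypic effect, so the estimate targets the
env-specific genetic variance. Stage-2 combination fits the two-way model
(genotype fixed, environment random, GxE confounded with residual) on
unweighted stage-1 adjusted means; PEBVs are the genotype BLUEs.

## Genomic prediction

All three models are the single-kernel mixed model y = 1μ + Zu + ε,
u ~ N(0, σ²_u K), solved by one eigendecomposition of the kernel projected
onto the complement of the fixed-effect column space, followed by a 1-D
REML search in λ = σ²_e/σ²_u: a 50-point log grid spanning ten orders of
magnitude scaled by the kernel's mean diagonal, then bounded refinement to
xatol 10⁻⁸ in log λ. Scaling the grid by the kernel mean diagonal makes
the search invariant to kernel rescaling, which is what guarantees RRBLUP
(Z = W, K = I over markers) and GBLUP (K = WW′/2Σp(1−p), VanRaden method
1) produce identical GEBVs rather than merely similar ones. The Gaussian
kernel uses Euclidean dosage distances divided by their mean, with the
bandwidth θ profiled over 20 log-spaced points in [0.1, 5] by restricted
likelihood (ties to the smallest θ). Out-of-sample GEBVs use the
conditional-mean extension K_test,train K_train,train⁻¹ û with the training
kernel inverted through its eigendecomposition (eigenvalue floor 10⁻⁸).
Fixed effects are an intercept only in the prediction pathway.

Cross-validation samples training accessions and markers uniformly without
replacement; the validation set is the full complement. Per-iteration RNG
streams derive from (master seed, grid cell, iteration), so the grid is
bit-reproducible regardless of evaluation order and of which cells are
requested. The default experiment follows the two-axis design: training
size varied at the largest marker count, marker density varied at training
size 200; full crossing is a flag. Desk default is 100 iterations per cell
(study-scale 1000 by flag). Accuracy is the per-iteration Pearson
correlation averaged over iterations; iterations with undefined
correlation are excluded and counted.

## Pipeline

Stage order is simulate|load → qc → {ld, structure} → pheno → gs. A master
seed spawns per-stage seeds through SHA-256, so stages never share RNG
state and enabling/disabling one stage does not shift another's stream.
Every artifact is hashed (SHA-256) into `manifest.json`; integer-valued
artifacts are machine-portable, floating-point artifacts are stable
per-platform.

## Known limitations

- Mean imputation ignores LD; no genotype-likelihood or depth-aware
  handling.
- The spatial model has no autoregressive residual option (AR1×AR1) and a
  single isotropic smoothing parameter.
- REML standard errors of variance components are not reported; the
  Monte-Carlo tests quantify estimator spread instead.
- The Hill–Weir fit summarizes decay; it is not a demographic inference.
- Prediction accuracy on the synthetic panel depends on the generator's LD
  and QTL architecture; it validates engine behavior (ordering,
  monotonicity, limits), not absolute accuracy values for any real panel.
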