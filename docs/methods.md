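# Methods

`shuttlegp` analyses early-generation progeny-testing data from a two-site
rice recurrent-selection programme and evaluates genomic-prediction
calibration strategies on such data. This note records the models, the
numerical choices, what the synthetic-data generator does and does not
emulate, and the design decisions taken where more than one reasonable
option existed.

## Mixed models

Plot-level phenotypes are analysed with two kernel mixed models fitted by
REML.

**Single-site model.** For one site x year trial,

    Y_ijk = mu + r_i + b(r)_ij + g_k + e_ijk

with fixed intercept and replicate effect, random block-within-replicate
`b ~ N(0, I s2_b)`, random genotype `g ~ N(0, M s2_g)` for a genomic
kernel `M` (or the identity for purely phenotypic BLUPs), and i.i.d.
residual. When every replicate holds a single block the block term is
completely confounded with the fixed replicate effect and is dropped.

**Two-site model.** For the two sites of one year,

    Y_ijkl = mu + s_i + rs_ij + b(rs)_ijk + g_l + gs_il + e_ijkl

adding a fixed site effect and replicate-within-site, a genotype-by-site
interaction with a separate variance per site
(`gs ~ N(0, blockdiag(M_a s2_gs.a, M_b s2_gs.b))`), and site-specific
residual variances (the residual covariance is the Kronecker product of
an identity with the per-site variance pair). Fixed effects use the
reference-level constraint (first level dropped), recorded in the
parameter names, so `mu` is the mean of the reference cell.

**Kernels.** GBLUP uses the linear kernel `M = X X' / N` on genotypes
coded -1/0/1 (proportional to the common genomic relationship matrix); a
single shared `M` serves the main and interaction terms. RKHS uses the
Gaussian kernel `K(x_m, x_n) = exp(-h ||x_m - x_n||^2)` with three
structures: one kernel from the pooled data (`M0`, main effect) and one
per site (interaction terms), each with its own bandwidth. Kernels are
symmetrised, checked for positive semi-definiteness to `1e-8 x trace`,
and ridged by `1e-8 x mean(diag)` before inversion.

**Bandwidth estimation.** The bandwidth `h` maximises
`log p(y | K_h) + log Gamma(h; shape 3, scale 1.5)` over a 50-point
log-spaced grid, where `p(y | K_h)` is the restricted likelihood of
`y = 1 mu + u + e`, `u ~ N(0, K_h s2_u)`, profiled over both variances
through an eigendecomposition; ties break to the smaller `h`. `y` is the
vector of BLUP-adjusted phenotypes, and during cross-validation the
bandwidths are re-estimated each cycle from the training set only. The
bandwidth acts on median-scaled squared distances,
`K = exp(-h d2 / median(d2))`, with the grid spanning `[1e-3, 1e2]`: a
gamma prior with mode 3 is only meaningful on a scale where `h ~ O(1)`
regardless of marker count — on raw squared distances (median in the
hundreds for ~1e3 markers) the prior would dominate the likelihood and
pin `h` at the grid edge. Degenerate inputs (constant phenotypes, or
identical genotypes) return the prior mode `(shape-1) x scale = 3.0` with
a warning.

## REML engine

Both models reduce to `y = X b + sum_i Z_i u_i + e` with
`u_i ~ N(0, K_i s2_i)` and grouped residual variances, estimated on
Henderson's mixed-model equations. Each iteration factorises
`C = W' R^-1 W + diag(0, K_i^-1/s2_i)` (one Cholesky per iteration; the
per-group Gram matrices `W' D_s W` are precomputed once per fit, so no
per-iteration sparse work). Updates are expectation-maximisation (EM) for
a short warm-up (3 iterations; 1 when warm-started), then
average-information (AI) steps with two safeguards: step-halving into the
parameter space, and fall-back to the guaranteed-ascent EM update
whenever an AI proposal would decrease the restricted likelihood. An
Aitken-accelerated pure-EM scheme was considered and dropped — the AI
switch supersedes it.

Variance components are floored rather than allowed to go negative, so
boundary estimates are reported as ~0 (as printed variance tables report
"<0.001"): genetic and block components at `1e-10 x var(y)`, residual
variances at `1e-8 x var(y)` because `R^-1` enters the equations directly
and smaller values destroy the Cholesky conditioning. Components whose EM
path decays geometrically toward the boundary (the signature of a
zero-variance component, which would otherwise never meet a relative
tolerance) are pinned at the floor once they fall below `1e-5 x var(y)`
with a negative score; a pinned component is released the moment its
score turns positive. Convergence requires relative change `< 1e-8` in
every free component and log-likelihood change `< 1e-9` (defaults; the
cross-validation driver uses `1e-6`/`1e-8` with warm starts, which
changes third-decimal PA values by less than the Monte-Carlo noise), with
at most 500 iterations. The solver contains no randomness; fits are
bit-reproducible and invariant to record order.

Standard errors: fixed effects from the corresponding block of `C^-1`;
variance components (when requested) from the inverse AI matrix at the
last AI step — the usual asymptotic approximation, unreliable for
components at the boundary.

**Predictions.** GEBVs are `mu + g_hat` (single-site) or
`mu + s_target + g_hat (+ gs_hat,target)` (two-site). The printed
two-site prediction formula in the source study omits the interaction
BLUP, while its discussion reasons about the relative size of `g` and
`gs` in a way that implies the interaction participates; both variants
are implemented and the default includes the interaction
(`include_interaction=True`), because the interaction BLUP for a
validation genotype is informed by its other-site phenotype and
measurably raises predictive ability whenever the interaction variance is
substantial (asserted in the test suite). Genotypes without phenotypes
are predicted through the kernel covariances.

## Heritability

Trial-level repeatability and the across-site broad-sense heritability
are

    H2_trial  = s2_g / (s2_g + s2_e / NR)
    H2_global = s2_g / (s2_g + (s2_gs.a + s2_gs.b)/NE + (s2_e.a + s2_e.b)/NR)

with `NR` the harmonic-mean number of plots per genotype and `NE` the
harmonic-mean number of sites per genotype, always computed from the
records actually fitted (the balanced two-site, three-replicate design
gives NR = 6, NE = 2, which reproduces the published heritabilities from
the published variance components — the package's check that the NR/NE
convention is right). Comparisons against printed tables use half-up
rounding and a tolerance of one unit in the last printed decimal, since
the printed components are themselves rounded (one published cell is
reproduced at 0.0051 rather than 0.005 for exactly this reason).

## Cross-validation schemes

Four calibration scenarios predict genotype merit at a target site; the
validation set is fixed at 100 genotypes so scheme comparisons reflect
only training-set composition.

| scheme | target-site training | other-site training | validation drawn from |
|--------|----------------------|---------------------|----------------------|
| SIN    | s genotypes          | —                   | the rest             |
| BAL1   | s genotypes          | the same s          | the rest             |
| BAL2   | s genotypes          | s genotypes, floor(s/2) shared | the rest  |
| IMB    | s genotypes          | whole population    | target-unphenotyped  |

BAL2 interprets "50% overlap" per site: `s` genotypes observed at each
site with `floor(s/2)` in common, hence `2s - floor(s/2)` distinct
genotypes in calibration — the only reading that leaves exactly 34
validation-eligible genotypes at `s = 200` on a 334-genotype population
(the validation set then shrinks to the remainder, with a warning). Odd
`s` rounds the overlap down.

Each cell runs 100 seeded partitions. Predictive ability is the Pearson
correlation between GEBVs and the reference — BLUP-adjusted phenotypes
(`mu + g_hat`) from the single-site identity-kernel model on the complete
target-site data, computed once before any masking. The master seed
spawns one stream per iteration index, shared across schemes, so scheme
contrasts are paired. Iterations whose REML fit does not converge are
flagged, excluded from summaries and never re-sampled (re-sampling would
bias toward easy partitions); their count is reported. Fits are
warm-started from the previous iteration's components within a cell, and
kernels are restricted to the genotypes involved in the iteration, which
is what keeps the 100-iteration protocol affordable.

## Eta-squared attribution

A fixed-effects OLS ANOVA is fitted to per-iteration PA with the
calibration factors (year, GP method, scheme, training-set size — size
treated as categorical) and their interactions up to a configurable order
(default all two-way plus the three-way). `Eta2 = SSq_effect/SSq_total`
where the total includes the residual, so shares sum to one;
`R2 = 1 - SSq_resid/SSq_total`. Sums of squares are sequential (type I)
in the declared factor order; the CV driver produces balanced grids in
which sequential and marginal sums of squares coincide, and the
implementation cross-checks this on balanced inputs. Empty factor cells
abort with the offending cell named.

## Synthetic data generator

The generator produces the exact generative mirror of the two-site model,
plus genotypes with the population features the analysis relies on.

*Genotypes.* Per-marker allele frequencies are drawn from a Beta
distribution (default Beta(1, 3): a spectrum in which rare alleles are
not depleted, as expected for an unselected synthetic population). Each
individual carries two haplotype chains per chromosome; adjacent markers
follow a first-order Markov dependence with correlation `ld_rho`
(default 0.6, slow LD decay). Heterozygotes arise naturally at rate
2p(1-p) and are thinned marker-wise i.i.d. by collapsing a call to one
donor haplotype chosen per individual — the same move selfing makes, so
allele frequencies and LD are preserved — until the expected 0-code
fraction matches `residual_heterozygosity` (default 0.25, slightly below
the panmictic expectation of ~0.30 under Beta(1, 3): partially fixed
early-generation material). Monomorphic markers are retained and flagged;
they carry no signal but count toward `N` in the linear kernel, as they
would in a real filtered panel.

*Genotypic effects.* Site effects are marker-effect sums `u_site =
X beta_site`. For `r_g >= 0` within the representable range the marker
effects decompose exactly as shared + site-specific, so `u_site = g +
gs_site` with kernel-scale variances `s2_g = r_g sqrt(V_a V_b)` and
`s2_gs.site = V_site - s2_g` known in closed form — the recorded truth
for recovery tests. The per-site variance `V_site` follows analytically
from `target_h2_trial`, the site residual variance and the replicate
count, converted to the kernel scale by the mean marker variance (the
expected between-genotype variance of `X beta` per unit kernel variance).
Effects are built from column-centred markers so the population mean is
not randomly displaced by the uncentred marker sums — statistically
equivalent for REML, whose error contrasts are orthogonal to the
intercept, but it keeps simulated trait means and coefficients of
variation at their configured values. No empirical rescaling of realised
effect vectors is applied, so the
kernel-scale truth is exact while realised variances fluctuate with the
drawn markers and effects, as they would across real populations. When
`r_g` is negative or exceeds what a nonnegative decomposition allows
(very unequal site variances), a correlation-exact bivariate construction
is used instead and the recorded truth components are the boundary
projection, with a warning.

*Trials.* One plot per genotype x replicate x site x year:
`Y = site mean (+ year shift) + replicate shift + block effect + u_site +
residual`, blocks re-randomised per site x year x replicate into
`n_blocks` incomplete blocks of near-equal size (default 16 blocks x 3
replicates). Incomplete blocks enter only through the random block
effect, exactly as the analysis models treat them; no alpha-design
optimality machinery is emulated. A second year redraws blocks, replicate
shifts and residuals with the same genotypic effects and an additive
site-wide year shift — the generation effect is fixed at zero, matching
the temporal-check finding that year, not generation, drives the
differences between the two evaluation seasons.

*Defaults.* The default configuration mirrors the experimental design:
334 genotypes, 992 markers (scalable to the full 9928; kernels built from
992 markers are nearly identical given the strong LD) on 12 chromosomes,
two sites with flowering-like means (88.2 / 82.2), per-site trial
repeatabilities 0.69 / 0.96 spanning the published range, residual
variances 5.6 / 4.9, block variance 0.9, between-site genetic correlation
0.55, 3 replicates x 16 blocks. Replicate shifts are drawn with variance
1.0 (same order as the block variance; they are fixed effects downstream,
so their scale only affects realism, not inference).

*What passing tests do and do not show.* The generator reproduces the
statistical skeleton the models assume — the design factors, variance
structure, LD and allele-frequency spectrum. It does not emulate spatial
field trends beyond blocks, trait-specific genetic architectures (effects
are infinitesimal Gaussian), genotype-by-year interaction, shared
machinery/assay error, or selection history in the marker data. Recovery
and cross-validation results on synthetic data therefore validate the
estimation and protocol machinery, and reproduce the qualitative
sparse-testing contrasts; they do not certify predictive-ability levels
on real field data.

## Problem sizes used in the test suite

The expensive checks run at the experimental scale (334 genotypes, 2
sites, 3 replicates): parameter recovery uses 30 simulation replicates of
the two-site and single-site fits; the sparse-testing contrast runs the
full 100-iteration protocol for SIN and IMB at s in {25, 50, 100, 200}
with between-site correlation 0.6 and per-site repeatability 0.8, plus
the weak-correlation contrast (r_g = 0.15) at s = 50 — one mid-range size
is sufficient to exhibit the vanishing sparse-testing advantage. Unit
tests use smaller populations (40-150 genotypes) where the property under
test does not depend on scale.

## Known limitations

- The two-site model is exactly two sites (the residual grouping
  generalises, but the interaction structure and heritability formulas
  are written for the paired-site design).
- Variance-component standard errors come from the AI matrix and are not
  trustworthy at the boundary; no delta-method standard error for H2 is
  provided.
- Marker imputation is by marker mean only; no LD-aware imputation.
- REML is a local optimiser; with the EM warm-up it has not been observed
  to miss the optimum on tested instances (tiny cases are verified
  against grid search and a direct-likelihood optimiser), but multimodal
  surfaces cannot be ruled out in general.
- The Eta2 ANOVA assumes the balanced grids the CV driver produces;
  heavily unbalanced tables make type-I shares order-dependent (the
  factor order is recorded in the output for that reason).
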