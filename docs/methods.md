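# Methods

## Scope and data model

The package predicts genomic estimated breeding values (GEBVs) for
continuous, pre-corrected phenotypes from biallelic SNP genotypes coded
0/1/2 (count of the second allele). Fixed-effect correction (contemporary
groups, covariates) is assumed to have happened upstream; the phenotype fed
in is already the "corrected phenotype" that genomic analyses regress on.

## Marker quality control

Markers are filtered on three statistics computed from non-missing
genotypes: minor allele frequency, call rate, and a 1-degree-of-freedom
chi-square goodness-of-fit test of genotype counts against Hardy–Weinberg
expectations (no continuity correction, no exact test — the standard
chip-QC choice, and desk-checkable). Thresholds are strict inequalities
(`maf > t` etc.). Two presets mirror common beef-chip
(MAF>0.05, CR>0.95, HWE p>1e-5) and dairy-chip (MAF>0.01, CR>0.95,
HWE p>1e-4) pipelines. Residual missingness after QC is mean-imputed
(missing → 2p̂_j), which preserves allele frequencies exactly; the choice
is documented because real post-QC panels are nearly complete and the GRM
requires completeness.

## Genomic relationship matrix

VanRaden method 1: G = MM'/Σ2p_jq_j with in-sample allele frequencies.
Frequencies are computed from the full matrix passed in (train and test
individuals together) because the learners consume whole-population G rows;
the mild train/test frequency sharing this implies is a property of the
protocol being emulated, not a leak of phenotypes. With in-sample
frequencies every row of G sums to zero and G is PSD up to round-off; both
are asserted in tests. Alternative scalings (per-marker standardization,
dominance G) are out of scope.

## Base learners and features

All machine-learning methods use rows of G as features: training
individuals get G[train, train], test individuals G[test, train]. This
keeps the design n×n rather than n×m, trading a little single-model
accuracy for a large reduction in dimensionality and overfitting risk.
SVR (ε-insensitive loss, Gaussian kernel), KRR (closed-form dual) and ENET
(coordinate descent) are delegated to scikit-learn behind a uniform
fit/predict surface; tests verify each against an independent oracle
(a scipy QP solve of the SVR dual, the explicit (K+λI)⁻¹ formula, and the
closed-form ridge solution). The ENET penalty follows sklearn's
parameterization ((1/2n)·RSS + αρ‖w‖₁ + α(1−ρ)/2‖w‖²).

Hyperparameters are chosen by grid search maximizing mean inner 5-fold
Pearson accuracy; ties break to the first lattice point, failed fits score
−∞. Default lattices: C ∈ {0.1,1,10,100}, ε ∈ {0.01,0.1,0.5},
γ ∈ {1/n, 1/2n, 10/n}; λ ∈ {1e-3,1e-2,0.1,1,10} × {linear, gaussian};
ENET α log-spaced 1e-4…1, ρ ∈ {0.1,0.5,0.9}. These are package defaults
(no canonical values exist) and everything is overridable.

## Stacking

Metadata are generated by a 5-fold split of the training set: learner j is
fit on train∖f and predicts fold f, so metadata row i never depends on
y_i (the leakage contract, enforced by a mock-based test). The meta-learner
is exact OLS with intercept (SVD least squares; minimum-norm with a warning
if the metadata are rank deficient). Test-set metadata come from base
learners refit on the full training set; a fold-model-averaging variant and
an intercept-free meta-fit are available behind flags. When a grid is
attached, hyperparameters are re-searched inside each metadata fold by
default (strictly leak-free); `tune_once` searches once on the whole
training portion and reuses the winner — cheaper, and the held-out
metadata fold then influences tuning, though never the outer test fold.

With a single base learner the ensemble is an affine map of that learner,
so its Pearson accuracy is identical — a structural guarantee asserted to
1e-12 in tests.

## GBLUP / REML

Exact REML for the one-random-effect model via eigendecomposition of G:
with δ = σe²/σg², the restricted likelihood profiles analytically over μ
and σg², leaving a bounded 1-D minimization over log10 δ ∈ [−8, 8]
(optima within 0.5 of the bounds are flagged `boundary`). Prediction uses
ĝ_test = G[test,train](G[train,train]+δI)⁻¹(y−μ̂1) with the GLS mean μ̂
and one jittered retry on singular systems. GBLUP is dual to KRR with the
precomputed kernel K = G at λ = δ fit on y−μ̂; this cross-module identity
is asserted to 1e-6 on every build.

## BayesB

Model: y = 1μ + Σ m_jα_jδ_j + e with P(δ_j=0) = π,
α_j|δ_j=1 ~ N(0, σ²_αj), σ²_αj ~ scaled-inv-χ²(ν, S),
σe² ~ scaled-inv-χ²(ν_e, S_e). The sampler is Gibbs with the inclusion
indicator drawn from the likelihood ratio with α_j integrated out
(marginalized indicators mix far better than Metropolis-within-Gibbs when
effects are near zero), then α_j from its Gaussian full conditional;
excluded markers redraw σ²_αj from the prior, which keeps the chain on the
joint posterior. The per-marker sweep is numba-compiled; chains are
deterministic given the seed.

Defaults: π=0.95, 10 000 iterations, 2 000 burn-in, thinning 5, ν=4.2,
ν_e=4. S is set so the prior mean effect variance equals
var(y)·h²_prior/((1−π)·Σ2p_jq_j) with h²_prior=0.5 — i.e. included
markers jointly explain about half the phenotypic variance a priori; S_e
targets a prior mean residual variance of var(y)/2. π is a judgment call
in practice, so every prior constant is config-exposed. A
`fixed_effect_var` switch freezes σ²_αj at a common value; with π=0 this
reduces the model to marker-effect ridge regression, whose GEBVs are
checked against GBLUP (r > 0.98) as a degeneracy test.

## Cross-validation

k-fold (default 20) with balanced uniformly random folds. The entire
pipeline — tuning, metadata generation, refits, REML — runs inside the
training side of each fold. Accuracy is the sample Pearson correlation of
held-out phenotypes with predictions; folds with constant predictions are
recorded as missing, warned about, and excluded from the mean rather than
zero-filled (zero-filling would bias comparisons downward for shrinkage
methods). Reported ± is the sd across folds; a standard-error accessor is
also provided since the field's tables are ambiguous about which they
print. Method comparisons draw one fold plan and share it, making mean
differences paired. Fold sizes below 3 (including leave-one-out) are
rejected because fold-level Pearson r is then undefined or degenerate.

## Simulator

Unlinked biallelic sites: marker j draws p_j ~ Uniform(maf window), then
genotypes i.i.d. Binomial(2, p_j). No LD, no missingness, no genotyping
error — so a green simulation test establishes correctness of the
estimators under the stated sampling model, not robustness to linkage or
ascertainment structure in real panels. Phenotypes are y = g + e with
g built from centered genotypes at randomly drawn polymorphic QTL and
e ~ N(0, var(g)(1−h²)/h²), which makes corr(g,y) = √h² in expectation
(the simulator's calibration test). Effects are Normal (not gamma); the
three architectures are parameterized as:

- **major_gene** — 1 QTL scaled to carry `major_gene_var_share` (default
  0.5) of the genetic variance plus 100 small effects;
- **few_moderate** — 10 moderate loci jointly scaled to half the genetic
  variance plus 490 small effects;
- **polygenic** — 500 i.i.d. small effects.

The share constants are package choices; the field describes such
architectures qualitatively and no canonical quantitative definition of
"major"/"moderate"/"small" exists. Phenotypes can be standardized to
mean 0 / sd 1 (genetic values and effects are rescaled consistently).
Simulation-based tests standardize, because SVR's (C, ε) are
scale-sensitive and real dairy reference panels circulate standardized.

## Known limitations

- **Exact-OLS stacking in weak-signal regimes.** With three strongly
  collinear base learners and low predictive signal (r ≈ 0.15, as in the
  n=600, m=2000 unlinked-marker worlds used for acceptance), the variance
  of the OLS meta-weights costs more than learner complementarity gains:
  measured margins versus the best base learner were −0.002 at r ≈ 0.45–0.55
  but −0.01 to −0.03 at r ≈ 0.15, with the worst case on the few-moderate
  architecture where the three learners tie. The ensemble-never-worse
  property therefore holds in strong-signal regimes but is not guaranteed
  near the noise floor; the acceptance test records this honestly rather
  than relaxing its tolerance. Remedies (non-negative or shrunken meta
  weights) would leave the exact-OLS meta-learner this package defines.
- REML at n ≲ 400 with a flat G spectrum (m ≫ n unlinked markers) has a
  wide sampling distribution for ĥ² (observed spread ±0.2); heritability
  estimates at that scale should be treated as noisy.
- BayesB chain settings are defaults, not convergence guarantees; the
  two-seed GEBV-correlation check (r > 0.95) is a reproducibility test,
  not a formal diagnostic.
- VCF input handles diploid GT fields of biallelic records only;
  multi-allelic sites are rejected explicitly rather than split.
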