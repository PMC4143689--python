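# Methods

## Model and procedure

The package tests, SNP by SNP, whether a (SNP, environment) pair carries
association with a quantitative trait beyond both variables' marginal
effects. The procedure has two steps.

**Step 1: stepwise main-effect removal by projection pursuit
regression.** The trait is modelled as an additive combination of ridge
functions, `y = Σₘ S_αₘ(αₘ·x) + ε`, with each `S` a smooth 1-D function
of a linear projection of the predictors. Fitting is the classic
alternating scheme: refit the scatterplot smoother on the current
projection, then update the direction by a Gauss–Newton step on the
linearized smoother, until the relative change in residual sum of
squares falls below 1e-8 (at most 50 iterations; non-convergence returns
the best iterate with a flag). Residualization is stepwise and marginal:
first the environment's effect is removed from the trait, then the SNP's
effect from that residual — no joint term is ever fitted, so interaction
structure cannot be absorbed.

In the single-SNP pipeline each step has one predictor, so the direction
is fixed and fitting reduces to 1-D smoothing. One ridge term per step
(`M=1`) is the default; multivariate predictors and larger `M` are
supported for general use.

**Step 2: partition-based influence measure.** Samples are partitioned
by the joint levels of the discrete variables under test (genotype 0/1/2
× dichotomized environment, at most 6 non-empty cells; genotype alone,
at most 3). On the Step-1 residual the influence measure is

    I = n⁻¹ Σᵢ nᵢ² (res̄ᵢ − res̄)² ,

with empty cells contributing zero. The response is standardized to unit
variance by default, making I scale-free; under the null the expectation
for a partition of c comparably sized cells is 1 − Σ(nᵢ/n)² ≈ 1 − 1/c,
approaching the reference level 1 as the partition grows. An unstandardized
mode is kept for exactness checks (I then scales as c² under y ↦ c·y).

## Smoothers

* **Level means** (discrete predictors, ≤ `max_levels` = 4 distinct
  values): exact one-way ANOVA fit; deterministic, annihilates the
  predictor's main effect exactly.
* **LOWESS** (continuous predictors, e.g. age): statsmodels lowess with
  the span chosen from {0.7, 0.5, 0.35, 0.2} by 5-fold cross-validation,
  folds interleaved along the sorted predictor; ties prefer the stiffer
  span. Robustness iterations are off so fitting stays deterministic;
  prediction interpolates the fitted curve and clamps outside the
  training range.

## Exact margin annihilation

Removing the environment's level means and then the genotype's leaves a
small environment margin whenever the two factors are unbalanced. After
Step 2 the residual is therefore polished by alternating level-mean
centering (environment group, genotype level) to convergence — the
projection orthogonal to both sets of level indicators. The scanned
statistic is thus computed on a residual whose mean within every
environment group and every genotype level is zero to machine precision,
which is the operational meaning of "pure" here. For a continuous
environment, Step 1 removes the smooth age effect and the polish zeroes
the dichotomized-age margins used by the partition.

## Permutation significance

The p-value of an observed I-score is `(1 + #{I_perm ≥ I_obs}) / (1 + B)`
over B shuffles of the response across samples, partition held fixed —
never exactly zero, ties counted conservatively. Two subtleties:

* **Margin removal inside the null.** A naive shuffle of the
  main-effect-free residual regains random margin variation that the
  observed statistic cannot have, which makes the test wildly
  conservative (empirical rejection ~0.005 at nominal 0.05). Every
  permuted vector is therefore passed through the same margin-removal
  projection as the observed residual (three alternating centering
  sweeps, a no-op on the already margin-free observed vector) before
  scoring. With this, empirical rejection at 0.05 on fully null cohorts
  is 0.04 (200 SNPs, B=2000), and score- and p-rankings agree in a
  signal-rich top tail (Spearman ρ ≈ 0.93 on the top 20).
* **Fixed fits vs refitting.** By default the Step-1 fits are held fixed
  across permutations; `refit_permutations` re-runs the full
  residualization inside every shuffle for exactness at roughly a
  thousandfold cost. Budgets of 10⁷ permutations stream through
  vectorized batches (`batch_size` = 20,000) in constant memory, with
  counter-derived per-SNP substreams so results do not depend on scan
  order.

## Dichotomization

Continuous environments are split by exact 1-D 2-means: every breakpoint
between consecutive distinct sorted values is evaluated in O(1) via
prefix sums and the within-cluster sum-of-squares minimizer is taken.
This is deterministic, optimal, and independent of initialization; the
reported cutoff is the largest value of the lower cluster, so the rule
"value > cutoff → 1" reproduces the split.

## Subgroup scans and overlap arithmetic

`scan_g_only` ranks SNPs by the genotype-only I-score within a sample
subgroup (e.g. the two halves of the age split; at least 20 samples
required) and reports the all-sample score alongside. Two subgroup scans
are compared by:

* the **first-overlap rank pair** — the joint rank frontier is scanned so
  the reported pair minimizes max(rank₁, rank₂) of a shared SNP (the
  convention is ours; a rank pair does not define a scan order by
  itself);
* the **FDR/expected-TP/hypergeometric chain** — the implied FDR of the
  k smallest of m permutation p-values is `q̂ = p_k·m/k` (the smallest q*
  satisfying the Benjamini–Hochberg inequality `p_k ≤ (k/m)q*`, capped at
  1), expected true positives are `round((1−FDR)·k)` with half away from
  zero (so 11.7 → 12 and 57.7 → 58), and the zero-overlap probability is
  the hypergeometric `C(T−t₁, t₂)/C(T, t₂)`, computed through log-gamma.
  The number of truly associated SNPs T is a user assumption, not
  estimated.

## Synthetic cohorts

The generator emulates the shape of a small unrelated blood-pressure
cohort. Defaults: 130 samples, 200 SNPs with per-SNP MAF uniform on
[0.05, 0.5] and Hardy–Weinberg genotypes; age from a two-component
normal mixture (means 44 and 67 years, sd 8, weight 0.58 on the younger
component) whose population two-means cutoff sits at ~55 years — the
same value as the generator's interaction/regime threshold, so the
estimated dichotomy is consistent with the generative one, as it is in a
real cohort where the cutoff is itself the clustering output; smoking
(prevalence 0.25) and medication (0.30) indicators; trait = 120 mmHg
baseline + 0.4 mmHg/yr age slope + 4 mmHg smoking − 3 mmHg medication +
genetic terms + N(0, 10 mmHg).

Genetic effect kinds:

* **main** — `β·g` added for everyone;
* **pure-interaction** — `β·(g − E[g])·(z − E[z])` with z the
  over-threshold age indicator and both expectations population ones, so
  the marginal association of g and of z vanish in expectation (finite
  samples show them only at sampling-noise scale, hence tolerance bands
  in tests);
* **regime-switch** — `β·g` applied only within one age regime,
  producing disjoint subgroup rankings.

The generator deliberately omits linkage disequilibrium, pedigree
structure, longitudinal measurements, and genotype missingness patterns
correlated with phenotype. Passing tests therefore demonstrate the
machinery's behaviour under idealized sampling, not robustness to the
correlation structure of real genotype panels.

## Study conditions used by the tests

The recovery study plants one pure-interaction SNP among 200 (130
samples) and asks for a top-5 I-score rank in ≥80% of 20 replicates.
Its effect size, β = 14 mmHg, was calibrated against a true-model oracle
(exact generative main-effect subtraction, true age split, same ranking
rule): oracle top-5 power is 0.78/0.88/0.90/0.95 at β = 10/11/12/14 on
calibration replicates disjoint from the test's. The two-step method
trails this oracle by ~10–15 points at this sample size — the price of
estimating the age cutoff from 130 samples — so the frozen β sits at the
top of that range; at it the method recovers the causal SNP in 95% of
the test replicates. Type-I calibration uses a fully null cohort (200
SNPs, B=2000). The regime-switch study uses ten older-active and ten
younger-active SNPs at β = 15 mmHg and checks disjoint top-10 lists plus
higher active-subgroup scores, on average, for causal SNPs — the
qualitative subgroup phenomenon, asserted as an average because per-SNP
comparisons at subgroup n ≈ 55 are noise-dominated.

Problem sizes throughout (n = 130–1000, 200 SNPs, B ≤ 2×10⁴ in tests)
are chosen so the full suite runs on a single CPU in minutes; the
method itself streams arbitrarily large permutation budgets.

## Numerical and degenerate-input conventions

* Zero-variance response: I-score 0 by convention (logged), permutation
  p-value 1; zero-variance trait residualizes to an all-zero residual.
* Monomorphic SNPs and SNPs with fewer than `min_cell_total` = 20 usable
  samples are flagged and skipped, never raised.
* Per-SNP missing genotypes are handled by pairwise deletion within each
  single-SNP test (Step 1 is refit on that SNP's complete samples); no
  imputation.
* Multi-allelic VCF records are rejected by default; an opt-in splits
  them into one pseudo-SNP per alternate allele.
* Cells may be empty (they contribute 0 to I); no merging rule is
  applied.
* Two-means requires ≥2 distinct values and no missing entries; ties on
  cross-validated smoother spans resolve to the stiffer span; direction
  updates keep orientation continuous (sign flips suppressed).

## Known limitations

* The fixed-fit permutation null is a conditional approximation; the
  exact refit mode exists but is costly at GWAS scale.
* The I-score's null scale depends on cell-size imbalance (1 − Σ(nᵢ/n)²),
  so raw scores are comparable across SNPs only approximately when MAFs
  differ strongly; permutation p-values account for this per SNP.
* FDR inversion assumes the permutation p-values are well calibrated and
  exchangeable across SNPs; no dependence correction is attempted.
* Family structure, dosage genotypes, covariate-adjusted joint models
  and G×G scans are out of scope.
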