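# Methods

This note documents the models and procedures `glrisk` implements, the
parameter choices that matter, what the synthetic cohort generator does
and does not emulate, and the numerical conventions.

## Data model and quality control

A cohort is three aligned tables: an n×p genotype matrix of minor-allele
counts {0, 1, 2} (NaN for missing calls), a covariate table, and a
right-censored outcome (follow-up in years, binary event). SNP QC removes
variants with a missing-call rate ≥ 2% or an exact Hardy–Weinberg test
p < 1e-4. The HWE test is the exact conditional test (the distribution of
the heterozygote count given the allele counts), not the χ² approximation:
it is well defined at small counts, and — like all discrete exact tests —
mildly super-uniform under the null (its p-values are stochastically
larger than uniform; the test suite checks validity, P(p ≤ α) ≤ α, rather
than exact uniformity).

Missing genotypes are excluded pairwise for HWE and allele-frequency
computation; for modelling, per-SNP mode imputation is used, which at the
≤2% missingness tolerated by QC preserves the marginal genotype
distribution. Covariate missingness is handled complete-case by default.

Obesity strata use the conventional cutoffs with their conventional
boundary sides — BMI <30 vs ≥30 kg/m², waist ≤88 vs >88 cm,
waist-to-hip ratio ≤0.85 vs >0.85, exercise ≥10 vs <10 MET-h/week,
saturated-fat intake <9 vs ≥9% of calories. The mixed ≤/< conventions are
stored per stratum in `StratumSpec` so tests can pin them.

## Random survival forest

Each tree is grown on a bootstrap sample drawn with replacement (n draws
from n subjects), so on average 1 − e⁻¹ ≈ 63.2% of subjects are in-bag
and ≈36.8% out-of-bag (OOB). Splits maximize the standardized two-sample
log-rank statistic over `mtry = ⌈√p⌉` candidate variables and up to
`nsplit = 10` random candidate cut points per variable (on nodes of ≤256
subjects all observed cut points are scanned). Tied event times use
Breslow-style d/Y increments. A split is admissible only if both
daughters retain at least `min_events = 3` events; a node with no
admissible split is terminal and stores the Nelson–Aalen cumulative
hazard of its in-bag members, evaluated on the cohort's event-time grid.

The ensemble cumulative hazard is the average of terminal-node estimators
over trees; predicted cumulative incidence is 1 − exp(−CHF); the risk
score for concordance ("ensemble mortality") is the CHF summed over the
grid — the standard RSF convention. The OOB c-index is Harrell's
concordance of OOB ensemble mortality with the outcome, with the usual
comparable-pair convention (an event at t is comparable with anyone
followed beyond t or censored at t; tied event times are not comparable;
tied scores count ½). `error = 1 − c` throughout.

Variable ranking:

* **Minimal depth** — per tree, the depth of the first node split on the
  variable (root = 0); variables unused in a tree contribute that tree's
  maximal depth + 1 (this keeps the ranking a total order; the choice
  only matters for variables rarely used at all). MD is averaged over
  trees.
* **Permutation VIMP** — baseline OOB concordance minus the OOB
  concordance after permuting the variable among each tree's OOB subjects,
  averaged over `vimp_reps = 5` permutations with a fixed per-variable
  sub-seed (so results do not depend on evaluation order). Only trees
  that actually split on the variable, and only subjects whose decision
  path traverses such a split, are re-evaluated — an exact optimization,
  not an approximation.
* **Nested error curve** — with variables ordered by MD, e_k is the OOB
  error of a fresh forest on the top k variables; e₀ = 0.5 by convention
  (a forest with no variables cannot order any pair). Drop errors
  d_k = e_{k−1} − e_k telescope exactly: 0.5 − e_k = Σ_{j≤k} d_j.

Defaults are `n_trees = 5000` (analysis scale); tests and the acceptance
script use 25–500 trees as noted below.

## Two-stage multimodal selection

Stage 1 fits a forest per variable group (SNPs alone, lifestyles alone)
and keeps variables with MD below the group mean **and** VIMP > 0 — a
deterministic, scale-free operationalization of "distinctly low MD and
high VIMP in agreement". Under all-noise input this rule admits roughly a
fifth to a quarter of variables (MD below the mean and positive VIMP are
each near-coin-flips for noise and only weakly coupled); it is a *screen*,
intentionally permissive, with false positives removed by stage 2.
Stage 2 fits one forest on all survivors, orders by MD, computes the
nested error curve, and keeps variables with drop error ≥ δ = 0.005.
δ was chosen as the value that separates materially contributing
variables from noise in the published example ranking bundled with the
package (it includes a drop of 0.0073 and excludes one of 0.0033); it is
configurable. Per-stratum runs abort below 50 events: forests and CV on
smaller subgroups overfit badly.

## GMDR

Subjects carry score residuals y − ŷ from a null logistic model of the
event on the adjustment covariates (GMDR's GLM formulation; martingale
residuals from a null Cox model are available where the time dimension
matters). For a candidate SNP combination, subjects are binned into the
3^k multilocus cells; a cell is high-risk when its summed score exceeds 0,
with ties assigned low-risk (conservative, deterministic) and cells empty
in training predicting low-risk at test time (the majority class under
rare events). Balanced accuracy treats score sign as truth; TBA is the
mean over 10 stratified CV folds (folds stratified by event status, fixed
by seed). CVC counts the folds in which a combination has the best
training balanced accuracy; the reported combination is the plurality
winner (ties: higher mean training BA, then lexicographic order).
Significance is a one-sided permutation test of TBA with the add-one
estimator p = (1 + #{perm ≥ obs}) / (n_perm + 1), default n_perm = 1000.
The best model overall is the highest-TBA model among those with full CVC
and p < 0.05; if none qualifies, full CVC takes precedence and the result
is flagged non-significant. The exhaustive search is capped at a pool of
25 SNPs (configurable) — beyond that, order-5 enumeration is
combinatorially infeasible and a deliberate error is raised.

## Risk profiles and Cox models

Risk genotypes are per-SNP genotype sets (carrier or homozygote codings);
risk behaviors are cutoff dichotomies — alcohol ≥ 18 g/day,
estrogen+progestin use ≥ 10 years, past oral-contraceptive use **< 5
years** (short use is the risk side), BMI ≥ 30 kg/m². The binary G
(all panel risk genotypes present, threshold configurable) and binary B
(any risk behavior; a 0/1/2-or-more coding is available) combine as
C = G + B ∈ {0, 1, 2}.

Hazard ratios come from Cox partial-likelihood fits — Efron tie handling
by default (better than Breslow at the event rates simulated; Breslow is
available through the statsmodels backend) — with Wald 95% CIs. Joint
tables report HRs per C level against the lowest level, overall and by
stratified refits within each level of a binary stratifier (e.g. alcohol
< 18 vs ≥ 18 g/day), with cell counts, one BH family per table, and a
Wald trend test on linearly coded C. Interaction is reported on both
scales: the multiplicative product-term HR, and the additive RERI =
HR₁₁ − HR₁₀ − HR₀₁ + 1 with a delta-method CI. Proportional hazards is
checked per covariate by the Pearson correlation ρ between scaled
Schoenfeld residuals and event-time rank, with residual-vs-time data
exported for plotting. Covariates under stratification or joint testing
are dropped from the adjustment set.

## Synthetic cohort generator

The generator's defaults describe a postmenopausal US cohort at study
scale: n = 10,179, 156 SNPs with MAFs drawn once from Uniform(0.05, 0.5),
and covariate marginals matching the typical published baseline table —
age ~ N(66, 6.65²) truncated to the 50–79 enrollment window (truncated-
normal locations are pre-solved so the truncated means hit their
targets), BMI ~ 27.8 (SD 5.4) kg/m², dietary alcohol as a zero-inflated
gamma (30% non-drinkers, shape 0.62, scale 14.1) giving mean ≈ 6.1 g/day
and ≈10% of women at ≥ 18 g/day, hormone-use durations as zero-inflated
gammas matching never-use fractions (82% E+P, 70% E-only), and so on.
Event times are exponential given the planted linear predictor (constant
baseline hazard) with administrative censoring at Uniform(12, 20) years —
a mean 16-year horizon. The constant baseline admits closed-form
calibration: P(event) = 1 − (e^{−λa} − e^{−λb})/(λ(b−a)) averaged over
the linear predictor, solved by Brent's method so the marginal event
fraction equals its target (537/10179 ≈ 5.28% by default). The planted
linear predictor is centered before calibration so the baseline keeps its
marginal-rate interpretation.

What the generator does **not** emulate: linkage disequilibrium between
SNPs, population structure, covariate correlations (independence by
default; a joint structure would need a copula layer), non-constant
baseline hazards, competing risks, and informative censoring. Passing
tests therefore demonstrate that the pipeline recovers structure *under
its own assumptions*; they say nothing about robustness to LD-induced
ranking ties or confounded covariates in real cohorts.

## Problem sizes and numerical conventions

The test and acceptance runs use deliberately reduced forests — the
package's own choice of scale for simulation studies: stage-recovery
simulations use 60-tree stage forests and 40-tree nested refits at
n = 5000 with 103 SNPs over 20 seeds; the noise-calibration forest uses
500 trees at n = 2000; GMDR recovery uses n = 3000, a 10-SNP pool and a
planted joint-carrier interaction with HR 2.5 (MAF 0.35, ~13% events —
chosen so the interaction is strong but not trivially dominant); Cox
coverage uses 200 replicates of n = 600. The acceptance script scales the
stage-recovery study to 8 seeds and reports every problem size in its
output.

Numerical conventions: log-rank variances use the hypergeometric form
with the (Y−d)/(Y−1) tie correction, and candidate splits with zero
variance are inadmissible; concordance ties count ½; permutation of a
constant column is the identity, so its VIMP is exactly 0; BH adjustment
is the standard step-up with enforced monotonicity (statsmodels); the
published example ranking is rounded to 4 decimals, so drop errors
recomputed from its error column are determined only to ±1e-4.

## Known limitations

* Forest-ranking behavior under strongly correlated predictors (LD) is
  untested by design (the generator draws SNPs independently).
* The stage-1 "agreement" rule is one of several defensible readings of a
  visual criterion; the drop-error stage is the load-bearing filter.
* GMDR's score residuals default to the logistic (binary-event)
  formulation; the martingale option exists but the cross-validated
  machinery treats score sign as truth either way.
* The Schoenfeld ρ test is slightly conservative at moderate event counts
  (null rejection ≈ 2–5% at α = 0.05 in the calibration suite).
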