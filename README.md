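# glrisk

Gene–lifestyle survival risk profiling for post-GWAS cohort studies.

`glrisk` implements, as a reusable and tested pipeline, the analysis
pattern used in post-GWAS breast-cancer risk profiling of postmenopausal
cohorts: given a panel of candidate SNPs (e.g. variants associated with
inflammatory biomarkers such as CRP and IL-6), a set of lifestyle
variables, and a right-censored time-to-event outcome, it

1. **QC-filters** the genotype matrix (missing-call rate < 2%, exact
   Hardy–Weinberg test p ≥ 1e-4) and builds obesity strata (BMI 30 kg/m²,
   waist 88 cm, waist-to-hip ratio 0.85, 10 MET-h/week, 9% calories from
   saturated fat);
2. runs a **two-stage multimodal random survival forest** selection.
   The RSF (written from scratch here) grows bootstrap survival trees with
   log-rank splitting; each variable is ranked by *minimal depth* (MD, the
   depth of the first node split on it; small = predictive) and
   *permutation VIMP* (the drop in out-of-bag Harrell concordance when the
   variable is permuted among out-of-bag subjects). Stage 1 screens SNPs
   and lifestyles separately (MD below the group mean and VIMP > 0);
   stage 2 combines the survivors, orders them by MD, computes the nested
   out-of-bag error curve e₁…e_K (null model error e₀ = 0.5) and keeps
   variables whose *drop error* d_k = e_{k−1} − e_k reaches δ = 0.005;
3. searches **gene–gene interactions with GMDR** (generalized multifactor
   dimensionality reduction): multilocus genotype cells are labelled
   high/low risk by the sign of summed covariate-adjusted score residuals,
   evaluated by 10-fold testing balanced accuracy (TBA),
   cross-validation consistency (CVC) and a permutation p-value; the best
   model has the highest TBA among models with 10/10 CVC and p < 0.05;
4. builds **combined risk profiles**: risk genotypes (e.g. carrier or
   homozygote codings) and risk behaviors (alcohol ≥ 18 g/day, E+P use
   ≥ 10 years, past OC use < 5 years, BMI ≥ 30) are counted, binarized,
   and added into a 0/1/2 gene–lifestyle score whose dose–response is
   estimated by Cox proportional-hazards models with Benjamini–Hochberg
   correction, trend tests, multiplicative (product-term) and additive
   (RERI) interaction measures, and Schoenfeld-residual diagnostics.

Because the cohorts such analyses run on are access-restricted, the
package ships a **synthetic cohort generator** (`glrisk.simulate`) that
reproduces the statistical structure the pipeline assumes — HWE
genotypes, realistic postmenopausal covariate marginals, ~5.3% cumulative
incidence over a mean 16-year follow-up — with plantable
proportional-hazards main and interaction effects, so every stage is
testable end to end.

## Worked example

```python
import glrisk as gl

spec = gl.default_simspec(n=2000, n_snps=30, seed=7)       # planted effects
cohort = gl.simulate_cohort(spec, calibrate_to=537/10179)  # ~5.3% events
cohort, qc = gl.qc_filter(cohort)

cfg = gl.ForestConfig(n_trees=60, vimp_reps=2, seed=7)
snps, table = gl.stage1_select(cohort, "snps", cfg)
print(table.head(3)[["variable", "minimal_depth", "vimp"]])
```

prints (seed 7):

```
  variable  minimal_depth      vimp
0   rs0002       4.016667  0.009726
1   rs0003       4.233333  0.001827
2   rs0017       4.500000  0.025952
```

`rs0001`–`rs0005` carry planted hazard ratios of 1.4–1.7, and two of the
three top-ranked SNPs here (`rs0002`, `rs0003`) are planted signals: they
split trees ~4 levels from the root on average, while noise SNPs in this
run average MD ≈ 6. Stage 2 (`gl.stage2_multimodal`), the GMDR search
(`gl.model_search`, `gl.select_best`) and the risk profile
(`gl.joint_effect_table`, `gl.interaction_test`) continue from this
selection; `glrisk run-all --config cfg.json --out out/ --seed 7` runs
everything and writes tab-delimited reports plus a manifest with every
resolved seed.

The bundled `glrisk.datasets.load_published_ranking()` table shows the
second-stage report format on real published numbers (25 variables with
MD, VIMP, nested c-index/error and drop error); applying the δ = 0.005
drop-error rule to it keeps exactly 8 variables — 5 SNPs plus OC
duration, BMI and E+P duration.

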