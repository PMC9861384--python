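# rox — rank-order association for data with limit-of-detection missingness

Omics feature tables (metabolomics, proteomics, glycomics, microbiome
abundances) routinely contain missing values because concentrations fall
below the platform's limit of detection (LOD). The two standard
workarounds both distort inference: complete-case analysis (CCA) throws
away exactly the samples that carry the "low" signal, and minimum
imputation invents numbers that warp the distribution. **rox** associates
a left-censored response with covariates *without imputing anything*, by
exploiting the one thing a below-LOD missing value does tell you: it is
smaller than every observed value.

## The statistic

For a response *Y* with missing entries and a fully observed covariate
*X*, every unordered pair of observations falls into one of four groups:
both observed and untied in *Y* (the complete stratum, π₁), exactly one
missing (the bridge stratum, π_b — still rankable, because missing <
observed under the LOD assumption), both missing (noncomparable), or
tied in *Y* (dropped). With concordance tallies Γ(π₁) and Γ(π_b)
(covariate ties score ½), the debiased estimator is

    rox = ( Γ(π₁) + p·Γ(π_b) ) / ( |π₁| + p·|π_b| ),    p = n₁/n,

where n₁/n is the observed fraction. The weight removes the bias caused
by discarding the noncomparable (missing–missing) pairs; p = 1 gives the
strict-LOD estimator and p = 0 gives complete-case concordance. A
self-adjusting check compares the stratum concordances d₁ = Γ(π₁)/|π₁|
and d_b = Γ(π_b)/|π_b|: under a genuine LOD with positive association
the bridge stratum must be the more concordant one (d₁ < d_b; mirrored
for negative association). If the check fails, the missingness is not
LOD-like and the estimator falls back to complete-case analysis (p = 0).

Inference tests H₀: rox = 0.5 with z = (rox − ½) / √((cvar + ivar)/2),
averaging a conservative permutation-null variance (cvar) and an
infinitesimal-jackknife variance (ivar). A multivariable extension
models pairwise ranking probabilities with an exponential link,
P(yᵢ < yⱼ) = σ(ηⱼ − ηᵢ) with η = Xβ, maximizing the same
bridge-weighted pairwise likelihood by Newton iteration; Wald tests use
sandwich (Godambe) standard errors.

## Worked example

```python
import numpy as np
from rox import apply_strict_lod, rox_test, tune_lambda

# simulate a metabolite with true concordance 0.85 to the outcome,
# then censor the lowest 50% of values as "below LOD"
lam, _ = tune_lambda(0.85, n=10_000, seed=101)
rng = np.random.default_rng(202)
x = rng.standard_normal(2000)
y = x + lam * rng.standard_normal(2000)
y_cens = apply_strict_lod(y, 0.5)

res = rox_test(y_cens, x, mode="auto")
print(f"estimate={res.estimate:.3f}  p_weight={res.detail.p_weight:.2f} "
      f"lod_consistent={res.detail.lod_consistent}  z={res.z:.1f}")
```

```
estimate=0.842  p_weight=0.50 lod_consistent=True  z=49.7
```

The estimator recognized the strict-LOD pattern (d₁ < d_b), kept the
bridge pairs at weight n₁/n = 0.5, and recovered the true concordance
0.85 to within sampling error; on the same draw, complete-case analysis
gives 0.75 and minimum imputation 0.87. The z-statistic rejects
independence decisively.

The same analysis runs from the shell on a TSV/CSV feature table
(samples as rows; `NA`, `NaN` or empty cells are missing):

```sh
rox test  -i table.tsv -o results.tsv --outcome diabetes
rox fit   -i table.tsv -o fit.tsv --response metabolite_7 \
          --covariates age,bmi,sex
rox benchmark --preset strict --reps 10 --seed 1 -o bench.tsv
```

Every command writes the results TSV plus a JSON run summary echoing the
resolved configuration and seed.

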