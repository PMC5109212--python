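# corrmr

Two-sample Mendelian randomization (MR) with **correlated instruments**,
built around the question of whether habitual coffee consumption causally
affects type 2 diabetes, ischemic heart disease (IHD), depression,
Alzheimer's disease and cardiovascular risk factors.

## Who this is for

Epidemiologists and statistical geneticists who have only *summary*
GWAS statistics — per-SNP effect sizes with standard errors — from separate
exposure and outcome studies, whose instruments are partially in linkage
disequilibrium (LD), and whose outcome may be reported by two consortia that
share participants.

## The statistics

**Correlated-instrument IVW.** For instruments with harmonized exposure
effects `bx` (cups/day per allele), outcome effects `by` (log odds or trait
units per allele), outcome standard errors `sy` and signed LD matrix `R`,
the causal effect per cup/day is estimated by generalized least squares
through the origin,

    Omega_ij = sy_i * sy_j * R_ij
    theta    = (bx' Omega^-1 bx)^-1 * bx' Omega^-1 by
    se       = sqrt( (bx' Omega^-1 bx)^-1 )

with Wald 95% CIs (`z = 1.959964`) and two-sided normal p-values.  With
`R = I` this is exactly the classical fixed-effect IVW average of per-SNP
Wald ratios `by_i / bx_i`; with one SNP it is the Wald ratio itself.

**Overlap-adjusted pooling.** Two case-control studies of the same disease
that share `sc` cases and `sk` controls have correlated estimation errors,

    r = [ sk * sqrt(c1 c2 / (k1 k2)) + sc * sqrt(k1 k2 / (c1 c2)) ] / sqrt(n1 n2)

(`c` cases, `k` controls, `n = c + k`).  Their estimates are pooled by GLS
with covariance `[[se1^2, r se1 se2], [r se1 se2, se2^2]]`, reducing to the
textbook fixed-effect meta-analysis at `r = 0`.

**Instrument curation.** Genome-wide-significance filtering, greedy LD
pruning at `r^2 > 0.8` (the larger-p member of a correlated pair is
discarded), pleiotropy-defined subsets (*all*, *no known pleiotropy*,
*functionally relevant to caffeine metabolism*), and substitution of a
high-LD proxy for instruments missing from an outcome dataset.

The estimator is a scikit-learn `BaseEstimator`
(`CorrelatedIVW().fit(X, y, y_se=..., correlation=...)` with fitted
`effect_`, `se_`, `ci_low_`, `ci_high_`, `p_` attributes); the functions
`ivw_correlated` / `wald_ratio` are thin wrappers over it.

## Worked example

```python
import math
from corrmr import fixtures
from corrmr.instruments import ld_prune, select_genomewide, subset_instruments
from corrmr.pipeline import default_analysis_config
from corrmr.pooling import estimate_from_or_ci, overlap_correlation, pool_correlated

cfg = default_analysis_config()
exposure, ld, ann = (fixtures.coffee_instruments(), fixtures.coffee_ld(),
                     fixtures.coffee_annotations())
selected = select_genomewide(exposure, cfg.selection)
pruned = ld_prune(selected, ld, cfg.selection.r2_prune)
print(f"instruments: {len(selected)} certified -> {len(pruned)} after LD pruning")
for mode in ("no_known_pleiotropy", "functional"):
    print(f"  subset {mode}: {len(subset_instruments(pruned, ann, mode))} SNPs")

r = overlap_correlation(fixtures.IHD_OVERLAP)
e1 = estimate_from_or_ci(*fixtures.IHD_GWAS_OR["all"])
e2 = estimate_from_or_ci(*fixtures.IHD_METABOCHIP_OR["all"])
pooled = pool_correlated(e1, e2, r)
print(f"overlap correlation between IHD consortia: r = {r:.3f}")
print(f"pooled IHD odds ratio (all 9 SNPs): {math.exp(pooled.theta):.2f} "
      f"(95% CI {math.exp(pooled.ci_low):.2f}, {math.exp(pooled.ci_high):.2f})")
```

prints

```
instruments: 10 certified -> 9 after LD pruning
  subset no_known_pleiotropy: 5 SNPs
  subset functional: 3 SNPs
overlap correlation between IHD consortia: r = 0.505
pooled IHD odds ratio (all 9 SNPs): 1.02 (95% CI 0.91, 1.14)
```

Reading: one of the ten certified coffee SNPs is discarded for high LD with
a stronger hit; the two IHD consortia share 57.5% of cases and 40.1% of
controls, inducing a correlation of about 0.5 between their estimates; the
overlap-adjusted pooled odds ratio of 1.02 per cup/day is compatible with no
effect of coffee on IHD.

A Monte-Carlo check of the estimator under known truth:

```python
from corrmr.simulate import SimConfig, recovery_report
report = recovery_report(SimConfig(theta_true=0.2, ld_rho=0.3, seed=1), n_reps=1000)
print(*report.summary_lines(), sep="\n")
```

```
replicates            1000
true effect           +0.2000
bias                  -0.00814 (MC SE 0.00275)
RMSE                  0.08719
95% CI coverage       0.949 (MC SE 0.007)
mean model SE         0.08610
empirical SD          0.08686
reject rate (a=0.05)  0.607 (MC SE 0.015)
```

The small negative bias (≈ 4% of the true effect) is the expected regression
dilution from exposure-side estimation error; see `docs/methods.md`.

## Command line

```bash
corr-mr run --config analysis.yaml --out results/    # full analysis -> TSV + log
corr-mr simulate --seed 7 --out simdata/             # synthetic dataset with known truth
corr-mr pool --or1 1.06 --ci1 0.94,1.20 --or2 0.96 --ci2 0.84,1.10 \
             --overlap-spec overlap.yaml             # standalone pooling
```

The consortium outcome files themselves are not redistributable; the packaged
default configuration enumerates the 18 association tests (and the Bonferroni
threshold 0.05/18) with `path: null` placeholders — point each study's `path`
at a local summary TSV to estimate those cells.

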