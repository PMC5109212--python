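# Methods

## The model

corrmr estimates the causal effect of habitual coffee consumption (cups of
regular coffee per day) on disease outcomes and cardiovascular risk factors
by two-sample Mendelian randomization: genetic variants robustly associated
with coffee intake serve as instrumental variables, and only summary
statistics are required — per-SNP effect sizes with standard errors from a
coffee GWAS on one side and from disease/risk-factor consortia on the other.

The identifying assumptions are the usual instrumental-variable triple:
each SNP (i) is associated with coffee intake, (ii) shares no confounder
with the outcome (plausible because genotypes are fixed at conception), and
(iii) affects the outcome only through coffee (the exclusion restriction —
the assumption the pleiotropy subsets probe).

### Correlated-instrument IVW

With harmonized per-SNP exposure effects `bx`, outcome effects `by`, outcome
standard errors `sy` and a signed LD correlation matrix `R`, the estimator
is the generalized-least-squares slope through the origin weighted by the
inverse of `Omega_ij = sy_i sy_j R_ij`:

    theta = (bx' Omega^-1 bx)^-1 bx' Omega^-1 by,   se = sqrt((bx' Omega^-1 bx)^-1)

This is a *fixed-effect, first-order* formulation: exposure standard errors
`sx` do not enter the weights (they are retained in the data model), and no
heterogeneity component is estimated.  Identity `R` recovers the classical
IVW average of Wald ratios `by_i/bx_i` with weights `bx_i^2/sy_i^2`; a single
instrument recovers the Wald ratio.  All confidence intervals use
`z = 1.959964` and natural logarithms throughout; binary-outcome effects are
estimated on the log-odds scale and exponentiated only for reporting.

`Omega` must be positive definite.  If its smallest eigenvalue is at or
below 1e-10 the fit fails loudly, naming the most collinear instrument
pair — there is no silent ridge repair, because a near-singular weight
matrix means the instrument set still contains effective duplicates that
pruning should have removed.

### Instrument curation

* **Significance filter.** `select_genomewide` keeps records with
  `p < p_threshold` (default 5e-8), ordered by ascending p.  The packaged
  coffee instrument table is the discovery GWAS's *certified* genome-wide
  significant list — that GWAS used a Bayesian criterion (log10 Bayes
  factor > 5.64, approximating p < 5e-8) that cannot be recomputed from
  summary statistics, and two of its ten SNPs have printed p-values slightly
  above 5e-8.  The packaged configuration therefore sets `p_threshold: 1.0`,
  accepting the source's certification rather than re-filtering; the
  p-filter remains active for any user-supplied exposure table.
* **LD pruning.** Greedy sweep in ascending-p order: keep the current SNP
  unless it has `r^2 > 0.8` with an already-kept SNP (the larger-p member of
  each violating pair loses; ties break on the lexicographically smaller
  rsid).  The sweep is deterministic, idempotent, and always retains the
  smallest-p member.  On the packaged table it removes exactly one SNP
  (the AHR-region twin).
* **Pleiotropy subsets.** `all` (9 SNPs), `no_known_pleiotropy` (5 SNPs with
  no recorded pleiotropic trait), `functional` (3 SNPs in AHR/CYP1A1/CYP1A2,
  functionally linked to caffeine metabolism).  Annotations are inputs
  (curated from phenotype databases), not computed.
* **Proxy substitution.** An instrument missing from an outcome dataset is
  replaced by its best annotated proxy: highest `r^2` first, then smallest
  distance, then closest allele frequency (within 0.08 absolute when both
  frequencies are known).  The admission threshold `proxy_r2_min` defaults
  to 0.65 rather than the conventional 0.8 because published practice admits
  proxies somewhat below it (one documented substitution in this analysis
  used r^2 = 0.694); any admission below 0.8 is logged.  The proxy inherits
  the index SNP's exposure effect (justified by the high `r^2`), re-keyed to
  the proxy rsid and allele orientation.  A member with no admissible proxy
  is dropped with a warning, never an error.

### Harmonization

Outcome betas are re-expressed per copy of the exposure's effect allele.
Non-palindromic SNPs resolve exactly from the allele letters (same order,
swapped, strand-complemented, or both; swapped orientations negate the
beta).  Palindromic SNPs (A/T, C/G) are strand-ambiguous: they are resolved
by allele-frequency agreement when both frequencies are more than
`freq_margin = 0.08` from 0.5, and excluded otherwise.  The margin is a
conservative standard default; the packaged instruments are all
non-palindromic, so the coffee analyses are unaffected by the policy.

The signed LD matrix is stored in the exposure effect-allele orientation,
which harmonization never alters, so `R` passes through unchanged
(restricted and reordered to the harmonized pairs).

### Overlap-adjusted pooling

The two IHD consortia share 57.5% of cases and 40.1% of controls.  The
induced correlation between their estimates is

    r = [ sk sqrt(c1 c2/(k1 k2)) + sc sqrt(k1 k2/(c1 c2)) ] / sqrt(n1 n2)

which is 0 for disjoint studies and exactly 1 for a study paired with itself
(clipped to 0.999 so pooling stays nonsingular).  The published overlap
percentages name no denominators; this package takes shared cases as 57.5%
of the *smaller* study's cases and shared controls as 40.1% of the
*first-listed* study's controls (both config-overridable), giving r ≈ 0.505
and reproducing the published pooled odds ratios at two decimals.  Pooling
is GLS with covariance `[[se1^2, r se1 se2],[r se1 se2, se2^2]]` on the
log-odds scale; when r exceeds the SE ratio one weight goes negative, which
is logged but honoured (the variance formula still holds).

### Multiple testing

The default configuration enumerates 18 association tests — four diseases,
thirteen cardiovascular risk factors and one negative-control outcome
(childhood cognition, which coffee cannot plausibly affect).  The published
table prints eleven risk-factor rows; the count of thirteen follows the
study's own tally, which additionally includes the earlier-release fasting
glucose and fasting insulin datasets used as fallbacks.  The corrected
threshold is the exact quotient `alpha/n_tests = 0.05/18 ≈ 0.00278` (the
rounded presentation value 0.002 is not used for flagging); rows carry both
nominal and corrected significance flags.

## The synthetic-data generator

`simulate_dataset` draws summary statistics directly from their sampling
distributions — no individual-level genotypes — which makes standard errors
exact by construction and keeps a full replicate under a millisecond:

* true exposure effects `bx*` uniform on 0.03–0.14 cups/day per allele with
  `sx = 0.01` (the scale of the real instrument table); observed `bx` add
  LD-correlated noise;
* true outcome effects `by* = theta bx* + alpha_i`, with optional direct
  (pleiotropic) effects `alpha_i ~ N(mean, sd^2)`;
* observed `by` are multivariate normal around `by*` with per-SNP SDs
  `1/sqrt(2 n f(1-f))` for a unit-variance continuous trait, or
  `1/sqrt(2 n phi(1-phi) f(1-f))` for a binary outcome with case fraction
  `phi` (logistic-information approximation), correlated across SNPs with
  the LD matrix;
* with an `OverlapSpec`, two outcome studies' error vectors are additionally
  correlated across studies with the overlap-induced correlation above;
* default conditions mirror the coffee study: nine instruments in an
  equicorrelated block (`rho = 0.3`), exposure GWAS n = 129,788, a binary
  case-control outcome with case fraction 0.33 (the IHD ratio) of size
  n = 50,000 — mid-scale among the consortia analysed (18.8k–322k) and
  small enough that thousand-replicate experiments run in under a second.

What the generator does **not** emulate: genotype-level sampling, population
stratification, allele-frequency differences between samples, LD estimation
error, and winner's-curse in instrument discovery.  Passing recovery tests
therefore validate the estimator's algebra and calibration under the model's
own assumptions, not robustness to those real-data complications.

### Known finite-sample property: regression dilution

Because the weights are first-order (exposure error ignored), measurement
error in `bx` attenuates the estimate.  With `sx = 0.01` against effects of
0.03–0.14 the expected shrinkage is roughly `(m-2) sx^2 / (bx' R^-1 bx)`,
about 2% of theta for the default nine-instrument block — visible as a bias
of ≈ -0.005 at `theta = 0.2` in thousand-replicate runs, comparable to the
Monte-Carlo standard error at that scale, while 95% CI coverage stays inside
[0.93, 0.97].  The bias vanishes at the null, so type-I error is calibrated.
Under directional pleiotropy (nonzero-mean direct effects) coverage degrades
sharply — the designed illustration of exclusion-restriction sensitivity.

## Numerical choices

* `Omega` solved by Cholesky factorisation; positive-definiteness gate at
  eigenvalue 1e-10.
* LD matrices: symmetry enforced at 1e-8, entries clipped to [-1, 1] after
  validation, unit diagonal required.  When only `r^2` is available the sign
  defaults to positive with a logged warning (allele phase is not inferable
  from summary data).
* Text round-trips write floats at 17 significant digits, preserving values
  to better than 1e-12 relative.
* Reported odds ratios, mean differences and CI bounds round to two
  decimals, matching the published table's presentation.
* All randomness flows from one seeded `numpy` generator per dataset.

## Limitations

* Fixed-effect only: no MR-Egger, weighted-median or mode estimators, and no
  heterogeneity statistics — the analysis this package reproduces reports
  none, and the instrument count (3–9) is small for those methods anyway.
* The packaged LD fixture carries only the published pairwise values; all
  unpublished pairs are zero.  Real reference-panel LD would perturb the
  estimates (not the curation counts, which depend only on the published
  above-threshold pair).
* The published per-consortium disease cells cannot be recomputed here
  because the underlying consortium summary files are inputs, not package
  data; the pipeline reproduces their *format* and the pooled quantities
  that are derivable from printed numbers alone.
* Non-linear exposure-outcome relationships are not modelled (untestable
  with summary statistics).
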