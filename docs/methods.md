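# Methods

This note documents the statistical models implemented in `isocompass`,
the defaults and why they were chosen, what the synthetic-data generator
does and does not emulate, and the numerical decisions that a maintainer
would otherwise have to reverse-engineer.

## Calibration model

Raw GC-IRMS delta values are mapped to the international scales in three
steps.

**Drift.** If reference-standard runs carry a run index, a linear drift
is estimated as the OLS slope of (measured − accepted) on run index and
subtracted from the measured values (`drift_rate`, ‰ per run). Estimates
below 1e-8 ‰/run are snapped to zero so that drift-free sequences do not
acquire a spurious run-index requirement. Non-linear drift and
amplitude (linearity) dependence are out of scope; amplitude correction
is assumed done upstream.

**Scale normalization.** An OLS line through the certified FAME
standards maps measured to accepted values (two-point minimum,
three-point with USGS70/71/72 by default). With standards measured
exactly at their accepted values the map is the identity; applying a
fitted model to already-calibrated rows raises, because an affine map
silently applied twice corrupts the scale.

**Methylation correction.** Derivatization adds a methanol-derived
methyl group (1 C, 3 H) to each fatty acid. The correction is a linear
isotope mass balance on the delta scale,

    delta_FA = (n * delta_FAME − n_Me * delta_MeOH) / (n − n_Me),

with `n` the total C atoms (¹³C, `n_Me = 1`) or H atoms (²H,
`n_Me = 3`) of the methyl ester. For a straight-chain acyl methyl ester
with c carbons and d double bonds, n_C = c + 1 and n_H = 2c − 2d + 2.
Working in delta space rather than atom-fraction space deviates from
exact bookkeeping by well under 0.1 ‰ over the natural-abundance range,
which is standard field practice; the linear form makes the
mass-conservation identity exact (tested to 1e-9 ‰). Acyl hydrogen is
treated as non-exchangeable; the methanol delta values are lab-specific
measurements with no defensible default, so the pipeline requires them
explicitly and never falls back silently.

The registry maps trivial names to structures (LIN = 18:2n-6,
ALA = 18:3n-3, SDA = 18:4n-3, ARA = 20:4n-6, ETA = 20:4n-3,
EPA = 20:5n-3, DPA = 22:5n-3, DHA = 22:6n-3). "HTA", quantified only in
brain tissue and without a standardized structure, parses as an
identity-only placeholder: it can label a feature column but refuses to
report atom counts until the user registers an explicit structure, so a
wrong silent guess can never enter the mass balance.

## Composites

The bulk composite is the mass-fraction-weighted mean over *all
identified peaks* of a sample and isotope (not only the 11-FA panel); a
panel-restricted variant exists for sensitivity analysis. Because the
hydrogen runs typically resolve fewer peaks than the carbon runs, the
composite is computed per isotope from that isotope's own peak set. The
weighted mean is convex (bounded by the input deltas) and invariant
under rescaling of the mass fractions, both of which are property
tested.

## Repeatability

Site repeatability of one variable is

    R = sigma2_site / (sigma2_site + sigma2_residual)

from the linear mixed model `y ~ covariates (fixed) + (1 | site)`.
"Controlling for" taxon, tissue, or year means their group means are
absorbed as fixed effects inside the model, not by pre-residualizing.
The REML fit is computed by an in-package profiled likelihood: for a
single random intercept the covariance is block diagonal,
V = sigma2_e (I + lambda·J) per site block with
lambda = sigma2_site/sigma2_e, so beta and sigma2_e profile out in
closed form and REML reduces to a bounded one-dimensional search over
log lambda. The boundary lambda = 0 is always evaluated; data that
would give a negative moment estimate land on the floor with a warning.
This implementation agrees with `statsmodels` MixedLM to about 1e-6 on
the study-sized layout and with the one-way ANOVA moment estimator
(MS-based, with the unbalanced-design n₀) to within 0.02 on balanced
designs — both comparisons are tests, not fallbacks. The profiled form
exists because the confidence interval is a 1000-replicate parametric
bootstrap (resimulate from the fitted components, refit, take
percentiles), which needs a fast and numerically robust refit.

A covariate whose levels map one-to-one onto sites is rejected by name:
its fixed effect would absorb the site variance entirely.

## Canonical correlation and dimension tests

CCA between the δ¹³C and δ²H blocks is computed from the SVD of the
whitened cross-covariance: each centered block is SVD-whitened with rank
truncation (tolerance 1e-10 relative to the leading singular value,
truncation warned), and the singular values of U_xᵀU_y are the canonical
correlations. Coefficients are scaled so canonical variates have unit
variance (ddof = 1), matching the usual raw-coefficient convention.
Sequential dimension tests use Rao's F approximation of Wilks'
Λ_k = Π_{i≥k}(1 − r_i²); for a single pair of variables the statistic
collapses to the ordinary correlation F-test, which is used as an exact
oracle in the tests, and the general case is cross-checked against a
brute-force generalized-eigenvalue solution to 1e-8.

Variance attribution uses Type II sums of squares (drop one term,
keep the other main effects) through `statsmodels.anova_lm`; Type III
with sum-to-zero contrasts is available behind `typ=3` for designs with
interactions. Attribution tables are qualitative — which factor
dominates — so the simpler Type II default is preferred over committing
to a contrast coding. Holm adjustment is step-down with monotonicity;
Šidák is 1 − (1 − p)^m. Marginal means are model-based predictions
averaged over a balanced reference grid, with Šidák-adjusted pairwise
contrasts and 95% t-intervals.

## Discriminant site assignment

The classifier keeps per-site centroids, the pooled within-site
covariance, and equal priors (sites are compared as locations, not
prevalences; empirical priors are a flag). Assignment maximizes the
Gaussian discriminant score, equivalent to the nearest centroid in
Mahalanobis distance; posteriors are the softmax of the scores. Ties
(within 1e-12) break lexicographically by site id and are flagged,
never randomized. Canonical axes are the generalized eigenvectors of
the between- vs within-site scatter, with proportion of trace per axis;
both the axes and the tie-free predictions are checked against
brute-force oracles.

A ridge of 1e-6·trace(W)/p is added to the pooled covariance only when
its condition number exceeds 1e8 (or when p ≥ n − k), and the event is
logged. Cross-validated accuracy uses the bootstrap: each of the
(default 999) replicates resamples rows with replacement within class,
fits, and scores the out-of-bag rows; correct counts are pooled over
replicates, and the percentile spread of per-replicate accuracies is
reported as an interval. Resubstitution accuracy is reported alongside
as the optimistic upper reference.

Cross-year transfer freezes the training year's model — centroids and
pooled covariance, the "grand means" classifier — and predicts the test
year without any refitting. Exact accuracy is trace/total of the
confusion matrix; tolerant accuracy additionally credits predictions
whose site lies within a distance tolerance (default 1 km) of the true
site according to the user-supplied distance matrix, which may be
stream distances and need not satisfy the triangle inequality. Site
pooling is only ever applied through an explicit user-supplied map;
`suggest_pooling` proposes pairs close in both Mahalanobis and
geographic distance but never applies them.

The multi-tissue consensus rule: a fish is site-specific when at least
3 of its available tissues are assigned to its true site; with fewer
than 3 tissues available, all of them must be correct.

## Synthetic-data generator

The generator mirrors the hierarchical structure the analysis assumes:
15 sites spanning 525–1070 m a.s.l. along a ~35 km transect (with two
site pairs closer than 1 km so tolerant scoring has something to
credit), three taxa, four tissues, two years, and the 11-FA panel in
both isotopes. Each value is a sum of a per-FA baseline, an altitude
term (δ¹³C only), a site random effect, tissue and taxon offsets, a
per-(site, FA) year shock in the second year, and residual noise. Site
effects are drawn once per (site, isotope) and propagated to the FA
panel through an equicorrelation structure — the simplest mechanism
that makes δ¹³C values correlate strongly across compounds (ρ = 0.7)
and δ²H weakly (ρ = 0.3). Mass fractions are Dirichlet draws around a
typical fish-tissue FA profile. Values are emitted on the raw
instrument FAME scale by inverting the methylation mass balance and a
configurable true calibration line, together with a standards run
table, so the calibration stage is exercised rather than bypassed.

Defaults (per mil): site effect SD 1.5 (¹³C) / 8 (²H), residual SD 1.0
/ 10, altitude slope −2 ‰ per km of altitude, year-shock SD 2.0 / 16,
taxon offsets small with the main hydrogen contrast between bullheads
and salmonids, brain the most offset tissue. These were chosen so that
default simulations sit in the qualitative regime the method is meant
for: within-year bootstrap-CV accuracy of the 22-feature classifier
around 70–90%, bulk-composite (2-feature) accuracy several-fold lower,
and cross-year exact accuracy roughly 30–60%. The fixture sizes match
the study design (159 fish in the first year with a 0.40/0.23/0.37
taxa mix; 49 sedentary bullheads in the second).

What the generator does *not* emulate — and therefore what passing
tests do not show about real data: mechanistic isotope fractionation
(trophic discrimination, bioconversion kinetics), spatially correlated
site effects (each site's effect is independent, so neighbouring sites
are no more confusable than distant ones), tissue-specific turnover
times, peak-detection failures that differ between isotopes, and any
instrument non-linearity beyond the affine calibration. Parameter
recovery on these simulations demonstrates correctness of the
estimators under the assumed variance structure, not field performance.

## Degenerate inputs and tie-breaks

- Feature matrices are complete-case per analysis (never imputed);
  dropped samples are listed in the build report.
- Peak tables with duplicated (sample, fa, isotope) keys, unknown
  isotope labels, or negative mass fractions are rejected at read time.
- `bulk_delta` with all-zero mass fractions raises; zero-mass peaks are
  excluded from the weighted mean but counted in the mass-coverage
  denominator.
- Repeatability requires at least two sites with two samples each.
- LDA requires at least two samples per class and warns (and
  regularizes) when p ≥ n − k.
- Classes absent from a bootstrap training draw invalidate that
  replicate; more than 50% invalid replicates raises a warning.

## Known limitations

- The repeatability model has a single random site effect; nested or
  crossed random structures (e.g. fish within site) and heteroscedastic
  residuals are out of scope.
- Bootstrap-CV out-of-bag accuracy is pessimistic relative to
  leave-one-out for small classes; `loo_cv_accuracy` is provided as a
  sensitivity alternative.
- The Wilks/Rao approximation degrades for n close to p + q; the
  implementation warns when n ≤ p + q and raises when the approximation
  degrees of freedom become non-positive.
- H₃⁺-factor, memory-effect, and exchangeable-hydrogen corrections are
  assumed handled upstream of the peak table.
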