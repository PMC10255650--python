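# Methods

`uavpheno` implements a two-part analysis of replicated cereal variety
trials observed with UAV multispectral cameras: (i) retrieval of grain
yield and canopy biophysical variables from plot-level reflectance, and
(ii) a quantitative-genetic evaluation of the retrieved traits as
selection criteria. Because raw trial data of this kind are rarely
deposited, the package ships a synthetic-trial generator with fully known
genetic architecture; every downstream claim is tested against that
planted truth.

## Trial model and synthetic generator

Each trial is a randomized complete block design: `g` genotypes, each
occurring exactly once in each of `r` blocks (replicates). Per trait the
observation model is the one-way mixed model

    y_ij = mu + alpha_i + tau_j + eps_ij,

with genotype effects `alpha_i ~ N(0, sigma2_g)` random, block effects
`tau_j` fixed with a sum-to-zero constraint, and residuals
`eps_ij ~ N(0, sigma2_e)`.

The generator draws genotype effects for all traits jointly from a
zero-mean multivariate normal whose covariance combines per-trait
genotypic variances with a genetic correlation matrix (validated
symmetric, unit-diagonal, positive semidefinite; the offending eigenvalue
is reported otherwise). Residuals are likewise drawn jointly with an
environmental correlation matrix `s*C + (1-s)*I` (default `s = 0.7`,
where `C` is the genetic correlation matrix), so that plot-level
correlations between traits do not vanish for low-heritability traits —
without this, spectra could carry almost no yield information at the plot
level, which contradicts how such trials behave. Block effects default to
equally spaced offsets spanning ±0.25 residual SD and summing to zero.

Simulator conventions (not field relationships):

- fAPAR is derived as `min(1, 0.95*fCover + N(0, 0.01))` by default; a
  config flag restores the joint-Gaussian path.
- Physical ranges (fractions in [0,1], non-negative yield/LAI/LCC) are
  enforced by clipping *after* simulation; clip events are counted and a
  warning is emitted if more than 1% of values clip.

Default parameters place the pooled trial at a grain-yield mean of
6280 kg/ha with CV ≈ 27%, LAI mean 3.8 (CV ≈ 26%), LCC mean
394 mg m⁻², and entry-mean heritabilities between 0.61 (ground NDVI) and
0.87 (LCC) at r = 4 — the moderate-to-high band typical of rainfed
winter-barley variety trials. The genetic correlation of each trait with
yield is in the 0.4–0.7 range. These defaults were fixed once, before any
acceptance measurements, and are packaged as configuration, not
constants.

## Forward reflectance model

Plot reflectance in band `b` follows two-endmember linear mixing:

    R_b = fCover * leaf_b(LCC) + (1 - fCover) * soil_b + noise,

clipped to [0,1]. The leaf endmember is a fixed five-point template over
blue/green/red/red-edge/NIR; chlorophyll acts multiplicatively,
`exp(-k*(LCC - 400))` with `k = 0.002` per mg m⁻² on the red band and at
half that sensitivity on the red edge, making red reflectance monotone
decreasing in LCC. When fCover is absent it is derived from LAI by
Beer–Lambert extinction `1 - exp(-0.5*LAI)`. This is a deliberately
simple monotone model, not a radiative-transfer simulation: it produces
the qualitative structure the retrieval methods exploit (soil–vegetation
mixing, chlorophyll absorption, NIR brightness) without claiming spectral
fidelity. Consequently the synthetic retrieval skill (validation R²
0.8–1.0) is higher than what real mosaics yield; passing tests
demonstrate correctness of the machinery, not field-level accuracy.

Two sensors are modelled: a 4-band camera (G 550, R 660, RE 735,
NIR 790 nm) and a 5-band camera (B 450, G 560, R 650, RE 730,
NIR 840 nm). Late-season (dough-ripening) missions are emulated by a
per-mission `fcover_scale < 1` (senescence shrinking the vegetation
signal) plus higher additive noise; defaults 0.45 and 0.018–0.020
reflectance SD.

## Plot extraction

Plot polygons (projected metric CRS only; geographic coordinates are
rejected rather than silently reprojected) are shrunk by a 10 cm inward
buffer to avoid mixed edge pixels, then per-band means are taken over
pixels whose *centres* fall inside the buffered polygon — the inclusion
rule is a documented choice. Nodata pixels are excluded from the mean and
the surviving pixel count is reported; a plot with zero covered pixels or
all-nodata coverage is an error, never a silent NaN. Extraction is tested
against a brute-force per-pixel point-in-polygon loop.

## Retrieval protocol

All models share one protocol: a single random split into 2/3 training
(bare-soil samples included, with all supervision targets set to 0) and
1/3 validation; ten-fold cross-validation on the training set, folds
stratified so soil samples spread across folds; model selection strictly
by cross-validated nRMSE; one final score on the untouched validation
third. Perturbing validation labels provably leaves the selected model
unchanged (tested).

*Parametric route.* Fourteen generic vegetation-index families over one
to four reflectance arguments are instantiated with every ordered tuple
of distinct sensor bands (645 assignments on 5 bands, 256 on 4); ordered
tuples are kept because the formulas are asymmetric, and symmetric
duplicates are cheap at this band count. Each index is paired with five
function families — linear, degree-2 polynomial (the degree is a fixed
choice), logarithmic, exponential and power — fitted by least squares,
the last two via log-linearization with out-of-domain points dropped and
counted. Non-finite index values (zero denominators) become missing;
candidates whose predictions are undefined for more than 10% of samples
are excluded from ranking. A singular fit is a flagged non-model, not an
exception.

*Nonparametric route.* PLSR, random-forest, kernel-ridge and
Gaussian-process regression over all sensor bands (scikit-learn
estimators behind this module's surface). RBF kernels for KRR/GPR. The
hyperparameter grids are documented defaults, not reconstructions of any
reference tool: PLSR components 1..min(bands, 10); RFR trees {100, 500} ×
depth {unlimited, 10}; KRR alpha 1e-6..1 × gamma 1e-3..1e3 (log grids);
GPR length-scale 1e-2..1e2 × noise 1e-7..1e-2, kernel fixed per grid
point (the marginal-likelihood optimizer is disabled so selection mirrors
the other methods). KRR has no intercept, so its target is centred and
scaled; the heavy-regularization limit then shrinks predictions to the
training mean. GPR additionally returns predictive SDs; the uncertainty
summary is the mean of `100*SD/prediction` over vegetation samples
(bare-soil samples and zero predictions excluded — a relative measure is
meaningless at a zero target).

Metrics: R² is the squared Pearson correlation (so it can exceed NSE for
biased predictions — both are reported, and the OLS case where they
coincide is tested); nRMSE normalizes by the observed range and rRMSE by
the observed mean of the evaluation subset, in percent; NSE is
1 − SSE/SST; AIC = n·ln(SSE/n) + 2k with k = coefficient count for
parametric models and, as a documented proxy, tuned-hyperparameter count
+ 1 for ML models. Normalizers are recorded in every report for
auditability.

Applying a fitted model to all plots yields the remotely sensed
phenotypic trait (RSPT) table: one retrieved value per plot per trait,
with negative retrieved GY/LAI/LCC clipped to zero and logged (fAPAR and
fCover are reported raw).

## Quantitative genetics

For a balanced trial the restricted likelihood of the mixed model
factorizes into two strata: the `g-1` genotype contrasts with variance
`lambda = sigma2_e + r*sigma2_g` and the `(g-1)(r-1)` residual contrasts
with variance `sigma2_e`. REML estimates maximize this stratum likelihood
exactly, with the `sigma2_g >= 0` boundary handled by pooling the strata;
the maximized restricted log-likelihood is retained for testing. An
independent method-of-moments route (`anova_components`, via a
statsmodels two-way ANOVA) must agree to 1e-6 relative whenever its
genotypic component is positive; negative components are truncated at
zero with a warning. A third cross-check against statsmodels MixedLM runs
in the test suite.

Pooled analyses across trials treat trial and replicate-within-trial as
fixed and genotype as random with components shared across trials, so the
strata simply accumulate — this pooling model is this package's
convention.

The genotype likelihood-ratio test compares the full REML fit against
`sigma2_g = 0` with identical fixed effects; the statistic is
`2*(l_full - l_reduced)` and the p-value uses the boundary mixture
`0.5*chi2_0 + 0.5*chi2_1` (about half the null replicates sit exactly at
zero with p = 1).

Broad-sense heritability is reported on the entry-mean basis
`sigma2_g/(sigma2_g + sigma2_e/r)` by default — the scale on which
genotype means are compared in selection — with the plot basis
`sigma2_g/(sigma2_g + sigma2_e)` always co-reported.

The genotypic covariance of two traits on the same design comes from
genotype and error mean cross-products, `COV_G = (MCP_G - MCP_E)/r`, and
is verified at run time against the variance-of-sum identity
`0.5*[s2g(x+y) - s2g(x) - s2g(y)]` to 1e-10 relative. The genotypic
correlation `r_G = COV_G / sqrt(s2g_x * s2g_y)` can exceed 1 in magnitude
by sampling; it is then flagged and reported raw, never clamped.
Significance uses a t-approximation with `g - 2` degrees of freedom — a
documented convention, since component-based correlations have no exact
small-sample test.

Selection responses use unit selection intensity: direct response
`R = sqrt(H2)*sigma_g`; correlated response of yield to selection on a
secondary trait x, `CR = sqrt(H2_x)*r_g*sigma_g(yield)`; relative
selection efficiency is `CR/R`, defined only for `R > 0`. The algebraic
identity `CR/R = (h_x/h_y)*r_g` when both use the same genotypic SD is
covered by a test.

## Pipeline and reproducibility

Stages run in a fixed order (simulate → spectra → yield models per
sensor×mission → biophysical retrieval on the best mission → apply to all
replicates → quantitative genetics), communicate only through CSV files,
and derive their random streams from one root seed via per-stage CRC
mixing, so a config determines every output byte; the manifest records
SHA-256 hashes per file along with collected warnings. Biophysical
ground truth exists only on designated measurement replicates (default 1
and 2), mirroring how ceptometer and chlorophyll-meter campaigns are
actually conducted; training for those traits uses only those plots plus
the soil samples, while the winning model is applied to all four
replicates.

## Problem sizes and numerical choices

The packaged defaults — 25 + 30 genotypes × 4 replicates, 60 soil
samples, 4 missions, full 14-family search — complete in a few minutes
on one core; the test suite uses reduced family/method lists and
10–20-genotype trials for pipeline checks, and its Monte-Carlo recovery
studies use g = 300, r = 4 with 200 replicates per parameter cell.
Degenerate inputs are errors, not guesses: unbalanced designs, duplicate
genotype×replicate cells, single replicates, zero total variance, zero
genotypic variance in a correlation, geographic rasters, collapsed
buffer polygons, and constant observed vectors in NSE all raise with a
named cause.

## Known limitations

- The forward model is not radiative transfer; absolute retrieval skill
  on synthetic data overstates field performance.
- Residuals are spatially unstructured; within-trial spatial trends
  (fertility gradients) are not modelled because the underlying study
  reports none.
- Genotype-by-environment interaction, narrow-sense heritability and
  marker-based relationship matrices are out of scope.
- The AIC parameter count for nonparametric models is a proxy; AIC values
  are comparable within this package only.
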