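# Methods

## The model

`overlapshift` fits Besag–York–Mollié (BYM) spatial models for one or two
species observed as per-cell densities on a masked regular lattice, and
prices the change between a present and a future (projected) scenario.

For species *s* at active cell *i* the linear predictor is

    eta_si = alpha_s + sum_k f_k(x_ki) + delta_s * z_i + v_si

* `alpha_s` — species intercept (log scale).
* `f_k` — smooth effect of biophysical covariate *k* (bottom temperature,
  chlorophyll-a, net primary production, potential energy anomaly,
  current speed, or any user field), discretised into 25 equal-width bins
  over the observed range with a first- or second-order random-walk (RW1 /
  RW2) penalty.  Smooths are *shared* between the coupled species.
* `z` — the shared intrinsic-CAR (ICAR) spatial field over the cell
  adjacency graph (queen contiguity by default, rook available): the
  **common spatial trend**, the residual spatial structure unexplained by
  the covariates.  Cells where its posterior is significantly positive are
  the joint high-density areas of the pair.  `delta_1 = 1` anchors the
  scale; `delta_2` is a free loading for the second species.
* `v_s` — iid Gaussian heterogeneity per species.

Positive densities are Gamma with mean `mu = exp(eta)` and shape `a_s`
(variance `mu^2 / a_s`).  Species with excess zeros use a hurdle: a
Bernoulli occupancy part on a logit predictor that shares the covariate
smooths and the scaled trend but has its own intercept (the binary part's
exact wiring is a modelling choice; sharing keeps the synthetic truth
identifiable, and the alternative — an independent occupancy field — would
only change the occupancy block of the design).  Expected density for
downstream metrics is `E = pi * mu` for hurdle species, `mu` otherwise.

Identifiability constraints: `z` sums to zero over active cells; each
smooth satisfies a *cell-weighted* sum-to-zero constraint (each bin
weighted by its cell count), so the smooth level and the intercept separate
on the data scale.  The RW2 null space also contains a linear trend; it is
left unconstrained (weakly regularised by a 1e-6 diagonal jitter) so
monotone covariate relationships remain representable — the convention of
the standard areal-model software.

## Inference

Conditional on the hyperparameters the model is latent-Gaussian, and the
backend is an empirical-Bayes Laplace scheme:

1. **Latent field.** Newton ascent on the penalised log-likelihood with the
   sparse precision `Q = Q_prior + A' W A`; linear constraints are imposed
   at every step by conditioning-by-kriging.  Factorisations use SuperLU in
   symmetric mode (minimum-degree ordering), which keeps a 30 x 30 joint
   hurdle fit (latent dimension ~2750) at ~20 ms per factorisation.
2. **Hyperparameters** (`tau_z`, tied `tau_v`, tied `tau_f`, gamma shapes,
   `delta_2`) maximise the constrained Laplace approximation of their
   marginal posterior on a transformed scale (log for precisions and
   shapes).  The surface can put optima many log-units from generic starts
   — a vanishing variance component drifts to its prior mode — so the
   optimiser runs bounded golden-section sweeps per coordinate (widths 8,
   2, 0.6) before a Nelder–Mead polish.  Precisions carry the historical
   Gamma(1, 5e-5) prior; log-shapes and `delta_2` carry wide normal priors.
   All are configurable.
3. **Hyperparameter uncertainty** comes from a finite-difference Hessian of
   the negative log marginal posterior at the optimum (delta-method sds;
   log-scale CIs for positive parameters).  The latent modes computed at
   the axial Hessian points also give the sensitivity `dx*/dpsi`, whose
   quadratic form with the hyperparameter covariance is added to the
   latent marginal variances — the plug-in-free part of integrating over
   the hyperparameter posterior.
4. **Skewness correction.** The joint latent mode is systematically offset
   from the marginal means for skewed likelihoods (the model fits part of
   the observation noise into the per-cell fields).  Expanding the
   log-posterior to third order and taking expectations gives the mean
   shift `delta = Sigma A' (T s / 2)` with `T_i` the third derivative of
   the log-likelihood in its predictor and `s_i` the predictor's posterior
   variance.  On a 12 x 12 gamma/ICAR test the corrected intercept matches
   a long MALA chain to ~0.005 where the raw mode is ~0.05 low.  The
   correction is exactly zero for Gaussian likelihoods, so the Gaussian
   oracle below is untouched.
5. **Monte-Carlo summaries** (DIC's expected deviance, predictive
   densities) use seeded draws from the corrected Gaussian approximation;
   every fit is therefore deterministic given its configuration.

With a Gaussian likelihood the whole scheme is exact, which the test suite
verifies against a dense closed-form GMRF conditional to 1e-6.

**DIC** is `D-bar + pD` with `pD = D-bar − D(theta-hat)`; `theta-hat` is the
(skew-corrected) posterior mean of the latent field with hyperparameters at
their estimates, the conventional plug-in.  Candidate models are all
covariate subsets whose pairwise Pearson |r| (on active cells, present
scenario) stays at or below 0.5; ranking is by DIC with the runner-up
reported when it is within 2 units (single-species convention) and the
winner flagged decisive at a 5-unit gap (joint convention) — both
thresholds configurable.

**Percent deviance explained** per covariate is
`(null − reduced) / null × 100`, where both the intercept-only null model
and the one-covariate reduced model are fitted *without* random effects:
with a free spatial field the "null" model would be nearly saturated and
the diagnostic meaningless.  Negative values (a covariate fitting worse
than the intercept) are reported and flagged, not clipped.

## Prediction and the future common trend

Future densities follow the missing-response convention: rows with
unobserved responses contribute no likelihood, so the future posterior is
the fitted latent posterior pushed through the future covariates — the
shared smooths evaluated at the future values (clamped to the binned range
with a warning) plus the same spatial and heterogeneity fields.  Summaries
are seeded Monte-Carlo over the latent approximation.

A shared static `z` cannot itself differ between scenarios, so the
present/future *common-trend comparison* uses matched scenario refits: the
joint model, with hyperparameters held at the primary fit's estimates, is
refit to the posterior-mean predicted surfaces of each scenario (strictly
positive, hence plain gamma), and the two refit trends are compared.  The
refits are symmetric and share one seed, so an identity scenario (future
covariates equal to present) yields exactly null costs — a property the
acceptance suite asserts.

## Ecological-cost metrics

1. **Relative population change** — `100 (ΣF − ΣP)/ΣP` over active cells.
2. **Overall spatial percentage difference** — share of cells whose value
   changed by more than a third, `100 |F−P| / max(|P|, floor)` per cell;
   thirds-rule categories with contiguous bins [0, 33] "fairly similar",
   (33, 67) "fairly different", [67, 100] "very different" (the verbal
   convention leaves (33, 34) and (66, 67) unassigned; we close the gaps).
   A zero present value with no floor is a hard error; a floor quantile of
   the positive present values makes the small-value caveat an explicit
   control.  Pair-level reports apply the metric to the common-trend
   surfaces (floored at a low quantile of |present trend| because trends
   are signed), per-species reports to the predicted densities.
3. **Local loss/gain** — single species: Getis–Ord G* z-scores with binary
   weights over each cell and its neighbours; hot (z > 1.96) to cold
   (z < −1.96) transitions and the reverse, as percentages of all active
   cells.  Joint: cells significantly positive in the present trend and
   significantly negative in the future (loss) or the reverse (gain), as
   percentages of the significantly-positive present area; percentages of
   the total area are also emitted because the denominator convention for
   gains is ambiguous in the source analysis.
4. **Weighted centroids** — first moments of the (positive-part) surfaces;
   displacement by the haversine formula (R = 6371 km) and the initial
   great-circle bearing binned into 8 (optionally 16) half-open compass
   sectors centred on the winds.

RMSE and the Bhattacharyya distance (−ln Σ√(p_i q_i) after positive-part
normalisation; min-shift normalisation available) compare the trend
surfaces as conventional cross-checks.  The exact normalisation the
original analysis used for signed trends is not recoverable, so it is
exposed as an option rather than fixed.

## Synthetic data

The generator stands in for survey and ocean-model products and defines the
package's study conditions:

* **Covariates**: ICAR+nugget Gaussian random fields (nugget 2/range²,
  default range 8 cells), standardised; requested cross-correlations are
  imposed exactly by empirical whitening/recolouring.  Future scenarios add
  a uniform mean shift plus a fraction `w` of an independent field,
  rescaled so the marginal sd is preserved (present–future correlation
  `1/√(1+w²)`).  Defaults emulate a warming, more stratified 2050: PEA
  +0.5 sd, NPP −0.3 sd, pattern fraction 0.3.
* **Depth**: a smooth synthetic bathymetry (mean 250 m, sd 180 m) with the
  >500 m mask applied strictly.
* **Species**: drawn from the joint model itself.  Defaults: predator
  `alpha = 1.0`, gamma shape 3; prey `alpha = 0.5`, shape 2, hurdle
  occupancy intercept 1.0 (≈30% zeros, sandeel-like); `delta_2 = 1`;
  covariate effects on the log scale of realistic magnitude (PEA −0.6·x,
  the dominant negative stratification response; NPP an interior optimum
  0.25 − 0.35(x−0.1)²; roughly one decade of density across the field
  range); heterogeneity sd 0.05; shared trend an ICAR draw scaled to
  sd 0.6.  The trend is drawn from the model's own spatial prior because
  recovery experiments are only calibrated when the truth process matches
  the prior; a localisable Gaussian bump is available for detection tests.
  Before use, the generative trend is orthogonalised against the span of
  the binned covariate smooths (and rescaled): the common spatial trend is
  *defined* as residual spatial autocorrelation unexplained by covariates,
  and without the projection a very smooth lattice draw can be almost
  exactly a function of equally smooth covariate fields, leaving the
  trend-vs-covariate split in the truth ill-defined and `delta_2`
  unidentifiable for some seeds.

Two deliberate limitations of the generator, hence of what green tests
show: it has no temporal structure (the source data are climatological
means), and the iid heterogeneity is kept small because, with a single
gamma observation per cell, lognormal cell noise and gamma dispersion are
separable only through higher-moment information (~1 nat at n = 900); with
larger heterogeneity the Gamma(1, 5e-5) precision prior resolves the ridge
by absorbing `v` into an effective shape `1/(e^{sd²}(1+1/a) − 1)`.  Real
survey data will sit on that ridge, and fitted shapes should be read as
effective dispersions.  Binned smooths also contribute a small
within-bin dispersion for steep effects.

## Problem sizes and budgets

Unit tests run on 10–25 cell-side grids; the parameter-recovery experiment
uses a 30 x 30 grid with 20 replicates; selection recovery uses 12 x 12
with 20 replicates; the packaged demonstration pipeline and the
reproduction script use 20–30 cell sides with a reduced optimiser budget
(40–120 marginal-likelihood evaluations).  These sizes keep each joint fit
in the tens of seconds on one CPU while leaving the statistical behaviour
(coverage, selection, detection) intact.

## Known limitations

* Empirical-Bayes point estimates of hyperparameters with a delta-method
  Hessian; no full integration over multimodal hyperparameter posteriors.
* The skewness correction adjusts means, not higher moments; credible
  intervals for strongly skewed per-cell quantities remain symmetric on
  the latent scale.
* Percentages of deviance explained depend on the no-random-effects
  convention above.
* Isolated cells (degree 0 after masking) are retained with their CAR
  conditional reduced to the heterogeneous effect, and logged.
* The future common trend is a model-based construction (matched refits on
  predicted surfaces); other conventions exist and would change Table-4
  style numbers, though not the identity-scenario null.
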