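# Methods

This note documents the models implemented in `reefcarb`, their
assumptions, the defaults that matter, and the design choices made where
the design was genuinely open.

## 1. Survey model

A campaign is a grid of stations (site × depth below mean sea level).
Each station carries paired 2-m benthic line-intercept transects and
0.25-m² urchin quadrats (the quadrat centred over the transect), plus
25 × 5 m parrotfish belt transects.

* **Benthic transects** record the substrate category under every
  centimetre of a tape contoured over the reef surface.  Intercepts must
  tile the contoured tape exactly once at 1-cm resolution; partial
  centimetres and tape overlaps are assumed resolved in the field.  The
  vocabulary is closed: coral (with taxon), coralline algae, *Halimeda*,
  carbonate substrate, rubble, turf/macroalgae on carbonate, sand, other
  non-carbonate.  Planar proportions are computed relative to the
  **contour** length (per unit of surveyed surface); rugosity multiplies
  only where the budget equations call for it, so surface area is never
  double-counted.
* **Rugosity** = contour length / planar length, ≥ 1 by validation; a
  reading below 1 is rejected as a tape inconsistency rather than
  silently clamped.
* **Depth standardization** subtracts a per-station tidal offset
  (config data, default 0); negative results clamp to 0 with a warning.
* **Replicate-number analysis**: the coefficient of variation of the
  most abundant species' counts over the first *n* quadrats, *n* =
  3…max.  The plateau is the smallest *n* whose successive CV changes
  stay below a tolerance (default 0.05) for *k* = 2 consecutive steps;
  both knobs are configurable because no numeric plateau rule is
  standard.

## 2. Gross carbonate production

Per transect, `gross = r·(x + ca + h)` in kg CaCO₃ m⁻² y⁻¹:

* Corals: `x = Σ_j m_j·px_j·d_j·g_j·10` over coral taxa.  Morphology
  coefficients *m* (dimensionless), skeletal densities *d* (g cm⁻³) and
  extension rates *g* (cm y⁻¹) resolve species-first, then genus, from
  editable CSV tables shipped with the package (`reefcarb/data/`); the
  shipped values are representative Indo-Pacific defaults for the common
  Hawaiian taxa and are intended to be replaced by study-specific tables.
  The engine hard-codes only the equations, the *Porites* depth-model
  coefficients and the two algal constants (all overridable).
* *Porites* extension is depth-dependent: linear `(13.37 − 0.21·z)/10`
  for z < 6 m, exponential `16.2·e^(−0.032·z)/10` for z ≥ 6 m.  The two
  branches disagree by ~0.13 cm y⁻¹ at the 6-m breakpoint; they are
  applied exactly as published, and the test suite pins both one-sided
  values.  The depth used is the transect's standardized MSL depth, not
  its design label.  Non-*Porites* rates are depth-invariant table
  values; a depth scaling for them is deliberately not applied (data to
  support one are lacking).
* Coralline algae: `ca = 0.036·pca·10` (rate in g cm⁻² y⁻¹ × 10 → kg
  m⁻²).  *Halimeda*: `h = 1.694·ph` (kg m⁻² y⁻¹).  The *Halimeda*
  constant is a deep-reef (20-m) literature rate applied wherever
  *Halimeda* occurs; in practice it occurs only on deep transects.

## 3. Bioerosion

`E_i = parrotfish_k + urchin_i + macro_i + micro_i`, every term ≥ 0.

* **Parrotfish** (station-level *k*, broadcast to the station's
  transects): per fish, bite volume `e^(1.3172+0.0624·L)/1000` cm³, scar
  proportion `logistic(−2.46142 + 0.08864·L)`, bite rate
  `60·|(4.31 + brc − 0.355) − 0.045·bitetime·L|` bites d⁻¹ with
  `bitetime` = 10 h d⁻¹ and species bite-rate constants from an editable
  table (sister-species/genus fallback).  The absolute-value structure
  and its constants are reproduced as published; their upstream
  derivation is not recoverable and deliberately not guessed.  Per-belt
  erosion multiplies by the station's coral-cover-weighted mean skeletal
  density D_k, converts days→years (×365) and g→kg (×0.001), and
  divides by the 125-m² belt area; the published factor string for this
  step is typographically garbled and is implemented per its unit
  glosses as ×365×0.001/(25×5).  The station rate is the arithmetic mean
  over the belts present (design: 6; a warning is emitted otherwise).
  With no coral at a station, D_k falls back to the unweighted mean of
  all species-level table densities (logged).
* **Sea urchins**: per individual, `a·D^b` g d⁻¹ in test diameter D
  (mm) with group-specific (a, b): diadematids (*Diadema* +
  *Echinothrix*, combined) (3·10⁻⁶, 3.2887); *Echinometra*
  (3·10⁻⁴, 1.9671); other eroding species (3·10⁻⁵, 2.6414);
  *Tripneustes gratilla* erodes nothing.  Each rate is scaled by 0.365
  (g d⁻¹ → kg y⁻¹) and 0.57 (fraction not re-ingested), summed over the
  quadrat and divided by the 0.25-m² quadrat area.  The trailing 0.25 in
  the published equations is interpreted as this per-m² normalization —
  consistent with the ×4 quadrat-to-m² density scaling used in the
  source tables.
* **Borers**: `macro = r·0.21·pmacro`, `micro = r·0.20·pmicro`.
  Macroborer substrate includes carbonate, rubble, algae-covered
  carbonate **and** coralline algae (a crust does not protect the rock
  beneath); microborer substrate excludes coral and coralline algae,
  whose net rates already include microboring.  The category→
  availability mapping is a module-level table, not scattered logic.

## 4. Net production, accretion, aggregation

* `Cp = gross + sgn·0.53 − E`; the sedimentation sign is positive while
  the observed terrigenous daily load stays below 0.05 kg m⁻² d⁻¹ and
  negative above it (smothering).
* Accretion potential (mm y⁻¹): `Cp − 0.01949·Cp²` (written
  `Cp + Cp·(Cp·(−0.01949))`), an empirical best-fit conversion that
  shrinks |Cp| toward zero for |Cp| < 1/0.01949.
* Aggregation reports mean ± SE at station, depth and overall levels.
  Accretion summaries canonically apply the conversion to the **mean**
  net production (matching the source's reporting convention); the mean
  of per-transect accretions is also emitted (`accretion_transect_mean`)
  since the two differ by a Jensen gap.  Accretion SEs are from
  per-transect accretions, which need not match an SE transformed from
  the net-production SE.  Report tables round to 2 decimals, half-up.

## 5. Cover-threshold model

`Cp_is = β₀ + f(LCC_is) + depth_is + a_s + ε_is` with depth a categorical
fixed effect and a Gaussian site random intercept.

* **Spline**: O'Sullivan construction — cubic B-splines with 5 interior
  knots at quantiles of the observed cover, boundary at 0–100% cover,
  penalized by the exact integrated squared second derivative (computed
  by 3-point Gauss–Legendre per inter-knot interval, exact for the
  piecewise-polynomial integrand).  The penalty's 2-dimensional null
  space (constants + lines) is absorbed into the fixed effects through
  the eigen-decomposition, leaving i.i.d. Gaussian random spline
  coefficients — the standard mixed-model representation.
* **Priors**: normal(0, 10⁶) on fixed effects; half-Cauchy(0, 25) on the
  three standard deviations (residual, spline, site), via the
  inverse-gamma scale-mixture expansion so every full conditional stays
  closed-form.  These concretize "diffuse"; all are overridable.
* **Sampler**: Gibbs — a joint multivariate-normal update of all
  coefficients (Cholesky solve of a ~15-dimensional system) and
  inverse-gamma variance updates.  Defaults 3 chains × 20,000 iterations,
  5,000 burn-in, thinning 5; a seed is mandatory and the fit is bit
  reproducible.  The residual variance is floored at 10⁻¹⁰ to keep the
  coefficient update conditioned on noise-free data.  Convergence is
  declared when every parameter's split-chain R̂ < 1.1; otherwise the fit
  carries a warning flag and thresholds are marked unreliable.
* **Threshold extraction**: with two sites only β₀ + mean(a_s) is well
  identified, so fitted curves are evaluated at the **average surveyed
  site** (each draw's mean site intercept added); leaving the site
  intercept at zero lets the unidentified β₀ component inflate the
  credible intervals to the boundaries.  Per posterior draw, the curve at
  the requested depth is evaluated on a 0.01%-cover grid over 0–100% and
  the smallest cover where it crosses from ≤ 0 to > 0 is the draw's
  threshold; draws with no upcrossing censor at 0 (curve everywhere
  positive) or 100 (never positive).  The point estimate is the
  upcrossing of the posterior-mean curve; the 95% credible interval is
  the 2.5/97.5 percentiles of the per-draw thresholds (per-draw roots,
  not credible-band crossings — a documented choice, since band-crossing
  intervals are not proper posterior summaries of the crossing).

## 6. Upscaling

* Collinearity screen: pairwise |r| ≥ 0.7 drops the lower-priority
  feature; priority is configuration (cover highest), since which
  collinear variable to keep is a domain judgement.  Constant features
  drop with a warning.
* Outliers: Cook's distance from the full-data OLS; flag D_i > 3·mean(D).
* PLSR: k-fold (default 10) cross-validated error per component count;
  `rule="min"` (default) or the one-standard-error parsimony rule.
* Model selection: one seeded 70:30 split; per candidate predictor set,
  backward-drop predictors with p ≥ 0.05 on the training fit and re-run;
  the candidate with the lowest test RMSE wins and is refit on all
  non-outlier data.  Training/test discipline is enforced by
  construction and asserted in tests.  Reports mirror the conventional
  model-comparison table (RMSE, R² train/test/full).
* Raster prediction requires a cover-only final model (the raster has one
  band); cover values outside 0–100 are clamped and counted, nodata
  propagates, and predictions are deliberately not truncated — negative
  predictions mean net erosion.  An optional second band applies the
  accretion conversion pixelwise.
* Raster I/O uses `tifffile` with GeoTIFF georeferencing tags
  (ModelPixelScale, ModelTiepoint, GDAL nodata) and the CRS carried as
  JSON metadata; output georeferencing is copied from the input grid.

## 7. Synthetic data

The generators emulate the census design for testing without field data:
2 sites × depths {2, 3, 6, 9, 17} m × 15 paired transects/quadrats and 6
belts per station.

* Urchin counts per quadrat are **negative binomial** (dispersion 5, not
  Poisson — reported quadrat standard errors in such surveys imply
  overdispersion), with per-depth, per-group means reflecting an
  extreme-density *Echinometra*-dominated Hawaiian assemblage
  (e.g. ~15 *Echinometra* per 0.25 m² on the shallow reef, collapsing by
  17 m).  Test diameters are truncated normal (diadematids 60 ± 15 mm,
  *Echinometra* 30 ± 8 mm, lower bound 5 mm).
* Benthic composition is Dirichlet per depth (total concentration 30),
  with coral means following the surveyed cover-by-depth profile
  (~23–35%) and *Halimeda* present only at depth.  Tapes are tiled by
  **largest-remainder apportionment** of the contour centimetres, so
  realized proportions equal the drawn ones exactly and downstream
  numerics are isolated from multinomial noise.
* Rugosity is 1 + lognormal(−1.2, 0.4) (mean ≈ 1.33, support ≥ 1);
  parrotfish are Poisson-sparse (mean 1 per belt) reflecting the
  near-negligible grazing erosion regime the package targets.
* The cover raster is a Gaussian random field smoothed to a configured
  correlation length, re-standardized and mapped through Φ and a beta
  quantile (default Beta(2, 5), mean ≈ 28.6% cover), so the marginal
  cover distribution is exactly the configured beta; a known linear
  cover→production truth (default −4 + 0.2·LCC, zero crossing at 20%)
  accompanies every raster for recovery tests.
* A hand-checkable tabletop fixture (2 transects, 2 quadrats, 1 belt)
  carries a fully hand-computed budget oracle in the test suite.

What passing tests on these data do **not** show: robustness to observer
error and taxonomic misclassification, non-Dirichlet spatial patchiness
within transects, size-structured urchin demography, classification
error in real remote-sensing cover products, or transferability of the
coefficient tables to other regions.

## 8. Problem sizes used in validation

Statistical recovery checks run at the campaign's own scale: threshold
recovery uses 20 replicates of n = 150 transects, 2 sites, with reduced
but convergent MCMC schedules (2 chains × 3,000 iterations, 1,000
burn-in — R̂ is checked on every fit); scaling-model recovery uses 50
replicates of n = 150.  Sampler correctness is verified against the
closed-form conjugate posterior on a reduced model, and every
closed-form budget equation against independent straight-line
evaluations on 1,000 random inputs at 10⁻⁹ tolerance.

## 9. Known limitations

* Ocean-acidification and physical (storm) erosion are outside the
  budget; estimates are upper bounds on realized net production.
* Crown-of-thorns predation is not modelled.
* The shipped coefficient tables are regional defaults, not measurements;
  serious use requires study-specific tables.
* The 70:30 split makes test metrics split-dependent; the split seed is
  recorded so any reported table is exactly reproducible.
* With two sites, the site-variance posterior is prior-sensitive; the
  half-Cauchy scale matters and is exposed.
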