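# Methods

`standineq` studies a single question: holding stand density, development
stage and climate fixed, does tree size *inequality* change how much a
forest stand produces, and if so, through which part of the light budget?
This note documents the models, the synthetic data they are tested on,
and the numerical choices made where the design was genuinely open.

## Stand metrics

A plot is a list of tree records: circumference at breast height
`c130` (cm), 5-year radial increment `ir5` (cm), a per-hectare weight `w`
(trees/ha, from a concentric-subplot sampling design), and a status
(alive / dead / recruited / simplified).

* Tree basal area: `g = 1e-4·c130²/(4π)` m².
* Stand basal area `G` (m²/ha) is the weighted sum over live trees;
  quadratic mean diameter `Dq = sqrt(Σ w·d² / Σ w)` (m).
* The 5-years-earlier stand is reconstructed from back-projected
  circumferences `c_prior = c130 − 2π·ir5` for surviving trees, plus
  dead trees at their recorded size (no increment is available for
  them), excluding recruits that were then below the census threshold
  (default 23.5 cm circumference ≈ 7.5 cm dbh, configurable).
* Mean annual basal-area increment:

  `dG = (1/5) Σ_i 1e-4/(4π) · (c130_i² − c_prior_i²) · w_i`  (m²/ha/yr)

  over trees alive at the end of the interval. Dead trees contribute no
  growth; recruits contribute, by default, only growth above the
  census-entry circumference (a `full` convention is available). With no
  turnover this is algebraically `(G_now − G_prior)/5`, which the tests
  assert exactly.
* Size inequality is the Gini coefficient of individual tree basal
  areas, computed over the sampled trees unweighted:

  `Gini = 2·Σ i·g_(i) / (n·Σ g) − (n+1)/n`,  g sorted ascending.

  It is 0 for identical trees and approaches (n−1)/n under extreme
  dominance. Because inventory trees carry unequal weights, a
  frequency-weighted variant (Lorenz trapezoid form) is provided behind
  a flag; the unweighted form is the default and is what all headline
  numbers use. Lorenz curves rank trees in *descending* order of size,
  so curves lie on or above the diagonal.
* Plots qualify as monospecific when one species holds ≥ 80% of the
  weighted basal area (inclusive threshold); plots with fewer than two
  live trees are excluded.
* "Simplified" trees (present but not increment-measured) receive the
  mean increment of measured conspecifics in the same 10 cm
  circumference class, falling back to the nearest non-empty class
  (equidistant ties averaged), then the species mean, then the plot
  mean.

## Production model

The response (dG, or a simulator output dV / LIE / LUE) is modelled
multiplicatively:

    y = exp(α0 + α1·WB + α2·SGDD) · G^β · exp(γ·Dq) · exp(δ·Gini) · exp(ε)

with ε ~ N(0, σ²) on the log scale. WB is the annual water budget (mm)
and SGDD the growing-degree-day sum above 5.56 °C (°C·day; computed as
Σ max(T−5.56, 0), with a raw-sum variant behind a flag). δ is the
quantity of interest: the proportional change in production per unit of
basal-area Gini, all else equal.

Fitting is OLS on `log y` (multiplicative error), giving the Gaussian
log-likelihood with the ML variance estimate; AIC counts the variance as
a parameter (`AIC = 2(k+1) − 2·logLik`). Optional standardization
centres/scales the regressors *as they enter the linear predictor*
(i.e. `log G`, not `G`); the scaling record lets natural-scale
coefficients and predictions be recovered, and log-likelihood, AIC and
LRTs are invariant to it (asserted to 1e-8). Predictions are
`exp(linear predictor)` without the log-normal mean correction
`exp(σ²/2)` by default (flag available).

A natural-scale fit of the same mean function with additive error
(`NonlinearProductionModel`, trust-region least squares initialised from
the log fit) is provided for model comparison. Its AIC is comparable to
the log-scale fit only after the change-of-variables (Jacobian)
correction — subtracting `Σ log y` from the log-scale likelihood —
implemented as `FitResult.aic_natural_scale()`. On data with
multiplicative noise the log fit wins this comparison in most
replicates; with additive noise the nonlinear fit has the lower
natural-scale RMSE. Both behaviours are tested.

Model comparison: chi-square likelihood-ratio tests between nested fits
on identical rows; `ΔAIC = AIC(without Gini) − AIC(with Gini)` so
positive values favour keeping the inequality term; backward selection
drops the least significant covariate (p ≥ 0.05, ties broken by larger p
then lexicographically) until all survivors are significant — the
with/without-Gini comparison is run explicitly regardless of whether
selection keeps the term. δ's interval is the Wald
`estimate ± 1.96·SE`.

Calibration, verified in the acceptance suite at the study conditions
(800 plots per dataset, σ = 0.3, β = 0.55, γ = −0.5, δ = −0.12): 95%
CI coverage of δ within [0.93, 0.97] and |mean bias| < 0.01 over 200
replicates; the LRT for δ = 0 rejects at 3–7% at nominal 5% over 500
replicates of 300 plots.

## Synthetic inventory generator

No plot data ship with the package; the generator emulates the
structural envelope of a large national inventory so every downstream
stage is testable:

* Circumference distributions: truncated Weibull (shape ≲ 1.5 gives
  reverse-J, uneven-aged structure; shape ≈ 6 a unimodal cohort), a
  two-component Weibull mixture, or a single uniform class. With the
  default scale of 60 cm, shape 1.1 yields a population basal-area Gini
  of ≈ 0.61 and shape 6 ≈ 0.21 (both frozen from a Lorenz-functional
  integration oracle). Randomising shape and scale across plots spans
  Gini ≈ 0–0.8, G ≈ 2–100+ m²/ha, Dq ≈ 0.1–0.8 m.
* Weights come from a three-radius concentric-subplot design (6 / 10 /
  15 m circles by size class), so the weighted formulas are exercised
  non-trivially. Stem density targets are drawn from 80–1200 stems/ha.
* Climate: WB ~ U(0, 130) mm, SGDD ~ U(400, 3500) °C·day, independent
  of structure (no soil model).
* Growth: the plot's dG is drawn from the production model above
  (defaults α0 = −2.5, α1 = 2e-3 /mm, α2 = 1e-4 /°C·day, β = 0.55,
  γ = −0.5, δ = −0.12, σ = 0.3 — chosen so typical plots produce
  ~0.2–1 m²/ha/yr and coefficients sit inside the field-reported
  ranges), then the implied 5-year basal-area growth is partitioned
  across trees ∝ g^η (η = 1.4 by default; η > 1 mimics asymmetric
  competition, η = 0 gives equal absolute growth) and inverted to
  radial increments via `c_prior = sqrt(c² − 4π·Δg)`. Shares that would
  drive `c_prior` to zero are capped with a warning and redistributed.
  With σ = 0 the tree-level records round-trip to the closed-form dG to
  1e-9 relative — the key identity connecting generator and metrics.
* Turnover: trees whose back-projected circumference falls below the
  census threshold are labelled recruits; `recruit_rate` seeds extra
  near-threshold trees to provoke this, `death_rate` adds dead trees to
  the prior state, `simplified_rate` blanks increments to exercise
  imputation. All default to 0.
* Determinism: everything flows from one `numpy` Generator seeded by the
  config; identical configs give byte-identical CSVs. A
  `TrueParamRecord` sidecar (true parameters + seed + config hash)
  accompanies every dataset.
* A vectorised plot-level path (`generate_plot_table`) draws the same
  structures and responses without materialising tree records; it is
  what the replicated calibration studies use (200 × 800 plots runs in
  ~2 minutes), and its equivalence to the tree-level path is pinned by
  the σ = 0 round-trip test.

What the generator does *not* emulate: spatial field protocol
(azimuth/distance), measurement error in circumferences, correlated
climate–structure gradients, multi-species plots with realistic
admixture. Passing calibration tests therefore demonstrates correctness
of the estimator under the stated generative model, not robustness to
those real-data complications.

## Light-competition simulator

A deliberately small individual-based model captures the mechanism —
asymmetric competition for light — with honest geometry:

* Stand: trees at uniform-random (optionally minimum-spacing) positions
  on an L × L plot with torus boundaries; dbh drawn uniformly within
  diameter classes.
* Allometry (per species preset): saturating height
  `h = 1.3 + (h_max−1.3)(1−exp(−h_rate·d))`, crown base a fixed
  fraction of height, saturating crown radius, stem volume
  `v = vk·d^e1·h^e2`. Crowns are ellipsoids (vertical semi-axis =
  half crown depth, horizontal = crown radius).
* Light: diffuse sky discretised into 5 elevation bands × 8 azimuths
  weighted like a standard overcast sky (radiance ∝ 1 + 2 sin θ),
  2500 MJ/m²/yr on the horizontal by default; rays aimed at 5 m ground
  cells. Each crown crossing captures a fixed proportion p (default
  0.8) of the ray's remaining energy, independent of path length
  (path-length/Beer–Lambert attenuation is an explicit non-goal). Torus
  wrapping is exact: each sky direction tests crowns against every
  plot-period image its wrapped rays can reach (shallow rays cross
  several periods — a fixed 3×3 image set is not enough), so energy is
  conserved to machine precision and translating the stand by whole
  ground cells leaves every tree's energy unchanged exactly.
* Growth: annual per-tree basal-area increment `Δg = a·E^b` from
  intercepted energy E (MJ/yr), synchronous update, crowns re-derived
  each year; no mortality or regeneration. Ten-year runs report
  endpoint-difference dG and dV, and LIE/LUE from the mean annual
  budget: LIE = intercepted/incident, LUE = dG per intercepted
  MJ/ha/yr (`dG = LUE × interception` holds exactly by construction).

Two preset choices deserve justification because the observable
behaviour hinges on them:

* **Light–growth exponent b < 1 (default 0.8).** Tree growth shows
  diminishing returns to light: dominant, fully lit crowns gain little
  from extra energy while suppressed trees respond strongly. With b < 1
  a stand that concentrates light on a few large individuals converts
  energy less efficiently, so size inequality depresses LUE — and the
  simulator reproduces exactly that. With b > 1 the logic inverts
  (δ_LUE > 0 and even δ_dG > 0 at b = 1.3), which the test suite
  demonstrates as a sensitivity check over b ∈ [0.7, 1.3]. b is an
  ordinary parameter of `GrowthParams`.
* **Volume exponent e1 < 2 (presets 1.75–1.9).** Stem form factor
  declines with diameter; encoding this as `v ∝ d^e1·h^e2` with e1
  slightly below 2 makes volume yield per unit basal-area growth
  highest for mid-sized trees. That is what lets inequality hit volume
  increment harder than basal-area increment (|δ_dV| > |δ_dG|): in
  unequal stands growth is concentrated in large trees whose height
  growth — and with it the cheap volume — is over. With e1 = 2 the
  composition effect reverses and |δ_dV| < |δ_dG|.

The Gini-gradient experiment holds G and Dq fixed across inequality
levels using a two-point diameter mixture solved in closed form: a
fraction f of small trees (d1) and 1−f of large (d2) satisfying
`Dq² = f·d1² + (1−f)·d2²` and the two-point population Gini
`f(1−f)(g2−g1)/ḡ = target`, with total count set by G. The solver
rejects infeasible (G, Dq, Gini) triples (it needs f > Gini). Default
experiment: 60 stands of 0.25 ha (L = 50 m) cycling through Gini
targets 0.1–0.6 at G = 30 m²/ha, Dq = 0.25 m, 10-year runs, then
production-model fits with α constant (no climate terms, matching a
simulator without site variability). At these conditions all four δ
(dG, dV, LIE, LUE) are negative with |z| > 2 and |δ_dV| > |δ_dG|; a
null design with a single structural target shows |z| < 2 in ≥ 90% of
seeds. Species presets are illustrative ("fir-like", "spruce-like",
"beech-like" differ in allometry and p), not calibrated to any field
data, so only signs and orderings — not magnitudes — are meaningful.

## Problem sizes and tolerances

* Calibration suites: 200 replicates × 800 plots (coverage/bias), 500 ×
  300 plots (LRT size) — sizes chosen so each suite completes in a few
  minutes on one core while leaving Monte-Carlo error well inside the
  asserted bands.
* Gini identities: 1e-10 against the pairwise mean-absolute-difference
  oracle; energy balance: 1e-9 relative; σ = 0 round trips: 1e-9
  relative; standardization invariance: 1e-8.
* Ray discretisation (5 × 8 directions, 5 m cells) is coarse; LIE/LUE
  are therefore discretisation-dependent quantities and only compared
  within a common sky configuration.

## Known limitations

* The simulator's δ magnitudes depend on uncalibrated presets; only the
  qualitative structure is claimed.
* LUE here is defined on basal-area production (not biomass or carbon).
* No mixed-effects or spatial-autocorrelation structure in the model
  fits; plots are treated as independent.
* The weighted Gini variant is provided but unvalidated against any
  field convention; the unweighted form is canonical here.
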