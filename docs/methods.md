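# Methods

## Scope and data model

`thermetab` analyses a single-snapshot campaign: one thermal scene, one
point weather record, one leaf sampling. The scene is a 2-D
brightness-temperature raster with labelled plant ROIs and wet/dry reference
ROIs; physiology (leaf stomatal conductance `g_s`, stem sap flow) and a
plants × metabolites abundance table are per-plant covariates. Time series,
two-source (soil + canopy) energy balance, aerodynamic stability
corrections, orthomosaic construction and MS spectral processing are out of
scope; the pipeline starts from a built raster and an annotated metabolite
matrix.

## Micrometeorology

Saturation vapour pressure uses the Tetens form
`e_s(T) = 610.78 · exp(17.27 T / (T + 237.3))` Pa, smooth and accurate over
0–50 °C; its analytic derivative supplies the slope `s`, and
`D = e_s(Ta)(1 − RH/100)`. The psychrometric constant is
`γ = c_p P / (0.622 λ)` with `c_p = 1010 J kg⁻¹ K⁻¹` and
`λ = 2.45 × 10⁶ J kg⁻¹`; air density follows the ideal gas law
(`R_air = 287.05 J kg⁻¹ K⁻¹`); default pressure 101 325 Pa (site near sea
level).

Boundary-layer resistance uses the flat-plate forced-convection
approximation `r_aH = 100 √(d/u)` with characteristic leaf dimension
`d = 0.09 m` — the width of the artificial reference leaves (ca.
12 × 9 cm) — and `r_aw = 0.93 r_aH` from the heat/vapour diffusivity ratio.
Wind speed is clamped below at `u_min = 0.5 m s⁻¹` so calm air does not
produce divergent resistances; both `d` and `u_min` are configurable. The
radiative transfer resistance is `r_R = ρ c_p / (4 σ ε T_K³)` (linearised
longwave exchange at air temperature) and combines with `r_aH` in parallel
to `r_HR`.

Net isothermal radiation is parameterised as `R_ni = α · SWR + L_iso` with
shortwave absorptance `α = 0.5` and an additive isothermal longwave term
defaulting to 0 (longwave exchange is then carried entirely by `r_R`). A
single station-level `R_ni` formulation cannot be recovered from a weather
record alone, so both knobs are exposed; absolute conductances shift with
`α`, while ranks, indices and all round-trip properties do not.

## Energy balance and indices

The forward model and its inversion are exact algebraic counterparts; the
inversion recovers the forward resistance to ~1e−14 relative in double
precision (tested at 1e−8 over random weather). The forward ΔT is strictly
increasing in `r_c` — its derivative is proportional to
`A·E + B·C` with all four terms positive — so canopy temperature orders
plants by conductance. Convergence to the dry asymptote
`ΔT∞ = r_HR R_ni / (ρ c_p)` is first-order in `1/r_c` with coefficient
`s·r_HR/γ + ρ c_p D/(γ R_ni)`; under hot, dry midday conditions the
relative deviation at `r_c = 10⁶ s m⁻¹` is a few 1e−4.

Inverted resistances are clipped to `[0, 10⁵] s m⁻¹`: noisy canopy pixels
can fall below the wet limit (negative algebraic solution, flagged
`clipped_low`) or above the dry asymptote (flagged `clipped_high`). Index
singularities (`Tc` exactly at a reference) return signed infinities with a
warning rather than raising, because noise legitimately crosses the
references.

Measured reference ROI temperatures are used when present; the
energy-balance limits (`r_c = 0` and `r_c → ∞`) provide a model fallback.
If the dry reference does not exceed the wet one the pair is returned
un-validated with a degenerate-reference warning so downstream indices can
be flagged.

## Scene handling

Temperatures are Kelvin internally and Celsius only at user interfaces
(avoids sign errors in radiative terms). Brightness is converted to surface
temperature with the graybody fourth-root inversion `Ts = Tb ε^(−1/4)`,
canopy ε = 0.96 and reference ε = 0.95; reflected sky radiance is
neglected, which under clear midday skies biases all ROIs by a common small
offset that cancels in the indices. ROI aggregation is a 5 % symmetric
trimmed mean with a 10-pixel minimum — robust to occasional soil pixels
leaking into a canopy ROI. Rasters round-trip through single-band float32
TIFF, NPY or CSV with a JSON sidecar (pixel size, origin, emissivities);
ROIs are named rectangles or polygons in 0-based, row-major pixel
coordinates with half-open rectangle bounds. Canopy delineation itself is
an input: the package performs no segmentation.

## Chemometrics

Predictors are autoscaled (mean 0, SD 1, ddof = 1); the response is
centered but not scaled, the single-response chemometrics convention.
Zero-variance metabolites are dropped with a warning before scaling.

PLS uses the orthogonal-scores NIPALS algorithm, exact for a single
response: `w_a ∝ X_aᵀ y_a` (unit norm), `t_a = X_a w_a`, loadings and
deflation per component; coefficients `B = W (PᵀW)⁻¹ q`. Weight vectors are
oriented so their largest-magnitude element is positive, removing the sign
indeterminacy. Score columns are mutually orthogonal by construction and
the full-rank fit reproduces ordinary least squares on the predictor span.

Cross-validation is leave-one-out by default — natural at n = 18 — with
seeded k-fold available. Reported per component count: raw CV RMSEP, the
bias-corrected (adjusted) RMSEP
`MSEP_adj(a) = MSEP_train(a) + MSEP_cv(a) − mean_k MSEP_all(model₋ₖ, a)`
(the correction term is each fold model's error over all n samples), the
cross-validated R² (1 − PRESS/TSS) and the fitted R². Component selection
is the argmin of the adjusted RMSEP over 1..max components, ties toward
fewer. Both R² variants are reported because field studies often do not
state which definition they print.

VIP scores weight squared PLS weights by the y-variance each component
explains (`SS_a = q_a² t_aᵀt_a`); their squares average to 1, and the
above-mean rule defines the selected metabolite set. Note a finite-sample
property: with ~60 predictors and n = 18, a handful of unlinked metabolites
sit above the mean-VIP threshold by sampling variability even when the
linked metabolites carry no noise at all — selection should be read as a
ranking with a soft threshold, not a sharp support recovery.

Missing values are imputed by a seeded chained-prediction imputer with
tree-ensemble regressors (default), or column means, or k-nearest samples;
observed cells are never modified, and a metabolite with no observed value
raises. PCA overviews are centered (optionally autoscaled) with
explained-variance fractions from the covariance eigenvalues.

## Treatment statistics

Per variable: classical one-way ANOVA, Tukey HSD pairwise comparisons
(Tukey–Kramer for unbalanced designs such as sap flow measured in only two
treatments), a compact letter display built by the insert-and-absorb
algorithm (processing order and tie-break fixed as W, C, D), and log2
fold-changes of treatment means versus the watered control, reported as
significant only when the corresponding Tukey comparison rejects at α.
No correction is applied across the 60 metabolites beyond the
per-metabolite Tukey procedure; an FDR column can be added by the caller
from the reported per-metabolite p values.

## Synthetic campaign generator

The generator defines the study conditions the tests run under:

- **Weather** — Ta 31.4 °C, RH 41.7 %, u 0.91 m s⁻¹, SWR 659.5 W m⁻²,
  P 101 325 Pa (a Mediterranean midday flight), optionally jittered.
- **Design** — treatments W/C/D, 6 plants each (n = 18).
- **Conductance** — per-plant `g_c` lognormal around treatment means
  0.15/0.04/0.02 mol m⁻² s⁻¹ (W/C/D) with coefficient of variation 0.4;
  lognormal keeps conductances positive and right-skewed, and cv = 0.4 is
  representative of the within-treatment spread such campaigns report.
- **Scene** — row-structured rectangular canopies (12 × 12 px at
  0.025 m/pixel, one row per treatment), soil painted 3 K above the dry
  reference, wet/dry reference patches from the energy-balance limits,
  additive Gaussian sensor noise SD 0.05 K (uncooled-microbolometer
  sensitivity class). Painting goes through the same emissivities the
  extractor inverts, so the zero-noise round trip is exact.
- **Physiology** — `g_s = g_c + ε` and `sap = 0.23 g_c + 0.005 + ε'`, noise
  SDs calibrated from the realised conductance spread so the population R²
  hits the targets (0.75 and 0.78); values floored at a small positive
  number since a conductance measurement cannot be negative (this censors
  the low tail slightly and nudges realised R² upward). Sap flow is emitted
  only for W and D, mimicking gauges installed in two treatments.
- **Metabolome** — 60 metabolites; six influential ones (malate and
  myo-inositol positive, caffeate and three flavonol glycosides negative)
  linear in standardised conductance with effect size 1 over noise SD 1/3
  (SNR 3 — recoverable but not trivial); the remainder are block-correlated
  noise (blocks of 6, inter-metabolite correlation 0.3) on a baseline of 10
  so abundances stay positive; 2 % of cells masked at random. True effect
  sizes in real leaves are unknowable from summary statistics; these are
  exercise parameters, chosen once.

What the generator does **not** emulate: treatment effects on the 54
background metabolites (so the fraction of significantly changed
metabolites is far below what real campaigns report), metabolite–metabolite
biochemical structure beyond block correlation, within-canopy temperature
gradients, soil/canopy mixed pixels, and georeferencing error. Passing
tests therefore demonstrate correctness of the estimators and the
recoverability of planted structure at realistic n and noise — not that
real field data will behave this tamely.

## Numerical and design choices

- Seeding: every generator is a pure function of (parameters, seed); the
  pipeline derives stage seeds from the master seed via a PCG64 stream.
- Problem sizes in the repeated-run experiments (50 seeded metabolome
  recoveries, 100 end-to-end scene runs in the test suite; 20 and 30 in the
  acceptance script) were chosen to give stable rate estimates at desk
  scale.
- The inversion's `rc_max = 10⁵ s m⁻¹` ceiling corresponds to
  `g_c ≈ 4 × 10⁻4 mol m⁻² s⁻¹`, an order of magnitude below the driest
  treatment mean — effectively a closed stomate.
- Ties in component selection go to fewer components (parsimony); ties in
  letter assignment follow treatment order W, C, D.
- The compact-letter algorithm is exact for the 3-group designs used here;
  for many groups insert-and-absorb is a heuristic that can emit
  non-minimal letter sets.

## Known limitations

- Absolute `g_c` depends on the `R_ni` and boundary-layer parameterisations;
  only relative comparisons, indices and round-trip properties are
  parameterisation-free. Field use should calibrate `α` (and `d`) against
  ground-truth conductance.
- The graybody correction ignores reflected longwave; under overcast skies
  the wet/dry references absorb this bias, the absolute temperatures do not.
- LOO RMSEP curves at n = 18 are noisy; the adjusted (bias-corrected)
  variant damps but does not remove this, and selected component counts
  vary across seeds.
- PLS/VIP selection at p ≫ n is a ranking, not support recovery (see
  above).
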