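# Methods

`otolithchem` reconstructs environmental exposure histories of fish from
the trace-element chemistry of their otoliths and relates those histories
to basin-scale hydrography with repeated-measures mixed models.  This note
documents the models, the numerical choices, and what the synthetic data
generator does and does not emulate.

## The measurement and its processing

An LA-ICP-MS line scan across an otolith section, core to dorsal edge,
yields element mass fractions (ppm) for Mg, P, Mn, Sr and Ca at regular
distances.  Processing steps:

1. **Validation.** Distances strictly increasing, non-negative
   concentrations, Ca > 0; rows with non-finite values are dropped with a
   logged count.
2. **Mg interference correction.** Instrument batches affected by the
   ⁴⁸Ca²⁺ polyatomic interference on ²⁴Mg⁺ overestimate Mg by a constant
   factor; Mg from those batches is multiplied by 0.6
   (`CorrectionConfig.mg_interference_factor`, applied to ppm before ratio
   computation — the order is immaterial for Mg:Ca and merely rescales
   Mn:Mg).  A flag guards against double application.
3. **Molar ratios.** Me:Ca (mmol/mol) = (Me_ppm/M_Me)/(Ca_ppm/M_Ca)·1000
   with atomic masses Mg 24.305, P 30.974, Mn 54.938, Sr 87.62, Ca 40.078
   g/mol.  Mn:Ca is carried in µmol/mol (its natural magnitude in cod
   otoliths, a few µmol/mol), the others in mmol/mol.  Mn:Mg is computed
   pointwise and flagged undefined where Mg = 0, never fabricated.
4. **Diagenetic spike censoring.** Archaeological otoliths carry narrow
   Mn spikes from post-depositional alteration in cracks.  Points whose
   ratio exceeds mean + 3·sd are masked, iterating the mean/sd on the
   surviving points until none exceed.  The statistics are computed on the
   **log scale** by default: the ratios are strictly positive with
   multiplicative measurement error, so the raw-scale rule systematically
   trims the upper seasonal wing of honest points, while the log-scale
   rule catches the injected spikes without false positives in the
   truth-guided simulations of the test suite.  `spike_log_scale=False`
   restores the raw-scale variant.  Censored points are flagged, not deleted, in all
   outputs.
5. **Proximal-axis normalisation.** When the dorsal axis is unusable,
   proximal-axis scans are rescaled linearly onto the dorsal axis
   (distance × dorsal/proximal radius); ratios are untouched.

## Chemical ageing

Otolith Mg:Ca and P:Ca cycle seasonally, high in the growth season and low
in winter, one cycle per year of life.  Ageing is extrema-based:

- Each profile is smoothed with a Gaussian kernel
  (`smoothing_bandwidth_um`, default 40 µm — well under the narrowest
  annual increment of an old cod, a few hundred µm) excluding censored
  points; if the bandwidth falls below the sampling step, a 3-point moving
  average substitutes.
- Local minima with prominence ≥ `min_prominence` (default 0.10) of the
  profile's interquartile range are candidate winter boundaries.
- Candidates from the two elements within half a bandwidth of each other
  count as the same winter and their positions are averaged with
  `element_weights`; an unmatched candidate is accepted only at twice the
  prominence threshold (and flags the fish low-confidence).
- Annual increments never widen with age, so two soft merge rules apply: a
  boundary closer to its predecessor than `min_increment_fraction`
  (default 0.3) of the preceding increment is merged (deeper minimum
  kept), and a first zone much narrower than the second marks a spurious
  early minimum and is dropped.

Age = number of interior boundaries; zones (age + 1 of them, half-open,
covering the transect) are labelled backwards from the catch year, the
partial edge zone included.  Per-zone means over uncensored points give the
fish-year proxy rows; zones with < 3 usable points are flagged, never
dropped.  The whole procedure is deterministic and invariant to uniform
rescaling of the ratios.

## Proxies and growth

- **Hypoxia exposure:** annual mean Mn:Mg.  Dissolved Mn rises under low
  redox; dividing by Mg adjusts for growth effects on uptake.  Averaged
  pointwise within zones by default (`mn_mg_mode="ratio_of_means"` for the
  alternative).
- **Metabolic status:** annual mean Mg:Ca.
- **Salinity habitat:** annual mean Sr:Ca, split into four groups at 3.0,
  4.0 and 4.6 mmol/mol with half-open-upward intervals ([3.0, 4.0) → 2,
  boundary values assigned upward — range notation like "3.0–4.0" is
  ambiguous at its endpoints, so the convention is fixed here and tested.  Salinity in PSU is separately predicted from Sr
  concentration via exp((ln Sr − 6.241)/0.442); the equation and the
  grouping play distinct roles and are deliberately not interconverted
  (their scales are mutually inconsistent under a molar conversion, an
  artefact of the external calibration).
- **Back-calculated length:** biological-intercept method,
  L(O_a) = TL + (O_a − O_c)(TL − L_i)/(O_c − O_i), anchored at hatch
  (L_i = 4 mm, O_i = 10 µm); O_a for a zone is the zone's outer boundary,
  so the edge zone reproduces the catch length exactly.  Fish without a
  measured length get TL = 0.1323 · dorsal radius (µm) − 31.033 mm.

## Environmental covariates

The hydrographic record carries annual mean DO (ml/l, 30–90 m), quarter-4
temperature and salinity at 30–90 m, and basin anoxic/hypoxic volumes
(km³).  DO is converted to percent saturation against the Benson–Krause
equilibrium solubility as fitted by Garcia & Gordon (coefficients in
`hydrography.py`, computed directly in ml/l; validated against the
published freshwater table at 10 °C to < 0.5%).  The conversion uses the
same-year Q4 temperature and salinity.  The 3-year moving average is
centered, with the available 2-year partial window at the series ends
(`edges="na"` switches to missing).  Covariates join fish-year rows by
calendar year; rows outside the 1960–2019 fit window are kept but flagged
`in_model=False`.

## Repeated-measures models

Three models, all with individually varying fish measured repeatedly over
their lives:

| model | response (log) | fixed effects | random effects |
|---|---|---|---|
| hypoxia | annual mean Mn:Mg | anoxic volume, salinity, age | (age \| fish), (1 \| year) |
| metabolic | annual mean Mg:Ca | DO %sat, temperature, age | (age \| fish), (1 \| year) |
| growth | back-calc. length | age (categorical), per decade | (1 \| fish) |

Age-0 rows are excluded from the proxy models (juveniles occupy inshore
habitat with different chemistry); rows with non-positive response cannot
be logged and are dropped with a count.

The crossed design — correlated random intercept and age slope per fish
*crossed* with a random year intercept — is fitted by a dedicated profiled
REML routine (`lmm.py`): fixed effects and the residual variance are
profiled out and the criterion minimised over the relative covariance
factor (per-fish lower-triangular 2×2 plus a year scale) with L-BFGS-B
from a fixed deterministic start (Powell polish on non-convergence).  The
linear algebra is the standard mixed-model-equations Cholesky
factorisation, dense because q = 2·n_fish + n_years stays modest.  Fits
agree with lme4 to ~4 significant figures on fixed effects and variance
components (tested).  Boundary estimates (a variance scale below 1e-4)
flag the fit singular; non-convergence flags rather than raises.

**Inference.** Wald t statistics use Satterthwaite degrees of freedom:
df_j = 2·C_jj²/Var(C_jj), with the variance of the variance-parameter
estimates taken from the numerically differentiated REML information
matrix.  This matters: a covariate such as anoxic volume varies only
between years, so its effective df is of order the number of years, and
residual df would badly overstate the evidence.  With Satterthwaite df the
fixed-effect tests hold their nominal 5% size to within the Monte Carlo
band in our null simulations at 60 fish / 12 years with study-like
repeated-measures depth (ages to 8).  With very small cohorts of
short-lived fish (2–3 rows each) many fits sit on the slope-variance
boundary and the REML standard error of the age effect runs slightly
small, inflating its rejection rate above nominal — a known small-sample
limit.  `df_method="residual"` restores the naive choice.

**R².** Marginal and conditional R² follow the variance-partition
definition: var(Xβ̂) over, respectively, var(Xβ̂) + var_random + σ², with
var_random = Σ_f[0,0] + 2·Σ_f[0,1]·mean(age) + Σ_f[1,1]·mean(age²) +
σ²_year evaluated at the observed ages.

**Multicollinearity.** VIF_j = 1/(1 − R²_j) on the fixed-effects design;
VIF > 5 flags a problematic predictor; exact collinearity reports ∞.

**Nonparametric comparisons.** Within each salinity group, decades with at
least `min_n` (default 5) fish-year values enter a Kruskal–Wallis test;
only when it rejects at 0.05 do all pairwise two-sided Wilcoxon rank-sum
tests run, Bonferroni-multiplied by the number of pairs tested within that
salinity group (the family is all retained pairs in the group; samples are
independent fish-years, hence rank-sum rather than paired).

## The synthetic generator

`synthetic_data` emulates the study system with known ground truth.

- **Environment.** Anoxic volume: baseline 150 km³ with a post-1999 linear
  ramp of 55 km³/yr and 15% lognormal interannual noise; hypoxic volume =
  2×anoxic + 600 km³.  DO 5.5 ml/l declining 0.025 ml/l/yr (sd 0.35);
  Q4 temperature 5 °C (+0.01 °C/yr, sd 0.5); Q4 salinity 8.5 PSU
  (−0.005 PSU/yr, sd 0.45).  The interannual noise is not decoration: with
  deterministic trends the year-level covariates would be collinear and
  the fixed effects unidentifiable.
- **Cohort.** Catch decades 1930s–2010s (uniform by default), ages at
  catch 1–8 (mode 2–4), quarter-4 catches, von Bertalanffy growth
  (L∞ = 1150 mm, k = 0.18 /yr, t₀ = −0.3 yr — chosen so a 1990s-era cod
  reaches ~850 mm by age 7), 8% lognormal scatter on catch length.  The
  otolith radius at capture inverts the length regression (3% noise);
  interior annulus radii follow the biological-intercept line, making
  back-calculation exactly self-consistent.  Hatch is idealised at the
  start of the birth calendar year so growth zone *a* spans calendar year
  birth + *a* exactly (cod spawn in spring; the simplification shifts
  seasonal phase, not structure).
- **Chemistry.** Annual levels follow log-linear links mirroring the
  fitted models: ln Mn:Mg = −2.526 + 8·10⁻⁴·anoxic − 0.10·salinity −
  0.12·age; ln Mg:Ca = −2.91 + 0.006·DO% + 0.04·temp − 0.10·age; Sr:Ca =
  1.2 + 0.28·habitat salinity (fish-level habitat offset sd 2.5 PSU, Age-0
  fish 2 PSU fresher), spanning all four salinity groups.  Random effects
  (fish intercept sd 0.25, age-slope sd 0.06, correlation −0.3; year sd
  0.12; fish-year residual 0.10) are drawn exactly as the models assume,
  so parameter recovery is well-posed.  Within a year, Mg:Ca and P:Ca are
  modulated sinusoidally in the *time* domain (amplitudes 0.30/0.40,
  winter minima at integer ages, shared phase by default with the offset a
  scenario parameter) and mapped to distance through the radius-at-age
  curve, so increments shrink with age.  Mn shares Mg's within-year
  modulation, which keeps the pointwise Mn:Mg constant within a year and
  the annual-mean truth exact.  Ca is the constant aragonite matrix
  (400 780 ppm).  Measurement noise is multiplicative lognormal per sample
  per element (default sd 0.15; 0.01 for Ca).
- **Truth.** Per fish-year: calendar year, annulus radius (zone outer
  boundary), length at zone completion, driver values, link-level annual
  ratios, and the realised noiseless *discrete* zone means over the actual
  sample grid (the quantity a perfect downstream pipeline would recover,
  well-defined on a finite grid where the continuous integral is not).
- **Prehistoric fixtures.** `neolithic_scenario()`: no ramps or trends,
  low anoxia, higher Mg:Ca baseline, diagenetic Mn spikes on (50× over one
  sample, positions recorded in the truth table).
- **Fast path.** `generate_annual_table` emits fish-year rows straight
  from the links — identical statistical structure, no transects — used
  for the replicate simulation studies.

What the generator does **not** emulate: instrument drift and
quantification against standards, fine-scale migration (habitat salinity
is a static fish-level offset), within-year environmental excursions,
age-reading error in the truth itself, and any mechanistic
biomineralisation.  Passing recovery tests therefore demonstrates the
pipeline's internal consistency under the stated error model, not
robustness to every field artefact.

## Validation studies and problem sizes

`otolithchem.validation` (driven by `scripts/acceptance.py`) recomputes:
formula fixed points; age recovery on 24 noiseless fish (ages 1–8,
expect 100% exact) and 200 fish at 15% noise (expect ≥ 90% within ±1
year); type-I error of each Wald test over 500 null replicates at 60 fish
× 12 years; 95% CI coverage over 100 replicates at 60 fish × 30 years;
sign recovery of all six generating coefficients in one 300-fish
study-scale fit; Kruskal–Wallis null rejection over 500 replicates; and
pipeline row-conservation plus bit-identical reruns at a fixed seed.
Replicate cohort sizes are deliberately smaller than the headline 300-fish
study so the full battery runs in minutes on one CPU.

## Known limitations

- Satterthwaite df are approximate; very small cohorts with frequent
  boundary fits are mildly anticonservative (above).
- The ageing consensus rule is an explicit stand-in for expert judgement
  on discordant Mg/P cycle counts; at 15% noise it over-ages roughly a
  quarter of fish by one year (spurious minima), which is within the
  ±1-year recovery band but not error-free.
- Predicted salinity (PSU) from Sr ppm inherits the external calibration's
  scale and should be read comparatively, not absolutely; habitat grouping
  uses Sr:Ca thresholds and is unaffected.
- The edge (catch-year) zone is a partial year yet contributes an annual
  mean like any other; its chemistry under-samples the winter season.
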