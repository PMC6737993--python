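# Methods

This note documents the model equations as implemented, the numerical
and design choices made where the procedure was genuinely open, what
the synthetic trial generator does and does not emulate, and the known
limitations — including where the package's output deliberately differs
from published table values.

## Forward model

All yields are kg grain/ha, supplies and uptakes kg nutrient/ha.
Nutrients are indexed `i, j, k ∈ {N, P, K}`, `i ≠ j ≠ k`.

**Uptake (step 2).** For supplies `S_i, S_j` and crop coefficients
`a_i < d_i` (kg grain per kg nutrient at maximum accumulation /
dilution) and minimum uptakes `r_i`:

```
U_i(j) = S_i                                  if S_i < r_i + (S_j−r_j) a_j/d_i
       = r_i + (S_j−r_j) d_j/a_i              if S_i > r_i + (S_j−r_j)(2 d_j/a_i − a_j/d_i)
       = S_i − ¼ (S_i − r_i − (S_j−r_j) a_j/d_i)²
               / ((S_j−r_j)(d_j/a_i − a_j/d_i))   otherwise
```

`(S_j − r_j)` is floored at 0; a partner supply at or below its minimum
then forces `U_i(j) = min(S_i, r_i)` and a zero yield downstream. The
function is continuous and non-decreasing in both supplies and never
exceeds `S_i`. The per-partner uptakes are merged with
`U_i = min_j U_i(j)` (the limiting partner governs); a `mean` option is
exposed (`uptake_combine`) because the merge rule is a convention, not
part of the published equations.

**Yield ranges (step 3).** `Y_ia = a_i (U_i − r_i)`,
`Y_id = d_i (U_i − r_i)`, floored at zero for `U_i ≤ r_i` — negative
yields are meaningless.

**Pair combination (step 4).** With cap `m = min(Y_jd, Y_kd, Ymax)` the
pair estimate interpolates parabolically from `Y_ja` (reached at net
uptake `x = Y_ja/d_i`) to `m` (at `x = m/a_i`). Guards: `m ≤ Y_ja`
returns `Y_ja` (collapsed parabola); `x` is clamped into
`[Y_ja/d_i, m/a_i]`, which keeps `Y_ij ∈ [Y_ja, m]` — outside that
interval the raw parabola would dip below the lower knot or descend
past its apex. `YU` is the mean of the six ordered pair estimates,
clipped to `[0, Ymax]`, and zero whenever any `U_i ≤ r_i`.

The engine is verified against an independent straight-line
transcription of the four steps on a 20³ supply grid (≤ 1e−9 relative)
and by property tests (continuity, monotonicity, bounds).

## Supply equations

Indigenous supplies are evaluated from stored equation records keyed by
(zone, nutrient, source). Two sources ship as YAML data: the savanna
calibration and the default forms. Units are fixed at read time —
OC_tot, N_tot g/kg; P_av mg/kg (Mehlich-3); K cmol_c/kg; pH in water
1:1 — because unit confusion is the dominant failure mode for these
regressions. Negative evaluations (possible at low pH / low P with the
calibrated intercepts) are floored at zero and logged. Total supply
adds `R_i F_i` with zone-average recovery fractions bounded to [0, 1];
plot-level recovery values may be negative and are retained.

## Parameterization pipeline

Order of operations, and why it matters:

1. **Screening.** Squared Mahalanobis distance of each plot's
   (soil, yield, stover, uptakes) vector against the classical mean and
   covariance, cut at the chi-square `1 − α` quantile (α = 0.05
   default); a minimum-covariance-determinant option exists. A singular
   covariance falls back to the pseudo-inverse with a warning.
2. **Field-level 80/20 split** (seeded; all plots of a field stay
   together) into calibration and validation sets.
3. **Minimum uptake** `r_i` = smallest uptake among calibration control
   plots with non-zero grain yield. Computed before the envelopes
   because the envelope slopes pass through `(r_i, 0)`.
4. **Efficiency envelopes.** Plots with grain harvest index < 0.40 are
   excluded here (and only here): a low GHI flags stress by factors
   other than nutrition, which corrupts efficiency estimates but not
   minimum uptake or supply fitting. Each remaining plot with
   `U_i > r_i` contributes the slope `grain_yield / (U_i − r_i)`;
   `a_i, d_i` are the 2.5th and 97.5th slope percentiles (configurable
   `q_low`, `q_high`). The estimator is order-invariant and
   scale-consistent.
5. **Supply regression.** Best-subset search over the five soil
   predictors (subsets up to two terms) and five families — linear,
   polynomial (per-term powers 2, 3), logarithmic, exponential
   `c0 + c1 e^{c2 x}`, and Cauchy `c0 + c1 / (1 + ((x−c2)/c3)²)`, the
   last two single-predictor nonlinear fits with data-scaled bounds.
   Selection by minimum BIC; ties break toward fewer terms, then family
   order. OLS uses one 3σ residual-trimming pass for the coefficients
   (a single near-barren field otherwise drags the fit) while model
   comparison uses full-sample RSS with trimmed contributions capped,
   so flexible candidates gain no advantage from discarding points.
   The "Cauchy" family's exact form is an interpretation; it is
   documented here as such.
6. **Recovery fractions** from per-field NPK/omission plot pairs,
   averaged per zone, clipped into [0, 1] with a warning.

## Balanced uptake requirements

The requirement curve answers: what uptake triple reaches a target
yield with no nutrient in accumulation or dilution excess? The search
implemented is fixed-ratio supply scaling iterated to an uptake-ratio
fixed point: starting from supply shares proportional to
`r_i + Y/((a_i+d_i)/2)`, the direction is scaled by a 1-D root find
(`brentq`; `YU` is monotone in the scale) until `YU` equals the target,
the direction is replaced by the resulting uptake shares, and the map
is iterated to a fixed point. Plain iteration converges linearly
(observed ratio ≈ 0.85), so the loop applies Steffensen (vector Aitken)
acceleration — convergence in < 10 cycles at a 1e−6 relative share
tolerance, 100-cycle cap. At convergence the three yield ranges overlap
at the target (`max_i Y_ia ≤ Y ≤ min_i Y_id`), verified in tests, and a
plain bisection along the converged direction reproduces the uptakes to
0.1%.

Reported quantities per target: uptakes `U_i`, reciprocal physiological
efficiency `RPhE_i = 1000 U_i / Y` (kg nutrient per tonne grain), and
`PhE_i = 1000 / RPhE_i`. Targets at the yield potential are allowed but
uptakes grow steeply near the asymptote and results there are
tolerance-sensitive. Reporting rounds RPhE to 0.1 kg/t.

**Shape of the curve.** Because `r_i > 0`, the per-tonne requirement
`U/Y = r/Y + 1/eff` diverges as `Y → 0`: RPhE *falls* over roughly the
first half of the yield range before dilution drives it up again. The
uptake-target relation itself is near-exactly linear below half the
potential (R² ≥ 0.99) and the per-tonne requirement is non-decreasing
from 60% of the potential upward; both are tested.

## Validation statistics

RMSE, squared Pearson correlation, Willmott's index of agreement and
percent bias, computed on kg/ha and reported in t/ha at two decimals.
The index of agreement is implemented in its standard form
`d = 1 − Σ(o−p)² / Σ(|p−ō| + |o−ō|)²` so perfect agreement scores 1;
the source formula for this statistic is sometimes printed without the
"1 −", which would score 0 for perfect agreement and contradict its
interpretation. PBIAS is positive when the model underestimates.
R² is symmetric and bias-blind (an anti-correlated series scores 1),
which is why it is never reported alone.

## Synthetic trial generator

The generator emulates the statistical structure the pipeline assumes,
with defaults fixed at the study conditions:

- **Soils**: truncated lognormals per property matching the zone-wise
  means, CVs and ranges (NGS and SS sets built in); organic C and total
  N share a latent factor (ρ = 0.8, configurable — the between-property
  correlation is an assumption, not a published value).
- **Supplies**: zone supply equations plus a field-level Gaussian
  residual (NGS σ = 17/4/38, SS 8/3.5/28 kg/ha for N/P/K) sized so the
  equations explain roughly half to two-thirds of supply variance, as
  their published fit statistics indicate. Without this residual the
  refitted equations would score R² ≈ 1, unlike any real calibration.
- **Design**: six treatments per field (control, −N, −P, −K, NPK,
  NPK+) at zone rates (NGS 140/50/50, SS 120/40/40 kg/ha N/P/K); the
  NPK+ treatment is generated identically to NPK (secondary and
  micronutrients carry no yield effect by default); season and variety
  labels carry no effect.
- **Noise**: multiplicative lognormal on yield (sd 0.15) and uptakes
  (sd 0.10) applied after the deterministic model; grain harvest index
  from a truncated normal (0.46 ± 0.05 on [0.25, 0.65]); tissue
  concentrations are back-computed from the noisy uptakes and a
  per-nutrient grain allocation (N 0.62, P 0.75, K 0.25), so the
  uptake-tissue identity holds exactly on every record.
- **Subsistence fields**: three fields per nutrient have that
  nutrient's supply pinned just above `r_i` (factor 1.02–1.30),
  standing in for the near-barren fields every large on-farm survey
  contains. They are what makes the extreme-value estimator `r_i`
  identifiable, and they are population structure, not noise — the
  noise-free configuration keeps them.
- **Outliers** (2% of plots by default): one component — a yield or a
  single nutrient uptake — shifted upward by 5–9 column standard
  deviations, with tissue data rebuilt consistently. A proportional
  inflation of a whole plot would stay on the yield-uptake correlation
  and be invisible to a distance-based screen; isolated implausible
  values are what screening targets.

Everything runs off one seeded generator; a fixed seed makes the full
generate → fit → validate pipeline bit-reproducible.

What the generator does **not** emulate: spatial autocorrelation
between fields, season × field interactions, weather-driven yield
variation, measurement error in the soil covariates, or any systematic
deviation of the field response from the model equations. Passing
recovery tests therefore show the pipeline is consistent — that it
recovers the data-generating parameters when the model family is
correct — not that the model family describes real savanna fields.

## Problem sizes

Unit and property tests run on grids up to 20³ supply triples and
simulated trials of 30–170 fields (≈ 180–1000 plots); the recovery
checks use 84 fields (≈ 500 plots). The full suite and the acceptance
script each complete in well under a minute on one CPU.

## Known limitations

- **Balanced-requirement table values.** The published balancing
  procedure behind the zone requirement tables is not described in its
  source, and its printed values cannot be regenerated from the printed
  coefficients under the canonical equations: the printed 6 t/ha uptake
  triples evaluate to ≈ target/0.85 under steps 3–4 in all three zones
  (a yield-basis inconsistency); the SS column's P efficiencies at
  6–10 t fall below `a_P`, implying luxury uptake incompatible with
  "balanced" nutrition; SS per-tonne values are constant in the target,
  contradicting the dilution trend; and the printed NGS PhE values are
  not the reciprocals of the printed per-tonne uptakes. Several
  candidate procedures (uptake-ratio fixed point under both merge
  conventions, pair-yield equalization, fixed supply directions from
  zone-mean soils, minimum-total-uptake and maximum-yield allocations)
  were evaluated; none reproduces all printed values. The package
  implements the fixed-point procedure described above and reports its
  output; the acceptance tests that compare against the printed table
  fail and are left failing by design.
- **Envelope recovery under noise.** Pointwise slope quantiles at
  (0.025, 0.975) are inflated by measurement noise: under the default
  multiplicative noise the 97.5th percentile overshoots `d` by up to
  ~e^{1.96·0.18} ≈ 1.4, so envelope recovery to ±10% is not achievable
  at that noise level with this (standard) estimator; at low noise
  recovery is within a few percent, except `d_K` in K-rich zones where
  dilution is rarely expressed at all — an identifiability limit of the
  data design, not of the code.
- **Uptake–supply attenuation.** Omission-plot uptake slightly
  underestimates supply wherever the omitted nutrient is not fully
  limiting, so supply-equation refits are biased by a few percent even
  on noise-free data; the same approximation is inherent to the
  original calibration approach.
- The model treats nutrients as the only limiting factor: no water,
  temperature or pest stress, no secondary/micronutrient response, and
  no conversion of uptake requirements into fertilizer recommendations.
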