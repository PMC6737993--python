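# quefts

Nutrient-limited yield modelling for maize on low-input savanna soils:
an implementation of the QUEFTS approach (QUantitative Evaluation of the
Fertility of Tropical Soils) parameterized for the Northern Guinea and
Sudan Savanna agro-ecological zones of northern Nigeria, together with
the full toolchain around it — indigenous soil nutrient supply
equations, coefficient fitting from nutrient-omission trials, balanced
NPK uptake requirement curves, model validation statistics, and a
synthetic trial generator so every stage can be exercised without field
data.

It is written for agronomists and soil scientists working on
site-specific nutrient management: given a handful of routine topsoil
measurements (pH, organic C, total N, Mehlich-3 P, exchangeable K) and
fertilizer rates, the model predicts maize grain yield; inverted, it
answers "how much N, P and K must the crop take up, in balance, to
reach a target yield".

## The model

QUEFTS proceeds in four steps:

1. **Supply.** The potential supply of each macronutrient is the
   indigenous soil supply — an empirical regression on topsoil
   properties, fitted on plots where that nutrient was omitted — plus
   the fertilizer input times an average recovery fraction:
   `S_i = f_i(soil) + R_i F_i`.
2. **Uptake.** Actual uptake `U_i(j)` is a piecewise function of the
   supplies of `i` and each partner `j`: all of `S_i` is taken up while
   the partner can dilute it, a parabolic transition follows, and
   uptake plateaus at `r_i + (S_j − r_j) d_j / a_i` when `i` is in
   excess. The limiting partner governs: `U_i = min_j U_i(j)`.
3. **Yield ranges.** An uptake `U_i` supports grain yields between
   `Y_ia = a_i (U_i − r_i)` (maximum accumulation, least efficient
   conversion) and `Y_id = d_i (U_i − r_i)` (maximum dilution), where
   `r_i` is the minimum uptake to produce any grain.
4. **Combination.** For every ordered nutrient pair the yield ranges
   are combined by parabolic interpolation, capped by the partner
   dilution yields and the yield potential `Ymax`; the ultimate
   estimate `YU` is the mean of the six pair estimates.

The crop coefficients for the savanna zones (kg grain per kg nutrient;
`r` in kg/ha, `Ymax` = 10,000 kg/ha):

| zone | a_N/d_N | a_P/d_P | a_K/d_K | r_N, r_P, r_K |
|------|---------|---------|---------|----------------|
| NGS  | 35 / 79 | 200 / 527 | 25 / 117 | 4.0, 0.5, 4.5 |
| SS   | 32 / 79 | 164 / 528 | 24 / 136 | 6.1, 0.8, 7.3 |
| All  | 35 / 79 | 199 / 528 | 24 / 124 | 4.0, 0.5, 4.5 |

Both these calibrated sets and the classic default coefficient set ship
as data files; see `quefts.builtin_registry()`.

## Worked example

```python
from quefts import builtin_registry, total_supply, ultimate_yield

ngs = builtin_registry()["NGS"]
soil = dict(pH=5.8, OC_tot=7.25, N_tot=0.47, P_av=8.43, K_exch=0.22)

s = total_supply(soil, ngs.equations,
                 fert={"N": 140, "P": 50, "K": 50}, rec=ngs.recovery)
print({k: round(v, 1) for k, v in s.items()})
# {'N': 104.1, 'P': 17.5, 'K': 108.3}

res = ultimate_yield(s, ngs.coeffs)
print(round(res.yu), {k: round(v, 1) for k, v in res.uptake.items()})
# 5470 {'N': 100.3, 'P': 16.7, 'K': 103.5}
```

A zone-average NGS field given the trial fertilizer rates supplies about
104 kg N, 18 kg P and 108 kg K per hectare; the model converts that to
an actual uptake of 100/17/104 kg/ha and a grain yield of ≈ 5.5 t/ha —
phosphorus is the limiting nutrient here (nearly all of its supply is
taken up while part of the N and K supply goes unused).

The balanced requirement curve for the same zone:

```python
from quefts import requirement_curve
curve = requirement_curve(ngs.coeffs, [2000, 4000, 6000])
print(curve[["target_yield", "RPhE_N", "RPhE_P", "RPhE_K"]].round(1))
#    target_yield  RPhE_N  RPhE_P  RPhE_K
# 0        2000.0    19.9     3.1    20.4
# 1        4000.0    18.9     3.0    19.1
# 2        6000.0    18.6     3.0    18.7
```

i.e. to produce one tonne of grain at a 6 t/ha target the crop must
take up about 18.6 kg N, 3.0 kg P and 18.7 kg K in balance.

The same surface is available from a shell:

```
quefts simulate --zone NGS --n-fields 40 --seed 4 --out trials.csv
quefts parameterize --input trials.csv --zone NGS --out-coefficients fit.yaml
quefts requirements --zone NGS --targets 1000..10000:1000 --out curve.csv
quefts validate --coefficients fit.yaml --zone NGS --input trials.csv
```

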