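"""Synthetic nutrient-omission-trial generator.

Emulates the statistical structure of on-farm omission trials in the two
savanna agro-ecological zones so the fitting and validation pipeline can
be exercised without field data:

* topsoil properties drawn from truncated lognormals matching the
  zone-wise means, CVs and ranges, with organic carbon and total N
  coupled through a shared latent factor;
* indigenous supplies from the zone's supply equations plus a Gaussian
  field-level residual calibrated so the equations explain roughly the
  published share of variance (R^2 ~ 0.5-0.6), not all of it;
* six treatments per field at the zone's fertilizer rates; true yields
  and uptakes from the forward model, then multiplicative lognormal
  noise;
* grain harvest index from a truncated normal; tissue concentrations
  back-computed from the noisy uptakes so every record satisfies the
  uptake-consistency identity exactly;
* a small number of "subsistence" fields whose supply of one nutrient
  sits just above the minimum uptake (the near-barren fields every
  large survey contains, which identify r_i), and a configurable
  fraction of inflated outlier plots.

Everything is driven by one seeded generator; a fixed seed makes the
whole generate -> fit -> validate pipeline reproducible.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Dict, Optional, Tuple

import numpy as np
import pandas as pd

from .core import NUTRIENTS, CropCoefficients, ultimate_yield
from .records import TREATMENTS
from .supply import CoefficientBundle, SoilProfile, builtin_registry, indigenous_supply

__all__ = ["SOIL_DISTRIBUTIONS", "FERTILIZER_RATES", "GeneratorConfig",
           "generate_soils", "generate_trials"]

log = logging.getLogger(__name__)

#: per-zone topsoil distributions: (mean, CV %, min, max)
SOIL_DISTRIBUTIONS: Dict[str, Dict[str, Tuple[float, float, float, float]]] = {
    "NGS": {
        "pH": (5.8, 8.0, 4.8, 7.2),
        "OC_tot": (7.25, 36.0, 2.44, 15.45),
        "N_tot": (0.47, 30.0, 0.25, 0.98),
        "P_av": (8.43, 82.0, 0.64, 31.77),
        "K_exch": (0.22, 78.0, 0.06, 1.35),
    },
    "SS": {
        "pH": (6.2, 9.0, 5.2, 7.2),
        "OC_tot": (5.01, 36.0, 2.04, 10.12),
        "N_tot": (0.36, 36.0, 0.17, 0.66),
        "P_av": (16.54, 71.0, 1.44, 50.0),
        "K_exch": (0.24, 43.0, 0.07, 0.50),
    },
}

#: N/P/K application rates (kg/ha) of the trial design, per zone
FERTILIZER_RATES: Dict[str, Dict[str, float]] = {
    "NGS": {"N": 140.0, "P": 50.0, "K": 50.0},
    "SS": {"N": 120.0, "P": 40.0, "K": 40.0},
}

#: field-level supply-residual standard deviations (kg/ha), sized so the
#: supply equations explain roughly their published share of variance
SUPPLY_RESIDUAL_SD: Dict[str, Dict[str, float]] = {
    "NGS": {"N": 17.0, "P": 4.0, "K": 38.0},
    "SS": {"N": 8.0, "P": 3.5, "K": 28.0},
}

#: share of each nutrient's uptake allocated to grain (maize-typical)
GRAIN_FRACTION = {"N": 0.62, "P": 0.75, "K": 0.25}


def _treatment_rates(zone_rates: Dict[str, float]) -> Dict[str, Dict[str, float]]:
    full = dict(zone_rates)
    return {
        "control": dict.fromkeys(NUTRIENTS, 0.0),
        "minusN": {**full, "N": 0.0},
        "minusP": {**full, "P": 0.0},
        "minusK": {**full, "K": 0.0},
        "NPK": full,
        "NPKplus": dict(full),  # secondary/micronutrients carry no yield effect
    }


@dataclass
class GeneratorConfig:
    """All knobs of the trial generator; defaults are the study design.

    ``bundle`` holds the "true" crop coefficients, supply equations and
    recovery fractions (defaults to the zone's calibrated set);
    fertilizer rates default to the zone's trial design.
    """

    zone: str = "NGS"
    n_fields: int = 100
    seed: int = 0
    soil_props: Optional[Dict[str, Tuple[float, float, float, float]]] = None
    oc_n_rho: float = 0.8
    bundle: Optional[CoefficientBundle] = None
    rates: Optional[Dict[str, float]] = None
    ghi_mean: float = 0.46
    ghi_sd: float = 0.05
    ghi_range: Tuple[float, float] = (0.25, 0.65)
    yield_noise_sd: float = 0.15
    uptake_noise_sd: float = 0.10
    supply_residual_sd: Optional[Dict[str, float]] = None
    n_subsistence_fields_per_nutrient: int = 3
    subsistence_margin: Tuple[float, float] = (1.02, 1.30)
    outlier_fraction: float = 0.02
    outlier_shift_sd: Tuple[float, float] = (5.0, 9.0)
    grain_fraction: Dict[str, float] = field(default_factory=lambda: dict(GRAIN_FRACTION))
    grain_moisture: float = 0.15
    uptake_combine: str = "min"

    def __post_init__(self) -> None:
        if self.zone not in SOIL_DISTRIBUTIONS:
            raise ValueError(f"unknown zone {self.zone!r} (expected NGS or SS)")
        if self.soil_props is None:
            self.soil_props = dict(SOIL_DISTRIBUTIONS[self.zone])
        if self.rates is None:
            self.rates = dict(FERTILIZER_RATES[self.zone])
        if self.supply_residual_sd is None:
            self.supply_residual_sd = dict(SUPPLY_RESIDUAL_SD[self.zone])
        if self.bundle is None:
            self.bundle = builtin_registry("parameterized")[self.zone]

    def noise_free(self) -> "GeneratorConfig":
        """Copy with every stochastic disturbance switched off (the
        deterministic round-trip configuration)."""
        return replace(
            self,
            yield_noise_sd=0.0,
            uptake_noise_sd=0.0,
            supply_residual_sd=dict.fromkeys(NUTRIENTS, 0.0),
            outlier_fraction=0.0,
        )


def _lognormal_trunc(rng, mean, cv_pct, lo, hi, size, latent=None):
    cv = cv_pct / 100.0
    if cv <= 0.0:
        return np.full(size, mean)
    sigma2 = np.log1p(cv**2)
    mu = np.log(mean) - sigma2 / 2.0
    z = rng.standard_normal(size) if latent is None else latent
    return np.clip(np.exp(mu + np.sqrt(sigma2) * z), lo, hi)


def generate_soils(config: GeneratorConfig, rng=None) -> pd.DataFrame:
    """Draw one soil profile per field.

    Each property follows a truncated lognormal matching the configured
    (mean, CV), clipped to the configured range; OC_tot and N_tot share
    a latent factor with correlation ``oc_n_rho``.
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    n = config.n_fields
    z_oc = rng.standard_normal(n)
    z_n = config.oc_n_rho * z_oc + np.sqrt(1.0 - config.oc_n_rho**2) * rng.standard_normal(n)
    latents = {"OC_tot": z_oc, "N_tot": z_n}
    data = {"field_id": [f"F{i:04d}" for i in range(n)]}
    for prop, (mean, cv, lo, hi) in config.soil_props.items():
        data[prop] = _lognormal_trunc(rng, mean, cv, lo, hi, n, latents.get(prop))
    return pd.DataFrame(data)


def generate_trials(config: GeneratorConfig) -> pd.DataFrame:
    """Generate the full plot table: n_fields x six treatments.

    Returns a DataFrame in the standard plot-table layout plus a
    bookkeeping column ``_outlier`` marking planted outliers (dropped on
    write; used by screening tests).
    """
    rng = np.random.default_rng(config.seed)
    soils = generate_soils(config, rng)
    n = config.n_fields
    bundle = config.bundle
    coeffs = bundle.coeffs
    rates = _treatment_rates(config.rates)

    # field-level indigenous supplies: equation value + residual, floored
    indig = {}
    for nut in NUTRIENTS:
        eq = bundle.equations[nut]
        base = np.array([
            indigenous_supply(
                SoilProfile(**{p: soils.at[i, p] for p in ("pH", "OC_tot", "N_tot", "P_av", "K_exch")}),
                eq,
            )
            for i in range(n)
        ])
        resid = rng.normal(0.0, config.supply_residual_sd[nut], size=n)
        indig[nut] = np.maximum(base + resid, 0.0)

    # subsistence fields: pin one nutrient's supply just above its
    # minimum uptake, cycling through N, P, K
    n_sub = config.n_subsistence_fields_per_nutrient
    sub_fields = []
    if n_sub > 0:
        order = [nut for nut in NUTRIENTS for _ in range(n_sub)]
        idx = rng.choice(n, size=min(len(order), n), replace=False)
        for i, nut in zip(idx, order):
            lo, hi = config.subsistence_margin
            indig[nut][i] = coeffs.r[nut] * rng.uniform(lo, hi)
            sub_fields.append((int(i), nut))

    seasons = rng.choice(["2015", "2016"], size=n)
    varieties = rng.choice(["OPV", "hybrid"], size=n)

    # first pass: true model outputs plus measurement noise
    base = []
    ghi_lo, ghi_hi = config.ghi_range
    for i in range(n):
        for trt in TREATMENTS:
            f = rates[trt]
            s = {
                nut: indig[nut][i] + bundle.recovery.R[nut] * f[nut]
                for nut in NUTRIENTS
            }
            res = ultimate_yield(s, coeffs, config.uptake_combine)
            grain = res.yu * np.exp(rng.normal(0.0, config.yield_noise_sd)) \
                if config.yield_noise_sd > 0 else res.yu
            uptake = {
                nut: res.uptake[nut] * np.exp(rng.normal(0.0, config.uptake_noise_sd))
                if config.uptake_noise_sd > 0 else res.uptake[nut]
                for nut in NUTRIENTS
            }
            ghi = float(np.clip(rng.normal(config.ghi_mean, config.ghi_sd), ghi_lo, ghi_hi))
            base.append([i, trt, f, grain, uptake, ghi, False])

    # outliers: shift a single component (a yield or one nutrient's
    # uptake) several column standard deviations upward, emulating the
    # isolated implausible values real screening targets; a proportional
    # scaling of a whole plot would stay on the yield-uptake correlation
    # and be invisible to the distance screen
    if config.outlier_fraction > 0.0:
        n_out = int(round(config.outlier_fraction * len(base)))
        sds = {
            "grain_yield": np.std([b[3] for b in base]),
            **{nut: np.std([b[4][nut] for b in base]) for nut in NUTRIENTS},
        }
        lo, hi = config.outlier_shift_sd
        for j in rng.choice(len(base), size=n_out, replace=False):
            component = rng.choice(["grain_yield", "N", "P", "K"])
            shift = rng.uniform(lo, hi) * sds[component]
            if component == "grain_yield":
                base[j][3] += shift
            else:
                base[j][4][component] += shift
            base[j][6] = True

    # second pass: build tissue data consistent with the (possibly
    # inflated) uptakes and yields
    rows = []
    for i, trt, f, grain, uptake, ghi, is_out in base:
        grain_dry = grain * (1.0 - config.grain_moisture)
        if grain_dry > 0.0:
            stover = grain_dry * (1.0 - ghi) / ghi
            conc_g = {nut: 1000.0 * config.grain_fraction[nut] * uptake[nut] / grain_dry
                      for nut in NUTRIENTS}
            conc_s = {nut: 1000.0 * (1.0 - config.grain_fraction[nut]) * uptake[nut] / stover
                      for nut in NUTRIENTS}
        else:
            grain = grain_dry = 0.0
            ghi = 0.0
            stover = 250.0  # residual biomass of a failed plot
            conc_g = dict.fromkeys(NUTRIENTS, 0.0)
            conc_s = {nut: 1000.0 * uptake[nut] / stover for nut in NUTRIENTS}

        rows.append({
            "field_id": soils.at[i, "field_id"],
            "zone": config.zone,
            "season": seasons[i],
            "variety_group": varieties[i],
            "treatment": trt,
            **{p: soils.at[i, p] for p in ("pH", "OC_tot", "N_tot", "P_av", "K_exch")},
            **{f"applied_{nut}": f[nut] for nut in NUTRIENTS},
            "grain_yield": grain,
            "stover_yield": stover,
            "ghi": ghi,
            **{f"grain_{nut}": conc_g[nut] for nut in NUTRIENTS},
            **{f"stover_{nut}": conc_s[nut] for nut in NUTRIENTS},
            **{f"uptake_{nut}": uptake[nut] for nut in NUTRIENTS},
            "_outlier": is_out,
        })

    df = pd.DataFrame(rows)
    df.attrs["subsistence_fields"] = sub_fields
    return df
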