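"""Step 1 of the model: potential supply of plant-available N, P and K.

The potential supply of a nutrient is the indigenous soil supply -- an
empirical function of topsoil properties fitted on nutrient-omission
plots -- plus the fertilizer input times the average recovery fraction:

    S_i = f_i(soil) + R_i * F_i

Two equation registries are bundled: the locally calibrated savanna
forms and the default forms after Janssen, both keyed by agro-ecological
zone (NGS, SS, All) and nutrient.  Units are enforced at read time:
OC_tot and N_tot in g/kg, P_av in mg/kg (Mehlich-3), exchangeable K in
cmol_c/kg, pH in water (1:1).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Dict, Iterable, List, Mapping, Optional, Tuple

import yaml

from .core import NUTRIENTS, CropCoefficients, _as_triple

__all__ = [
    "SoilProfile",
    "Term",
    "SupplyEquation",
    "RecoveryFractions",
    "FertilizerInput",
    "MissingPredictorError",
    "indigenous_supply",
    "recovery_fraction",
    "total_supply",
    "load_registry",
    "builtin_registry",
    "CoefficientBundle",
]

log = logging.getLogger(__name__)

#: canonical predictor names and their units
PREDICTORS = {
    "pH": "unitless (1:1 water)",
    "OC_tot": "g/kg",
    "N_tot": "g/kg",
    "P_av": "mg/kg",
    "K_exch": "cmol_c/kg",
}

FAMILIES = ("linear", "polynomial", "logarithmic", "exponential", "cauchy")


class MissingPredictorError(KeyError):
    """A supply equation requires a soil property the profile lacks."""


@dataclass
class SoilProfile:
    """Topsoil (0-20 cm) properties of one field.

    Extended properties (Ca, Mg, ECEC, micronutrients, texture...) ride
    along in ``extra`` for screening and the trial generator; the supply
    equations only ever use the five canonical predictors.
    """

    pH: float
    OC_tot: float
    N_tot: float
    P_av: float
    K_exch: float
    extra: Dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 3.0 < self.pH < 10.0:
            raise ValueError(f"pH {self.pH} outside plausible range (3, 10)")
        for name in ("OC_tot", "N_tot", "P_av", "K_exch"):
            if getattr(self, name) < 0.0:
                raise ValueError(f"{name} must be non-negative")

    def __getitem__(self, key: str) -> float:
        if hasattr(self, key) and key != "extra":
            return float(getattr(self, key))
        try:
            return float(self.extra[key])
        except KeyError:
            raise MissingPredictorError(key) from None

    def __contains__(self, key: str) -> bool:
        return (hasattr(self, key) and key != "extra") or key in self.extra


@dataclass(frozen=True)
class Term:
    """One additive term of a supply equation: ``coef * g(x)``.

    ``g`` is selected by ``func``: ``identity`` evaluates ``x ** power``
    (power 1 for linear, 2 or 3 for the polynomial family), ``log`` the
    natural logarithm, ``exp`` is ``exp(rate * x)``, ``cauchy`` the
    Lorentzian bump ``1 / (1 + ((x - loc) / scale)^2)``.
    """

    predictor: str
    coef: float
    power: int = 1
    func: str = "identity"
    params: Tuple[float, ...] = ()

    def __call__(self, soil: SoilProfile | Mapping[str, float]) -> float:
        x = soil[self.predictor]
        if self.func == "identity":
            v = x**self.power
        elif self.func == "log":
            if x <= 0:
                raise ValueError(f"log transform of non-positive {self.predictor}={x}")
            v = math.log(x)
        elif self.func == "exp":
            v = math.exp(self.params[0] * x)
        elif self.func == "cauchy":
            loc, scale = self.params
            v = 1.0 / (1.0 + ((x - loc) / scale) ** 2)
        else:
            raise ValueError(f"unknown term transform {self.func!r}")
        return self.coef * v


@dataclass(frozen=True)
class SupplyEquation:
    """Fitted indigenous-supply equation for one nutrient (kg/ha)."""

    nutrient: str
    family: str
    intercept: float
    terms: Tuple[Term, ...]
    r2: Optional[float] = None
    bic: Optional[float] = None
    zone: str = ""
    source: str = ""

    def predictors(self) -> List[str]:
        return [t.predictor for t in self.terms]

    def evaluate(self, soil: SoilProfile | Mapping[str, float]) -> float:
        """Raw evaluation; may be negative for extreme soils."""
        return self.intercept + sum(t(soil) for t in self.terms)


def indigenous_supply(soil: SoilProfile | Mapping[str, float], eq: SupplyEquation) -> float:
    """Indigenous soil supply of one nutrient, kg/ha, floored at zero.

    Negative evaluations are physically meaningless (possible at low pH
    or low P_av with the calibrated intercepts) and are clipped, with a
    log message.
    """
    for p in eq.predictors():
        if p not in soil:
            raise MissingPredictorError(p)
    value = eq.evaluate(soil)
    if value < 0.0:
        log.info(
            "indigenous %s supply %.2f kg/ha < 0 floored to 0 (zone=%s)",
            eq.nutrient, value, eq.zone,
        )
        return 0.0
    return float(value)


@dataclass(frozen=True)
class RecoveryFractions:
    """Zone-average fertilizer recovery fractions R_i (unitless)."""

    R: Dict[str, float]
    zone: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "R", _as_triple(self.R))
        for n, v in self.R.items():
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"zone-average recovery R_{n}={v} outside [0, 1]")


@dataclass(frozen=True)
class FertilizerInput:
    """Applied nutrient rates F_i, kg/ha."""

    F: Dict[str, float]

    def __post_init__(self) -> None:
        object.__setattr__(self, "F", _as_triple(self.F))
        for n, v in self.F.items():
            if v < 0.0:
                raise ValueError(f"applied rate F_{n} must be >= 0")


def recovery_fraction(u_npk: float, u_omission: float, f_applied: float) -> float:
    """Per-plot fertilizer recovery fraction ``(U_i - U_i0) / F_i``.

    ``u_npk`` is the uptake in the fully fertilized plot, ``u_omission``
    the uptake in the plot where the nutrient was omitted (the indigenous
    supply estimate).  Plot-level values may be negative under field
    noise; they are retained and only zone averages are bounded.
    """
    if f_applied <= 0.0:
        raise ValueError("recovery fraction undefined for zero application")
    r = (u_npk - u_omission) / f_applied
    if r < 0.0:
        log.info("negative plot-level recovery fraction %.3f retained", r)
    return r


def total_supply(
    soil: SoilProfile | Mapping[str, float],
    eqs: Mapping[str, SupplyEquation],
    fert: FertilizerInput | Mapping[str, float] | None = None,
    rec: RecoveryFractions | Mapping[str, float] | None = None,
) -> Dict[str, float]:
    """Potential supply triple ``S_i = indigenous_i + R_i * F_i`` (kg/ha)."""
    f = _as_triple(fert.F if isinstance(fert, FertilizerInput) else (fert or dict.fromkeys(NUTRIENTS, 0.0)))
    r = _as_triple(rec.R if isinstance(rec, RecoveryFractions) else (rec or dict.fromkeys(NUTRIENTS, 0.0)))
    out = {}
    for n in NUTRIENTS:
        if n not in eqs:
            raise KeyError(f"no supply equation for nutrient {n}")
        out[n] = indigenous_supply(soil, eqs[n]) + r[n] * f[n]
    return out


# ---------------------------------------------------------------------------
# registries


def _parse_equation(nutrient: str, zone: str, source: str, spec: Mapping) -> SupplyEquation:
    terms = tuple(
        Term(
            predictor=t["predictor"],
            coef=float(t["coef"]),
            power=int(t.get("power", 1)),
            func=t.get("func", "identity"),
            params=tuple(t.get("params", ())),
        )
        for t in spec.get("terms", ())
    )
    return SupplyEquation(
        nutrient=nutrient,
        family=spec.get("family", "linear"),
        intercept=float(spec["intercept"]),
        terms=terms,
        r2=spec.get("r2"),
        bic=spec.get("bic"),
        zone=zone,
        source=source,
    )


@dataclass(frozen=True)
class CoefficientBundle:
    """Everything one forward run needs for a zone: crop coefficients,
    recovery fractions and the three supply equations."""

    coeffs: CropCoefficients
    recovery: RecoveryFractions
    equations: Dict[str, SupplyEquation]
    source: str = ""


def load_registry(stream_or_text) -> Dict[str, CoefficientBundle]:
    """Parse a coefficient file into one bundle per zone."""
    doc = yaml.safe_load(stream_or_text)
    source = doc.get("source", "")
    out: Dict[str, CoefficientBundle] = {}
    for zone, zdoc in doc["zones"].items():
        crop = zdoc["crop"]
        coeffs = CropCoefficients(
            a=crop["a"], d=crop["d"], r=crop["r"],
            y_max=float(crop.get("y_max", 10_000.0)), zone=zone,
        )
        rec = RecoveryFractions(R=zdoc["recovery"], zone=zone)
        eqs = {
            n: _parse_equation(n, zone, source, zdoc["supply"][n]) for n in NUTRIENTS
        }
        out[zone] = CoefficientBundle(coeffs, rec, eqs, source)
    return out


def builtin_registry(source: str = "parameterized") -> Dict[str, CoefficientBundle]:
    """Bundled coefficient sets: ``parameterized`` (savanna calibration)
    or ``janssen_default`` (default model forms)."""
    fname = {
        "parameterized": "coefficients_parameterized.yaml",
        "janssen_default": "coefficients_default.yaml",
    }
    if source not in fname:
        raise ValueError(f"unknown registry source {source!r}")
    text = resources.files("quefts.data").joinpath(fname[source]).read_text()
    return load_registry(text)
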