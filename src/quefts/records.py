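"""Plot-level trial records and the nutrient-omission treatment design."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict

from .core import NUTRIENTS
from .supply import SoilProfile

__all__ = ["TREATMENTS", "OMISSION_OF", "PlotRecord", "uptake_from_tissue"]

#: treatment codes of a nutrient omission trial: an unfertilized control,
#: one omission plot per macronutrient, the full NPK plot, and NPK plus
#: secondary/micronutrients.
TREATMENTS = ("control", "minusN", "minusP", "minusK", "NPK", "NPKplus")

#: omission treatment that estimates the indigenous supply of each nutrient
OMISSION_OF = {"N": "minusN", "P": "minusP", "K": "minusK"}


def uptake_from_tissue(
    grain_yield: float,
    stover_yield: float,
    conc_grain: float,
    conc_stover: float,
    grain_moisture: float = 0.15,
) -> float:
    """Total above-ground uptake (kg/ha) from yields and mass fractions.

    Grain yield is stored at field moisture (default 15%) and converted
    to dry matter before applying the g/kg tissue mass fractions; stover
    is stored oven-dry.
    """
    grain_dry = grain_yield * (1.0 - grain_moisture)
    return (grain_dry * conc_grain + stover_yield * conc_stover) / 1000.0


@dataclass
class PlotRecord:
    """One treatment plot: identity, soil, management, harvest, tissue.

    Yields in kg/ha (grain at 15% moisture, stover oven-dry), tissue
    mass fractions in g/kg, uptakes in kg/ha.  ``uptake`` must be
    consistent with the tissue data to within 0.1%; use
    :func:`uptake_from_tissue` to derive it.
    """

    field_id: str
    zone: str
    season: str
    variety_group: str
    treatment: str
    soil: SoilProfile
    applied: Dict[str, float]
    grain_yield: float
    stover_yield: float
    ghi: float
    conc_grain: Dict[str, float]
    conc_stover: Dict[str, float]
    uptake: Dict[str, float] = field(default_factory=dict)
    grain_moisture: float = 0.15

    def __post_init__(self) -> None:
        if self.treatment not in TREATMENTS:
            raise ValueError(f"unknown treatment code {self.treatment!r}")
        if not 0.0 <= self.ghi <= 1.0:
            raise ValueError(f"GHI {self.ghi} outside [0, 1]")
        if self.grain_yield < 0.0 or self.stover_yield < 0.0:
            raise ValueError("yields must be non-negative")
        if not self.uptake:
            self.uptake = {
                n: uptake_from_tissue(
                    self.grain_yield, self.stover_yield,
                    self.conc_grain[n], self.conc_stover[n], self.grain_moisture,
                )
                for n in NUTRIENTS
            }
        else:
            for n in NUTRIENTS:
                implied = uptake_from_tissue(
                    self.grain_yield, self.stover_yield,
                    self.conc_grain[n], self.conc_stover[n], self.grain_moisture,
                )
                if implied > 0 and abs(self.uptake[n] - implied) > 1e-3 * max(implied, 1e-9):
                    raise ValueError(
                        f"uptake of {n} ({self.uptake[n]:.3f}) inconsistent with "
                        f"tissue data (implies {implied:.3f})"
                    )
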