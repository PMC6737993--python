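"""Model-evaluation statistics for observed vs predicted grain yields.

Four statistics summarize agreement: root mean square error (RMSE),
coefficient of determination (R^2, the squared Pearson correlation),
Willmott's index of agreement (d), and percent bias (PBIAS, positive
for underestimation, negative for overestimation).

The index of agreement is implemented in its standard form

    d = 1 - sum((o - p)^2) / sum((|p - mean(o)| + |o - mean(o)|)^2)

so that perfect agreement gives d = 1.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, Mapping, Optional

import numpy as np

from .core import NUTRIENTS, CropCoefficients, ultimate_yield
from .supply import RecoveryFractions, SupplyEquation, total_supply

__all__ = [
    "rmse",
    "r_squared",
    "willmott_d",
    "pbias",
    "ValidationReport",
    "validate",
]


def _pair(obs, pred) -> tuple[np.ndarray, np.ndarray]:
    o = np.asarray(obs, dtype=float)
    p = np.asarray(pred, dtype=float)
    if o.shape != p.shape or o.ndim != 1:
        raise ValueError("observed and predicted must be 1-D and equal length")
    return o, p


def rmse(obs, pred) -> float:
    o, p = _pair(obs, pred)
    if o.size < 1:
        raise ValueError("need at least one observation")
    return float(np.sqrt(np.mean((o - p) ** 2)))


def r_squared(obs, pred) -> float:
    """Squared Pearson correlation.

    Note this is symmetric and insensitive to bias: an anti-correlated or
    affinely shifted prediction still scores 1.  It is reported together
    with d and PBIAS for that reason.
    """
    o, p = _pair(obs, pred)
    if o.size < 2:
        raise ValueError("need at least two observations")
    if np.std(o) == 0.0 or np.std(p) == 0.0:
        raise ValueError("R^2 undefined for a constant series")
    return float(np.corrcoef(o, p)[0, 1] ** 2)


def willmott_d(obs, pred) -> float:
    o, p = _pair(obs, pred)
    if o.size < 2:
        raise ValueError("need at least two observations")
    om = o.mean()
    denom = np.sum((np.abs(p - om) + np.abs(o - om)) ** 2)
    if denom == 0.0:
        raise ValueError("index of agreement undefined: no potential error")
    return float(1.0 - np.sum((o - p) ** 2) / denom)


def pbias(obs, pred) -> float:
    """Percent bias, ``100 * sum(obs - pred) / sum(obs)``."""
    o, p = _pair(obs, pred)
    s = o.sum()
    if s == 0.0:
        raise ValueError("PBIAS undefined when observations sum to zero")
    return float(100.0 * np.sum(o - p) / s)


@dataclass(frozen=True)
class ValidationReport:
    """Observed-vs-predicted summary for one validation set."""

    n: int
    rmse: float  # kg/ha
    r2: float
    d: float
    pbias: float  # percent
    zone: str = ""
    n_failed: int = 0

    def as_dict(self) -> Dict[str, float]:
        return {
            "n": self.n,
            "rmse_kg_ha": self.rmse,
            "rmse_t_ha": round(self.rmse / 1000.0, 2),
            "r2": self.r2,
            "d": self.d,
            "pbias_pct": self.pbias,
            "n_failed": self.n_failed,
        }


def validate(
    records,
    coeffs: CropCoefficients,
    eqs: Mapping[str, SupplyEquation],
    rec: RecoveryFractions | Mapping[str, float],
    uptake_combine: str = "min",
    zone: str = "",
) -> ValidationReport:
    """Predict yield for each plot and score against the observed yields.

    ``records`` is an iterable of plot records (see
    :class:`quefts.io.PLOT_COLUMNS` for the table layout) carrying a soil
    profile, applied rates and an observed grain yield.  Plots whose
    prediction fails (e.g. a missing predictor) are skipped and counted.
    """
    obs, pred = [], []
    n_failed = 0
    for recd in records:
        try:
            s = total_supply(recd.soil, eqs, recd.applied, rec)
            y = ultimate_yield(s, coeffs, uptake_combine).yu
        except Exception:
            n_failed += 1
            continue
        obs.append(recd.grain_yield)
        pred.append(y)
    o = np.asarray(obs)
    p = np.asarray(pred)
    return ValidationReport(
        n=o.size,
        rmse=rmse(o, p),
        r2=r_squared(o, p),
        d=willmott_d(o, p),
        pbias=pbias(o, p),
        zone=zone,
        n_failed=n_failed,
    )
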