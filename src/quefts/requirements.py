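"""Balanced NPK uptake requirements: the uptake needed per tonne of grain.

For a target yield, the balanced requirement is the uptake triple at which
no nutrient is in accumulation or dilution excess -- the three yield ranges
overlap at the target.  The model then converts uptakes to the reciprocal
physiological efficiency RPhE (kg nutrient per tonne grain) reported in
requirement tables.

The search scales a supply triple along a fixed direction until the
ultimate yield matches the target (1-D root find), then replaces the
direction with the resulting uptake ratio and repeats to a fixed point.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .core import NUTRIENTS, CropCoefficients, YieldResult, ultimate_yield

__all__ = [
    "BalancedUptake",
    "balanced_uptake",
    "requirement_curve",
    "ConvergenceError",
    "InfeasibleTargetError",
]


class ConvergenceError(RuntimeError):
    """Fixed-point iteration on the uptake ratio failed to settle."""


class InfeasibleTargetError(ValueError):
    """Target yield not achievable for the given coefficients."""


@dataclass(frozen=True)
class BalancedUptake:
    """Converged balanced state for one target yield."""

    target_yield: float  # kg/ha
    uptake: Dict[str, float]  # kg/ha
    supply: Dict[str, float]  # kg/ha at convergence
    result: YieldResult
    n_iter: int

    @property
    def rphe(self) -> Dict[str, float]:
        """kg nutrient per tonne of grain at the target."""
        return {n: self.uptake[n] * 1000.0 / self.target_yield for n in NUTRIENTS}

    @property
    def phe(self) -> Dict[str, float]:
        """kg grain per kg nutrient at the target."""
        return {n: self.target_yield / self.uptake[n] for n in NUTRIENTS}


def _solve_scale(
    rho: np.ndarray,
    target: float,
    coeffs: CropCoefficients,
    uptake_combine: str,
    scale_max: float = 1e6,
) -> float:
    """Scale factor s with ultimate_yield(s * rho) == target (monotone in s)."""

    def f(s: float) -> float:
        return ultimate_yield(s * rho, coeffs, uptake_combine).yu - target

    lo, hi = 1e-9, 1.0
    while f(hi) < 0.0:
        hi *= 2.0
        if hi > scale_max:
            raise InfeasibleTargetError(
                f"target {target} kg/ha not achievable (yield saturates below it)"
            )
    return brentq(f, lo, hi, xtol=1e-10, rtol=1e-14)


def balanced_uptake(
    target_yield: float,
    coeffs: CropCoefficients,
    ratio_seed: Optional[Sequence[float]] = None,
    tol: float = 1e-6,
    max_iter: int = 100,
    uptake_combine: str = "min",
) -> BalancedUptake:
    """Balanced uptake triple reaching ``target_yield`` exactly.

    Parameters
    ----------
    target_yield : float
        Grain yield to reach, kg/ha, in ``(0, y_max]``.  Targets at the
        potential-yield asymptote are allowed but uptakes grow steeply and
        become tolerance-sensitive there.
    ratio_seed : sequence of 3 floats, optional
        Initial supply direction; defaults to ``r_i + Y/((a_i+d_i)/2)``,
        the uptake a mid-envelope efficiency would need for the target.
    tol : float
        Relative tolerance on the uptake-share fixed point.
    """
    if not 0.0 < target_yield <= coeffs.y_max:
        raise InfeasibleTargetError(
            f"target must be in (0, {coeffs.y_max}], got {target_yield}"
        )
    a = np.array([coeffs.a[n] for n in NUTRIENTS])
    d = np.array([coeffs.d[n] for n in NUTRIENTS])
    r = np.array([coeffs.r[n] for n in NUTRIENTS])

    rho = (
        np.asarray(ratio_seed, dtype=float)
        if ratio_seed is not None
        else r + target_yield / ((a + d) / 2.0)
    )
    if rho.shape != (3,) or np.any(rho <= 0.0):
        raise ValueError("ratio seed must be three positive values")

    def step(shares: np.ndarray):
        """One pass: scale the direction to the target, return the
        resulting uptake shares (and the full state)."""
        s = _solve_scale(shares, target_yield, coeffs, uptake_combine)
        res = ultimate_yield(s * shares, coeffs, uptake_combine)
        u = np.array([res.uptake[n] for n in NUTRIENTS])
        return u / u.sum(), u, s * shares, res

    # Steffensen (vector Aitken) acceleration of the linearly convergent
    # share iteration; each cycle spends two map evaluations
    shares = rho / rho.sum()
    for it in range(1, max_iter + 1):
        s1, u, supply_vec, res = step(shares)
        if np.max(np.abs(s1 - shares) / shares) < tol:
            supply = dict(zip(NUTRIENTS, supply_vec))
            return BalancedUptake(
                target_yield, dict(zip(NUTRIENTS, u)), supply, res, it
            )
        s2, _, _, _ = step(s1)
        d1, d2 = s1 - shares, s2 - s1
        denom = d2 - d1
        accel = np.where(np.abs(denom) > 1e-15, shares - d1**2 / denom, s2)
        accel = np.clip(accel, 1e-12, None)
        shares = accel / accel.sum()
    raise ConvergenceError(
        f"uptake-ratio fixed point not reached in {max_iter} iterations"
    )


def requirement_curve(
    coeffs: CropCoefficients,
    targets: Iterable[float],
    tol: float = 1e-6,
    uptake_combine: str = "min",
) -> pd.DataFrame:
    """Balanced requirement table over a set of target yields.

    Returns one row per target with uptakes (kg/ha), RPhE (kg nutrient per
    tonne grain) and PhE (kg grain per kg nutrient).  Infeasible targets
    are kept as rows of NaN with ``feasible = False``.
    """
    targets = sorted(float(t) for t in targets)
    rows = []
    for t in targets:
        row: Dict[str, float] = {"target_yield": t, "feasible": True}
        try:
            bal = balanced_uptake(t, coeffs, tol=tol, uptake_combine=uptake_combine)
        except (InfeasibleTargetError, ConvergenceError):
            row["feasible"] = False
            for n in NUTRIENTS:
                row[f"U_{n}"] = np.nan
                row[f"RPhE_{n}"] = np.nan
                row[f"PhE_{n}"] = np.nan
            rows.append(row)
            continue
        for n in NUTRIENTS:
            row[f"U_{n}"] = bal.uptake[n]
            row[f"RPhE_{n}"] = bal.rphe[n]
            row[f"PhE_{n}"] = bal.phe[n]
        rows.append(row)
    df = pd.DataFrame(rows)
    df.attrs["zone"] = coeffs.zone
    df.attrs["y_max"] = coeffs.y_max
    return df
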