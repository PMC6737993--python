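"""Forward QUEFTS engine: supplies -> uptakes -> yield ranges -> ultimate yield.

QUEFTS (QUantitative Evaluation of the Fertility of Tropical Soils) converts
the potential supplies of plant-available N, P and K into a grain-yield
estimate in four steps.  This module implements steps 2-4:

* step 2 -- piecewise relation between the supply of a nutrient and its
  actual uptake, accounting for the supply of each partner nutrient;
* step 3 -- yield range of each nutrient between maximum accumulation
  (slope ``a``, the least efficient conversion of nutrient to grain) and
  maximum dilution (slope ``d``, the most efficient conversion);
* step 4 -- parabolic combination of yield ranges for every ordered
  nutrient pair, capped by the partner dilution yields and the potential
  yield, averaged into the ultimate estimate ``YU``.

All yields are kg grain per ha, uptakes and supplies kg nutrient per ha.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Dict, Iterable, Mapping, Tuple

import numpy as np

__all__ = [
    "NUTRIENTS",
    "CropCoefficients",
    "YieldResult",
    "actual_uptake",
    "yield_range",
    "pairwise_yield",
    "ultimate_yield",
]

#: The three macronutrients of the model, in canonical order.
NUTRIENTS: Tuple[str, str, str] = ("N", "P", "K")


def _as_triple(values: Mapping[str, float] | Iterable[float]) -> Dict[str, float]:
    if isinstance(values, Mapping):
        return {n: float(values[n]) for n in NUTRIENTS}
    seq = [float(v) for v in values]
    if len(seq) != 3:
        raise ValueError("expected one value per nutrient (N, P, K)")
    return dict(zip(NUTRIENTS, seq))


@dataclass(frozen=True)
class CropCoefficients:
    """Physiological coefficients of the crop for one zone.

    Parameters
    ----------
    a : mapping or triple
        Physiological efficiency at maximum accumulation, kg grain per kg
        nutrient.  The lower envelope slope of the yield-uptake cloud.
    d : mapping or triple
        Physiological efficiency at maximum dilution, kg grain per kg
        nutrient.  The upper envelope slope; ``a_i < d_i`` for every
        nutrient.
    r : mapping or triple
        Minimum uptake (kg/ha) required to produce any grain.
    y_max : float
        Maximum (potential) yield cap, kg grain per ha.
    zone : str
        Free-form tag ("NGS", "SS", "All", ...), carried for reporting.
    """

    a: Dict[str, float]
    d: Dict[str, float]
    r: Dict[str, float]
    y_max: float = 10_000.0
    zone: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "a", _as_triple(self.a))
        object.__setattr__(self, "d", _as_triple(self.d))
        object.__setattr__(self, "r", _as_triple(self.r))
        for n in NUTRIENTS:
            if not 0.0 < self.a[n] < self.d[n]:
                raise ValueError(
                    f"invalid coefficients for {n}: need 0 < a < d, "
                    f"got a={self.a[n]}, d={self.d[n]}"
                )
            if self.r[n] < 0.0:
                raise ValueError(f"minimum uptake r_{n} must be >= 0")
        if self.y_max <= 0.0:
            raise ValueError("y_max must be positive")

    def replace(self, **kwargs) -> "CropCoefficients":
        data = {"a": self.a, "d": self.d, "r": self.r, "y_max": self.y_max, "zone": self.zone}
        data.update(kwargs)
        return CropCoefficients(**data)


@dataclass(frozen=True)
class YieldResult:
    """Full trace of one forward model evaluation."""

    yu: float
    uptake: Dict[str, float]
    #: uptake of i as limited by each partner j, keyed (i, j)
    pair_uptake: Dict[Tuple[str, str], float]
    #: (Y_ia, Y_id) per nutrient
    ranges: Dict[str, Tuple[float, float]]
    #: Y_ij for every ordered pair, keyed (i, j)
    pair_yield: Dict[Tuple[str, str], float] = field(default_factory=dict)


def actual_uptake(
    s_i: float, s_j: float, coeffs: CropCoefficients, i: str, j: str
) -> float:
    """Uptake of nutrient *i* given its own supply and the supply of *j*.

    Piecewise in ``s_i`` for fixed ``s_j``: full uptake while the partner
    can dilute all of it, a parabolic transition, then a plateau at the
    uptake the partner's maximum-dilution yield can support.  Continuous
    and non-decreasing in both supplies; never exceeds ``s_i``.

    A partner supply at or below its minimum uptake contributes nothing
    (``s_j - r_j`` is floored at zero); uptake then degenerates to
    ``min(s_i, r_i)`` and the downstream yield is zero.
    """
    if i == j:
        raise ValueError("nutrient pair must be distinct")
    if s_i < 0.0 or s_j < 0.0:
        raise ValueError("supplies must be non-negative")
    a_i, d_i = coeffs.a[i], coeffs.d[i]
    a_j, d_j = coeffs.a[j], coeffs.d[j]
    r_i, r_j = coeffs.r[i], coeffs.r[j]

    sj = max(s_j - r_j, 0.0)
    lower = r_i + sj * a_j / d_i
    upper = r_i + sj * (2.0 * d_j / a_i - a_j / d_i)
    if s_i < lower:
        return s_i
    if s_i > upper:
        return r_i + sj * d_j / a_i
    if sj == 0.0:  # lower == upper == r_i
        return min(s_i, r_i)
    return s_i - 0.25 * (s_i - lower) ** 2 / (sj * (d_j / a_i - a_j / d_i))


def yield_range(u_i: float, coeffs: CropCoefficients, i: str) -> Tuple[float, float]:
    """Yield range (Y_ia, Y_id) supported by an uptake of nutrient *i*.

    ``Y_ia = a_i (U_i - r_i)`` and ``Y_id = d_i (U_i - r_i)``; uptake at or
    below the minimum ``r_i`` supports no grain at all, so both ends are
    floored at zero rather than going negative.
    """
    net = u_i - coeffs.r[i]
    if net <= 0.0:
        return (0.0, 0.0)
    return (coeffs.a[i] * net, coeffs.d[i] * net)


def pairwise_yield(
    u_i: float,
    ranges: Mapping[str, Tuple[float, float]],
    coeffs: CropCoefficients,
    i: str,
    j: str,
    k: str,
) -> float:
    """Yield estimate for the ordered nutrient pair (i, j).

    Parabolic interpolation from the accumulation yield of *j* up to the
    cap ``m = min(Y_jd, Y_kd, y_max)`` as the net uptake of *i* grows from
    ``Y_ja / d_i`` (where *i* can just dilute enough to match *j*'s
    accumulation yield) to ``m / a_i`` (where even full accumulation of
    *i* reaches the cap).  Net uptake is clamped to that interval so the
    estimate stays within ``[Y_ja, m]``.
    """
    if len({i, j, k}) != 3:
        raise ValueError("nutrient indices must be distinct")
    y_ja, y_jd = ranges[j]
    y_kd = ranges[k][1]
    m = min(y_jd, y_kd, coeffs.y_max)
    if m <= y_ja:  # degenerate cap: parabola collapses
        return y_ja
    a_i, d_i, r_i = coeffs.a[i], coeffs.d[i], coeffs.r[i]
    lo = y_ja / d_i
    hi = m / a_i
    if hi <= lo:  # division guard
        return y_ja
    x = min(max(u_i - r_i, lo), hi)
    span = hi - lo
    return y_ja + 2.0 * (m - y_ja) * (x - lo) / span - (m - y_ja) * (x - lo) ** 2 / span**2


def ultimate_yield(
    supplies: Mapping[str, float] | Iterable[float],
    coeffs: CropCoefficients,
    uptake_combine: str = "min",
) -> YieldResult:
    """Run steps 2-4: supplies to the ultimate yield estimate.

    The pairwise uptakes ``U_i(j)`` are merged into a single uptake per
    nutrient with ``uptake_combine`` ("min", the limiting partner governs,
    or "mean").  The ultimate estimate is the mean of the six ordered
    pairwise yields, clipped to ``[0, y_max]``; if any nutrient's uptake
    is at or below its minimum ``r_i`` the yield is zero.
    """
    s = _as_triple(supplies)
    for n in NUTRIENTS:
        if s[n] < 0.0:
            raise ValueError("supplies must be non-negative")
    if uptake_combine not in ("min", "mean"):
        raise ValueError("uptake_combine must be 'min' or 'mean'")

    pair_uptake = {
        (i, j): actual_uptake(s[i], s[j], coeffs, i, j)
        for i, j in itertools.permutations(NUTRIENTS, 2)
    }
    agg = min if uptake_combine == "min" else (lambda v: sum(v) / len(list(v)))
    uptake = {
        i: agg([pair_uptake[(i, j)] for j in NUTRIENTS if j != i]) for i in NUTRIENTS
    }
    ranges = {i: yield_range(uptake[i], coeffs, i) for i in NUTRIENTS}

    if any(uptake[i] <= coeffs.r[i] for i in NUTRIENTS):
        return YieldResult(0.0, uptake, pair_uptake, ranges)

    pair_yield = {}
    for i, j in itertools.permutations(NUTRIENTS, 2):
        (k,) = set(NUTRIENTS) - {i, j}
        pair_yield[(i, j)] = pairwise_yield(uptake[i], ranges, coeffs, i, j, k)
    yu = float(np.clip(sum(pair_yield.values()) / 6.0, 0.0, coeffs.y_max))
    return YieldResult(yu, uptake, pair_uptake, ranges, pair_yield)
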