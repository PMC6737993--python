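"""Fitting all model coefficients from plot-level omission-trial data.

The pipeline mirrors how such trials are analysed in practice:

1. multivariate outlier screening (Mahalanobis distance, chi-square cut);
2. field-level 80/20 split into calibration and validation sets;
3. minimum uptake ``r_i`` from the control plots that produced grain;
4. boundary lines of physiological efficiency: the per-plot slopes
   ``grain_yield / (U_i - r_i)`` are enveloped by their lower and upper
   quantiles, giving the efficiency at maximum accumulation (``a_i``)
   and maximum dilution (``d_i``);
5. indigenous-supply equations by best-subset regression of omission-plot
   uptake on soil properties over several functional families, selected
   by BIC;
6. average fertilizer recovery fractions from NPK/omission plot pairs.

Plots with grain harvest index below 0.40 are treated as stressed by
factors other than nutrition and excluded from the efficiency analysis
(steps 4), but kept for minimum uptake and supply fitting.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import curve_fit

from .core import NUTRIENTS, CropCoefficients
from .records import OMISSION_OF
from .supply import FAMILIES, PREDICTORS, RecoveryFractions, SupplyEquation, Term

__all__ = [
    "screen_outliers",
    "filter_ghi",
    "physiological_efficiency",
    "fit_minimum_uptake",
    "fit_boundary_lines",
    "fit_supply_equation",
    "split_calibration_validation",
    "parameterize",
    "FitReport",
]

log = logging.getLogger(__name__)

#: default variable set for multivariate screening: all canonical soil
#: properties plus the harvest and uptake magnitudes
SCREEN_VARIABLES = [
    "pH", "OC_tot", "N_tot", "P_av", "K_exch",
    "grain_yield", "stover_yield", "uptake_N", "uptake_P", "uptake_K",
]

GHI_THRESHOLD = 0.40


def screen_outliers(
    records: pd.DataFrame,
    alpha: float = 0.05,
    variables: Optional[Sequence[str]] = None,
    robust: bool = False,
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Split records into (retained, removed) by Mahalanobis distance.

    Squared distances from the column mean/covariance (classical by
    default, minimum covariance determinant if ``robust``) are compared
    with the chi-square quantile at ``1 - alpha`` for the number of
    screened variables.
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    cols = list(variables or [c for c in SCREEN_VARIABLES if c in records.columns])
    x = records[cols].to_numpy(dtype=float)
    n, p = x.shape
    if n < p + 2:
        raise ValueError(f"need at least {p + 2} records to screen {p} variables")
    if robust:
        from sklearn.covariance import MinCovDet

        mcd = MinCovDet(random_state=0).fit(x)
        center, cov = mcd.location_, mcd.covariance_
    else:
        center = x.mean(axis=0)
        cov = np.cov(x, rowvar=False)
    try:
        vi = np.linalg.inv(cov)
    except np.linalg.LinAlgError:
        log.warning("singular covariance in outlier screen; using pseudo-inverse")
        vi = np.linalg.pinv(cov)
    delta = x - center
    d2 = np.einsum("ij,jk,ik->i", delta, vi, delta)
    cut = stats.chi2.ppf(1.0 - alpha, df=p)
    keep = d2 <= cut
    return records.loc[keep], records.loc[~keep]


def filter_ghi(records: pd.DataFrame, threshold: float = GHI_THRESHOLD) -> pd.DataFrame:
    """Drop records with grain harvest index below the threshold.

    A GHI exactly at the threshold is retained.
    """
    return records.loc[records["ghi"] >= threshold]


def physiological_efficiency(ghi, conc_grain, conc_stover):
    """Physiological efficiency, kg grain (dry) per kg nutrient.

    ``PhE = 1000 * GHI / (GHI * X_g + (1 - GHI) * X_s)`` with tissue mass
    fractions in g/kg.  Vectorized over array inputs.
    """
    ghi = np.asarray(ghi, dtype=float)
    xg = np.asarray(conc_grain, dtype=float)
    xs = np.asarray(conc_stover, dtype=float)
    denom = ghi * xg + (1.0 - ghi) * xs
    if np.any(denom <= 0.0):
        raise ZeroDivisionError("physiological efficiency undefined: zero tissue mass fraction")
    out = 1000.0 * ghi / denom
    return float(out) if out.ndim == 0 else out


def fit_minimum_uptake(records: pd.DataFrame, nutrient: str) -> float:
    """Minimum uptake r_i: the smallest uptake of the nutrient among
    control plots that produced any grain."""
    ctrl = records.loc[
        (records["treatment"] == "control") & (records["grain_yield"] > 0.0)
    ]
    if ctrl.empty:
        raise ValueError("no control plots with non-zero grain yield")
    return float(ctrl[f"uptake_{nutrient}"].min())


def fit_boundary_lines(
    records: pd.DataFrame,
    r_i: float,
    nutrient: str,
    q_low: float = 0.025,
    q_high: float = 0.975,
    min_n: int = 30,
) -> Tuple[float, float]:
    """Envelope slopes (a_i, d_i) of the yield-uptake cloud.

    Each plot with uptake above ``r_i`` contributes the slope of the line
    from (r_i, 0) through its (uptake, yield) point; the a/d envelope is
    the (q_low, q_high) quantile pair of those slopes.  Order-invariant
    and scale-consistent by construction.
    """
    u = records[f"uptake_{nutrient}"].to_numpy(dtype=float)
    y = records["grain_yield"].to_numpy(dtype=float)
    ok = (u > r_i) & (y > 0.0)
    if ok.sum() < min_n:
        raise ValueError(
            f"only {int(ok.sum())} usable plots for the {nutrient} boundary "
            f"lines (need {min_n})"
        )
    slopes = y[ok] / (u[ok] - r_i)
    a_i = float(np.quantile(slopes, q_low))
    d_i = float(np.quantile(slopes, q_high))
    if a_i > d_i:
        raise ValueError("degenerate envelope: a > d")
    if a_i == d_i:
        log.warning("collapsed envelope for %s: all slopes identical", nutrient)
    return a_i, d_i


# ---------------------------------------------------------------------------
# best-subset supply regression


def _ols(
    y: np.ndarray, cols: List[np.ndarray], trim_sigma: float = 3.0
) -> Optional[Tuple[np.ndarray, float]]:
    """Least squares with intercept and one residual-trimming pass.

    Records with residuals beyond ``trim_sigma`` standard deviations are
    dropped once and the model refit: gross single-record deviations
    (e.g. a near-barren field in a supply regression) otherwise drag the
    coefficients.  The returned RSS is over the retained records.
    """
    X = np.column_stack([np.ones_like(y)] + cols) if cols else np.ones((y.size, 1))
    beta, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    if rank < X.shape[1]:
        return None
    resid = y - X @ beta
    if trim_sigma > 0:
        sd = resid.std()
        keep = np.abs(resid) <= trim_sigma * sd if sd > 0 else np.ones_like(resid, bool)
        if keep.sum() >= X.shape[1] + 2 and not keep.all():
            beta2, _, rank2, _ = np.linalg.lstsq(X[keep], y[keep], rcond=None)
            if rank2 == X.shape[1]:
                beta = beta2
    # model comparison uses the full-sample RSS of the final coefficients
    # so trimmed candidates gain no unfair advantage, with the trimmed
    # records' contribution capped at the trim threshold
    resid = y - X @ beta
    if trim_sigma > 0:
        sd = resid.std()
        if sd > 0:
            resid = np.clip(resid, -trim_sigma * sd, trim_sigma * sd)
    return beta, float(resid @ resid)


def _bic(rss: float, n: int, k: int) -> float:
    return n * np.log(max(rss, 1e-10) / n) + k * np.log(n)


def _r2(rss: float, y: np.ndarray) -> float:
    tss = float(np.sum((y - y.mean()) ** 2))
    return 1.0 - rss / tss if tss > 0 else 0.0


def fit_supply_equation(
    soils: pd.DataFrame,
    uptake: Sequence[float],
    nutrient: str,
    candidate_predictors: Optional[Sequence[str]] = None,
    families: Sequence[str] = FAMILIES,
    max_terms: int = 2,
) -> SupplyEquation:
    """Best-subset indigenous-supply regression over functional families.

    Enumerates predictor subsets (up to ``max_terms``) within each family
    -- linear terms, single-predictor powers 2 and 3 (polynomial), log
    transforms, and the single-predictor exponential and Cauchy forms
    fitted by nonlinear least squares -- and returns the minimum-BIC
    equation.  Ties break toward fewer terms, then family order.
    """
    preds = list(candidate_predictors or PREDICTORS)
    y = np.asarray(uptake, dtype=float)
    if y.size < 10:
        raise ValueError("need at least 10 fields to fit a supply equation")
    xcol = {p: soils[p].to_numpy(dtype=float) for p in preds}

    candidates = []  # (bic, n_terms, family_rank, eq)

    def push(family: str, intercept: float, terms: List[Term], rss: float, k: int):
        rank = families.index(family) if family in families else len(families)
        candidates.append(
            (
                _bic(rss, y.size, k),
                len(terms),
                rank,
                SupplyEquation(
                    nutrient=nutrient,
                    family=family,
                    intercept=float(intercept),
                    terms=tuple(terms),
                    r2=_r2(rss, y),
                    bic=_bic(rss, y.size, k),
                ),
            )
        )

    # intercept-only null model (listed as linear with no terms)
    fit = _ols(y, [])
    push("linear", fit[0][0], [], fit[1], 1)

    for family in families:
        if family == "linear":
            for size in range(1, max_terms + 1):
                for subset in itertools.combinations(preds, size):
                    fit = _ols(y, [xcol[p] for p in subset])
                    if fit is None:
                        log.warning("collinear subset %s dropped", subset)
                        continue
                    beta, rss = fit
                    terms = [Term(p, float(b)) for p, b in zip(subset, beta[1:])]
                    push(family, beta[0], terms, rss, 1 + size)
        elif family == "polynomial":
            for size in range(1, max_terms + 1):
                for subset in itertools.combinations(preds, size):
                    for powers in itertools.product((1, 2, 3), repeat=size):
                        if all(p == 1 for p in powers):
                            continue  # identical to the linear candidate
                        cols = [xcol[p] ** w for p, w in zip(subset, powers)]
                        fit = _ols(y, cols)
                        if fit is None:
                            continue
                        beta, rss = fit
                        terms = [
                            Term(p, float(b), power=w)
                            for p, w, b in zip(subset, powers, beta[1:])
                        ]
                        push(family, beta[0], terms, rss, 1 + size)
        elif family == "logarithmic":
            for size in range(1, max_terms + 1):
                for subset in itertools.combinations(preds, size):
                    if any(np.any(xcol[p] <= 0.0) for p in subset):
                        continue
                    cols = [np.log(xcol[p]) for p in subset]
                    fit = _ols(y, cols)
                    if fit is None:
                        continue
                    beta, rss = fit
                    terms = [Term(p, float(b), func="log") for p, b in zip(subset, beta[1:])]
                    push(family, beta[0], terms, rss, 1 + size)
        elif family == "exponential":
            # single-predictor c0 + c1 exp(rate x); amplitude and rate
            # bounded to the data scale to exclude degenerate plateaus
            yspan = max(float(y.max() - y.min()), 1e-6)
            for p in preds:
                x = xcol[p]
                xspan = max(float(x.max() - x.min()), 1e-6)

                def f(x, c0, c1, rate):
                    return c0 + c1 * np.exp(np.clip(rate * x, -50.0, 50.0))

                try:
                    popt, _ = curve_fit(
                        f, x, y, p0=(float(y.mean()), yspan / 2, 1.0 / xspan),
                        bounds=([y.min() - 5 * yspan, -5 * yspan, -10.0 / xspan],
                                [y.max() + 5 * yspan, 5 * yspan, 10.0 / xspan]),
                        maxfev=5000,
                    )
                except (RuntimeError, ValueError):
                    continue
                rss = float(np.sum((y - f(x, *popt)) ** 2))
                terms = [Term(p, float(popt[1]), func="exp", params=(float(popt[2]),))]
                push(family, popt[0], terms, rss, 3)
        elif family == "cauchy":
            yspan = max(float(y.max() - y.min()), 1e-6)
            for p in preds:
                x = xcol[p]
                sx = max(float(np.std(x)), 1e-6)
                xr = (float(x.min()), float(x.max()))

                def f(x, c0, c1, loc, scale):
                    return c0 + c1 / (1.0 + ((x - loc) / scale) ** 2)

                try:
                    popt, _ = curve_fit(
                        f, x, y,
                        p0=(float(y.min()), yspan, float(np.median(x)), sx),
                        bounds=([y.min() - 5 * yspan, -5 * yspan,
                                 xr[0] - (xr[1] - xr[0]), sx / 10],
                                [y.max() + 5 * yspan, 5 * yspan,
                                 xr[1] + (xr[1] - xr[0]), 10 * (xr[1] - xr[0]) + sx]),
                        maxfev=5000,
                    )
                except (RuntimeError, ValueError):
                    continue
                rss = float(np.sum((y - f(x, *popt)) ** 2))
                terms = [
                    Term(p, float(popt[1]), func="cauchy", params=(float(popt[2]), abs(float(popt[3]))))
                ]
                push(family, popt[0], terms, rss, 4)
        else:
            raise ValueError(f"unknown family {family!r}")

    candidates.sort(key=lambda c: (c[0], c[1], c[2]))
    return candidates[0][3]


def split_calibration_validation(
    records: pd.DataFrame, fraction: float = 0.8, seed: int = 0
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Random field-level split: all plots of a field stay together."""
    if not 0.0 < fraction < 1.0:
        raise ValueError("fraction must be in (0, 1)")
    fields = np.array(sorted(records["field_id"].unique()))
    rng = np.random.default_rng(seed)
    rng.shuffle(fields)
    n_cal = int(round(fraction * fields.size))
    cal_fields = set(fields[:n_cal])
    mask = records["field_id"].isin(cal_fields)
    return records.loc[mask], records.loc[~mask]


# ---------------------------------------------------------------------------
# full pipeline


@dataclass
class FitReport:
    """Counts and fitted quantities of one parameterization run."""

    zone: str
    seed: int
    n_input: int
    n_outliers_removed: int
    n_calibration: int
    n_validation: int
    n_ghi_removed: int
    coeffs: CropCoefficients
    equations: Dict[str, SupplyEquation]
    recovery: RecoveryFractions
    q_low: float = 0.025
    q_high: float = 0.975
    alpha: float = 0.05

    def summary(self) -> str:
        lines = [
            f"zone: {self.zone}   seed: {self.seed}",
            f"records: {self.n_input} in, {self.n_outliers_removed} outliers removed, "
            f"{self.n_calibration} calibration / {self.n_validation} validation, "
            f"{self.n_ghi_removed} below GHI {GHI_THRESHOLD} (efficiency analysis only)",
            "crop coefficients (a / d kg grain per kg nutrient, r kg/ha):",
        ]
        for n in NUTRIENTS:
            lines.append(
                f"  {n}: a={self.coeffs.a[n]:.1f} d={self.coeffs.d[n]:.1f} r={self.coeffs.r[n]:.2f}"
            )
        lines.append("recovery fractions: " + ", ".join(
            f"{n}={self.recovery.R[n]:.2f}" for n in NUTRIENTS))
        for n in NUTRIENTS:
            eq = self.equations[n]
            lines.append(
                f"supply {n}: {eq.family}, {len(eq.terms)} term(s), "
                f"R2={eq.r2:.2f}"
            )
        return "\n".join(lines)


def _recovery_from_pairs(records: pd.DataFrame, nutrient: str) -> float:
    """Zone-average recovery fraction from per-field NPK/omission pairs."""
    omission = OMISSION_OF[nutrient]
    vals = []
    for _, grp in records.groupby("field_id"):
        npk = grp.loc[grp["treatment"] == "NPK"]
        omi = grp.loc[grp["treatment"] == omission]
        if npk.empty or omi.empty:
            continue
        f_i = float(npk[f"applied_{nutrient}"].iloc[0])
        if f_i <= 0.0:
            continue
        vals.append(
            (float(npk[f"uptake_{nutrient}"].iloc[0]) - float(omi[f"uptake_{nutrient}"].iloc[0]))
            / f_i
        )
    if not vals:
        raise ValueError(f"no NPK/{omission} plot pairs to estimate recovery of {nutrient}")
    mean = float(np.mean(vals))
    if not 0.0 <= mean <= 1.0:
        log.warning("zone-average recovery of %s = %.3f clipped into [0, 1]", nutrient, mean)
        mean = min(max(mean, 0.0), 1.0)
    return mean


def parameterize(
    records: pd.DataFrame,
    zone: str = "All",
    seed: int = 0,
    alpha: float = 0.05,
    fraction: float = 0.8,
    q_low: float = 0.025,
    q_high: float = 0.975,
    y_max: float = 10_000.0,
    robust_screen: bool = False,
    max_terms: int = 2,
    families: Sequence[str] = FAMILIES,
) -> Tuple[FitReport, pd.DataFrame]:
    """Run the full fitting pipeline; returns the report and the
    validation partition (screened, un-filtered by GHI)."""
    df = records if zone == "All" else records.loc[records["zone"] == zone]
    n_input = len(df)
    retained, removed = screen_outliers(df, alpha=alpha, robust=robust_screen)
    cal, val = split_calibration_validation(retained, fraction=fraction, seed=seed)

    r = {n: fit_minimum_uptake(cal, n) for n in NUTRIENTS}

    env = filter_ghi(cal)
    n_ghi_removed = len(cal) - len(env)
    a, d = {}, {}
    for n in NUTRIENTS:
        a[n], d[n] = fit_boundary_lines(env, r[n], n, q_low=q_low, q_high=q_high)

    eqs = {}
    for n in NUTRIENTS:
        omi = cal.loc[cal["treatment"] == OMISSION_OF[n]]
        fields = omi.drop_duplicates(subset="field_id")
        eqs[n] = fit_supply_equation(
            fields, fields[f"uptake_{n}"].to_numpy(), n,
            families=families, max_terms=max_terms,
        )
        eqs[n] = SupplyEquation(
            nutrient=n, family=eqs[n].family, intercept=eqs[n].intercept,
            terms=eqs[n].terms, r2=eqs[n].r2, bic=eqs[n].bic,
            zone=zone, source="fitted",
        )

    rec = RecoveryFractions(
        R={n: _recovery_from_pairs(cal, n) for n in NUTRIENTS}, zone=zone
    )
    report = FitReport(
        zone=zone, seed=seed,
        n_input=n_input, n_outliers_removed=len(removed),
        n_calibration=len(cal), n_validation=len(val),
        n_ghi_removed=n_ghi_removed,
        coeffs=CropCoefficients(a=a, d=d, r=r, y_max=y_max, zone=zone),
        equations=eqs, recovery=rec,
        q_low=q_low, q_high=q_high, alpha=alpha,
    )
    return report, val
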