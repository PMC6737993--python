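"""Plot-table CSV schema and coefficient-file round trips.

The plot table is one CSV row per treatment plot.  Column dictionary:

====================  =========================================================
column                meaning / units
====================  =========================================================
field_id              field identifier (all plots of a field share it)
zone                  agro-ecological zone tag (NGS or SS)
season                cropping season label
variety_group         OPV or hybrid
treatment             control | minusN | minusP | minusK | NPK | NPKplus
pH                    topsoil pH in water (1:1)
OC_tot                total organic carbon, g/kg
N_tot                 total nitrogen, g/kg
P_av                  available P (Mehlich-3), mg/kg
K_exch                exchangeable K, cmol_c/kg
applied_N/P/K         fertilizer applied, kg/ha
grain_yield           grain yield at 15% moisture, kg/ha
stover_yield          stover yield, oven-dry kg/ha
ghi                   grain harvest index (dry grain / total dry matter)
grain_N/P/K           nutrient mass fraction in grain, g/kg
stover_N/P/K          nutrient mass fraction in stover, g/kg
uptake_N/P/K          total above-ground uptake, kg/ha (derived; recomputed
                      and checked on read)
====================  =========================================================
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Dict, Iterator, List, Union

import numpy as np
import pandas as pd
import yaml

from .core import NUTRIENTS, CropCoefficients
from .parameterization import FitReport
from .records import TREATMENTS, PlotRecord, uptake_from_tissue
from .supply import (
    CoefficientBundle,
    RecoveryFractions,
    SoilProfile,
    SupplyEquation,
    load_registry,
)

__all__ = [
    "PLOT_COLUMNS",
    "SchemaError",
    "read_plot_table",
    "write_plot_table",
    "records_from_frame",
    "read_coefficients",
    "write_coefficients",
]

log = logging.getLogger(__name__)

SOIL_COLUMNS = ["pH", "OC_tot", "N_tot", "P_av", "K_exch"]

PLOT_COLUMNS: List[str] = (
    ["field_id", "zone", "season", "variety_group", "treatment"]
    + SOIL_COLUMNS
    + [f"applied_{n}" for n in NUTRIENTS]
    + ["grain_yield", "stover_yield", "ghi"]
    + [f"grain_{n}" for n in NUTRIENTS]
    + [f"stover_{n}" for n in NUTRIENTS]
    + [f"uptake_{n}" for n in NUTRIENTS]
)

GRAIN_MOISTURE = 0.15


class SchemaError(ValueError):
    """The plot table does not match the documented column layout."""


def _check_units(df: pd.DataFrame) -> None:
    if (df["P_av"] > 1000).any():
        log.warning("P_av values above 1000 mg/kg: check units (expected mg/kg)")
    if (df["K_exch"] > 20).any():
        log.warning("K_exch values above 20 cmol_c/kg: check units")
    if ((df["pH"] < 3) | (df["pH"] > 10)).any():
        log.warning("pH values outside (3, 10): check the column")
    if (df["grain_yield"] > 20_000).any():
        log.warning("grain yields above 20 t/ha: check units (expected kg/ha)")


def read_plot_table(path: Union[str, Path], grain_moisture: float = GRAIN_MOISTURE) -> pd.DataFrame:
    """Read and validate a plot-table CSV.

    The header must match the documented schema exactly (uptake columns
    are optional and recomputed from the tissue data either way; stored
    uptakes off by more than 0.1% raise).  Unknown treatment codes raise
    with the offending row number.
    """
    df = pd.read_csv(path)
    optional = {f"uptake_{n}" for n in NUTRIENTS}
    required = [c for c in PLOT_COLUMNS if c not in optional]
    missing = [c for c in required if c not in df.columns]
    extra = [c for c in df.columns if c not in PLOT_COLUMNS]
    if missing or extra:
        raise SchemaError(f"plot table schema mismatch: missing={missing}, extra={extra}")

    bad = df.loc[~df["treatment"].isin(TREATMENTS)]
    if not bad.empty:
        row = bad.index[0]
        raise SchemaError(
            f"unknown treatment code {bad['treatment'].iloc[0]!r} at row {row + 2}"
        )
    for col in PLOT_COLUMNS[5:]:
        if col in df.columns:
            df[col] = pd.to_numeric(df[col])
    _check_units(df)

    for n in NUTRIENTS:
        implied = uptake_from_tissue(
            df["grain_yield"], df["stover_yield"],
            df[f"grain_{n}"], df[f"stover_{n}"], grain_moisture,
        )
        col = f"uptake_{n}"
        if col in df.columns:
            off = np.abs(df[col] - implied) > 1e-3 * np.maximum(implied, 1e-9)
            if off.any():
                row = int(np.argmax(off.to_numpy()))
                raise SchemaError(
                    f"stored uptake_{n} inconsistent with tissue data at row {row + 2}"
                )
        df[col] = implied
    return df[PLOT_COLUMNS]


def write_plot_table(df: pd.DataFrame, path: Union[str, Path]) -> None:
    """Write a plot table in the documented column order; bookkeeping
    columns (leading underscore) are dropped."""
    out = df[[c for c in PLOT_COLUMNS if c in df.columns]]
    out.to_csv(path, index=False)


def records_from_frame(df: pd.DataFrame, grain_moisture: float = GRAIN_MOISTURE) -> Iterator[PlotRecord]:
    """Iterate typed :class:`PlotRecord` objects over a plot table."""
    for _, row in df.iterrows():
        yield PlotRecord(
            field_id=str(row["field_id"]),
            zone=str(row["zone"]),
            season=str(row["season"]),
            variety_group=str(row["variety_group"]),
            treatment=str(row["treatment"]),
            soil=SoilProfile(**{c: float(row[c]) for c in SOIL_COLUMNS}),
            applied={n: float(row[f"applied_{n}"]) for n in NUTRIENTS},
            grain_yield=float(row["grain_yield"]),
            stover_yield=float(row["stover_yield"]),
            ghi=float(row["ghi"]),
            conc_grain={n: float(row[f"grain_{n}"]) for n in NUTRIENTS},
            conc_stover={n: float(row[f"stover_{n}"]) for n in NUTRIENTS},
            uptake={n: float(row[f"uptake_{n}"]) for n in NUTRIENTS}
            if f"uptake_N" in df.columns else {},
            grain_moisture=grain_moisture,
        )


# ---------------------------------------------------------------------------
# coefficient files


def _term_to_dict(t) -> Dict:
    d = {"predictor": t.predictor, "coef": round(float(t.coef), 10)}
    if t.power != 1:
        d["power"] = int(t.power)
    if t.func != "identity":
        d["func"] = t.func
    if t.params:
        d["params"] = [round(float(p), 10) for p in t.params]
    return d


def _equation_to_dict(eq: SupplyEquation) -> Dict:
    d = {
        "family": eq.family,
        "intercept": round(float(eq.intercept), 10),
        "terms": [_term_to_dict(t) for t in eq.terms],
    }
    if eq.r2 is not None:
        d["r2"] = round(float(eq.r2), 6)
    if eq.bic is not None:
        d["bic"] = round(float(eq.bic), 6)
    return d


def _zone_to_dict(bundle: CoefficientBundle) -> Dict:
    c = bundle.coeffs
    return {
        "crop": {
            "a": {n: float(c.a[n]) for n in NUTRIENTS},
            "d": {n: float(c.d[n]) for n in NUTRIENTS},
            "r": {n: float(c.r[n]) for n in NUTRIENTS},
            "y_max": float(c.y_max),
        },
        "recovery": {n: float(bundle.recovery.R[n]) for n in NUTRIENTS},
        "supply": {n: _equation_to_dict(bundle.equations[n]) for n in NUTRIENTS},
    }


def write_coefficients(
    fit: Union[FitReport, Dict[str, CoefficientBundle]], path: Union[str, Path]
) -> None:
    """Serialize fitted coefficients (a FitReport or a zone->bundle map)
    to the structured YAML format read by :func:`read_coefficients`.

    write -> read -> write is byte-identical.
    """
    if isinstance(fit, FitReport):
        bundles = {
            fit.zone: CoefficientBundle(fit.coeffs, fit.recovery, fit.equations, "fitted")
        }
        source = "fitted"
    else:
        bundles = fit
        source = next(iter(bundles.values())).source or "fitted"
    doc = {
        "version": 1,
        "source": source,
        "zones": {z: _zone_to_dict(b) for z, b in sorted(bundles.items())},
    }
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=True))


def read_coefficients(path: Union[str, Path]) -> Dict[str, CoefficientBundle]:
    """Load a coefficient file into one bundle per zone."""
    text = Path(path).read_text()
    doc = yaml.safe_load(text)
    if doc.get("version", 1) != 1:
        log.warning("coefficient file version %s newer than supported (1)", doc.get("version"))
    return load_registry(text)
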