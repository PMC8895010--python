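"""CSV and JSON structured I/O for the analysis stages.

Input schemas (headers required, UTF-8, decimal point):

======================  ==============================================
dataset                 columns
======================  ==============================================
SLS / Debye plot        ``conc_mg_per_ml, kc_over_r[, sigma]``
NMR dilution shifts     ``carbon, conc_M, shift_ppm[, sigma]`` (long)
DOSY attenuation        ``gradient_T_per_m, intensity``
======================  ==============================================

Reports are JSON objects whose entries carry ``value``, ``unit`` and
``provenance`` so a derived constant can always be traced to the fit or
printed constant that produced it.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import SchemaError
from .hydrodynamics import GAMMA_1H, DosyExperiment
from .sls_thermo import ConcentrationSeries

SLS_SCHEMA = ["conc_mg_per_ml", "kc_over_r"]
SHIFTS_SCHEMA = ["carbon", "conc_M", "shift_ppm"]
DOSY_SCHEMA = ["gradient_T_per_m", "intensity"]


def read_table(path: str | Path, schema: list[str]) -> pd.DataFrame:
    """Read a CSV and validate it against a required-column schema.

    Missing columns raise :class:`SchemaError` naming the column;
    non-numeric cells in numeric columns raise with the offending row
    index.  Extra columns (e.g. ``sigma``) pass through.
    """
    path = Path(path)
    if not path.exists():
        raise SchemaError(f"input file not found: {path}")
    df = pd.read_csv(path, float_precision="round_trip")
    for col in schema:
        if col not in df.columns:
            raise SchemaError(f"missing required column {col!r} in {path.name}")
    numeric_cols = [c for c in df.columns if c != "carbon"]
    for col in numeric_cols:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[coerced.isna() & df[col].notna()]
        if len(bad):
            raise SchemaError(
                f"non-numeric value in column {col!r} at row(s) {list(bad)} of {path.name}"
            )
        if coerced.isna().any():
            raise SchemaError(f"missing value in column {col!r} of {path.name}")
        df[col] = coerced
    return df


def read_sls_csv(path: str | Path, temperature: float = 298.15) -> ConcentrationSeries:
    """Load a Debye-plot series (``conc_mg_per_ml, kc_over_r[, sigma]``)."""
    df = read_table(path, SLS_SCHEMA)
    df = df.sort_values("conc_mg_per_ml")
    sigma = df["sigma"].to_numpy() if "sigma" in df.columns else None
    return ConcentrationSeries(
        concentration=df["conc_mg_per_ml"].to_numpy(), value=df["kc_over_r"].to_numpy(),
        unit="mg/ml", sigma=sigma, temperature=temperature, label="sls",
    )


def read_shifts_csv(path: str | Path, temperature: float = 298.15) -> list[ConcentrationSeries]:
    """Load long-format dilution shifts (``carbon, conc_M, shift_ppm[, sigma]``)."""
    df = read_table(path, SHIFTS_SCHEMA)
    out = []
    for carbon, grp in df.groupby("carbon", sort=True):
        grp = grp.sort_values("conc_M")
        sigma = grp["sigma"].to_numpy() if "sigma" in grp.columns else None
        out.append(ConcentrationSeries(
            concentration=grp["conc_M"].to_numpy(), value=grp["shift_ppm"].to_numpy(),
            unit="M", sigma=sigma, temperature=temperature, label=str(carbon),
        ))
    return out


def read_dosy_csv(
    path: str | Path,
    gamma: float = GAMMA_1H,
    delta_little: float = 4e-3,
    delta_big: float = 0.1,
) -> DosyExperiment:
    """Load a gradient-attenuation series; pulse parameters come from the caller."""
    df = read_table(path, DOSY_SCHEMA)
    df = df.sort_values("gradient_T_per_m")
    return DosyExperiment(
        gradient_strengths=df["gradient_T_per_m"].to_numpy(),
        intensities=df["intensity"].to_numpy(),
        gamma=gamma, delta_little=delta_little, delta_big=delta_big,
    )


def write_sls_csv(series: ConcentrationSeries, path: str | Path) -> None:
    data = {"conc_mg_per_ml": series.concentration, "kc_over_r": series.value}
    if series.sigma is not None:
        data["sigma"] = series.sigma
    pd.DataFrame(data).to_csv(path, index=False, float_format="%.17g")


def write_shifts_csv(series_list: list[ConcentrationSeries], path: str | Path) -> None:
    frames = []
    for s in series_list:
        data = {"carbon": s.label, "conc_M": s.concentration, "shift_ppm": s.value}
        if s.sigma is not None:
            data["sigma"] = s.sigma
        frames.append(pd.DataFrame(data))
    pd.concat(frames, ignore_index=True).to_csv(path, index=False, float_format="%.17g")


def write_dosy_csv(experiment: DosyExperiment, path: str | Path) -> None:
    pd.DataFrame({
        "gradient_T_per_m": experiment.gradient_strengths,
        "intensity": experiment.intensities,
    }).to_csv(path, index=False, float_format="%.17g")


def _jsonable(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def write_report(report: dict, path: str | Path) -> None:
    """Write a structured report as indented JSON."""
    Path(path).write_text(json.dumps(_jsonable(report), indent=2) + "\n")


def read_report(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())
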