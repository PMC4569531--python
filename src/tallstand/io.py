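"""CSV readers and writers for census, plot and species tables.

Dialect: comma-separated UTF-8 with a mandatory header row; the empty
string encodes a missing value. Column names carry units (``dbh_cm``,
``map_mm``) in files and are stripped to bare field names in memory.
"""
from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .errors import DuplicateTagError, SchemaError
from .records import Census, _coerce_bool

# file column -> in-memory field
STEM_COLUMNS = {
    "stem_tag": "stem_tag",
    "plot_id": "plot_id",
    "species": "species",
    "dbh_cm": "dbh",
    "pom_m": "pom",
    "x_m": "x",
    "y_m": "y",
    "canopy_position": "canopy_position",
    "growth_stage": "growth_stage",
    "stem_form": "stem_form",
    "alive": "alive",
    "mortality_code": "mortality_code",
    "height_m": "height",
    "buttressed": "buttressed",
}
PLOT_COLUMNS = {
    "plot_id": "plot_id",
    "region": "region",
    "area_ha": "area_ha",
    "mat_c": "mat",
    "map_mm": "map",
    "pan_evap_mm": "pan_evap",
    "elevation_m": "elevation",
    "establishment_year": "establishment_year",
    "census_date": "census_date",
    "agc_excluded": "agc_excluded",
}
SPECIES_COLUMNS = {"species": "species", "guild": "guild", "is_eucalypt": "is_eucalypt"}

_STEM_FLOATS = ["dbh", "pom", "x", "y", "height"]
_PLOT_FLOATS = ["area_ha", "mat", "map", "pan_evap", "elevation"]


def _read_table(path, columns: dict, label: str) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise SchemaError(f"{label} file not found: {path}")
    df = pd.read_csv(path, dtype=str, keep_default_na=False, encoding="utf-8")
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise SchemaError(f"{label} file {path} missing mandatory column(s): {', '.join(missing)}")
    df = df[list(columns)].rename(columns=columns)
    return df


def _parse_float(v):
    # builtin float() is a correctly-rounded parser; pandas' fast path is not
    if v == "":
        return np.nan
    try:
        return float(v)
    except ValueError:
        return None


def _to_float(df: pd.DataFrame, cols, label: str, optional=()) -> None:
    for col in cols:
        parsed = df[col].map(_parse_float)
        bad = parsed.isna() & (df[col] != "")
        vals = parsed.astype(float)
        if bad.any():
            rows = ", ".join(str(i) for i in df.index[bad][:10])
            raise SchemaError(f"{label}: unparseable numeric value(s) in '{col}' at row(s) {rows}")
        if col not in optional and vals.isna().any():
            rows = ", ".join(str(i) for i in df.index[vals.isna()][:10])
            raise SchemaError(f"{label}: missing value(s) in mandatory column '{col}' at row(s) {rows}")
        df[col] = vals


def read_census(census_path, plots_path, species_path) -> Census:
    """Read a stem census, its plot table and species-guild lookup.

    Every row is parsed or the offending rows are reported in the raised
    error; nothing is silently dropped. Duplicate stem tags raise
    :class:`DuplicateTagError`.
    """
    stems = _read_table(census_path, STEM_COLUMNS, "census")
    plots = _read_table(plots_path, PLOT_COLUMNS, "plots")
    species = _read_table(species_path, SPECIES_COLUMNS, "species")

    _to_float(stems, _STEM_FLOATS, "census", optional=("height",))
    stems["alive"] = _coerce_bool(stems["alive"])
    stems["buttressed"] = _coerce_bool(stems["buttressed"])

    dup = stems["stem_tag"][stems["stem_tag"].duplicated()]
    if len(dup):
        raise DuplicateTagError(dup.unique())

    _to_float(plots, _PLOT_FLOATS, "plots", optional=("elevation",))
    plots["agc_excluded"] = _coerce_bool(plots["agc_excluded"])
    year = plots["establishment_year"].map(lambda v: np.nan if v == "" else float(v))
    plots["establishment_year"] = year.astype("Int64")

    species["is_eucalypt"] = _coerce_bool(species["is_eucalypt"])

    return Census(plots=plots, stems=stems, species=species)


def write_census(census: Census, census_path, plots_path, species_path) -> None:
    """Write the three tables with the documented file column names.

    Round-trips with :func:`read_census`: numeric values are written with
    :func:`repr` precision so re-reading reproduces them bit for bit.
    """
    stems = census.stems.rename(columns={v: k for k, v in STEM_COLUMNS.items()})
    plots = census.plots.rename(columns={v: k for k, v in PLOT_COLUMNS.items()})
    species = census.species.rename(columns={v: k for k, v in SPECIES_COLUMNS.items()})
    for df, path, cols in (
        (stems, census_path, STEM_COLUMNS),
        (plots, plots_path, PLOT_COLUMNS),
        (species, species_path, SPECIES_COLUMNS),
    ):
        df[list(cols)].to_csv(path, index=False, encoding="utf-8", float_format="%.17g")
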