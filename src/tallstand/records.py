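"""Domain types for permanent-plot stem censuses.

A census couples three tables: one row per tagged stem (>= 10 cm DBH),
one row per 1-ha plot with its climate attributes, and a species lookup
assigning every censused species to one of three guilds (eucalypt, wet
sclerophyll, rainforest).
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import SchemaError

#: Crown position of a stem relative to the canopy. "none" covers stems
#: (e.g. dead trees) without an assessed position.
CANOPY_POSITIONS = ("suppressed", "dominant", "co-dominant", "emergent", "none")

#: Developmental state of a tree.
GROWTH_STAGES = ("regrowth", "regenerating", "mature", "senescent", "none")

#: Species guilds: eucalypts (incl. Corymbia), wet sclerophyll, rainforest.
GUILDS = ("Euc", "Scl", "RF")


@dataclass
class StemRecord:
    """One tagged stem.

    DBH is in cm, measured at the point of measurement ``pom`` (m above
    ground, 1.3 m unless buttressing or deformity forces it higher).
    Coordinates are metres from the georeferenced (0, 0) plot corner.
    """

    stem_tag: str
    plot_id: str
    species: str
    dbh: float
    pom: float = 1.3
    x: float = 0.0
    y: float = 0.0
    canopy_position: str = "none"
    growth_stage: str = "none"
    stem_form: str = ""
    alive: bool = True
    mortality_code: str = ""
    height: float | None = None
    buttressed: bool = False


@dataclass
class PlotRecord:
    """One permanent plot with its climate and exclusion attributes."""

    plot_id: str
    region: str
    area_ha: float = 1.0
    mat: float = float("nan")
    map: float = float("nan")
    pan_evap: float = float("nan")
    elevation: float = float("nan")
    establishment_year: int | None = None
    census_date: str = ""
    agc_excluded: bool = False


@dataclass
class SpeciesRecord:
    """Species-to-guild assignment; eucalypt covers Eucalyptus and Corymbia."""

    species: str
    guild: str
    is_eucalypt: bool = False

    def __post_init__(self) -> None:
        if self.guild not in GUILDS:
            raise SchemaError(f"unknown guild {self.guild!r} for {self.species!r}")
        if (self.guild == "Euc") != self.is_eucalypt:
            raise SchemaError(
                f"species {self.species!r}: guild {self.guild!r} inconsistent "
                f"with is_eucalypt={self.is_eucalypt}"
            )


STEM_FIELDS = [f.name for f in dataclasses.fields(StemRecord)]
PLOT_FIELDS = [f.name for f in dataclasses.fields(PlotRecord)]
SPECIES_FIELDS = [f.name for f in dataclasses.fields(SpeciesRecord)]


def _records_to_frame(records: Iterable, fields: Sequence[str]) -> pd.DataFrame:
    rows = [dataclasses.asdict(r) for r in records]
    if not rows:
        return pd.DataFrame(columns=fields)
    return pd.DataFrame(rows, columns=fields)


def stems_frame(stems) -> pd.DataFrame:
    """Coerce a stems argument (DataFrame or iterable of StemRecord)."""
    if isinstance(stems, pd.DataFrame):
        return stems
    return _records_to_frame(stems, STEM_FIELDS)


def plots_frame(plots) -> pd.DataFrame:
    if isinstance(plots, pd.DataFrame):
        return plots
    return _records_to_frame(plots, PLOT_FIELDS)


def species_frame(species) -> pd.DataFrame:
    if isinstance(species, pd.DataFrame):
        return species
    return _records_to_frame(species, SPECIES_FIELDS)


@dataclass
class Census:
    """A single-census snapshot: stems, plots and the species lookup."""

    plots: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(columns=PLOT_FIELDS))
    stems: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(columns=STEM_FIELDS))
    species: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(columns=SPECIES_FIELDS))

    @classmethod
    def from_records(cls, plots, stems, species) -> "Census":
        return cls(
            plots=plots_frame(plots),
            stems=stems_frame(stems),
            species=species_frame(species),
        )

    def live_stems(self, include_dead: bool = False) -> pd.DataFrame:
        if include_dead:
            return self.stems
        return self.stems[self.stems["alive"].astype(bool)]

    def stems_in_plots(self, plot_ids, include_dead: bool = False) -> pd.DataFrame:
        df = self.live_stems(include_dead=include_dead)
        if plot_ids is None:
            return df
        return df[df["plot_id"].isin(list(plot_ids))]

    def stems_with_guild(self, plot_ids=None, include_dead: bool = False) -> pd.DataFrame:
        """Stem table joined with guild / eucalypt flags from the species lookup."""
        df = self.stems_in_plots(plot_ids, include_dead=include_dead)
        lut = self.species[["species", "guild", "is_eucalypt"]]
        return df.merge(lut, on="species", how="left")

    def plot_area(self, plot_id: str) -> float:
        row = self.plots.loc[self.plots["plot_id"] == plot_id]
        if row.empty:
            raise SchemaError(f"unknown plot_id {plot_id!r}")
        return float(row["area_ha"].iloc[0])

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"Census({len(self.plots)} plots, {len(self.stems)} stems, "
            f"{len(self.species)} species)"
        )


def _coerce_bool(series: pd.Series) -> pd.Series:
    """Parse booleans written as True/False/1/0/yes/no (case-insensitive)."""
    if series.dtype == bool:
        return series
    mapping = {
        "true": True, "false": False, "1": True, "0": False,
        "yes": True, "no": False, "t": True, "f": False, "": False,
    }

    def one(v):
        if isinstance(v, (bool, np.bool_)):
            return bool(v)
        if pd.isna(v):
            return False
        s = str(v).strip().lower()
        if s not in mapping:
            raise SchemaError(f"unparseable boolean value {v!r}")
        return mapping[s]

    return series.map(one)
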