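"""Protocol validation for parsed censuses.

Violations are data, not exceptions: :func:`validate_census` returns a
deterministic, ordered report so field teams can fix records in bulk.
"""
from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .records import CANOPY_POSITIONS, GROWTH_STAGES, GUILDS, Census

#: Minimum admissible diameter (cm): the census protocol tags stems >= 10 cm.
MIN_DBH_CM = 10.0

#: Plot coordinate bounds (m) relative to the georeferenced (0, 0) corner.
COORD_RANGE = (0.0, 100.0)


@dataclass(frozen=True)
class Violation:
    """One broken protocol rule, referencing the offending record."""

    rule: str
    plot_id: str
    stem_tag: str
    detail: str

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"[{self.rule}] plot={self.plot_id} tag={self.stem_tag}: {self.detail}"


ValidationReport = list


def validate_census(census: Census) -> list[Violation]:
    """Check every type invariant; empty report means a conformant census.

    The report is ordered by (plot_id, stem_tag, rule) and the function is
    side-effect free, so repeated validation of the same census is stable.
    """
    out: list[Violation] = []
    stems = census.stems
    known_plots = set(census.plots["plot_id"])
    known_species = set(census.species["species"])

    def add(rule, plot, tag, detail):
        out.append(Violation(rule, str(plot), str(tag), detail))

    dup_mask = stems["stem_tag"].duplicated(keep=False)
    for _, row in stems[dup_mask].iterrows():
        add("duplicate_stem_tag", row["plot_id"], row["stem_tag"], "tag occurs more than once")

    for _, row in stems.iterrows():
        plot, tag = row["plot_id"], row["stem_tag"]
        if row["dbh"] < MIN_DBH_CM:
            add("dbh_below_minimum", plot, tag, f"dbh={row['dbh']:g} cm < {MIN_DBH_CM:g} cm")
        if not (row["pom"] > 0):
            add("pom_not_positive", plot, tag, f"pom={row['pom']:g} m")
        lo, hi = COORD_RANGE
        if not (lo <= row["x"] <= hi and lo <= row["y"] <= hi):
            add("coordinate_out_of_range", plot, tag, f"(x, y)=({row['x']:g}, {row['y']:g})")
        if row["canopy_position"] not in CANOPY_POSITIONS:
            add("unknown_canopy_position", plot, tag, repr(row["canopy_position"]))
        if row["growth_stage"] not in GROWTH_STAGES:
            add("unknown_growth_stage", plot, tag, repr(row["growth_stage"]))
        if row["alive"] and row["mortality_code"]:
            add("mortality_code_on_live_stem", plot, tag, repr(row["mortality_code"]))
        h = row["height"]
        if h is not None and pd.notna(h) and not (h > 0):
            add("height_not_positive", plot, tag, f"height={h:g} m")
        if plot not in known_plots:
            add("unknown_plot", plot, tag, "plot_id absent from plot table")
        if row["species"] not in known_species:
            add("unclassified_species", plot, tag, repr(row["species"]))

    for _, row in census.plots.iterrows():
        if not (row["area_ha"] > 0):
            add("plot_area_not_positive", row["plot_id"], "", f"area_ha={row['area_ha']:g}")

    for _, row in census.species.iterrows():
        if row["guild"] not in GUILDS:
            add("unknown_guild", "", row["species"], repr(row["guild"]))
        elif (row["guild"] == "Euc") != bool(row["is_eucalypt"]):
            add("guild_eucalypt_mismatch", "", row["species"],
                f"guild={row['guild']} is_eucalypt={row['is_eucalypt']}")

    out.sort(key=lambda v: (v.plot_id, v.stem_tag, v.rule))
    return out
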