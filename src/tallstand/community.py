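"""Community importance statistics.

The Importance Value (IV) of a taxon is the sum of its relative frequency
(share of plot occurrences), relative density (share of stems) and
relative dominance (share of basal area), each normalized to sum to 100
across taxa, so IV ranges 0-300 and sums to 300 over a community.
"""
from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import EmptyCensusError, UnclassifiedSpeciesError
from .records import Census


def importance_values(census: Census, plot_ids=None, level: str = "species") -> pd.DataFrame:
    """Importance Value table for a plot subset at species or guild level.

    Returns a DataFrame with columns ``taxon, guild, frq, rde, rdo, iv,
    plot_occupancy_pct`` sorted by IV descending (ties alphabetical).

    * ``frq``: plot-occurrence share, 100·f_i/Σf where f_i is the number
      of subset plots containing taxon i (normalized, so Σfrq = 100);
      the raw percentage of plots occupied is kept as
      ``plot_occupancy_pct``.
    * ``rde``: stem-count share, 100·n_i/Σn.
    * ``rdo``: basal-area share, 100·BA_i/ΣBA.
    * ``iv`` = frq + rde + rdo.

    Live stems only. At guild level each guild is treated as one
    aggregated taxon.
    """
    if level not in ("species", "guild"):
        raise ValueError(f"level must be 'species' or 'guild', got {level!r}")
    df = census.stems_with_guild(plot_ids)
    if df.empty:
        raise EmptyCensusError("no live stems in the requested plot subset")
    if level == "guild":
        missing = df.loc[df["guild"].isna(), "species"].unique()
        if len(missing):
            raise UnclassifiedSpeciesError(missing)
        key = "guild"
    else:
        key = "species"

    n_plots = df["plot_id"].nunique() if plot_ids is None else len(set(plot_ids))
    df = df.assign(ba=np.pi * (df["dbh"].astype(float) / 200.0) ** 2)

    grouped = df.groupby(key)
    stats = pd.DataFrame(
        {
            "n_stems": grouped.size(),
            "ba": grouped["ba"].sum(),
            "n_plots_occupied": grouped["plot_id"].nunique(),
        }
    )
    if level == "species":
        guild_of = df.drop_duplicates("species").set_index("species")["guild"]
        stats["guild"] = guild_of.reindex(stats.index)
    else:
        stats["guild"] = stats.index

    stats["frq"] = 100.0 * stats["n_plots_occupied"] / stats["n_plots_occupied"].sum()
    stats["rde"] = 100.0 * stats["n_stems"] / stats["n_stems"].sum()
    stats["rdo"] = 100.0 * stats["ba"] / stats["ba"].sum()
    stats["iv"] = stats["frq"] + stats["rde"] + stats["rdo"]
    stats["plot_occupancy_pct"] = 100.0 * stats["n_plots_occupied"] / n_plots

    stats.index.name = "taxon"
    out = stats.reset_index()
    out = out.sort_values(["iv", "taxon"], ascending=[False, True], kind="mergesort")
    cols = ["taxon", "guild", "frq", "rde", "rdo", "iv", "plot_occupancy_pct"]
    return out[cols].reset_index(drop=True)


def rank_species(table: pd.DataFrame, k: int) -> pd.DataFrame:
    """Top-k rows by IV, descending; ties broken alphabetically by taxon."""
    if k < 1:
        raise ValueError("k must be >= 1")
    ranked = table.sort_values(["iv", "taxon"], ascending=[False, True], kind="mergesort")
    return ranked.head(k).reset_index(drop=True)


def guild_richness(census: Census, plot_ids=None) -> dict[str, int]:
    """Distinct censused species per guild plus the network total.

    Counts species that actually occur in the (live) stem table, not the
    whole lookup. A censused species missing from the lookup raises
    :class:`UnclassifiedSpeciesError` naming the species.
    """
    df = census.stems_with_guild(plot_ids)
    missing = df.loc[df["guild"].isna(), "species"].unique()
    if len(missing):
        raise UnclassifiedSpeciesError(missing)
    counts = df.groupby("guild")["species"].nunique().to_dict()
    out = {g: int(counts.get(g, 0)) for g in ("Euc", "Scl", "RF")}
    out["total"] = sum(out.values())
    return out
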