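"""Allometric aboveground biomass and live carbon accounting.

Tree biomass follows the generic ln-linear allometry
``ln(AGB kg) = alpha + beta·ln(DBH cm)`` with an optional multiplicative
back-transform correction. Eucalypt stems (Eucalyptus and Corymbia) use
the eucalypt equation, everything else the rainforest equation. Plot AGB
(t/ha) times a carbon fraction (default 0.50) gives live aboveground
carbon, AGC (tC/ha). Plots where buttressing inflates diameter-based
estimates can be excluded wholesale via the plot table's ``agc_excluded``
flag.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigError, UnclassifiedSpeciesError
from .records import Census

#: Default live-biomass-to-carbon conversion.
CARBON_FRACTION = 0.50

#: Diameter classes (cm) used to partition plot AGC; last class is open.
DEFAULT_DIAMETER_CLASSES = ((10.0, 50.0), (50.0, 100.0), (100.0, 150.0), (150.0, float("inf")))


@dataclass(frozen=True)
class AllometryModel:
    """ln-ln biomass equation bound to a guild scope.

    ``tree AGB (kg) = correction_factor · exp(alpha + beta·ln(dbh))``.
    """

    label: str
    guild_scope: str  # "eucalypt" | "non_eucalypt"
    alpha: float
    beta: float
    correction_factor: float = 1.0
    source: str = ""

    def __post_init__(self):
        if self.guild_scope not in ("eucalypt", "non_eucalypt"):
            raise ConfigError(f"guild_scope must be eucalypt/non_eucalypt, got {self.guild_scope!r}")
        if not self.beta > 0:
            raise ConfigError(f"beta must be positive, got {self.beta}")
        if not self.correction_factor > 0:
            raise ConfigError(f"correction_factor must be positive, got {self.correction_factor}")


@dataclass(frozen=True)
class CarbonSummary:
    """Per-plot biomass and carbon; all fields None when the plot is excluded."""

    plot_id: str
    agb_eucalypt: float | None  # t/ha
    agb_non_eucalypt: float | None  # t/ha
    agc_total: float | None  # tC/ha
    agc_by_class: dict | None = field(default=None)  # (lo, hi) cm -> tC/ha
    excluded: bool = False


def load_allometry_config(path=None) -> dict[str, AllometryModel]:
    """Load allometry coefficients from a JSON config.

    With no path, loads the packaged default config. The packaged
    coefficients are synthetic placeholders of the standard generic form
    — they are NOT the published values, which the network's source
    papers do not print — and must be replaced for real carbon accounting.
    """
    if path is None:
        text = resources.files("tallstand.data").joinpath("allometry_generic.json").read_text()
    else:
        text = Path(path).read_text()
    raw = json.loads(text)
    models = {}
    for entry in raw["models"]:
        m = AllometryModel(
            label=entry["label"],
            guild_scope=entry["scope"],
            alpha=float(entry["alpha"]),
            beta=float(entry["beta"]),
            correction_factor=float(entry.get("correction_factor", 1.0)),
            source=entry.get("source", ""),
        )
        models[m.guild_scope] = m
    for scope in ("eucalypt", "non_eucalypt"):
        if scope not in models:
            raise ConfigError(f"allometry config missing a model for scope {scope!r}")
    return models


def tree_agb(dbh, model: AllometryModel):
    """Aboveground biomass (kg) of a tree of diameter ``dbh`` (cm).

    Accepts a scalar or array; strictly increasing in dbh since beta > 0.
    """
    arr = np.asarray(dbh, dtype=float)
    if np.any(arr <= 0):
        raise ValueError("dbh must be positive")
    out = model.correction_factor * np.exp(model.alpha + model.beta * np.log(arr))
    return float(out) if np.isscalar(dbh) or arr.ndim == 0 else out


def _stem_agb_kg(df: pd.DataFrame, allometries: dict[str, AllometryModel]) -> np.ndarray:
    """Per-stem AGB (kg) for a guild-joined live stem table."""
    if df["is_eucalypt"].isna().any():
        raise UnclassifiedSpeciesError(df.loc[df["is_eucalypt"].isna(), "species"].unique())
    for scope in ("eucalypt", "non_eucalypt"):
        if scope not in allometries:
            raise ConfigError(f"no allometry model configured for scope {scope!r}")
    euc = df["is_eucalypt"].astype(bool).to_numpy()
    dbh = df["dbh"].to_numpy(dtype=float)
    agb = np.empty(len(df))
    if euc.any():
        agb[euc] = tree_agb(dbh[euc], allometries["eucalypt"])
    if (~euc).any():
        agb[~euc] = tree_agb(dbh[~euc], allometries["non_eucalypt"])
    return agb


def plot_agc(
    census: Census,
    allometries: dict[str, AllometryModel],
    carbon_fraction: float = CARBON_FRACTION,
    classes=DEFAULT_DIAMETER_CLASSES,
) -> list[CarbonSummary]:
    """Live aboveground carbon per plot.

    Live stems only; per-stem AGB (kg) is summed by guild scope,
    converted to t/ha, and multiplied by ``carbon_fraction`` for AGC.
    Plots flagged ``agc_excluded`` yield excluded summaries with all
    carbon fields None.
    """
    _check_classes(classes)
    stems = census.stems_with_guild()
    out = []
    for _, plot in census.plots.iterrows():
        pid = plot["plot_id"]
        if bool(plot["agc_excluded"]):
            out.append(CarbonSummary(pid, None, None, None, None, excluded=True))
            continue
        sub = stems[stems["plot_id"] == pid]
        area = float(plot["area_ha"])
        if sub.empty:
            out.append(CarbonSummary(pid, 0.0, 0.0, 0.0, {c: 0.0 for c in classes}))
            continue
        agb_kg = _stem_agb_kg(sub, allometries)
        euc = sub["is_eucalypt"].astype(bool).to_numpy()
        agb_e = agb_kg[euc].sum() / 1000.0 / area
        agb_n = agb_kg[~euc].sum() / 1000.0 / area
        dbh = sub["dbh"].to_numpy(dtype=float)
        by_class = {}
        for lo, hi in classes:
            in_class = (dbh >= lo) & (dbh < hi)
            by_class[(lo, hi)] = carbon_fraction * agb_kg[in_class].sum() / 1000.0 / area
        out.append(
            CarbonSummary(
                plot_id=pid,
                agb_eucalypt=float(agb_e),
                agb_non_eucalypt=float(agb_n),
                agc_total=float(carbon_fraction * (agb_e + agb_n)),
                agc_by_class=by_class,
            )
        )
    return out


def _check_classes(classes) -> None:
    cs = sorted(classes)
    for (lo, hi) in cs:
        if not hi > lo:
            raise ValueError(f"empty diameter class ({lo}, {hi})")
    for (_, hi_prev), (lo, _) in zip(cs, cs[1:]):
        if lo < hi_prev:
            raise ValueError("diameter classes overlap")
        if lo > hi_prev:
            raise ValueError("diameter classes leave a gap")
    if cs[0][0] != 10.0 or not np.isinf(cs[-1][1]):
        raise ValueError("classes must partition [10, inf)")


def agc_by_diameter_class(
    census: Census,
    allometries: dict[str, AllometryModel],
    classes=DEFAULT_DIAMETER_CLASSES,
    carbon_fraction: float = CARBON_FRACTION,
    eucalypt_only: bool = False,
) -> pd.DataFrame:
    """Network AGC partitioned by diameter class, with percentage shares.

    Sums over all non-excluded plots. ``eucalypt_only`` restricts to the
    eucalypt component (the partition conventionally reported for the
    overstorey). Shares sum to 100% whenever any carbon is present.
    """
    _check_classes(classes)
    included = census.plots[~census.plots["agc_excluded"].astype(bool)]
    stems = census.stems_with_guild(set(included["plot_id"]))
    if eucalypt_only:
        stems = stems[stems["is_eucalypt"].astype(bool)]
    totals = {c: 0.0 for c in classes}
    if not stems.empty:
        agb_kg = _stem_agb_kg(stems, allometries)
        area = included.set_index("plot_id")["area_ha"].astype(float)
        per_stem_agc = carbon_fraction * agb_kg / 1000.0 / stems["plot_id"].map(area).to_numpy()
        dbh = stems["dbh"].to_numpy(dtype=float)
        for lo, hi in classes:
            totals[(lo, hi)] = float(per_stem_agc[(dbh >= lo) & (dbh < hi)].sum())
    grand = sum(totals.values())
    rows = [
        {
            "dbh_lower_cm": lo,
            "dbh_upper_cm": hi,
            "agc_tc_ha": totals[(lo, hi)],
            "share_pct": (100.0 * totals[(lo, hi)] / grand) if grand > 0 else 0.0,
        }
        for lo, hi in classes
    ]
    return pd.DataFrame(rows)
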