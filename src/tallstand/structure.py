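"""Per-plot and per-region stand structure.

Basal area, stocking density, diameter distributions, height summaries
and the diameter-height site-productivity model ``height = a + b·ln(DBH)``.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import InsufficientDataError, TallstandError
from .records import Census, stems_frame

#: Canopy positions that form the dominant overstorey cohort.
DOMINANT_POSITIONS = ("dominant", "co-dominant")


@dataclass(frozen=True)
class DiameterDistribution:
    """Histogram of stem diameters; bins are lower-closed, upper-open."""

    bin_edges: np.ndarray  # ascending, cm; len = len(counts) + 1
    counts: np.ndarray  # non-negative ints
    subset_label: str = "all"

    @property
    def n(self) -> int:
        return int(self.counts.sum())

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "dbh_lower_cm": self.bin_edges[:-1],
                "dbh_upper_cm": self.bin_edges[1:],
                "count": self.counts,
            }
        )


@dataclass(frozen=True)
class HeightDiameterModel:
    """OLS fit of height (m) on ln(DBH cm): height = a + b·ln(dbh)."""

    intercept: float  # a, m
    slope: float  # b, m per ln(cm)
    n: int
    residual_sd: float  # m

    def predict(self, dbh_cm) -> np.ndarray:
        dbh = np.asarray(dbh_cm, dtype=float)
        if np.any(dbh <= 0):
            raise ValueError("dbh must be positive")
        return self.intercept + self.slope * np.log(dbh)


def _live(df: pd.DataFrame, include_dead: bool) -> pd.DataFrame:
    if include_dead or "alive" not in df.columns:
        return df
    return df[df["alive"].astype(bool)]


def basal_area(stems, area_ha: float, include_dead: bool = False) -> float:
    """Stand basal area in m²·ha⁻¹ from diameters at the point of measurement.

    Each stem contributes pi·(dbh/200)² m² (dbh in cm); dead stems are
    excluded unless ``include_dead`` is set.
    """
    if not area_ha > 0:
        raise ValueError(f"area_ha must be positive, got {area_ha}")
    df = _live(stems_frame(stems), include_dead)
    if df.empty:
        return 0.0
    dbh = df["dbh"].to_numpy(dtype=float)
    if np.any(dbh <= 0):
        raise ValueError("all dbh values must be positive")
    return float(np.sum(np.pi * (dbh / 200.0) ** 2) / area_ha)


def stocking_density(stems, area_ha: float, include_dead: bool = False) -> float:
    """Live stems per hectare; every stem of a multi-stemmed tree counts."""
    if not area_ha > 0:
        raise ValueError(f"area_ha must be positive, got {area_ha}")
    df = _live(stems_frame(stems), include_dead)
    return len(df) / area_ha


def diameter_distribution(
    stems,
    bin_width: float = 10.0,
    subset: tuple[str, ...] | None = None,
    min_dbh: float = 10.0,
    include_dead: bool = False,
) -> DiameterDistribution:
    """Bin stem diameters into ``bin_width``-cm classes starting at 10 cm.

    ``subset`` filters on canopy position, e.g. ``("dominant",
    "co-dominant")`` for the overstorey cohort. Bins are [10, 20), [20, 30)
    ... so every admitted stem falls in exactly one bin.
    """
    if not bin_width > 0:
        raise ValueError("bin_width must be positive")
    df = _live(stems_frame(stems), include_dead)
    if subset is not None:
        df = df[df["canopy_position"].isin(subset)]
        label = "+".join(subset)
    else:
        label = "all"
    dbh = df["dbh"].to_numpy(dtype=float)
    dbh = dbh[dbh >= min_dbh]
    if dbh.size:
        top = min_dbh + bin_width * (np.floor((dbh.max() - min_dbh) / bin_width) + 1)
    else:
        top = min_dbh + bin_width
    edges = np.arange(min_dbh, top + bin_width / 2, bin_width)
    # np.histogram closes the last bin on the right; widen it so the max
    # value stays in its own lower-closed bin.
    counts, _ = np.histogram(dbh, bins=np.append(edges[:-1], edges[-1] + 1e-9))
    return DiameterDistribution(bin_edges=edges, counts=counts.astype(int), subset_label=label)


def fit_height_diameter(pairs) -> HeightDiameterModel:
    """Least-squares fit of ``height = a + b·ln(dbh)``.

    ``pairs`` is an iterable of (dbh cm, height m) or a 2-column array.
    Requires at least 3 pairs with positive diameters.
    """
    arr = np.asarray(list(pairs) if not isinstance(pairs, np.ndarray) else pairs, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValueError("pairs must be (dbh, height) tuples")
    if arr.shape[0] < 3:
        raise InsufficientDataError(f"need >= 3 (dbh, height) pairs, got {arr.shape[0]}")
    dbh, height = arr[:, 0], arr[:, 1]
    if np.any(dbh <= 0):
        raise ValueError("dbh must be positive")
    X = np.column_stack([np.ones_like(dbh), np.log(dbh)])
    coef, *_ = np.linalg.lstsq(X, height, rcond=None)
    resid = height - X @ coef
    dof = max(arr.shape[0] - 2, 1)
    return HeightDiameterModel(
        intercept=float(coef[0]),
        slope=float(coef[1]),
        n=int(arr.shape[0]),
        residual_sd=float(np.sqrt(np.sum(resid**2) / dof)),
    )


@dataclass(frozen=True)
class HeightSummary:
    """Height statistics over stems with measured heights only."""

    mean_dominant_eucalypt: float | None  # m, dominant + co-dominant eucalypts
    max_eucalypt: float | None  # m
    max_non_eucalypt: float | None  # m
    n_measured: int


def height_summary(stems, species=None) -> HeightSummary:
    """Mean dominant/co-dominant eucalypt height and per-group maxima.

    Uses measured heights only; a class with no measured heights yields
    ``None``. ``stems`` must carry an ``is_eucalypt`` column or ``species``
    (a species lookup with ``species``/``is_eucalypt``) must be given.
    """
    df = stems_frame(stems)
    if "is_eucalypt" not in df.columns:
        if species is None:
            raise TallstandError("stems lack is_eucalypt; pass the species lookup")
        from .records import species_frame

        df = df.merge(species_frame(species)[["species", "is_eucalypt"]], on="species", how="left")
    df = _live(df, include_dead=False)
    measured = df[pd.notna(df["height"])]
    euc = measured[measured["is_eucalypt"].astype(bool)]
    non = measured[~measured["is_eucalypt"].astype(bool)]
    dom = euc[euc["canopy_position"].isin(DOMINANT_POSITIONS)]
    return HeightSummary(
        mean_dominant_eucalypt=float(dom["height"].mean()) if len(dom) else None,
        max_eucalypt=float(euc["height"].max()) if len(euc) else None,
        max_non_eucalypt=float(non["height"].max()) if len(non) else None,
        n_measured=int(len(measured)),
    )


def plot_structure_table(census: Census) -> pd.DataFrame:
    """One row per plot: basal area, stocking and height summaries."""
    rows = []
    stems = census.stems_with_guild(include_dead=True)
    for _, plot in census.plots.iterrows():
        sub = stems[stems["plot_id"] == plot["plot_id"]]
        hs = height_summary(sub)
        rows.append(
            {
                "plot_id": plot["plot_id"],
                "region": plot["region"],
                "basal_area_m2_ha": basal_area(sub, plot["area_ha"]),
                "stocking_stems_ha": stocking_density(sub, plot["area_ha"]),
                "mean_dominant_euc_height_m": hs.mean_dominant_eucalypt,
                "max_euc_height_m": hs.max_eucalypt,
                "max_non_euc_height_m": hs.max_non_eucalypt,
            }
        )
    return pd.DataFrame(rows)


def region_structure_table(census: Census) -> pd.DataFrame:
    """Regional structure summary.

    Height means are reported both pooled across a region's stems
    (``*_pooled``) and as the mean of per-plot means (``*_plot_mean``);
    the two differ when measurement effort varies between plots.
    """
    per_plot = plot_structure_table(census)
    stems = census.stems_with_guild()
    out = []
    for region, plots in census.plots.groupby("region"):
        ids = set(plots["plot_id"])
        sub = stems[stems["plot_id"].isin(ids)]
        hs = height_summary(sub)
        pp = per_plot[per_plot["region"] == region]
        out.append(
            {
                "region": region,
                "n_plots": len(ids),
                "basal_area_m2_ha": pp["basal_area_m2_ha"].mean(),
                "stocking_stems_ha": pp["stocking_stems_ha"].mean(),
                "dominant_euc_height_pooled_m": hs.mean_dominant_eucalypt,
                "dominant_euc_height_plot_mean_m": pp["mean_dominant_euc_height_m"].mean(),
                "max_euc_height_m": hs.max_eucalypt,
                "max_non_euc_height_m": hs.max_non_eucalypt,
            }
        )
    return pd.DataFrame(out).sort_values("region").reset_index(drop=True)
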