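# tallstand

Baseline analysis for permanent forest-plot networks in tall eucalypt
forest: a stem-census data model with validation, stand-structure
summaries, community importance values, allometric aboveground-carbon
accounting, climate–carbon model selection, and hemispherical-photo
canopy cover — plus a synthetic census generator so the whole pipeline
can be exercised and tested without field data.

It is written for forest ecologists and inventory analysts working with
one-hectare permanent plots in which every stem ≥ 10 cm diameter at
breast height (DBH, measured at 1.3 m) is tagged, identified, mapped,
and assigned a canopy position and growth stage.

## What it computes

* **Stand structure** — basal area `BA = Σ π(DBH/200)²` (m² ha⁻¹),
  stocking density (stems ha⁻¹), 10-cm diameter distributions, and the
  diameter–height productivity model `height = a + b·ln(DBH)` fitted by
  ordinary least squares.
* **Importance Values** — for each species (or guild: eucalypt, wet
  sclerophyll, rainforest) the relative frequency, relative density and
  relative dominance, each normalized to sum to 100 across taxa, and
  their sum `IV = Frq + RDe + RDo ∈ [0, 300]`.
* **Aboveground carbon** — tree biomass from the generic ln–ln allometry
  `ln(AGB kg) = α + β·ln(DBH cm)` with guild-specific coefficients,
  summed to plot AGB (t ha⁻¹) and converted to live aboveground carbon
  `AGC = 0.50 × AGB` (tC ha⁻¹), with diameter-class partitioning and
  plot-level exclusion for buttressed stands.
* **Climate–carbon model selection** — OLS fits of plot AGC on mean
  annual temperature (MAT), precipitation (MAP) and the
  precipitation-to-pan-evaporation ratio (P:E), ranked by
  `AIC = n(ln 2π + ln(RSS/n) + 1) + 2k` with `k` counting slopes,
  intercept and error variance; plus convex-hull climate-envelope
  placement and stand height classes (25–35 m, 35–45 m, >45 m).
* **Canopy cover** — percent of hemispherical-photo pixels below an
  intensity cut-off of 125 (canopy), averaged over a plot's 16 photo
  stations.

## Worked example

```python
import tallstand as ts

census, manifest = ts.generate_network(ts.SyntheticConfig(seed=1))
print(census)                       # Census(48 plots, 13131 stems, 185 species)
print(len(ts.validate_census(census)))   # 0 — the census is protocol-conformant

allom = ts.load_allometry_config()  # synthetic placeholder coefficients
plots = census.plots.set_index("plot_id")
rows = [
    {"agc": s.agc_total, "mat": plots.loc[s.plot_id, "mat"],
     "map": plots.loc[s.plot_id, "map"],
     "pe": ts.pe_ratio(plots.loc[s.plot_id, "map"], plots.loc[s.plot_id, "pan_evap"])}
    for s in ts.plot_agc(census, allom) if not s.excluded
]
import pandas as pd
fits = ts.fit_agc_climate(pd.DataFrame(rows))
best = fits[0]
print(best.predictors, round(best.coefficients["mat"], 1), round(best.r2, 2))
# ('mat',) -12.8 0.38
```

The best-supported model is the MAT regression: simulated carbon storage
declines by about 13 tC ha⁻¹ for every degree of mean annual warming
(the generator imposes −14.3, recovered here within sampling error),
explaining ~38 % of between-plot variance across the 46 plots that enter
the carbon analysis (two are excluded for buttressing).

A CLI mirrors the library:

```sh
tallstand simulate --seed 1 --out sim/
tallstand structure --census sim/census.csv --plots sim/plots.csv --species sim/species.csv --out structure.csv
tallstand iv --census sim/census.csv --plots sim/plots.csv --species sim/species.csv --region VIC --top 5 --out iv.csv
tallstand carbon --census sim/census.csv --plots sim/plots.csv --species sim/species.csv --out carbon.csv
tallstand climate-fit --carbon carbon.csv --plots sim/plots.csv --out fits.csv
tallstand canopy --images photos/ --threshold 125 --out canopy.csv
```

## Notes

The packaged allometry coefficients
(`src/tallstand/data/allometry_generic.json`) are synthetic placeholders
in the standard generic form; replace them with vetted published
coefficients before any real carbon accounting. See `docs/methods.md`
for the model assumptions, generator design, numerical conventions and
known limitations.
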