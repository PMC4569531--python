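# Methods

This note documents the models, conventions and design choices behind
`tallstand`, and what the synthetic data generator does and does not
emulate.

## Census data model

A census couples three tables. Stems: one row per tagged stem ≥ 10 cm
DBH with species, DBH (cm) at the point of measurement (default 1.3 m;
higher above prominent buttressing, with the `buttressed` flag and `pom`
recording the deviation), plot coordinates x, y ∈ [0, 100] m from the
georeferenced (0, 0) corner, canopy position (suppressed / dominant /
co-dominant / emergent), growth stage (regrowth / regenerating / mature /
senescent), stem form and — for dead trees — a mortality code. Plots:
region, area (1 ha in this network), MAT (°C), MAP (mm yr⁻¹), pan
evaporation (mm yr⁻¹), elevation, and an `agc_excluded` flag. Species:
guild assignment (eucalypt incl. *Corymbia*; wet sclerophyll;
rainforest).

Conventions, chosen once and applied everywhere:

* Dead stems are retained in the tables but excluded from all live-stand
  metrics (basal area, stocking, importance, carbon) unless
  `include_dead=True`; heights and importance always use live stems.
* Each stem of a multi-stemmed tree is a separate record; there is no
  tree-level deduplication.
* Stem-form and mortality-code vocabularies are free code strings, not a
  fixed enumeration — field protocols differ in their code lists, and the
  only enforced rule is that a non-empty mortality code implies a dead
  stem.
* CSV interchange is comma-separated UTF-8 with a header row; `""` is
  missing. Floats are written with 17 significant digits and parsed with
  the correctly-rounded built-in parser, so write→read round-trips are
  bit-exact.
* Validation returns an ordered list of violations (rule id + record
  reference) rather than raising, so a field team can fix records in
  bulk; parsing errors (missing columns, unparseable numbers, duplicate
  tags) do raise, naming the column or rows.

## Stand structure

Basal area sums `π(DBH/200)²` per stem and divides by plot area.
Diameter distributions use lower-closed, upper-open 10-cm bins starting
at 10 cm (`[10, 20), [20, 30), …`), so every stem belongs to exactly one
bin; the convention is arbitrary but fixed and documented.

The diameter–height model is `height = a + b·ln(DBH)` fitted by OLS.
The logarithm is natural: "log" in model formulas of the major
statistical environments denotes ln, and the base only rescales `b`.
Height summaries (mean height of dominant + co-dominant eucalypts,
maxima by eucalypt / non-eucalypt) use measured heights only — the field
protocol measures a subset of trees — and never impute from the fitted
model unless `predict` is called explicitly. Regional height means are
reported both pooled across stems and as means of per-plot means, since
the two differ when measurement effort varies between plots; both are
labelled in `region_structure_table`.

## Importance values

For taxa i with stem counts nᵢ, basal areas BAᵢ and plot-occurrence
counts fᵢ within the chosen plot subset:

    RDeᵢ = 100·nᵢ/Σn,  RDoᵢ = 100·BAᵢ/ΣBA,  Frqᵢ = 100·fᵢ/Σf,
    IVᵢ = Frqᵢ + RDeᵢ + RDoᵢ.

Relative frequency is normalized across taxa (fᵢ/Σf) rather than being
the raw percentage of plots occupied: only the normalized form makes the
three components sum to 100 each and IV span 0–300, and only it
reproduces published regional tables in which a species occupying most
plots of a small region still has Frq well below 100. The raw occupancy
percentage is informative in its own right and is exposed as a separate
`plot_occupancy_pct` column. Guild-level tables treat each guild as one
aggregated taxon normalized across the three guilds. Regional tables are
computed over stems pooled across the region's plots. Ties in ranking
break alphabetically so output is deterministic.

## Aboveground carbon

Tree biomass uses the generic ln-linear allometry
`AGB (kg) = CF·exp(α + β·ln(DBH cm))` with separate coefficients for
eucalypts (incl. *Corymbia*) and non-eucalypts, an optional
multiplicative back-transform correction CF (default 1), plot AGB in
t ha⁻¹, and `AGC = carbon_fraction × AGB` with the fraction defaulting
to 0.50. The packaged coefficient file is a clearly-labelled synthetic
placeholder (α = −2.2, β = 2.49 eucalypt; α = −1.9, β = 2.37
non-eucalypt) of realistic magnitude — roughly 4 t for a 70-cm eucalypt —
because no authoritative generic coefficients ship with this package;
all tests use synthetic coefficients and real analyses must supply their
own config.

Diameter-class partitioning uses `[10,50), [50,100), [100,150), [150,∞)`
cm; the classes must partition `[10, ∞)` and shares always sum to 100 %.
Plot-level exclusion (`agc_excluded`) reproduces the handling of stands
whose buttressed dominants make diameter-based allometry unreliable:
excluded plots yield summaries with all carbon fields missing and never
enter network carbon statistics or climate fits.

## Climate analyses

P:E is MAP divided by pan evaporation. The AGC–climate comparison fits
each candidate predictor set by OLS and ranks by AIC under the full
Gaussian log-likelihood, `AIC = n(ln 2π + ln(RSS/n) + 1) + 2k` with
`k = slopes + intercept + variance` — the convention of mainstream
statistical environments, so ΔAIC values are comparable across nested
and non-nested candidates. Candidates within ΔAIC < 2 are flagged as
equivalently supported and the simpler model lists first. Numerical
choices: a rank-deficient design raises an error naming the collinear
predictors; an RSS at floating-point rounding level (≤ n·(10⁻¹⁰·max|y|)²)
is treated as an exact fit (AIC −∞) so candidate ranking cannot be
driven by numerical noise — in that regime the simplicity tie-break
decides, which is why a constant response selects the null model.

The climate envelope is the convex hull of the reference (MAT, MAP)
cloud after standardizing each axis by its reference standard deviation.
A hull is the least-assumption definition of an "envelope" — published
figures draw one without defining it — and the output labels it as such.
Placement reports inside/outside (boundary counts as inside, tolerance
10⁻¹²) and the distance to the nearest hull edge in standardized units.
Height classes `[25,35), [35,45), [45,∞)` m are lower-closed; heights
below 25 m are labelled `below-range`. The height-from-climate
predictive model itself is not bundled: `classify_height_class` takes
predicted heights (or a user-fitted model) as input.

## Canopy cover

A photo is segmented by a fixed intensity cut-off, default 125 on the
0–255 scale; pixels strictly below it are canopy, pixels at or above it
are sky (the boundary convention is configurable and documented because
published descriptions leave it open). Colour images are reduced to one
channel before thresholding — blue by default, the standard choice for
canopy/sky contrast. No fisheye masking is applied by default; an
optional circular mask is available. Plot cover is the unweighted mean
over the (nominally 16) stations.

## Synthetic data generator

The generator emulates the study conditions of a continental
tall-eucalypt network: 7 regions totalling 48 one-ha plots with regional
MAT ranges spanning 6.6–20.5 °C and MAP 853–1895 mm (pan evaporation is
not published per region; plausible Australian ranges of 700–1800 mm
were chosen once so P:E spans ≈ 0.6–2). Two plots of the warm-seasonal
region are flagged `agc_excluded` to exercise the buttressing pathway.

Per plot: a climate-determined carbon target
`AGC* = 400 − 14.3·(MAT − 6) + N(0, 60)` tC ha⁻¹ (the −14.3 slope is the
linear decline from ≈ 400 tC ha⁻¹ at 6 °C to ≈ 200 tC ha⁻¹ at 20 °C; the
60 tC ha⁻¹ noise keeps r² near the observed ≈ 0.4 at 46 plots). Stems
are then drawn until their allometric carbon reaches the target — 90 %
from a eucalypt overstorey cohort with lognormal diameters (median 70 cm,
σ = 0.35, dominant/co-dominant/emergent positions), 10 % from a
suppressed non-eucalypt understorey that is left-skewed (10 cm +
exponential, scale 12 cm) in warm regions and peaked (lognormal median
22 cm) in the cool-temperate ones. Because the coupling acts through
stand composition rather than post-hoc label edits, carbon accounting,
basal area and diameter distributions remain mutually consistent. The
overstorey σ = 0.35 keeps every plot's dominant-cohort histogram mode in
[50, 100) cm while reproducing the observed rarity of very large stems
(≈ 1–2 % of eucalypts above 150 cm) and the concentration of roughly
half the eucalypt carbon in the 50–100 cm class.

Heights are measured for a 30 % subset,
`height = −20 + 16.5·ln(DBH) + N(0, 4)` m clipped at 2 m — giving ≈ 50 m
dominants at 70 cm DBH and ≈ 18 m understorey trees at 10 cm. About 2 %
of stems are standing dead with a mortality code. Species pools default
to 30 eucalypt (incl. *Corymbia*), 47 wet sclerophyll and 108 rainforest
names; each region samples a sub-pool with one dominant eucalypt, so
realized network richness is below the pool total and is recorded in the
manifest. All randomness derives from a single master seed through
per-plot spawned streams, so output is bit-identical for a fixed seed.

What the generator does **not** emulate: spatial point patterns within
plots (coordinates are uniform), interspecific size differences within a
guild, multi-census dynamics (growth, mortality, recruitment),
measurement error in DBH, and real allometric coefficients. Passing
tests therefore demonstrate the correctness and internal consistency of
the analysis chain under known ground truth — not the field accuracy of
any coefficient.

Canopy images are Bernoulli grids: each pixel is canopy (intensity 40)
with probability target/100, else sky (220), so expected measured cover
equals the target and a 512² image concentrates within ±1 point.

## Problem sizes and test design

Unit and property tests run on reduced networks (2–4 regions, 1–3 plots
each) generated by `small_config`; the full 48-plot default network is
exercised once per session for realism checks and by the acceptance
script. The generator→carbon→regression recovery test uses 100
replicates of a 12-plot network: with fewer plots the residual-based
slope standard error has too few degrees of freedom for a 3-SE band to
hold its nominal coverage. The climate-selection property uses 200
direct simulations at n = 46 plots, matching the scale at which the
published comparison was made.

## Known limitations

* Published r²/AIC values for the real network depend on the real plot
  data, which are not bundled; the package reproduces the method and the
  direction/magnitude of the climate effect on synthetic data only.
* The importance-value normalization cannot be validated against the
  unpublished per-plot data behind regional tables; it is validated
  against the printed component/sum arithmetic and internal invariants.
* Convex-hull envelopes are sensitive to reference outliers; no peeling
  or density-based envelope is implemented.
* The allometric form is diameter-only; height-and-diameter bivariate
  allometry is out of scope.
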