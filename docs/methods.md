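# Methods

## Panel construction and cold-season alignment

The modelling unit is the region (*aimag*) × cold season. A cold season
spanning October of year Y−1 through April of year Y is labelled Y, the
year containing the spring losses. Predictors are aligned to that label:

* **P₆₋₈** — precipitation anomaly percentage of the *preceding* summer,
  `100·(P_JJA(Y−1) − P̄)/P̄`, with `P̄` the baseline (default 1981–2010)
  mean of the June–August total. Drought ahead of the winter weakens
  animals and cuts hay/forage yields, so the index enters with a lag.
* **T₁₁₋₂** — additive °C anomaly of the mean of Nov(Y−1), Dec(Y−1),
  Jan(Y), Feb(Y) monthly temperatures against the baseline mean of the
  same composite. (Temperature anomalies are additive; precipitation
  anomalies are percentages — the two indices are deliberately on
  different scales.)
* **SD** — monthly maximum snow depth (cm). Default: the raw January
  value of year Y, the month of peak depth and the strongest association
  with losses; a November–March window and an anomaly form are available
  by option. The raw-value default and the anomaly flag are both exposed
  because either convention is defensible; results are invariant to the
  choice up to an affine shift, which the regression absorbs.
* **POP_pre** — the December census of year Y−1 in sheep units: the herd
  standing on January 1 of the loss year. **LOSS_pre** is the previous
  season's deaths in SU.
* Socioeconomic indicators attach with a one-year lag (pre-winter state):
  season Y uses the year-Y−1 record.

Species counts convert to sheep units with fixed feed-requirement rates
(camel 5, horse 7, cow 6, sheep 1, goat 0.9). The prepared hay/forage
composite is a weighted sum of eight raw feed components per SU
(hay 0.45, planted feed 0.35, silage 0.25, artificial feed & mineral salt
1.0, potatoes/vegetable scraps 0.22, imperfectly ripened wheat 0.9,
residuals 0.4, straw 0.25).

SU death totals are non-integer in general; the count likelihood uses the
nearest integer (flooring available), with the un-rounded total kept in
the panel. Rows with any missing field are dropped listwise and logged;
fewer than three complete rows is an error.

## Indicator screening

Fourteen candidate indicators sit in six groups — livestock conditions
(POP_pre, LOSS_pre), herder experience (H_young, H_exp), poverty (five
herd-size-class household fractions), facilities (trucks, TV), winter
preparedness (hay/forage, shelters), economy (GDP). For each indicator the
Pearson correlation with deaths (SU) is computed per region and averaged
unweighted across regions; each group's winner is the member with maximum
|r̄| (ties break by listing order). Magnitude rather than signed value is
used because protective factors correlate negatively; screening on deaths
in SU (not relative mortality) is the default. Zero-variance indicators in
a region are excluded from that indicator's average with a warning.

## The Poisson multi-regression

`MortalityModel.fit()` maximises the Poisson likelihood by Newton/IRLS
with step-halving, guaranteeing a monotone log-likelihood sequence;
convergence is a relative log-likelihood change below 1e-10 (cap 100
iterations; a non-converged fit is flagged, never silently returned).
Predictors are z-scored internally (population SD, ddof 0) for
conditioning; coefficients and standard errors are reported on both the
standardized and raw scales. The log-likelihood uses the log-gamma form of
ln y!, stable for counts up to ~1e8. Design checks: constant columns and
rank deficiency raise with the offending column names; n < p+2 warns but
is permitted (the reference setting of 15 seasons on 9 predictors is
deliberately allowed). Standard errors come from the observed information
matrix — for the canonical log link this equals the expected information.

No exposure offset is used by default: the model explains raw death
counts, with POP_pre as an ordinary covariate; `use_offset=True` switches
to a `log(POP_pre)` offset (a rate model) for sensitivity analyses.
Overdispersion is not modelled; the Pearson dispersion statistic is
reported as a diagnostic only.

## Dominance analysis

All 2^p subset models are fitted (ceiling p = 15) and each predictor's
general dominance weight is its R²_M increment averaged within subset
sizes, then across sizes. The weights sum to the full-model R²_M by
construction, giving an exact partition into hazard, POP_pre and
coping-capacity blocks. Non-converged subset fits are excluded from the
averages with a logged count; more than 20 % non-converged aborts the
decomposition as unreliable. The conventional nested sequence (hazards →
POP_pre → coping-capacity) is also reported as sequential R²_M increments;
the two attributions coincide only for orthogonal predictors, so both are
emitted side by side.

## Cross-validation

Leave-one-out: each season is held out, the full model refitted on the
remaining n−1 rows, and the held-out deaths predicted on the natural count
scale. `Q² = 1 − Σ(ŷᵢ−yᵢ)²/Σ(yᵢ−ȳ)²` uses the mean of **all** n observed
values in the denominator (not fold-wise training means), and squared
error is on counts, not logs. One failed fold is tolerated (recorded);
more than one aborts with an error rather than reporting a misleading Q².
Q² ≥ 0.4 is flagged as conventionally acceptable.

## National aggregation and hotspots

Per-region dominance blocks (as percentages, R²_M × 100) are combined
into a national attribution. The default weights regions by their share of
national cold-season deaths — regions where the deaths happen dominate the
national statement — and an unweighted mean is always reported alongside,
since no single aggregation convention is canonical; the report header
states which is shown. Regions with ≥ 5.1 % of national deaths are flagged
as mortality hotspots (threshold configurable). Percentages are printed to
one decimal.

## The synthetic-data generator

The generator emulates the study conditions end to end: 21 regions on a
south-arid → north-cold gradient; a 1971–2014 monthly climate record
(sinusoidal temperature seasonality, summer-concentrated precipitation,
Nov–Apr snow peaking in January) with additive temperature noise and
multiplicative, zero-floored precipitation/snow noise; discrete hazard
regimes — drought years (probability 0.25, Jun–Aug precipitation × 0.55)
and severe winters (probability 0.25, −3 °C on Nov–Feb, snow × 2);
December censuses growing ~2 %/yr with shocks; socioeconomic indicators
drawn i.i.d. around realistic means with fractions clipped to [0,1] and
herd-size-class fractions renormalised to sum ≤ 1. An optional coupling
reduces prepared hay in drought summers (off by default, switchable for
pathway experiments).

Mortality is drawn from the same log-linear model the fitter assumes:
predictors are computed with the package's own index functions, z-scored
per region against their simulated analysis-window distribution (so
configured β are effect sizes on the standardized scale and directly
comparable to fitted standardized coefficients), and deaths ~
Poisson(exp(β₀ + Σβⱼzⱼ)). The default β₀ = 12.4 puts expected deaths near
2.4×10⁵ SU per region-year — large counts, as in aggregate regional data.
A spin-up season one year before the analysis window provides LOSS_pre
for the first analysis season. LOSS_pre itself cannot carry a generative
coefficient: it is a lagged outcome, and standardizing it against its own
yet-undrawn distribution would be circular; it is still emitted in panels
so the screening stage sees it.

Drawn SU death totals are split into per-species head counts
proportionally to each species' SU share of the herd, with goat deaths
quantised to blocks of ten head (10 goats = 9 SU exactly) and sheep
absorbing the integer remainder — so the per-species counts re-sum to the
drawn Poisson total exactly and panel reconstruction matches the
generative truth to machine precision. An optional cap limits deaths to
the January-1 herd total; off by default, since deaths are otherwise
unbounded Poisson draws (both behaviours are exercised in tests).

**What the generator does not emulate.** Real panels are overdispersed
relative to Poisson (herd-level loss clustering), climate is spatially and
temporally autocorrelated across regions and years, socioeconomic
indicators trend and co-move, and station-to-region aggregation error
exists. Because synthetic counts are exactly Poisson and large, the
fitted R²_M and Q² on default panels approach 1 — passing tests
demonstrate the machinery is correct and the attribution identifiable
under the assumed model, not that real-data fits would be that clean.

## Problem sizes and numerical choices

Tests and the acceptance script run the full setting — 21 regions × 15
seasons, 2⁹ = 512 subset refits per region for dominance, 15 LOO refits
per region — in seconds; recovery and attribution experiments use
repeated seeds on 2-region panels (100 seeds for ±3·SE coverage of all
nine coefficients; 20 seeds per direction for the hazard-vs-vulnerability
attribution check). Convergence tolerance 1e-10 (relative log-likelihood);
dominance additivity holds to 1e-9; the linear predictor is clipped at
±500 before exponentiation as an overflow guard. Ties in indicator
selection break deterministically by listing order; the all-zero-deaths
panel is rejected as degenerate (the null MLE does not exist).

## Known limitations

* Regions are modelled independently; no pooling, spatial smoothing or
  mixed effects — per-region estimates on 15 seasons with 9 predictors
  are weakly determined by design, and the dominance decomposition, not
  the individual coefficients, is the intended inferential target.
* Poisson-only likelihood; with real overdispersed counts the standard
  errors are optimistic (the dispersion diagnostic will show it).
* The correlation screen is univariate; collinear candidates within a
  group are not disambiguated beyond |r̄|.
* NDVI/pasture-biomass data and station-level climate interpolation are
  out of scope; climate inputs must already be regional.
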