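# dzudrisk

Attribution of cold-season livestock mortality on the Eurasian steppe
(*dzud* disasters) to climate hazards versus herder vulnerability.

On the Mongolian steppe, anomalously harsh cold seasons — summer drought
that starves pastures, followed by deep snow and extreme cold — kill
livestock in the millions. Whether those losses are "climate-made" or
"man-made" depends on how much of the year-to-year variation in deaths is
carried by the climate hazards themselves versus by the herders'
pre-winter socioeconomic condition (herd overpopulation, hay/forage
preparedness, experience, transport, wealth). `dzudrisk` implements that
attribution analysis as a tested pipeline for region×year panels, for
researchers in disaster risk, rangeland ecology and biostatistics.

## The model

Deaths are standardized across species into **sheep units** (SU): 1 camel
= 5 SU, 1 horse = 7 SU, 1 cow = 6 SU, 1 sheep = 1 SU, 1 goat = 0.9 SU.
For each region, cold-season deaths *y<sub>i</sub>* (SU, season *i*) follow
a Poisson multi-regression (PMR):

```
y_i ~ Poisson(mu_i),    mu_i = exp(beta_0 + sum_j beta_j x_ij)
```

with nine predictors: three **climate hazards** — the preceding-summer
precipitation anomaly P₆₋₈ (%), the November–February temperature anomaly
T₁₁₋₂ (°C), and the January maximum snow depth SD (cm), anomalies taken
against a 1981–2010 climatology — and six **vulnerability** factors — the
January-1 herd size POP_pre (SU) and five coping-capacity indicators
(prepared hay/forage per SU, herder experience H_exp, trucks per
household, the poverty class L₁₀₁₋₂₀₀, and regional GDP per capita).
The six vulnerability factors are chosen from fourteen candidates by
maximum absolute region-averaged Pearson correlation with deaths, one per
indicator group.

Explained variance is McFadden's pseudo-R², `R²_M = 1 − ℓ_model/ℓ_null`.
Its attribution to predictors uses **general dominance analysis**: the
weight of predictor *j* is its R²_M increment averaged over all 2⁸ subsets
of the other predictors (weights sum exactly to the full-model R²_M).
Block sums over {P₆₋₈, T₁₁₋₂, SD}, {POP_pre} and the coping-capacity
factors give the hazard/vulnerability split; regions holding ≥ 5.1 % of
national deaths are classified as mortality hotspots. Predictive ability
is leave-one-out cross-validation
`Q² = 1 − Σ(ŷᵢ−yᵢ)²/Σ(yᵢ−ȳ)²` (≥ 0.4 conventionally acceptable).

A synthetic-data module generates full panels (monthly climate with
drought/severe-winter regimes, growing herd censuses, socioeconomic
indicators, Poisson mortality with configurable coefficients) so the whole
chain is testable with known truth.

## Worked example

```python
import dzudrisk as dz

cfg = dz.SimulationConfig(n_regions=3)          # default generative truth
sim = dz.simulate_panel(cfg, seed=42)
panel = dz.build_risk_panel(sim.climate, sim.census, sim.socio, "R02")

res = dz.fit_pmr(panel)                         # MortalityResults
print(res.summary())

dom = dz.dominance(panel)
print({k: round(v, 3) for k, v in dom.block_sums().items()})
print("Q2 =", round(dz.loo_cv(panel).q2, 4))
```

prints

```
Poisson mortality regression — region R02
  n obs: 15   predictors: 9
  log-likelihood: -107.4481   null: -3186099.2171
  McFadden R2_M: 1.0000   dispersion: 0.265
  converged: True in 7 iterations   cond(X'WX): 99.4

  term           coef(std)   se(std)     coef(raw)     se(raw)
  intercept        12.4002    0.0007       10.0017       0.018
  p68              -0.3505    0.0009    -0.0142087    3.55e-05
  t112             -0.1997    0.0011     -0.137968    0.000788
  sd                0.3509    0.0012     0.0265051     9.4e-05
  pop_pre           0.2994    0.0008   5.51407e-07    1.39e-09
  hay_forage       -0.2986    0.0007    -0.0300649    7.49e-05
  h_exp            -0.1003    0.0008      -1.61567      0.0128
  trucks           -0.0996    0.0008      -1.18006     0.00894
  l_101_200         0.1017    0.0008       2.82589       0.022
  gdp              -0.1002    0.0005   -0.00039455    2.12e-06

{'hazards': 0.644, 'pop_pre': 0.137, 'coping': 0.219}
Q2 = 1.0
```

The standardized coefficients recover the generative truth (−0.35, −0.20,
0.35, 0.30, −0.30, −0.10, −0.10, 0.10, −0.10) to within a few estimated
standard errors: dry summers (negative P₆₋₈), cold winters (negative
T₁₁₋₂), deep snow, large herds and poor preparedness all raise expected
deaths. In this region 64 % of the explained variance sits in the hazard
block and 36 % in vulnerability, and the model predicts held-out seasons
essentially perfectly (counts are large, so Poisson noise is tiny).

The same stages are exposed as a CLI:

```bash
dzudrisk simulate --out tables/ --seed 1
dzudrisk indices --climate tables/climate.csv --census tables/census.csv \
    --socio tables/socio.csv --baseline 1981:2010 --out panel.csv
dzudrisk select   --panel panel.csv --out selection.json
dzudrisk fit      --panel panel.csv --out fits.json
dzudrisk validate --panel panel.csv --out cv.json
dzudrisk report   --out report/ --seed 1
```

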