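# remiforest

Analysis pipeline for a question in payments-for-ecosystem-services (PES)
research: **does money sent home by rural out-migrants mediate the forest
recovery that a reforestation subsidy aims to produce?** The motivating
setting is China's Conversion of Cropland to Forest Program (CCFP), which
pays households a fixed rate per m² of retired sloped cropland; freed farm
labour migrates to cities, and remittance flowing back may substitute for
fuelwood extraction and so let forests around the origin households
regrow.

The package implements the full inference chain as a tested, reusable
library, exercised end-to-end on a synthetic two-site household survey and
raster landscape with known planted parameters:

1. **Remittance models** — two-level random-intercept models with
   sampling weights, fit by adaptive Gauss–Hermite quadrature (logistic,
   Pr(y<sub>ic</sub>=1 | x<sub>ic</sub>, u<sub>c</sub>) = L(x<sub>ic</sub>β + u<sub>c</sub>))
   and by profiled marginal ML/REML (linear, on log₁₀ amounts among
   senders), with marginal effects, predictive margins, and a weighted
   household bootstrap of the margin distribution.
2. **Buffer metrics** — forest-cover and EVI change between two dates
   inside circular buffers around house points (radii 25–200 m) and ring
   buffers around resident-group polygons, with exact fractional
   cell-overlap weights (256-gon clipping, cells below 0.5% overlap
   excluded): ΔForest = Σw·K₁/Σw − Σw·K₀/Σw, and ΔEVI the analogous
   difference of forest-conditional EVI means.
3. **Matching** — logistic propensity of receiving remittance, one-to-one
   nearest-score matching of no-remittance controls to remittance
   households (treated reusable, weighted 1/m when matched m times),
   balance diagnostics, and caliper sensitivity.
4. **Effects** — pairwise-bootstrap average treatment effects with three
   directional hypotheses (H1: treated−control > 0; H2: treated > 0;
   H3: control ≤ 0) and their occurrence of significance across
   replicates, plus OLS associations of buffer change with log₁₀
   remittance at household and resident-group (ring) level.
5. **Mechanism** — fuelwood-share, energy-ladder, livestock and
   extraction-cost indicators compared between remittance groups
   (weighted t, χ², OLS on log₁₀ remittance).
6. **Additionality** — the socioeconomic and ecological gain estimators

       G_Econ% = Σᵢ 10^(β̂·Mᵢ·Pᵢ/1000) / Σₕ Pₕ × 100%
       G_Ecol% = Σₕ γ̂·Lₕ·A / (Σₕ Pₕ/λ) × 100%

   with uncertainty from β̂ ± σ̂ and γ̂ ± σ̂, outlier exclusion, and
   multiplicative scaling to program-level totals.
7. **Flows** — migration/remittance networks by destination city and
   province, log₁₀-km distance bins (short/medium/long) and one-way
   ANOVA across bins.

## Worked example

```python
from remiforest import ScenarioConfig
from remiforest.synthetic import generate_scenario
from remiforest.mixed import fit_mixed_logit, marginal_effects

bundle = generate_scenario(ScenarioConfig(seed=7))
m = bundle.migrants
logit = fit_mixed_logit(
    m, "sent_remittance",
    ["payment_cum_kyuan", "gender", "age_years", "education_years",
     "outside_province"],
    "group_id", weights="sampling_weight",
)
me = marginal_effects(logit, m[logit.columns[1:]].mean(),
                      variables=["payment_cum_kyuan"])
```

This prints (via the fit and effect objects):

```
migrants: 767, senders: 36.1%
payment coefficient (log-odds per 1,000 Yuan): 0.117 +/- 0.042
group-intercept s.d.: 0.335  ICC: 0.033
marginal effect on P(send) per 1,000 Yuan: 0.0264 +/- 0.0095
```

Read: in the default synthetic survey (767 migrants from 458 households in
63 resident groups, 36% of migrants sending remittance), each additional
1,000 Yuan of cumulative CCFP payment raises a migrant's log-odds of
sending remittance by 0.117 (the generator's planted truth is 0.10);
holding other covariates at their means this is a 2.6-percentage-point
increase in the sending probability. The ICC says ~3% of the latent
outcome variance sits between resident groups.

The full chain — simulate → fit models → buffer metrics → match → bootstrap
ATE → mechanism → additionality → flows — runs from the command line:

```bash
remiforest all --seed 7 --out results/
```

writing one CSV/JSON artefact per stage (`ate_by_radius.csv`,
`additionality.json`, …) plus a log; identical seeds give identical
artefacts.

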