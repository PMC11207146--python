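# Methods

This note documents the models, the synthetic-data generator, the
numerical choices and the known limitations of `remiforest`.

## The inference chain

The scientific object is a mediation chain: PES payments → remittance →
forest recovery. It is estimated in three statistical stages plus two
derived estimators.

**Stage 1: payments → remittance.** Migrant *i* in resident group *c*
sends remittance with probability L(x<sub>ic</sub>β + u<sub>c</sub>),
u<sub>c</sub> ~ N(0, σ<sub>u</sub>²) — a two-level random-intercept
logistic model; among senders, log₁₀ of the amount follows the analogous
linear model. The payment covariate is the cumulative inflation-adjusted
CCFP payment in **thousand Yuan** (annual payment = enrolled area ×
site rate λ, accumulated over the migration years), so coefficients read
"per additional 1,000 Yuan". Amounts are modelled in log base 10: the
additionality estimator exponentiates 10^(β̂·M·P/1000), and effects are
reported as the consequence of a 10-times increase in remittance. The
amount model is fit on senders only (a hurdle-style separation; zero
amounts are never imputed).

*Sampling weights* enter both likelihoods as observation-level
pseudo-likelihood weights, normalised to mean one so the information
matches the sample size and a uniform rescaling of the weight column
cannot move the fit. Model-based standard errors are used; for the mildly
variable weights of a two-stratum design this approximation is confirmed
by the replicated coverage check (94–96% at the nominal 95%).

*Estimation.* The logistic marginal likelihood integrates the group
intercept by adaptive Gauss–Hermite quadrature: per likelihood
evaluation, a damped Newton iteration finds each group's posterior mode,
the integrand is re-centred and scaled by the local curvature, and 15
nodes are applied (log-sum-exp accumulation). The linear model profiles
the fixed effects out in closed form (Woodbury identity per group) and
optimises the two variance parameters on the log scale; ML is the
default, REML a flag. With the group variance constrained to zero both
reduce to weighted GLM/WLS, which is asserted against statsmodels to
1e-3 / 1e-6; the unweighted linear fit is cross-checked against
statsmodels MixedLM. Convergence uses a scaled-gradient criterion
(max |g| < 1e-5·(1+|ℓ|)); non-convergence flags the fit rather than
raising, and complete separation raises.

*Marginal effects* for the logistic model are population-averaged:
dP/dx_j = β_j·E<sub>u</sub>[P(1−P)], the expectation taken by 41-node
Gauss–Hermite over the fitted intercept distribution, with delta-method
standard errors from the joint covariance of (β, log σ<sub>u</sub>);
the quadrature derivative is verified against a finite-difference oracle.
ICC = σ<sub>u</sub>²/(σ<sub>u</sub>² + π²/3) (logistic) or
σ<sub>u</sub>²/(σ<sub>u</sub>² + σ<sub>τ</sub>²) (linear). AIC/BIC
comparisons flag a favourite only beyond a difference of 10.

**Stage 2: remittance → forest.** Outcomes are ΔForest (change in the
weighted forest-cover proportion) and ΔEVI (change in the weighted mean
EVI of forested cells) inside buffers around each house point, at radii
25–200 m in 25 m steps. Cell weights are the exact fraction of the cell
inside the buffer, computed by polygon clipping against a 256-gon circle
(relative area error < 1e-4; verified to 1e-3 against 100×100
supersampling); cells below 0.5% overlap are excluded before
renormalisation. ΔEVI is undefined when a date has zero forest weight,
and forested cells with missing EVI drop out of that term's numerator
and denominator together.

Because remittance is not randomised, households receiving it (treated)
are matched one-to-one to households with migrants but no remittance
(controls) on a logistic propensity score built from household
covariates (site, topography, market access, cropland, asset scores,
head education). Each control takes the nearest-score treated household;
treated households are reusable and weighted by the inverse of their
multiplicity; score ties break on the smallest household id, making the
matching invariant to row order. Balance is checked by a t-test on
matched score gaps and by absolute standardised mean differences
before/after; a caliper sweep records how the matched count and the
effect respond to tighter calipers.

The treatment effect is estimated by pairwise bootstrap: each of 1,000
replicates draws 60% of the matched pairs and evaluates t-tests for
H1 (paired treated−control difference > 0), H2 (treated change > 0) and
H3 (control change ≤ 0, scored separately as significantly-negative and
as not-significant). Because a treated household can appear in several
pairs, all t statistics first collapse duplicates — values sharing a
household are averaged so each household contributes once; without this
the reused treated households pseudo-replicate and the null rejection
rate triples. The per-replicate ATE uses the same inverse-multiplicity
weights. Two resampling modes exist: with replacement (default for
effect estimation) and a plain 60% subsample. Under the null, a
with-replacement replicate's t statistic has variance ≈ 1 + 0.6 from the
parent draw and rejects far above the nominal level by construction —
the occurrence measures *consistency*, not size; a plain subsample is
marginally an i.i.d. draw and its t statistic is exactly calibrated, so
the null-calibration evaluation uses subsample mode. Occurrences are
reported both direction-gated (p < 0.05 *and* the hypothesised sign) and
as raw two-sided rates.

The remittance–forest association is an OLS slope of buffer change on
log₁₀ remittance (household total, or per-migrant average), bootstrapped
the same way; at the resident-group level the same regression runs on
ring buffers (within the group polygon, 0–100 m and 100–200 m dilation
rings around its boundary, Minkowski dilation via shapely buffering),
with a robustness refit excluding points whose |studentised residual|
exceeds 3.

**Stage 3: mechanism.** Fuelwood value = collected kg × 0.4 Yuan/kg;
fuelwood share = fuelwood value / (fuelwood value + gas cost), undefined
if both are zero. Households are placed on a three-stage energy ladder
(share > 0.6 → fuelwood/coal main; 0.4–0.6 → half-half; < 0.4 → modern
fuels; boundaries configurable since they are survey-reported in the
original design). Group differences use weighted Welch t-tests; the
ladder composition uses χ² on weighted shares scaled to the Kish
effective sample size and rounded; each indicator is also regressed on
log₁₀ remittance (weighted OLS). Livestock is compared per site and
extraction costs only at the subtropical site, mirroring the survey's
availability.

**Additionality.** G_Econ% divides payment-stimulated remittance,
Σᵢ 10^(β̂·Mᵢ·Pᵢ/1000), by the payments Σₕ Pₕ; G_Ecol% converts each
household's attributable remittance Lₕ = log₁₀ Σ_{i∈Sₕ} 10^(β̂·Mᵢ·Pᵢ/1000)
into forest area through the slope γ̂ and the buffer area A (default the
100 m disc, the radius where effects peak), against the enrolled area
Σₕ Pₕ/λ. Only migrants with payment exposure enter the 10^ sums — the
literal formula would award 10⁰ = 1 Yuan of "stimulated" remittance to
every unexposed migrant (a flag restores the literal reading); a
household with no exposed migrant contributes Lₕ = 0. Bounds come from
β̂ ± σ̂ (econ) and from multiplying the lower/upper limits of both
estimators (ecol). Receiving households whose attributable remittance is
a gross outlier (z > 10 by default) are excluded. The published
formula's units are internally tense (a 10^ stock over an annual flow);
it is implemented as printed. National scaling is purely multiplicative:
G% times the program totals (US$64 billion invested; 29.8 Mha enrolled;
6.22 Yuan/US$).

**Flows.** Migrants aggregate by destination city and province;
distances classify into half-open log₁₀-km bins [1.7, 2.2), [2.2, 2.7),
[2.7, 3.2] (short/medium/long; the top edge belongs to the last bin;
out-of-range distances are flagged, never silently binned), and one-way
ANOVA compares migrant volume, total remittance and remittance per
sender across bins (per-sender and per-migrant denominators both
reported).

## The synthetic-data generator

The generator is first-class, tested code; its defaults *are* the study
conditions: two sites — semi-arid "JC" (22 resident groups, λ = 0.135
Yuan/year/m²) and subtropical "TTZ" (41 groups, λ = 0.1875) — with 458
migrant households, 767 migrants (a truncated-Poisson draw with mean 1.7
per household, repaired to the exact total), ~36% of migrants sending,
~49% of households receiving, sender amounts averaging ~16k Yuan, and
cumulative payments spanning the observed 0–12k Yuan. Sampling weights
follow a two-stratum disproportionate design (participants oversampled).
Household covariates confound remittance receipt with strength chosen so
the propensity model's accuracy sits in the published ~0.7 range. A
single master seed feeds fixed substreams (layout, households, migrants,
rasters, energy/flows), so every stage is independently reproducible and
identical seeds give byte-identical output.

*Settlement geometry.* Resident-group centres scatter over a 6 km site
with mutual spacing; households scatter around their group centre with a
**150 m minimum separation** (dispersed hamlet settlement). This spacing
matters: each cell within the 100 m effect radius responds to its
*nearest* migrant household, so the minimum separation keeps a
household's buffer essentially its own and makes the planted
remittance–forest slope the actual estimand of the household-level
regression (without it the estimand is diluted several-fold by
neighbour attribution).

*Rasters.* The date-0 forest indicator is a Bernoulli draw from a
logistic-smoothed Gaussian field (correlation length ~90 m, ~50%
forest); EVI follows the same field plus noise. Date-1 arises from
directional flips: gain probability = background + target⁺/(1−f̄) on
non-forest cells, loss probability = background·(1−p₀)/p₀ + target⁻/f̄
on forest cells, where the per-cell target is
γ·log₁₀(remittance) + drift within the effect radius of a receiving
household, the drift (−0.015) alone near zero-remittance migrant
households, and zero elsewhere. Two properties are engineered in: the
expected buffer ΔForest equals the planted target, and the *background*
turnover is balanced per cell so that with all effects at zero the
expected net change is exactly zero given the landscape — the zero-effect
scenario is genuinely null (an earlier unbalanced design carried a
latent spatially-correlated drift that broke the one-sample null tests).
The per-buffer noise floor (background rate 0.02) puts the OLS slope
standard error near 0.004–0.005, the precision scale of the published
estimate. The generator records, per household, the expected ΔForest/ΔEVI
integrated over its buffer *with the same fractional-overlap kernel the
metrics use* — the realised estimand that the ATE is tested against.

*What the generator does not emulate:* classification error in the
forest/EVI layers, geographic coordinate systems, seasonal and
return migration, within-household bargaining, spatial autocorrelation
of covariates, or any economic feedback from forest back to livelihoods.
Passing recovery tests therefore shows the estimators are consistent for
their estimands under the assumed data-generating process — not that the
published survey-specific values are reproduced; those depend on
confidential data and are covered by magnitude-level and
formula-arithmetic checks instead.

## Numerical and formula choices

- The ΔForest formula is read as a difference of weighted proportions
  (the normaliser applies to both dates); the alternative literal
  reading leaves the second sum unnormalised and outside [−1, 1].
- The 0.5% cell-inclusion threshold applies before weight
  renormalisation (exclude, then renormalise).
- Circle clipping uses shapely's 256-gon buffer; the supersampling
  oracle is retained in the tests.
- Default caliper 0.05 on the probability scale; sweep grid
  0.01–0.10; matching is with replacement on treated, without on
  controls.
- P<sub>i</sub>, a migrant's payment exposure, equals the household's
  annual payment (household-level exposure applied to each migrant); an
  equal split is the configurable alternative. The household's
  cumulative payment accumulates over its longest-migrating migrant's
  years, with the price deflator ≡ 1 in synthetic data.
- Degenerate inputs: groups of size 1 are allowed with a warning; a
  buffer fully outside the raster returns an empty weight list with a
  warning; a household at the raster edge warns and uses the included
  cells; duplicate radii, invalid polygons, non-binary forest bands,
  orphan ids and negative weights raise with the offending values named.

## Problem sizes in the evaluation runs

The replicated evaluations use: 200 table-only survey replicates for the
amount-coefficient recovery; one full default scenario for the
slope/ATE recovery (1,000 bootstrap replicates); 50 reduced two-site
scenarios × 20 subsample replicates (1,000 total) for the null
calibration; and 50 random 20×20 rasters for the geometry oracle. These
sizes put Monte-Carlo error comfortably inside the tolerances asserted
on them while a complete run stays around a minute on one CPU.

## Known limitations

- Sampling weights are treated as pseudo-likelihood weights with
  model-based standard errors; a design-based (linearised or replicate-
  weight) variance estimator is not implemented.
- The bootstrap treats matched pairs as the resampling unit and ignores
  uncertainty in the propensity model itself.
- Spatial spillover is addressed by group-level aggregation, not by
  spatially-correlated standard errors.
- The additionality bounds propagate only the two regression
  coefficients' uncertainty, as in the original design; sampling
  variability of the payment and migration inputs is not propagated.
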