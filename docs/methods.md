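# Methods

This note documents the models and procedures implemented in
`cropcarbon`, the assumptions behind them, the parameters that matter,
and what the synthetic-data tests do and do not demonstrate.

## Problem setting

Process-based agroecosystem models simulate management effects on crop
yield and soil organic carbon (SOC) annually and in absolute units;
integrated assessment models (IAMs) represent agricultural technologies
through per-period fractional yield changes and a maximum soil-carbon
density reached after a fixed equilibration time (50 years by default).
The package implements the translation between the two
representations, and a reduced-form land-allocation model that shows
what carbon-price incentives do to technology adoption, production,
trade and land-use-change (LUC) emissions once the translated
parameters are in place.

## Synthetic trajectory generator

The generator stands in for a biogeochemical model. It produces, per
(basin, crop, technology), annual series for 2016–2100:

- yield: `Y(t) = Y0 * (1 + beta) * g(t) + eps_t`, with conventional-
  fallow base yield `Y0` (crop-level means modified ×1.15 for
  irrigation, ×0.90 for low fertilization), technology effect `beta`,
  background trend `g` (default 1), Gaussian noise;
- SOC: `S(t) = S0 + (S_eq - S0) * (1 - exp(-k (t - 2016))) + eps_t`,
  with `k` chosen so 99% of the asymptotic change is reached at the
  true equilibrium year.

The saturating-exponential form and the 99% convention are design
choices: the emulated model class describes SOC approaching a peak
density without prescribing a functional form, and a single-rate
exponential is the simplest curve with the right qualitative shape.
Effects are assigned per (crop, tillage, cover) class; water and
fertilizer scale the base yield but not the relative effect, mirroring
how the effects are reported as averages over those dimensions. The
two quantitative anchors are wheat no-till + legume cover (+33% yield,
+80% equilibrium SOC); the rest of the table encodes the qualitative
ordering (no-till corn gains far more SOC than soybean; soybean yields
dip without a legume cover; other grain is a slightly weaker wheat;
fiber crop modest throughout). Times to equilibrium are anchored at
the IAM's 50-year default: 40 years for conventional-fallow (already
near steady state), 45 with cover crops only, 50 for no-till, 55 for
no-till plus cover (inputs keep accumulating).

Initial SOC varies deterministically across basins (45–75 Mg C/ha);
conventional-fallow equilibria sit 5% above the initial stock. Noise
defaults are 5% of base yield and 1% of initial SOC per year —
interannual variability of the right order for managed cropland
without weather forcing (the emulated projections likewise recycled
historical weather without climate change). Every run's parameters are
emitted in a ground-truth ledger; per-run seeds derive deterministically
from the study seed, so regeneration is bit-identical.

A loam soil texture (40/40/20 sand/silt/clay) is carried as metadata
only; texture does not enter the emulator's math.

What the generator does *not* emulate: carbon/nitrogen pool dynamics,
management transitions mid-series, weather-driven autocorrelation,
yield–SOC covariance, or declining-SOC systems (supported by the
detector, not produced by the default table). Passing parameter-
recovery tests therefore show the harmonization recovers *this* curve
family, not that it would recover arbitrary process-model output.

## Yield harmonization

The IAM side carries per-period (5-year) fractional yield changes; a
dimensionless index anchored at 1.0 in 2015 compounds them:
`I(p) = I(p-1) * (1 + dy(p))`. The process-model side contributes the
annual ratio of each technology's yield to its conventional-fallow
reference minus one; ratios are averaged over each period's 5 calendar
years (window ending at the period label, first projected period
2020), *added* to the baseline index, and the modified index is
differenced back into yield changes. Differencing is the exact inverse
of compounding, so a zero-delta technology reproduces the baseline
table exactly — this round trip is property-tested.

The delta is oriented technology/reference − 1, so beneficial
technologies carry positive deltas that raise the index; the additive
application to the index follows the harmonization procedure this
package reproduces.

## SOC harmonization

Annual SOC is smoothed with one least-squares cubic over the full
85-year window. On the smoothed curve the equilibrium is:

1. the earliest grid year at which the fitted curve attains its
   maximum, when that maximum is interior to the window; otherwise
2. the earliest grid year whose fitted rate of change (the cubic's
   analytic derivative sampled annually) is the smallest non-negative
   value on the grid.

All-negative rates mark a declining trajectory: flagged, equilibrium
at the first year. Ties break to the earliest year. Years-to-
equilibrium is the equilibrium year minus 2015. `soc_max` is the
fitted value at the equilibrium year (rule 2 included).

Scaling: for each (basin, crop), the conventional-fallow equilibrium
(mean over its water × fertilizer variants) is mapped onto the IAM's
default maximum density via `SF = SOC_max_IAM / SOC_max_model(conv)`,
and every technology is multiplied by the same SF. The orientation is
chosen so the conventional technology lands on the IAM default
*exactly* — the only testable statement of the procedure — and a
positive scalar preserves the relative SOC ordering and ratios between
technologies. Timing is not rescaled.

### Known bias of the equilibrium detector

A single cubic cannot localize the 99%-of-asymptote year of a
saturating exponential: the fitted cubic's peak sits near where the
curve visibly flattens (roughly 96–99% of the asymptote depending on
the rate), not at a fixed fraction. On the noiseless reference study
the detected year is exact for 40-year classes, ~7 years early for
50-year classes, ~10 years early for 55-year classes, and for 45-year
classes rule 2's "smallest non-negative rate on the grid" lands on the
cubic's late near-zero-rate branch, ~24 years late. Equilibrium *SOC*
is insensitive to this (max error 0.6% on the reference study) because
the curve is flat near the equilibrium. The bias is a property of the
published detection rule applied to this curve family, and it is
reported rather than patched; the corresponding strict ±5-year
recovery test is expected to fail and documents the discrepancy. Under
small noise the detected year can jump between the two near-zero-rate
branches; detection converges to the noiseless answer as noise → 0.

## Carbon policy

Price: `p(t) = 183.50 * 1.05^(t - 2020)` USD/tCO2, 2020–2100. The
incentive is an annuity `rho * p(t) * dC` per hectare-year on carbon
held above reference, with annuitization rate `rho = 0.05`/yr exposed
in configuration (the emulated analysis states an annuity is paid but
not its formula). The reference stock is the 2020 technology-mix
equilibrium density, so payments reward additionality and ramp up as
soils actually accumulate carbon. Eligibility: AC pays all terrestrial
pools on all land; CC/CCPL pay soil carbon on cropland exclusively;
REF pays nothing. Prices are per tCO2; carbon masses convert at 44/12.

## Land-allocation demonstrator

Two regions (US, rest-of-world aggregate), 5-year steps 2020–2100,
exogenous per-crop demand (+15% by 2070, flat after, a stylized
population-driven path). Within each crop, technology shares follow
`share_i ∝ w_i * profit_i^lambda` with `lambda = 2`; the weights `w_i`
are calibrated once so that 2020 profits reproduce the configured 2020
technology mix. The plain power rule (uniform weights) is exposed and
tested; calibration is necessary because 20 of 24 technologies are
conservation technologies, so uncalibrated shares would hand them a
majority in 2020 regardless of economics, contradicting observed
adoption. The 2020 mix itself is a placeholder independence product
over the dimensions (20/80 irrigated, 70/30 high fertilizer, 65/35
conventional tillage, 90/7/3 fallow/non-legume/legume).

Demand splits between regions by relative unit cost (cost net of
subsidy per Mg) through a logit with exponent `mu = 4`, calibrated to
the 2020 production split. Land balance holds per region (cropland +
natural land constant); natural land may not fall below the scenario's
protection floor, and a region at its floor passes unmet production to
the other region (infeasibility in both regions raises an error naming
the constraint). Under the all-terrestrial scenario the natural-land
annuity acts as a rent that blocks cropland expansion when it exceeds
the best crop profit.

Carbon: each (crop, technology) pool and each natural pool carries an
area and a stock. Land moving between pools carries carbon at the
donor pool's density; each pool's density then relaxes toward its
equilibrium, closing `step / years_to_eq` of the remaining gap per
step (capped at 1) — the IAM-style linear approach that consumes only
(SOC_max, years_to_eq) from the harmonization. Emissions per period
are `-44/12 ×` the regional stock change; cumulative emissions
therefore equal the total stock change identically, which is asserted
in every scenario run.

The demonstrator's economics (crop prices, per-technology cost
adders, ROW cost/yield factors, natural-land densities of 100 and
90 Mg C/ha) are stylized constants of the right order for US
agriculture, chosen once to make all profits positive and the 2020
calibration meaningful. The demonstrator is directional: it reproduces
the sign structure of the emulated full-IAM results (incentives →
conservation majority, stronger cropland sink, US expansion / ROW
contraction, lower US unit costs) and none of their magnitudes.

## Numerical choices

- Cubic fits use `numpy.polynomial.Polynomial.fit` (scaled domain) for
  conditioning; coefficients are converted back on demand.
- Equilibrium rule ties break to the earliest year via tolerance-based
  argmax (`1e-9` relative) so constant series detect their first year.
- Profits are floored at $1/ha before exponentiation; all-non-positive
  profit vectors fall back to uniform shares with a warning.
- Protected-land comparisons in tests allow 1e-6 thousand km² slack
  for floating-point equality at the binding floor.
- Problem sizes: the reference study is 30 systems × 24 technologies ×
  85 years; harmonization fits 720 cubics in ~10 s; a scenario run is
  17 periods and takes ~1 s.

## Limitations

- No general equilibrium, trade flows, bioenergy, non-CO2 gases, or
  climate feedback; demand is exogenous.
- Above-ground carbon is represented only in the aggregate natural-
  land density; cropland vegetation carbon is ignored.
- The basin dimension is synthetic: identifiers and areas are
  placeholders, not georeferenced basins.
- The 2020 technology shares and all demonstrator economics are
  stylized configuration, not estimates.
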