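# cropcarbon

Tools for translating process-based agroecosystem model output — annual
crop-yield and soil-organic-carbon (SOC) trajectories under no-till and
cover-crop management — into the parameters an integrated assessment
model (IAM) consumes, and for exercising those parameters under
carbon-price incentive scenarios.

It is aimed at researchers studying soil-carbon sequestration policy on
US cropland: people who have (or emulate) biogeochemical-model runs for
factorial management treatments and want reproducible, tested
harmonization into IAM yield-change and soil-carbon-density parameters,
plus a transparent reduced-form land-allocation model to explore the
directional consequences of paying farmers for stored carbon.

## What it computes

**Technology grid.** A management *technology* is a crop grown under
water source (IRR/RFD) × fertilizer rate (hi/lo) × tillage (C/N) ×
cover crop (F/NonLgm/Lgm) — 24 technologies per crop. Crossing the 30
basin-crop systems of the reference design with their grids gives 720
runs.

**Synthetic trajectories.** A generator emulates process-model output
2016–2100 with known ground truth: yield Y(t) = Y₀(1+β)g(t)+ε with
technology effect β, and SOC following a saturating curve
S(t) = S₀ + (S_eq − S₀)(1 − e^(−kt)) with k set so 99% of the change is
reached at the true equilibrium year. Anchor effects: wheat under
no-till + legume cover gains 33% yield and up to 80% SOC over
conventional-fallow.

**Yield harmonization.** Per-period yield changes compound a yield
index anchored at 1.0 in 2015: I(p) = I(p−1)(1+Δy(p)). Annual
technology/reference yield ratios minus one are averaged onto the
5-year period grid, added to the baseline index, and the modified index
is differenced back into per-period yield changes — an exact
round trip.

**SOC harmonization.** Annual SOC is smoothed with a least-squares
cubic; the equilibrium point is the earliest year the fitted curve
attains its maximum (when interior), else the earliest year whose
fitted rate of change is the smallest non-negative value; years-to-
equilibrium = equilibrium year − 2015. The conventional-fallow
equilibrium is scaled onto the IAM's default maximum soil-carbon
density, SF = SOC_max^IAM / SOC_max^model(conv), and every technology
of the same (basin, crop) is multiplied by the same SF, preserving
relative SOC differences.

**Policy.** A carbon price of $183.50/tCO₂ in 2020 growing 5%/yr,
annuitized at rate ρ (default 0.05/yr) on carbon held above the 2020
technology-mix equilibrium: payment = ρ · p(t) · ΔC. Scenario presets:
AC (all terrestrial carbon), CC (cropland soil only), REF (no
incentive, 90% of natural land protected), CCPL (cropland soil
incentive + 90% protection).

**Land demonstrator.** A two-region (US / rest-of-world) model
allocates each crop's land across technologies by a calibrated
power-share rule on per-hectare profit, splits exogenous demand between
regions by relative unit cost, enforces land balance and the
protected-land floor, moves carbon with land at the donor pool's
density, and relaxes each pool's density linearly toward equilibrium.
Land-use-change emissions are −44/12 × ΔC, so cumulative emissions
equal the total stock change exactly.

## Worked example

```
python examples/04_scenarios.py
```

prints (seed 1):

```
REF: conservation share of US cropland 2100 = 40.6%, cumulative US-cropland LUC emissions =  -0.79 GtCO2
CCPL: conservation share of US cropland 2100 = 99.1%, cumulative US-cropland LUC emissions = -12.66 GtCO2

CCPL - REF cropland area 2100: US +338, rest-of-world -469 thousand km2
```

Without an incentive (REF) the 2020 technology mix barely moves and
cropland soils sequester little. Pricing cropland soil carbon (CCPL)
drives nearly all US cropland into no-till and/or cover cropping by
2100, turns US cropland into a ~12 GtCO₂ cumulative sink relative to
the reference, and shifts production into the US (cropland +338
thousand km², while the rest of the world contracts), with natural land
never dropping below its 90% protection floor. The other examples walk
through the grid, the generator, harmonization and reporting
individually.

A thin CLI mirrors the pipeline stages
(`cropcarbon generate|harmonize|simulate|compare|report`).

## Layout

- `src/cropcarbon/technologies.py` — factorial grid, study designs
- `src/cropcarbon/synthetic.py` — trajectory generator + ground truth
- `src/cropcarbon/yields.py`, `soc.py` — harmonization stages
- `src/cropcarbon/policy.py` — price path, annuity, scenario presets
- `src/cropcarbon/landsim.py` — two-region land-allocation demonstrator
- `src/cropcarbon/reporting.py`, `pipeline.py`, `cli.py`
- `docs/methods.md` — model description, assumptions, limitations
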