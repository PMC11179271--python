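"""Reduced-form two-region land-allocation demonstrator.

Converts harmonized technology parameters (per-period yield indices,
equilibrium soil-carbon densities) and a carbon-incentive scenario into
technology shares, cropland areas, production, carbon stocks and
land-use-change (LUC) emissions for the US and an aggregate
rest-of-world (ROW) region, on the 5-year period grid 2020-2100.

This is a deliberately simplified stand-in for a full integrated
assessment model, built to reproduce *directional* behavior only:

- technology competition within each crop by a calibrated power-share
  (logit-like) rule on per-hectare profit, with calibration weights
  that reproduce the configured 2020 technology mix;
- a two-region supply split of exogenous crop demand by relative unit
  production cost, likewise calibrated to the 2020 production split;
- land balance per region (cropland + natural land constant), with a
  protected-land floor on natural land;
- carbon accounting in which carbon moves with land at the donor pool's
  density and each pool's density then relaxes linearly toward its
  equilibrium, closing step/years_to_eq of the remaining gap per step.

Cumulative LUC emissions therefore equal -44/12 times the change in
total terrestrial carbon stock by construction.  Negative emissions
denote net sequestration.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import policy as policy_mod
from .policy import CROPLAND, Scenario, annuity_payment
from .synthetic import (
    BASE_YIELDS,
    BASELINE_YIELD_CHANGE,
    FERTILIZER_YIELD_FACTOR,
    WATER_YIELD_FACTOR,
)
from .technologies import DEFAULT_CROPS, ManagementTechnology

PERIODS = tuple(range(2020, 2101, 5))
STEP = 5
C_TO_CO2 = 44.0 / 12.0

US = "US"
ROW = "ROW"
GLOBAL = "Global"


def _stock_gtc(area_tkm2: float, density_mgc_ha: float) -> float:
    """Carbon stock in GtC from area (thousand km^2) and density (Mg C/ha)."""
    return area_tkm2 * density_mgc_ha * 1e-4


@dataclass
class HarmonizedInputs:
    """Bundle of harmonized tables the demonstrator consumes.

    yield_table: long (basin_id, crop, technology, period, yield_index,
    yield_change); soc_table: long (basin_id, crop, technology, soc_max,
    years_to_eq, soc_max_scaled, ...); areas: (basin_id, crop, area).
    """

    yield_table: pd.DataFrame
    soc_table: pd.DataFrame
    areas: pd.DataFrame


@dataclass
class LandSimConfig:
    """Economic and land configuration of the demonstrator.

    Monetary values in USD; areas in thousand km^2; densities in
    Mg C/ha.  The 2020 technology-mix shares are placeholders built as
    an independence product over the four management dimensions (the
    analysis this emulates drew them from a national survey report
    without printed values).
    """

    crops: tuple[str, ...] = DEFAULT_CROPS
    crop_price: dict = field(default_factory=lambda: {
        "corn": 170.0, "soybean": 360.0, "wheat": 220.0,
        "other-grain": 180.0, "fiber-crop": 900.0,
    })
    base_cost: dict = field(default_factory=lambda: {
        "corn": 900.0, "soybean": 500.0, "wheat": 450.0,
        "other-grain": 450.0, "fiber-crop": 900.0,
    })
    cover_cost: dict = field(default_factory=lambda: {
        "F": 0.0, "NonLgm": 90.0, "Lgm": 110.0})
    tillage_cost: dict = field(default_factory=lambda: {"C": 0.0, "N": -15.0})
    water_cost: dict = field(default_factory=lambda: {"IRR": 150.0, "RFD": 0.0})
    fertilizer_cost: dict = field(default_factory=lambda: {"hi": 0.0, "lo": -40.0})
    # 2020 technology-mix placeholder (independence product).
    init_share_water: dict = field(default_factory=lambda: {"IRR": 0.20, "RFD": 0.80})
    init_share_fert: dict = field(default_factory=lambda: {"hi": 0.70, "lo": 0.30})
    init_share_tillage: dict = field(default_factory=lambda: {"C": 0.65, "N": 0.35})
    init_share_cover: dict = field(default_factory=lambda: {
        "F": 0.90, "NonLgm": 0.07, "Lgm": 0.03})
    lambda_share: float = 2.0       # profit exponent of the share rule
    mu_trade: float = 4.0           # unit-cost exponent of the trade split
    profit_floor: float = 1.0       # USD/ha floor before exponentiation
    natural_area: dict = field(default_factory=lambda: {US: 3000.0, ROW: 20000.0})
    natural_density: dict = field(default_factory=lambda: {US: 100.0, ROW: 90.0})
    natural_years_to_eq: float = 50.0
    row_cropland_multiple: float = 4.0   # ROW cropland area per crop / US
    row_yield_factor: float = 0.8        # ROW yield relative to US CF base
    row_cost_factor: float = 0.9         # ROW cost relative to US base cost
    row_soc_density: float = 55.0        # ROW cropland soil density (static eq)
    demand_growth_total: float = 0.15    # demand multiplier reached by ...
    demand_growth_until: int = 2070      # ... this year, flat afterwards

    @classmethod
    def from_yaml(cls, path) -> "LandSimConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def tech_cost(self, tech: ManagementTechnology) -> float:
        """Non-land production cost, USD/ha/yr."""
        return (
            self.base_cost[tech.crop]
            + self.cover_cost[tech.cover]
            + self.tillage_cost[tech.tillage]
            + self.water_cost[tech.water]
            + self.fertilizer_cost[tech.fertilizer]
        )

    def init_share(self, tech: ManagementTechnology) -> float:
        return (
            self.init_share_water[tech.water]
            * self.init_share_fert[tech.fertilizer]
            * self.init_share_tillage[tech.tillage]
            * self.init_share_cover[tech.cover]
        )

    def base_yield(self, tech: ManagementTechnology) -> float:
        """Conventional-fallow 2015 base yield of the tech's water/fert
        variant, Mg/ha."""
        return (
            BASE_YIELDS[tech.crop]
            * WATER_YIELD_FACTOR[tech.water]
            * FERTILIZER_YIELD_FACTOR[tech.fertilizer]
        )

    def demand_multiplier(self, period: int) -> float:
        frac = min(1.0, (period - PERIODS[0]) / (self.demand_growth_until - PERIODS[0]))
        return 1.0 + self.demand_growth_total * frac


@dataclass
class ScenarioResult:
    """Full time-series output of one scenario run."""

    scenario: Scenario
    areas: pd.DataFrame        # region, crop, technology, period, area
    shares: pd.DataFrame       # region, crop, technology, period, share
    production: pd.DataFrame   # region, crop, period, production_mt
    economics: pd.DataFrame    # crop, technology, period, yield, cost, subsidy, profit
    prices: pd.DataFrame       # region, crop, period, unit_cost
    stocks: pd.DataFrame       # region, pool, period, stock_gtc
    emissions: pd.DataFrame    # region, scope, period, emissions_gtco2, cumulative_gtco2
    natural: pd.DataFrame      # region, period, natural_area, floor

    _FRAMES = (
        "areas", "shares", "production", "economics",
        "prices", "stocks", "emissions", "natural",
    )

    def write(self, outdir) -> None:
        """Write the result as a directory of delimited tables plus a
        small run manifest."""
        import json

        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        for name in self._FRAMES:
            getattr(self, name).to_csv(out / f"{name}.csv", index=False)
        manifest = {
            "scenario": self.scenario.name,
            "incentive_scope": self.scenario.incentive_scope,
            "protected_fraction": self.scenario.protected_fraction,
            "price_p0": None if self.scenario.price_path is None
            else self.scenario.price_path.p0,
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))

    @classmethod
    def read(cls, indir, scenario: Scenario) -> "ScenarioResult":
        d = Path(indir)
        frames = {n: pd.read_csv(d / f"{n}.csv") for n in cls._FRAMES}
        return cls(scenario=scenario, **frames)


def allocate_shares(profits, lam: float, weights=None, floor: float = 1e-6):
    """Power-share allocation: share_i ~ w_i * max(profit_i, floor)^lam.

    With uniform weights this is the plain profit-power rule; with
    calibration weights it reproduces a base-year technology mix at
    base-year profits.  If every profit is non-positive the shares are
    uniform (with a warning).
    """
    p = np.asarray(profits, dtype=float)
    if lam <= 0:
        raise ValueError(f"lambda must be > 0, got {lam}")
    w = np.ones_like(p) if weights is None else np.asarray(weights, dtype=float)
    if np.all(p <= 0):
        warnings.warn("all profits non-positive; falling back to uniform shares")
        return np.full_like(p, 1.0 / p.size)
    scores = w * np.maximum(p, floor) ** lam
    return scores / scores.sum()


def step_soc_stocks(stocks, areas, soc_eq, years_to_eq, step: int = STEP):
    """Move soil stocks toward area * equilibrium density.

    Each stock closes ``min(1, step / years_to_eq)`` of its remaining
    gap to ``area * soc_eq`` per call.  Arguments are aligned arrays (or
    scalars); stocks and the return value are in the same carbon unit as
    ``area * soc_eq``.
    """
    stocks = np.asarray(stocks, dtype=float)
    target = np.asarray(areas, dtype=float) * np.asarray(soc_eq, dtype=float)
    frac = np.minimum(1.0, step / np.maximum(np.asarray(years_to_eq, float), 1e-9))
    return stocks + frac * (target - stocks)


def luc_emissions(stock_before_gtc, stock_after_gtc):
    """LUC emissions (GtCO2) from a carbon-stock change (GtC).

    Negative emissions indicate a net terrestrial carbon increase.
    """
    return -(np.asarray(stock_after_gtc, float) - np.asarray(stock_before_gtc, float)) * C_TO_CO2


def _aggregate_inputs(inputs: HarmonizedInputs, config: LandSimConfig):
    """Area-weighted aggregation of harmonized tables over basins to the
    (crop, technology) level the demonstrator operates on."""
    areas = inputs.areas.set_index(["basin_id", "crop"])["area"]

    yt = inputs.yield_table.copy()
    yt["w"] = [
        areas.loc[(b, c)] for b, c in zip(yt.basin_id, yt.crop)
    ]
    yt["wx"] = yt.w * yt.yield_index
    g = yt.groupby(["crop", "technology", "period"])
    yield_index = (g.wx.sum() / g.w.sum()).rename("yield_index")

    st = inputs.soc_table.copy()
    st["w"] = [areas.loc[(b, c)] for b, c in zip(st.basin_id, st.crop)]
    st["ws"] = st.w * st.soc_max_scaled
    st["wy"] = st.w * st.years_to_eq
    g = st.groupby(["crop", "technology"])
    soc_eq = (g.ws.sum() / g.w.sum()).rename("soc_eq")
    years_to_eq = (
        (g.wy.sum() / g.w.sum()).round().clip(lower=1).astype(int).rename("years_to_eq")
    )
    return yield_index, soc_eq, years_to_eq


class _Region:
    """Mutable land/carbon state of one region during a run."""

    def __init__(self, name, pools, natural_area, natural_density, floor):
        self.name = name
        # pools: code -> [area, density, eq_density, years_to_eq]
        self.pools = pools
        self.natural_area = natural_area
        self.natural_density = natural_density
        self.floor = floor

    @property
    def cropland_area(self) -> float:
        return sum(a for a, *_ in self.pools.values())

    @property
    def total_land(self) -> float:
        return self.cropland_area + self.natural_area

    def cropland_stock(self) -> float:
        return sum(_stock_gtc(a, d) for a, d, *_ in self.pools.values())

    def natural_stock(self) -> float:
        return _stock_gtc(self.natural_area, self.natural_density)

    def reallocate(self, new_areas: dict) -> None:
        """Move land between pools (incl. natural), carbon travelling at
        the donor pool's density.  Land total is conserved exactly."""
        new_natural = self.total_land - sum(new_areas.values())
        if new_natural < self.floor - 1e-9:
            raise RuntimeError(
                f"protected-land constraint binding in {self.name}: natural "
                f"land {new_natural:.2f} would fall below floor {self.floor:.2f}"
            )
        donated_area = 0.0
        donated_c = 0.0  # GtC
        deltas = {}
        for code, (a, d, *_rest) in self.pools.items():
            da = new_areas[code] - a
            deltas[code] = da
            if da < 0:
                donated_area += -da
                donated_c += _stock_gtc(-da, d)
        dnat = new_natural - self.natural_area
        if dnat < 0:
            donated_area += -dnat
            donated_c += _stock_gtc(-dnat, self.natural_density)
        pot_density = (
            donated_c / (donated_area * 1e-4) if donated_area > 1e-12 else 0.0
        )
        for code, rec in self.pools.items():
            a, d, eq, yte = rec
            da = deltas[code]
            if da > 0:
                new_stock = _stock_gtc(a, d) + _stock_gtc(da, pot_density)
                new_a = a + da
                rec[0] = new_a
                rec[1] = new_stock / (new_a * 1e-4) if new_a > 1e-12 else eq
            else:
                rec[0] = a + da  # density unchanged for donors
        if dnat > 0:
            new_stock = self.natural_stock() + _stock_gtc(dnat, pot_density)
            self.natural_area += dnat
            self.natural_density = new_stock / (self.natural_area * 1e-4)
        else:
            self.natural_area += dnat

    def relax(self, natural_eq_density, natural_years, step=STEP) -> None:
        """Densities approach their equilibria (linear gap closing)."""
        for rec in self.pools.values():
            a, d, eq, yte = rec
            stock = step_soc_stocks(a * d, a, eq, yte, step)
            rec[1] = stock / a if a > 1e-12 else d + min(1.0, step / yte) * (eq - d)
        nd = self.natural_density
        self.natural_density = nd + min(1.0, step / natural_years) * (
            natural_eq_density - nd
        )


def run_scenario(
    scenario: Scenario,
    inputs: HarmonizedInputs,
    config: LandSimConfig | None = None,
    seed: int | None = None,
) -> ScenarioResult:
    """Simulate one scenario, 2020-2100 in 5-year steps.

    The default run is fully deterministic; ``seed`` is accepted for
    interface symmetry with stochastic configurations.
    """
    del seed  # deterministic demonstrator
    config = config or LandSimConfig()
    yield_index, soc_eq_agg, years_agg = _aggregate_inputs(inputs, config)

    crops = [c for c in config.crops if c in set(inputs.areas.crop)]
    techs: dict[str, list[ManagementTechnology]] = {}
    for crop in crops:
        codes = sorted(
            soc_eq_agg.loc[crop].index.unique()
        )
        techs[crop] = [ManagementTechnology.from_code(c) for c in codes]

    us_area0 = inputs.areas.groupby("crop").area.sum()

    # --- region states ------------------------------------------------
    def baseline_density(crop):
        # conventional-fallow equilibrium == IAM default after scaling
        cf = [t for t in techs[crop] if t.tillage == "C" and t.cover == "F"]
        return float(np.mean([soc_eq_agg.loc[(crop, t.code)] for t in cf]))

    us_pools = {}
    s0 = {}
    for crop in crops:
        d0 = baseline_density(crop)
        shares0 = np.array([config.init_share(t) for t in techs[crop]])
        shares0 = shares0 / shares0.sum()
        s0[crop] = shares0
        for t, sh in zip(techs[crop], shares0):
            us_pools[t.code] = [
                float(us_area0[crop]) * sh,
                d0,
                float(soc_eq_agg.loc[(crop, t.code)]),
                int(years_agg.loc[(crop, t.code)]),
            ]
    us = _Region(
        US, us_pools, config.natural_area[US], config.natural_density[US],
        scenario.protected_fraction * config.natural_area[US],
    )
    row_pools = {
        crop: [
            float(us_area0[crop]) * config.row_cropland_multiple,
            config.row_soc_density,
            config.row_soc_density,
            50,
        ]
        for crop in crops
    }
    row = _Region(
        ROW, row_pools, config.natural_area[ROW], config.natural_density[ROW],
        scenario.protected_fraction * config.natural_area[ROW],
    )

    # reference density for the annuity: 2020 technology-mix equilibrium
    ref_density = {
        crop: float(
            np.dot(s0[crop], [soc_eq_agg.loc[(crop, t.code)] for t in techs[crop]])
        )
        for crop in crops
    }

    # --- economics helpers --------------------------------------------
    def tech_yield(crop, tech, period):
        return config.base_yield(tech) * float(
            yield_index.loc[(crop, tech.code, period)]
        )

    def economics(crop, period):
        ys, costs, subs = [], [], []
        for t in techs[crop]:
            y = tech_yield(crop, t, period)
            cost = config.tech_cost(t)
            d = us.pools[t.code][1]
            delta_c = max(0.0, d - ref_density[crop]) * C_TO_CO2
            sub = annuity_payment(scenario, period, CROPLAND, "soil", delta_c)
            ys.append(y)
            costs.append(cost)
            subs.append(sub)
        ys, costs, subs = map(np.array, (ys, costs, subs))
        profits = config.crop_price[crop] * ys - costs + subs
        return ys, costs, subs, profits

    def row_yield(crop, period):
        steps = (period - PERIODS[0]) // STEP
        return (
            BASE_YIELDS[crop]
            * config.row_yield_factor
            * (1.0 + BASELINE_YIELD_CHANGE) ** steps
        )

    # calibrate share weights and trade weights at 2020
    w_share = {}
    v_trade = {}
    prod0 = {}
    for crop in crops:
        ys, costs, subs, profits = economics(crop, PERIODS[0])
        w_share[crop] = s0[crop] / np.maximum(profits, config.profit_floor) ** config.lambda_share
        yield_mix = float(np.dot(s0[crop], ys))
        cost_mix = float(np.dot(s0[crop], costs - subs))
        u_us = max(cost_mix, config.profit_floor) / yield_mix
        u_row = config.row_cost_factor * config.base_cost[crop] / row_yield(crop, PERIODS[0])
        us_prod = float(us_area0[crop]) * 1e5 * yield_mix / 1e6  # Mt
        row_prod = row.pools[crop][0] * 1e5 * row_yield(crop, PERIODS[0]) / 1e6
        share0 = us_prod / (us_prod + row_prod)
        v_trade[crop] = share0 / (1.0 - share0) * (u_us / u_row) ** config.mu_trade
        prod0[crop] = us_prod + row_prod

    # --- recording -----------------------------------------------------
    rec = {name: [] for name in ScenarioResult._FRAMES}

    def record_state(period, share_map, prod_map, econ_map, price_map):
        for crop in crops:
            for i, t in enumerate(techs[crop]):
                rec["areas"].append(
                    dict(region=US, crop=crop, technology=t.code,
                         period=period, area=us.pools[t.code][0]))
                rec["shares"].append(
                    dict(region=US, crop=crop, technology=t.code,
                         period=period, share=share_map[crop][i]))
                if econ_map is not None:
                    y, c, sb, pf = econ_map[crop]
                    rec["economics"].append(
                        dict(crop=crop, technology=t.code, period=period,
                             yield_mg_ha=y[i], cost_usd_ha=c[i],
                             subsidy_usd_ha=sb[i], profit_usd_ha=pf[i]))
            rec["areas"].append(
                dict(region=ROW, crop=crop, technology="aggregate",
                     period=period, area=row.pools[crop][0]))
            rec["production"].append(
                dict(region=US, crop=crop, period=period,
                     production_mt=prod_map[(US, crop)]))
            rec["production"].append(
                dict(region=ROW, crop=crop, period=period,
                     production_mt=prod_map[(ROW, crop)]))
            rec["prices"].append(
                dict(region=US, crop=crop, period=period,
                     unit_cost=price_map[(US, crop)]))
            rec["prices"].append(
                dict(region=ROW, crop=crop, period=period,
                     unit_cost=price_map[(ROW, crop)]))
        for region in (us, row):
            rec["stocks"].append(
                dict(region=region.name, pool="cropland", period=period,
                     stock_gtc=region.cropland_stock()))
            rec["stocks"].append(
                dict(region=region.name, pool="natural", period=period,
                     stock_gtc=region.natural_stock()))
            rec["natural"].append(
                dict(region=region.name, period=period,
                     natural_area=region.natural_area, floor=region.floor))

    def record_emissions(period, before, after):
        for region in (US, ROW):
            for scope in ("all", "cropland"):
                e = luc_emissions(before[(region, scope)], after[(region, scope)])
                rec["emissions"].append(
                    dict(region=region, scope=scope, period=period,
                         emissions_gtco2=float(e)))

    def snapshot():
        return {
            (US, "all"): us.cropland_stock() + us.natural_stock(),
            (US, "cropland"): us.cropland_stock(),
            (ROW, "all"): row.cropland_stock() + row.natural_stock(),
            (ROW, "cropland"): row.cropland_stock(),
        }

    # initial state at 2020
    share_map0 = {crop: s0[crop] for crop in crops}
    prod_map0 = {}
    price_map0 = {}
    econ_map0 = {}
    for crop in crops:
        ys, costs, subs, profits = economics(crop, PERIODS[0])
        econ_map0[crop] = (ys, costs, subs, profits)
        yield_mix = float(np.dot(s0[crop], ys))
        prod_map0[(US, crop)] = float(us_area0[crop]) * 1e5 * yield_mix / 1e6
        prod_map0[(ROW, crop)] = row.pools[crop][0] * 1e5 * row_yield(crop, PERIODS[0]) / 1e6
        price_map0[(US, crop)] = max(float(np.dot(s0[crop], costs - subs)), config.profit_floor) / yield_mix
        price_map0[(ROW, crop)] = config.row_cost_factor * config.base_cost[crop] / row_yield(crop, PERIODS[0])
    record_state(PERIODS[0], share_map0, prod_map0, econ_map0, price_map0)
    for region in (US, ROW):
        for scope in ("all", "cropland"):
            rec["emissions"].append(
                dict(region=region, scope=scope, period=PERIODS[0],
                     emissions_gtco2=0.0))

    # --- main loop -----------------------------------------------------
    for period in PERIODS[1:]:
        share_map, econ_map, prod_map, price_map = {}, {}, {}, {}
        desired_us, desired_row, yield_mix_map, u_map = {}, {}, {}, {}
        for crop in crops:
            ys, costs, subs, profits = economics(crop, period)
            shares = allocate_shares(
                profits, config.lambda_share, weights=w_share[crop],
                floor=config.profit_floor,
            )
            share_map[crop] = shares
            econ_map[crop] = (ys, costs, subs, profits)
            yield_mix = float(np.dot(shares, ys))
            yield_mix_map[crop] = yield_mix
            net_cost = float(np.dot(shares, costs - subs))
            u_us = max(net_cost, config.profit_floor) / yield_mix
            u_row = config.row_cost_factor * config.base_cost[crop] / row_yield(crop, period)
            u_map[crop] = (u_us, u_row)
            s_us = (
                v_trade[crop] * u_us ** -config.mu_trade
                / (v_trade[crop] * u_us ** -config.mu_trade + u_row ** -config.mu_trade)
            )
            demand = prod0[crop] * config.demand_multiplier(period)
            desired_us[crop] = s_us * demand * 1e6 / (yield_mix * 1e5)
            desired_row[crop] = (1.0 - s_us) * demand * 1e6 / (
                row_yield(crop, period) * 1e5
            )

        # all-terrestrial incentive: holding natural carbon pays, which
        # blocks cropland expansion when the natural-land rent beats the
        # best crop profit.
        cap_us = us.total_land - us.floor
        if scenario.incentive_scope == "all-terrestrial":
            ref_nat = float(np.mean([ref_density[c] for c in crops]))
            nat_rent = annuity_payment(
                scenario, period, "natural", "vegetation",
                max(0.0, us.natural_density - ref_nat) * C_TO_CO2,
            )
            best_profit = max(
                float(np.dot(share_map[c], econ_map[c][3])) for c in crops
            )
            if nat_rent > best_profit:
                cap_us = min(cap_us, us.cropland_area)

        # land-balance caps: scale back the constrained region and shift
        # the unmet production to the other region.
        tot_us = sum(desired_us.values())
        if tot_us > cap_us:
            scale = cap_us / tot_us
            for crop in crops:
                shifted = desired_us[crop] * (1.0 - scale)
                desired_us[crop] *= scale
                desired_row[crop] += (
                    shifted * yield_mix_map[crop] / row_yield(crop, period)
                )
        cap_row = row.total_land - row.floor
        tot_row = sum(desired_row.values())
        if tot_row > cap_row:
            if tot_us >= cap_us - 1e-9:
                raise RuntimeError(
                    "infeasible demand: protected-land constraint binding "
                    "in both regions"
                )
            scale = cap_row / tot_row
            for crop in crops:
                desired_row[crop] *= scale

        new_us_areas = {}
        for crop in crops:
            for t, sh in zip(techs[crop], share_map[crop]):
                new_us_areas[t.code] = desired_us[crop] * sh

        before = snapshot()
        us.reallocate(new_us_areas)
        row.reallocate(dict(desired_row))
        us.relax(config.natural_density[US], config.natural_years_to_eq)
        row.relax(config.natural_density[ROW], config.natural_years_to_eq)
        after = snapshot()
        record_emissions(period, before, after)

        for crop in crops:
            prod_map[(US, crop)] = desired_us[crop] * 1e5 * yield_mix_map[crop] / 1e6
            prod_map[(ROW, crop)] = desired_row[crop] * 1e5 * row_yield(crop, period) / 1e6
            price_map[(US, crop)] = u_map[crop][0]
            price_map[(ROW, crop)] = u_map[crop][1]
        record_state(period, share_map, prod_map, econ_map, price_map)

    frames = {name: pd.DataFrame(rows) for name, rows in rec.items()}
    em = frames["emissions"]
    gl = (
        em.groupby(["scope", "period"], as_index=False).emissions_gtco2.sum()
        .assign(region=GLOBAL)
    )
    em = pd.concat([em, gl[["region", "scope", "period", "emissions_gtco2"]]],
                   ignore_index=True)
    em = em.sort_values(["region", "scope", "period"]).reset_index(drop=True)
    em["cumulative_gtco2"] = em.groupby(["region", "scope"]).emissions_gtco2.cumsum()
    frames["emissions"] = em
    return ScenarioResult(scenario=scenario, **frames)


def compare_scenarios(a: ScenarioResult, b: ScenarioResult) -> dict[str, pd.DataFrame]:
    """Elementwise differences a - b for areas, production, prices,
    emissions and stocks.  Both results must share the same grid."""
    out = {}
    specs = {
        "areas": (["region", "crop", "technology", "period"], ["area"]),
        "production": (["region", "crop", "period"], ["production_mt"]),
        "prices": (["region", "crop", "period"], ["unit_cost"]),
        "stocks": (["region", "pool", "period"], ["stock_gtc"]),
        "emissions": (["region", "scope", "period"],
                      ["emissions_gtco2", "cumulative_gtco2"]),
    }
    for name, (keys, values) in specs.items():
        fa = getattr(a, name).set_index(keys).sort_index()
        fb = getattr(b, name).set_index(keys).sort_index()
        if not fa.index.equals(fb.index):
            raise ValueError(f"mismatched {name} grids between scenarios")
        out[name] = (fa[values] - fb[values]).reset_index()
    return out
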