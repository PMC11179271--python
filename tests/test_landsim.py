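"""Land-allocation demonstrator: share rule, stock dynamics, emissions
accounting, conservation laws and scenario comparison."""

import numpy as np
import pytest

import cropcarbon as cc
from cropcarbon.landsim import GLOBAL, PERIODS, allocate_shares


class TestAllocateShares:
    def test_equal_profits_give_equal_shares(self):
        shares = allocate_shares([5.0, 5.0, 5.0], lam=2.0)
        assert np.allclose(shares, 1 / 3)

    def test_hand_example(self):
        shares = allocate_shares([1.0, 1.0, 2.0], lam=1.0)
        assert np.allclose(shares, [0.25, 0.25, 0.5])

    def test_large_lambda_concentrates_on_maximum(self):
        shares = allocate_shares([1.0, 1.2, 2.0], lam=50.0)
        assert shares[2] > 0.999

    def test_all_nonpositive_profits_fall_back_to_uniform(self):
        with pytest.warns(UserWarning):
            shares = allocate_shares([-1.0, 0.0, -5.0], lam=2.0)
        assert np.allclose(shares, 1 / 3)

    def test_shares_always_sum_to_one(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            p = rng.uniform(-10, 100, size=8)
            if np.all(p <= 0):
                continue
            assert allocate_shares(p, lam=3.0).sum() == pytest.approx(1.0)

    def test_calibration_weights_reproduce_target_mix(self):
        profits = np.array([100.0, 250.0, 40.0])
        target = np.array([0.6, 0.3, 0.1])
        w = target / profits**2.0
        assert np.allclose(allocate_shares(profits, 2.0, weights=w), target)


class TestStockStep:
    def test_stock_at_equilibrium_unchanged(self):
        assert cc.step_soc_stocks(100.0, 2.0, 50.0, 50) == pytest.approx(100.0)

    def test_short_equilibration_reaches_target_in_one_step(self):
        assert cc.step_soc_stocks(0.0, 2.0, 50.0, 5) == pytest.approx(100.0)

    def test_linear_gap_closing(self):
        # gap 10, 50 years to equilibrium -> one tenth per 5-year step
        out = cc.step_soc_stocks(90.0, 2.0, 50.0, 50)
        assert out == pytest.approx(91.0)


class TestLucEmissions:
    def test_no_change_is_zero(self):
        assert cc.luc_emissions(5.0, 5.0) == 0.0

    def test_molar_mass_conversion(self):
        assert cc.luc_emissions(0.0, 1.0) == pytest.approx(-44 / 12)

    def test_regional_additivity(self, ccpl_result):
        em = ccpl_result.emissions
        for scope in ("all", "cropland"):
            per = em[em.scope == scope].pivot(
                index="period", columns="region", values="emissions_gtco2"
            )
            assert np.allclose(per[GLOBAL], per["US"] + per["ROW"])


class TestRunScenario:
    def test_reference_run_has_zero_subsidies(self, ref_result):
        assert (ref_result.economics.subsidy_usd_ha == 0).all()

    def test_ccpl_run_pays_subsidies_eventually(self, ccpl_result):
        assert ccpl_result.economics.subsidy_usd_ha.max() > 0

    def test_shares_sum_to_one_every_period(self, ccpl_result):
        sums = ccpl_result.shares.groupby(["crop", "period"]).share.sum()
        assert np.allclose(sums, 1.0)

    def test_land_totals_conserved(self, ccpl_result):
        for region in ("US", "ROW"):
            crop = (
                ccpl_result.areas.query("region == @region")
                .groupby("period").area.sum()
            )
            nat = (
                ccpl_result.natural.query("region == @region")
                .set_index("period").natural_area
            )
            total = crop + nat
            assert np.allclose(total, total.iloc[0])

    def test_protected_floor_never_violated(self, ccpl_result, ref_result):
        for res in (ccpl_result, ref_result):
            nat = res.natural
            assert (nat.natural_area >= nat.floor - 1e-6).all()

    def test_cumulative_emissions_match_stock_change(self, ccpl_result):
        """Conservation: cumulative LUC emissions equal -44/12 times the
        total terrestrial carbon-stock change."""
        stocks = ccpl_result.stocks.groupby("period").stock_gtc.sum()
        cum = (
            ccpl_result.emissions
            .query("region == @GLOBAL and scope == 'all'")
            .set_index("period").cumulative_gtco2
        )
        expect = -(stocks - stocks.iloc[0]) * 44 / 12
        assert np.allclose(cum, expect, atol=1e-9)

    def test_ccpl_conservation_exceeds_reference(self, ccpl_result, ref_result):
        cons_ccpl = cc.conservation_share(ccpl_result, 2100)
        cons_ref = cc.conservation_share(ref_result, 2100)
        assert cons_ccpl > cons_ref

    def test_us_expands_row_contracts_under_incentive(
        self, ccpl_result, ref_result
    ):
        def area(res, region, period):
            return res.areas.query(
                "region == @region and period == @period"
            ).area.sum()

        assert area(ccpl_result, "US", 2100) > area(ref_result, "US", 2100)
        assert area(ccpl_result, "ROW", 2100) < area(ref_result, "ROW", 2100)
        assert area(ccpl_result, "US", 2100) > area(ccpl_result, "US", 2020)
        assert area(ccpl_result, "ROW", 2100) < area(ccpl_result, "ROW", 2020)

    def test_result_round_trips_through_directory(self, tmp_path, ref_result):
        ref_result.write(tmp_path / "run")
        back = cc.ScenarioResult.read(tmp_path / "run", ref_result.scenario)
        assert np.allclose(
            back.emissions.emissions_gtco2,
            ref_result.emissions.emissions_gtco2,
        )


class TestCompareScenarios:
    def test_self_difference_is_zero(self, ref_result):
        diffs = cc.compare_scenarios(ref_result, ref_result)
        for frame in diffs.values():
            num = frame.select_dtypes("number").drop(columns="period")
            assert np.allclose(num, 0.0)

    def test_antisymmetry(self, ref_result, ccpl_result):
        ab = cc.compare_scenarios(ccpl_result, ref_result)
        ba = cc.compare_scenarios(ref_result, ccpl_result)
        assert np.allclose(
            ab["areas"].area.to_numpy(), -ba["areas"].area.to_numpy()
        )

    def test_cumulative_difference_linearity(self, ref_result, ccpl_result):
        """diff of cumulative emissions equals cumsum of per-period diff."""
        diff = cc.compare_scenarios(ccpl_result, ref_result)["emissions"]
        sel = diff.query("region == 'US' and scope == 'cropland'").sort_values(
            "period"
        )
        assert np.allclose(
            sel.cumulative_gtco2, sel.emissions_gtco2.cumsum(), atol=1e-9
        )

    def test_mismatched_grids_rejected(self, ref_result, ccpl_result):
        clipped = cc.ScenarioResult(
            scenario=ccpl_result.scenario,
            **{
                name: getattr(ccpl_result, name)[
                    getattr(ccpl_result, name).period < 2100
                ]
                for name in cc.ScenarioResult._FRAMES
            },
        )
        with pytest.raises(ValueError, match="grid"):
            cc.compare_scenarios(ref_result, clipped)
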