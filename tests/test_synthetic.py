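"""Synthetic trajectory generator: closed forms, determinism, study
assembly and ground-truth bookkeeping."""

import numpy as np
import pytest

import cropcarbon as cc
from cropcarbon.synthetic import (
    DEFAULT_EFFECTS,
    YEARS,
    TrajectoryParams,
    generate_soc_trajectory,
    generate_yield_trajectory,
)


def params(**kw):
    base = dict(
        yield_base=3.0,
        yield_effect=0.0,
        soc_init=50.0,
        soc_eq_true=90.0,
        year_eq_true=2066,
    )
    base.update(kw)
    return TrajectoryParams(**base)


class TestSOCTrajectory:
    def test_flat_when_init_equals_equilibrium(self):
        s = generate_soc_trajectory(params(soc_init=60.0, soc_eq_true=60.0))
        assert np.allclose(s.to_numpy(), 60.0)

    def test_reaches_99_percent_at_true_equilibrium_year(self):
        # closed form: S(2066) = 50 + 40 * 0.99 = 89.6
        s = generate_soc_trajectory(params())
        assert s.loc[2066] == pytest.approx(89.6, abs=1e-9)
        assert s.loc[2016] == pytest.approx(50.0)

    def test_monotone_saturating_shape(self):
        s = generate_soc_trajectory(params())
        assert (np.diff(s.to_numpy()) > 0).all()
        assert s.to_numpy()[-1] < 90.0

    def test_annual_grid_2016_2100(self):
        s = generate_soc_trajectory(params())
        assert len(s) == 85
        assert s.index[0] == 2016 and s.index[-1] == 2100

    def test_same_seed_is_bit_identical(self):
        a = generate_soc_trajectory(params(noise_sd_soc=1.0, seed=5))
        b = generate_soc_trajectory(params(noise_sd_soc=1.0, seed=5))
        assert (a.to_numpy() == b.to_numpy()).all()
        c = generate_soc_trajectory(params(noise_sd_soc=1.0, seed=6))
        assert not (a.to_numpy() == c.to_numpy()).all()

    def test_noise_converges_to_closed_form(self):
        clean = generate_soc_trajectory(params())
        dev = [
            np.abs(
                generate_soc_trajectory(params(noise_sd_soc=sd, seed=3)) - clean
            ).max()
            for sd in (1.0, 0.1, 0.01)
        ]
        assert dev[0] > dev[1] > dev[2]
        assert dev[2] < 0.05

    def test_year_eq_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            params(year_eq_true=2016)
        with pytest.raises(ValueError):
            params(year_eq_true=2101)


class TestYieldTrajectory:
    def test_constant_at_base_without_effect(self):
        y = generate_yield_trajectory(params())
        assert np.allclose(y.to_numpy(), 3.0)

    @pytest.mark.parametrize("effect", [0.33, -0.05])
    def test_effect_scales_every_year(self, effect):
        y = generate_yield_trajectory(params(yield_effect=effect))
        assert np.allclose(y.to_numpy(), 3.0 * (1 + effect))

    def test_background_trend_applies(self):
        y = generate_yield_trajectory(
            params(), trend=lambda t: 1.0 + 0.001 * (t - 2016)
        )
        assert y.loc[2016] == pytest.approx(3.0)
        assert y.loc[2100] == pytest.approx(3.0 * 1.084)

    def test_nonpositive_base_rejected(self):
        with pytest.raises(ValueError):
            params(yield_base=0.0)


class TestStudy:
    def test_reference_design_has_720_trajectories(self, noiseless_study):
        runs = noiseless_study.truth
        assert len(runs) == 720
        assert noiseless_study.trajectories.groupby(
            ["basin_id", "technology"]
        ).ngroups == 720
        assert len(noiseless_study.trajectories) == 720 * 85

    def test_noiseless_study_matches_closed_forms(self, small_study):
        truth = small_study.truth.set_index("technology")
        for tech in ("wheat_RFD_hi_C_F", "wheat_RFD_hi_N_Lgm"):
            row = truth.loc[tech]
            traj = small_study.trajectory("B01", tech)
            expect_y = generate_yield_trajectory(
                TrajectoryParams(
                    yield_base=row.yield_base,
                    yield_effect=row.yield_effect,
                    soc_init=row.soc_init,
                    soc_eq_true=row.soc_eq_true,
                    year_eq_true=int(row.year_eq_true),
                )
            )
            assert np.allclose(traj["yield"].to_numpy(), expect_y.to_numpy())

    def test_wheat_no_till_legume_anchors(self, small_study):
        """The headline technology carries +33% yield and +80% SOC."""
        truth = small_study.truth.set_index("technology")
        nl = truth.loc["wheat_RFD_hi_N_Lgm"]
        cf = truth.loc["wheat_RFD_hi_C_F"]
        assert nl.yield_effect == pytest.approx(0.33)
        assert nl.soc_eq_true / cf.soc_eq_true == pytest.approx(1.8)

    def test_regeneration_is_bit_identical(self):
        design = [cc.BasinCropSystem("B01", "corn", 10.0)]
        a = cc.generate_study(design=design, seed=11)
        b = cc.generate_study(design=design, seed=11)
        assert a.trajectories.equals(b.trajectories)

    def test_missing_effect_entry_names_class(self):
        effects = {k: v for k, v in DEFAULT_EFFECTS.items()
                   if k != ("corn", "N", "Lgm")}
        with pytest.raises(KeyError, match="corn.*N.*Lgm"):
            cc.generate_study(
                design=[cc.BasinCropSystem("B01", "corn", 10.0)],
                effects=effects,
            )

    def test_qualitative_effect_ordering(self):
        """No-till SOC uplift: corn far above soybean; wheat legume-cover
        yield gain is the largest in the table."""
        corn = DEFAULT_EFFECTS[("corn", "N", "Lgm")].soc_uplift
        soy = DEFAULT_EFFECTS[("soybean", "N", "Lgm")].soc_uplift
        assert corn > 2 * soy
        best = max(DEFAULT_EFFECTS.values(), key=lambda e: e.yield_effect)
        assert best is DEFAULT_EFFECTS[("wheat", "N", "Lgm")]

    def test_baseline_table_defaults(self, noiseless_study):
        base = noiseless_study.baseline
        assert len(base) == 30
        assert (base.years_to_eq_default == 50).all()
        assert (base.soc_max_default > 0).all()

    def test_round_trip_through_csv(self, tmp_path, small_study):
        small_study.write(tmp_path / "study")
        back = cc.StudyData.read(tmp_path / "study")
        assert np.allclose(
            back.trajectories["soc"], small_study.trajectories["soc"]
        )
        assert len(back.truth) == len(small_study.truth)
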