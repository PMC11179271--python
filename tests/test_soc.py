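"""SOC harmonization: cubic smoothing, equilibrium rules, scaling."""

import numpy as np
import pandas as pd
import pytest

import cropcarbon as cc
from cropcarbon.soc import find_equilibrium, smooth_soc
from cropcarbon.synthetic import TrajectoryParams, generate_soc_trajectory

YEARS = pd.RangeIndex(2016, 2101)


def as_series(values):
    return pd.Series(np.asarray(values, dtype=float), index=YEARS)


class TestSmoothing:
    def test_exact_cubic_is_interpolated(self):
        t = YEARS.to_numpy(dtype=float) - 2016
        cubic = 50 + 0.9 * t - 0.012 * t**2 + 0.00004 * t**3
        fit = smooth_soc(as_series(cubic))
        assert np.allclose(fit.fitted.to_numpy(), cubic, atol=1e-6)

    def test_constant_series_fits_constant(self):
        fit = smooth_soc(as_series(np.full(85, 61.5)))
        assert np.allclose(fit.fitted.to_numpy(), 61.5, atol=1e-8)

    def test_beats_linear_fit_on_saturating_input(self):
        s = generate_soc_trajectory(
            TrajectoryParams(yield_base=3, yield_effect=0, soc_init=50,
                             soc_eq_true=90, year_eq_true=2066)
        )
        cubic_resid = np.linalg.norm(s - smooth_soc(s).fitted)
        # independent linear least-squares oracle
        t = s.index.to_numpy(dtype=float)
        lin = np.polynomial.Polynomial.fit(t, s.to_numpy(), 1)
        linear_resid = np.linalg.norm(s.to_numpy() - lin(t))
        assert cubic_resid < linear_resid

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            smooth_soc(pd.Series([1.0, 2.0, 3.0], index=[2016, 2017, 2018]))


class TestEquilibriumRules:
    def test_interior_maximum_found_analytically(self):
        """A quadratic peaking at 2065 lies in the cubic model class, so
        the detected year must match the analytic argmax exactly."""
        t = YEARS.to_numpy(dtype=float)
        s = as_series(90.0 - 0.005 * (t - 2065.0) ** 2)
        eq = find_equilibrium(smooth_soc(s))
        assert eq.year_eq == 2065
        assert eq.years_to_eq == 50
        assert eq.soc_max == pytest.approx(90.0, abs=1e-6)
        assert not eq.declining

    def test_increasing_concave_curve_ends_at_2100(self):
        t = YEARS.to_numpy(dtype=float) - 2016
        s = as_series(50 + 1.0 * t - 0.004 * t**2)  # rising, rate falling
        eq = find_equilibrium(smooth_soc(s))
        assert eq.year_eq == 2100
        assert not eq.declining

    def test_constant_series_ties_to_first_year(self):
        eq = find_equilibrium(smooth_soc(as_series(np.full(85, 70.0))))
        assert eq.year_eq == 2016
        assert eq.years_to_eq == 1

    def test_declining_series_flagged(self):
        t = YEARS.to_numpy(dtype=float) - 2016
        eq = find_equilibrium(smooth_soc(as_series(80.0 - 0.2 * t)))
        assert eq.declining
        assert eq.year_eq == 2016
        assert eq.years_to_eq == 1

    def test_noise_perturbation_vanishes_with_noise(self):
        """With a fixed seed, the detected year converges to the
        noiseless detection as the noise sd shrinks."""
        def detect(sd):
            p = TrajectoryParams(
                yield_base=3, yield_effect=0, soc_init=50, soc_eq_true=90,
                year_eq_true=2070, noise_sd_soc=sd, seed=42,
            )
            return find_equilibrium(smooth_soc(generate_soc_trajectory(p))).year_eq

        clean = detect(0.0)
        assert abs(detect(0.01) - clean) <= 1
        assert abs(detect(0.001) - clean) == 0


class TestScaling:
    def test_identity_factor(self):
        assert cc.compute_scaling_factor(50.0, 50.0) == 1.0

    def test_factor_orientation_recovers_iam_default(self):
        factor = cc.compute_scaling_factor(50.0, 40.0)
        assert factor == pytest.approx(0.8)
        assert 50.0 * factor == pytest.approx(40.0)

    def test_scaling_applies_to_all_technologies(self):
        eqs = {
            "c": cc.SOCEquilibrium(soc_max=50.0, year_eq=2060, years_to_eq=45),
            "n": cc.SOCEquilibrium(soc_max=60.0, year_eq=2070, years_to_eq=55),
        }
        scaled = cc.scale_technologies(eqs, 0.8)
        assert scaled["c"].soc_max_scaled == pytest.approx(40.0)
        assert scaled["n"].soc_max_scaled == pytest.approx(48.0)
        # timing untouched, ordering preserved
        assert scaled["n"].years_to_eq == 55
        assert scaled["n"].soc_max_scaled > scaled["c"].soc_max_scaled

    def test_ratios_invariant_under_scaling(self):
        eqs = {
            "a": cc.SOCEquilibrium(soc_max=45.0, year_eq=2050, years_to_eq=35),
            "b": cc.SOCEquilibrium(soc_max=81.0, year_eq=2070, years_to_eq=55),
        }
        scaled = cc.scale_technologies(eqs, 1.7)
        assert scaled["b"].soc_max_scaled / scaled["a"].soc_max_scaled == (
            pytest.approx(81.0 / 45.0)
        )

    def test_nonpositive_inputs_rejected(self):
        with pytest.raises(ValueError):
            cc.compute_scaling_factor(0.0, 40.0)
        with pytest.raises(ValueError):
            cc.compute_scaling_factor(50.0, -1.0)


class TestHarmonizeStudy:
    def test_conventional_anchor_hits_iam_default(self, small_study):
        table = cc.harmonize_soc(small_study)
        base = small_study.baseline.set_index(["basin_id", "crop"])
        cf = table[table.technology.str.endswith("_C_F")]
        for row in cf.itertuples():
            assert row.soc_max_scaled == pytest.approx(
                base.loc[(row.basin_id, row.crop), "soc_max_default"]
            )

    def test_soc_recovery_within_two_percent(self, small_study):
        table = cc.harmonize_soc(small_study).merge(
            small_study.truth, on=["basin_id", "crop", "technology"]
        )
        rel = (table.soc_max - table.soc_eq_true).abs() / table.soc_eq_true
        assert rel.max() < 0.02

    def test_output_schema(self, small_study):
        table = cc.harmonize_soc(small_study)
        assert set(table.columns) >= {
            "basin_id", "crop", "technology", "soc_max", "year_eq",
            "years_to_eq", "soc_max_scaled", "scaling_factor", "declining",
        }
        assert (table.years_to_eq >= 1).all()
        assert (table.soc_max_scaled > 0).all()
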