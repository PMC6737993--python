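"""Screening, efficiency envelopes, minimum uptake, supply regression
and the calibration/validation split."""

import numpy as np
import pandas as pd
import pytest

from quefts.parameterization import (
    filter_ghi,
    fit_boundary_lines,
    fit_minimum_uptake,
    fit_supply_equation,
    physiological_efficiency,
    screen_outliers,
    split_calibration_validation,
)


def mvn_frame(n=100, p=3, seed=0):
    rng = np.random.default_rng(seed)
    return pd.DataFrame(rng.standard_normal((n, p)), columns=list("abc")[:p])


class TestScreenOutliers:
    def test_identical_records_none_removed(self):
        df = pd.DataFrame({"a": [1.0] * 20, "b": [2.0] * 20})
        kept, removed = screen_outliers(df, variables=["a", "b"])
        assert len(removed) == 0

    def test_planted_ten_sigma_point_removed(self):
        df = mvn_frame(100)
        df.loc[100] = [10.0, 10.0, 10.0]
        kept, removed = screen_outliers(df, alpha=0.05, variables=list("abc"))
        assert 100 in removed.index

    def test_tiny_alpha_removes_nothing(self):
        df = mvn_frame(200, seed=1)
        kept, removed = screen_outliers(df, alpha=1e-12, variables=list("abc"))
        assert len(removed) == 0

    def test_false_removal_near_alpha_on_clean_data(self):
        df = mvn_frame(2000, seed=2)
        kept, removed = screen_outliers(df, alpha=0.05, variables=list("abc"))
        assert len(removed) / len(df) < 0.07

    def test_robust_screen_agrees_on_gross_outlier(self):
        df = mvn_frame(100, seed=3)
        df.loc[100] = [10.0, 10.0, 10.0]
        kept, removed = screen_outliers(df, alpha=0.05, variables=list("abc"), robust=True)
        assert 100 in removed.index


class TestGhiFilter:
    def test_threshold_boundary_kept(self):
        df = pd.DataFrame({"ghi": [0.35, 0.40, 0.45]})
        assert filter_ghi(df)["ghi"].tolist() == [0.40, 0.45]

    def test_identity_when_all_pass(self):
        df = pd.DataFrame({"ghi": [0.41, 0.50]})
        assert len(filter_ghi(df)) == 2

    def test_planted_fraction_removed(self):
        rng = np.random.default_rng(4)
        low = rng.uniform(0.20, 0.399, 40)
        high = rng.uniform(0.40, 0.65, 160)
        df = pd.DataFrame({"ghi": np.concatenate([low, high])})
        assert len(filter_ghi(df)) == 160


class TestPhysiologicalEfficiency:
    def test_all_mass_in_grain(self):
        assert physiological_efficiency(1.0, 15.0, 8.0) == pytest.approx(1000 / 15)

    def test_equal_concentrations_reduce(self):
        assert physiological_efficiency(0.45, 12.0, 12.0) == pytest.approx(
            1000 * 0.45 / 12.0
        )

    def test_worked_example(self):
        assert physiological_efficiency(0.5, 15.0, 8.0) == pytest.approx(
            1000 * 0.5 / 11.5
        )
        assert physiological_efficiency(0.5, 15.0, 8.0) == pytest.approx(43.5, abs=0.05)

    def test_zero_denominator_rejected(self):
        with pytest.raises(ZeroDivisionError):
            physiological_efficiency(0.5, 0.0, 0.0)


def slope_frame(u, y):
    return pd.DataFrame({"uptake_N": u, "grain_yield": y})


class TestBoundaryLines:
    def test_collapsed_envelope(self):
        r = 4.0
        u = np.linspace(10, 100, 50)
        df = slope_frame(u, 40.0 * (u - r))
        a, d = fit_boundary_lines(df, r, "N")
        assert a == pytest.approx(40.0)
        assert d == pytest.approx(40.0)

    def test_uniform_slopes_quantiles(self):
        rng = np.random.default_rng(6)
        s = rng.uniform(30.0, 80.0, 2000)
        u = rng.uniform(20.0, 120.0, 2000)
        df = slope_frame(u, s * (u - 4.0))
        a, d = fit_boundary_lines(df, 4.0, "N")
        assert a == pytest.approx(31.25, abs=0.6)
        assert d == pytest.approx(78.75, abs=0.6)

    def test_order_invariance(self):
        rng = np.random.default_rng(7)
        s = rng.uniform(30.0, 80.0, 500)
        u = rng.uniform(20.0, 120.0, 500)
        df = slope_frame(u, s * (u - 4.0))
        a1, d1 = fit_boundary_lines(df, 4.0, "N")
        shuffled = df.sample(frac=1.0, random_state=1)
        a2, d2 = fit_boundary_lines(shuffled, 4.0, "N")
        assert (a1, d1) == (a2, d2)

    def test_insufficient_data_rejected(self):
        df = slope_frame([10.0, 20.0], [400.0, 900.0])
        with pytest.raises(ValueError, match="usable plots"):
            fit_boundary_lines(df, 4.0, "N")


def control_frame(uptakes, yields):
    return pd.DataFrame({
        "treatment": ["control"] * len(uptakes),
        "uptake_N": uptakes,
        "grain_yield": yields,
    })


class TestMinimumUptake:
    def test_simple_minimum(self):
        df = control_frame([6.1, 9.0, 7.2], [500, 900, 700])
        assert fit_minimum_uptake(df, "N") == pytest.approx(6.1)

    def test_zero_yield_plot_discarded(self):
        df = control_frame([2.0, 4.0, 6.0], [0.0, 400, 800])
        assert fit_minimum_uptake(df, "N") == pytest.approx(4.0)

    def test_planted_minimum_recovered(self):
        rng = np.random.default_rng(8)
        u = np.concatenate([[3.7], rng.uniform(5, 60, 99)])
        df = control_frame(u, np.full(100, 500.0))
        assert fit_minimum_uptake(df, "N") == pytest.approx(3.7)

    def test_no_valid_controls_rejected(self):
        df = control_frame([2.0], [0.0])
        with pytest.raises(ValueError, match="control plots"):
            fit_minimum_uptake(df, "N")


class TestSupplyRegression:
    @staticmethod
    def soils(n, seed=9):
        rng = np.random.default_rng(seed)
        return pd.DataFrame({
            "pH": rng.uniform(4.8, 7.2, n),
            "OC_tot": rng.uniform(2.4, 15.5, n),
            "N_tot": rng.uniform(0.25, 0.98, n),
            "P_av": rng.uniform(0.6, 31.8, n),
            "K_exch": rng.uniform(0.06, 1.35, n),
        }), rng

    def test_planted_linear_model_recovered(self):
        soils, rng = self.soils(300)
        y = 10.0 + 150.0 * soils["N_tot"] + rng.normal(0, 0.5, 300)
        eq = fit_supply_equation(soils, y, "N")
        assert eq.family == "linear"
        assert [t.predictor for t in eq.terms] == ["N_tot"]
        assert eq.intercept == pytest.approx(10.0, rel=0.05)
        assert eq.terms[0].coef == pytest.approx(150.0, rel=0.05)

    def test_pure_noise_favors_intercept_only(self):
        soils, rng = self.soils(200, seed=10)
        y = rng.normal(50.0, 5.0, 200)
        eq = fit_supply_equation(soils, y, "N")
        assert len(eq.terms) == 0
        assert eq.r2 == pytest.approx(0.0, abs=0.05)


class TestSplit:
    @staticmethod
    def plots(n_fields=10):
        return pd.DataFrame({
            "field_id": np.repeat([f"F{i}" for i in range(n_fields)], 6),
            "treatment": np.tile(
                ["control", "minusN", "minusP", "minusK", "NPK", "NPKplus"], n_fields
            ),
        })

    def test_exact_field_count(self):
        cal, val = split_calibration_validation(self.plots(), 0.8, seed=0)
        assert cal["field_id"].nunique() == 8
        assert val["field_id"].nunique() == 2

    def test_deterministic_given_seed(self):
        a1 = split_calibration_validation(self.plots(), 0.8, seed=5)[0]
        a2 = split_calibration_validation(self.plots(), 0.8, seed=5)[0]
        assert a1.equals(a2)
        b = split_calibration_validation(self.plots(50), 0.8, seed=6)[0]
        c = split_calibration_validation(self.plots(50), 0.8, seed=7)[0]
        assert not b.equals(c)

    def test_partitions_disjoint_by_field(self):
        cal, val = split_calibration_validation(self.plots(25), 0.8, seed=1)
        assert not set(cal["field_id"]) & set(val["field_id"])
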