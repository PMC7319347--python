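"""Crossover, regions of significance, PoI, PA, simple slopes and verdicts."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from scipy import stats

from dsgxe.config import SimulationConfig
from dsgxe.diffsusc import (
    crossover_point,
    ros_bounds,
    moderator_effect_t,
    poi,
    pa,
    simple_slopes_split,
    classify_ds,
    ds_report,
    DSIndices,
    RoSResult,
)
from dsgxe.moderation import ModelSpec, synthetic_interaction_fit, fit_model, quadratic_robustness
from dsgxe.simulate import simulate_analysis_frame
from .conftest import random_interaction_fit

SPEC = ModelSpec(outcome="y")


def grid_scan_roots(fit, alpha=0.05, lo=-6.0, hi=6.0, step=1e-4):
    """Brute-force region bounds: sign changes of |t| - t_crit on a fine grid."""
    x = np.arange(lo, hi, step)
    t_crit = stats.t.ppf(1 - alpha / 2, fit.df_resid)
    f = np.abs(moderator_effect_t(fit, x)) - t_crit
    sign_change = np.where(np.diff(np.sign(f)) != 0)[0]
    return [0.5 * (x[i] + x[i + 1]) for i in sign_change]


class TestCrossover:
    def test_zero_main_effect(self):
        fit = synthetic_interaction_fit(0.0, 0.5, 0.01, 0.0, 0.01, 65)
        assert crossover_point(fit) == 0.0

    def test_arithmetic(self):
        fit = synthetic_interaction_fit(0.4, 0.4, 0.01, 0.0, 0.01, 65)
        assert crossover_point(fit) == pytest.approx(-1.0)

    def test_lines_intersect_at_crossover(self):
        fit = synthetic_interaction_fit(0.3, -0.6, 0.01, 0.0, 0.01, 65, b0=1.0, b2=0.2)
        xc = crossover_point(fit)
        b = fit.params
        for z in (-1.5, 0.0, 2.0):
            y = b["const"] + b["pred_expr"] * z + b["ses_composite"] * xc \
                + b["pred_expr:ses_composite"] * z * xc
            y0 = b["const"] + b["ses_composite"] * xc
            assert y == pytest.approx(y0, abs=1e-10)

    def test_degenerate_interaction_errors(self):
        fit = synthetic_interaction_fit(0.4, 0.0, 0.01, 0.0, 0.01, 65)
        with pytest.raises(ValueError):
            crossover_point(fit)


class TestRoS:
    def test_symmetric_hand_case(self):
        # (b1 + X)^2 = 4 (0.04 + 0.04 X^2)  =>  0.84 X^2 = 0.16
        df = 65
        alpha = 2 * stats.t.sf(2.0, df)  # t_crit exactly 2
        fit = synthetic_interaction_fit(0.0, 1.0, 0.04, 0.0, 0.04, df)
        ros = ros_bounds(fit, alpha=alpha)
        root = np.sqrt(0.16 / 0.84)
        assert ros.lower == pytest.approx(-root, abs=1e-10)
        assert ros.upper == pytest.approx(root, abs=1e-10)
        assert ros.significant_outside is True

    def test_degenerate_no_x_dependence(self):
        fit = synthetic_interaction_fit(5.0, 0.0, 1e-4, 0.0, 0.0, 65)
        ros = ros_bounds(fit)
        assert ros.status == "degenerate_no_interaction"

    def test_no_real_roots_reports_which_side(self):
        # weak effect, large variance: the t statistic never reaches t_crit
        fit = synthetic_interaction_fit(0.1, 0.05, 1.0, 0.0, 1.0, 65)
        ros = ros_bounds(fit)
        assert ros.status == "no_real_roots"
        assert "nowhere" in ros.note

    def test_matches_grid_scan(self, rng):
        checked = 0
        for _ in range(30):
            fit = random_interaction_fit(rng)
            ros = ros_bounds(fit)
            roots = [r for r in grid_scan_roots(fit) if -6 < r < 6]
            if ros.status == "two_real_roots":
                expected = [b for b in (ros.lower, ros.upper) if -6 < b < 6]
                assert len(roots) == len(expected)
                for a, b in zip(sorted(roots), sorted(expected)):
                    assert a == pytest.approx(b, abs=1e-3)
                checked += 1
            else:
                assert roots == []
        assert checked > 5


class TestPoI:
    def test_center_crossover_half(self):
        fit = synthetic_interaction_fit(0.0, 0.5, 0.01, 0.0, 0.01, 65)
        assert poi(fit, x_mean=0.0, x_sd=1.0) == 0.5

    def test_offset_crossover_tenth(self):
        # crossover at +1 in window [-2, 2]: areas 1^2 vs 3^2
        fit = synthetic_interaction_fit(-0.5, 0.5, 0.01, 0.0, 0.01, 65)
        assert poi(fit, 0.0, 1.0) == pytest.approx(1 / 10)

    def test_edge_crossover_clamps(self):
        fit = synthetic_interaction_fit(1.0, 0.5, 0.01, 0.0, 0.01, 65)  # xc = -2
        assert poi(fit, 0.0, 1.0) == 1.0
        fit = synthetic_interaction_fit(-2.0, 0.5, 0.01, 0.0, 0.01, 65)  # xc = +4
        assert poi(fit, 0.0, 1.0) == 0.0

    def test_matches_trapezoid_integration(self, rng):
        for _ in range(30):
            fit = random_interaction_fit(rng)
            xm, xs = rng.normal(0, 0.5), rng.uniform(0.5, 2.0)
            closed = poi(fit, xm, xs)
            assert closed == pytest.approx(
                trapezoid_poi(fit, xm, xs), abs=1e-6
            )

    def test_mirror_symmetry(self, rng):
        # negating the moderator main effect mirrors the crossover about the
        # window center, so PoI reflects to its complement
        for _ in range(20):
            b1, b3 = rng.normal(0, 0.5), rng.uniform(0.2, 1.0)
            fit = synthetic_interaction_fit(b1, b3, 0.01, 0.0, 0.01, 65)
            mirror = synthetic_interaction_fit(-b1, b3, 0.01, 0.0, 0.01, 65)
            assert poi(mirror, 0.0, 1.0) == pytest.approx(
                1 - poi(fit, 0.0, 1.0), abs=1e-12
            )


def trapezoid_poi(fit, x_mean, x_sd):
    """Numeric PoI: integrate |line difference| on each side of the crossover."""
    b1 = fit.term("pred_expr")
    b3 = fit.term("pred_expr:ses_composite")
    lo, hi = x_mean - 2 * x_sd, x_mean + 2 * x_sd
    xc = min(max(-b1 / b3, lo), hi)

    def area(a, b):
        if b <= a:
            return 0.0
        x = np.linspace(a, b, 20001)
        return np.trapezoid(np.abs(b1 + b3 * x), x)

    right, left = area(xc, hi), area(lo, xc)
    return right / (right + left)


class TestPA:
    def test_counting(self):
        assert pa([-2, -1, 0, 1, 2], 0.5) == pytest.approx(0.4)

    def test_crossover_below_min(self):
        assert pa([1.0, 2.0], 0.0) == 1.0

    def test_ties_count_below(self):
        assert pa([0.0, 0.0, 1.0, 2.0], 0.0) == pytest.approx(0.5)

    def test_normal_symmetry(self, rng):
        x = rng.standard_normal(20000)
        assert pa(x, 0.0) == pytest.approx(0.5, abs=0.02)

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            pa([], 0.0)

    @given(st.lists(st.floats(-5, 5), min_size=1, max_size=50), st.floats(-5, 5))
    def test_negation_complement(self, xs, c):
        x = np.array(xs)
        if np.any(x == c):  # ties break the strict complement; tested above
            return
        assert pa(x, c) == pytest.approx(1 - pa(-x, -c), abs=1e-12)

    def test_permutation_invariance(self, rng):
        x = rng.standard_normal(100)
        assert pa(x, 0.3) == pa(np.sort(x), 0.3)


class TestSimpleSlopes:
    def _data(self, rng, slope_low, slope_high, noise=0.0, n=120):
        z = np.concatenate([np.zeros(n // 2), np.ones(n // 2)])
        x = rng.standard_normal(n)
        cov = {c: rng.standard_normal(n) for c in ("age", "bmi_z", "pc1", "pc2")}
        sex = rng.integers(0, 2, n).astype(float)
        y = np.where(z == 0, slope_low * x, slope_high * x) + noise * rng.standard_normal(n)
        return pd.DataFrame({"pred_expr": z, "ses_composite": x, "sex": sex, "y": y, **cov})

    def test_noiseless_recovery(self, rng):
        data = self._data(rng, -100.0, 50.0)
        low, high = simple_slopes_split(data, SPEC)
        assert low.slope == pytest.approx(-100.0, abs=1e-8)
        assert high.slope == pytest.approx(50.0, abs=1e-8)

    def test_equal_slopes_when_groups_identical(self, rng):
        data = self._data(rng, 30.0, 30.0, noise=0.0)
        low, high = simple_slopes_split(data, SPEC)
        assert low.slope == pytest.approx(high.slope, abs=1e-8)

    def test_ds_scenario_group_slopes_recovered(self):
        """Mean-split slopes track the model-implied values b2 + b3*E[Z|group]:
        the low-moderator group slope is negative and reliably detected in
        differential-susceptibility cohorts."""
        hits_low, low_slopes, high_slopes = 0, [], []
        reps = 60
        for s in range(reps):
            frame = simulate_analysis_frame(
                SimulationConfig(n_subjects=500, seed=900 + s)
            )
            low, high = simple_slopes_split(frame, SPEC)
            hits_low += low.p < 0.05 and low.slope < 0
            low_slopes.append(low.slope)
            high_slopes.append(high.slope)
        z_half = np.sqrt(2 / np.pi)  # E[Z | Z > 0] for standard-normal Z
        assert hits_low / reps >= 0.8
        assert np.mean(low_slopes) == pytest.approx(0.125 - 0.4 * z_half, abs=0.05)
        assert np.mean(high_slopes) == pytest.approx(0.125 + 0.4 * z_half, abs=0.05)

    def test_tiny_group_errors(self, rng):
        data = self._data(rng, 1.0, 2.0, n=120)
        data.loc[:, "pred_expr"] = 0.0
        data.loc[0, "pred_expr"] = 1.0  # high group of size 1
        with pytest.raises(ValueError):
            simple_slopes_split(data, SPEC)


class TestClassify:
    @pytest.mark.parametrize(
        "bounds,poi_v,pa_v,expected",
        [
            ((-1.696, 0.736), 0.59, 0.563, "prototypical_differential_susceptibility"),
            ((-2.690, 4.113), 0.43, 0.439, "not_supported"),
            ((-1.024, 0.397), 0.60, 0.578, "prototypical_differential_susceptibility"),
        ],
    )
    def test_reported_index_triples(self, bounds, poi_v, pa_v, expected):
        ros = RoSResult(lower=bounds[0], upper=bounds[1], t_crit=2.0, df=65,
                        status="two_real_roots", significant_outside=True)
        idx = DSIndices(crossover_x=0.0, poi=poi_v, pa=pa_v, x_mean=0.0, x_sd=1.0)
        verdict = classify_ds(ros, idx, nonlinear_flag=False, x_mean=0.0, x_sd=1.0)
        assert verdict.verdict == expected

    def test_nonlinearity_excludes(self):
        ros = RoSResult(lower=-1.0, upper=0.5, t_crit=2.0, df=65,
                        status="two_real_roots", significant_outside=True)
        idx = DSIndices(0.0, 0.5, 0.5, 0.0, 1.0)
        verdict = classify_ds(ros, idx, nonlinear_flag=True, x_mean=0.0, x_sd=1.0)
        assert verdict.verdict == "excluded_nonlinear"
        assert verdict.nonlinear_excluded


class TestDSReport:
    def test_report_is_json_serializable_and_complete(self):
        import json

        frame = simulate_analysis_frame(SimulationConfig(n_subjects=400, seed=5))
        fit = fit_model(frame, SPEC)
        quad = quadratic_robustness(frame, SPEC)
        report = ds_report(frame, SPEC, fit, quad.nonlinear_flag)
        text = json.dumps(report)
        assert "verdict" in report and "ros" in report and "simple_slopes" in report
        assert "poi_band" in report["conventions"]
        assert isinstance(text, str)
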