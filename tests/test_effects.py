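"""Effect curves, square-root retransformation, effect sizes, reporting."""

import numpy as np
import pandas as pd
import pytest

from mrtmod import (
    DesignConfig,
    EffectCurve,
    WCLSFit,
    build_design_matrix,
    effect_curve,
    exploratory_curves,
    fit_wcls,
    render_report,
    retransform_sqrt,
    simulate_trial,
    standardized_effect,
    weekly_panel,
)
from mrtmod.aggregate import default_controls
from mrtmod.design import default_truths
from mrtmod.effects import _curve_from_coefs
from mrtmod.errors import UsageError

UNIFORM = {"none": 0.25, "activity": 0.25, "sleep": 0.25, "mood": 0.25}


def _fit_with(b_by_name, columns=None):
    """Construct a fit object with chosen coefficients (identity cov)."""
    columns = columns or list(b_by_name)
    params = np.array([b_by_name.get(c, 0.0) for c in columns])
    return WCLSFit(
        params=params,
        cov=np.eye(len(columns)) * 1e-4,
        columns=columns,
        n_clusters=100,
        n_obs=1000,
        arm_probs=UNIFORM,
    )


class TestEffectCurve:
    def test_mood_line_reproduces_reported_endpoints(self):
        # slope -0.052 through an effect of +0.19 at previous mood 3
        # gives -0.12 (two decimals) at previous mood 9
        b1 = -0.052
        b0 = 0.19 - b1 * 3.0
        fit = _fit_with({"trt_any": b0, "trt_any:moderator": b1})
        curve = effect_curve(fit, "any", [3.0, 9.0])
        assert curve.delta[0] == pytest.approx(0.19)
        assert round(curve.delta[1], 2) == -0.12

    def test_slope_between_reported_endpoints(self):
        # the line through (3, 0.19) and (9, -0.12) has slope -0.052 to 3 dp
        slope = (-0.12 - 0.19) / (9.0 - 3.0)
        assert round(slope, 3) == -0.052

    def test_zero_slope_gives_constant_curve(self):
        fit = _fit_with({"trt_any": 0.33, "trt_any:moderator": 0.0})
        curve = effect_curve(fit, "any", np.linspace(0, 10, 11))
        assert np.allclose(curve.delta, 0.33)
        assert curve.crossing is None

    def test_crossing_point_solves_delta_zero(self):
        fit = _fit_with({"trt_any": 0.345, "trt_any:moderator": -0.052})
        curve = effect_curve(fit, "any", [3.0])
        m_star = curve.crossing
        assert 0.345 - 0.052 * m_star == pytest.approx(0.0, abs=1e-12)

    def test_sqrt_crossing_on_natural_scale(self):
        c = _curve_from_coefs(4.017, -0.039, [5625.0], "sqrt", "activity")
        m_star = c.crossing
        assert 4.017 - 0.039 * np.sqrt(m_star) == pytest.approx(0.0, abs=1e-12)
        # natural effect changes sign exactly there
        lo = _curve_from_coefs(4.017, -0.039, [m_star * 0.99], "sqrt", "a")
        hi = _curve_from_coefs(4.017, -0.039, [m_star * 1.01], "sqrt", "a")
        assert lo.natural[0] > 0 > hi.natural[0]

    def test_grid_outside_plausible_range_warns(self):
        fit = _fit_with({"trt_any": 0.3, "trt_any:moderator": -0.05})
        with pytest.warns(UserWarning):
            effect_curve(fit, "any", [0.0, 15.0], plausible_range=(1.0, 10.0))


class TestRetransform:
    def test_zero_delta_zero_effect(self):
        m = np.array([0.0, 100.0, 5625.0])
        assert np.allclose(retransform_sqrt(0.0, m), 0.0)

    def test_steps_calibrated_example(self):
        # b1 = -0.039 with the intercept set so the natural effect is
        # +165 steps at previous steps 5625; at 12100 it is -60 steps
        b1 = -0.039
        delta_at_75 = np.sqrt(5625.0 + 165.0) - np.sqrt(5625.0)
        b0 = delta_at_75 - b1 * np.sqrt(5625.0)
        c = _curve_from_coefs(b0, b1, [5625.0, 12100.0], "sqrt", "activity")
        assert round(c.natural[0]) == 165
        assert round(c.natural[1]) == -60

    def test_sleep_calibrated_example(self):
        # b1 = -0.075 anchored at +8 min for 300 min; -5 min at 480 min
        b1 = -0.075
        delta_at_300 = np.sqrt(300.0 + 8.0) - np.sqrt(300.0)
        b0 = delta_at_300 - b1 * np.sqrt(300.0)
        c = _curve_from_coefs(b0, b1, [300.0, 480.0], "sqrt", "sleep")
        assert round(c.natural[0]) == 8
        assert round(c.natural[1]) == -5

    def test_inverse_consistency(self):
        rng = np.random.default_rng(8)
        m = rng.uniform(1.0, 20000.0, size=200)
        e = rng.uniform(-0.5, 0.5, size=200) * m
        delta = np.sqrt(m + e) - np.sqrt(m)
        back = retransform_sqrt(delta, m)
        np.testing.assert_allclose(back, e, atol=1e-9 * max(1.0, np.abs(e).max()))

    def test_negative_moderator_rejected(self):
        with pytest.raises(UsageError):
            retransform_sqrt(0.1, [-1.0])


class TestStandardizedEffect:
    @pytest.mark.parametrize(
        "effect, sd, expected",
        [
            (165.0, 3285.0, 0.05),
            (-60.0, 3285.0, -0.02),
            (8.0, 75.0, 0.11),
            (-5.0, 75.0, -0.07),
            (0.0, 1.43, 0.0),
        ],
    )
    def test_reported_ratios(self, effect, sd, expected):
        assert round(standardized_effect(effect, sd), 2) == expected

    def test_nonpositive_sd_rejected(self):
        with pytest.raises(UsageError):
            standardized_effect(1.0, 0.0)


class TestExploratoryCurves:
    def test_shared_truth_curves_coincide(self):
        # identical b0k/b1k across categories: curves agree within CI widths
        truth = default_truths()["mood"].with_(
            b0=(0.345, 0.345, 0.345), b1=(-0.052, -0.052, -0.052),
            clip_range=None, integer_scale=False,
        )
        others = default_truths()
        cfg = DesignConfig(n_participants=400, n_weeks=26, seed=61)
        daily = simulate_trial(
            cfg,
            {"mood": truth, "steps": others["steps"],
             "sleep_minutes": others["sleep_minutes"]},
            missingness={},
        )
        panel = weekly_panel(daily, "mood", "none")
        dm = build_design_matrix(panel, UNIFORM, controls=default_controls("mood"))
        fit = fit_wcls(dm)
        grid = np.linspace(4.0, 9.0, 6)
        curves = exploratory_curves(fit, grid)
        cats = ["activity", "sleep", "mood"]
        for a in cats:
            for b in cats:
                half = 1.96 * np.sqrt(curves[a].se**2 + curves[b].se**2)
                assert np.all(np.abs(curves[a].delta - curves[b].delta) <= half)

    def test_pooled_line_in_convex_hull(self):
        fit = _fit_with(
            {
                "trt_activity": 0.31, "trt_activity:moderator": -0.050,
                "trt_sleep": 0.39, "trt_sleep:moderator": -0.053,
                "trt_mood": 0.345, "trt_mood:moderator": -0.052,
            }
        )
        grid = np.linspace(1.0, 10.0, 10)
        curves = exploratory_curves(fit, grid)
        lo = np.min([curves[k].delta for k in ("activity", "sleep", "mood")], axis=0)
        hi = np.max([curves[k].delta for k in ("activity", "sleep", "mood")], axis=0)
        assert np.all(curves["pooled"].delta >= lo - 1e-12)
        assert np.all(curves["pooled"].delta <= hi + 1e-12)

    def test_flat_category_stays_flat(self):
        fit = _fit_with(
            {
                "trt_activity": 0.2, "trt_activity:moderator": 0.0,
                "trt_sleep": 0.1, "trt_sleep:moderator": -0.05,
                "trt_mood": 0.0, "trt_mood:moderator": -0.02,
            }
        )
        curves = exploratory_curves(fit, np.linspace(1, 9, 9))
        assert np.allclose(curves["activity"].delta, 0.2)


class TestRenderReport:
    def test_table_shape_and_determinism(self, tmp_path, small_daily):
        panel = weekly_panel(small_daily, "mood", "none")
        dm = build_design_matrix(panel, UNIFORM, controls=default_controls("mood"))
        fit = fit_wcls(dm)
        grid = np.linspace(3, 9, 7)
        curves = exploratory_curves(fit, grid)
        p1, p2 = tmp_path / "a.csv", tmp_path / "b.csv"
        t1 = render_report(curves, panel, p1, figure_path=tmp_path / "fig.png")
        t2 = render_report(curves, panel, p2)
        assert len(t1) == len(curves) * len(grid)
        assert p1.read_bytes() == p2.read_bytes()
        assert (tmp_path / "fig.png").stat().st_size > 0

    def test_histogram_counts_sum_to_observed_weeks(self, small_daily):
        panel = weekly_panel(small_daily, "mood", "none")
        mod = panel["moderator"].dropna().to_numpy()
        counts, _ = np.histogram(mod, bins=30)
        assert counts.sum() == panel["moderator"].notna().sum()

    def test_empty_panel_rejected(self, tmp_path):
        fit = _fit_with({"trt_any": 0.1, "trt_any:moderator": 0.0})
        curve = effect_curve(fit, "any", [1.0, 2.0])
        with pytest.raises(UsageError):
            render_report(curve, pd.DataFrame(), tmp_path / "t.csv")
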