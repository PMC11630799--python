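"""Survival-model unit and property tests."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from radhab.dose import DoseScenario, ParticleMix, ParticleWeights
from radhab.errors import NonInactivatingCurveError, ValidationError
from radhab.survival import (
    PUBLISHED_THRESHOLDS,
    InactivationThreshold,
    SurvivalCurve,
    dose_to_fraction,
    fit_loglinear,
    format_years,
    read_survival_curves,
    survival_table,
    threshold_from_curve,
    time_to_inactivation,
)

W = ParticleWeights()
GAMMA = ParticleMix(gamma=1.0)
ALPHA = ParticleMix(alpha=1.0, gamma=0.0)
MIXED = ParticleMix(alpha=0.5, gamma=0.5)


class TestCurveValidation:
    def test_needs_two_points(self):
        with pytest.raises(ValidationError, match=">= 2 points"):
            SurvivalCurve("x", [(0, 1)])

    def test_doses_strictly_increasing(self):
        with pytest.raises(ValidationError, match="strictly increasing"):
            SurvivalCurve("x", [(0, 1), (0, 0.5)])

    def test_fraction_bounds(self):
        with pytest.raises(ValidationError, match="surviving fraction"):
            SurvivalCurve("x", [(0, 1), (100, 1.5)])
        with pytest.raises(ValidationError, match="surviving fraction"):
            SurvivalCurve("x", [(0, 1), (100, 0.0)])


class TestFitLogLinear:
    def test_one_decade_drop(self):
        fit = fit_loglinear(SurvivalCurve("x", [(0, 1), (2500, 0.1)]))
        assert fit.d10 == pytest.approx(2500, rel=1e-12)
        assert fit.intercept == 0.0

    def test_exact_two_decade_curve(self):
        curve = SurvivalCurve("x", [(0, 1), (1000, 1e-2), (2000, 1e-4)])
        fit = fit_loglinear(curve)
        assert fit.d10 == pytest.approx(500, rel=1e-12)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_free_intercept_without_control_point(self):
        # log-linear data not passing through (0, 1): slope still -1/500
        curve = SurvivalCurve("x", [(1000, 1e-2), (2000, 1e-4)])
        fit = fit_loglinear(curve)
        assert fit.d10 == pytest.approx(500, rel=1e-12)
        assert fit.intercept == pytest.approx(0.0, abs=1e-9)

    def test_non_inactivating_curve_rejected(self):
        with pytest.raises(NonInactivatingCurveError):
            fit_loglinear(SurvivalCurve("x", [(0, 0.5), (100, 0.5), (200, 0.9)]))

    def test_flat_curve_at_one_rejected(self):
        with pytest.raises(NonInactivatingCurveError, match="fraction < 1"):
            fit_loglinear(SurvivalCurve("x", [(0, 1.0), (100, 1.0)]))

    @given(d10=st.floats(10, 1e5, allow_nan=False))
    @settings(max_examples=50, derandomize=True)
    def test_noiseless_recovery_is_identity(self, d10):
        doses = np.linspace(0, 6 * d10, 7)
        points = [(float(d), 10.0 ** (-d / d10)) for d in doses]
        points[0] = (0.0, 1.0)
        fit = fit_loglinear(SurvivalCurve("x", points))
        assert fit.d10 == pytest.approx(d10, rel=1e-9)


class TestDoseToFraction:
    @pytest.mark.parametrize(
        "d10,target,expected",
        [
            (2500, 1e-6, 15_000),  # radio-resistant reference organism
            (1400, 1e-6, 8_400),  # radio-tolerant reference organism
            (1000, 1.0, 0.0),
        ],
    )
    def test_threshold_doses(self, d10, target, expected):
        assert dose_to_fraction(d10, target) == pytest.approx(expected, rel=1e-9)

    @pytest.mark.parametrize("k", [1, 2, 3, 6, 9])
    def test_integer_decades_exact(self, k):
        assert dose_to_fraction(1234.0, 10.0 ** (-k)) == pytest.approx(
            k * 1234.0, rel=1e-12
        )

    def test_invalid_fraction(self):
        with pytest.raises(ValidationError):
            dose_to_fraction(1000, 0.0)
        with pytest.raises(ValidationError):
            dose_to_fraction(1000, 1.1)
        with pytest.raises(ValidationError):
            dose_to_fraction(-5, 0.5)

    def test_threshold_from_curve_matches_six_d10(self):
        curve = SurvivalCurve("x", [(0, 1), (2500, 0.1)])
        t = threshold_from_curve(curve)
        assert t.threshold_dose_gy == pytest.approx(15_000, rel=1e-9)
        assert t.source == "fitted"


class TestTimeToInactivation:
    def test_gamma_low_dose_bounds(self):
        low = DoseScenario("low", 0.02, GAMMA)
        radiodurans = PUBLISHED_THRESHOLDS[2]
        ecoli = PUBLISHED_THRESHOLDS[0]
        assert time_to_inactivation(
            radiodurans, low, W
        ).time_to_inactivation_yr == pytest.approx(750_000, rel=1e-9)
        assert time_to_inactivation(
            ecoli, low, W
        ).time_to_inactivation_yr == pytest.approx(50_000, rel=1e-9)

    def test_zero_rate_never_sentinel(self):
        res = time_to_inactivation(
            PUBLISHED_THRESHOLDS[2], DoseScenario("none", 0.0, GAMMA), W
        )
        assert res.never
        assert math.isinf(res.time_to_inactivation_yr)
        assert res.assumes_dormant_cells

    def test_mixed_high_dose(self):
        res = time_to_inactivation(
            PUBLISHED_THRESHOLDS[2], DoseScenario("high", 0.3, MIXED), W
        )
        assert res.time_to_inactivation_yr == pytest.approx(15_000 / 3.15, rel=1e-12)

    @given(k=st.floats(1e-3, 1e3, allow_nan=False))
    @settings(max_examples=50, derandomize=True)
    def test_inverse_proportional_to_dose_rate(self, k):
        t1 = time_to_inactivation(
            PUBLISHED_THRESHOLDS[1], DoseScenario("a", 0.1, GAMMA), W
        ).time_to_inactivation_yr
        tk = time_to_inactivation(
            PUBLISHED_THRESHOLDS[1], DoseScenario("b", 0.1 * k, GAMMA), W
        ).time_to_inactivation_yr
        assert tk == pytest.approx(t1 / k, rel=1e-12)

    def test_strictly_increasing_in_threshold(self):
        s = DoseScenario("s", 0.3, ALPHA)
        times = [
            time_to_inactivation(t, s, W).time_to_inactivation_yr
            for t in PUBLISHED_THRESHOLDS
        ]
        assert times[0] < times[1] < times[2]

    def test_mixed_time_strictly_between_pure_times(self):
        t = PUBLISHED_THRESHOLDS[2]
        t_alpha = time_to_inactivation(t, DoseScenario("a", 0.3, ALPHA), W)
        t_mixed = time_to_inactivation(t, DoseScenario("m", 0.3, MIXED), W)
        t_gamma = time_to_inactivation(t, DoseScenario("g", 0.3, GAMMA), W)
        assert (
            t_alpha.time_to_inactivation_yr
            < t_mixed.time_to_inactivation_yr
            < t_gamma.time_to_inactivation_yr
        )


class TestSurvivalTable:
    def test_full_grid_low_exceeds_high_by_rate_ratio(self):
        scenarios = [
            DoseScenario("low_gamma", 0.02, GAMMA),
            DoseScenario("high_gamma", 0.3, GAMMA),
            DoseScenario("low_alpha", 0.02, ALPHA),
            DoseScenario("high_alpha", 0.3, ALPHA),
            DoseScenario("low_mixed", 0.02, MIXED),
            DoseScenario("high_mixed", 0.3, MIXED),
        ]
        table = survival_table(PUBLISHED_THRESHOLDS, scenarios, W)
        assert len(table) == 18
        t = table.set_index(["scenario", "organism"])["years"]
        for org in ("E. coli", "B. subtilis", "D. radiodurans"):
            ratio = t[("low_gamma", org)] / t[("high_gamma", org)]
            assert ratio == pytest.approx(15.0, rel=1e-12)

    def test_degenerate_single_cell_table(self):
        s = DoseScenario("s", 0.3, GAMMA)
        table = survival_table([PUBLISHED_THRESHOLDS[0]], [s], W)
        expected = time_to_inactivation(PUBLISHED_THRESHOLDS[0], s, W)
        assert len(table) == 1
        assert table["years"].iloc[0] == expected.time_to_inactivation_yr

    def test_radioresistance_ordering_within_each_scenario(self):
        table = survival_table(
            PUBLISHED_THRESHOLDS, [DoseScenario("s", 0.3, MIXED)], W
        ).set_index("organism")["years"]
        assert table["E. coli"] < table["B. subtilis"] < table["D. radiodurans"]

    def test_duplicate_labels_rejected(self):
        s = DoseScenario("s", 0.3, GAMMA)
        dup = [PUBLISHED_THRESHOLDS[0], PUBLISHED_THRESHOLDS[0]]
        with pytest.raises(ValidationError, match="duplicate organism"):
            survival_table(dup, [s], W)
        with pytest.raises(ValidationError, match="duplicate scenario"):
            survival_table(PUBLISHED_THRESHOLDS, [s, s], W)

    def test_empty_inputs_rejected(self):
        with pytest.raises(ValidationError, match="non-empty"):
            survival_table([], [DoseScenario("s", 0.3, GAMMA)], W)


class TestIOAndFormatting:
    def test_format_years_two_significant_figures(self):
        assert format_years(4761.9) == "4 800"
        assert format_years(750_000.0) == "750 000"
        assert format_years(math.inf) == "never"

    def test_read_survival_curves(self, tmp_path):
        path = tmp_path / "curves.tsv"
        path.write_text(
            "organism\tdose_gy\tsurviving_fraction\n"
            "x\t0\t1.0\nx\t2500\t0.1\n"
            "y\t0\t1.0\ny\t500\t0.01\n"
        )
        curves = {c.organism: c for c in read_survival_curves(path)}
        assert fit_loglinear(curves["x"]).d10 == pytest.approx(2500)
        assert fit_loglinear(curves["y"]).d10 == pytest.approx(250)

    def test_invalid_threshold(self):
        with pytest.raises(ValidationError):
            InactivationThreshold("x", -5.0)
        with pytest.raises(ValidationError, match="source"):
            InactivationThreshold("x", 100.0, source="guessed")
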