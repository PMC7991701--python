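"""Protocol readouts: grid detectors and clinical decision rules."""

import pandas as pd
import pytest

from carotidsim.experiment import (
    StenosisCategory,
    classify_ica_stenosis,
    detect_inversion,
    detect_onset,
    detect_zero,
    shunt_decision,
)

GRID = [round(0.1 * i, 1) for i in range(11)]


def series(values):
    return pd.Series(values, index=GRID[: len(values)])


class TestDetectOnset:
    def test_constant_series_never_triggers(self):
        assert detect_onset(series([100.0] * 11), "flow_decrease") is None

    def test_flow_decrease_uses_relative_threshold(self):
        # 2% of baseline 100 -> first excursion beyond 2.0 units
        vals = [100, 100, 100, 99.5, 97.5, 95, 80, 50, 20, 5, 0]
        assert detect_onset(series(vals), "flow_decrease") == 0.4

    def test_flow_increase_direction(self):
        vals = [50, 50, 50, 50, 50.5, 52, 60, 80, 95, 100, 102]
        assert detect_onset(series(vals), "flow_increase") == 0.5

    def test_pressure_decline_uses_absolute_threshold(self):
        vals = [80, 80, 79.8, 79.5, 79.2, 79.1, 78.9, 70, 60, 50, 45]
        assert detect_onset(series(vals), "pressure_decline") == 0.6

    def test_missing_baseline_is_an_error(self):
        s = pd.Series([1.0, 2.0], index=[0.1, 0.2])
        with pytest.raises(ValueError, match="baseline"):
            detect_onset(s, "flow_decrease")

    def test_unknown_kind_rejected(self):
        with pytest.raises(ValueError, match="kind"):
            detect_onset(series([1.0] * 11), "sideways")


class TestDetectZero:
    def test_vanishing_flow_found_on_grid(self):
        vals = [160, 160, 159, 158, 152, 130, 90, 40, 10, 1.2, 0.3]
        assert detect_zero(series(vals)) == 0.9

    def test_strictly_positive_series_gives_none(self):
        assert detect_zero(series([10.0] * 11)) is None

    def test_zero_crossing_between_grid_points_reports_first_past(self):
        vals = [100, 80, 60, 40, 20, 0.5, -15, -30, -40, -45, -50]
        assert detect_zero(series(vals)) == 0.5

    def test_zero_baseline_is_an_error(self):
        with pytest.raises(ValueError, match="baseline"):
            detect_zero(series([0.0] * 11))


class TestDetectInversion:
    def test_sign_flip_found(self):
        vals = [70, 69, 68, 66, 60, 45, 20, 5, -10, -25, -30]
        assert detect_inversion(series(vals)) == 0.8

    def test_all_same_sign_gives_none(self):
        assert detect_inversion(series([3.0] * 11)) is None

    def test_convention_flip_gives_same_ratio(self):
        vals = [70, 69, 68, 66, 60, 45, 20, 5, -10, -25, -30]
        s = series(vals)
        assert detect_inversion(s) == detect_inversion(-s)

    def test_numerically_zero_baseline_is_an_error(self):
        with pytest.raises(ValueError, match="direction"):
            detect_inversion(series([1e-9] + [1.0] * 10))


class TestClinicalRules:
    @pytest.mark.parametrize(
        "psv, ratio, flow, expected",
        [
            (300.0, 4.5, True, StenosisCategory.SEVERE),
            (100.0, 1.2, True, StenosisCategory.NO_STENOSIS),
            (0.0, 0.0, False, StenosisCategory.OCCLUSION),
            (130.0, 1.5, True, StenosisCategory.MODERATE),
            (124.9, 3.9, True, StenosisCategory.NO_STENOSIS),
            # precedence: occlusion beats severe beats moderate
            (300.0, 5.0, False, StenosisCategory.OCCLUSION),
            (200.0, 4.0, True, StenosisCategory.SEVERE),
        ],
    )
    def test_duplex_grading(self, psv, ratio, flow, expected):
        assert classify_ica_stenosis(psv, ratio, flow) == expected

    def test_negative_velocity_rejected(self):
        with pytest.raises(ValueError):
            classify_ica_stenosis(-1.0, 1.0, True)

    @pytest.mark.parametrize(
        "csp, shunt", [(33.0, True), (46.0, False), (40.0, False), (39.9, True)]
    )
    def test_shunt_rule_strict_threshold(self, csp, shunt):
        assert shunt_decision(csp) is shunt

    def test_smallest_integer_csp_without_shunt_is_40(self):
        no_shunt = [c for c in range(0, 101) if not shunt_decision(float(c))]
        assert min(no_shunt) == 40


def test_measure_csp_requires_clamp(bifurcation_net):
    from carotidsim.experiment import measure_csp
    from carotidsim.solver import SolverConfig, init_state, run_to_periodic

    cfg = SolverConfig()
    st = init_state(bifurcation_net, cfg)
    st, _ = run_to_periodic(st, bifurcation_net, cfg)
    with pytest.raises(ValueError, match="clamp"):
        measure_csp(st)
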