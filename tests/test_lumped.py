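"""0D elements: inflow waveform, Windkessel, autoregulation."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from carotidsim.lumped import (
    AutoregulationBed,
    InflowWaveform,
    adapt_resistances,
    autoregulation_target,
    default_curve,
    windkessel_step,
)
from carotidsim.units import MMHG


class TestInflowWaveform:
    def test_cycle_mean_equals_cardiac_output(self):
        wf = InflowWaveform()
        t = np.linspace(0.0, wf.cardiac_period, 200001)
        mean = np.trapezoid(wf(t), t) / wf.cardiac_period
        assert mean == pytest.approx(wf.mean_flow, rel=1e-8)

    def test_exact_periodicity(self):
        wf = InflowWaveform()
        t = np.linspace(0.0, 2.0, 57)
        # equality up to the roundoff of the floating-point modulo
        assert np.allclose(wf(t), wf(t + wf.cardiac_period), rtol=0, atol=1e-9)

    def test_diastole_is_flowless_and_flow_nonnegative(self):
        wf = InflowWaveform()
        t = np.linspace(0.0, wf.cardiac_period, 9001)
        q = wf(t)
        assert np.all(q >= 0.0)
        assert np.all(q[t > wf.systolic_duration] == 0.0)

    def test_rejects_systole_longer_than_period(self):
        with pytest.raises(ValueError):
            InflowWaveform(cardiac_period=0.5, systolic_duration=0.6)


class TestWindkessel:
    R1, R2, C, PV = 100.0, 1200.0, 1e-4, 5 * MMHG

    def test_constant_inflow_reaches_resistive_steady_state(self):
        q = 10.0
        pc = self.PV
        for _ in range(200000):
            pc, pb = windkessel_step(pc, q, 1e-3, self.R1, self.R2, self.C, self.PV)
        assert pb == pytest.approx(self.PV + (self.R1 + self.R2) * q, rel=1e-6)

    def test_rest_state_is_invariant(self):
        pc, pb = windkessel_step(self.PV, 0.0, 0.01, self.R1, self.R2, self.C, self.PV)
        assert pc == self.PV and pb == self.PV

    def test_decay_time_constant_matches_analytic_solution(self):
        # free decay from an elevated compartment pressure: the analytic
        # solution is Pv + (P0-Pv)*exp(-t/(R2*C))
        tau = self.R2 * self.C
        p0 = 100 * MMHG
        dt = tau / 5000.0
        pc = p0
        for _ in range(5000):  # one time constant
            pc, _ = windkessel_step(pc, 0.0, dt, self.R1, self.R2, self.C, self.PV)
        expected = self.PV + (p0 - self.PV) * math.exp(-1.0)
        assert pc == pytest.approx(expected, rel=1e-3)

    def test_rejects_nonpositive_dt(self):
        with pytest.raises(ValueError):
            windkessel_step(0.0, 0.0, 0.0, self.R1, self.R2, self.C, self.PV)


class TestAutoregulationCurve:
    def test_plateau_holds_baseline_flow(self):
        curve = default_curve(q0=2.5)
        for p in (60.0, 90.0, 120.0, 150.0):
            assert autoregulation_target(p, curve) == pytest.approx(2.5, rel=0.02)

    def test_zero_pressure_gives_zero_flow(self):
        curve = default_curve(q0=2.5)
        assert curve(0.0) == 0.0

    def test_negative_pressure_rejected(self):
        curve = default_curve(q0=2.5)
        with pytest.raises(ValueError):
            curve(-1.0)

    def test_nondecreasing_over_physiological_range(self):
        curve = default_curve(q0=1.0)
        p = np.arange(0.0, 201.0, 1.0)
        q = curve(p)
        assert np.all(np.diff(q) >= -1e-12)


class TestAdaptResistances:
    def _bed(self, q0=2.5, R=45000.0, kappa=0.5):
        return AutoregulationBed("MCA", default_curve(q0), R, kappa=kappa)

    def test_fixed_point_leaves_resistance_unchanged(self):
        pv = 5 * MMHG
        bed = self._bed()
        p_bar = pv + bed.R * 2.5  # plateau pressure for q0=2.5
        assert 60.0 < (p_bar - pv) / MMHG / 2.5 * 2.5  # sanity: inside plateau
        new_R, converged = adapt_resistances({"MCA": (p_bar, 2.5)}, [bed], {"MCA": pv})
        assert converged
        assert new_R["MCA"] == pytest.approx(bed.R, rel=1e-12)

    def test_kappa_zero_never_converges_off_fixed_point(self):
        pv = 5 * MMHG
        bed = self._bed(kappa=0.0)
        p_bar = pv + bed.R * 2.5 * 1.5  # 50% off target
        new_R, converged = adapt_resistances({"MCA": (p_bar, 3.0)}, [bed], {"MCA": pv})
        assert not converged
        assert new_R["MCA"] == bed.R

    def test_update_moves_resistance_toward_target(self):
        pv = 5 * MMHG
        bed = self._bed(kappa=0.5)
        p_bar = 90 * MMHG
        target = (p_bar - pv) / bed.curve(90.0)
        new_R, _ = adapt_resistances({"MCA": (p_bar, 2.0)}, [bed], {"MCA": pv})
        assert new_R["MCA"] == pytest.approx(0.5 * bed.R + 0.5 * target)


@settings(derandomize=True, max_examples=50, deadline=None)
@given(p=st.floats(min_value=0.0, max_value=250.0),
       q0=st.floats(min_value=0.5, max_value=10.0))
def test_autoregulation_curve_is_scale_invariant_in_q0(p, q0):
    base = default_curve(1.0)
    scaled = default_curve(q0)
    assert scaled(p) == pytest.approx(q0 * base(p), rel=1e-12, abs=1e-12)
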