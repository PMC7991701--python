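"""Lumped (0D) elements closing the 1D arterial domain.

Three elements live here:

* :class:`InflowWaveform` — the prescribed periodic aortic-root flow. The
  heart is not modelled as a closed loop; a half-sine systolic ejection
  with a flat (zero-flow) diastole is prescribed, normalised so that the
  cycle mean equals the configured cardiac output.
* :func:`windkessel_step` — the RCR (Windkessel) terminal update. The
  compartment pressure Pc obeys ``C dPc/dt = Q - (Pc - Pv)/R2`` and the
  boundary sees ``P = Pc + R1*Q``.
* :class:`AutoregulationCurve` / :func:`adapt_resistances` — cerebral
  autoregulation as slow resistance adaptation: each cerebral outlet
  carries a target flow-pressure curve q_target(P) (Lassen-type plateau)
  and its total resistance is relaxed toward ``(P - Pv)/q_target(P)``
  between converged periodic runs.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
from scipy.interpolate import PchipInterpolator

from .units import MMHG


@dataclass
class InflowWaveform:
    """T-periodic aortic inflow: half-sine systole, zero-flow diastole.

    mean_flow is the cardiac output in cm^3/s; systolic_duration is the
    ejection time in s. The systolic peak is derived so the period
    integral equals mean_flow * T.
    """

    cardiac_period: float = 0.9       # s
    systolic_duration: float = 0.3    # s
    mean_flow: float = 5000.0 / 60.0  # cm^3/s (5 L/min)

    def __post_init__(self) -> None:
        if not 0 < self.systolic_duration < self.cardiac_period:
            raise ValueError("systolic duration must lie inside the cardiac period")
        if self.mean_flow < 0:
            raise ValueError("mean flow must be nonnegative")

    @property
    def peak_flow(self) -> float:
        # integral of Qp*sin(pi t/Ts) over [0,Ts] is Qp*2*Ts/pi
        return self.mean_flow * self.cardiac_period * math.pi / (2.0 * self.systolic_duration)

    def __call__(self, t: float | np.ndarray) -> float | np.ndarray:
        tau = np.mod(t, self.cardiac_period)
        q = np.where(
            tau < self.systolic_duration,
            self.peak_flow * np.sin(np.pi * tau / self.systolic_duration),
            0.0,
        )
        if np.ndim(t) == 0:
            return float(q)
        return q


def windkessel_step(
    Pc: float, Q_in: float, dt: float, R1: float, R2: float, C: float, Pv: float
) -> tuple[float, float]:
    """Advance one RCR terminal by dt; return (new Pc, boundary pressure).

    Semi-implicit (backward Euler in Pc, explicit in Q_in), matching the
    update used inside the 1D solver's boundary coupling.
    """
    if dt <= 0:
        raise ValueError("dt must be > 0")
    # C dPc/dt = Q - (Pc - Pv)/R2, implicit in Pc
    Pc_new = (Pc + dt / C * (Q_in + Pv / R2)) / (1.0 + dt / (R2 * C))
    return Pc_new, Pc_new + R1 * Q_in


# ---------------------------------------------------------------------------
# cerebral autoregulation


class AutoregulationCurve:
    """Target cerebral flow as a function of perfusion pressure.

    The curve is a monotone PCHIP interpolant through tabulated anchor
    points (P in mmHg, q as a fraction of the baseline flow q0), with the
    classic Lassen shape: zero flow at zero pressure, a steep rise, a
    plateau at q0 across the autoregulatory range, and a pressure-passive
    rise above it. Beyond the last anchor the curve continues linearly
    with its end slope.
    """

    def __init__(
        self,
        q0: float,
        anchors_p_mmhg: np.ndarray,
        anchors_frac: np.ndarray,
        plateau: tuple[float, float] = (60.0, 150.0),
    ) -> None:
        if q0 <= 0:
            raise ValueError("baseline flow q0 must be > 0")
        p = np.asarray(anchors_p_mmhg, dtype=float)
        f = np.asarray(anchors_frac, dtype=float)
        if p[0] != 0.0 or f[0] != 0.0:
            raise ValueError("curve anchors must start at (0, 0)")
        if np.any(np.diff(p) <= 0) or np.any(np.diff(f) < 0):
            raise ValueError("curve anchors must be increasing in P, nondecreasing in q")
        self.q0 = q0                       # cm^3/s
        self.plateau = plateau             # mmHg
        self._p = p
        self._f = f
        self._interp = PchipInterpolator(p, f, extrapolate=False)
        self._end_slope = float(self._interp.derivative()(p[-1]))

    def fraction(self, P_mmhg: float | np.ndarray) -> np.ndarray:
        """q_target / q0 at perfusion pressure P (mmHg)."""
        P = np.asarray(P_mmhg, dtype=float)
        out = self._interp(np.clip(P, 0.0, self._p[-1]))
        high = P > self._p[-1]
        if np.any(high):
            out = np.where(high, self._f[-1] + self._end_slope * (P - self._p[-1]), out)
        return out

    def __call__(self, P_mmhg: float | np.ndarray) -> float | np.ndarray:
        """Target flow q_target(P) in cm^3/s."""
        if np.any(np.asarray(P_mmhg) < 0):
            raise ValueError("perfusion pressure must be >= 0")
        q = self.q0 * self.fraction(P_mmhg)
        if np.ndim(P_mmhg) == 0:
            return float(q)
        return q


def autoregulation_target(P_mean_mmhg: float, curve: AutoregulationCurve) -> float:
    """Target cerebral flow (cm^3/s) at cycle-mean perfusion pressure (mmHg)."""
    return curve(P_mean_mmhg)


_DEFAULT_CURVE_RESOURCE = "autoregulation_v1.json"


def load_autoregulation_anchors(path: str | Path | None = None) -> dict:
    """Read the packaged (or an explicit) autoregulation anchor table."""
    if path is None:
        text = (
            resources.files("carotidsim.data")
            .joinpath(_DEFAULT_CURVE_RESOURCE)
            .read_text()
        )
    else:
        text = Path(path).read_text()
    return json.loads(text)


def default_curve(q0: float, anchors: dict | None = None) -> AutoregulationCurve:
    """Build the shipped Lassen-type curve scaled to baseline flow q0 (cm^3/s)."""
    doc = anchors if anchors is not None else load_autoregulation_anchors()
    return AutoregulationCurve(
        q0=q0,
        anchors_p_mmhg=np.array(doc["P_mmhg"]),
        anchors_frac=np.array(doc["q_fraction"]),
        plateau=tuple(doc.get("plateau_mmhg", (60.0, 150.0))),
    )


@dataclass
class AutoregulationBed:
    """One autoregulating cerebral outlet and its adaptation settings."""

    terminal_id: str               # segment id of the terminal
    curve: AutoregulationCurve
    R: float                       # current total resistance R1+R2, dyn*s/cm^5
    kappa: float = 0.5             # relaxation factor in (0, 1]
    max_iter: int = 20
    tol: float = 1e-3
    non_autoregulable: bool = field(default=False, init=False)

    def __post_init__(self) -> None:
        if self.R <= 0:
            raise ValueError("bed resistance must be > 0")
        if not 0.0 <= self.kappa <= 1.0:
            raise ValueError("kappa must lie in [0, 1]")


def adapt_resistances(
    metrics: dict[str, tuple[float, float]],
    beds: list[AutoregulationBed],
    Pv_by_bed: dict[str, float] | None = None,
    resistance_cap: float = 1e8,
) -> tuple[dict[str, float], bool]:
    """One outer-loop resistance update toward the autoregulation target.

    metrics maps terminal id -> (cycle-mean bed-inlet pressure in
    dyn/cm^2, cycle-mean bed flow in cm^3/s) from a converged periodic
    run. Each bed's resistance is relaxed:

        R <- R*(1-kappa) + kappa * (P - Pv) / q_target(P)

    Returns the new resistances and a converged flag: the maximum
    relative distance of each resistance from its own fixed-point target
    is below tol. (Measuring the residual rather than the applied change
    means kappa = 0 never reports convergence unless the bed already sits
    at its fixed point.) A bed whose target flow is zero at positive
    pressure is flagged non-autoregulable and its resistance capped.
    """
    new_R: dict[str, float] = {}
    max_rel = 0.0
    tol = min((b.tol for b in beds), default=1e-3)
    for bed in beds:
        P_bar, _q_bar = metrics[bed.terminal_id]
        Pv = (Pv_by_bed or {}).get(bed.terminal_id, 0.0)
        P_mmhg = max(P_bar, 0.0) / MMHG
        q_t = bed.curve(P_mmhg)
        if q_t <= 0.0 and P_bar > Pv:
            bed.non_autoregulable = True
            target = resistance_cap
        else:
            target = max(P_bar - Pv, 0.0) / q_t if q_t > 0 else resistance_cap
            target = min(target, resistance_cap)
        R_new = bed.R * (1.0 - bed.kappa) + bed.kappa * target
        max_rel = max(max_rel, abs(target - bed.R) / bed.R)
        new_R[bed.terminal_id] = R_new
    return new_R, bool(max_rel < tol)
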