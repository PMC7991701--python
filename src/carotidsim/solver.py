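"""1D pulse-wave solver: public API over the compiled kernel.

The solver advances cross-sectionally averaged blood flow (area A, flow
Q) on every vessel segment, coupled at junctions, clamps, stenoses and
lumped terminals, one cardiac cycle at a time, until a periodic regime
is reached.

The constitutive closure is the algebraic thin-wall tube law

    P(A) = P_ext + beta * (sqrt(A) - sqrt(A0)),
    beta = sqrt(pi) * E * h / ((1 - nu^2) * A0),   nu = 0.5

with P_ext the diastolic reference pressure at which the fixture radii
are quoted. The wave speed is c = sqrt((A/rho) dP/dA) =
sqrt(beta*sqrt(A)/(2 rho)).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _kernel
from .discretize import DiscreteModel, discretize
from .lumped import InflowWaveform
from .network import ArterialNetwork, VesselSegment
from .units import MMHG


class SolverError(RuntimeError):
    """Solver failure with location diagnostics (segment, position, time)."""


_STATUS_MSG = {
    _kernel.ERR_NEG_AREA: "non-positive cross-sectional area",
    _kernel.ERR_NAN: "NaN encountered",
    _kernel.ERR_NEWTON: "boundary Newton iteration failed to converge",
    _kernel.ERR_REFLECT: "reflective boundary produced a non-physical state",
}


@dataclass
class SolverConfig:
    """Numerical settings for the 1D solver.

    dx_target is the desired grid spacing (cm); every tube keeps at
    least 5 nodes, so short vessels are resolved finer. cfl is the
    Courant number used for the adaptive time step. p_ext is the
    external/diastolic reference pressure of the tube law, in mmHg.
    """

    dx_target: float = 0.25          # cm
    cfl: float = 0.9
    max_cycles: int = 30
    cycle_tolerance: float = 1e-3
    p_ext_mmhg: float = 80.0
    inflow: InflowWaveform = field(default_factory=InflowWaveform)

    def __post_init__(self) -> None:
        if self.dx_target <= 0:
            raise ValueError("dx_target must be > 0")
        if not 0.0 < self.cfl < 1.0:
            raise ValueError("cfl must lie in (0, 1)")
        if self.max_cycles < 2:
            raise ValueError("max_cycles must be >= 2")
        if self.cycle_tolerance <= 0:
            raise ValueError("cycle_tolerance must be > 0")

    @property
    def cardiac_period(self) -> float:
        return self.inflow.cardiac_period

    @property
    def p_ext(self) -> float:
        return self.p_ext_mmhg * MMHG


@dataclass
class SolverState:
    """Per-node fields (A, Q) plus terminal states, advanced in time."""

    model: DiscreteModel
    A: np.ndarray
    Q: np.ndarray
    tPc: np.ndarray            # terminal compartment pressures
    sQprev: np.ndarray         # stenosis interface flow at previous step
    t: float = 0.0
    cycles_run: int = 0
    # cycle means of the most recent completed cycle (None before that)
    Pmean: np.ndarray | None = None
    Qmean: np.ndarray | None = None
    last_mass_defect: float = 0.0
    last_steps: int = 0

    # ------------------------------------------------------------------
    def mean_pressure_at(self, segment_id: str, x: float, side: str = "nearest") -> float:
        """Cycle-mean pressure (dyn/cm^2) at a position in a segment."""
        if self.Pmean is None:
            raise SolverError("no completed cycle yet")
        return float(self.Pmean[self.model.node_at(segment_id, x, side)])

    def mean_flow_at(self, segment_id: str, x: float, side: str = "nearest") -> float:
        """Cycle-mean flow (cm^3/s) at a position in a segment."""
        if self.Qmean is None:
            raise SolverError("no completed cycle yet")
        return float(self.Qmean[self.model.node_at(segment_id, x, side)])

    def mean_segment_flow(self, segment_name: str) -> float:
        """Cycle-mean flow at the axial midpoint of a named segment."""
        seg = self.model.net.segment_by_name(segment_name)
        return self.mean_flow_at(seg.id, seg.length / 2.0)

    def mean_terminal_pressure(self, segment_id: str) -> float:
        """Cycle-mean pressure at the inlet of a terminal bed (dyn/cm^2)."""
        if self.Pmean is None:
            raise SolverError("no completed cycle yet")
        return float(self.Pmean[self.model.terminal_face_node(segment_id)])

    def mean_terminal_flow(self, segment_id: str) -> float:
        if self.Qmean is None:
            raise SolverError("no completed cycle yet")
        return float(self.Qmean[self.model.terminal_face_node(segment_id)])


@dataclass
class ConvergenceReport:
    converged: bool
    cycles: int
    residuals: list[float]
    max_mass_defect: float


# ---------------------------------------------------------------------------
# constitutive relations (thin wrappers used by tests and the experiment code)

def tube_law(A, segment: VesselSegment, x: float = 0.0, p_ext: float = 0.0):
    """Transmural pressure P(A) of a segment at axial position x (CGS)."""
    A = np.asarray(A, dtype=float)
    if np.any(A <= 0):
        raise ValueError("area must be > 0")
    beta = segment.beta_at(x)
    a0 = segment.area0_at(x)
    p = p_ext + beta * (np.sqrt(A) - np.sqrt(a0))
    return float(p) if p.ndim == 0 else p


def wave_speed(A, segment: VesselSegment, x: float = 0.0, rho: float = 1.06):
    """Pulse-wave speed c(A) = sqrt((A/rho) dP/dA) of a segment (cm/s)."""
    A = np.asarray(A, dtype=float)
    if np.any(A <= 0):
        raise ValueError("area must be > 0")
    beta = segment.beta_at(x)
    c = np.sqrt(beta * np.sqrt(A) / (2.0 * rho))
    return float(c) if c.ndim == 0 else c


# ---------------------------------------------------------------------------
# time advancement

def init_state(net: ArterialNetwork, config: SolverConfig) -> SolverState:
    """Cold start: A = A0 everywhere, Q = 0, terminals at venous pressure."""
    model = discretize(net, config.dx_target)
    return SolverState(
        model=model,
        A=model.A0n.copy(),
        Q=np.zeros(model.n_nodes),
        tPc=model.tPv.copy(),
        sQprev=np.zeros(len(model.sten_geoms)),
    )


def _locate(model: DiscreteModel, node: int) -> str:
    for t in model.tubes:
        if t.start <= node < t.start + t.n:
            x = t.x_lo + (node - t.start) * t.dx
            return f"segment {t.segment_id!r} at x = {x:.3f} cm"
    return f"node {node}"


def advance_cycle(
    state: SolverState,
    net: ArterialNetwork | None = None,
    config: SolverConfig | None = None,
    duration: float | None = None,
) -> SolverState:
    """Advance the state by exactly one cardiac period (in place).

    ``net`` is accepted for interface symmetry; the discretized model
    already carried by the state is what is advanced. ``duration``
    overrides the advancement window (sub-cycle probing); the reported
    means then refer to that window.
    """
    if config is None:
        config = SolverConfig()
    m = state.model
    Psum = np.empty(m.n_nodes)
    Qsum = np.empty(m.n_nodes)
    audit = np.zeros(4)
    wf = config.inflow
    span = wf.cardiac_period if duration is None else float(duration)
    status, t_new = _kernel.advance_cycle(
        state.A, state.Q, state.tPc, state.sQprev,
        state.t, span,
        m.tube_start, m.tube_n, m.tube_dx, m.tube_alpha, m.tube_KR,
        m.A0n, m.betan, m.dA0n, m.dbetan, m.A0h, m.betah, m.dA0h, m.dbetah,
        m.ctype, m.cfaces, m.cneigh, m.cdir, m.cdx, m.cnf, m.cterm, m.csten,
        m.tR1, m.tR2, m.tC, m.tPv,
        m.sVisc, m.sTurb, m.sInert,
        m.net.rho, config.p_ext, config.cfl,
        wf.cardiac_period, wf.systolic_duration, wf.peak_flow,
        Psum, Qsum, audit,
    )
    if status != _kernel.OK:
        where = _locate(m, int(audit[2]))
        raise SolverError(
            f"{_STATUS_MSG.get(status, 'solver failure')} in {where} "
            f"at t = {audit[3]:.5f} s"
        )
    state.t = t_new
    state.cycles_run += 1
    state.Pmean = Psum / span
    state.Qmean = Qsum / span
    state.last_mass_defect = float(audit[0])
    state.last_steps = int(audit[1])
    return state


def run_to_periodic(
    state: SolverState,
    net: ArterialNetwork | None = None,
    config: SolverConfig | None = None,
) -> tuple[SolverState, ConvergenceReport]:
    """Advance whole cycles until the periodic regime is reached.

    Convergence: the max change of cycle-averaged nodal pressure and
    flow between consecutive cycles, normalised by the network-wide
    scale of each field, falls below ``cycle_tolerance``. At least two
    cycles are always run; gives up after ``max_cycles``.
    """
    if config is None:
        config = SolverConfig()
    residuals: list[float] = []
    max_defect = 0.0
    prev_P = state.Pmean.copy() if state.Pmean is not None else None
    prev_Q = state.Qmean.copy() if state.Qmean is not None else None
    converged = False
    for cyc in range(config.max_cycles):
        advance_cycle(state, net, config)
        max_defect = max(max_defect, state.last_mass_defect)
        if prev_P is not None:
            p_scale = max(np.max(np.abs(state.Pmean)), 1e-30)
            q_scale = max(np.max(np.abs(state.Qmean)), 1e-30)
            resid = max(
                np.max(np.abs(state.Pmean - prev_P)) / p_scale,
                np.max(np.abs(state.Qmean - prev_Q)) / q_scale,
            )
            residuals.append(float(resid))
            if cyc >= 1 and resid < config.cycle_tolerance:
                converged = True
                break
        prev_P = state.Pmean.copy()
        prev_Q = state.Qmean.copy()
    return state, ConvergenceReport(
        converged=converged,
        cycles=state.cycles_run,
        residuals=residuals,
        max_mass_defect=max_defect,
    )
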