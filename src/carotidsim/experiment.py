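"""The carotid-endarterectomy protocol and its readouts.

The protocol clamps one internal carotid artery (the surgical side) and
sweeps a 10 mm stenosis on the opposite ICA, starting 10 mm above the
carotid bifurcation, through diameter-reduction ratios 0-100% in 10%
steps. For every ratio the cerebral outlets are re-converged against
their autoregulation curves and the following are extracted:

* carotid stump pressure (CSP): cycle-mean pressure at the grid node
  immediately distal to the clamp;
* signed communicating-artery flows — Acom (positive toward the clamped
  side), both Pcoms (positive posterior -> anterior), and the clamped
  side's ACA A1 segment (positive toward the MCA, i.e. the direction it
  feeds the MCA through the Acom collateral path at 0% stenosis);
* "peripheral" cerebral pressures: cycle-mean pressure at the inlet of
  the ACA / MCA / PCA terminal beds on the clamped side.

Onset/zero/inversion detectors operate on the 10% grid exactly (no
interpolation), with documented operational criteria: a flow series has
"moved" when it deviates from its 0% baseline by more than 2% of the
baseline magnitude, a pressure series when it has declined by more than
1 mmHg.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .lumped import AutoregulationBed, adapt_resistances, default_curve
from .network import ArterialNetwork, ClampSpec, StenosisSpec, apply_clamp, apply_stenosis
from .solver import ConvergenceReport, SolverConfig, SolverState, init_state, run_to_periodic
from .units import MMHG, flow_to_ml_min


# ---------------------------------------------------------------------------
# autoregulation outer loop

@dataclass
class AutoregulationConfig:
    """Cerebral-bed targets and outer-loop settings.

    Total cerebral baseline flow is split per hemisphere across the
    ACA : MCA : PCA beds in the given ratios.
    """

    total_cerebral_flow_ml_min: float = 700.0
    split_aca_mca_pca: tuple[float, float, float] = (2.0, 3.0, 2.0)
    kappa: float = 0.5
    tol: float = 1e-3
    max_iter: int = 20

    def bed_flows(self) -> dict[str, float]:
        """Baseline flow q0 (cm^3/s) per cerebral bed segment name."""
        a, m, p = self.split_aca_mca_pca
        tot = 2.0 * (a + m + p)
        unit = self.total_cerebral_flow_ml_min / 60.0 / tot
        return {
            "R_ACA_A2": a * unit, "L_ACA_A2": a * unit,
            "R_MCA": m * unit, "L_MCA": m * unit,
            "R_PCA_P2": p * unit, "L_PCA_P2": p * unit,
        }


@dataclass
class AutoregulatedRun:
    state: SolverState
    flow_report: ConvergenceReport
    beds: list[AutoregulationBed]
    iterations: int
    converged: bool
    residual_history: list[float] = field(default_factory=list)


def make_beds(
    net: ArterialNetwork, config: AutoregulationConfig
) -> list[AutoregulationBed]:
    """Autoregulating beds for every cerebral terminal in the network."""
    flows = config.bed_flows()
    beds = []
    for seg_id, term in net.terminals.items():
        if term.kind != "autoregulating_bed":
            continue
        seg = net.segments[seg_id]
        q0 = flows.get(seg.name)
        if q0 is None:
            raise KeyError(f"no baseline flow configured for bed {seg.name!r}")
        beds.append(
            AutoregulationBed(
                terminal_id=seg_id,
                curve=default_curve(q0),
                R=term.R1 + term.R2,
                kappa=config.kappa,
                tol=config.tol,
                max_iter=config.max_iter,
            )
        )
    return beds


def run_autoregulated(
    net: ArterialNetwork,
    solver_config: SolverConfig | None = None,
    areg_config: AutoregulationConfig | None = None,
    initial_resistances: dict[str, float] | None = None,
) -> AutoregulatedRun:
    """Periodic solve with cerebral resistance adaptation.

    Alternates converged periodic 1D runs with resistance updates until
    every bed sits on its target flow-pressure curve (or max_iter).
    The input network is not mutated; adapted resistances live in the
    returned state's discretized model. ``initial_resistances`` warm-
    starts the outer loop (the adapted fixed point does not depend on
    the start, so this is purely an accelerator).
    """
    scfg = solver_config or SolverConfig()
    acfg = areg_config or AutoregulationConfig()
    beds = make_beds(net, acfg)
    state = init_state(net, scfg)
    model = state.model
    tidx = {seg_id: model.terminal_ids.index(seg_id) for seg_id in
            (b.terminal_id for b in beds)}
    if initial_resistances:
        for b in beds:
            R0 = initial_resistances.get(b.terminal_id)
            if R0 is not None and R0 > 0:
                ti = tidx[b.terminal_id]
                scale = R0 / (model.tR1[ti] + model.tR2[ti])
                model.tR1[ti] *= scale
                model.tR2[ti] *= scale
                b.R = R0
    state, report = run_to_periodic(state, net, scfg)
    history: list[float] = []
    converged = not beds
    iterations = 0
    for it in range(acfg.max_iter):
        metrics = {
            b.terminal_id: (
                state.mean_terminal_pressure(b.terminal_id),
                state.mean_terminal_flow(b.terminal_id),
            )
            for b in beds
        }
        Pv_by_bed = {b.terminal_id: model.tPv[tidx[b.terminal_id]] for b in beds}
        new_R, converged = adapt_resistances(metrics, beds, Pv_by_bed)
        resid = max(
            abs(new_R[b.terminal_id] - b.R) / b.R for b in beds
        ) if beds else 0.0
        history.append(resid)
        iterations = it + 1
        if converged:
            break
        for b in beds:
            ti = tidx[b.terminal_id]
            total_old = model.tR1[ti] + model.tR2[ti]
            scale = new_R[b.terminal_id] / total_old
            model.tR1[ti] *= scale
            model.tR2[ti] *= scale
            b.R = new_R[b.terminal_id]
        state, report = run_to_periodic(state, net, scfg)
    return AutoregulatedRun(
        state=state,
        flow_report=report,
        beds=beds,
        iterations=iterations,
        converged=converged and report.converged,
        residual_history=history,
    )


# ---------------------------------------------------------------------------
# protocol geometry

#: lesion geometry of the contralateral stenosis (mm)
STENOSIS_START_MM = 10.0
STENOSIS_LENGTH_MM = 10.0
#: clamp position on the surgical-side ICA (mm above the bifurcation)
CLAMP_POSITION_MM = 10.0

_SIDES = {"left": ("L", "R"), "right": ("R", "L")}


def protocol_network(
    patient: ArterialNetwork, side: str, ratio: float
) -> ArterialNetwork:
    """Clamped + stenosed network for one sweep point.

    ``side`` is the surgical (clamped, ipsilateral) side; the stenosis
    goes on the opposite ICA.
    """
    ipsi, contra = _SIDES[side]
    net = apply_clamp(
        patient, ClampSpec(segment_id=f"{ipsi}_ICA", position_mm=CLAMP_POSITION_MM)
    )
    if ratio > 0.0:
        net = apply_stenosis(
            net,
            StenosisSpec(
                segment_id=f"{contra}_ICA",
                start_offset_mm=STENOSIS_START_MM,
                length_mm=STENOSIS_LENGTH_MM,
                ratio=ratio,
            ),
        )
    return net


def measure_csp(state: SolverState, clamp: ClampSpec | None = None) -> float:
    """Carotid stump pressure (mmHg): cycle-mean pressure at the node
    immediately distal to the clamp."""
    clamps = state.model.net.clamps
    if clamp is None:
        if not clamps:
            raise ValueError("network carries no clamp; stump pressure undefined")
        clamp = clamps[0]
    elif not any(
        c.segment_id == clamp.segment_id and c.position_mm == clamp.position_mm
        for c in clamps
    ):
        raise ValueError("given clamp is not installed on the solved network")
    p = state.mean_pressure_at(
        clamp.segment_id, clamp.position_mm * 0.1, side="distal"
    )
    return p / MMHG


# ---------------------------------------------------------------------------
# signed flow extraction

def _signed_flows(state: SolverState, side: str) -> dict[str, float]:
    """Clinical-convention signed mean flows (cm^3/s).

    Fixture orientation: Acom runs right -> left; each Pcom runs
    anterior (ICA) -> posterior (PCA); each A1 runs ICA-top -> Acom.
    """
    ipsi, contra = _SIDES[side]
    q_acom_rl = state.mean_segment_flow("Acom")
    # positive = contralateral -> ipsilateral
    q_acom = q_acom_rl if (contra, ipsi) == ("R", "L") else -q_acom_rl
    # positive = posterior -> anterior
    q_pcom_ipsi = -state.mean_segment_flow(f"{ipsi}_Pcom")
    q_pcom_contra = -state.mean_segment_flow(f"{contra}_Pcom")
    # positive = toward the MCA (retrograde in the anatomical A1 direction)
    q_a1_ipsi = -state.mean_segment_flow(f"{ipsi}_ACA_A1")
    return {
        "q_acom": q_acom,
        "q_pcom_ipsi": q_pcom_ipsi,
        "q_pcom_contra": q_pcom_contra,
        "q_a1_ipsi": q_a1_ipsi,
    }


DEFAULT_RATIOS = tuple(round(0.1 * i, 1) for i in range(11))


@dataclass
class SweepResult:
    """Per-ratio readouts of the clamp + stenosis sweep."""

    table: pd.DataFrame
    side: str
    metadata: dict

    def series(self, column: str) -> pd.Series:
        return self.table.set_index("ratio")[column]

    def thresholds(self) -> dict[str, float | None]:
        """The four grid-detected thresholds of the default protocol."""
        return {
            "acom_decrease_onset": detect_onset(self.series("q_acom_ml_min"), "flow_decrease"),
            "pcom_ipsi_increase_onset": detect_onset(
                self.series("q_pcom_ipsi_ml_min"), "flow_increase"
            ),
            "mca_pressure_decline_onset": detect_onset(
                self.series("p_mca_ipsi_mmhg"), "pressure_decline"
            ),
            "acom_zero": detect_zero(self.series("q_acom_ml_min")),
            "a1_inversion": detect_inversion(self.series("q_a1_ipsi_ml_min")),
        }


def run_cea_sweep(
    patient: ArterialNetwork,
    side: str = "left",
    ratios: tuple[float, ...] = DEFAULT_RATIOS,
    solver_config: SolverConfig | None = None,
    areg_config: AutoregulationConfig | None = None,
) -> SweepResult:
    """Run the full protocol: one autoregulation-converged periodic solve
    per stenosis ratio, rows sorted by ratio.

    Non-converged points are kept but flagged; the sweep continues.
    """
    if side not in _SIDES:
        raise ValueError(f"side must be 'left' or 'right', got {side!r}")
    ipsi, _contra = _SIDES[side]
    rows = []
    warm_R: dict[str, float] | None = None
    for ratio in sorted(ratios):
        if not 0.0 <= ratio <= 1.0:
            raise ValueError(f"stenosis ratio {ratio} outside [0, 1]")
        net = protocol_network(patient, side, ratio)
        run = run_autoregulated(net, solver_config, areg_config, initial_resistances=warm_R)
        warm_R = {b.terminal_id: b.R for b in run.beds}
        st = run.state
        flows = _signed_flows(st, side)
        rows.append(
            {
                "ratio": ratio,
                "csp_mmhg": measure_csp(st),
                "q_acom_ml_min": flow_to_ml_min(flows["q_acom"]),
                "q_pcom_ipsi_ml_min": flow_to_ml_min(flows["q_pcom_ipsi"]),
                "q_pcom_contra_ml_min": flow_to_ml_min(flows["q_pcom_contra"]),
                "q_a1_ipsi_ml_min": flow_to_ml_min(flows["q_a1_ipsi"]),
                "p_aca_ipsi_mmhg": st.mean_terminal_pressure(f"{ipsi}_ACA_A2") / MMHG,
                "p_mca_ipsi_mmhg": st.mean_terminal_pressure(f"{ipsi}_MCA") / MMHG,
                "p_pca_ipsi_mmhg": st.mean_terminal_pressure(f"{ipsi}_PCA_P2") / MMHG,
                "converged": run.converged,
                "autoreg_iterations": run.iterations,
            }
        )
    table = pd.DataFrame(rows)
    meta = {
        "side": side,
        "stenosis_basis": "diameter",
        "stenosis_start_mm": STENOSIS_START_MM,
        "stenosis_length_mm": STENOSIS_LENGTH_MM,
        "clamp_position_mm": CLAMP_POSITION_MM,
        "fixture_version": patient.version,
        "sign_conventions": {
            "q_acom": "positive = contralateral to ipsilateral",
            "q_pcom": "positive = posterior to anterior",
            "q_a1_ipsi": "positive = toward the ipsilateral MCA (Acom collateral path)",
        },
        "onset_criteria": {"flow": "2% of 0%-baseline magnitude", "pressure": "1 mmHg"},
    }
    return SweepResult(table=table, side=side, metadata=meta)


# ---------------------------------------------------------------------------
# grid detectors

def _check_baseline(series: pd.Series) -> float:
    if 0.0 not in series.index:
        raise ValueError("series must include the 0% baseline")
    return float(series.loc[0.0])


def detect_onset(series: pd.Series, kind: str, flow_tol: float = 0.02,
                 pressure_tol_mmhg: float = 1.0) -> float | None:
    """Smallest grid ratio whose value deviates from the 0% baseline
    beyond the operational threshold, in the stated direction.

    kind: "flow_decrease" | "flow_increase" | "pressure_decline".
    Flow thresholds are relative to the baseline magnitude; the pressure
    threshold is absolute (series in mmHg). Returns None if never.
    """
    base = _check_baseline(series)
    for ratio in sorted(series.index):
        if ratio == 0.0:
            continue
        v = float(series.loc[ratio])
        if kind == "flow_decrease":
            if base - v > flow_tol * abs(base):
                return float(ratio)
        elif kind == "flow_increase":
            if v - base > flow_tol * abs(base):
                return float(ratio)
        elif kind == "pressure_decline":
            if base - v > pressure_tol_mmhg:
                return float(ratio)
        else:
            raise ValueError(f"unknown onset kind {kind!r}")
    return None


def detect_zero(series: pd.Series, tol: float = 0.01) -> float | None:
    """Smallest grid ratio where |flow| falls below tol x baseline |flow|."""
    base = _check_baseline(series)
    if base == 0.0:
        raise ValueError("baseline flow is zero; vanishing threshold undefined")
    for ratio in sorted(series.index):
        if ratio == 0.0:
            continue
        if abs(float(series.loc[ratio])) < tol * abs(base):
            return float(ratio)
    return None


def detect_inversion(series: pd.Series, baseline_tol: float = 1e-6) -> float | None:
    """Smallest grid ratio whose sign is opposite to the 0% baseline.

    The detected ratio is invariant under flipping the sign convention
    of the whole series. Returns None if the flow never inverts.
    """
    base = _check_baseline(series)
    if abs(base) < baseline_tol:
        raise ValueError("baseline flow is (numerically) zero; direction undefined")
    s0 = math.copysign(1.0, base)
    for ratio in sorted(series.index):
        if ratio == 0.0:
            continue
        v = float(series.loc[ratio])
        if v != 0.0 and math.copysign(1.0, v) == -s0:
            return float(ratio)
    return None


# ---------------------------------------------------------------------------
# clinical decision rules

class StenosisCategory:
    """Duplex-ultrasound ICA stenosis grades."""

    NO_STENOSIS = "no_stenosis"
    MODERATE = "moderate"
    SEVERE = "severe"
    OCCLUSION = "occlusion"


def classify_ica_stenosis(
    psv_ica: float, psv_ratio_ica_cca: float, flow_present: bool
) -> str:
    """Duplex grading of ICA stenosis.

    Occlusion: no flow. Severe (70-99%): ICA/CCA peak-systolic-velocity
    ratio >= 4. Moderate (50-69%): ICA PSV >= 125 cm/s. Otherwise no
    stenosis. Precedence: occlusion > severe > moderate.
    """
    if psv_ica < 0 or psv_ratio_ica_cca < 0:
        raise ValueError("velocities must be nonnegative")
    if not flow_present:
        return StenosisCategory.OCCLUSION
    if psv_ratio_ica_cca >= 4.0:
        return StenosisCategory.SEVERE
    if psv_ica >= 125.0:
        return StenosisCategory.MODERATE
    return StenosisCategory.NO_STENOSIS


def shunt_decision(mean_csp_mmhg: float) -> bool:
    """Intraoperative rule: place a carotid shunt iff mean CSP < 40 mmHg."""
    if mean_csp_mmhg < 0:
        raise ValueError("mean CSP must be nonnegative")
    return mean_csp_mmhg < 40.0
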