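import numpy as np
import pytest

from carotidsim.lumped import InflowWaveform
from carotidsim.network import (
    ArterialNetwork,
    Junction,
    TerminalElement,
    VesselSegment,
)
from carotidsim.solver import SolverConfig

MMHG = 1333.22


def make_segment(sid="s", name=None, length=10.0, r=0.5, r_dist=None,
                 h=0.05, E=4.0e6) -> VesselSegment:
    return VesselSegment(
        id=sid,
        name=name or sid,
        length=length,
        radius_prox=r,
        radius_dist=r if r_dist is None else r_dist,
        wall_thickness=h,
        youngs_modulus=E,
    )


def make_terminal(sid, R=2000.0, r1_frac=0.15, tau=1.3, Pv=5 * MMHG) -> TerminalElement:
    R1 = r1_frac * R
    R2 = R - R1
    return TerminalElement(sid, "windkessel", R1, R2, tau / R2, Pv)


@pytest.fixture
def single_vessel_net():
    """One 10 cm vessel with an RCR outflow."""
    seg = make_segment("ao", "Ao")
    return ArterialNetwork(
        segments={"ao": seg},
        junctions=[],
        terminals={"ao": make_terminal("ao", R=1400.0)},
        inflow_segment="ao",
    )


@pytest.fixture
def bifurcation_net():
    """Symmetric parent -> two identical daughters."""
    segs = {
        "p": make_segment("p", "Parent", length=10.0, r=0.5),
        "d1": make_segment("d1", "D1", length=8.0, r=0.35, h=0.04),
        "d2": make_segment("d2", "D2", length=8.0, r=0.35, h=0.04),
    }
    j = Junction("j1", [("p", "distal"), ("d1", "proximal"), ("d2", "proximal")])
    terms = {k: make_terminal(k, R=2600.0) for k in ("d1", "d2")}
    return ArterialNetwork(segments=segs, junctions=[j], terminals=terms,
                           inflow_segment="p")


@pytest.fixture
def mirror_net():
    """Two-generation mirror-symmetric tree (L/R homologous branches)."""
    segs = {
        "root": make_segment("root", "Root", length=8.0, r=0.6),
        "L_a": make_segment("L_a", "L_a", length=6.0, r=0.4, h=0.04),
        "R_a": make_segment("R_a", "R_a", length=6.0, r=0.4, h=0.04),
        "L_b1": make_segment("L_b1", "L_b1", length=5.0, r=0.25, h=0.03),
        "L_b2": make_segment("L_b2", "L_b2", length=4.0, r=0.2, h=0.03),
        "R_b1": make_segment("R_b1", "R_b1", length=5.0, r=0.25, h=0.03),
        "R_b2": make_segment("R_b2", "R_b2", length=4.0, r=0.2, h=0.03),
    }
    juncs = [
        Junction("j0", [("root", "distal"), ("L_a", "proximal"), ("R_a", "proximal")]),
        Junction("jL", [("L_a", "distal"), ("L_b1", "proximal"), ("L_b2", "proximal")]),
        Junction("jR", [("R_a", "distal"), ("R_b1", "proximal"), ("R_b2", "proximal")]),
    ]
    terms = {k: make_terminal(k, R=5200.0) for k in ("L_b1", "L_b2", "R_b1", "R_b2")}
    return ArterialNetwork(segments=segs, junctions=juncs, terminals=terms,
                           inflow_segment="root")


@pytest.fixture
def fast_config():
    return SolverConfig(dx_target=0.5, cfl=0.9)


# ---------------------------------------------------------------------------
# expensive shared runs (computed once per session, reused by many tests)

@pytest.fixture(scope="session")
def calibrated_patient():
    from carotidsim.patient import build_virtual_patient, calibrate_map

    net = build_virtual_patient(age=70)
    patient, achieved = calibrate_map(net)
    return patient, achieved


@pytest.fixture(scope="session")
def default_sweep(calibrated_patient):
    from carotidsim.experiment import run_cea_sweep

    patient, _ = calibrated_patient
    return run_cea_sweep(patient, side="left")


@pytest.fixture(scope="session")
def autoregulated_baseline(calibrated_patient):
    """Unclamped autoregulation-converged run of the calibrated patient."""
    from carotidsim.experiment import AutoregulationConfig, run_autoregulated

    patient, _ = calibrated_patient
    acfg = AutoregulationConfig()
    return run_autoregulated(patient, areg_config=acfg), acfg


@pytest.fixture(scope="session")
def baseline_periodic(calibrated_patient):
    """Converged unclamped periodic run of the calibrated patient."""
    from carotidsim.solver import init_state, run_to_periodic

    patient, _ = calibrated_patient
    cfg = SolverConfig()
    state = init_state(patient, cfg)
    state, report = run_to_periodic(state, patient, cfg)
    return state, report
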