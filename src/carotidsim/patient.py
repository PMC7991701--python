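"""Construction and calibration of the virtual patient.

The study subject is an imaginary 70-year-old male with a mean arterial
pressure of 90 mmHg. He is assembled from the packaged population-average
fixture (reference age 40) in three steps:

1. age adjustment — arterial stiffening of 10% per decade above the
   reference age, applied to every segment's Young's modulus;
2. resistance calibration — one global scale factor on all terminal
   resistances (R1 and R2 jointly) found by bracketing root-finding so
   the converged cycle-mean aortic-root pressure hits the target MAP;
3. (optionally) lognormal perturbation of geometry/stiffness/resistance
   for robustness studies.

Sex is accepted for interface completeness but has no effect on the
default fixture, which carries no sex-specific parameters.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
from scipy.optimize import brentq

from .network import ArterialNetwork, load_network, validate_network
from .solver import SolverConfig, init_state, run_to_periodic
from .units import MMHG

_DEFAULT_FIXTURE = "network_v1.json"
REFERENCE_AGE = 40.0
STIFFENING_PER_DECADE = 0.10


@dataclass
class CalibrationConfig:
    """Settings for the MAP calibration root-find."""

    target_map_mmhg: float = 90.0
    tolerance_mmhg: float = 1.0
    max_iter: int = 40
    scale_bracket: tuple[float, float] = (0.2, 5.0)

    def __post_init__(self) -> None:
        if self.target_map_mmhg <= 0:
            raise ValueError("target MAP must be > 0")
        if self.tolerance_mmhg <= 0:
            raise ValueError("tolerance must be > 0")


@dataclass
class AgeAdjustment:
    """Linear arterial-stiffening law: E grows by `slope` per decade."""

    reference_age: float = REFERENCE_AGE
    slope_per_decade: float = STIFFENING_PER_DECADE

    def stiffness_factor(self, age: float) -> float:
        decades = max(age - self.reference_age, 0.0) / 10.0
        return 1.0 + self.slope_per_decade * decades


def default_fixture_path() -> Path:
    return Path(str(resources.files("carotidsim.data").joinpath(_DEFAULT_FIXTURE)))


def build_virtual_patient(
    age: float = 70.0,
    sex: str = "male",
    fixture: str | Path | None = None,
    age_adjustment: AgeAdjustment | None = None,
) -> ArterialNetwork:
    """Load the population-average fixture and apply the age adjustment.

    Returns an uncalibrated network: terminal resistances still need
    :func:`calibrate_map` to hit the target mean arterial pressure.
    """
    del sex  # accepted, but the default fixture is not sex-specific
    path = Path(fixture) if fixture is not None else default_fixture_path()
    net = load_network(path)
    adj = age_adjustment or AgeAdjustment()
    factor = adj.stiffness_factor(age)
    for seg in net.segments.values():
        seg.youngs_modulus *= factor
    validate_network(net)
    return net


def _scaled(net: ArterialNetwork, scale: float) -> ArterialNetwork:
    out = net.copy()
    for term in out.terminals.values():
        term.R1 *= scale
        term.R2 *= scale
    return out


def simulated_map(
    net: ArterialNetwork, solver_config: SolverConfig | None = None
) -> tuple[float, bool]:
    """Converged cycle-mean aortic-root pressure (mmHg) of a network."""
    cfg = solver_config or SolverConfig()
    state = init_state(net, cfg)
    state, report = run_to_periodic(state, net, cfg)
    root = net.inflow_segment
    return state.mean_pressure_at(root, 0.0) / MMHG, report.converged


def calibrate_map(
    net: ArterialNetwork,
    config: CalibrationConfig | None = None,
    solver_config: SolverConfig | None = None,
) -> tuple[ArterialNetwork, float]:
    """Scale all terminal resistances so the converged MAP hits the target.

    MAP is monotone increasing in the global resistance scale (at fixed
    cardiac output an open-loop model's mean pressure is resistance-
    determined), so a bracketing root-find on the scale factor is
    guaranteed to converge when the target lies inside the bracket.
    Returns (calibrated network, achieved MAP in mmHg).
    """
    if net.clamps:
        raise ValueError("calibration requires an unclamped network")
    cfg = config or CalibrationConfig()
    scfg = solver_config or SolverConfig()

    cache: dict[float, float] = {}

    def err(scale: float) -> float:
        if scale not in cache:
            cache[scale], _ = simulated_map(_scaled(net, scale), scfg)
        return cache[scale] - cfg.target_map_mmhg

    lo, hi = cfg.scale_bracket
    e1 = err(1.0)
    if abs(e1) <= cfg.tolerance_mmhg:
        return _scaled(net, 1.0), cache[1.0]
    # only probe the bracket end on the side the root lies (MAP is
    # monotone in the scale, so the other end is never needed)
    if e1 > 0:
        if err(lo) > 0:
            raise RuntimeError(
                f"target MAP {cfg.target_map_mmhg} mmHg unreachable within "
                f"scale bracket {cfg.scale_bracket}: MAP at scale {lo} is "
                f"{cache[lo]:.1f} mmHg"
            )
        a, b = lo, 1.0
    else:
        if err(hi) < 0:
            raise RuntimeError(
                f"target MAP {cfg.target_map_mmhg} mmHg unreachable within "
                f"scale bracket {cfg.scale_bracket}: MAP at scale {hi} is "
                f"{cache[hi]:.1f} mmHg"
            )
        a, b = 1.0, hi
    scale = brentq(
        err, a, b, xtol=1e-4, rtol=1e-5, maxiter=cfg.max_iter,
    )
    achieved = cache.get(scale)
    if achieved is None:
        achieved = err(scale) + cfg.target_map_mmhg
    if abs(achieved - cfg.target_map_mmhg) > cfg.tolerance_mmhg:
        raise RuntimeError(
            f"calibration landed at {achieved:.2f} mmHg, outside tolerance "
            f"{cfg.tolerance_mmhg} mmHg of target {cfg.target_map_mmhg}"
        )
    return _scaled(net, scale), achieved


def perturb_patient(
    net: ArterialNetwork, seed: int, cv: float = 0.1
) -> ArterialNetwork:
    """Multiply radii, stiffness and terminal resistances by independent
    lognormal factors with coefficient of variation ``cv``.

    Deterministic given ``seed``; cv = 0 returns an identical network.
    """
    if not 0.0 <= cv <= 0.3:
        raise ValueError("cv must lie in [0, 0.3]")
    out = net.copy()
    if cv == 0.0:
        return out
    rng = np.random.default_rng(seed)
    sigma = np.sqrt(np.log(1.0 + cv * cv))
    mu = -0.5 * sigma * sigma  # unit-mean lognormal

    def draw() -> float:
        return float(rng.lognormal(mean=mu, sigma=sigma))

    for seg in out.segments.values():
        f_r = draw()
        seg.radius_prox *= f_r
        seg.radius_dist *= f_r
        seg.youngs_modulus *= draw()
    for term in out.terminals.values():
        f = draw()
        term.R1 *= f
        term.R2 *= f
    validate_network(out)
    return out
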