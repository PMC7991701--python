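"""Unit conversions.

All internal computation is in CGS units (cm, g, s, dyn). Clinical
quantities cross the package boundary in mmHg and mL/min.
"""

MMHG = 1333.22  # dyn/cm^2 per mmHg
ML_PER_MIN = 1.0 / 60.0  # cm^3/s per mL/min


def pressure_to_mmhg(p_cgs: float) -> float:
    """dyn/cm^2 -> mmHg."""
    return p_cgs / MMHG


def pressure_from_mmhg(p_mmhg: float) -> float:
    """mmHg -> dyn/cm^2."""
    return p_mmhg * MMHG


def flow_to_ml_min(q_cgs: float) -> float:
    """cm^3/s -> mL/min."""
    return q_cgs * 60.0


def flow_from_ml_min(q_ml_min: float) -> float:
    """mL/min -> cm^3/s."""
    return q_ml_min / 60.0
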