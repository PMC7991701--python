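"""Lumped trans-stenotic pressure loss (Young-Tsai-type three-term model).

A stenosis of length Ls inside a host vessel of unstenosed area A0s
(diameter D0) with stenosed lumen area As produces, at instantaneous flow
Q (cm^3/s):

    dP = Kv*mu/(A0s*D0) * Q
       + Kt*rho/(2*A0s^2) * (A0s/As - 1)^2 * Q*|Q|
       + Ku*rho*Ls/A0s * dQ/dt

with the viscous coefficient Kv = 32*(Ls/D0)*(A0s/As)^2 and empirical
turbulent/inertial coefficients Kt = 1.52, Ku = 1.2 (overridable). The
viscous and turbulent terms are odd in Q, so steady dP carries the sign
of the flow. Full occlusion (As = 0) is not handled here: the solver
routes it to a zero-flow (clamp-like) interface.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .network import StenosisSpec, VesselSegment, MM

KT_DEFAULT = 1.52
KU_DEFAULT = 1.2


class OccludedStenosisError(ValueError):
    """Raised when the pressure-loss formula is asked about a closed lumen."""


@dataclass(frozen=True)
class StenosisGeometry:
    """Resolved lumped-element geometry at the stenosis site (CGS)."""

    A0s: float   # unstenosed reference area at the site, cm^2
    As: float    # stenosed lumen area, cm^2
    Ls: float    # stenosis length, cm
    D0: float    # unstenosed diameter, cm

    @property
    def area_ratio(self) -> float:
        return self.A0s / self.As


def resolve_geometry(spec: StenosisSpec, host: VesselSegment) -> StenosisGeometry:
    """Evaluate A0s, As, Ls, D0 from the host segment's reference geometry.

    The reference area is taken at the stenosis start offset; the
    diameter basis means As = A0s*(1-r)^2.
    """
    spec.validate(host)
    x = spec.start_offset_mm * MM
    r0 = host.radius_at(x)
    A0s = math.pi * r0 * r0
    As = A0s * (1.0 - spec.ratio) ** 2
    return StenosisGeometry(A0s=A0s, As=As, Ls=spec.length_mm * MM, D0=2.0 * r0)


def stenosis_pressure_drop(
    Q: float,
    dQdt: float,
    spec: StenosisSpec,
    host: VesselSegment,
    rho: float = 1.06,
    mu: float = 0.04,
    Kt: float = KT_DEFAULT,
    Ku: float = KU_DEFAULT,
) -> float:
    """Pressure loss (dyn/cm^2) across the stenosis at flow Q (cm^3/s)."""
    geo = resolve_geometry(spec, host)
    if geo.As <= 0.0:
        raise OccludedStenosisError(
            f"stenosis on {spec.segment_id!r} is fully occluded; "
            "use the zero-flow (clamp) interface instead"
        )
    a, b, c = pressure_drop_coefficients(geo, rho, mu, Kt, Ku)
    return a * Q + b * Q * abs(Q) + c * dQdt


def pressure_drop_coefficients(
    geo: StenosisGeometry,
    rho: float,
    mu: float,
    Kt: float = KT_DEFAULT,
    Ku: float = KU_DEFAULT,
) -> tuple[float, float, float]:
    """(viscous, turbulent, inertial) coefficients so dP = a*Q + b*Q|Q| + c*dQdt."""
    if geo.As <= 0.0:
        raise OccludedStenosisError("occluded lumen has no pressure-drop coefficients")
    Kv = 32.0 * (geo.Ls / geo.D0) * geo.area_ratio**2
    a = Kv * mu / (geo.A0s * geo.D0)
    b = Kt * rho / (2.0 * geo.A0s**2) * (geo.area_ratio - 1.0) ** 2
    c = Ku * rho * geo.Ls / geo.A0s
    return a, b, c
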