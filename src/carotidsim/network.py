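"""Arterial network domain model, fixture I/O and surgical interventions.

The network is a directed tree of 1D vessel segments joined at junctions,
terminated by lumped (0D) outflow elements, and fed by a single inflow
boundary at the aortic root. Two interventions can be installed on a
network: a stenosis (lumped pressure-loss interface inside a segment) and
a clamp (zero-flow internal boundary, as applied during carotid
endarterectomy). Both are pure transformations: they return a new network
and never mutate their input.

Geometry is in cm, pressures in dyn/cm^2, stiffness (Young's modulus) in
dyn/cm^2; intervention positions are specified in mm, as a surgeon would.
"""

from __future__ import annotations

import copy
import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import networkx as nx

MM = 0.1  # cm per mm

#: Segment names that must all be present for a complete circle of Willis.
COW_SEGMENT_NAMES = frozenset(
    [
        "L_ICA", "R_ICA",
        "L_ACA_A1", "R_ACA_A1",
        "L_ACA_A2", "R_ACA_A2",
        "L_MCA", "R_MCA",
        "L_PCA_P1", "R_PCA_P1",
        "L_PCA_P2", "R_PCA_P2",
        "Acom",
        "L_Pcom", "R_Pcom",
        "BA",
        "L_VA", "R_VA",
        "L_ECA", "R_ECA",
        "L_CCA", "R_CCA",
    ]
)

NU_POISSON = 0.5  # wall Poisson ratio in the thin-shell tube law


class NetworkValidationError(ValueError):
    """A network fixture or assembled network violates an invariant.

    The message names the offending record (segment id, junction id, ...).
    """


@dataclass
class VesselSegment:
    """One 1D arterial segment with linear taper.

    Radii are the reference (diastolic) lumen radii at the proximal and
    distal ends; the reference area A0(x) and tube-law stiffness beta(x)
    are derived from them.
    """

    id: str
    name: str
    length: float            # cm
    radius_prox: float       # cm
    radius_dist: float       # cm
    wall_thickness: float    # cm
    youngs_modulus: float    # dyn/cm^2
    alpha: float = 1.0       # momentum correction factor
    friction_coeff: float | None = None  # K_R, cm^2/s; None -> 22*pi*mu/rho

    def validate(self) -> None:
        if self.length <= 0:
            raise NetworkValidationError(f"segment {self.id!r}: length must be > 0")
        if self.radius_prox <= 0 or self.radius_dist <= 0:
            raise NetworkValidationError(f"segment {self.id!r}: radii must be > 0")
        if self.wall_thickness <= 0:
            raise NetworkValidationError(f"segment {self.id!r}: wall thickness must be > 0")
        if self.youngs_modulus <= 0:
            raise NetworkValidationError(f"segment {self.id!r}: Young's modulus must be > 0")
        if self.alpha < 1.0:
            raise NetworkValidationError(f"segment {self.id!r}: alpha must be >= 1")

    def radius_at(self, x: float) -> float:
        """Reference radius at axial position x in [0, length] (cm)."""
        t = min(max(x / self.length, 0.0), 1.0)
        return self.radius_prox + t * (self.radius_dist - self.radius_prox)

    def area0_at(self, x: float) -> float:
        """Reference cross-sectional area A0(x) in cm^2."""
        r = self.radius_at(x)
        return math.pi * r * r

    def beta_at(self, x: float) -> float:
        """Tube-law stiffness beta(x) = sqrt(pi)*E*h / ((1-nu^2)*A0(x))."""
        a0 = self.area0_at(x)
        return (
            math.sqrt(math.pi)
            * self.youngs_modulus
            * self.wall_thickness
            / ((1.0 - NU_POISSON**2) * a0)
        )


@dataclass
class Junction:
    """A node joining 2 or 3 segment ends (bifurcation or anastomosis)."""

    node_id: str
    attached: list[tuple[str, str]]  # (segment id, "proximal" | "distal")

    def validate(self) -> None:
        if not 2 <= len(self.attached) <= 3:
            raise NetworkValidationError(
                f"junction {self.node_id!r}: must join 2 or 3 segment ends, "
                f"got {len(self.attached)}"
            )
        if len(set(self.attached)) != len(self.attached):
            raise NetworkValidationError(
                f"junction {self.node_id!r}: duplicate attachment"
            )
        for seg_id, end in self.attached:
            if end not in ("proximal", "distal"):
                raise NetworkValidationError(
                    f"junction {self.node_id!r}: bad end {end!r} for segment {seg_id!r}"
                )


@dataclass
class TerminalElement:
    """Lumped RCR (Windkessel) outflow element at a segment's distal end.

    kind "autoregulating_bed" marks cerebral outlets whose total
    resistance is adapted toward a target flow-pressure curve.
    """

    segment_id: str
    kind: str                # "windkessel" | "autoregulating_bed"
    R1: float                # dyn*s/cm^5, proximal (characteristic) resistance
    R2: float                # dyn*s/cm^5, distal resistance
    C: float                 # cm^5/dyn, compliance
    Pv: float = 0.0          # dyn/cm^2, venous pressure

    def validate(self) -> None:
        if self.kind not in ("windkessel", "autoregulating_bed"):
            raise NetworkValidationError(
                f"terminal {self.segment_id!r}: unknown kind {self.kind!r}"
            )
        if self.R1 < 0 or self.R2 < 0:
            raise NetworkValidationError(
                f"terminal {self.segment_id!r}: resistances must be >= 0"
            )
        if self.C <= 0:
            raise NetworkValidationError(
                f"terminal {self.segment_id!r}: compliance must be > 0"
            )
        if self.Pv < 0:
            raise NetworkValidationError(
                f"terminal {self.segment_id!r}: venous pressure must be >= 0"
            )


@dataclass
class StenosisSpec:
    """A lumped stenosis inside a segment.

    ratio is the fractional *diameter* reduction (NASCET-style): the
    stenosed lumen area is As = A0 * (1 - ratio)^2. ratio = 1 marks full
    occlusion and is realized as a zero-flow interface rather than through
    the pressure-loss formula.
    """

    segment_id: str
    start_offset_mm: float
    length_mm: float
    ratio: float
    basis: str = "diameter"

    def validate(self, segment: VesselSegment | None = None) -> None:
        if self.basis != "diameter":
            raise NetworkValidationError(
                f"stenosis on {self.segment_id!r}: unsupported basis {self.basis!r}"
            )
        if self.start_offset_mm < 0:
            raise NetworkValidationError(
                f"stenosis on {self.segment_id!r}: start offset must be >= 0"
            )
        if self.length_mm <= 0:
            raise NetworkValidationError(
                f"stenosis on {self.segment_id!r}: length must be > 0"
            )
        if not 0.0 <= self.ratio <= 1.0:
            raise NetworkValidationError(
                f"stenosis on {self.segment_id!r}: ratio must be in [0, 1]"
            )
        if segment is not None:
            if (self.start_offset_mm + self.length_mm) * MM > segment.length + 1e-12:
                raise NetworkValidationError(
                    f"stenosis on {self.segment_id!r}: extends beyond segment "
                    f"length {segment.length} cm"
                )


@dataclass
class ClampSpec:
    """A surgical cross-clamp: a zero-flow internal boundary in a segment.

    Both sides of the clamp remain part of the solved domain, so the
    pressure in the distal stump (the carotid stump pressure) is
    observable.
    """

    segment_id: str
    position_mm: float

    def validate(self, segment: VesselSegment | None = None) -> None:
        if segment is not None:
            if not 0.0 < self.position_mm * MM < segment.length:
                raise NetworkValidationError(
                    f"clamp on {self.segment_id!r}: position {self.position_mm} mm "
                    f"outside segment (length {segment.length} cm)"
                )


@dataclass
class ArterialNetwork:
    """A validated arterial tree plus installed interventions."""

    segments: dict[str, VesselSegment]
    junctions: list[Junction]
    terminals: dict[str, TerminalElement]
    inflow_segment: str
    rho: float = 1.06        # g/cm^3
    mu: float = 0.04         # poise
    stenoses: list[StenosisSpec] = field(default_factory=list)
    clamps: list[ClampSpec] = field(default_factory=list)
    version: str = "unversioned"

    # -- derived helpers -------------------------------------------------
    def segment_by_name(self, name: str) -> VesselSegment:
        for seg in self.segments.values():
            if seg.name == name:
                return seg
        raise KeyError(f"no segment named {name!r}")

    def friction_coeff(self, seg: VesselSegment) -> float:
        """K_R for a segment: explicit value or the default profile closure."""
        if seg.friction_coeff is not None:
            return seg.friction_coeff
        return 22.0 * math.pi * self.mu / self.rho

    def copy(self) -> "ArterialNetwork":
        return copy.deepcopy(self)


def validate_network(net: ArterialNetwork) -> None:
    """Check all structural invariants; raise NetworkValidationError on failure."""
    if net.rho <= 0 or net.mu <= 0:
        raise NetworkValidationError("blood density and viscosity must be > 0")
    if not net.segments:
        raise NetworkValidationError("network has no segments")

    for seg in net.segments.values():
        seg.validate()
    for j in net.junctions:
        j.validate()
    for term in net.terminals.values():
        term.validate()

    node_ids = [j.node_id for j in net.junctions]
    if len(set(node_ids)) != len(node_ids):
        dup = sorted({n for n in node_ids if node_ids.count(n) > 1})
        raise NetworkValidationError(f"duplicate junction ids: {dup}")

    # every segment end attached to exactly one junction / terminal / inflow
    attachments: dict[tuple[str, str], list[str]] = {}
    for j in net.junctions:
        for seg_id, end in j.attached:
            if seg_id not in net.segments:
                raise NetworkValidationError(
                    f"junction {j.node_id!r}: unknown segment {seg_id!r}"
                )
            attachments.setdefault((seg_id, end), []).append(j.node_id)
    if net.inflow_segment not in net.segments:
        raise NetworkValidationError(
            f"inflow boundary references unknown segment {net.inflow_segment!r}"
        )
    attachments.setdefault((net.inflow_segment, "proximal"), []).append("<inflow>")
    for seg_id in net.terminals:
        if seg_id not in net.segments:
            raise NetworkValidationError(
                f"terminal references unknown segment {seg_id!r}"
            )
        attachments.setdefault((seg_id, "distal"), []).append("<terminal>")

    for seg_id in net.segments:
        for end in ("proximal", "distal"):
            owners = attachments.get((seg_id, end), [])
            if len(owners) == 0:
                raise NetworkValidationError(
                    f"segment {seg_id!r}: {end} end is dangling"
                )
            if len(owners) > 1:
                raise NetworkValidationError(
                    f"segment {seg_id!r}: {end} end attached more than once "
                    f"({owners})"
                )

    # connectivity of the vessel graph (segments as edges between nodes)
    g = nx.Graph()
    end_node: dict[tuple[str, str], str] = {}
    for j in net.junctions:
        for seg_id, end in j.attached:
            end_node[(seg_id, end)] = j.node_id
    for seg_id in net.segments:
        a = end_node.get((seg_id, "proximal"), f"<free:{seg_id}:p>")
        b = end_node.get((seg_id, "distal"), f"<free:{seg_id}:d>")
        if a == b:
            raise NetworkValidationError(
                f"segment {seg_id!r}: both ends attached to junction {a!r}"
            )
        g.add_edge(a, b, segment=seg_id)
    if g.number_of_nodes() and not nx.is_connected(g):
        comps = sorted(len(c) for c in nx.connected_components(g))
        raise NetworkValidationError(
            f"network is not connected (component sizes {comps})"
        )

    # a cerebral network must carry a complete circle of Willis
    names = {seg.name for seg in net.segments.values()}
    if names & {"L_MCA", "R_MCA"}:
        missing = COW_SEGMENT_NAMES - names
        if missing:
            raise NetworkValidationError(
                "cerebral network is missing circle-of-Willis segments: "
                f"{sorted(missing)}"
            )

    for spec in net.stenoses:
        if spec.segment_id not in net.segments:
            raise NetworkValidationError(
                f"stenosis references unknown segment {spec.segment_id!r}"
            )
        spec.validate(net.segments[spec.segment_id])
    for spec in net.clamps:
        if spec.segment_id not in net.segments:
            raise NetworkValidationError(
                f"clamp references unknown segment {spec.segment_id!r}"
            )
        spec.validate(net.segments[spec.segment_id])


# ---------------------------------------------------------------------------
# fixture I/O

FORMAT_TAG = "carotidsim-network"


def load_network(path: str | Path) -> ArterialNetwork:
    """Load and validate a network fixture (JSON dialect documented in README)."""
    with open(path) as fh:
        doc = json.load(fh)
    return network_from_dict(doc)


def network_from_dict(doc: dict) -> ArterialNetwork:
    if doc.get("format") != FORMAT_TAG:
        raise NetworkValidationError(
            f"not a {FORMAT_TAG} document (format={doc.get('format')!r})"
        )
    segments: dict[str, VesselSegment] = {}
    for rec in doc["segments"]:
        seg = VesselSegment(
            id=rec["id"],
            name=rec.get("name", rec["id"]),
            length=rec["length_cm"],
            radius_prox=rec["r_prox_cm"],
            radius_dist=rec["r_dist_cm"],
            wall_thickness=rec["h_cm"],
            youngs_modulus=rec["E_dyn_cm2"],
            alpha=rec.get("alpha", 1.0),
            friction_coeff=rec.get("K_R_cm2_s"),
        )
        if seg.id in segments:
            raise NetworkValidationError(f"duplicate segment id {seg.id!r}")
        segments[seg.id] = seg
    junctions = [
        Junction(rec["node_id"], [tuple(a) for a in rec["attached"]])
        for rec in doc.get("junctions", [])
    ]
    terminals: dict[str, TerminalElement] = {}
    for rec in doc.get("terminals", []):
        term = TerminalElement(
            segment_id=rec["segment"],
            kind=rec.get("kind", "windkessel"),
            R1=rec["R1"],
            R2=rec["R2"],
            C=rec["C"],
            Pv=rec.get("Pv", 0.0),
        )
        if term.segment_id in terminals:
            raise NetworkValidationError(
                f"duplicate terminal for segment {term.segment_id!r}"
            )
        terminals[term.segment_id] = term
    blood = doc.get("blood", {})
    net = ArterialNetwork(
        segments=segments,
        junctions=junctions,
        terminals=terminals,
        inflow_segment=doc["inflow_segment"],
        rho=blood.get("rho", 1.06),
        mu=blood.get("mu", 0.04),
        stenoses=[StenosisSpec(**rec) for rec in doc.get("stenoses", [])],
        clamps=[ClampSpec(**rec) for rec in doc.get("clamps", [])],
        version=doc.get("version", "unversioned"),
    )
    validate_network(net)
    return net


def network_to_dict(net: ArterialNetwork) -> dict:
    return {
        "format": FORMAT_TAG,
        "version": net.version,
        "blood": {"rho": net.rho, "mu": net.mu},
        "inflow_segment": net.inflow_segment,
        "segments": [
            {
                "id": s.id,
                "name": s.name,
                "length_cm": s.length,
                "r_prox_cm": s.radius_prox,
                "r_dist_cm": s.radius_dist,
                "h_cm": s.wall_thickness,
                "E_dyn_cm2": s.youngs_modulus,
                "alpha": s.alpha,
                **({"K_R_cm2_s": s.friction_coeff} if s.friction_coeff is not None else {}),
            }
            for s in net.segments.values()
        ],
        "junctions": [
            {"node_id": j.node_id, "attached": [list(a) for a in j.attached]}
            for j in net.junctions
        ],
        "terminals": [
            {
                "segment": t.segment_id,
                "kind": t.kind,
                "R1": t.R1,
                "R2": t.R2,
                "C": t.C,
                "Pv": t.Pv,
            }
            for t in net.terminals.values()
        ],
        "stenoses": [asdict(s) for s in net.stenoses],
        "clamps": [asdict(c) for c in net.clamps],
    }


def write_network(net: ArterialNetwork, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(network_to_dict(net), fh, indent=1)
        fh.write("\n")


# ---------------------------------------------------------------------------
# interventions

def apply_stenosis(net: ArterialNetwork, spec: StenosisSpec) -> ArterialNetwork:
    """Return a copy of ``net`` carrying ``spec`` as a lumped stenosis.

    A ratio of 0 leaves the network hemodynamically identical to the
    input; a ratio of 1 marks the site as fully occluded (realized as a
    zero-flow interface by the solver).
    """
    if spec.segment_id not in net.segments:
        raise NetworkValidationError(
            f"stenosis references unknown segment {spec.segment_id!r}"
        )
    spec.validate(net.segments[spec.segment_id])
    out = net.copy()
    out.stenoses.append(copy.deepcopy(spec))
    return out


def apply_clamp(net: ArterialNetwork, spec: ClampSpec) -> ArterialNetwork:
    """Return a copy of ``net`` with a cross-clamp installed.

    Flow across the clamp is identically zero; both sides stay in the
    solved domain so the distal stump pressure can be measured.
    """
    if spec.segment_id not in net.segments:
        raise NetworkValidationError(
            f"clamp references unknown segment {spec.segment_id!r}"
        )
    spec.validate(net.segments[spec.segment_id])
    out = net.copy()
    out.clamps.append(copy.deepcopy(spec))
    return out
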