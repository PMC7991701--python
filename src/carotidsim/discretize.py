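"""Discretization of an arterial network into flat solver arrays.

Each vessel segment is split at intervention sites (clamps, stenoses)
into "tubes" — contiguous 1D grids. A clamp becomes a pair of reflective
(zero-flow) faces; a stenosis with 0 < r < 1 removes the stenosed stretch
from the grid and joins the two tubes through a lumped pressure-loss
interface; r = 1 is routed to the reflective (occlusion) path; r = 0 is
hemodynamically inert and creates no interface at all.

All per-node geometry (reference area A0, tube-law stiffness beta and
their axial slopes) is precomputed here so the time-stepping kernel works
on plain float arrays.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .network import ArterialNetwork, NetworkValidationError, MM
from .stenosis import StenosisGeometry, pressure_drop_coefficients, resolve_geometry

# coupler type codes shared with the kernel
INFLOW = 0
JUNCTION = 1
TERMINAL = 2
REFLECT = 3
STENOSIS = 4

MIN_NODES = 5


@dataclass
class Tube:
    """A contiguous grid piece of a host segment."""

    segment_id: str
    x_lo: float      # position of first node within the host segment, cm
    x_hi: float      # position of last node, cm
    start: int       # offset of first node in the global arrays
    n: int
    dx: float


@dataclass
class DiscreteModel:
    """Flat-array representation of a network ready for time stepping."""

    net: ArterialNetwork
    tubes: list[Tube]
    n_nodes: int
    # per-tube
    tube_start: np.ndarray
    tube_n: np.ndarray
    tube_dx: np.ndarray
    tube_alpha: np.ndarray
    tube_KR: np.ndarray
    # per-node geometry
    A0n: np.ndarray
    betan: np.ndarray
    dA0n: np.ndarray
    dbetan: np.ndarray
    # per-half-node geometry (index g holds the half node between g and g+1)
    A0h: np.ndarray
    betah: np.ndarray
    dA0h: np.ndarray
    dbetah: np.ndarray
    # couplers
    ctype: np.ndarray        # (nc,)
    cfaces: np.ndarray       # (nc, 3) global node index of each face, -1 pad
    cneigh: np.ndarray       # (nc, 3) interior neighbour node index
    cdir: np.ndarray         # (nc, 3) +1 distal-end face, -1 proximal-end face
    cdx: np.ndarray          # (nc, 3) grid spacing of each face's tube
    cnf: np.ndarray          # (nc,) number of faces
    cterm: np.ndarray        # (nc,) terminal index or -1
    csten: np.ndarray        # (nc,) stenosis-element index or -1
    coupler_names: list[str]
    # terminals (ordered)
    terminal_ids: list[str]
    tR1: np.ndarray
    tR2: np.ndarray
    tC: np.ndarray
    tPv: np.ndarray
    # stenosis elements (ordered)
    sten_geoms: list[StenosisGeometry] = field(default_factory=list)
    sVisc: np.ndarray = None
    sTurb: np.ndarray = None
    sInert: np.ndarray = None

    # ------------------------------------------------------------------
    def tubes_of(self, segment_id: str) -> list[Tube]:
        return [t for t in self.tubes if t.segment_id == segment_id]

    def node_at(self, segment_id: str, x: float, side: str = "nearest") -> int:
        """Global node index nearest to position x (cm) in a segment.

        ``side`` resolves ties at an intervention cut: "distal" prefers
        the tube starting at x (the stump side distal to a clamp),
        "proximal" the tube ending at x.
        """
        cands = []
        for t in self.tubes_of(segment_id):
            if t.x_lo - 1e-9 <= x <= t.x_hi + 1e-9:
                cands.append(t)
        if not cands:
            raise KeyError(f"position {x} cm is not on the grid of segment {segment_id!r}")
        if side == "distal":
            tube = max(cands, key=lambda t: t.x_lo)
        elif side == "proximal":
            tube = min(cands, key=lambda t: t.x_lo)
        else:
            tube = cands[0]
        i = int(round((x - tube.x_lo) / tube.dx))
        i = min(max(i, 0), tube.n - 1)
        return tube.start + i

    def terminal_face_node(self, segment_id: str) -> int:
        """Global node index of the boundary node feeding a terminal."""
        idx = self.terminal_ids.index(segment_id)
        for c in range(len(self.ctype)):
            if self.ctype[c] == TERMINAL and self.cterm[c] == idx:
                return int(self.cfaces[c, 0])
        raise KeyError(f"no terminal coupler for segment {segment_id!r}")

    def segment_mid_node(self, segment_id: str) -> int:
        """Node nearest the axial midpoint of a (possibly split) segment."""
        seg = self.net.segments[segment_id]
        return self.node_at(segment_id, seg.length / 2.0)


def _node_geometry(seg, net, x):
    a0 = seg.area0_at(x)
    beta = seg.beta_at(x)
    drdx = (seg.radius_dist - seg.radius_prox) / seg.length
    da0 = 2.0 * math.pi * seg.radius_at(x) * drdx
    dbeta = -beta / a0 * da0
    return a0, beta, da0, dbeta


def discretize(net: ArterialNetwork, dx_target: float) -> DiscreteModel:
    """Build the flat-array model. Interventions are resolved here."""
    # ---- collect cut events per segment -------------------------------
    # event: (x_lo, x_hi, kind, payload); kind in {"clamp", "stenosis", "occlusion"}
    events: dict[str, list[tuple[float, float, str, object]]] = {}
    for spec in net.clamps:
        x = spec.position_mm * MM
        events.setdefault(spec.segment_id, []).append((x, x, "clamp", spec))
    for spec in net.stenoses:
        if spec.ratio == 0.0:
            continue  # hemodynamically inert
        x0 = spec.start_offset_mm * MM
        x1 = x0 + spec.length_mm * MM
        kind = "occlusion" if spec.ratio >= 1.0 else "stenosis"
        events.setdefault(spec.segment_id, []).append((x0, x1, kind, spec))
    for seg_id, evs in events.items():
        evs.sort(key=lambda e: e[0])
        for (a0, a1, *_), (b0, b1, *_) in zip(evs, evs[1:]):
            if b0 < a1 - 1e-12:
                raise NetworkValidationError(
                    f"overlapping interventions on segment {seg_id!r}"
                )
        seg = net.segments[seg_id]
        if evs[0][0] <= 1e-12 or evs[-1][1] >= seg.length - 1e-12:
            raise NetworkValidationError(
                f"intervention on segment {seg_id!r} touches a segment end; "
                "cannot clamp or narrow a terminal-only stub"
            )

    # ---- build tubes ---------------------------------------------------
    tubes: list[Tube] = []
    seg_first_tube: dict[str, int] = {}
    seg_last_tube: dict[str, int] = {}
    internal: list[tuple[int, int, str, object]] = []  # (tube_L, tube_R, kind, payload)
    offset = 0
    for seg_id, seg in net.segments.items():
        spans: list[float] = [0.0]
        kinds: list[tuple[str, object]] = []
        for x0, x1, kind, payload in events.get(seg_id, []):
            spans.extend([x0, x1])
            kinds.append((kind, payload))
        spans.append(seg.length)
        first_idx = len(tubes)
        for p in range(0, len(spans), 2):
            lo, hi = spans[p], spans[p + 1]
            length = hi - lo
            n = max(MIN_NODES, int(round(length / dx_target)) + 1)
            dx = length / (n - 1)
            tubes.append(Tube(seg_id, lo, hi, offset, n, dx))
            offset += n
        seg_first_tube[seg_id] = first_idx
        seg_last_tube[seg_id] = len(tubes) - 1
        for j, (kind, payload) in enumerate(kinds):
            internal.append((first_idx + j, first_idx + j + 1, kind, payload))

    n_nodes = offset
    ntubes = len(tubes)
    tube_start = np.array([t.start for t in tubes], dtype=np.int64)
    tube_n = np.array([t.n for t in tubes], dtype=np.int64)
    tube_dx = np.array([t.dx for t in tubes], dtype=np.float64)
    tube_alpha = np.empty(ntubes)
    tube_KR = np.empty(ntubes)

    A0n = np.empty(n_nodes)
    betan = np.empty(n_nodes)
    dA0n = np.empty(n_nodes)
    dbetan = np.empty(n_nodes)
    for k, t in enumerate(tubes):
        seg = net.segments[t.segment_id]
        tube_alpha[k] = seg.alpha
        tube_KR[k] = net.friction_coeff(seg)
        for i in range(t.n):
            x = t.x_lo + i * t.dx
            A0n[t.start + i], betan[t.start + i], dA0n[t.start + i], dbetan[t.start + i] = \
                _node_geometry(seg, net, x)

    # half-node geometry: arithmetic averages of the adjacent nodes (this
    # exact choice makes the rest state discretely well-balanced)
    A0h = np.empty(n_nodes)
    betah = np.empty(n_nodes)
    dA0h = np.empty(n_nodes)
    dbetah = np.empty(n_nodes)
    for t in tubes:
        s, e = t.start, t.start + t.n - 1
        A0h[s:e] = 0.5 * (A0n[s:e] + A0n[s + 1:e + 1])
        betah[s:e] = 0.5 * (betan[s:e] + betan[s + 1:e + 1])
        dA0h[s:e] = 0.5 * (dA0n[s:e] + dA0n[s + 1:e + 1])
        dbetah[s:e] = 0.5 * (dbetan[s:e] + dbetan[s + 1:e + 1])
        A0h[e] = betah[e] = dA0h[e] = dbetah[e] = np.nan  # last index unused

    # ---- face bookkeeping ---------------------------------------------
    def face(tube_idx: int, end: str) -> tuple[int, int, int, float]:
        t = tubes[tube_idx]
        if end == "proximal":
            return t.start, t.start + 1, -1, t.dx
        return t.start + t.n - 1, t.start + t.n - 2, +1, t.dx

    covered: set[tuple[int, str]] = set()

    ctype_l, cfaces_l, cneigh_l, cdir_l, cdx_l, cterm_l, csten_l, cname_l = \
        [], [], [], [], [], [], [], []

    def add_coupler(kind, faces, name, term=-1, sten=-1):
        fx = [-1, -1, -1]
        nb = [-1, -1, -1]
        dr = [0, 0, 0]
        dxs = [1.0, 1.0, 1.0]
        for i, f in enumerate(faces):
            fx[i], nb[i], dr[i], dxs[i] = f
        ctype_l.append(kind)
        cfaces_l.append(fx)
        cneigh_l.append(nb)
        cdir_l.append(dr)
        cdx_l.append(dxs)
        cterm_l.append(term)
        csten_l.append(sten)
        cname_l.append(name)

    # inflow
    root_tube = seg_first_tube[net.inflow_segment]
    add_coupler(INFLOW, [face(root_tube, "proximal")], "inflow")
    covered.add((root_tube, "proximal"))

    # terminals
    terminal_ids = list(net.terminals.keys())
    tR1 = np.array([net.terminals[i].R1 for i in terminal_ids])
    tR2 = np.array([net.terminals[i].R2 for i in terminal_ids])
    tC = np.array([net.terminals[i].C for i in terminal_ids])
    tPv = np.array([net.terminals[i].Pv for i in terminal_ids])
    for ti, seg_id in enumerate(terminal_ids):
        tb = seg_last_tube[seg_id]
        add_coupler(TERMINAL, [face(tb, "distal")], f"terminal:{seg_id}", term=ti)
        covered.add((tb, "distal"))

    # network junctions
    for j in net.junctions:
        faces = []
        for seg_id, end in j.attached:
            tb = seg_first_tube[seg_id] if end == "proximal" else seg_last_tube[seg_id]
            faces.append(face(tb, end))
            covered.add((tb, end))
        add_coupler(JUNCTION, faces, f"junction:{j.node_id}")

    # internal interfaces from interventions
    sten_geoms: list[StenosisGeometry] = []
    sA_l, sB_l, sC_l = [], [], []
    for tube_L, tube_R, kind, payload in internal:
        fL = face(tube_L, "distal")
        fR = face(tube_R, "proximal")
        covered.add((tube_L, "distal"))
        covered.add((tube_R, "proximal"))
        if kind in ("clamp", "occlusion"):
            tag = "clamp" if kind == "clamp" else "occlusion"
            add_coupler(REFLECT, [fL], f"{tag}:{payload.segment_id}:prox_face")
            add_coupler(REFLECT, [fR], f"{tag}:{payload.segment_id}:dist_face")
        else:
            host = net.segments[payload.segment_id]
            geo = resolve_geometry(payload, host)
            a, b, c = pressure_drop_coefficients(geo, net.rho, net.mu)
            si = len(sten_geoms)
            sten_geoms.append(geo)
            sA_l.append(a)
            sB_l.append(b)
            sC_l.append(c)
            add_coupler(STENOSIS, [fL, fR], f"stenosis:{payload.segment_id}", sten=si)

    # every face must be coupled exactly once
    for k in range(ntubes):
        for end in ("proximal", "distal"):
            if (k, end) not in covered:
                raise NetworkValidationError(
                    f"tube {k} of segment {tubes[k].segment_id!r}: {end} face uncoupled"
                )

    return DiscreteModel(
        net=net,
        tubes=tubes,
        n_nodes=n_nodes,
        tube_start=tube_start,
        tube_n=tube_n,
        tube_dx=tube_dx,
        tube_alpha=tube_alpha,
        tube_KR=tube_KR,
        A0n=A0n, betan=betan, dA0n=dA0n, dbetan=dbetan,
        A0h=A0h, betah=betah, dA0h=dA0h, dbetah=dbetah,
        ctype=np.array(ctype_l, dtype=np.int64),
        cfaces=np.array(cfaces_l, dtype=np.int64),
        cneigh=np.array(cneigh_l, dtype=np.int64),
        cdir=np.array(cdir_l, dtype=np.int64),
        cdx=np.array(cdx_l, dtype=np.float64),
        cnf=np.array([sum(1 for x in f if x >= 0) for f in cfaces_l], dtype=np.int64),
        cterm=np.array(cterm_l, dtype=np.int64),
        csten=np.array(csten_l, dtype=np.int64),
        coupler_names=cname_l,
        terminal_ids=terminal_ids,
        tR1=tR1, tR2=tR2, tC=tC, tPv=tPv,
        sten_geoms=sten_geoms,
        sVisc=np.array(sA_l, dtype=np.float64),
        sTurb=np.array(sB_l, dtype=np.float64),
        sInert=np.array(sC_l, dtype=np.float64),
    )
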