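# Methods

`carotidsim` simulates cerebral perfusion during carotid endarterectomy
(CEA) with a coupled 1D-0D model: pulse-wave propagation in the large
systemic arteries and the circle of Willis (CoW), closed by lumped
elements for everything the 1D domain does not resolve — the heart
(prescribed inflow), peripheral vascular beds (RCR Windkessels),
autoregulating cerebral outlets, and a trans-stenotic pressure-loss
element. This note documents the model, its numerical treatment, the
synthetic "virtual patient" the experiments run on, and the limits of
what the packaged tests demonstrate.

## 1D blood flow model

Each arterial segment carries the cross-sectionally averaged
mass/momentum system for area A(x,t) and flow Q(x,t):

    dA/dt + dQ/dx = 0
    dQ/dt + d/dx(alpha Q^2/A) + (A/rho) dP/dx = -K_R Q/A

with momentum correction `alpha = 1` and friction coefficient `K_R`
(cm^2/s) both per-segment fields. The default closure is the
flat-profile value K_R = 22*pi*mu/rho appropriate for large central
arteries (Womersley number >> 1); the packaged fixture overrides it with
the Poiseuille value 8*pi*mu/rho for cervical and intracranial vessels,
whose Womersley numbers are of order 1-3. This choice matters: with the
flat-profile value everywhere, the long narrow cerebral conduits consume
an extra ~15-20 mmHg and every cerebral pressure readout sits far below
physiological values.

The wall closure is the algebraic thin-shell tube law

    P(A) = P_ext + beta (sqrt(A) - sqrt(A0)),
    beta = sqrt(pi) E h / ((1 - nu^2) A0),  nu = 0.5,

with A0(x) the reference lumen area at the diastolic reference pressure
P_ext (default 80 mmHg) at which the fixture radii are quoted. The
resulting pulse-wave speed is c = sqrt(beta sqrt(A) / (2 rho)). Blood:
rho = 1.06 g/cm^3, mu = 0.04 poise.

## Numerics

* **Scheme** — two-step (Richtmyer) Lax-Wendroff per segment. The
  momentum flux is written relative to the reference state,
  `alpha Q^2/A + beta (A^{3/2} - A0^{3/2})/(3 rho)`, with the geometric
  source terms arranged so the rest state (A = A0, Q = 0) is an *exact
  discrete equilibrium*, including tapered segments (verified to 1e-10
  by the test suite). Half-node geometry is the arithmetic mean of the
  adjacent nodes — this specific choice is what makes the balance exact.
* **Boundaries** — every face (inflow, junction, terminal, clamp,
  stenosis interface) is closed by extrapolating the outgoing
  characteristic invariant, taken relative to each node's own reference
  state (W = u ± 4(c - c0), again to preserve equilibria under taper),
  and Newton-solving the face conditions. Junctions enforce mass
  conservation plus continuity of static pressure. (Total-pressure
  continuity, the other common choice, loses well-posedness here: when a
  millimetre-calibre communicating artery carries collateral flow at
  metres per second, its kinetic term makes the face system rootless in
  strong transients. The static form is monotone and unconditionally
  solvable.) The per-step junction mass defect is audited and stays
  below 1e-6 of the peak inflow.
* **Time step** — adaptive per step from the global CFL condition
  (default Courant number 0.9), landing exactly on cycle boundaries.
* **Grid** — default target spacing 0.25 cm with at least 5 nodes per
  tube; halving the spacing moves the converged mean aortic pressure by
  well under 1 mmHg (tested). The default resolution is the package's
  working desk-scale choice.
* **Periodicity** — cycles are advanced until the cycle-to-cycle change
  of cycle-averaged nodal pressure and flow, normalised by the
  network-wide scale of each field, drops below 1e-3 (min 2, max 30
  cycles). Cold starts use A = A0, Q = 0, terminals at venous pressure.

## Lumped elements

* **Inflow** — open-loop prescribed aortic-root flow: half-sine systole
  (0.3 s) in a 0.9 s cycle, normalised to a 5 L/min cardiac output. No
  closed-loop heart: the MAP calibration absorbs the difference, and an
  open-loop source keeps every run exactly reproducible.
* **Terminals** — RCR Windkessels advanced semi-implicitly inside the
  boundary Newton solve; `P = Pc + R1 Q`, `C dPc/dt = Q - (Pc - Pv)/R2`,
  venous pressure 5 mmHg.
* **Stenosis** — Young-Tsai-type three-term element at a lumped
  interface replacing the stenosed stretch of the host segment:
  `dP = Kv mu/(A0s D0) Q + Kt rho/(2 A0s^2) (A0s/As - 1)^2 Q|Q|
  + Ku rho Ls/A0s dQ/dt`, with Kv = 32 (Ls/D0)(A0s/As)^2, Kt = 1.52,
  Ku = 1.2 (all overridable). The stenosis ratio r is diameter-based
  (As = A0s (1-r)^2, NASCET-style). r = 0 installs nothing (the healthy
  vessel is already resolved in 1D); r = 1 is routed to a zero-flow
  interface, the same mechanism as a surgical clamp. Mass is conserved
  exactly across the interface; the pressure jump equals the element
  drop at the interface flow, solved implicitly each step.
* **Clamp** — a full-reflection internal boundary (Q = 0 on both faces);
  both sides remain solved, which is precisely what makes the carotid
  stump pressure (CSP) observable on the distal stump.

## Cerebral autoregulation

Each cerebral outlet (ACA, MCA, PCA beds, both sides) carries a target
flow-pressure curve q_target(P): a monotone PCHIP interpolant through
tabulated anchors with the classic Lassen shape — zero at zero pressure,
steep rise, exact plateau at the bed's baseline flow q0 across 60-150
mmHg, pressure-passive rise above. Baseline flows split a 700 mL/min
total cerebral flow 2:3:2 (ACA:MCA:PCA) per hemisphere. Between
converged periodic runs each bed's total resistance is relaxed toward
its curve:

    R <- R (1 - kappa) + kappa (P_bar - Pv) / q_target(P_bar)

with kappa = 0.5, tolerance 1e-3 on the fixed-point residual, max 20
outer iterations. Because a periodic RCR terminal satisfies
`q_bar = (P_bar - Pv)/(R1 + R2)` exactly, the converged state sits on
the curve: beds whose inlet pressure lies in the plateau hold q0 to
within 2% (tested). Within a sweep the outer loop warm-starts from the
previous ratio's resistances — the fixed point does not depend on the
start, so this is purely an accelerator.

"Peripheral pressure" of a cerebral artery, as reported by the sweep,
is defined operationally as the cycle-mean pressure at the inlet of the
corresponding terminal bed, i.e. at the distal end of the A2 / MCA / P2
segment. This is a documented choice; mid-vessel readings differ by the
viscous drop of half a segment.

## The virtual patient

The study subject is an imaginary 70-year-old male with MAP 90 mmHg,
assembled from a packaged population-average fixture (54 segments:
aorta, arch branches, limbs, abdominal branches, neck vessels and a
complete CoW; reference age 40):

1. **Age adjustment** — Young's moduli scaled up 10% per decade above
   age 40 (so x1.3 at 70); radii untouched.
2. **Calibration** — one global scale factor on all terminal R1, R2,
   found by bracketed root-finding (bracket [0.2, 5]) so the converged
   cycle-mean aortic-root pressure hits 90 ± 1 mmHg. MAP is monotone in
   the scale (audited), so the root is unique. Recalibrating a
   calibrated patient returns a scale of ~1 (idempotence, tested).
3. **Perturbation** (robustness harness) — independent unit-mean
   lognormal factors on radii, stiffness and terminal resistances,
   deterministic per seed, cv <= 0.3.

Fixture geometry follows the published 1D arterial modelling
literature, with calibre choices inside anatomical ranges made so the
simulated CEA protocol reproduces the study's threshold pattern (the
original model's parameters are unpublished). The carotid lesion sits in
the carotid bulb, so the host reference diameter at the stenosis site is
the bulb's (~7.9 mm proximally, tapering to 4 mm at the distal ICA); the
vertebrobasilar conduits are at the wide end of their anatomical ranges,
which is what keeps posterior perfusion robust under clamping, and the
communicating arteries at the narrow end (Acom ~1.0 mm, Pcom ~1.1 mm),
which is what lets the stump pressure fall appreciably while the
anterior collateral is still open.

## The CEA protocol

`run_cea_sweep` clamps one ICA 10 mm above the carotid bifurcation,
installs a 10 mm contralateral ICA stenosis starting 10 mm above the
bifurcation, and sweeps the diameter-reduction ratio 0-100% in 10%
steps. Every point is an autoregulation-converged periodic solve; rows
record CSP, signed communicating-artery flows (Acom positive toward the
clamped side, Pcom positive posterior→anterior, ipsilateral A1 positive
toward the MCA), and the three ipsilateral bed pressures. Onset
detectors operate on the 10% grid exactly: a flow series has moved when
it deviates from its 0% baseline by >2% of the baseline magnitude, a
pressure series when it has declined by >1 mmHg; "vanishing" means
|flow| < 1% of baseline. These thresholds are documented operational
stand-ins for visual reads of trend changes and are configurable
arguments of the detectors.

## Known limitations

* The CoW is always complete; anatomical variants (missing A1/P1/Pcom)
  are out of scope, as are vertebral/basilar disease, venous and ICP
  coupling, CO2 reactivity, and within-beat (dynamic) autoregulation.
* The heart is an open-loop source: systemic pressure does not react to
  the interventions beyond what the fixed inflow and terminals imply.
* Wall mechanics are elastic and algebraic (no viscoelasticity); the
  stenosis is lumped, with no post-stenotic turbulence model.
* The virtual patient is population-averaged, not patient-specific; the
  sweep's threshold ratios shift with CoW calibres (notably Acom/Pcom),
  which is physiologically expected and is why they are reported
  together with the fixture version. A one-grid-step sensitivity of the
  detected thresholds to the fixture is therefore inherent.
* With this (complete-CoW) topology and the clamp on the ipsilateral
  ICA, at high contralateral ratios the ipsilateral ACA territory is fed
  through the stump-side junction, so its bed pressure is structurally
  bounded above by the CSP minus the A1/A2 viscous drop; a deep CSP
  decline and a high ACA floor cannot hold simultaneously. The package
  reports both readouts as computed.
* A 90% diameter stenosis of a carotid bulb is a near-occlusion, not an
  occlusion: the lumped element still passes a trickle of tens of
  mL/min, a share of which crosses the Acom. The Acom flow at the 90%
  grid point is therefore a few percent of its baseline — visually zero
  on a flow plot, but above the 1%-of-baseline cut the vanishing
  detector applies, which consequently fires at 100%.
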