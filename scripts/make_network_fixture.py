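#!/usr/bin/env python
"""Regenerate the packaged population-average arterial network fixture.

The tree covers the major systemic arteries (aorta, arch branches, limbs,
abdominal branches) plus the cervical and intracranial vessels forming a
complete circle of Willis. Geometry (lengths, radii) follows
population-averaged values from the 1D arterial modelling literature;
wall stiffness is specified through a target reference pulse-wave speed
per vessel and converted to an equivalent Young's modulus. Terminal RCR
elements are sized from target organ flows at a 90 mmHg mean arterial
pressure: R1 matches the characteristic impedance of the feeding vessel,
R2 takes the remainder, and C sets a 1.3 s Windkessel decay.

Run from the repository root:

    python scripts/make_network_fixture.py
"""

import json
import math
from pathlib import Path

RHO = 1.06      # g/cm^3
MU = 0.04       # poise
MMHG = 1333.22
MAP_TARGET = 90.0   # mmHg, design point for terminal resistances
PV = 5.0 * MMHG     # venous pressure
TAU = 1.3           # s, terminal Windkessel decay time R2*C
CO = 5000.0 / 60.0  # cm^3/s

# name, length (cm), r_prox, r_dist (cm), c0 (cm/s, reference wave speed),
# wall thickness fraction of mean radius
SEGMENTS = [
    # aorta
    ("AscAo",          4.0, 1.450, 1.400, 470, 0.10),
    ("AoArch1",        2.0, 1.300, 1.280, 480, 0.10),
    ("AoArch2",        3.9, 1.270, 1.220, 480, 0.10),
    ("ThorAo1",        5.2, 1.200, 1.120, 500, 0.10),
    ("ThorAo2",       10.4, 1.100, 1.000, 510, 0.10),
    ("AbdAo1",         5.3, 0.950, 0.900, 520, 0.11),
    ("AbdAo2",         1.0, 0.880, 0.860, 520, 0.11),
    ("AbdAo3",         1.0, 0.850, 0.830, 530, 0.11),
    ("AbdAo4",        10.6, 0.820, 0.750, 540, 0.11),
    ("AbdAo5",         1.0, 0.730, 0.720, 540, 0.11),
    # arch branches and upper limbs
    ("Brachiocephalic", 3.4, 0.700, 0.650, 500, 0.12),
    ("R_Subclavian",   3.4, 0.450, 0.420, 520, 0.13),
    ("L_Subclavian",   3.4, 0.450, 0.420, 520, 0.13),
    ("R_Brachial",    42.2, 0.400, 0.300, 560, 0.14),
    ("L_Brachial",    42.2, 0.400, 0.300, 560, 0.14),
    ("R_Radial",      23.5, 0.170, 0.170, 700, 0.20),
    ("L_Radial",      23.5, 0.170, 0.170, 700, 0.20),
    ("R_Ulnar",       23.9, 0.190, 0.190, 700, 0.20),
    ("L_Ulnar",       23.9, 0.190, 0.190, 700, 0.20),
    # abdominal branches
    ("Celiac",         2.0, 0.350, 0.350, 520, 0.16),
    ("SMA",            5.9, 0.400, 0.400, 520, 0.16),
    ("R_Renal",        3.2, 0.280, 0.280, 520, 0.16),
    ("L_Renal",        3.2, 0.280, 0.280, 520, 0.16),
    ("IMA",            5.0, 0.200, 0.200, 560, 0.16),
    # pelvis and lower limbs
    ("R_CommonIliac",  5.8, 0.400, 0.370, 560, 0.13),
    ("L_CommonIliac",  5.8, 0.400, 0.370, 560, 0.13),
    ("R_ExternalIliac", 14.4, 0.320, 0.290, 600, 0.14),
    ("L_ExternalIliac", 14.4, 0.320, 0.290, 600, 0.14),
    ("R_Femoral",     44.3, 0.260, 0.190, 650, 0.15),
    ("L_Femoral",     44.3, 0.260, 0.190, 650, 0.15),
    # neck
    ("R_CCA",         17.7, 0.250, 0.250, 600, 0.15),
    ("L_CCA",         17.7, 0.250, 0.250, 600, 0.15),
    ("R_ECA",         17.7, 0.150, 0.150, 650, 0.20),
    ("L_ECA",         17.7, 0.150, 0.150, 650, 0.20),
    ("R_ICA",         17.7, 0.395, 0.200, 650, 0.18),
    ("L_ICA",         17.7, 0.395, 0.200, 650, 0.18),
    ("R_ICA_term",     0.5, 0.200, 0.200, 800, 0.22),
    ("L_ICA_term",     0.5, 0.200, 0.200, 800, 0.22),
    ("R_VA",          14.8, 0.175, 0.175, 800, 0.22),
    ("L_VA",          14.8, 0.175, 0.175, 800, 0.22),
    # circle of Willis and cerebral arteries
    ("BA",             2.9, 0.170, 0.170, 800, 0.25),
    ("R_MCA",         11.9, 0.143, 0.143, 850, 0.25),
    ("L_MCA",         11.9, 0.143, 0.143, 850, 0.25),
    ("R_ACA_A1",       1.2, 0.117, 0.117, 850, 0.25),
    ("L_ACA_A1",       1.2, 0.117, 0.117, 850, 0.25),
    ("R_ACA_A2",      10.3, 0.120, 0.120, 850, 0.25),
    ("L_ACA_A2",      10.3, 0.120, 0.120, 850, 0.25),
    ("R_PCA_P1",       1.2, 0.0865, 0.0865, 850, 0.25),
    ("L_PCA_P1",       1.2, 0.0865, 0.0865, 850, 0.25),
    ("R_PCA_P2",       6.0, 0.115, 0.115, 850, 0.25),
    ("L_PCA_P2",       6.0, 0.115, 0.115, 850, 0.25),
    ("Acom",           0.5, 0.049, 0.049, 850, 0.25),
    ("R_Pcom",         1.5, 0.0545, 0.0545, 850, 0.25),
    ("L_Pcom",         1.5, 0.0545, 0.0545, 850, 0.25),
]

# junctions: (node id, [(segment, end), ...])
JUNCTIONS = [
    ("jArch1",  [("AscAo", "distal"), ("AoArch1", "proximal"), ("Brachiocephalic", "proximal")]),
    ("jArch2",  [("AoArch1", "distal"), ("AoArch2", "proximal"), ("L_CCA", "proximal")]),
    ("jArch3",  [("AoArch2", "distal"), ("ThorAo1", "proximal"), ("L_Subclavian", "proximal")]),
    ("jBrachio", [("Brachiocephalic", "distal"), ("R_Subclavian", "proximal"), ("R_CCA", "proximal")]),
    ("jRsub",   [("R_Subclavian", "distal"), ("R_VA", "proximal"), ("R_Brachial", "proximal")]),
    ("jLsub",   [("L_Subclavian", "distal"), ("L_VA", "proximal"), ("L_Brachial", "proximal")]),
    ("jRarm",   [("R_Brachial", "distal"), ("R_Radial", "proximal"), ("R_Ulnar", "proximal")]),
    ("jLarm",   [("L_Brachial", "distal"), ("L_Radial", "proximal"), ("L_Ulnar", "proximal")]),
    ("jThor",   [("ThorAo1", "distal"), ("ThorAo2", "proximal")]),
    ("jCeliac", [("ThorAo2", "distal"), ("AbdAo1", "proximal"), ("Celiac", "proximal")]),
    ("jSMA",    [("AbdAo1", "distal"), ("AbdAo2", "proximal"), ("SMA", "proximal")]),
    ("jRRenal", [("AbdAo2", "distal"), ("AbdAo3", "proximal"), ("R_Renal", "proximal")]),
    ("jLRenal", [("AbdAo3", "distal"), ("AbdAo4", "proximal"), ("L_Renal", "proximal")]),
    ("jIMA",    [("AbdAo4", "distal"), ("AbdAo5", "proximal"), ("IMA", "proximal")]),
    ("jBifAo",  [("AbdAo5", "distal"), ("R_CommonIliac", "proximal"), ("L_CommonIliac", "proximal")]),
    ("jRIl",    [("R_CommonIliac", "distal"), ("R_ExternalIliac", "proximal")]),
    ("jLIl",    [("L_CommonIliac", "distal"), ("L_ExternalIliac", "proximal")]),
    ("jRFem",   [("R_ExternalIliac", "distal"), ("R_Femoral", "proximal")]),
    ("jLFem",   [("L_ExternalIliac", "distal"), ("L_Femoral", "proximal")]),
    ("jRcar",   [("R_CCA", "distal"), ("R_ICA", "proximal"), ("R_ECA", "proximal")]),
    ("jLcar",   [("L_CCA", "distal"), ("L_ICA", "proximal"), ("L_ECA", "proximal")]),
    ("jRica",   [("R_ICA", "distal"), ("R_Pcom", "proximal"), ("R_ICA_term", "proximal")]),
    ("jLica",   [("L_ICA", "distal"), ("L_Pcom", "proximal"), ("L_ICA_term", "proximal")]),
    ("jRtop",   [("R_ICA_term", "distal"), ("R_MCA", "proximal"), ("R_ACA_A1", "proximal")]),
    ("jLtop",   [("L_ICA_term", "distal"), ("L_MCA", "proximal"), ("L_ACA_A1", "proximal")]),
    ("jAcomR",  [("R_ACA_A1", "distal"), ("Acom", "proximal"), ("R_ACA_A2", "proximal")]),
    ("jAcomL",  [("L_ACA_A1", "distal"), ("Acom", "distal"), ("L_ACA_A2", "proximal")]),
    ("jBA",     [("R_VA", "distal"), ("L_VA", "distal"), ("BA", "proximal")]),
    ("jBasTop", [("BA", "distal"), ("R_PCA_P1", "proximal"), ("L_PCA_P1", "proximal")]),
    ("jRpca",   [("R_PCA_P1", "distal"), ("R_Pcom", "distal"), ("R_PCA_P2", "proximal")]),
    ("jLpca",   [("L_PCA_P1", "distal"), ("L_Pcom", "distal"), ("L_PCA_P2", "proximal")]),
]

# terminal flows in mL/min at the 90 mmHg design point; cerebral beds
# split 700 mL/min total cerebral flow 2:3:2 (ACA:MCA:PCA) per hemisphere
TERMINAL_FLOWS = {
    "R_ECA": 150.0, "L_ECA": 150.0,
    "R_Radial": 150.0, "L_Radial": 150.0,
    "R_Ulnar": 200.0, "L_Ulnar": 200.0,
    "Celiac": 700.0, "SMA": 700.0,
    "R_Renal": 550.0, "L_Renal": 550.0,
    "IMA": 160.0,
    "R_Femoral": 320.0, "L_Femoral": 320.0,
    "R_MCA": 150.0, "L_MCA": 150.0,
    "R_ACA_A2": 100.0, "L_ACA_A2": 100.0,
    "R_PCA_P2": 100.0, "L_PCA_P2": 100.0,
}
CEREBRAL_BEDS = {"R_MCA", "L_MCA", "R_ACA_A2", "L_ACA_A2", "R_PCA_P2", "L_PCA_P2"}


# Cervical and intracranial vessels have Womersley numbers of order 1-3,
# so their friction uses the Poiseuille closure K_R = 8*pi*mu/rho instead
# of the flat-profile large-artery value 22*pi*mu/rho (the loader default).
POISEUILLE_KR = {
    "R_CCA", "L_CCA", "R_ECA", "L_ECA", "R_ICA", "L_ICA",
    "R_ICA_term", "L_ICA_term", "R_VA", "L_VA", "BA",
    "R_MCA", "L_MCA", "R_ACA_A1", "L_ACA_A1", "R_ACA_A2", "L_ACA_A2",
    "R_PCA_P1", "L_PCA_P1", "R_PCA_P2", "L_PCA_P2",
    "Acom", "R_Pcom", "L_Pcom",
}


def build() -> dict:
    segments = []
    seg_lookup = {}
    for name, L, rp, rd, c0, hfrac in SEGMENTS:
        rmean = 0.5 * (rp + rd)
        a0 = math.pi * rmean * rmean
        h = hfrac * rmean
        # c0^2 = sqrt(pi)*E*h / (1.5 * rho * sqrt(A0))  (nu = 0.5 tube law)
        Eh = 1.5 * RHO * math.sqrt(a0) * c0 * c0 / math.sqrt(math.pi)
        E = Eh / h
        rec = {
            "id": name,
            "name": name,
            "length_cm": L,
            "r_prox_cm": rp,
            "r_dist_cm": rd,
            "h_cm": round(h, 5),
            "E_dyn_cm2": round(E, 1),
            "alpha": 1.0,
        }
        if name in POISEUILLE_KR:
            rec["K_R_cm2_s"] = round(8.0 * math.pi * MU / RHO, 6)
        segments.append(rec)
        seg_lookup[name] = (rec, c0)

    total_q = sum(TERMINAL_FLOWS.values())
    assert abs(total_q - 5000.0) < 1e-9, total_q

    terminals = []
    for name, q_ml_min in TERMINAL_FLOWS.items():
        q = q_ml_min / 60.0
        r_total = (MAP_TARGET * MMHG - PV) / q
        rec, c0 = seg_lookup[name]
        a0_dist = math.pi * rec["r_dist_cm"] ** 2
        z0 = RHO * c0 / a0_dist
        r1 = min(z0, 0.4 * r_total)
        r2 = r_total - r1
        terminals.append(
            {
                "segment": name,
                "kind": "autoregulating_bed" if name in CEREBRAL_BEDS else "windkessel",
                "R1": round(r1, 1),
                "R2": round(r2, 1),
                "C": round(TAU / r2, 10),
                "Pv": PV,
            }
        )

    return {
        "format": "carotidsim-network",
        "version": "1",
        "comment": "Population-average adult arterial tree with complete circle of Willis; "
                   "reference age 40; radii at diastolic pressure. Regenerate with "
                   "scripts/make_network_fixture.py.",
        "blood": {"rho": RHO, "mu": MU},
        "inflow_segment": "AscAo",
        "segments": segments,
        "junctions": [
            {"node_id": nid, "attached": [list(a) for a in att]} for nid, att in JUNCTIONS
        ],
        "terminals": terminals,
    }


if __name__ == "__main__":
    out = Path(__file__).resolve().parent.parent / "src" / "carotidsim" / "data" / "network_v1.json"
    doc = build()
    out.write_text(json.dumps(doc, indent=1) + "\n")
    print(f"wrote {out} ({len(doc['segments'])} segments, "
          f"{len(doc['junctions'])} junctions, {len(doc['terminals'])} terminals)")
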