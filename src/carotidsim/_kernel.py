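"""Compiled time-stepping kernel for the 1D pulse-wave solver.

Interior nodes are advanced with the two-step (Richtmyer) Lax-Wendroff
scheme applied to the 1D mass/momentum system in the well-balanced flux
form

    dA/dt + dQ/dx = 0
    dQ/dt + d/dx[ alpha*Q^2/A + beta*(A^{3/2} - A0^{3/2})/(3 rho) ] = S

where S carries wall friction and the geometric (taper) terms; the flux
is written relative to the reference state so that A = A0, Q = 0 is an
exact discrete equilibrium. Boundary faces (inflow, junctions, RCR
terminals, clamps, stenosis interfaces) are closed each step with the
outgoing characteristic (Riemann invariant W = u +/- 4c) extrapolated
from the interior plus a Newton solve of the face conditions.

Everything here is numba-compiled; the public API lives in solver.py.
"""

import numpy as np
from numba import njit

# status codes
OK = 0
ERR_NEG_AREA = 1
ERR_NAN = 2
ERR_NEWTON = 3
ERR_REFLECT = 4

INFLOW = 0
JUNCTION = 1
TERMINAL = 2
REFLECT = 3
STENOSIS = 4

NEWTON_TOL = 1e-12
NEWTON_MAXIT = 60


@njit(cache=True, inline="always")
def _wave_speed(A, beta, rho):
    return np.sqrt(beta * np.sqrt(A) / (2.0 * rho))


@njit(cache=True, inline="always")
def _source(A, Q, A0, beta, dA0, dbeta, KR, rho):
    sq = np.sqrt(A)
    sq0 = np.sqrt(A0)
    t1 = dbeta * (A * sq - 3.0 * A * (sq - sq0) - A0 * sq0) / (3.0 * rho)
    t2 = dA0 * beta * (A - A0) / (2.0 * rho * sq0)
    return -KR * Q / A + t1 + t2


@njit(cache=True, inline="always")
def _inflow_q(t, T, Ts, qpeak):
    tau = t % T
    if tau < Ts:
        return qpeak * np.sin(np.pi * tau / Ts)
    return 0.0


@njit(cache=True, inline="always")
def _char_W(A, Q, A0m, betam, Ab, Qb, A0b, beta_b, d, dt, dx, rho):
    """Outgoing characteristic information at a face.

    The invariant is interpolated at the foot of the characteristic
    between the boundary node (Ab, Qb) and its interior neighbour
    (A, Q). In a tapered vessel the invariant is taken relative to each
    node's own reference state, W = u +/- 4*(c - c0), so that the rest
    state carries W = 0 everywhere; the returned value is re-based to
    the face reference (add d*4*c0_face), letting the face conditions
    use u = W - d*4*c(A) unchanged.
    """
    cb = _wave_speed(Ab, beta_b, rho)
    c0b = _wave_speed(A0b, beta_b, rho)
    ub = Qb / Ab
    lam = ub + d * cb
    xi = abs(lam) * dt / dx
    if xi > 1.0:
        xi = 1.0
    if lam * d < 0.0:
        xi = 0.0
    cm = _wave_speed(A, betam, rho)
    c0m = _wave_speed(A0m, betam, rho)
    um = Q / A
    Wb = ub + d * 4.0 * (cb - c0b)
    Wm = um + d * 4.0 * (cm - c0m)
    return (1.0 - xi) * Wb + xi * Wm + d * 4.0 * c0b


@njit(cache=True)
def _gauss_solve(J, F, n):
    """In-place Gaussian elimination with partial pivoting, n <= 3.
    Solution overwrites F. Returns False on a singular pivot."""
    for col in range(n):
        piv = col
        big = abs(J[col, col])
        for r in range(col + 1, n):
            if abs(J[r, col]) > big:
                big = abs(J[r, col])
                piv = r
        if big == 0.0:
            return False
        if piv != col:
            for c in range(n):
                tmp = J[col, c]
                J[col, c] = J[piv, c]
                J[piv, c] = tmp
            tmp = F[col]
            F[col] = F[piv]
            F[piv] = tmp
        for r in range(col + 1, n):
            fac = J[r, col] / J[col, col]
            for c in range(col, n):
                J[r, c] -= fac * J[col, c]
            F[r] -= fac * F[col]
    for col in range(n - 1, -1, -1):
        s = F[col]
        for c in range(col + 1, n):
            s -= J[col, c] * F[c]
        F[col] = s / J[col, col]
    return True


@njit(cache=True)
def advance_cycle(
    A, Q, tPc, sQprev,
    t0, T,
    # tubes
    tube_start, tube_n, tube_dx, tube_alpha, tube_KR,
    # nodal / half-node geometry
    A0n, betan, dA0n, dbetan, A0h, betah, dA0h, dbetah,
    # couplers
    ctype, cfaces, cneigh, cdir, cdx, cnf, cterm, csten,
    # terminals
    tR1, tR2, tC, tPv,
    # stenoses
    sVisc, sTurb, sInert,
    # globals
    rho, p_ext, cfl,
    # inflow
    q_T, q_Ts, q_peak,
    # outputs
    Psum, Qsum, audit,
):
    """Advance the state by exactly one cardiac period.

    Psum/Qsum accumulate time-integrals of nodal pressure and flow over
    the cycle (caller divides by T for cycle means). audit[0] receives
    the max junction mass defect, audit[1] the step count, audit[2] the
    failing node and audit[3] the failure time when status != OK.
    """
    nn = A.shape[0]
    ntubes = tube_start.shape[0]
    ncoup = ctype.shape[0]

    An = np.empty(nn)
    Qn = np.empty(nn)
    Ah = np.empty(nn)
    Qh = np.empty(nn)
    Jm = np.empty((3, 3))
    Fv = np.empty(3)
    Av = np.empty(3)
    Wv = np.empty(3)
    bet = np.empty(3)
    a0f = np.empty(3)

    Psum[:] = 0.0
    Qsum[:] = 0.0
    max_defect = 0.0
    t = t0
    t_end = t0 + T
    steps = 0

    while t < t_end - 1e-12:
        # ---- CFL time step -------------------------------------------
        dt = t_end - t
        for k in range(ntubes):
            s = tube_start[k]
            n = tube_n[k]
            dx = tube_dx[k]
            for i in range(s, s + n):
                a = A[i]
                if not a > 0.0:
                    audit[2] = float(i)
                    audit[3] = t
                    return ERR_NEG_AREA, t
                c = _wave_speed(a, betan[i], rho)
                sp = abs(Q[i] / a) + c
                lim = cfl * dx / sp
                if lim < dt:
                    dt = lim
        if not dt > 0.0:
            audit[3] = t
            return ERR_NAN, t

        # ---- accumulate cycle means (left endpoint rule) -------------
        for i in range(nn):
            p = p_ext + betan[i] * (np.sqrt(A[i]) - np.sqrt(A0n[i]))
            Psum[i] += p * dt
            Qsum[i] += Q[i] * dt

        # ---- prepare new state ---------------------------------------
        for i in range(nn):
            An[i] = A[i]
            Qn[i] = Q[i]

        # ---- couplers -------------------------------------------------
        t_new = t + dt
        for cidx in range(ncoup):
            kind = ctype[cidx]
            nf = cnf[cidx]
            # gather faces and their outgoing characteristic invariants
            for f in range(nf):
                b = cfaces[cidx, f]
                m = cneigh[cidx, f]
                d = cdir[cidx, f]
                bet[f] = betan[b]
                a0f[f] = A0n[b]
                Av[f] = A[b]
                Wv[f] = _char_W(
                    A[m], Q[m], A0n[m], betan[m],
                    A[b], Q[b], a0f[f], bet[f],
                    d, dt, cdx[cidx, f], rho,
                )

            if kind == REFLECT:
                d = cdir[cidx, 0]
                cnew = d * Wv[0] / 4.0
                if cnew <= 0.0:
                    audit[2] = float(cfaces[cidx, 0])
                    audit[3] = t
                    return ERR_REFLECT, t
                anew = (2.0 * rho * cnew * cnew / bet[0]) ** 2
                An[cfaces[cidx, 0]] = anew
                Qn[cfaces[cidx, 0]] = 0.0

            elif kind == INFLOW:
                qin = _inflow_q(t_new, q_T, q_Ts, q_peak)
                a = Av[0]
                ok = False
                for _ in range(NEWTON_MAXIT):
                    c = _wave_speed(a, bet[0], rho)
                    u = Wv[0] + 4.0 * c  # proximal face: d = -1
                    F0 = a * u - qin
                    dF = u + c
                    da = -F0 / dF
                    if da < -0.5 * a:
                        da = -0.5 * a
                    elif da > a:
                        da = a
                    a += da
                    if abs(da) < NEWTON_TOL * a:
                        ok = True
                        break
                if not ok or not a > 0.0:
                    audit[2] = float(cfaces[cidx, 0])
                    audit[3] = t
                    return ERR_NEWTON, t
                c = _wave_speed(a, bet[0], rho)
                An[cfaces[cidx, 0]] = a
                Qn[cfaces[cidx, 0]] = a * (Wv[0] + 4.0 * c)

            elif kind == TERMINAL:
                ti = cterm[cidx]
                R1 = tR1[ti]
                R2 = tR2[ti]
                Cc = tC[ti]
                Pv = tPv[ti]
                Pc = tPc[ti]
                denom = 1.0 + dt / (R2 * Cc)
                a = Av[0]
                ok = False
                for _ in range(NEWTON_MAXIT):
                    c = _wave_speed(a, bet[0], rho)
                    u = Wv[0] - 4.0 * c  # distal face: d = +1
                    q = a * u
                    Pcn = (Pc + dt / Cc * (q + Pv / R2)) / denom
                    P = p_ext + bet[0] * (np.sqrt(a) - np.sqrt(a0f[0]))
                    F0 = P - R1 * q - Pcn
                    dq = u - c
                    dF = bet[0] / (2.0 * np.sqrt(a)) - R1 * dq - (dt / Cc * dq) / denom
                    da = -F0 / dF
                    if da < -0.5 * a:
                        da = -0.5 * a
                    elif da > a:
                        da = a
                    a += da
                    if abs(da) < NEWTON_TOL * a:
                        ok = True
                        break
                if not ok or not a > 0.0:
                    audit[2] = float(cfaces[cidx, 0])
                    audit[3] = t
                    return ERR_NEWTON, t
                c = _wave_speed(a, bet[0], rho)
                q = a * (Wv[0] - 4.0 * c)
                tPc[ti] = (Pc + dt / Cc * (q + Pv / R2)) / denom
                An[cfaces[cidx, 0]] = a
                Qn[cfaces[cidx, 0]] = q

            elif kind == JUNCTION:
                ok = False
                for _ in range(NEWTON_MAXIT):
                    # residuals
                    qsum = 0.0
                    for f in range(nf):
                        d = cdir[cidx, f]
                        c = _wave_speed(Av[f], bet[f], rho)
                        u = Wv[f] - d * 4.0 * c
                        qsum += d * Av[f] * u
                    Fv[0] = qsum
                    # static pressure continuity across the node: with a
                    # kinetic (total-pressure) term the system loses its
                    # root when a small side branch runs fast, so the
                    # static form is used for well-posedness
                    p0 = bet[0] * (np.sqrt(Av[0]) - np.sqrt(a0f[0]))
                    for f in range(1, nf):
                        Fv[f] = bet[f] * (np.sqrt(Av[f]) - np.sqrt(a0f[f])) - p0
                    # Jacobian
                    for r in range(nf):
                        for cc in range(nf):
                            Jm[r, cc] = 0.0
                    for f in range(nf):
                        d = cdir[cidx, f]
                        c = _wave_speed(Av[f], bet[f], rho)
                        u = Wv[f] - d * 4.0 * c
                        dudA = -d * c / Av[f]
                        dQdA = u + Av[f] * dudA
                        Jm[0, f] = d * dQdA
                        dpdA = bet[f] / (2.0 * np.sqrt(Av[f]))
                        if f == 0:
                            for r in range(1, nf):
                                Jm[r, 0] = -dpdA
                        else:
                            Jm[f, f] = dpdA
                    if not _gauss_solve(Jm, Fv, nf):
                        break
                    conv = True
                    for f in range(nf):
                        da = -Fv[f]
                        if da < -0.5 * Av[f]:
                            da = -0.5 * Av[f]
                        elif da > Av[f]:
                            da = Av[f]
                        Av[f] += da
                        if abs(da) > NEWTON_TOL * Av[f]:
                            conv = False
                    if conv:
                        ok = True
                        break
                if not ok:
                    audit[2] = float(cfaces[cidx, 0])
                    audit[3] = t
                    return ERR_NEWTON, t
                defect = 0.0
                for f in range(nf):
                    d = cdir[cidx, f]
                    c = _wave_speed(Av[f], bet[f], rho)
                    u = Wv[f] - d * 4.0 * c
                    q = Av[f] * u
                    defect += d * q
                    An[cfaces[cidx, f]] = Av[f]
                    Qn[cfaces[cidx, f]] = q
                if abs(defect) > max_defect:
                    max_defect = abs(defect)

            elif kind == STENOSIS:
                si = csten[cidx]
                av = sVisc[si]
                bt = sTurb[si]
                ci = sInert[si]
                qprev = sQprev[si]
                ok = False
                for _ in range(NEWTON_MAXIT):
                    cL = _wave_speed(Av[0], bet[0], rho)
                    uL = Wv[0] - 4.0 * cL            # left face is distal (d=+1)
                    cR = _wave_speed(Av[1], bet[1], rho)
                    uR = Wv[1] + 4.0 * cR            # right face is proximal (d=-1)
                    qL = Av[0] * uL
                    qR = Av[1] * uR
                    dP = av * qL + bt * qL * abs(qL) + ci * (qL - qprev) / dt
                    Fv[0] = qL - qR
                    Fv[1] = (
                        bet[0] * (np.sqrt(Av[0]) - np.sqrt(a0f[0]))
                        - bet[1] * (np.sqrt(Av[1]) - np.sqrt(a0f[1]))
                        - dP
                    )
                    duL = -cL / Av[0]
                    dqL = uL + Av[0] * duL
                    duR = cR / Av[1]
                    dqR = uR + Av[1] * duR
                    ddP = (av + 2.0 * bt * abs(qL) + ci / dt) * dqL
                    Jm[0, 0] = dqL
                    Jm[0, 1] = -dqR
                    Jm[1, 0] = bet[0] / (2.0 * np.sqrt(Av[0])) - ddP
                    Jm[1, 1] = -bet[1] / (2.0 * np.sqrt(Av[1]))
                    if not _gauss_solve(Jm, Fv, 2):
                        break
                    conv = True
                    for f in range(2):
                        da = -Fv[f]
                        if da < -0.5 * Av[f]:
                            da = -0.5 * Av[f]
                        elif da > Av[f]:
                            da = Av[f]
                        Av[f] += da
                        if abs(da) > NEWTON_TOL * Av[f]:
                            conv = False
                    if conv:
                        ok = True
                        break
                if not ok:
                    audit[2] = float(cfaces[cidx, 0])
                    audit[3] = t
                    return ERR_NEWTON, t
                cL = _wave_speed(Av[0], bet[0], rho)
                qL = Av[0] * (Wv[0] - 4.0 * cL)
                cR = _wave_speed(Av[1], bet[1], rho)
                qR = Av[1] * (Wv[1] + 4.0 * cR)
                if abs(qL - qR) > max_defect:
                    max_defect = abs(qL - qR)
                sQprev[si] = qL
                An[cfaces[cidx, 0]] = Av[0]
                Qn[cfaces[cidx, 0]] = qL
                An[cfaces[cidx, 1]] = Av[1]
                Qn[cfaces[cidx, 1]] = qR

        # ---- interior Richtmyer update -------------------------------
        # The outermost flux of each tube is the time-centred face flux
        # from the coupler solve rather than a Richtmyer half-flux; at a
        # periodic state this pins the cycle-mean interior flux to the
        # face flux, keeping the network globally mass-conservative.
        for k in range(ntubes):
            s = tube_start[k]
            n = tube_n[k]
            dx = tube_dx[k]
            al = tube_alpha[k]
            kr = tube_KR[k]
            r2dx = dt / (2.0 * dx)
            for i in range(s, s + n - 1):
                A1 = A[i]
                A2 = A[i + 1]
                Q1 = Q[i]
                Q2 = Q[i + 1]
                F1 = al * Q1 * Q1 / A1 + betan[i] * (A1 * np.sqrt(A1) - A0n[i] * np.sqrt(A0n[i])) / (3.0 * rho)
                F2 = al * Q2 * Q2 / A2 + betan[i + 1] * (A2 * np.sqrt(A2) - A0n[i + 1] * np.sqrt(A0n[i + 1])) / (3.0 * rho)
                Ab = 0.5 * (A1 + A2)
                Qb = 0.5 * (Q1 + Q2)
                Ah[i] = Ab - r2dx * (Q2 - Q1)
                Qh[i] = Qb - r2dx * (F2 - F1) + 0.5 * dt * _source(
                    Ab, Qb, A0h[i], betah[i], dA0h[i], dbetah[i], kr, rho
                )
                if not Ah[i] > 0.0:
                    audit[2] = float(i)
                    audit[3] = t
                    return ERR_NEG_AREA, t
            e = s + n - 1
            qfL = 0.5 * (Q[s] + Qn[s])
            ffL = 0.5 * (
                al * Q[s] * Q[s] / A[s]
                + betan[s] * (A[s] * np.sqrt(A[s]) - A0n[s] * np.sqrt(A0n[s])) / (3.0 * rho)
                + al * Qn[s] * Qn[s] / An[s]
                + betan[s] * (An[s] * np.sqrt(An[s]) - A0n[s] * np.sqrt(A0n[s])) / (3.0 * rho)
            )
            qfR = 0.5 * (Q[e] + Qn[e])
            ffR = 0.5 * (
                al * Q[e] * Q[e] / A[e]
                + betan[e] * (A[e] * np.sqrt(A[e]) - A0n[e] * np.sqrt(A0n[e])) / (3.0 * rho)
                + al * Qn[e] * Qn[e] / An[e]
                + betan[e] * (An[e] * np.sqrt(An[e]) - A0n[e] * np.sqrt(A0n[e])) / (3.0 * rho)
            )
            rdx = dt / dx
            for i in range(s + 1, s + n - 1):
                if i == s + 1:
                    qL = qfL
                    fL = ffL
                else:
                    qL = Qh[i - 1]
                    fL = al * Qh[i - 1] * Qh[i - 1] / Ah[i - 1] + betah[i - 1] * (
                        Ah[i - 1] * np.sqrt(Ah[i - 1]) - A0h[i - 1] * np.sqrt(A0h[i - 1])
                    ) / (3.0 * rho)
                if i == s + n - 2:
                    qR = qfR
                    fR = ffR
                else:
                    qR = Qh[i]
                    fR = al * Qh[i] * Qh[i] / Ah[i] + betah[i] * (
                        Ah[i] * np.sqrt(Ah[i]) - A0h[i] * np.sqrt(A0h[i])
                    ) / (3.0 * rho)
                An[i] = A[i] - rdx * (qR - qL)
                Qn[i] = Q[i] - rdx * (fR - fL) + dt * _source(
                    A[i], Q[i], A0n[i], betan[i], dA0n[i], dbetan[i], kr, rho
                )
                if not An[i] > 0.0:
                    audit[2] = float(i)
                    audit[3] = t
                    return ERR_NEG_AREA, t

        # ---- commit ---------------------------------------------------
        for i in range(nn):
            if np.isnan(An[i]) or np.isnan(Qn[i]):
                audit[2] = float(i)
                audit[3] = t
                return ERR_NAN, t
            A[i] = An[i]
            Q[i] = Qn[i]
        t = t_new
        steps += 1

    audit[0] = max_defect
    audit[1] = float(steps)
    return OK, t
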