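"""Explicit 1D pulse-propagation solver for branching elastic-tube networks.

Governing equations (per segment, lumen area A and mean velocity U):

    A_t + (A U)_x = 0
    U_t + (U^2/2 + P/rho)_x = -f U / (rho A)

with the elastic tube law P = p_ref + b(x) (sqrt(A) - sqrt(A_d(x))),
b = beta / A_d, beta = (4/3) sqrt(pi) E h, and wall friction
f = 2 (zeta + 2) pi mu for a prescribed axisymmetric velocity profile.
The local wave speed is c^2 = b sqrt(A) / (2 rho); at the reference area
this equals the Moens-Korteweg speed of an incompressible thin wall.

Discretisation: two-step MacCormack (forward predictor / backward
corrector) on a per-segment uniform grid, CFL-limited global time step.
Boundary and junction nodes are advanced with the Riemann invariants
W+- = U +- 4c of the frozen-coefficient system: prescribed inflow at the
root, RCR Windkessel at each leaf (implicit-Euler compliance update), and
continuity of mass and total pressure at bifurcations/conjunctions solved
by Newton iteration.

Everything in this module is numba-compiled and operates on the flat
arrays assembled by :func:`pulsebench.virtual_cohort.simulate_subject`.
"""

import numpy as np
from numba import njit

STATUS_OK = 0
STATUS_NEGATIVE_AREA = 1


@njit(cache=True, fastmath=False)
def _wave_speed(b, A, rho):
    return np.sqrt(0.5 * b * np.sqrt(A) / rho)


@njit(cache=True, fastmath=False)
def _ptrans(b, A, sqAd):
    # transmural pressure relative to the reference state
    return b * (np.sqrt(A) - sqAd)


@njit(cache=True, fastmath=False)
def _inlet_solve(A0, W, b, sqAd, rho, qin):
    """Solve A (W + 4 c(A)) = qin for the inlet area; returns (A, U)."""
    A = A0
    for _ in range(50):
        c = _wave_speed(b, A, rho)
        U = W + 4.0 * c
        g = A * U - qin
        dg = U + c
        dA = -g / dg
        if dA < -0.5 * A:
            dA = -0.5 * A
        A += dA
        if abs(dA) < 1e-14 * A0 + 1e-18:
            break
    c = _wave_speed(b, A, rho)
    return A, W + 4.0 * c


@njit(cache=True, fastmath=False)
def _outlet_solve(A0, W, b, sqAd, rho, R1, R2, C, Pout, Pc, dt):
    """Terminal RCR coupling: returns (A, U, Pc_new).

    The compliance pressure is advanced with implicit Euler so the outlet
    remains stable for any dt << R2*C; the 1D end state satisfies the
    outgoing characteristic W+ = U + 4c and P = Pc_new + R1 * Q.
    """
    den = 1.0 + dt / (R2 * C)
    A = A0
    for _ in range(60):
        c = _wave_speed(b, A, rho)
        U = W - 4.0 * c
        Q = A * U
        Pcn = (Pc + (dt / C) * Q + (dt / (R2 * C)) * Pout) / den
        g = _ptrans(b, A, sqAd) - R1 * Q - Pcn
        dQdA = U - c
        dg = rho * c * c / A - R1 * dQdA - (dt / C) * dQdA / den
        dA = -g / dg
        if dA < -0.5 * A:
            dA = -0.5 * A
        A += dA
        if abs(dA) < 1e-14 * A0 + 1e-18:
            break
    c = _wave_speed(b, A, rho)
    U = W - 4.0 * c
    Q = A * U
    Pcn = (Pc + (dt / C) * Q + (dt / (R2 * C)) * Pout) / den
    return A, U, Pcn


@njit(cache=True, fastmath=False)
def _junction2(Ap0, Ad0, Wp, Wd, bp, bd, sqAdp, sqAdd, rho):
    """Conjunction (one parent end, one daughter start).

    Unknowns (Ap, Ad); equations: mass conservation and continuity of
    total pressure P + rho U^2 / 2.
    """
    Ap = Ap0
    Ad = Ad0
    for _ in range(50):
        cp = _wave_speed(bp, Ap, rho)
        cd = _wave_speed(bd, Ad, rho)
        Up = Wp - 4.0 * cp
        Ud = Wd + 4.0 * cd
        f1 = Ap * Up - Ad * Ud
        f2 = (_ptrans(bp, Ap, sqAdp) + 0.5 * rho * Up * Up
              - _ptrans(bd, Ad, sqAdd) - 0.5 * rho * Ud * Ud)
        a11 = Up - cp
        a12 = -(Ud + cd)
        a21 = rho * cp * (cp - Up) / Ap
        a22 = -rho * cd * (cd + Ud) / Ad
        det = a11 * a22 - a12 * a21
        dAp = (-f1 * a22 + f2 * a12) / det
        dAd = (-a11 * f2 + a21 * f1) / det
        if dAp < -0.5 * Ap:
            dAp = -0.5 * Ap
        if dAd < -0.5 * Ad:
            dAd = -0.5 * Ad
        Ap += dAp
        Ad += dAd
        if abs(dAp) < 1e-14 * Ap0 and abs(dAd) < 1e-14 * Ad0:
            break
    cp = _wave_speed(bp, Ap, rho)
    cd = _wave_speed(bd, Ad, rho)
    return Ap, Wp - 4.0 * cp, Ad, Wd + 4.0 * cd


@njit(cache=True, fastmath=False)
def _junction3(Ap0, A10, A20, Wp, W1, W2, bp, b1, b2,
               sqAdp, sqAd1, sqAd2, rho):
    """Bifurcation: parent end feeding two daughter starts.

    Unknowns (Ap, A1, A2); equations: mass conservation and continuity of
    total pressure between the parent and each daughter.
    """
    Ap = Ap0
    A1 = A10
    A2 = A20
    for _ in range(50):
        cp = _wave_speed(bp, Ap, rho)
        c1 = _wave_speed(b1, A1, rho)
        c2 = _wave_speed(b2, A2, rho)
        Up = Wp - 4.0 * cp
        U1 = W1 + 4.0 * c1
        U2 = W2 + 4.0 * c2
        pp = _ptrans(bp, Ap, sqAdp) + 0.5 * rho * Up * Up
        f1 = Ap * Up - A1 * U1 - A2 * U2
        f2 = pp - _ptrans(b1, A1, sqAd1) - 0.5 * rho * U1 * U1
        f3 = pp - _ptrans(b2, A2, sqAd2) - 0.5 * rho * U2 * U2
        a11 = Up - cp
        a12 = -(U1 + c1)
        a13 = -(U2 + c2)
        a21 = rho * cp * (cp - Up) / Ap
        a22 = -rho * c1 * (c1 + U1) / A1
        a31 = a21
        a33 = -rho * c2 * (c2 + U2) / A2
        # | a11 a12 a13 | dAp   -f1
        # | a21 a22  0  | dA1 = -f2
        # | a31  0  a33 | dA2   -f3
        det = a11 * a22 * a33 - a12 * a21 * a33 - a13 * a22 * a31
        d1 = -f1 * a22 * a33 + a12 * f2 * a33 + a13 * a22 * f3
        d2 = -a11 * f2 * a33 + f1 * a21 * a33 + a13 * (a31 * f2 - a21 * f3)
        d3 = -a11 * a22 * f3 + a12 * (a21 * f3 - a31 * f2) + f1 * a22 * a31
        dAp = d1 / det
        dA1 = d2 / det
        dA2 = d3 / det
        if dAp < -0.5 * Ap:
            dAp = -0.5 * Ap
        if dA1 < -0.5 * A1:
            dA1 = -0.5 * A1
        if dA2 < -0.5 * A2:
            dA2 = -0.5 * A2
        Ap += dAp
        A1 += dA1
        A2 += dA2
        if (abs(dAp) < 1e-14 * Ap0 and abs(dA1) < 1e-14 * A10
                and abs(dA2) < 1e-14 * A20):
            break
    cp = _wave_speed(bp, Ap, rho)
    c1 = _wave_speed(b1, A1, rho)
    c2 = _wave_speed(b2, A2, rho)
    return Ap, Wp - 4.0 * cp, A1, W1 + 4.0 * c1, A2, W2 + 4.0 * c2


@njit(cache=True, fastmath=False)
def run_cycle(A, U, Pc, dt, qin, b, sqAd,
              seg_start, seg_n, seg_dx,
              jp_seg, jd1_seg, jd2_seg,
              out_seg, oR1, oR2, oC, oPout,
              inlet_seg, rho, fric,
              rec_nodes, recP, recQ, recA):
    """Advance one cardiac cycle (len(qin) steps), recording at rec_nodes.

    Mutates A, U, Pc in place. Returns STATUS_OK or STATUS_NEGATIVE_AREA.
    """
    nsteps = qin.shape[0]
    N = A.shape[0]
    nseg = seg_start.shape[0]
    As = np.empty(N)
    Us = np.empty(N)
    F1 = np.empty(N)
    F2 = np.empty(N)
    An = np.empty(N)
    Un = np.empty(N)
    njunc = jp_seg.shape[0]
    nout = out_seg.shape[0]
    # scratch for boundary solutions
    bA = np.empty(2 + 3 * njunc + nout)
    bU = np.empty(2 + 3 * njunc + nout)

    for step in range(nsteps):
        # ---- boundary states at t+dt from characteristics of state t ----
        # inlet
        s0 = seg_start[inlet_seg]
        dx0 = seg_dx[inlet_seg]
        c0 = _wave_speed(b[s0], A[s0], rho)
        lam = c0 - U[s0]
        frac = lam * dt / dx0
        if frac > 1.0:
            frac = 1.0
        w0 = U[s0] - 4.0 * _wave_speed(b[s0], A[s0], rho)
        w1 = U[s0 + 1] - 4.0 * _wave_speed(b[s0 + 1], A[s0 + 1], rho)
        Wm = (1.0 - frac) * w0 + frac * w1
        bA[0], bU[0] = _inlet_solve(A[s0], Wm, b[s0], sqAd[s0], rho, qin[step])

        # junctions
        for j in range(njunc):
            ps = jp_seg[j]
            e = seg_start[ps] + seg_n[ps] - 1
            dxp = seg_dx[ps]
            cp = _wave_speed(b[e], A[e], rho)
            frac = (U[e] + cp) * dt / dxp
            if frac > 1.0:
                frac = 1.0
            wp0 = U[e] + 4.0 * cp
            wp1 = U[e - 1] + 4.0 * _wave_speed(b[e - 1], A[e - 1], rho)
            Wp = (1.0 - frac) * wp0 + frac * wp1

            d1 = jd1_seg[j]
            s1 = seg_start[d1]
            c1 = _wave_speed(b[s1], A[s1], rho)
            frac = (c1 - U[s1]) * dt / seg_dx[d1]
            if frac > 1.0:
                frac = 1.0
            w10 = U[s1] - 4.0 * c1
            w11 = U[s1 + 1] - 4.0 * _wave_speed(b[s1 + 1], A[s1 + 1], rho)
            W1 = (1.0 - frac) * w10 + frac * w11

            if jd2_seg[j] >= 0:
                d2 = jd2_seg[j]
                s2 = seg_start[d2]
                c2 = _wave_speed(b[s2], A[s2], rho)
                frac = (c2 - U[s2]) * dt / seg_dx[d2]
                if frac > 1.0:
                    frac = 1.0
                w20 = U[s2] - 4.0 * c2
                w21 = U[s2 + 1] - 4.0 * _wave_speed(b[s2 + 1], A[s2 + 1], rho)
                W2 = (1.0 - frac) * w20 + frac * w21
                Ap, Up, A1, U1, A2, U2 = _junction3(
                    A[e], A[s1], A[s2], Wp, W1, W2,
                    b[e], b[s1], b[s2], sqAd[e], sqAd[s1], sqAd[s2], rho)
                k = 2 + 3 * j
                bA[k], bU[k] = Ap, Up
                bA[k + 1], bU[k + 1] = A1, U1
                bA[k + 2], bU[k + 2] = A2, U2
            else:
                Ap, Up, A1, U1 = _junction2(
                    A[e], A[s1], Wp, W1,
                    b[e], b[s1], sqAd[e], sqAd[s1], rho)
                k = 2 + 3 * j
                bA[k], bU[k] = Ap, Up
                bA[k + 1], bU[k + 1] = A1, U1

        # outlets
        for o in range(nout):
            ts = out_seg[o]
            e = seg_start[ts] + seg_n[ts] - 1
            ce = _wave_speed(b[e], A[e], rho)
            frac = (U[e] + ce) * dt / seg_dx[ts]
            if frac > 1.0:
                frac = 1.0
            w0 = U[e] + 4.0 * ce
            w1 = U[e - 1] + 4.0 * _wave_speed(b[e - 1], A[e - 1], rho)
            Wp = (1.0 - frac) * w0 + frac * w1
            Ae, Ue, Pcn = _outlet_solve(A[e], Wp, b[e], sqAd[e], rho,
                                        oR1[o], oR2[o], oC[o], oPout[o],
                                        Pc[o], dt)
            k = 2 + 3 * njunc + o
            bA[k], bU[k] = Ae, Ue
            Pc[o] = Pcn

        # ---- MacCormack predictor (forward differences) ----
        for i in range(N):
            F1[i] = A[i] * U[i]
            F2[i] = 0.5 * U[i] * U[i] + _ptrans(b[i], A[i], sqAd[i]) / rho
        for s in range(nseg):
            st = seg_start[s]
            en = st + seg_n[s]
            r = dt / seg_dx[s]
            for i in range(st, en - 1):
                As[i] = A[i] - r * (F1[i + 1] - F1[i])
                Us[i] = (U[i] - r * (F2[i + 1] - F2[i])
                         - dt * fric * U[i] / (rho * A[i]))
            As[en - 1] = A[en - 1]
            Us[en - 1] = U[en - 1]
        # ---- corrector (backward differences) ----
        for i in range(N):
            if As[i] <= 0.0:
                return STATUS_NEGATIVE_AREA
            F1[i] = As[i] * Us[i]
            F2[i] = 0.5 * Us[i] * Us[i] + _ptrans(b[i], As[i], sqAd[i]) / rho
        for s in range(nseg):
            st = seg_start[s]
            en = st + seg_n[s]
            r = dt / seg_dx[s]
            An[st] = A[st]
            Un[st] = U[st]
            for i in range(st + 1, en):
                An[i] = 0.5 * (A[i] + As[i] - r * (F1[i] - F1[i - 1]))
                Un[i] = 0.5 * (U[i] + Us[i] - r * (F2[i] - F2[i - 1])
                               - dt * fric * Us[i] / (rho * As[i]))

        # ---- write boundary nodes ----
        s0 = seg_start[inlet_seg]
        An[s0], Un[s0] = bA[0], bU[0]
        for j in range(njunc):
            ps = jp_seg[j]
            e = seg_start[ps] + seg_n[ps] - 1
            k = 2 + 3 * j
            An[e], Un[e] = bA[k], bU[k]
            s1 = seg_start[jd1_seg[j]]
            An[s1], Un[s1] = bA[k + 1], bU[k + 1]
            if jd2_seg[j] >= 0:
                s2 = seg_start[jd2_seg[j]]
                An[s2], Un[s2] = bA[k + 2], bU[k + 2]
        for o in range(nout):
            ts = out_seg[o]
            e = seg_start[ts] + seg_n[ts] - 1
            k = 2 + 3 * njunc + o
            An[e], Un[e] = bA[k], bU[k]

        for i in range(N):
            if An[i] <= 0.0 or not np.isfinite(An[i]) or not np.isfinite(Un[i]):
                return STATUS_NEGATIVE_AREA
            A[i] = An[i]
            U[i] = Un[i]

        # ---- record ----
        for k in range(rec_nodes.shape[0]):
            i = rec_nodes[k]
            recP[step, k] = _ptrans(b[i], A[i], sqAd[i])
            recQ[step, k] = A[i] * U[i]
            recA[step, k] = A[i]

    return STATUS_OK
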