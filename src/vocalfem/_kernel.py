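"""Compiled inner loop of the coupled fluid-structure simulation.

Replicates, step for step, the reference pipeline in :mod:`vocalfem.coupled_sim`
(channel extraction -> flow solve -> consistent surface loads -> Newmark step
-> contact projection) with sparse matvecs and precomputed LU triangular
solves so that the importance-sampling studies can afford thousands of
forward runs.  All quantities are in the internal mm-g-ms system.

Flow model codes: 0 = Bernoulli with fixed separation ratio, 1 = 1D viscous.
"""
from __future__ import annotations

import numpy as np
from numba import njit

BERNOULLI = 0
VISCOUS = 1


@njit(cache=True)
def _csc_lower_solve(data, indices, indptr, x):
    n = x.size
    for j in range(n):
        start, end = indptr[j], indptr[j + 1]
        diag = 1.0
        for k in range(start, end):
            if indices[k] == j:
                diag = data[k]
                break
        xj = x[j] / diag
        x[j] = xj
        for k in range(start, end):
            i = indices[k]
            if i > j:
                x[i] -= data[k] * xj


@njit(cache=True)
def _csc_upper_solve(data, indices, indptr, x):
    for j in range(x.size - 1, -1, -1):
        start, end = indptr[j], indptr[j + 1]
        diag = 1.0
        for k in range(start, end):
            if indices[k] == j:
                diag = data[k]
                break
        xj = x[j] / diag
        x[j] = xj
        for k in range(start, end):
            i = indices[k]
            if i < j:
                x[i] -= data[k] * xj


@njit(cache=True)
def _lu_solve(Ld, Li, Lp, Ud, Ui, Up, row_order, perm_c, b, out):
    """x = A^-1 b given the SuperLU factors of A (see splu convention)."""
    n = b.size
    tmp = np.empty(n)
    for i in range(n):
        tmp[i] = b[row_order[i]]
    _csc_lower_solve(Ld, Li, Lp, tmp)
    _csc_upper_solve(Ud, Ui, Up, tmp)
    for i in range(n):
        out[i] = tmp[perm_c[i]]


@njit(cache=True)
def _csr_matvec(data, indices, indptr, x, out):
    for i in range(out.size):
        s = 0.0
        for k in range(indptr[i], indptr[i + 1]):
            s += data[k] * x[indices[k]]
        out[i] = s


@njit(cache=True)
def _argmin_superior(gap):
    """Index of the minimum gap, ties broken toward the last (superior) station."""
    gmin = gap[0]
    imin = 0
    for j in range(1, gap.size):
        if gap[j] <= gmin:
            gmin = gap[j]
            imin = j
    return imin


@njit(cache=True)
def station_pressures(gap, z_st, depth, flow_model, p_sub, p_sup, r_sep,
                      alpha_st, rho_f, mu_f, chi_min, closed_tol, p_out):
    """Station pressures (internal MPa); returns True if the glottis is closed."""
    n = gap.size
    closed = False
    for j in range(n):
        if gap[j] <= closed_tol:
            closed = True
            break
    if closed:
        first = n
        last = -1
        for j in range(n):
            if gap[j] <= closed_tol:
                if first == n:
                    first = j
                last = j
        for j in range(n):
            if j < first:
                p_out[j] = p_sub
            elif j > last:
                p_out[j] = p_sup
            else:
                p_out[j] = 0.0
        return True

    i_min = _argmin_superior(gap)
    if flow_model == BERNOULLI:
        a_min = gap[i_min] * depth
        a_sep = r_sep * a_min
        i_sep = n
        for j in range(i_min, n):
            if gap[j] * depth >= a_sep:
                i_sep = j
                break
        dp = p_sub - p_sup
        for j in range(n):
            if j < i_sep:
                r = a_sep / (gap[j] * depth)
                p_out[j] = p_sub - dp * r * r
            else:
                p_out[j] = p_sup
        return False

    # viscous: exact-advection / trapezoid-friction quadratic in q
    S = 2.0 * depth
    dp = p_sub - p_sup
    inv2 = np.empty(n)
    inv3 = np.empty(n)
    for j in range(n):
        A = alpha_st[j] * gap[j] * depth
        inv2[j] = 1.0 / (A * A)
        inv3[j] = inv2[j] / A
    # cap the recovery constant so the outlet BC stays reachable (see
    # fluid_viscous.effective_chi_min)
    c0 = inv2[i_min] - inv2[0]
    c1 = inv2[n - 1] - inv2[i_min]
    if c0 + chi_min * c1 < 0.0 and c1 < 0.0:
        chi_min = 0.999 * (c0 / -c1)
    a_adv = 0.5 * rho_f * (c0 + chi_min * c1)
    I3 = 0.0
    for j in range(n - 1):
        I3 += 0.5 * (inv3[j] + inv3[j + 1]) * (z_st[j + 1] - z_st[j])
    b_fric = 2.0 * mu_f * S * S * I3
    if dp <= 0.0:
        q = 0.0
    elif a_adv > 1e-300:
        q = (-b_fric + np.sqrt(b_fric * b_fric + 4.0 * a_adv * dp)) / (2.0 * a_adv)
    elif b_fric > 0.0:
        q = dp / b_fric
    else:
        q = 0.0
    q2 = q * q
    dyn0 = 0.5 * rho_f * q2 * inv2[0]
    dynm = 0.5 * rho_f * q2 * inv2[i_min]
    fric = 0.0
    for j in range(n):
        dyn = 0.5 * rho_f * q2 * inv2[j]
        if j <= i_min:
            adv = dyn - dyn0
        else:
            adv = (dynm - dyn0) + chi_min * (dyn - dynm)
        if j > 0:
            fric += q * mu_f * S * S * (inv3[j] + inv3[j - 1]) * (z_st[j] - z_st[j - 1])
        p_out[j] = p_sub - adv - fric
    return False


@njit(cache=True)
def _pressure_at(z, z_in, z_out, z_st, p_st, p_below, p_above):
    if z < z_in:
        return p_below
    if z > z_out:
        return p_above
    return np.interp(z, z_st, p_st)


@njit(cache=True)
def simulate(
    # SuperLU factors of the Newmark effective operator
    Ld, Li, Lp, Ud, Ui, Up, row_order, perm_c,
    # free-dof operators
    Kd, Ki, Kp, Dd, Di, Dp,
    # initial free-dof state
    d0, v0, a0,
    dt, n_steps,
    # channel surface slice (reference z ascending, x includes support shift)
    surf_zref, surf_xref, surf_xdof,
    z_st, alpha_st,
    # surface edges for load integration
    edge_z1, edge_z2, edge_wx, edge_wz,
    edge_x1dof, edge_z1dof, edge_x2dof, edge_z2dof,
    # contact set
    contact_xdof, contact_refx,
    # scalars
    plane, depth, z_in, z_out,
    flow_model, p_sub, p_sup, r_sep, rho_f, mu_f, chi_min, closed_tol,
    zero_contact_velocity,
):
    """Run ``n_steps`` of the coupled loop; returns (widths, fail_step).

    ``widths[i]`` is the minimum channel gap at time i*dt (before step i).
    ``fail_step`` is -1 on success, else the step at which the displacement
    field stopped being finite.
    """
    beta = 0.25
    gamma = 0.5
    nf = d0.size
    n_st = z_st.size
    n_surf = surf_zref.size
    d = d0.copy()
    v = v0.copy()
    a = a0.copy()
    widths = np.empty(n_steps)
    xsurf = np.empty(n_surf)
    gap = np.empty(n_st)
    p_st = np.empty(n_st)
    F = np.empty(nf)
    tmpK = np.empty(nf)
    tmpD = np.empty(nf)
    rhs = np.empty(nf)
    a_new = np.empty(nf)

    for istep in range(n_steps):
        # channel extraction at material z
        for i in range(n_surf):
            k = surf_xdof[i]
            dx = d[k] if k >= 0 else 0.0
            xsurf[i] = surf_xref[i] + dx
        xst = np.interp(z_st, surf_zref, xsurf)
        wmin = 1e300
        for j in range(n_st):
            g = plane - xst[j]
            if g < 0.0:
                g = 0.0
            gap[j] = g
            if g < wmin:
                wmin = g
        widths[istep] = wmin
        if not np.isfinite(wmin) or wmin > 100.0:
            return widths, istep

        station_pressures(gap, z_st, depth, flow_model, p_sub, p_sup, r_sep,
                          alpha_st, rho_f, mu_f, chi_min, closed_tol, p_st)

        # consistent surface loads
        for i in range(nf):
            F[i] = 0.0
        for k in range(edge_z1.size):
            p1 = _pressure_at(edge_z1[k], z_in, z_out, z_st, p_st, p_sub, p_sup)
            p2 = _pressure_at(edge_z2[k], z_in, z_out, z_st, p_st, p_sub, p_sup)
            c1 = (2.0 * p1 + p2) / 6.0
            c2 = (p1 + 2.0 * p2) / 6.0
            if edge_x1dof[k] >= 0:
                F[edge_x1dof[k]] += c1 * edge_wx[k]
            if edge_z1dof[k] >= 0:
                F[edge_z1dof[k]] += c1 * edge_wz[k]
            if edge_x2dof[k] >= 0:
                F[edge_x2dof[k]] += c2 * edge_wx[k]
            if edge_z2dof[k] >= 0:
                F[edge_z2dof[k]] += c2 * edge_wz[k]

        # Newmark average-acceleration step
        c_d = dt * dt * (0.5 - beta)
        for i in range(nf):
            tmpK[i] = d[i] + dt * v[i] + c_d * a[i]      # displacement predictor
            tmpD[i] = v[i] + dt * (1.0 - gamma) * a[i]   # velocity predictor
        _csr_matvec(Kd, Ki, Kp, tmpK, rhs)
        _csr_matvec(Dd, Di, Dp, tmpD, a_new)
        for i in range(nf):
            rhs[i] = F[i] - rhs[i] - a_new[i]
        dpred = tmpK
        vpred = tmpD
        _lu_solve(Ld, Li, Lp, Ud, Ui, Up, row_order, perm_c, rhs, a_new)
        for i in range(nf):
            d[i] = dpred[i] + beta * dt * dt * a_new[i]
            v[i] = vpred[i] + gamma * dt * a_new[i]
            a[i] = a_new[i]

        # contact projection
        for c in range(contact_xdof.size):
            ix = contact_xdof[c]
            if contact_refx[c] + d[ix] > plane:
                d[ix] = plane - contact_refx[c]
                if zero_contact_velocity:
                    v[ix] = 0.0

    return widths, -1
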