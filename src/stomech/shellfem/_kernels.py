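"""Numba kernels for the shell solver.

Element formulation (all DOFs translational):

* membrane — constant-strain triangle, total-Lagrangian: deformation
  gradient F maps the reference triangle (expressed in its local material
  basis) to the current one; Green strain E = (FᵀF − I)/2, 2nd
  Piola–Kirchhoff stress S = Q·E with the orthotropic plane-stress Q.
* bending — discrete hinge on each interior edge: energy
  ½ k (θ − θ0)² with θ the dihedral angle; k carries the plate flexural
  rigidity of the adjacent elements (∝ t³).
* pressure — follower load: each wetted triangle contributes p·A·n̂/3 to
  its nodes, evaluated on the current geometry.

Consistent tangents are assembled per element by central finite differences
of the analytic element forces.
"""

import numpy as np
from numba import njit

FD_STEP = 1e-5  # μm, central-difference step for element tangents


@njit(cache=True)
def _cross3(a, b):
    out = np.empty(3)
    out[0] = a[1] * b[2] - a[2] * b[1]
    out[1] = a[2] * b[0] - a[0] * b[2]
    out[2] = a[0] * b[1] - a[1] * b[0]
    return out


@njit(cache=True)
def _membrane_force(x0, x1, x2, dminv, q, ta, f):
    """Internal membrane force (9,) and strain energy of one CST element."""
    # F = d · Dm⁻¹, d columns are current edge vectors
    f00 = (x1[0] - x0[0]) * dminv[0, 0] + (x2[0] - x0[0]) * dminv[1, 0]
    f01 = (x1[0] - x0[0]) * dminv[0, 1] + (x2[0] - x0[0]) * dminv[1, 1]
    f10 = (x1[1] - x0[1]) * dminv[0, 0] + (x2[1] - x0[1]) * dminv[1, 0]
    f11 = (x1[1] - x0[1]) * dminv[0, 1] + (x2[1] - x0[1]) * dminv[1, 1]
    f20 = (x1[2] - x0[2]) * dminv[0, 0] + (x2[2] - x0[2]) * dminv[1, 0]
    f21 = (x1[2] - x0[2]) * dminv[0, 1] + (x2[2] - x0[2]) * dminv[1, 1]
    # C = FᵀF
    c00 = f00 * f00 + f10 * f10 + f20 * f20
    c01 = f00 * f01 + f10 * f11 + f20 * f21
    c11 = f01 * f01 + f11 * f11 + f21 * f21
    e11 = 0.5 * (c00 - 1.0)
    e22 = 0.5 * (c11 - 1.0)
    g12 = c01  # engineering shear = 2·E12
    s11 = q[0, 0] * e11 + q[0, 1] * e22 + q[0, 2] * g12
    s22 = q[1, 0] * e11 + q[1, 1] * e22 + q[1, 2] * g12
    s12 = q[2, 0] * e11 + q[2, 1] * e22 + q[2, 2] * g12
    energy = 0.5 * ta * (e11 * s11 + e22 * s22 + g12 * s12)
    # P = F·S2pk, nodal forces H = ta · P · Dm⁻ᵀ
    p00 = f00 * s11 + f01 * s12
    p01 = f00 * s12 + f01 * s22
    p10 = f10 * s11 + f11 * s12
    p11 = f10 * s12 + f11 * s22
    p20 = f20 * s11 + f21 * s12
    p21 = f20 * s12 + f21 * s22
    h00 = ta * (p00 * dminv[0, 0] + p01 * dminv[0, 1])
    h01 = ta * (p00 * dminv[1, 0] + p01 * dminv[1, 1])
    h10 = ta * (p10 * dminv[0, 0] + p11 * dminv[0, 1])
    h11 = ta * (p10 * dminv[1, 0] + p11 * dminv[1, 1])
    h20 = ta * (p20 * dminv[0, 0] + p21 * dminv[0, 1])
    h21 = ta * (p20 * dminv[1, 0] + p21 * dminv[1, 1])
    f[3] = h00
    f[4] = h10
    f[5] = h20
    f[6] = h01
    f[7] = h11
    f[8] = h21
    f[0] = -(h00 + h01)
    f[1] = -(h10 + h11)
    f[2] = -(h20 + h21)
    return energy


@njit(cache=True)
def _dihedral(xi, xj, xk, xl):
    e = xj - xi
    n1 = _cross3(e, xk - xi)
    n2 = _cross3(xi - xj, xl - xj)
    # orient n2 consistently with triangle (j, i, l): normal already ccw
    ln1 = np.sqrt(n1[0] ** 2 + n1[1] ** 2 + n1[2] ** 2)
    ln2 = np.sqrt(n2[0] ** 2 + n2[1] ** 2 + n2[2] ** 2)
    le = np.sqrt(e[0] ** 2 + e[1] ** 2 + e[2] ** 2)
    cr = _cross3(n1, n2)
    s = (cr[0] * e[0] + cr[1] * e[1] + cr[2] * e[2]) / (ln1 * ln2 * le)
    c = (n1[0] * n2[0] + n1[1] * n2[1] + n1[2] * n2[2]) / (ln1 * ln2)
    return np.arctan2(s, c)


@njit(cache=True)
def _hinge_force(xi, xj, xk, xl, kb, th0, f):
    """Internal bending force (12,) of one hinge; returns the energy."""
    e = xj - xi
    n1 = _cross3(e, xk - xi)
    n2 = _cross3(xi - xj, xl - xj)
    n1sq = n1[0] ** 2 + n1[1] ** 2 + n1[2] ** 2
    n2sq = n2[0] ** 2 + n2[1] ** 2 + n2[2] ** 2
    le = np.sqrt(e[0] ** 2 + e[1] ** 2 + e[2] ** 2)
    if n1sq < 1e-30 or n2sq < 1e-30 or le < 1e-15:
        for a in range(12):
            f[a] = 0.0
        return 0.0
    cr = _cross3(n1, n2)
    s = (cr[0] * e[0] + cr[1] * e[1] + cr[2] * e[2]) / (np.sqrt(n1sq * n2sq) * le)
    c = (n1[0] * n2[0] + n1[1] * n2[1] + n1[2] * n2[2]) / np.sqrt(n1sq * n2sq)
    theta = np.arctan2(s, c)
    dpsi = kb * (theta - th0)  # dE/dθ
    a1 = ((xk[0] - xj[0]) * e[0] + (xk[1] - xj[1]) * e[1] + (xk[2] - xj[2]) * e[2]) / le
    a2 = ((xl[0] - xj[0]) * e[0] + (xl[1] - xj[1]) * e[1] + (xl[2] - xj[2]) * e[2]) / le
    b1 = ((xk[0] - xi[0]) * e[0] + (xk[1] - xi[1]) * e[1] + (xk[2] - xi[2]) * e[2]) / le
    b2 = ((xl[0] - xi[0]) * e[0] + (xl[1] - xi[1]) * e[1] + (xl[2] - xi[2]) * e[2]) / le
    for d in range(3):
        gi = -a1 * n1[d] / n1sq - a2 * n2[d] / n2sq
        gj = b1 * n1[d] / n1sq + b2 * n2[d] / n2sq
        gk = -le * n1[d] / n1sq
        gl = -le * n2[d] / n2sq
        f[d] = dpsi * gi
        f[3 + d] = dpsi * gj
        f[6 + d] = dpsi * gk
        f[9 + d] = dpsi * gl
    return 0.5 * kb * (theta - th0) ** 2


@njit(cache=True)
def _pressure_force(x0, x1, x2, p, f):
    """Consistent nodal follower-pressure load (9,), outward positive."""
    n = _cross3(x1 - x0, x2 - x0)  # 2·A·n̂
    for d in range(3):
        val = p * n[d] / 6.0
        f[d] = val
        f[3 + d] = val
        f[6 + d] = val


@njit(cache=True)
def assemble_forces(x, tris, dminv, q, ta, hinges, kb, th0, p):
    """Global internal force, external (pressure) force, and strain energy."""
    n = x.shape[0]
    fint = np.zeros((n, 3))
    fext = np.zeros((n, 3))
    energy = 0.0
    floc = np.empty(9)
    for e in range(tris.shape[0]):
        i0, i1, i2 = tris[e, 0], tris[e, 1], tris[e, 2]
        energy += _membrane_force(x[i0], x[i1], x[i2], dminv[e], q[e], ta[e], floc)
        for d in range(3):
            fint[i0, d] += floc[d]
            fint[i1, d] += floc[3 + d]
            fint[i2, d] += floc[6 + d]
        if p != 0.0:
            _pressure_force(x[i0], x[i1], x[i2], p, floc)
            for d in range(3):
                fext[i0, d] += floc[d]
                fext[i1, d] += floc[3 + d]
                fext[i2, d] += floc[6 + d]
    hloc = np.empty(12)
    for h in range(hinges.shape[0]):
        i, j, k, l = hinges[h, 0], hinges[h, 1], hinges[h, 2], hinges[h, 3]
        energy += _hinge_force(x[i], x[j], x[k], x[l], kb[h], th0[h], hloc)
        for d in range(3):
            fint[i, d] += hloc[d]
            fint[j, d] += hloc[3 + d]
            fint[k, d] += hloc[6 + d]
            fint[l, d] += hloc[9 + d]
    return fint, fext, energy


@njit(cache=True)
def assemble_tangent(x, tris, dminv, q, ta, hinges, kb, th0, p,
                     rows, cols, vals):
    """Element-wise central-difference tangent of the residual fint − fext.

    Fills COO triplets; returns the number of entries written.
    """
    h_fd = FD_STEP
    ptr = 0
    fp = np.empty(9)
    fm = np.empty(9)
    fp2 = np.empty(9)
    fm2 = np.empty(9)
    xe = np.empty((3, 3))
    for e in range(tris.shape[0]):
        for a in range(3):
            for d in range(3):
                xe[a, d] = x[tris[e, a], d]
        for col in range(9):
            a, d = col // 3, col % 3
            orig = xe[a, d]
            xe[a, d] = orig + h_fd
            _membrane_force(xe[0], xe[1], xe[2], dminv[e], q[e], ta[e], fp)
            if p != 0.0:
                _pressure_force(xe[0], xe[1], xe[2], p, fp2)
            xe[a, d] = orig - h_fd
            _membrane_force(xe[0], xe[1], xe[2], dminv[e], q[e], ta[e], fm)
            if p != 0.0:
                _pressure_force(xe[0], xe[1], xe[2], p, fm2)
            xe[a, d] = orig
            gcol = 3 * tris[e, a] + d
            for row in range(9):
                b, dd = row // 3, row % 3
                kval = (fp[row] - fm[row]) / (2.0 * h_fd)
                if p != 0.0:
                    kval -= (fp2[row] - fm2[row]) / (2.0 * h_fd)
                rows[ptr] = 3 * tris[e, b] + dd
                cols[ptr] = gcol
                vals[ptr] = kval
                ptr += 1
    hp = np.empty(12)
    hm = np.empty(12)
    xh = np.empty((4, 3))
    for hh in range(hinges.shape[0]):
        for a in range(4):
            for d in range(3):
                xh[a, d] = x[hinges[hh, a], d]
        for col in range(12):
            a, d = col // 3, col % 3
            orig = xh[a, d]
            xh[a, d] = orig + h_fd
            _hinge_force(xh[0], xh[1], xh[2], xh[3], kb[hh], th0[hh], hp)
            xh[a, d] = orig - h_fd
            _hinge_force(xh[0], xh[1], xh[2], xh[3], kb[hh], th0[hh], hm)
            xh[a, d] = orig
            gcol = 3 * hinges[hh, a] + d
            for row in range(12):
                b, dd = row // 3, row % 3
                rows[ptr] = 3 * hinges[hh, b] + dd
                cols[ptr] = gcol
                vals[ptr] = (hp[row] - hm[row]) / (2.0 * h_fd)
                ptr += 1
    return ptr


@njit(cache=True)
def membrane_strain_stress(x, tris, dminv, q):
    """Mid-surface Green strain and 2nd PK stress per element (material
    frame, Voigt (11, 22, 12) with engineering shear)."""
    m = tris.shape[0]
    strain = np.empty((m, 3))
    stress = np.empty((m, 3))
    floc = np.empty(9)
    for e in range(m):
        x0, x1, x2 = x[tris[e, 0]], x[tris[e, 1]], x[tris[e, 2]]
        f00 = (x1[0] - x0[0]) * dminv[e][0, 0] + (x2[0] - x0[0]) * dminv[e][1, 0]
        f01 = (x1[0] - x0[0]) * dminv[e][0, 1] + (x2[0] - x0[0]) * dminv[e][1, 1]
        f10 = (x1[1] - x0[1]) * dminv[e][0, 0] + (x2[1] - x0[1]) * dminv[e][1, 0]
        f11 = (x1[1] - x0[1]) * dminv[e][0, 1] + (x2[1] - x0[1]) * dminv[e][1, 1]
        f20 = (x1[2] - x0[2]) * dminv[e][0, 0] + (x2[2] - x0[2]) * dminv[e][1, 0]
        f21 = (x1[2] - x0[2]) * dminv[e][0, 1] + (x2[2] - x0[2]) * dminv[e][1, 1]
        c00 = f00 * f00 + f10 * f10 + f20 * f20
        c01 = f00 * f01 + f10 * f11 + f20 * f21
        c11 = f01 * f01 + f11 * f11 + f21 * f21
        strain[e, 0] = 0.5 * (c00 - 1.0)
        strain[e, 1] = 0.5 * (c11 - 1.0)
        strain[e, 2] = c01
        for a in range(3):
            stress[e, a] = (q[e][a, 0] * strain[e, 0]
                            + q[e][a, 1] * strain[e, 1]
                            + q[e][a, 2] * strain[e, 2])
    return strain, stress
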