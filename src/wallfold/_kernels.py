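"""Numba-compiled numerical kernels: energy/force terms and the BAOAB loop.

Unit system: Å, ps, kcal/mol, amu.  Accelerations need the conversion
1 kcal/mol = 418.4 amu Å²/ps², applied by the callers via per-bead
coefficients; the kernels themselves are unit-agnostic.
"""

from __future__ import annotations

import numpy as np
from numba import njit

#: 1 kcal/mol expressed in amu Å²/ps².
ACC_CONV = 418.4


@njit(cache=True, error_model="numpy")
def bond_ef(x, idx, r0, k, f):
    e = 0.0
    for n in range(idx.shape[0]):
        i, j = idx[n, 0], idx[n, 1]
        dx = x[i, 0] - x[j, 0]
        dy = x[i, 1] - x[j, 1]
        dz = x[i, 2] - x[j, 2]
        r = np.sqrt(dx * dx + dy * dy + dz * dz)
        dr = r - r0[n]
        e += k[n] * dr * dr
        c = -2.0 * k[n] * dr / max(r, 1e-12)
        f[i, 0] += c * dx
        f[i, 1] += c * dy
        f[i, 2] += c * dz
        f[j, 0] -= c * dx
        f[j, 1] -= c * dy
        f[j, 2] -= c * dz
    return e


@njit(cache=True, error_model="numpy")
def angle_ef(x, idx, th0, k, f):
    e = 0.0
    for n in range(idx.shape[0]):
        a, b, c = idx[n, 0], idx[n, 1], idx[n, 2]
        ux = x[a, 0] - x[b, 0]
        uy = x[a, 1] - x[b, 1]
        uz = x[a, 2] - x[b, 2]
        vx = x[c, 0] - x[b, 0]
        vy = x[c, 1] - x[b, 1]
        vz = x[c, 2] - x[b, 2]
        nu = np.sqrt(ux * ux + uy * uy + uz * uz)
        nv = np.sqrt(vx * vx + vy * vy + vz * vz)
        cosang = (ux * vx + uy * vy + uz * vz) / (nu * nv)
        if cosang > 1.0:
            cosang = 1.0
        elif cosang < -1.0:
            cosang = -1.0
        theta = np.arccos(cosang)
        dth = theta - th0[n]
        e += k[n] * dth * dth
        sin = np.sqrt(1.0 - cosang * cosang)
        if sin < 1e-8:
            sin = 1e-8
        coef = -2.0 * k[n] * dth / sin  # = dE/dcos(theta) sign folded in
        # d(theta)/d(a) = (cos*u_hat - v_hat) / (|u| sin)
        gax = coef * (cosang * ux / nu - vx / nv) / nu
        gay = coef * (cosang * uy / nu - vy / nv) / nu
        gaz = coef * (cosang * uz / nu - vz / nv) / nu
        gcx = coef * (cosang * vx / nv - ux / nu) / nv
        gcy = coef * (cosang * vy / nv - uy / nu) / nv
        gcz = coef * (cosang * vz / nv - uz / nu) / nv
        f[a, 0] += gax
        f[a, 1] += gay
        f[a, 2] += gaz
        f[c, 0] += gcx
        f[c, 1] += gcy
        f[c, 2] += gcz
        f[b, 0] -= gax + gcx
        f[b, 1] -= gay + gcy
        f[b, 2] -= gaz + gcz
    return e


@njit(cache=True, error_model="numpy")
def dihedral_ef(x, idx, phi0, k, f):
    """Torsions U = k (1 - cos(phi - phi0)); bounded forces everywhere."""
    e = 0.0
    for n in range(idx.shape[0]):
        a1, a2, a3, a4 = idx[n, 0], idx[n, 1], idx[n, 2], idx[n, 3]
        b1x = x[a2, 0] - x[a1, 0]
        b1y = x[a2, 1] - x[a1, 1]
        b1z = x[a2, 2] - x[a1, 2]
        b2x = x[a3, 0] - x[a2, 0]
        b2y = x[a3, 1] - x[a2, 1]
        b2z = x[a3, 2] - x[a2, 2]
        b3x = x[a4, 0] - x[a3, 0]
        b3y = x[a4, 1] - x[a3, 1]
        b3z = x[a4, 2] - x[a3, 2]
        n1x = b1y * b2z - b1z * b2y
        n1y = b1z * b2x - b1x * b2z
        n1z = b1x * b2y - b1y * b2x
        n2x = b2y * b3z - b2z * b3y
        n2y = b2z * b3x - b2x * b3z
        n2z = b2x * b3y - b2y * b3x
        nb2 = np.sqrt(b2x * b2x + b2y * b2y + b2z * b2z)
        n1sq = n1x * n1x + n1y * n1y + n1z * n1z
        n2sq = n2x * n2x + n2y * n2y + n2z * n2z
        if n1sq < 1e-12 or n2sq < 1e-12 or nb2 < 1e-12:
            continue  # collinear: torsion undefined, zero contribution
        # floor the denominators: near-collinear bonds otherwise give
        # divergent torsion forces (1/sin^2 of the bond angle)
        b1sq = b1x * b1x + b1y * b1y + b1z * b1z
        b3sq = b3x * b3x + b3y * b3y + b3z * b3z
        floor1 = 0.01 * b1sq * nb2 * nb2
        floor2 = 0.01 * b3sq * nb2 * nb2
        if n1sq < floor1:
            n1sq = floor1
        if n2sq < floor2:
            n2sq = floor2
        # phi = atan2((n1 x n2).b2hat, n1.n2)
        mx = n1y * n2z - n1z * n2y
        my = n1z * n2x - n1x * n2z
        mz = n1x * n2y - n1y * n2x
        sphi = (mx * b2x + my * b2y + mz * b2z) / nb2
        cphi = n1x * n2x + n1y * n2y + n1z * n2z
        phi = np.arctan2(sphi, cphi)
        dphi = phi - phi0[n]
        e += k[n] * (1.0 - np.cos(dphi))
        dU = k[n] * np.sin(dphi)
        c1_ = -nb2 / n1sq
        c4_ = nb2 / n2sq
        t1x, t1y, t1z = c1_ * n1x, c1_ * n1y, c1_ * n1z
        t4x, t4y, t4z = c4_ * n2x, c4_ * n2y, c4_ * n2z
        p12 = (b1x * b2x + b1y * b2y + b1z * b2z) / (nb2 * nb2)
        p32 = (b3x * b2x + b3y * b2y + b3z * b2z) / (nb2 * nb2)
        t2x = -(1.0 + p12) * t1x + p32 * t4x
        t2y = -(1.0 + p12) * t1y + p32 * t4y
        t2z = -(1.0 + p12) * t1z + p32 * t4z
        t3x = -(t1x + t2x + t4x)
        t3y = -(t1y + t2y + t4y)
        t3z = -(t1z + t2z + t4z)
        f[a1, 0] -= dU * t1x
        f[a1, 1] -= dU * t1y
        f[a1, 2] -= dU * t1z
        f[a2, 0] -= dU * t2x
        f[a2, 1] -= dU * t2y
        f[a2, 2] -= dU * t2z
        f[a3, 0] -= dU * t3x
        f[a3, 1] -= dU * t3y
        f[a3, 2] -= dU * t3z
        f[a4, 0] -= dU * t4x
        f[a4, 1] -= dU * t4y
        f[a4, 2] -= dU * t4z
    return e


@njit(cache=True, error_model="numpy")
def wca_ef(x, pairs, sigma, eps, f):
    """Purely repulsive cut-and-shifted LJ (WCA) over the pair list."""
    e = 0.0
    rc2 = sigma * sigma * 2.0 ** (1.0 / 3.0)
    s2 = sigma * sigma
    for n in range(pairs.shape[0]):
        i, j = pairs[n, 0], pairs[n, 1]
        dx = x[i, 0] - x[j, 0]
        dy = x[i, 1] - x[j, 1]
        dz = x[i, 2] - x[j, 2]
        r2 = dx * dx + dy * dy + dz * dz
        if r2 < rc2:
            x6 = (s2 / r2) ** 3
            x12 = x6 * x6
            e += 4.0 * eps * (x12 - x6) + eps
            c = 24.0 * eps * (2.0 * x12 - x6) / r2
            f[i, 0] += c * dx
            f[i, 1] += c * dy
            f[i, 2] += c * dz
            f[j, 0] -= c * dx
            f[j, 1] -= c * dy
            f[j, 2] -= c * dz
    return e


@njit(cache=True, error_model="numpy")
def contact_ef(x, idx, r0, eps, f):
    """12-6 native-contact wells: U = eps[(r0/r)^12 - 2 (r0/r)^6]."""
    e = 0.0
    for n in range(idx.shape[0]):
        i, j = idx[n, 0], idx[n, 1]
        dx = x[i, 0] - x[j, 0]
        dy = x[i, 1] - x[j, 1]
        dz = x[i, 2] - x[j, 2]
        r2 = dx * dx + dy * dy + dz * dz
        x6 = (r0[n] * r0[n] / r2) ** 3
        x12 = x6 * x6
        e += eps[n] * (x12 - 2.0 * x6)
        c = 12.0 * eps[n] * (x12 - x6) / r2
        f[i, 0] += c * dx
        f[i, 1] += c * dy
        f[i, 2] += c * dz
        f[j, 0] -= c * dx
        f[j, 1] -= c * dy
        f[j, 2] -= c * dz
    return e


@njit(cache=True, error_model="numpy")
def total_force(
    x,
    bond_idx,
    bond_r0,
    bond_k,
    angle_idx,
    angle_th0,
    angle_k,
    dihedral_idx,
    dihedral_phi0,
    dihedral_k,
    ev_pairs,
    sigma,
    eps_ev,
    contact_idx,
    contact_r0,
    contact_eps,
    rc,
    n_res,
    bead_res0,
    anchors,
    k_restraint,
    f,
):
    """Force-field + (optional) harmonic-anchor forces; returns energy.

    ``rc`` is the number of released residues; beads of residues with
    0-based index >= rc are pulled toward their anchor with U = k|r-a|².
    """
    for i in range(x.shape[0]):
        f[i, 0] = 0.0
        f[i, 1] = 0.0
        f[i, 2] = 0.0
    e = bond_ef(x, bond_idx, bond_r0, bond_k, f)
    e += angle_ef(x, angle_idx, angle_th0, angle_k, f)
    e += dihedral_ef(x, dihedral_idx, dihedral_phi0, dihedral_k, f)
    e += wca_ef(x, ev_pairs, sigma, eps_ev, f)
    e += contact_ef(x, contact_idx, contact_r0, contact_eps, f)
    if k_restraint > 0.0 and rc < n_res:
        for i in range(x.shape[0]):
            if bead_res0[i] >= rc:
                for d in range(3):
                    dr = x[i, d] - anchors[i, d]
                    e += k_restraint * dr * dr
                    f[i, d] -= 2.0 * k_restraint * dr
    return e


@njit(cache=True, error_model="numpy")
def released_count(release_steps, g):
    rc = 0
    for r in range(release_steps.shape[0]):
        if release_steps[r] <= g:
            rc += 1
        else:
            break
    return rc


@njit(cache=True, error_model="numpy")
def baoab_chunk(
    x,
    v,
    f,
    acc_coef,  # 418.4 / mass, per bead
    sig_v,  # sqrt(kT (1-c1^2) * 418.4 / mass), per bead
    c1,
    dt,
    noise,  # (n_steps, N, 3)
    step0,
    bond_idx,
    bond_r0,
    bond_k,
    angle_idx,
    angle_th0,
    angle_k,
    dihedral_idx,
    dihedral_phi0,
    dihedral_k,
    ev_pairs,
    sigma,
    eps_ev,
    contact_idx,
    contact_r0,
    contact_eps,
    release_steps,  # per-residue release step, ascending
    plane_x_events,  # plane position after each release
    removal_step,
    wall_on,
    bead_res0,
    anchors,
    k_restraint,
    stride,
    frames_x,
    frames_v,
    frames_g,
    nframes0,
):
    """Advance ``noise.shape[0]`` BAOAB steps; record frames every ``stride``.

    The wall reflection (mirror the x coordinate, flip an inward normal
    velocity) is applied to released beads as a post-step correction while
    the wall is active.  Returns the updated frame count.
    """
    n_steps = noise.shape[0]
    n = x.shape[0]
    n_res = release_steps.shape[0]
    half = 0.5 * dt
    nf = nframes0
    for s in range(n_steps):
        g = step0 + s
        rc = released_count(release_steps, g)
        # B (half kick) + A (half drift)
        for i in range(n):
            ai = acc_coef[i]
            for d in range(3):
                v[i, d] += half * f[i, d] * ai
                x[i, d] += half * v[i, d]
        # O (thermostat) + A (half drift)
        for i in range(n):
            for d in range(3):
                v[i, d] = c1 * v[i, d] + sig_v[i] * noise[s, i, d]
                x[i, d] += half * v[i, d]
        # elastic wall on released beads
        if wall_on and g < removal_step and rc > 0:
            px = plane_x_events[rc - 1]
            for i in range(n):
                if bead_res0[i] < rc and x[i, 0] < px:
                    x[i, 0] = 2.0 * px - x[i, 0]
                    if v[i, 0] < 0.0:
                        v[i, 0] = -v[i, 0]
        rc2 = released_count(release_steps, g + 1)
        total_force(
            x,
            bond_idx,
            bond_r0,
            bond_k,
            angle_idx,
            angle_th0,
            angle_k,
            dihedral_idx,
            dihedral_phi0,
            dihedral_k,
            ev_pairs,
            sigma,
            eps_ev,
            contact_idx,
            contact_r0,
            contact_eps,
            rc2,
            n_res,
            bead_res0,
            anchors,
            k_restraint,
            f,
        )
        # final B (half kick)
        for i in range(n):
            ai = acc_coef[i]
            for d in range(3):
                v[i, d] += half * f[i, d] * ai
        if (g + 1) % stride == 0:
            for i in range(n):
                for d in range(3):
                    frames_x[nf, i, d] = x[i, d]
                    frames_v[nf, i, d] = v[i, d]
            frames_g[nf] = g + 1
            nf += 1
    return nf
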