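"""Numba force/energy kernels for the coarse-grained Hamiltonian.

All terms in one pass over precomputed index arrays.  Energies are
returned as a fixed-layout vector:

    0 bond, 1 angle, 2 dihedral, 3 contact, 4 repulsive, 5 link,
    6 electrostatic (Debye-Hueckel), 7 hydrophobic

Minimum-image convention is applied to every displacement when a cubic
box is in use (bond lengths are far below half the box side).
Displacements are computed component-wise; numba allocates no
temporaries in the pair loops.
"""

import numpy as np
from numba import njit

N_ENERGY_TERMS = 8
E_BOND, E_ANGLE, E_DIH, E_CONTACT, E_REP, E_LINK, E_ELEC, E_HP = range(8)


@njit(cache=True, fastmath=True)
def eval_all(
    pos, box, use_pbc,
    bonds, bond_r0, bond_k,
    angles, angle_t0, angle_k,
    dihedrals, dih_p0, dih_k1, dih_k3,
    contacts, c_rn, c_eps,
    rep, rep_sig, rep_eps, rep_rc_factor,
    link, link_r0, link_k,
    elec, elec_qq, kq, lam_d, elec_rc,
    hp, hp_eps, hp_r0, hp_c, hp_rc,
    forces,
):
    energies = np.zeros(N_ENERGY_TERMS)
    forces[:, :] = 0.0

    # harmonic bonds V = k (r - r0)^2, plus the single linkage bond
    for which in range(2):
        arr = bonds if which == 0 else link
        r0s = bond_r0 if which == 0 else link_r0
        ks = bond_k if which == 0 else link_k
        slot = E_BOND if which == 0 else E_LINK
        for b in range(arr.shape[0]):
            i, j = arr[b, 0], arr[b, 1]
            dx = pos[i, 0] - pos[j, 0]
            dy = pos[i, 1] - pos[j, 1]
            dz = pos[i, 2] - pos[j, 2]
            if use_pbc:
                dx -= box * np.rint(dx / box)
                dy -= box * np.rint(dy / box)
                dz -= box * np.rint(dz / box)
            r = np.sqrt(dx * dx + dy * dy + dz * dz)
            dr = r - r0s[b]
            energies[slot] += ks[b] * dr * dr
            fmag = -2.0 * ks[b] * dr / r
            forces[i, 0] += fmag * dx
            forces[i, 1] += fmag * dy
            forces[i, 2] += fmag * dz
            forces[j, 0] -= fmag * dx
            forces[j, 1] -= fmag * dy
            forces[j, 2] -= fmag * dz

    # harmonic angles V = k (theta - theta0)^2
    for a in range(angles.shape[0]):
        i, j, k2 = angles[a, 0], angles[a, 1], angles[a, 2]
        ux = pos[i, 0] - pos[j, 0]
        uy = pos[i, 1] - pos[j, 1]
        uz = pos[i, 2] - pos[j, 2]
        vx = pos[k2, 0] - pos[j, 0]
        vy = pos[k2, 1] - pos[j, 1]
        vz = pos[k2, 2] - pos[j, 2]
        if use_pbc:
            ux -= box * np.rint(ux / box)
            uy -= box * np.rint(uy / box)
            uz -= box * np.rint(uz / box)
            vx -= box * np.rint(vx / box)
            vy -= box * np.rint(vy / box)
            vz -= box * np.rint(vz / box)
        nu = np.sqrt(ux * ux + uy * uy + uz * uz)
        nv = np.sqrt(vx * vx + vy * vy + vz * vz)
        cost = (ux * vx + uy * vy + uz * vz) / (nu * nv)
        if cost > 1.0:
            cost = 1.0
        elif cost < -1.0:
            cost = -1.0
        theta = np.arccos(cost)
        dt = theta - angle_t0[a]
        energies[E_ANGLE] += angle_k[a] * dt * dt
        sint = np.sqrt(max(1.0 - cost * cost, 1e-12))
        coef = -2.0 * angle_k[a] * dt / sint
        fix = coef * (cost * ux / nu - vx / nv) / nu
        fiy = coef * (cost * uy / nu - vy / nv) / nu
        fiz = coef * (cost * uz / nu - vz / nv) / nu
        fkx = coef * (cost * vx / nv - ux / nu) / nv
        fky = coef * (cost * vy / nv - uy / nu) / nv
        fkz = coef * (cost * vz / nv - uz / nu) / nv
        forces[i, 0] += fix
        forces[i, 1] += fiy
        forces[i, 2] += fiz
        forces[k2, 0] += fkx
        forces[k2, 1] += fky
        forces[k2, 2] += fkz
        forces[j, 0] -= fix + fkx
        forces[j, 1] -= fiy + fky
        forces[j, 2] -= fiz + fkz

    # cosine dihedrals V = k1 (1 - cos(phi-phi0)) + k3 (1 - cos(3(phi-phi0)))
    for a in range(dihedrals.shape[0]):
        i, j, k2, l = dihedrals[a, 0], dihedrals[a, 1], dihedrals[a, 2], dihedrals[a, 3]
        b1x = pos[j, 0] - pos[i, 0]
        b1y = pos[j, 1] - pos[i, 1]
        b1z = pos[j, 2] - pos[i, 2]
        b2x = pos[k2, 0] - pos[j, 0]
        b2y = pos[k2, 1] - pos[j, 1]
        b2z = pos[k2, 2] - pos[j, 2]
        b3x = pos[l, 0] - pos[k2, 0]
        b3y = pos[l, 1] - pos[k2, 1]
        b3z = pos[l, 2] - pos[k2, 2]
        if use_pbc:
            b1x -= box * np.rint(b1x / box)
            b1y -= box * np.rint(b1y / box)
            b1z -= box * np.rint(b1z / box)
            b2x -= box * np.rint(b2x / box)
            b2y -= box * np.rint(b2y / box)
            b2z -= box * np.rint(b2z / box)
            b3x -= box * np.rint(b3x / box)
            b3y -= box * np.rint(b3y / box)
            b3z -= box * np.rint(b3z / box)
        n1x = b1y * b2z - b1z * b2y
        n1y = b1z * b2x - b1x * b2z
        n1z = b1x * b2y - b1y * b2x
        n2x = b2y * b3z - b2z * b3y
        n2y = b2z * b3x - b2x * b3z
        n2z = b2x * b3y - b2y * b3x
        nb2 = np.sqrt(b2x * b2x + b2y * b2y + b2z * b2z)
        cx = n1y * n2z - n1z * n2y
        cy = n1z * n2x - n1x * n2z
        cz = n1x * n2y - n1y * n2x
        y = (cx * b2x + cy * b2y + cz * b2z) / nb2
        x = n1x * n2x + n1y * n2y + n1z * n2z
        phi = np.arctan2(y, x)
        dphi = phi - dih_p0[a]
        energies[E_DIH] += dih_k1[a] * (1.0 - np.cos(dphi)) + dih_k3[a] * (
            1.0 - np.cos(3.0 * dphi)
        )
        dvdphi = dih_k1[a] * np.sin(dphi) + 3.0 * dih_k3[a] * np.sin(3.0 * dphi)
        n1sq = n1x * n1x + n1y * n1y + n1z * n1z
        n2sq = n2x * n2x + n2y * n2y + n2z * n2z
        if n1sq < 1e-12 or n2sq < 1e-12:
            continue
        p = (b1x * b2x + b1y * b2y + b1z * b2z) / (nb2 * nb2)
        q = (b3x * b2x + b3y * b2y + b3z * b2z) / (nb2 * nb2)
        ci = dvdphi * nb2 / n1sq
        cl = -dvdphi * nb2 / n2sq
        fix = ci * n1x
        fiy = ci * n1y
        fiz = ci * n1z
        flx = cl * n2x
        fly = cl * n2y
        flz = cl * n2z
        svx = -p * fix + q * flx
        svy = -p * fiy + q * fly
        svz = -p * fiz + q * flz
        forces[i, 0] += fix
        forces[i, 1] += fiy
        forces[i, 2] += fiz
        forces[j, 0] += svx - fix
        forces[j, 1] += svy - fiy
        forces[j, 2] += svz - fiz
        forces[k2, 0] += -svx - flx
        forces[k2, 1] += -svy - fly
        forces[k2, 2] += -svz - flz
        forces[l, 0] += flx
        forces[l, 1] += fly
        forces[l, 2] += flz

    # native contacts: 12-10 well with minimum at r_n
    for a in range(contacts.shape[0]):
        i, j = contacts[a, 0], contacts[a, 1]
        dx = pos[i, 0] - pos[j, 0]
        dy = pos[i, 1] - pos[j, 1]
        dz = pos[i, 2] - pos[j, 2]
        if use_pbc:
            dx -= box * np.rint(dx / box)
            dy -= box * np.rint(dy / box)
            dz -= box * np.rint(dz / box)
        r2 = dx * dx + dy * dy + dz * dz
        r = np.sqrt(r2)
        s2 = (c_rn[a] * c_rn[a]) / r2
        s10 = s2 * s2 * s2 * s2 * s2
        s12 = s10 * s2
        energies[E_CONTACT] += c_eps[a] * (5.0 * s12 - 6.0 * s10)
        fmag = 60.0 * c_eps[a] * (s12 - s10) / r2
        forces[i, 0] += fmag * dx
        forces[i, 1] += fmag * dy
        forces[i, 2] += fmag * dz
        forces[j, 0] -= fmag * dx
        forces[j, 1] -= fmag * dy
        forces[j, 2] -= fmag * dz

    # excluded-volume repulsion, truncated and shifted at rc = factor * sigma
    shift12 = rep_rc_factor ** (-12.0)
    for a in range(rep.shape[0]):
        i, j = rep[a, 0], rep[a, 1]
        dx = pos[i, 0] - pos[j, 0]
        dy = pos[i, 1] - pos[j, 1]
        dz = pos[i, 2] - pos[j, 2]
        if use_pbc:
            dx -= box * np.rint(dx / box)
            dy -= box * np.rint(dy / box)
            dz -= box * np.rint(dz / box)
        r2 = dx * dx + dy * dy + dz * dz
        rc = rep_rc_factor * rep_sig[a]
        if r2 >= rc * rc:
            continue
        s2 = (rep_sig[a] * rep_sig[a]) / r2
        s12 = s2 * s2 * s2 * s2 * s2 * s2
        energies[E_REP] += rep_eps * (s12 - shift12)
        fmag = 12.0 * rep_eps * s12 / r2
        forces[i, 0] += fmag * dx
        forces[i, 1] += fmag * dy
        forces[i, 2] += fmag * dz
        forces[j, 0] -= fmag * dx
        forces[j, 1] -= fmag * dy
        forces[j, 2] -= fmag * dz

    # Debye-Hueckel electrostatics, shifted truncation at elec_rc
    e_shift = np.exp(-elec_rc / lam_d) / elec_rc
    for a in range(elec.shape[0]):
        i, j = elec[a, 0], elec[a, 1]
        dx = pos[i, 0] - pos[j, 0]
        dy = pos[i, 1] - pos[j, 1]
        dz = pos[i, 2] - pos[j, 2]
        if use_pbc:
            dx -= box * np.rint(dx / box)
            dy -= box * np.rint(dy / box)
            dz -= box * np.rint(dz / box)
        r2 = dx * dx + dy * dy + dz * dz
        if r2 >= elec_rc * elec_rc:
            continue
        r = np.sqrt(r2)
        ex = np.exp(-r / lam_d)
        energies[E_ELEC] += kq * elec_qq[a] * (ex / r - e_shift)
        # -dV/dr / r
        fmag = kq * elec_qq[a] * ex * (1.0 / r2 + 1.0 / (lam_d * r)) / r
        forces[i, 0] += fmag * dx
        forces[i, 1] += fmag * dy
        forces[i, 2] += fmag * dz
        forces[j, 0] -= fmag * dx
        forces[j, 1] -= fmag * dy
        forces[j, 2] -= fmag * dz

    # hydrophobic attraction: V = -eps_hp (s(r) - s(rc)),
    # s(r) = (1 + tanh(C (r0 - r))) / 2
    s_rc = 0.5 * (1.0 + np.tanh(hp_c * (hp_r0 - hp_rc)))
    for a in range(hp.shape[0]):
        i, j = hp[a, 0], hp[a, 1]
        dx = pos[i, 0] - pos[j, 0]
        dy = pos[i, 1] - pos[j, 1]
        dz = pos[i, 2] - pos[j, 2]
        if use_pbc:
            dx -= box * np.rint(dx / box)
            dy -= box * np.rint(dy / box)
            dz -= box * np.rint(dz / box)
        r2 = dx * dx + dy * dy + dz * dz
        if r2 >= hp_rc * hp_rc:
            continue
        r = np.sqrt(r2)
        t = np.tanh(hp_c * (hp_r0 - r))
        s = 0.5 * (1.0 + t)
        energies[E_HP] += -hp_eps[a] * (s - s_rc)
        # dV/dr = eps_hp * C (1 - t^2) / 2 >= 0; fmag = -dV/dr / r
        fmag = -0.5 * hp_eps[a] * hp_c * (1.0 - t * t) / r
        forces[i, 0] += fmag * dx
        forces[i, 1] += fmag * dy
        forces[i, 2] += fmag * dz
        forces[j, 0] -= fmag * dx
        forces[j, 1] -= fmag * dy
        forces[j, 2] -= fmag * dz

    return energies
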