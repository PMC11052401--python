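"""Numba kernels for energies, forces and velocity-Verlet integration.

All arrays are float64; the unit system is nm / ps / amu / kJ/mol (see
:mod:`qmdff.units`).  The kernels are deliberately free of Python objects so
one compiled function serves energy evaluation, minimization, Hessians and
the MD inner loop.  ``fastmath`` stays off: trajectories must be bit-for-bit
reproducible for a given seed on one platform.

Energy-term slots in the returned vector:
0 bond, 1 angle, 2 stiff dihedral, 3 flexible dihedral (incl. one-sided
wall), 4 intramolecular LJ, 5 intermolecular LJ, 6 Coulomb, 7 restraints.
"""

import math

import numpy as np
from numba import njit

N_TERMS = 8

# Coulomb treatment codes
COUL_TRUNCATE = 0
COUL_SHIFT = 1
COUL_REACTION_FIELD = 2


@njit(cache=True, inline="always")
def _pbc(d, box):
    if box > 0.0:
        return d - box * math.floor(d / box + 0.5)
    return d


@njit(cache=True)
def _dihedral_geometry(pos, i, j, k, l, box):
    """Signed dihedral (rad) and d(phi)/dx for the four atoms.

    IUPAC convention: cis = 0, trans = pi; sign from the right-hand rule
    about the j->k axis.
    """
    b1x = _pbc(pos[j, 0] - pos[i, 0], box)
    b1y = _pbc(pos[j, 1] - pos[i, 1], box)
    b1z = _pbc(pos[j, 2] - pos[i, 2], box)
    b2x = _pbc(pos[k, 0] - pos[j, 0], box)
    b2y = _pbc(pos[k, 1] - pos[j, 1], box)
    b2z = _pbc(pos[k, 2] - pos[j, 2], box)
    b3x = _pbc(pos[l, 0] - pos[k, 0], box)
    b3y = _pbc(pos[l, 1] - pos[k, 1], box)
    b3z = _pbc(pos[l, 2] - pos[k, 2], box)

    # n1 = b1 x b2 ; n2 = b2 x b3
    n1x = b1y * b2z - b1z * b2y
    n1y = b1z * b2x - b1x * b2z
    n1z = b1x * b2y - b1y * b2x
    n2x = b2y * b3z - b2z * b3y
    n2y = b2z * b3x - b2x * b3z
    n2z = b2x * b3y - b2y * b3x

    b2n = math.sqrt(b2x * b2x + b2y * b2y + b2z * b2z)
    n1sq = n1x * n1x + n1y * n1y + n1z * n1z
    n2sq = n2x * n2x + n2y * n2y + n2z * n2z

    # m = n1 x n2
    mx = n1y * n2z - n1z * n2y
    my = n1z * n2x - n1x * n2z
    mz = n1x * n2y - n1y * n2x
    y = (mx * b2x + my * b2y + mz * b2z) / b2n
    x = n1x * n2x + n1y * n2y + n1z * n2z
    phi = math.atan2(y, x)

    g = np.zeros((4, 3))
    if n1sq > 1e-18 and n2sq > 1e-18:
        c1 = -b2n / n1sq
        c4 = b2n / n2sq
        g[0, 0] = c1 * n1x
        g[0, 1] = c1 * n1y
        g[0, 2] = c1 * n1z
        g[3, 0] = c4 * n2x
        g[3, 1] = c4 * n2y
        g[3, 2] = c4 * n2z
        p = (b1x * b2x + b1y * b2y + b1z * b2z) / (b2n * b2n)
        q = (b3x * b2x + b3y * b2y + b3z * b2z) / (b2n * b2n)
        for d in range(3):
            t = p * g[0, d] - q * g[3, d]
            g[1, d] = -g[0, d] - t
            g[2, d] = -g[3, d] + t
    return phi, g


@njit(cache=True)
def forces_energy(pos, box, cutoff,
                  bond_ij, bond_kf, bond_r0,
                  ang_ijk, ang_kf, ang_t0,
                  dih_ijkl, dih_kf, dih_phi0,
                  flex_ijkl, flex_c,
                  wall_ijkl, wall_phi0, wall_kf,
                  nb_ij, nb_qq, nb_c6, nb_c12, nb_intra,
                  xp_ij, xp_c6, xp_c12,
                  coul_mode, lj_shift,
                  posres_idx, posres_ref, posres_kf,
                  forces):
    """Accumulate forces into ``forces`` (zeroed here); return (terms, virial)."""
    terms = np.zeros(N_TERMS)
    virial = 0.0
    forces[:] = 0.0

    rc2 = cutoff * cutoff if cutoff > 0.0 else 1e30
    rc = cutoff if cutoff > 0.0 else 1e15

    # bonds: V = 1/2 k (r - r0)^2
    for b in range(bond_ij.shape[0]):
        i = bond_ij[b, 0]
        j = bond_ij[b, 1]
        dx = _pbc(pos[j, 0] - pos[i, 0], box)
        dy = _pbc(pos[j, 1] - pos[i, 1], box)
        dz = _pbc(pos[j, 2] - pos[i, 2], box)
        r = math.sqrt(dx * dx + dy * dy + dz * dz)
        dr = r - bond_r0[b]
        terms[0] += 0.5 * bond_kf[b] * dr * dr
        fmag = -bond_kf[b] * dr / r
        fx = fmag * dx
        fy = fmag * dy
        fz = fmag * dz
        forces[j, 0] += fx
        forces[j, 1] += fy
        forces[j, 2] += fz
        forces[i, 0] -= fx
        forces[i, 1] -= fy
        forces[i, 2] -= fz
        virial += fx * dx + fy * dy + fz * dz

    # angles: V = 1/2 k (theta - theta0)^2
    for a in range(ang_ijk.shape[0]):
        i = ang_ijk[a, 0]
        j = ang_ijk[a, 1]
        k = ang_ijk[a, 2]
        ux = _pbc(pos[i, 0] - pos[j, 0], box)
        uy = _pbc(pos[i, 1] - pos[j, 1], box)
        uz = _pbc(pos[i, 2] - pos[j, 2], box)
        vx = _pbc(pos[k, 0] - pos[j, 0], box)
        vy = _pbc(pos[k, 1] - pos[j, 1], box)
        vz = _pbc(pos[k, 2] - pos[j, 2], box)
        ru = math.sqrt(ux * ux + uy * uy + uz * uz)
        rv = math.sqrt(vx * vx + vy * vy + vz * vz)
        ct = (ux * vx + uy * vy + uz * vz) / (ru * rv)
        if ct > 1.0:
            ct = 1.0
        elif ct < -1.0:
            ct = -1.0
        theta = math.acos(ct)
        dth = theta - ang_t0[a]
        terms[1] += 0.5 * ang_kf[a] * dth * dth
        st = math.sqrt(1.0 - ct * ct)
        if st > 1e-8:
            coef = ang_kf[a] * dth / st
            fix = (coef / ru) * (vx / rv - ct * ux / ru)
            fiy = (coef / ru) * (vy / rv - ct * uy / ru)
            fiz = (coef / ru) * (vz / rv - ct * uz / ru)
            fkx = (coef / rv) * (ux / ru - ct * vx / rv)
            fky = (coef / rv) * (uy / ru - ct * vy / rv)
            fkz = (coef / rv) * (uz / ru - ct * vz / rv)
            forces[i, 0] += fix
            forces[i, 1] += fiy
            forces[i, 2] += fiz
            forces[k, 0] += fkx
            forces[k, 1] += fky
            forces[k, 2] += fkz
            forces[j, 0] -= fix + fkx
            forces[j, 1] -= fiy + fky
            forces[j, 2] -= fiz + fkz
            virial += fix * ux + fiy * uy + fiz * uz
            virial += fkx * vx + fky * vy + fkz * vz

    # stiff dihedrals: V = 1/2 k wrap(phi - phi0)^2
    for d in range(dih_ijkl.shape[0]):
        i = dih_ijkl[d, 0]
        j = dih_ijkl[d, 1]
        k = dih_ijkl[d, 2]
        l = dih_ijkl[d, 3]
        phi, g = _dihedral_geometry(pos, i, j, k, l, box)
        dphi = phi - dih_phi0[d]
        while dphi <= -math.pi:
            dphi += 2.0 * math.pi
        while dphi > math.pi:
            dphi -= 2.0 * math.pi
        terms[2] += 0.5 * dih_kf[d] * dphi * dphi
        dv = dih_kf[d] * dphi
        for m in range(4):
            am = dih_ijkl[d, m]
            for c in range(3):
                fa = -dv * g[m, c]
                forces[am, c] += fa
                virial += fa * _pbc(pos[am, c] - pos[j, c], box)

    # flexible dihedrals: V = sum_j c_j cos(j delta)
    for d in range(flex_ijkl.shape[0]):
        i = flex_ijkl[d, 0]
        j = flex_ijkl[d, 1]
        k = flex_ijkl[d, 2]
        l = flex_ijkl[d, 3]
        phi, g = _dihedral_geometry(pos, i, j, k, l, box)
        v = 0.0
        dv = 0.0
        for n in range(flex_c.shape[1]):
            v += flex_c[d, n] * math.cos(n * phi)
            dv -= flex_c[d, n] * n * math.sin(n * phi)
        terms[3] += v
        for m in range(4):
            am = flex_ijkl[d, m]
            for c in range(3):
                fa = -dv * g[m, c]
                forces[am, c] += fa
                virial += fa * _pbc(pos[am, c] - pos[j, c], box)

    # one-sided harmonic walls on dihedrals (clockwise-only restraint)
    for d in range(wall_ijkl.shape[0]):
        i = wall_ijkl[d, 0]
        j = wall_ijkl[d, 1]
        k = wall_ijkl[d, 2]
        l = wall_ijkl[d, 3]
        phi, g = _dihedral_geometry(pos, i, j, k, l, box)
        dphi = phi - wall_phi0[d]
        while dphi <= -math.pi:
            dphi += 2.0 * math.pi
        while dphi > math.pi:
            dphi -= 2.0 * math.pi
        if dphi < 0.0:
            terms[3] += 0.5 * wall_kf[d] * dphi * dphi
            dv = wall_kf[d] * dphi
            for m in range(4):
                am = wall_ijkl[d, m]
                for c in range(3):
                    fa = -dv * g[m, c]
                    forces[am, c] += fa
                    virial += fa * _pbc(pos[am, c] - pos[j, c], box)

    # explicit intramolecular LJ pairs (rotor-coupling contacts)
    for p in range(xp_ij.shape[0]):
        i = xp_ij[p, 0]
        j = xp_ij[p, 1]
        dx = _pbc(pos[j, 0] - pos[i, 0], box)
        dy = _pbc(pos[j, 1] - pos[i, 1], box)
        dz = _pbc(pos[j, 2] - pos[i, 2], box)
        r2 = dx * dx + dy * dy + dz * dz
        if r2 > rc2:
            continue
        ir2 = 1.0 / r2
        ir6 = ir2 * ir2 * ir2
        e = xp_c12[p] * ir6 * ir6 - xp_c6[p] * ir6
        if lj_shift:
            irc6 = 1.0 / (rc2 * rc2 * rc2)
            e -= xp_c12[p] * irc6 * irc6 - xp_c6[p] * irc6
        terms[4] += e
        fmag = (12.0 * xp_c12[p] * ir6 * ir6 - 6.0 * xp_c6[p] * ir6) * ir2
        fx = fmag * dx
        fy = fmag * dy
        fz = fmag * dz
        forces[j, 0] += fx
        forces[j, 1] += fy
        forces[j, 2] += fz
        forces[i, 0] -= fx
        forces[i, 1] -= fy
        forces[i, 2] -= fz
        virial += fx * dx + fy * dy + fz * dz

    # nonbonded pair list (LJ 12-6 + Coulomb), spherical cutoff, minimum image
    irc = 1.0 / rc
    irc6 = irc * irc * irc * irc * irc * irc
    krf = 0.5 * irc * irc * irc   # reaction-field (eps_rf -> inf)
    crf = 1.5 * irc
    for p in range(nb_ij.shape[0]):
        i = nb_ij[p, 0]
        j = nb_ij[p, 1]
        dx = _pbc(pos[j, 0] - pos[i, 0], box)
        dy = _pbc(pos[j, 1] - pos[i, 1], box)
        dz = _pbc(pos[j, 2] - pos[i, 2], box)
        r2 = dx * dx + dy * dy + dz * dz
        if r2 > rc2:
            continue
        ir2 = 1.0 / r2
        ir6 = ir2 * ir2 * ir2
        c6 = nb_c6[p]
        c12 = nb_c12[p]
        elj = c12 * ir6 * ir6 - c6 * ir6
        if lj_shift:
            elj -= c12 * irc6 * irc6 - c6 * irc6
        fmag = (12.0 * c12 * ir6 * ir6 - 6.0 * c6 * ir6) * ir2
        qq = nb_qq[p]
        if qq != 0.0:
            r = math.sqrt(r2)
            if coul_mode == COUL_REACTION_FIELD:
                ec = qq * (1.0 / r + krf * r2 - crf)
                fmag += qq * (1.0 / (r2 * r) - 2.0 * krf)
            else:
                ec = qq / r
                if coul_mode == COUL_SHIFT:
                    ec -= qq * irc
                fmag += qq / (r2 * r)
            terms[6] += ec
        if nb_intra[p]:
            terms[4] += elj
        else:
            terms[5] += elj
        fx = fmag * dx
        fy = fmag * dy
        fz = fmag * dz
        forces[j, 0] += fx
        forces[j, 1] += fy
        forces[j, 2] += fz
        forces[i, 0] -= fx
        forces[i, 1] -= fy
        forces[i, 2] -= fz
        virial += fx * dx + fy * dy + fz * dz

    # flat-bottom position restraints (equilibration stage 1)
    for p in range(posres_idx.shape[0]):
        i = posres_idx[p]
        for c in range(3):
            d = pos[i, c] - posres_ref[p, c]
            terms[7] += 0.5 * posres_kf[p] * d * d
            forces[i, c] -= posres_kf[p] * d

    return terms, virial


@njit(cache=True)
def md_chunk(pos, vel, frc, invmass, box, cutoff, dt, nsteps,
             bond_ij, bond_kf, bond_r0,
             ang_ijk, ang_kf, ang_t0,
             dih_ijkl, dih_kf, dih_phi0,
             flex_ijkl, flex_c,
             wall_ijkl, wall_phi0, wall_kf,
             nb_ij, nb_qq, nb_c6, nb_c12, nb_intra,
             xp_ij, xp_c6, xp_c12,
             coul_mode, lj_shift,
             posres_idx, posres_ref, posres_kf):
    """Advance ``nsteps`` velocity-Verlet steps in place.

    ``frc`` must hold the forces at the incoming positions; on return it
    holds the forces at the final positions.  Returns the final energy terms
    and virial; raises nothing — blowups surface as NaN checked by the
    caller.
    """
    n = pos.shape[0]
    terms = np.zeros(N_TERMS)
    virial = 0.0
    for _ in range(nsteps):
        for i in range(n):
            im = invmass[i]
            vel[i, 0] += 0.5 * dt * frc[i, 0] * im
            vel[i, 1] += 0.5 * dt * frc[i, 1] * im
            vel[i, 2] += 0.5 * dt * frc[i, 2] * im
            pos[i, 0] += dt * vel[i, 0]
            pos[i, 1] += dt * vel[i, 1]
            pos[i, 2] += dt * vel[i, 2]
        terms, virial = forces_energy(
            pos, box, cutoff,
            bond_ij, bond_kf, bond_r0,
            ang_ijk, ang_kf, ang_t0,
            dih_ijkl, dih_kf, dih_phi0,
            flex_ijkl, flex_c,
            wall_ijkl, wall_phi0, wall_kf,
            nb_ij, nb_qq, nb_c6, nb_c12, nb_intra,
            xp_ij, xp_c6, xp_c12,
            coul_mode, lj_shift,
            posres_idx, posres_ref, posres_kf,
            frc)
        for i in range(n):
            im = invmass[i]
            vel[i, 0] += 0.5 * dt * frc[i, 0] * im
            vel[i, 1] += 0.5 * dt * frc[i, 1] * im
            vel[i, 2] += 0.5 * dt * frc[i, 2] * im
    return terms, virial
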