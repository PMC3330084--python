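"""Numba-compiled energy/force kernels and integrator inner loops.

All kernels accumulate forces in place and return the term energy.  The
force-field arrays are plain float64/int64 numpy arrays prepared by
:mod:`tribasin.energetics`; lengths in Å, energies in reduced units.
"""

from __future__ import annotations

import numpy as np
from numba import njit

NB = dict(cache=True, fastmath=False)


@njit(**NB)
def bond_energy_forces(coords, ij, r0, k, forces):
    e = 0.0
    for n in range(ij.shape[0]):
        i, j = ij[n, 0], ij[n, 1]
        dx = coords[i, 0] - coords[j, 0]
        dy = coords[i, 1] - coords[j, 1]
        dz = coords[i, 2] - coords[j, 2]
        r = np.sqrt(dx * dx + dy * dy + dz * dz)
        dr = r - r0[n]
        e += 0.5 * k[n] * dr * dr
        if r > 1e-12:
            fmag = -k[n] * dr / r
            forces[i, 0] += fmag * dx
            forces[i, 1] += fmag * dy
            forces[i, 2] += fmag * dz
            forces[j, 0] -= fmag * dx
            forces[j, 1] -= fmag * dy
            forces[j, 2] -= fmag * dz
    return e


@njit(**NB)
def angle_energy_forces(coords, ijk, t0, k, forces):
    e = 0.0
    for n in range(ijk.shape[0]):
        i, j, l = ijk[n, 0], ijk[n, 1], ijk[n, 2]
        ax = coords[i, 0] - coords[j, 0]
        ay = coords[i, 1] - coords[j, 1]
        az = coords[i, 2] - coords[j, 2]
        bx = coords[l, 0] - coords[j, 0]
        by = coords[l, 1] - coords[j, 1]
        bz = coords[l, 2] - coords[j, 2]
        na = np.sqrt(ax * ax + ay * ay + az * az)
        nb = np.sqrt(bx * bx + by * by + bz * bz)
        cosq = (ax * bx + ay * by + az * bz) / (na * nb)
        if cosq > 1.0:
            cosq = 1.0
        elif cosq < -1.0:
            cosq = -1.0
        theta = np.arccos(cosq)
        dtheta = theta - t0[n]
        e += 0.5 * k[n] * dtheta * dtheta
        sinq = np.sqrt(1.0 - cosq * cosq)
        if sinq < 1e-8:
            continue
        coef = k[n] * dtheta / sinq
        # dcos/dri and dcos/drl
        fi_x = coef * (bx / (na * nb) - cosq * ax / (na * na))
        fi_y = coef * (by / (na * nb) - cosq * ay / (na * na))
        fi_z = coef * (bz / (na * nb) - cosq * az / (na * na))
        fl_x = coef * (ax / (na * nb) - cosq * bx / (nb * nb))
        fl_y = coef * (ay / (na * nb) - cosq * by / (nb * nb))
        fl_z = coef * (az / (na * nb) - cosq * bz / (nb * nb))
        forces[i, 0] += fi_x
        forces[i, 1] += fi_y
        forces[i, 2] += fi_z
        forces[l, 0] += fl_x
        forces[l, 1] += fl_y
        forces[l, 2] += fl_z
        forces[j, 0] -= fi_x + fl_x
        forces[j, 1] -= fi_y + fl_y
        forces[j, 2] -= fi_z + fl_z
    return e


@njit(**NB)
def dihedral_energy_forces(coords, ijkl, phi0, k1, k3, forces):
    e = 0.0
    for n in range(ijkl.shape[0]):
        i, j, k, l = ijkl[n, 0], ijkl[n, 1], ijkl[n, 2], ijkl[n, 3]
        b1x = coords[j, 0] - coords[i, 0]
        b1y = coords[j, 1] - coords[i, 1]
        b1z = coords[j, 2] - coords[i, 2]
        b2x = coords[k, 0] - coords[j, 0]
        b2y = coords[k, 1] - coords[j, 1]
        b2z = coords[k, 2] - coords[j, 2]
        b3x = coords[l, 0] - coords[k, 0]
        b3y = coords[l, 1] - coords[k, 1]
        b3z = coords[l, 2] - coords[k, 2]
        # n1 = b1 x b2 ; n2 = b2 x b3
        n1x = b1y * b2z - b1z * b2y
        n1y = b1z * b2x - b1x * b2z
        n1z = b1x * b2y - b1y * b2x
        n2x = b2y * b3z - b2z * b3y
        n2y = b2z * b3x - b2x * b3z
        n2z = b2x * b3y - b2y * b3x
        b2n = np.sqrt(b2x * b2x + b2y * b2y + b2z * b2z)
        n1sq = n1x * n1x + n1y * n1y + n1z * n1z
        n2sq = n2x * n2x + n2y * n2y + n2z * n2z
        if n1sq < 1e-12 or n2sq < 1e-12 or b2n < 1e-12:
            continue
        # phi via atan2
        mx = n1y * b2z - n1z * b2y
        my = n1z * b2x - n1x * b2z
        mz = n1x * b2y - n1y * b2x
        x = n1x * n2x + n1y * n2y + n1z * n2z
        y = (mx * n2x + my * n2y + mz * n2z) / b2n
        phi = np.arctan2(y, x)
        dphi = phi - phi0[n]
        e += k1[n] * (1.0 - np.cos(dphi)) + k3[n] * (1.0 - np.cos(3.0 * dphi))
        dudphi = k1[n] * np.sin(dphi) + 3.0 * k3[n] * np.sin(3.0 * dphi)
        # standard dihedral force distribution
        fi = -dudphi * b2n / n1sq
        fl = dudphi * b2n / n2sq
        fix = fi * n1x
        fiy = fi * n1y
        fiz = fi * n1z
        flx = fl * n2x
        fly = fl * n2y
        flz = fl * n2z
        t = -(b1x * b2x + b1y * b2y + b1z * b2z) / (b2n * b2n)
        s = (b3x * b2x + b3y * b2y + b3z * b2z) / (b2n * b2n)
        tjx = t * fix + s * flx
        tjy = t * fiy + s * fly
        tjz = t * fiz + s * flz
        forces[i, 0] += fix
        forces[i, 1] += fiy
        forces[i, 2] += fiz
        forces[l, 0] += flx
        forces[l, 1] += fly
        forces[l, 2] += flz
        forces[j, 0] += -fix + tjx
        forces[j, 1] += -fiy + tjy
        forces[j, 2] += -fiz + tjz
        forces[k, 0] += -flx - tjx
        forces[k, 1] += -fly - tjy
        forces[k, 2] += -flz - tjz
    return e


@njit(**NB)
def contact_energy_forces(coords, ij, r0, eps, form, gauss_width, forces):
    """Single-minimum attractive wells: 6-12 LJ (form=0) or Gaussian (form=1)."""
    e = 0.0
    for n in range(ij.shape[0]):
        if eps[n] == 0.0:
            continue
        i, j = ij[n, 0], ij[n, 1]
        dx = coords[i, 0] - coords[j, 0]
        dy = coords[i, 1] - coords[j, 1]
        dz = coords[i, 2] - coords[j, 2]
        r2 = dx * dx + dy * dy + dz * dz
        r = np.sqrt(r2)
        if form == 0:
            s = r0[n] * r0[n] / r2
            s6 = s * s * s
            s12 = s6 * s6
            e += eps[n] * (s12 - 2.0 * s6)
            # dU/dr = eps * (-12 s12 + 12 s6)/r ; F = -dU/dr * rhat
            fmag = 12.0 * eps[n] * (s12 - s6) / r2
        else:
            dr = r - r0[n]
            g = np.exp(-dr * dr / (2.0 * gauss_width * gauss_width))
            e += -eps[n] * g
            fmag = -eps[n] * g * dr / (gauss_width * gauss_width) / r
        forces[i, 0] += fmag * dx
        forces[i, 1] += fmag * dy
        forces[i, 2] += fmag * dz
        forces[j, 0] -= fmag * dx
        forces[j, 1] -= fmag * dy
        forces[j, 2] -= fmag * dz
    return e


@njit(**NB)
def repulsion_energy_forces(coords, ij, sigma, eps_rep, forces):
    e = 0.0
    min_r2 = 1e300
    for n in range(ij.shape[0]):
        i, j = ij[n, 0], ij[n, 1]
        dx = coords[i, 0] - coords[j, 0]
        dy = coords[i, 1] - coords[j, 1]
        dz = coords[i, 2] - coords[j, 2]
        r2 = dx * dx + dy * dy + dz * dz
        if r2 < min_r2:
            min_r2 = r2
        s2 = sigma[n] * sigma[n] / r2
        # skip far pairs: (sigma/r)^12 < 1e-12  <=>  s2 < 0.1
        if s2 < 0.1:
            continue
        s6 = s2 * s2 * s2
        s12 = s6 * s6
        e += eps_rep * s12
        fmag = 12.0 * eps_rep * s12 / r2
        forces[i, 0] += fmag * dx
        forces[i, 1] += fmag * dy
        forces[i, 2] += fmag * dz
        forces[j, 0] -= fmag * dx
        forces[j, 1] -= fmag * dy
        forces[j, 2] -= fmag * dz
    return e, np.sqrt(min_r2)


@njit(**NB)
def dh_energy_forces(coords, ij, qq, prefactor, kappa, r_cut, u_shift, forces):
    """Screened Coulomb U = B qq exp(-kappa r)/r, shifted to zero at r_cut.

    ``prefactor`` already includes the 1/eps_r factor.  ``r_cut <= 0`` means
    no cutoff (and ``u_shift`` is ignored).
    """
    e = 0.0
    for n in range(ij.shape[0]):
        i, j = ij[n, 0], ij[n, 1]
        dx = coords[i, 0] - coords[j, 0]
        dy = coords[i, 1] - coords[j, 1]
        dz = coords[i, 2] - coords[j, 2]
        r = np.sqrt(dx * dx + dy * dy + dz * dz)
        if r_cut > 0.0 and r >= r_cut:
            continue
        scr = np.exp(-kappa * r)
        u = prefactor * qq[n] * scr / r
        if r_cut > 0.0:
            e += u - u_shift * qq[n]
        else:
            e += u
        # dU/dr = -u * (kappa + 1/r)
        fmag = u * (kappa + 1.0 / r) / r
        forces[i, 0] += fmag * dx
        forces[i, 1] += fmag * dy
        forces[i, 2] += fmag * dz
        forces[j, 0] -= fmag * dx
        forces[j, 1] -= fmag * dy
        forces[j, 2] -= fmag * dz
    return e


@njit(**NB)
def total_forces(
    coords,
    bond_ij, bond_r0, bond_k,
    ang_ijk, ang_t0, ang_k,
    dih_ijkl, dih_phi0, dih_k1, dih_k3,
    con_ij, con_r0, con_eps, con_form, gauss_width,
    rep_ij, rep_sigma, eps_rep,
    chg_ij, chg_qq, dh_pref, dh_kappa, dh_rcut, dh_ushift,
    forces,
):
    forces[:] = 0.0
    e = bond_energy_forces(coords, bond_ij, bond_r0, bond_k, forces)
    e += angle_energy_forces(coords, ang_ijk, ang_t0, ang_k, forces)
    e += dihedral_energy_forces(coords, dih_ijkl, dih_phi0, dih_k1, dih_k3, forces)
    e += contact_energy_forces(coords, con_ij, con_r0, con_eps, con_form, gauss_width, forces)
    erep, _ = repulsion_energy_forces(coords, rep_ij, rep_sigma, eps_rep, forces)
    e += erep
    e += dh_energy_forces(coords, chg_ij, chg_qq, dh_pref, dh_kappa, dh_rcut, dh_ushift, forces)
    return e


@njit(**NB)
def langevin_baoab_chunk(
    coords, vels, forces, masses, dt, friction, temperature, noise,
    bond_ij, bond_r0, bond_k,
    ang_ijk, ang_t0, ang_k,
    dih_ijkl, dih_phi0, dih_k1, dih_k3,
    con_ij, con_r0, con_eps, con_form, gauss_width,
    rep_ij, rep_sigma, eps_rep,
    chg_ij, chg_qq, dh_pref, dh_kappa, dh_rcut, dh_ushift,
    out_coords, out_energy, stride,
):
    """BAOAB Langevin steps; noise is (n_steps, n_beads, 3) standard normals.

    Frames are stored every ``stride`` steps (step counting continues from
    the caller across chunks via the returned step offset handling there).
    Returns the final potential energy.
    """
    n_steps = noise.shape[0]
    n = coords.shape[0]
    c1 = np.exp(-friction * dt)
    e_pot = total_forces(
        coords,
        bond_ij, bond_r0, bond_k, ang_ijk, ang_t0, ang_k,
        dih_ijkl, dih_phi0, dih_k1, dih_k3,
        con_ij, con_r0, con_eps, con_form, gauss_width,
        rep_ij, rep_sigma, eps_rep,
        chg_ij, chg_qq, dh_pref, dh_kappa, dh_rcut, dh_ushift,
        forces,
    )
    n_out = 0
    for step in range(n_steps):
        # B: half kick
        for i in range(n):
            inv_m = dt * 0.5 / masses[i]
            vels[i, 0] += forces[i, 0] * inv_m
            vels[i, 1] += forces[i, 1] * inv_m
            vels[i, 2] += forces[i, 2] * inv_m
        # A: half drift
        for i in range(n):
            coords[i, 0] += vels[i, 0] * dt * 0.5
            coords[i, 1] += vels[i, 1] * dt * 0.5
            coords[i, 2] += vels[i, 2] * dt * 0.5
        # O: Ornstein-Uhlenbeck
        for i in range(n):
            c2 = np.sqrt(temperature * (1.0 - c1 * c1) / masses[i])
            vels[i, 0] = c1 * vels[i, 0] + c2 * noise[step, i, 0]
            vels[i, 1] = c1 * vels[i, 1] + c2 * noise[step, i, 1]
            vels[i, 2] = c1 * vels[i, 2] + c2 * noise[step, i, 2]
        # A: half drift
        for i in range(n):
            coords[i, 0] += vels[i, 0] * dt * 0.5
            coords[i, 1] += vels[i, 1] * dt * 0.5
            coords[i, 2] += vels[i, 2] * dt * 0.5
        # force update + B: half kick
        e_pot = total_forces(
            coords,
            bond_ij, bond_r0, bond_k, ang_ijk, ang_t0, ang_k,
            dih_ijkl, dih_phi0, dih_k1, dih_k3,
            con_ij, con_r0, con_eps, con_form, gauss_width,
            rep_ij, rep_sigma, eps_rep,
            chg_ij, chg_qq, dh_pref, dh_kappa, dh_rcut, dh_ushift,
            forces,
        )
        for i in range(n):
            inv_m = dt * 0.5 / masses[i]
            vels[i, 0] += forces[i, 0] * inv_m
            vels[i, 1] += forces[i, 1] * inv_m
            vels[i, 2] += forces[i, 2] * inv_m
        if (step + 1) % stride == 0:
            for i in range(n):
                out_coords[n_out, i, 0] = coords[i, 0]
                out_coords[n_out, i, 1] = coords[i, 1]
                out_coords[n_out, i, 2] = coords[i, 2]
            out_energy[n_out] = e_pot
            n_out += 1
    return e_pot


@njit(**NB)
def nve_chunk(
    coords, vels, forces, masses, dt, n_steps,
    bond_ij, bond_r0, bond_k,
    ang_ijk, ang_t0, ang_k,
    dih_ijkl, dih_phi0, dih_k1, dih_k3,
    con_ij, con_r0, con_eps, con_form, gauss_width,
    rep_ij, rep_sigma, eps_rep,
    chg_ij, chg_qq, dh_pref, dh_kappa, dh_rcut, dh_ushift,
    out_coords, out_energy, stride,
):
    """Plain velocity-Verlet (no bath); out_energy holds TOTAL energy."""
    n = coords.shape[0]
    e_pot = total_forces(
        coords,
        bond_ij, bond_r0, bond_k, ang_ijk, ang_t0, ang_k,
        dih_ijkl, dih_phi0, dih_k1, dih_k3,
        con_ij, con_r0, con_eps, con_form, gauss_width,
        rep_ij, rep_sigma, eps_rep,
        chg_ij, chg_qq, dh_pref, dh_kappa, dh_rcut, dh_ushift,
        forces,
    )
    n_out = 0
    for step in range(n_steps):
        for i in range(n):
            inv_m = dt * 0.5 / masses[i]
            vels[i, 0] += forces[i, 0] * inv_m
            vels[i, 1] += forces[i, 1] * inv_m
            vels[i, 2] += forces[i, 2] * inv_m
            coords[i, 0] += vels[i, 0] * dt
            coords[i, 1] += vels[i, 1] * dt
            coords[i, 2] += vels[i, 2] * dt
        e_pot = total_forces(
            coords,
            bond_ij, bond_r0, bond_k, ang_ijk, ang_t0, ang_k,
            dih_ijkl, dih_phi0, dih_k1, dih_k3,
            con_ij, con_r0, con_eps, con_form, gauss_width,
            rep_ij, rep_sigma, eps_rep,
            chg_ij, chg_qq, dh_pref, dh_kappa, dh_rcut, dh_ushift,
            forces,
        )
        e_kin = 0.0
        for i in range(n):
            inv_m = dt * 0.5 / masses[i]
            vels[i, 0] += forces[i, 0] * inv_m
            vels[i, 1] += forces[i, 1] * inv_m
            vels[i, 2] += forces[i, 2] * inv_m
            e_kin += 0.5 * masses[i] * (
                vels[i, 0] ** 2 + vels[i, 1] ** 2 + vels[i, 2] ** 2)
        if (step + 1) % stride == 0:
            for i in range(n):
                out_coords[n_out, i, 0] = coords[i, 0]
                out_coords[n_out, i, 1] = coords[i, 1]
                out_coords[n_out, i, 2] = coords[i, 2]
            out_energy[n_out] = e_pot + e_kin
            n_out += 1
    return e_pot
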