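"""Numba kernels: Go-model energy/forces and the Langevin integrator.

These are internal; use the `forcefield` and `dynamics` wrappers.  All
arithmetic is double precision with fastmath disabled so that trajectories
are bit-reproducible for a given seed on a given build.  Gaussian noise is
generated outside the kernel (numpy PCG64) in one chunk per MD step and
consumed by `md_chunk`, which advances the GJF Langevin velocity-Verlet
scheme in place.
"""

from __future__ import annotations

import numpy as np
from numba import njit

# flavour codes for the native-contact potential
LJ_12_6 = 0
LJ_12_10 = 1

_TWO_POW_SIXTH = 2.0 ** (1.0 / 6.0)


@njit(cache=True)
def energy_forces_into(pos, f, bond_r0, theta0, phi0, ci, cj, cr0,
                       native_mask, eps_bond, eps_angle, eps_dih,
                       eps_contact, eps_nn, sigma_nn, flavour):
    """Fill ``f`` with forces and return the energy components.

    Native term: 12/6 -> 4ε[(σ/r)^12-(σ/r)^6], σ = 2^{-1/6} r0, plain cut at
    2.5σ; 12/10 -> ε[5(r0/r)^12 - 6(r0/r)^10], plain cut at 3 r0.  Non-native
    pairs (j >= i+2, no native contact) are 12/6 repulsive with σ_NN, cut at
    2^{1/6}σ_NN and shifted to zero there.
    """
    n = pos.shape[0]
    for i in range(n):
        f[i, 0] = 0.0
        f[i, 1] = 0.0
        f[i, 2] = 0.0
    e_bond = 0.0
    e_angle = 0.0
    e_dih = 0.0
    e_nat = 0.0
    e_nn = 0.0

    # pseudo-bonds
    for i in range(n - 1):
        dx = pos[i + 1, 0] - pos[i, 0]
        dy = pos[i + 1, 1] - pos[i, 1]
        dz = pos[i + 1, 2] - pos[i, 2]
        r = np.sqrt(dx * dx + dy * dy + dz * dz)
        if r == 0.0:
            raise ValueError("zero bond length")
        dr = r - bond_r0[i]
        e_bond += eps_bond * dr * dr
        coef = -2.0 * eps_bond * dr / r
        f[i + 1, 0] += coef * dx
        f[i + 1, 1] += coef * dy
        f[i + 1, 2] += coef * dz
        f[i, 0] -= coef * dx
        f[i, 1] -= coef * dy
        f[i, 2] -= coef * dz

    # pseudo-bond angles
    for k in range(n - 2):
        ux = pos[k, 0] - pos[k + 1, 0]
        uy = pos[k, 1] - pos[k + 1, 1]
        uz = pos[k, 2] - pos[k + 1, 2]
        vx = pos[k + 2, 0] - pos[k + 1, 0]
        vy = pos[k + 2, 1] - pos[k + 1, 1]
        vz = pos[k + 2, 2] - pos[k + 1, 2]
        nu = np.sqrt(ux * ux + uy * uy + uz * uz)
        nv = np.sqrt(vx * vx + vy * vy + vz * vz)
        c = (ux * vx + uy * vy + uz * vz) / (nu * nv)
        if c > 1.0 - 1e-10:
            c = 1.0 - 1e-10
        elif c < -1.0 + 1e-10:
            c = -1.0 + 1e-10
        theta = np.arccos(c)
        s = np.sqrt(1.0 - c * c)
        dth = theta - theta0[k]
        e_angle += eps_angle * dth * dth
        coef = 2.0 * eps_angle * dth / s  # -dV/dθ · dθ/dcos = +dV/dθ / sinθ
        g0x = (vx / (nu * nv)) - c * ux / (nu * nu)
        g0y = (vy / (nu * nv)) - c * uy / (nu * nu)
        g0z = (vz / (nu * nv)) - c * uz / (nu * nu)
        g2x = (ux / (nu * nv)) - c * vx / (nv * nv)
        g2y = (uy / (nu * nv)) - c * vy / (nv * nv)
        g2z = (uz / (nu * nv)) - c * vz / (nv * nv)
        f[k, 0] += coef * g0x
        f[k, 1] += coef * g0y
        f[k, 2] += coef * g0z
        f[k + 2, 0] += coef * g2x
        f[k + 2, 1] += coef * g2y
        f[k + 2, 2] += coef * g2z
        f[k + 1, 0] -= coef * (g0x + g2x)
        f[k + 1, 1] -= coef * (g0y + g2y)
        f[k + 1, 2] -= coef * (g0z + g2z)

    # pseudo-dihedrals
    for k in range(n - 3):
        b1x = pos[k + 1, 0] - pos[k, 0]
        b1y = pos[k + 1, 1] - pos[k, 1]
        b1z = pos[k + 1, 2] - pos[k, 2]
        b2x = pos[k + 2, 0] - pos[k + 1, 0]
        b2y = pos[k + 2, 1] - pos[k + 1, 1]
        b2z = pos[k + 2, 2] - pos[k + 1, 2]
        b3x = pos[k + 3, 0] - pos[k + 2, 0]
        b3y = pos[k + 3, 1] - pos[k + 2, 1]
        b3z = pos[k + 3, 2] - pos[k + 2, 2]
        n1x = b1y * b2z - b1z * b2y
        n1y = b1z * b2x - b1x * b2z
        n1z = b1x * b2y - b1y * b2x
        n2x = b2y * b3z - b2z * b3y
        n2y = b2z * b3x - b2x * b3z
        n2z = b2x * b3y - b2y * b3x
        n1sq = n1x * n1x + n1y * n1y + n1z * n1z
        n2sq = n2x * n2x + n2y * n2y + n2z * n2z
        nb2 = np.sqrt(b2x * b2x + b2y * b2y + b2z * b2z)
        if n1sq < 1e-18 or n2sq < 1e-18:
            continue  # collinear: dihedral degenerate, no restoring force
        mx = n1y * b2z - n1z * b2y
        my = n1z * b2x - n1x * b2z
        mz = n1x * b2y - n1y * b2x
        x = n1x * n2x + n1y * n2y + n1z * n2z
        y = (mx * n2x + my * n2y + mz * n2z) / nb2
        phi = np.arctan2(y, x)
        dphi = phi - phi0[k]
        e_dih += eps_dih * ((1.0 - np.cos(dphi))
                            + 0.5 * (1.0 - np.cos(3.0 * dphi)))
        dvdphi = eps_dih * (np.sin(dphi) + 1.5 * np.sin(3.0 * dphi))
        # dφ/dp gradients for this atan2 sign convention (checked against
        # central differences)
        du = nb2 / n1sq   # multiplies n1 -> dφ/dp0
        dv = -nb2 / n2sq  # multiplies n2 -> dφ/dp3
        d0x, d0y, d0z = du * n1x, du * n1y, du * n1z
        d3x, d3y, d3z = dv * n2x, dv * n2y, dv * n2z
        sfac = (b1x * b2x + b1y * b2y + b1z * b2z) / (nb2 * nb2)
        tfac = (b3x * b2x + b3y * b2y + b3z * b2z) / (nb2 * nb2)
        d1x = -(1.0 + sfac) * d0x + tfac * d3x
        d1y = -(1.0 + sfac) * d0y + tfac * d3y
        d1z = -(1.0 + sfac) * d0z + tfac * d3z
        d2x = sfac * d0x - (1.0 + tfac) * d3x
        d2y = sfac * d0y - (1.0 + tfac) * d3y
        d2z = sfac * d0z - (1.0 + tfac) * d3z
        f[k, 0] -= dvdphi * d0x
        f[k, 1] -= dvdphi * d0y
        f[k, 2] -= dvdphi * d0z
        f[k + 1, 0] -= dvdphi * d1x
        f[k + 1, 1] -= dvdphi * d1y
        f[k + 1, 2] -= dvdphi * d1z
        f[k + 2, 0] -= dvdphi * d2x
        f[k + 2, 1] -= dvdphi * d2y
        f[k + 2, 2] -= dvdphi * d2z
        f[k + 3, 0] -= dvdphi * d3x
        f[k + 3, 1] -= dvdphi * d3y
        f[k + 3, 2] -= dvdphi * d3z

    # native contacts
    for c_idx in range(ci.shape[0]):
        i = ci[c_idx]
        j = cj[c_idx]
        r0 = cr0[c_idx]
        dx = pos[j, 0] - pos[i, 0]
        dy = pos[j, 1] - pos[i, 1]
        dz = pos[j, 2] - pos[i, 2]
        r = np.sqrt(dx * dx + dy * dy + dz * dz)
        if r == 0.0:
            raise ValueError("zero contact distance")
        if flavour == 0:
            sig = r0 / _TWO_POW_SIXTH
            if r > 2.5 * sig:
                continue
            sr6 = (sig / r) ** 6
            e_nat += 4.0 * eps_contact * (sr6 * sr6 - sr6)
            dvdr = 4.0 * eps_contact * (-12.0 * sr6 * sr6 + 6.0 * sr6) / r
        else:
            if r > 3.0 * r0:
                continue
            q10 = (r0 / r) ** 10
            q12 = q10 * (r0 / r) ** 2
            e_nat += eps_contact * (5.0 * q12 - 6.0 * q10)
            dvdr = eps_contact * (-60.0 * q12 + 60.0 * q10) / r
        coef = -dvdr / r
        f[j, 0] += coef * dx
        f[j, 1] += coef * dy
        f[j, 2] += coef * dz
        f[i, 0] -= coef * dx
        f[i, 1] -= coef * dy
        f[i, 2] -= coef * dz

    # non-native excluded volume, WCA-style cut & shift
    rc_nn_sq = (_TWO_POW_SIXTH * sigma_nn) ** 2
    for i in range(n):
        for j in range(i + 2, n):
            if native_mask[i, j]:
                continue
            dx = pos[j, 0] - pos[i, 0]
            dy = pos[j, 1] - pos[i, 1]
            dz = pos[j, 2] - pos[i, 2]
            rsq = dx * dx + dy * dy + dz * dz
            if rsq >= rc_nn_sq:
                continue
            if rsq == 0.0:
                raise ValueError("zero non-bonded distance")
            r = np.sqrt(rsq)
            sr6 = (sigma_nn / r) ** 6
            e_nn += 4.0 * eps_nn * (sr6 * sr6 - sr6) + eps_nn
            dvdr = 4.0 * eps_nn * (-12.0 * sr6 * sr6 + 6.0 * sr6) / r
            coef = -dvdr / r
            f[j, 0] += coef * dx
            f[j, 1] += coef * dy
            f[j, 2] += coef * dz
            f[i, 0] -= coef * dx
            f[i, 1] -= coef * dy
            f[i, 2] -= coef * dz

    return e_bond, e_angle, e_dih, e_nat, e_nn


def energy_forces(pos, *args):
    """Allocating convenience wrapper used by the forcefield module."""
    f = np.zeros_like(pos)
    comps = energy_forces_into(pos, f, *args)
    return (f,) + comps


@njit(cache=True)
def md_chunk(pos, vel, f, f_new, noise, bond_r0, theta0, phi0, ci, cj, cr0,
             native_mask, eps_bond, eps_angle, eps_dih, eps_contact, eps_nn,
             sigma_nn, flavour, dt, mass, gamma, noise_sd):
    """Advance one chunk of GJF Langevin velocity-Verlet steps in place.

    ``noise`` is (n_steps, N, 3) of standard normals; the thermal amplitude
    sqrt(2 γ k_B T Δt) enters through ``noise_sd``.  ``f`` must hold the
    forces of the incoming positions and holds those of the final positions
    on return.  Returns the final potential energy.
    """
    n = pos.shape[0]
    n_steps = noise.shape[0]
    bdt = 1.0 / (1.0 + gamma * dt / (2.0 * mass))
    adt = (1.0 - gamma * dt / (2.0 * mass)) * bdt
    c_pos_v = bdt * dt
    c_pos_f = bdt * dt * dt / (2.0 * mass)
    c_pos_n = bdt * dt / (2.0 * mass) * noise_sd
    c_vel_f = dt / (2.0 * mass)
    c_vel_n = bdt / mass * noise_sd
    etot = 0.0
    for s in range(n_steps):
        for i in range(n):
            for d in range(3):
                pos[i, d] += (c_pos_v * vel[i, d] + c_pos_f * f[i, d]
                              + c_pos_n * noise[s, i, d])
        eb, ea, ed, en, enn = energy_forces_into(
            pos, f_new, bond_r0, theta0, phi0, ci, cj, cr0, native_mask,
            eps_bond, eps_angle, eps_dih, eps_contact, eps_nn,
            sigma_nn, flavour)
        for i in range(n):
            for d in range(3):
                vel[i, d] = (adt * vel[i, d]
                             + c_vel_f * (adt * f[i, d] + f_new[i, d])
                             + c_vel_n * noise[s, i, d])
                f[i, d] = f_new[i, d]
        etot = eb + ea + ed + en + enn
    return etot
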