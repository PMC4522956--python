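"""Numba-compiled inner loops for the torsional Metropolis sampler.

The kernel mirrors the pure-numpy geometry/energy code in
:mod:`lipas.lipid_models` and :mod:`lipas.mc_ensemble`; agreement between
the two paths is asserted in the test suite. Everything here works in
radians and kcal/mol.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=False)
def nerf_build(n, r, theta, phi, out):
    out[0, 0] = 0.0
    out[0, 1] = 0.0
    out[0, 2] = 0.0
    out[1, 0] = r[0]
    out[1, 1] = 0.0
    out[1, 2] = 0.0
    out[2, 0] = r[0] - r[1] * np.cos(theta[0])
    out[2, 1] = r[1] * np.sin(theta[0])
    out[2, 2] = 0.0
    for i in range(3, n):
        ax, ay, az = out[i - 3, 0], out[i - 3, 1], out[i - 3, 2]
        bx, by, bz = out[i - 2, 0], out[i - 2, 1], out[i - 2, 2]
        cx, cy, cz = out[i - 1, 0], out[i - 1, 1], out[i - 1, 2]
        bcx, bcy, bcz = cx - bx, cy - by, cz - bz
        nb = np.sqrt(bcx * bcx + bcy * bcy + bcz * bcz)
        bcx, bcy, bcz = bcx / nb, bcy / nb, bcz / nb
        abx, aby, abz = bx - ax, by - ay, bz - az
        nx = aby * bcz - abz * bcy
        ny = abz * bcx - abx * bcz
        nz = abx * bcy - aby * bcx
        nn = np.sqrt(nx * nx + ny * ny + nz * nz)
        nx, ny, nz = nx / nn, ny / nn, nz / nn
        mx = ny * bcz - nz * bcy
        my = nz * bcx - nx * bcz
        mz = nx * bcy - ny * bcx
        bl = r[i - 1]
        th = theta[i - 2]
        ph = phi[i - 3]
        d0 = -bl * np.cos(th)
        d1 = bl * np.sin(th) * np.cos(ph)
        d2 = bl * np.sin(th) * np.sin(ph)
        out[i, 0] = cx + d0 * bcx + d1 * mx + d2 * nx
        out[i, 1] = cy + d0 * bcy + d1 * my + d2 * ny
        out[i, 2] = cz + d0 * bcz + d1 * mz + d2 * nz


@njit(cache=False)
def total_energy(n, r, theta, phi, a1, a3, pair_i, pair_j, eps4, sigma2,
                 cutoff2, coords):
    """Torsion series + truncated 12-6 LJ over the supplied pair list."""
    e = 0.0
    for t in range(phi.shape[0]):
        # a1/a3 are zero for frozen torsions
        e += a1[t] * (1.0 + np.cos(phi[t])) + a3[t] * (1.0 + np.cos(3.0 * phi[t]))
    nerf_build(n, r, theta, phi, coords)
    for k in range(pair_i.shape[0]):
        i = pair_i[k]
        j = pair_j[k]
        dx = coords[i, 0] - coords[j, 0]
        dy = coords[i, 1] - coords[j, 1]
        dz = coords[i, 2] - coords[j, 2]
        d2 = dx * dx + dy * dy + dz * dz
        if d2 < cutoff2:
            s2 = sigma2[k] / d2
            s6 = s2 * s2 * s2
            e += eps4[k] * (s6 * s6 - s6)
    return e


@njit(cache=False)
def run_metropolis(n, r, theta, phi0, a1, a3, rotatable, pair_i, pair_j,
                   eps4, sigma2, cutoff2, kT, n_steps, burn_in, seed,
                   max_step, states, record_snaps):
    """Single-torsion Metropolis chain.

    ``max_step`` > 0 selects continuous uniform(−max_step, +max_step)
    perturbations; otherwise proposals are drawn uniformly from the
    discrete ``states`` array (radians). Returns the post-burn-in energy
    trace, the overall acceptance fraction, the final torsions, and the
    post-burn-in torsion snapshots (for discrete-state analyses).
    """
    np.random.seed(seed)
    phi = phi0.copy()
    coords = np.zeros((n, 3))
    e = total_energy(n, r, theta, phi, a1, a3, pair_i, pair_j, eps4, sigma2,
                     cutoff2, coords)
    n_keep = n_steps - burn_in
    trace = np.empty(n_keep)
    snaps = np.empty((n_keep if record_snaps else 1, phi.shape[0]))
    accepted = 0
    two_pi = 2.0 * np.pi
    for step in range(n_steps):
        t = rotatable[np.random.randint(rotatable.shape[0])]
        old = phi[t]
        if max_step > 0.0:
            new = old + (np.random.random() * 2.0 - 1.0) * max_step
            if new > np.pi:
                new -= two_pi
            elif new <= -np.pi:
                new += two_pi
        else:
            new = states[np.random.randint(states.shape[0])]
        phi[t] = new
        e_new = total_energy(n, r, theta, phi, a1, a3, pair_i, pair_j, eps4,
                             sigma2, cutoff2, coords)
        de = e_new - e
        if de <= 0.0 or np.random.random() < np.exp(-de / kT):
            e = e_new
            accepted += 1
        else:
            phi[t] = old
        if step >= burn_in:
            k = step - burn_in
            trace[k] = e
            if record_snaps:
                for q in range(phi.shape[0]):
                    snaps[k, q] = phi[q]
    return trace, accepted / n_steps, phi, snaps
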