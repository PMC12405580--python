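"""JIT-compiled potential evaluation and integrators.

All functions operate on the flat arrays produced by ``dynamics._pack`` so the
inner loops stay allocation-free.  One implementation (`eval_energy_forces`)
serves both the energy breakdown and the force evaluation; the integrators
reuse it step by step.  Reduced units throughout: eps_0 = k_B = m = 1,
lengths in Angstrom, time in tau_ru.

Energy component layout (index into the ``ecomp`` output):
0 bonds, 1 angles, 2 impropers, 3 planar dihedrals, 4 backbone dihedrals,
5 sidechain dihedrals, 6 contacts, 7 noncontacts.
"""

import math

import numpy as np
from numba import njit

N_COMPONENTS = 8


@njit(cache=True)
def eval_energy_forces(
    coord,
    bonds_idx, bonds_r0, bonds_k,
    angles_idx, angles_t0, angles_k,
    hdih_idx, hdih_x0, hdih_k, hdih_comp,
    pdih_idx, pdih_p0, pdih_k, pdih_comp,
    con_idx, con_sig, con_eps, con_gw,
    nc_idx, eps_nc, sigma_nc, flavor,
    forces, ecomp,
):
    n = coord.shape[0]
    for i in range(n):
        forces[i, 0] = 0.0
        forces[i, 1] = 0.0
        forces[i, 2] = 0.0
    for c in range(N_COMPONENTS):
        ecomp[c] = 0.0

    # ---- bonds: V = k/2 (r - r0)^2
    for b in range(bonds_idx.shape[0]):
        i = bonds_idx[b, 0]
        j = bonds_idx[b, 1]
        dx = coord[j, 0] - coord[i, 0]
        dy = coord[j, 1] - coord[i, 1]
        dz = coord[j, 2] - coord[i, 2]
        r = math.sqrt(dx * dx + dy * dy + dz * dz)
        dr = r - bonds_r0[b]
        ecomp[0] += 0.5 * bonds_k[b] * dr * dr
        g = bonds_k[b] * dr / r  # dV/dr / r
        forces[i, 0] += g * dx
        forces[i, 1] += g * dy
        forces[i, 2] += g * dz
        forces[j, 0] -= g * dx
        forces[j, 1] -= g * dy
        forces[j, 2] -= g * dz

    # ---- angles: V = k/2 (theta - theta0)^2
    for a in range(angles_idx.shape[0]):
        i = angles_idx[a, 0]
        j = angles_idx[a, 1]
        k = angles_idx[a, 2]
        ux = coord[i, 0] - coord[j, 0]
        uy = coord[i, 1] - coord[j, 1]
        uz = coord[i, 2] - coord[j, 2]
        vx = coord[k, 0] - coord[j, 0]
        vy = coord[k, 1] - coord[j, 1]
        vz = coord[k, 2] - coord[j, 2]
        ru = math.sqrt(ux * ux + uy * uy + uz * uz)
        rv = math.sqrt(vx * vx + vy * vy + vz * vz)
        cosq = (ux * vx + uy * vy + uz * vz) / (ru * rv)
        if cosq > 1.0:
            cosq = 1.0
        elif cosq < -1.0:
            cosq = -1.0
        theta = math.acos(cosq)
        sinq = math.sqrt(1.0 - cosq * cosq)
        if sinq < 1e-8:
            sinq = 1e-8
        dv = angles_k[a] * (theta - angles_t0[a])
        ecomp[1] += 0.5 * angles_k[a] * (theta - angles_t0[a]) ** 2
        # dtheta/dri = -(1/sin) * d(cos)/dri ; d(cos)/dri = v/(ru rv) - cos * u/ru^2
        ci = -1.0 / sinq
        gix = ci * (vx / (ru * rv) - cosq * ux / (ru * ru))
        giy = ci * (vy / (ru * rv) - cosq * uy / (ru * ru))
        giz = ci * (vz / (ru * rv) - cosq * uz / (ru * ru))
        gkx = ci * (ux / (ru * rv) - cosq * vx / (rv * rv))
        gky = ci * (uy / (ru * rv) - cosq * vy / (rv * rv))
        gkz = ci * (uz / (ru * rv) - cosq * vz / (rv * rv))
        forces[i, 0] -= dv * gix
        forces[i, 1] -= dv * giy
        forces[i, 2] -= dv * giz
        forces[k, 0] -= dv * gkx
        forces[k, 1] -= dv * gky
        forces[k, 2] -= dv * gkz
        forces[j, 0] += dv * (gix + gkx)
        forces[j, 1] += dv * (giy + gky)
        forces[j, 2] += dv * (giz + gkz)

    # ---- dihedrals (harmonic and cosine F_D share the geometry)
    n_h = hdih_idx.shape[0]
    n_p = pdih_idx.shape[0]
    for d in range(n_h + n_p):
        if d < n_h:
            i = hdih_idx[d, 0]
            j = hdih_idx[d, 1]
            k = hdih_idx[d, 2]
            l = hdih_idx[d, 3]
        else:
            i = pdih_idx[d - n_h, 0]
            j = pdih_idx[d - n_h, 1]
            k = pdih_idx[d - n_h, 2]
            l = pdih_idx[d - n_h, 3]
        b1x = coord[j, 0] - coord[i, 0]
        b1y = coord[j, 1] - coord[i, 1]
        b1z = coord[j, 2] - coord[i, 2]
        b2x = coord[k, 0] - coord[j, 0]
        b2y = coord[k, 1] - coord[j, 1]
        b2z = coord[k, 2] - coord[j, 2]
        b3x = coord[l, 0] - coord[k, 0]
        b3y = coord[l, 1] - coord[k, 1]
        b3z = coord[l, 2] - coord[k, 2]
        n1x = b1y * b2z - b1z * b2y
        n1y = b1z * b2x - b1x * b2z
        n1z = b1x * b2y - b1y * b2x
        n2x = b2y * b3z - b2z * b3y
        n2y = b2z * b3x - b2x * b3z
        n2z = b2x * b3y - b2y * b3x
        nb2 = math.sqrt(b2x * b2x + b2y * b2y + b2z * b2z)
        n1sq = n1x * n1x + n1y * n1y + n1z * n1z
        n2sq = n2x * n2x + n2y * n2y + n2z * n2z
        if n1sq < 1e-12 or n2sq < 1e-12:
            continue  # degenerate (collinear) geometry carries no defined torque
        # phi = atan2((n1 x n2) . b2hat, n1 . n2)
        mx = n1y * n2z - n1z * n2y
        my = n1z * n2x - n1x * n2z
        mz = n1x * n2y - n1y * n2x
        y = (mx * b2x + my * b2y + mz * b2z) / nb2
        x = n1x * n2x + n1y * n2y + n1z * n2z
        phi = math.atan2(y, x)
        if d < n_h:
            delta = phi - hdih_x0[d]
            while delta > math.pi:
                delta -= 2.0 * math.pi
            while delta <= -math.pi:
                delta += 2.0 * math.pi
            kk = hdih_k[d]
            ecomp[2 + hdih_comp[d]] += 0.5 * kk * delta * delta
            dvdphi = kk * delta
        else:
            dp = d - n_h
            delta = phi - pdih_p0[dp]
            kk = pdih_k[dp]
            # F_D(x) = (1 - cos x) + 1/2 (1 - cos 3x)
            ecomp[4 + pdih_comp[dp]] += kk * (
                (1.0 - math.cos(delta)) + 0.5 * (1.0 - math.cos(3.0 * delta))
            )
            dvdphi = kk * (math.sin(delta) + 1.5 * math.sin(3.0 * delta))
        # dphi/dri = -nb2/|n1|^2 n1 ; dphi/drl = nb2/|n2|^2 n2
        gi = -nb2 / n1sq
        gl = nb2 / n2sq
        dpix = gi * n1x
        dpiy = gi * n1y
        dpiz = gi * n1z
        dplx = gl * n2x
        dply = gl * n2y
        dplz = gl * n2z
        p = (b1x * b2x + b1y * b2y + b1z * b2z) / (nb2 * nb2)
        q = (b3x * b2x + b3y * b2y + b3z * b2z) / (nb2 * nb2)
        dpjx = -(1.0 + p) * dpix + q * dplx
        dpjy = -(1.0 + p) * dpiy + q * dply
        dpjz = -(1.0 + p) * dpiz + q * dplz
        dpkx = p * dpix - (1.0 + q) * dplx
        dpky = p * dpiy - (1.0 + q) * dply
        dpkz = p * dpiz - (1.0 + q) * dplz
        forces[i, 0] -= dvdphi * dpix
        forces[i, 1] -= dvdphi * dpiy
        forces[i, 2] -= dvdphi * dpiz
        forces[j, 0] -= dvdphi * dpjx
        forces[j, 1] -= dvdphi * dpjy
        forces[j, 2] -= dvdphi * dpjz
        forces[k, 0] -= dvdphi * dpkx
        forces[k, 1] -= dvdphi * dpky
        forces[k, 2] -= dvdphi * dpkz
        forces[l, 0] -= dvdphi * dplx
        forces[l, 1] -= dvdphi * dply
        forces[l, 2] -= dvdphi * dplz

    # ---- contacts
    for c in range(con_idx.shape[0]):
        i = con_idx[c, 0]
        j = con_idx[c, 1]
        dx = coord[j, 0] - coord[i, 0]
        dy = coord[j, 1] - coord[i, 1]
        dz = coord[j, 2] - coord[i, 2]
        r2 = dx * dx + dy * dy + dz * dz
        r = math.sqrt(r2)
        e = con_eps[c]
        s = con_sig[c]
        if flavor == 1:
            sr2 = (s * s) / r2
            sr6 = sr2 * sr2 * sr2
            sr12 = sr6 * sr6
            ecomp[6] += e * (sr12 - 2.0 * sr6)
            dvdr = 12.0 * e * (sr6 - sr12) / r
        else:
            gw = con_gw[c]
            snr2 = (sigma_nc * sigma_nc) / r2
            snr6 = snr2 * snr2 * snr2
            snr12 = snr6 * snr6
            sns2 = (sigma_nc * sigma_nc) / (s * s)
            sns6 = sns2 * sns2 * sns2
            amp = 1.0 + sns6 * sns6
            gauss = math.exp(-((r - s) ** 2) / (2.0 * gw * gw))
            ecomp[6] += e * (snr12 - amp * gauss)
            dvdr = e * (-12.0 * snr12 / r + amp * gauss * (r - s) / (gw * gw))
        g = dvdr / r
        forces[i, 0] += g * dx
        forces[i, 1] += g * dy
        forces[i, 2] += g * dz
        forces[j, 0] -= g * dx
        forces[j, 1] -= g * dy
        forces[j, 2] -= g * dz

    # ---- noncontact repulsion: V = eps_nc (sigma_nc / r)^12
    for c in range(nc_idx.shape[0]):
        i = nc_idx[c, 0]
        j = nc_idx[c, 1]
        dx = coord[j, 0] - coord[i, 0]
        dy = coord[j, 1] - coord[i, 1]
        dz = coord[j, 2] - coord[i, 2]
        r2 = dx * dx + dy * dy + dz * dz
        snr2 = (sigma_nc * sigma_nc) / r2
        snr6 = snr2 * snr2 * snr2
        snr12 = snr6 * snr6
        ecomp[7] += eps_nc * snr12
        g = -12.0 * eps_nc * snr12 / r2
        forces[i, 0] += g * dx
        forces[i, 1] += g * dy
        forces[i, 2] += g * dz
        forces[j, 0] -= g * dx
        forces[j, 1] -= g * dy
        forces[j, 2] -= g * dz

    total = 0.0
    for c in range(N_COMPONENTS):
        total += ecomp[c]
    return total


@njit(cache=True)
def run_langevin_kernel(
    coord0, n_steps, dt, temperature, friction, stride, seed,
    bonds_idx, bonds_r0, bonds_k,
    angles_idx, angles_t0, angles_k,
    hdih_idx, hdih_x0, hdih_k, hdih_comp,
    pdih_idx, pdih_p0, pdih_k, pdih_comp,
    con_idx, con_sig, con_eps, con_gw,
    nc_idx, eps_nc, sigma_nc, flavor,
    probe_i, probe_j, stop_below, energy_bound,
):
    """BAOAB Langevin integrator, unit masses.

    Records a frame at step 0 and every ``stride`` steps.  If ``stop_below``
    is positive, stops at the first step where |r_probe_i - r_probe_j| drops
    below it (first-passage runs).  Returns
    (frames, times, n_recorded, stop_step, bad_step)."""
    n = coord0.shape[0]
    x = coord0.copy()
    v = np.empty((n, 3))
    f = np.empty((n, 3))
    ecomp = np.empty(N_COMPONENTS)
    max_frames = n_steps // stride + 2
    frames = np.empty((max_frames, n, 3))
    times = np.empty(max_frames)

    np.random.seed(seed)
    sqt = math.sqrt(temperature)
    xi = np.random.standard_normal(n * 3)
    for i in range(n):
        for d in range(3):
            v[i, d] = sqt * xi[3 * i + d]

    c1 = math.exp(-friction * dt)
    c2 = math.sqrt(temperature * (1.0 - c1 * c1))

    eval_energy_forces(
        x, bonds_idx, bonds_r0, bonds_k, angles_idx, angles_t0, angles_k,
        hdih_idx, hdih_x0, hdih_k, hdih_comp, pdih_idx, pdih_p0, pdih_k,
        pdih_comp, con_idx, con_sig, con_eps, con_gw, nc_idx, eps_nc,
        sigma_nc, flavor, f, ecomp,
    )
    frames[0] = x
    times[0] = 0.0
    nrec = 1
    stop_step = -1
    bad_step = -1
    half = 0.5 * dt

    for step in range(1, n_steps + 1):
        for i in range(n):
            for d in range(3):
                v[i, d] += half * f[i, d]
                x[i, d] += half * v[i, d]
        xi = np.random.standard_normal(n * 3)
        for i in range(n):
            for d in range(3):
                v[i, d] = c1 * v[i, d] + c2 * xi[3 * i + d]
                x[i, d] += half * v[i, d]
        pot = eval_energy_forces(
            x, bonds_idx, bonds_r0, bonds_k, angles_idx, angles_t0, angles_k,
            hdih_idx, hdih_x0, hdih_k, hdih_comp, pdih_idx, pdih_p0, pdih_k,
            pdih_comp, con_idx, con_sig, con_eps, con_gw, nc_idx, eps_nc,
            sigma_nc, flavor, f, ecomp,
        )
        for i in range(n):
            for d in range(3):
                v[i, d] += half * f[i, d]
        if step % stride == 0:
            frames[nrec] = x
            times[nrec] = step * dt
            nrec += 1
            if not math.isfinite(pot) or abs(pot) > energy_bound:
                bad_step = step
                break
        if stop_below > 0.0:
            dx = coord0[probe_i, 0] * 0.0  # keep typing stable
            dx = x[probe_j, 0] - x[probe_i, 0]
            dy = x[probe_j, 1] - x[probe_i, 1]
            dz = x[probe_j, 2] - x[probe_i, 2]
            if dx * dx + dy * dy + dz * dz < stop_below * stop_below:
                if (step % stride) != 0:
                    frames[nrec] = x
                    times[nrec] = step * dt
                    nrec += 1
                stop_step = step
                break
    return frames, times, nrec, stop_step, bad_step


@njit(cache=True)
def run_nve_kernel(
    coord0, vel0, n_steps, dt, stride,
    bonds_idx, bonds_r0, bonds_k,
    angles_idx, angles_t0, angles_k,
    hdih_idx, hdih_x0, hdih_k, hdih_comp,
    pdih_idx, pdih_p0, pdih_k, pdih_comp,
    con_idx, con_sig, con_eps, con_gw,
    nc_idx, eps_nc, sigma_nc, flavor,
    energy_bound,
):
    """Velocity-Verlet without thermostat.  Returns
    (frames, times, total_energies, n_recorded, bad_step)."""
    n = coord0.shape[0]
    x = coord0.copy()
    v = vel0.copy()
    f = np.empty((n, 3))
    ecomp = np.empty(N_COMPONENTS)
    max_frames = n_steps // stride + 2
    frames = np.empty((max_frames, n, 3))
    times = np.empty(max_frames)
    energies = np.empty(max_frames)

    pot = eval_energy_forces(
        x, bonds_idx, bonds_r0, bonds_k, angles_idx, angles_t0, angles_k,
        hdih_idx, hdih_x0, hdih_k, hdih_comp, pdih_idx, pdih_p0, pdih_k,
        pdih_comp, con_idx, con_sig, con_eps, con_gw, nc_idx, eps_nc,
        sigma_nc, flavor, f, ecomp,
    )
    kin = 0.0
    for i in range(n):
        for d in range(3):
            kin += 0.5 * v[i, d] * v[i, d]
    frames[0] = x
    times[0] = 0.0
    energies[0] = pot + kin
    nrec = 1
    bad_step = -1
    half = 0.5 * dt

    for step in range(1, n_steps + 1):
        for i in range(n):
            for d in range(3):
                v[i, d] += half * f[i, d]
                x[i, d] += dt * v[i, d]
        pot = eval_energy_forces(
            x, bonds_idx, bonds_r0, bonds_k, angles_idx, angles_t0, angles_k,
            hdih_idx, hdih_x0, hdih_k, hdih_comp, pdih_idx, pdih_p0, pdih_k,
            pdih_comp, con_idx, con_sig, con_eps, con_gw, nc_idx, eps_nc,
            sigma_nc, flavor, f, ecomp,
        )
        for i in range(n):
            for d in range(3):
                v[i, d] += half * f[i, d]
        if step % stride == 0:
            kin = 0.0
            for i in range(n):
                for d in range(3):
                    kin += 0.5 * v[i, d] * v[i, d]
            frames[nrec] = x
            times[nrec] = step * dt
            energies[nrec] = pot + kin
            nrec += 1
            if not math.isfinite(pot) or abs(pot) > energy_bound:
                bad_step = step
                break
    return frames, times, energies, nrec, bad_step
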