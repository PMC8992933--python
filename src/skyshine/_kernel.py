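"""Compiled analog photon-transport kernel (numba).

Pure analog transport: exponential free paths restarted at every material
boundary, channel selection proportional to the partial linear coefficients,
Klein-Nishina Compton scattering sampled by Kahn's rejection method,
photoelectric and pair-production events terminate the history (no secondary
particles), 10 keV cutoff.  Every crossing of the horizontal tally plane
scores the ring fluence/kerma estimator.

Geometry parameter array layout (metres, z above outside grade)::

    0 wall inner radius   5 roof bottom
    1 wall outer radius   6 roof top
    2 wall base           7 world radius
    3 wall top            8 world height
    4 roof radius (<0: none)   9 ground termination depth

Region codes: 0 air, 1 wall, 2 roof, 3 ground.
Termination codes: 0 escaped world, 1 photoelectric, 2 pair production,
3 below cutoff, 4 scatter limit, 5 killed at ground.
"""
from __future__ import annotations

import math

import numpy as np
from numba import njit

MEC2 = 0.51099895
JOULE_PER_MEV = 1.602176634e-13
PAIR_THRESHOLD = 1.022
_EPS = 1e-9          # m, forward nudge across boundaries
_LOG_TINY = -745.0

N_KILL_CODES = 6


# --------------------------------------------------------------------------
# random helpers

@njit(cache=True)
def seed_rng(seed):
    np.random.seed(seed)


@njit(cache=True)
def kahn_compton_x(energy):
    """Sample x = E/E' from the Klein-Nishina distribution (Kahn 1954)."""
    alpha = energy / MEC2
    p = (2.0 * alpha + 1.0) / (2.0 * alpha + 9.0)
    while True:
        r1 = np.random.random()
        r2 = np.random.random()
        r3 = np.random.random()
        if r1 <= p:
            x = 1.0 + 2.0 * alpha * r2
            if r3 <= 4.0 * (1.0 / x - 1.0 / (x * x)):
                return x
        else:
            x = (1.0 + 2.0 * alpha) / (1.0 + 2.0 * alpha * r2)
            cost = 1.0 - (x - 1.0) / alpha
            if r3 <= 0.5 * (cost * cost + 1.0 / x):
                return x


@njit(cache=True)
def sample_compton(energy):
    """One Compton scatter: returns (scattered energy, cos of polar angle)."""
    x = kahn_compton_x(energy)
    cost = 1.0 - (x - 1.0) / (energy / MEC2)
    if cost < -1.0:
        cost = -1.0
    elif cost > 1.0:
        cost = 1.0
    return energy / x, cost


@njit(cache=True)
def sample_compton_batch(energy, n, seed):
    """Seeded batch of Compton samples for distribution tests."""
    np.random.seed(seed)
    e_out = np.empty(n)
    cost = np.empty(n)
    for i in range(n):
        e_out[i], cost[i] = sample_compton(energy)
    return e_out, cost


# --------------------------------------------------------------------------
# geometry

@njit(cache=True)
def region_code(x, y, z, gp):
    if z < 0.0:
        return 3
    r2 = x * x + y * y
    if gp[4] > 0.0 and r2 <= gp[4] * gp[4] and gp[5] < z and z <= gp[6]:
        return 2
    if gp[0] * gp[0] < r2 and r2 <= gp[1] * gp[1] and gp[2] <= z and z <= gp[3]:
        return 1
    return 0


@njit(cache=True)
def distance_to_surface(x, y, z, u, v, w, gp):
    """Smallest positive distance to any region surface (finite: the world
    cylinder, top plane and ground termination depth bound every ray)."""
    tmin = 1e30
    if w != 0.0:
        for k in range(7):
            if k == 0:
                zp = 0.0
            elif k == 1:
                zp = gp[2]
            elif k == 2:
                zp = gp[3]
            elif k == 3:
                zp = gp[5]
            elif k == 4:
                zp = gp[6]
            elif k == 5:
                zp = gp[8]
            else:
                zp = gp[9]
            t = (zp - z) / w
            if _EPS < t < tmin:
                tmin = t
    a = u * u + v * v
    if a > 0.0:
        b = x * u + y * v
        for k in range(3):
            radius = gp[0] if k == 0 else (gp[1] if k == 1 else gp[7])
            if radius <= 0.0:
                continue
            c = x * x + y * y - radius * radius
            disc = b * b - a * c
            if disc > 0.0:
                sq = math.sqrt(disc)
                t = (-b - sq) / a
                if _EPS < t < tmin:
                    tmin = t
                t = (-b + sq) / a
                if _EPS < t < tmin:
                    tmin = t
    return tmin


# --------------------------------------------------------------------------
# cross-section lookup (log-log interpolation on the shared grid)

@njit(cache=True)
def _interp(lg_e, lg_v, le):
    n = lg_e.shape[0]
    i = np.searchsorted(lg_e, le)
    if i < 1:
        i = 1
    elif i > n - 1:
        i = n - 1
    f = (le - lg_e[i - 1]) / (lg_e[i] - lg_e[i - 1])
    val = lg_v[i - 1] + f * (lg_v[i] - lg_v[i - 1])
    if val < _LOG_TINY * 0.5:
        return 0.0
    return math.exp(val)


@njit(cache=True)
def mu_channels_per_m(mat, energy, lg_e, lg_pe, lg_inc, lg_pair, dens):
    """Linear coefficients (1/m) of the three channels for material ``mat``."""
    le = math.log(energy)
    scale = dens[mat] * 100.0      # cm^2/g * g/cm^3 -> 1/cm -> 1/m
    pe = _interp(lg_e, lg_pe[mat], le) * scale
    inc = _interp(lg_e, lg_inc[mat], le) * scale
    pp = 0.0
    if energy > PAIR_THRESHOLD:
        pp = _interp(lg_e, lg_pair[mat], le) * scale
    return pe, inc, pp


@njit(cache=True)
def muen_air_m2_per_kg(energy, lg_e, lg_muen_air):
    """Mass energy-absorption coefficient of air in m^2/kg."""
    return _interp(lg_e, lg_muen_air, math.log(energy)) * 0.1


# --------------------------------------------------------------------------
# transport

@njit(cache=True)
def rotate_direction(u, v, w, cost, phi):
    sint = math.sqrt(max(0.0, 1.0 - cost * cost))
    cp = math.cos(phi)
    sp = math.sin(phi)
    if abs(w) > 0.999999:
        sign = 1.0 if w > 0.0 else -1.0
        un = sint * cp
        vn = sint * sp
        wn = cost * sign
    else:
        den = math.sqrt(1.0 - w * w)
        un = u * cost + sint * (u * w * cp - v * sp) / den
        vn = v * cost + sint * (v * w * cp + u * sp) / den
        wn = w * cost - den * sint * cp
    norm = math.sqrt(un * un + vn * vn + wn * wn)
    return un / norm, vn / norm, wn / norm


@njit(cache=True)
def transport_one(x, y, z, u, v, w, energy,
                  gp, region_mat, dens,
                  lg_e, lg_pe, lg_inc, lg_pair, lg_muen_air,
                  z_tally, dr, w_floor, ground_kill, scatter_limit, cutoff,
                  kerma, phi_acc, e_phi, e_sum, count):
    """Track one photon to termination, scoring tally-plane crossings.

    Returns the termination code.
    """
    n_rings = kerma.shape[0]
    nscat = 0
    while True:
        reg = region_code(x, y, z, gp)
        if reg == 3 and ground_kill:
            return 5
        mat = region_mat[reg]
        pe, inc, pp = mu_channels_per_m(mat, energy, lg_e, lg_pe, lg_inc,
                                        lg_pair, dens)
        mu_t = pe + inc + pp
        t_b = distance_to_surface(x, y, z, u, v, w, gp)
        if mu_t > 0.0:
            s = -math.log(np.random.random()) / mu_t
        else:
            s = 1e30
        interacting = s < t_b
        d = s if interacting else t_b + _EPS

        # score every crossing of the tally plane along this flight segment
        z_new = z + w * d
        if (z - z_tally) * (z_new - z_tally) < 0.0:
            t_c = (z_tally - z) / w
            xc = x + u * t_c
            yc = y + v * t_c
            r_c = math.sqrt(xc * xc + yc * yc)
            ir = int(r_c / dr)
            if ir < n_rings:
                r_n = ir * dr
                area = math.pi * ((r_n + dr) * (r_n + dr) - r_n * r_n)
                aw = abs(w)
                if aw < w_floor:
                    aw = w_floor
                dphi = 1.0 / (area * aw)
                dk = (energy * JOULE_PER_MEV * dphi
                      * muen_air_m2_per_kg(energy, lg_e, lg_muen_air))
                kerma[ir] += dk
                phi_acc[ir] += dphi
                e_phi[ir] += dphi * energy
                e_sum[ir] += energy
                count[ir] += 1.0

        x += u * d
        y += v * d
        z += w * d
        if (x * x + y * y >= gp[7] * gp[7] or z >= gp[8] or z <= gp[9]):
            return 0
        if not interacting:
            continue

        if scatter_limit > 0 and nscat >= scatter_limit:
            return 4
        xi = np.random.random() * mu_t
        if xi < pe:
            return 1
        if xi >= pe + inc:
            return 2
        e_new, cost = sample_compton(energy)
        if e_new < cutoff:
            return 3
        energy = e_new
        phi_ang = 2.0 * math.pi * np.random.random()
        u, v, w = rotate_direction(u, v, w, cost, phi_ang)
        nscat += 1


@njit(cache=True)
def run_batch(seed, n_hist,
              src_z, cos_min, e_mode, e_arr, e_cdf,
              gp, region_mat, dens,
              lg_e, lg_pe, lg_inc, lg_pair, lg_muen_air,
              z_tally, dr, w_floor, ground_kill, scatter_limit, cutoff,
              kerma, phi_acc, e_phi, e_sum, count, kills):
    """One independent batch of analog histories (its own RNG stream)."""
    np.random.seed(seed)
    n_e = e_arr.shape[0]
    for _ in range(n_hist):
        # initial energy
        energy = e_arr[0]
        for _try in range(1000):
            if e_mode == 0:
                energy = e_arr[0]
            elif e_mode == 1:
                j = np.searchsorted(e_cdf, np.random.random())
                if j >= e_cdf.shape[0]:
                    j = e_cdf.shape[0] - 1
                energy = e_arr[j]
            else:
                j = np.searchsorted(e_cdf, np.random.random())
                if j >= e_cdf.shape[0]:
                    j = e_cdf.shape[0] - 1
                energy = e_arr[j] + np.random.random() * (e_arr[j + 1] - e_arr[j])
            if energy >= cutoff:
                break
        # initial direction: uniform in solid angle over the cone
        w0 = cos_min + np.random.random() * (1.0 - cos_min)
        ph = 2.0 * math.pi * np.random.random()
        s0 = math.sqrt(max(0.0, 1.0 - w0 * w0))
        u0 = s0 * math.cos(ph)
        v0 = s0 * math.sin(ph)
        code = transport_one(0.0, 0.0, src_z, u0, v0, w0, energy,
                             gp, region_mat, dens,
                             lg_e, lg_pe, lg_inc, lg_pair, lg_muen_air,
                             z_tally, dr, w_floor, ground_kill, scatter_limit,
                             cutoff, kerma, phi_acc, e_phi, e_sum, count)
        kills[code] += 1
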