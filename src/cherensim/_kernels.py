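"""Numba kernels for radiation and optical Monte Carlo transport.

All kernels are single-threaded and draw from numba's np.random stream,
seeded once per kernel call, so a fixed seed gives bit-identical histories.
Python-facing wrappers live in :mod:`cherensim.radtransport` and
:mod:`cherensim.optics`; the pure-python physics functions there are the
independent reference implementations the kernels are tested against.
"""

from __future__ import annotations

import numpy as np
from numba import njit

ELECTRON_REST = 0.511  # MeV
FINE_STRUCTURE_INV = 137.036

# photon status codes (optics)
ALIVE, ABSORBED, EXITED, CAPPED = 0, 1, 2, 3


@njit(cache=True)
def _poisson(lam):
    """Knuth Poisson sampler (lam is O(1) in all transport uses)."""
    if lam <= 0.0:
        return 0
    L = np.exp(-lam)
    k = 0
    p = 1.0
    while True:
        p *= np.random.random()
        if p <= L:
            return k
        k += 1


@njit(cache=True)
def _rotate(ux, uy, uz, cost, phi):
    """Rotate unit vector u by polar angle arccos(cost), azimuth phi."""
    sint = np.sqrt(max(0.0, 1.0 - cost * cost))
    cosp = np.cos(phi)
    sinp = np.sin(phi)
    if abs(uz) > 0.999999:
        sgn = 1.0 if uz >= 0 else -1.0
        return sint * cosp, sint * sinp * sgn, cost * sgn
    den = np.sqrt(1.0 - uz * uz)
    nx = sint * (ux * uz * cosp - uy * sinp) / den + ux * cost
    ny = sint * (uy * uz * cosp + ux * sinp) / den + uy * cost
    nz = -sint * cosp * den + uz * cost
    norm = np.sqrt(nx * nx + ny * ny + nz * nz)
    return nx / norm, ny / norm, nz / norm


@njit(cache=True)
def _beta(e_kin):
    gamma_inv = ELECTRON_REST / (e_kin + ELECTRON_REST)
    return np.sqrt(max(0.0, 1.0 - gamma_inv * gamma_inv))


@njit(cache=True)
def _table_interp(table, row, x, x0_log, dx_log):
    """Linear interpolation on a log-uniform energy grid, row = tissue."""
    f = (np.log(x) - x0_log) / dx_log
    if f <= 0.0:
        return table[row, 0]
    ncol = table.shape[1]
    if f >= ncol - 1:
        return table[row, ncol - 1]
    i = int(f)
    w = f - i
    return (1.0 - w) * table[row, i] + w * table[row, i + 1]


@njit(cache=True)
def _lam_interp(table, row, lam, lam0, dlam):
    f = (lam - lam0) / dlam
    if f <= 0.0:
        return table[row, 0]
    ncol = table.shape[1]
    if f >= ncol - 1:
        return table[row, ncol - 1]
    i = int(f)
    w = f - i
    return (1.0 - w) * table[row, i] + w * table[row, i + 1]


@njit(cache=True)
def _sample_kn_cost(e_mev):
    """Klein-Nishina scattering angle cosine by rejection (envelope: theta=0 value)."""
    k = e_mev / ELECTRON_REST
    while True:
        c = 2.0 * np.random.random() - 1.0
        ratio = 1.0 / (1.0 + k * (1.0 - c))  # E'/E
        sin2 = 1.0 - c * c
        f = 0.5 * ratio * ratio * (1.0 / ratio + ratio - sin2)
        if np.random.random() < f:  # f(theta=0) = 1
            return c


@njit(cache=True)
def _voxel_of(x, o, sp):
    return int(np.floor((x - o) / sp + 0.5))


@njit(cache=True)
def _enter_box(px, py, pz, dx, dy, dz, lo0, lo1, lo2, hi0, hi1, hi2):
    """Slab-method ray/AABB entry distance; -1 if the ray misses the box."""
    tmin = 0.0
    tmax = 1e30
    p = (px, py, pz)
    d = (dx, dy, dz)
    lo = (lo0, lo1, lo2)
    hi = (hi0, hi1, hi2)
    for a in range(3):
        if abs(d[a]) < 1e-14:
            if p[a] < lo[a] or p[a] > hi[a]:
                return -1.0
        else:
            t1 = (lo[a] - p[a]) / d[a]
            t2 = (hi[a] - p[a]) / d[a]
            if t1 > t2:
                t1, t2 = t2, t1
            if t1 > tmin:
                tmin = t1
            if t2 < tmax:
                tmax = t2
    if tmax < tmin:
        return -1.0
    return tmin


@njit(cache=True)
def _transport_electron_one(
    ex, ey, ez, dx, dy, dz, e_kin,
    tissue, density, o0, o1, o2, s0, s1, s2,
    stop_tab, rho_nom, e0_log, de_log,
    n_ref, ft_const, lam1, lam2,
    step_mm, e_cutoff, emission_fraction,
    edep, emission,
    bank_pos, bank_dir, bank_lam, bank_birth_tissue, bank_count, bank_generated,
    air_label,
):
    """CSDA straight-line electron transport with Cherenkov generation.

    Returns (deposited, escaped) energy in MeV.  ``bank_count`` /
    ``bank_generated`` are 1-element int64 arrays (cursor, total generated).
    """
    nx, ny, nz = tissue.shape
    deposited = 0.0
    inv_l1_l2 = 1.0 / lam1 - 1.0 / lam2
    cap = bank_pos.shape[0]
    while e_kin > e_cutoff:
        ix = _voxel_of(ex, o0, s0)
        iy = _voxel_of(ey, o1, s1)
        iz = _voxel_of(ez, o2, s2)
        if ix < 0 or iy < 0 or iz < 0 or ix >= nx or iy >= ny or iz >= nz:
            return deposited, e_kin
        t = tissue[ix, iy, iz]
        rho_scale = density[ix, iy, iz] / rho_nom[t]
        s_loc = _table_interp(stop_tab, t, e_kin, e0_log, de_log) * rho_scale
        de = s_loc * step_mm
        if de > e_kin:
            de = e_kin
        e_mid = e_kin - 0.5 * de
        beta = _beta(e_mid)
        n_med = n_ref[t]
        bn = beta * n_med
        if bn > 1.0 and t != air_label:
            yld = ft_const * (1.0 - 1.0 / (bn * bn)) * inv_l1_l2 * 1.0e6  # photons/mm
            k = _poisson(yld * step_mm)
            if k > 0:
                emission[ix, iy, iz] += k
                bank_generated[0] += k
                # birth at the step midpoint unless it falls outside the
                # emitting voxel's tissue (boundary steps): then the start
                mx = ex + 0.5 * step_mm * dx
                my = ey + 0.5 * step_mm * dy
                mz = ez + 0.5 * step_mm * dz
                mix = _voxel_of(mx, o0, s0)
                miy = _voxel_of(my, o1, s1)
                miz = _voxel_of(mz, o2, s2)
                if (mix < 0 or miy < 0 or miz < 0 or mix >= nx or miy >= ny
                        or miz >= nz or tissue[mix, miy, miz] == air_label):
                    mx, my, mz = ex, ey, ez
                cos_c = 1.0 / bn
                for _ in range(k):
                    if emission_fraction < 1.0 and np.random.random() >= emission_fraction:
                        continue
                    if bank_count[0] >= cap:
                        continue
                    u = np.random.random()
                    lam = 1.0 / (1.0 / lam1 - u * inv_l1_l2)
                    phi = 2.0 * np.pi * np.random.random()
                    px, py, pz = _rotate(dx, dy, dz, cos_c, phi)
                    j = bank_count[0]
                    bank_pos[j, 0] = mx
                    bank_pos[j, 1] = my
                    bank_pos[j, 2] = mz
                    bank_dir[j, 0] = px
                    bank_dir[j, 1] = py
                    bank_dir[j, 2] = pz
                    bank_lam[j] = lam
                    bank_birth_tissue[j] = t
                    bank_count[0] += 1
        edep[ix, iy, iz] += de
        deposited += de
        e_kin -= de
        ex += dx * step_mm
        ey += dy * step_mm
        ez += dz * step_mm
    # residual below cutoff deposited locally if still inside
    if e_kin > 0.0:
        ix = _voxel_of(ex, o0, s0)
        iy = _voxel_of(ey, o1, s1)
        iz = _voxel_of(ez, o2, s2)
        if 0 <= ix < nx and 0 <= iy < ny and 0 <= iz < nz:
            edep[ix, iy, iz] += e_kin
            deposited += e_kin
        else:
            return deposited, e_kin
    return deposited, 0.0


@njit(cache=True)
def run_xray_batch(
    seed,
    src_pos, src_dir, src_e,
    tissue, density, origin, spacing,
    mu_c_tab, mu_pe_tab, stop_tab, rho_nom, e0_log, de_log,
    n_ref, ft_const, lam1, lam2,
    e_step, e_cutoff, x_cutoff, emission_fraction,
    edep, emission,
    bank_pos, bank_dir, bank_lam, bank_birth_tissue,
    hist_dep, hist_esc,
    air_label,
):
    """Transport a batch of X-ray photons; secondary electrons inline.

    Returns (n_banked, n_generated, total_escaped_energy).
    """
    np.random.seed(seed)
    nx, ny, nz = tissue.shape
    o0, o1, o2 = origin[0], origin[1], origin[2]
    s0, s1, s2 = spacing[0], spacing[1], spacing[2]
    lo0 = o0 - 0.5 * s0
    lo1 = o1 - 0.5 * s1
    lo2 = o2 - 0.5 * s2
    hi0 = o0 + (nx - 0.5) * s0
    hi1 = o1 + (ny - 0.5) * s1
    hi2 = o2 + (nz - 0.5) * s2
    bank_count = np.zeros(1, dtype=np.int64)
    bank_generated = np.zeros(1, dtype=np.int64)
    total_escaped = 0.0

    for h in range(src_pos.shape[0]):
        px = src_pos[h, 0]
        py = src_pos[h, 1]
        pz = src_pos[h, 2]
        dx = src_dir[h, 0]
        dy = src_dir[h, 1]
        dz = src_dir[h, 2]
        e = src_e[h]
        dep_h = 0.0
        esc_h = 0.0

        # advance to the domain if the photon starts outside
        if px < lo0 or px > hi0 or py < lo1 or py > hi1 or pz < lo2 or pz > hi2:
            t_in = _enter_box(px, py, pz, dx, dy, dz, lo0, lo1, lo2, hi0, hi1, hi2)
            if t_in < 0.0:
                hist_dep[h] = 0.0
                hist_esc[h] = e
                total_escaped += e
                continue
            t_in += 1e-9
            px += t_in * dx
            py += t_in * dy
            pz += t_in * dz

        alive = True
        while alive:
            if e <= x_cutoff:
                ix = _voxel_of(px, o0, s0)
                iy = _voxel_of(py, o1, s1)
                iz = _voxel_of(pz, o2, s2)
                if 0 <= ix < nx and 0 <= iy < ny and 0 <= iz < nz:
                    edep[ix, iy, iz] += e
                    dep_h += e
                else:
                    esc_h += e
                break
            tau = -np.log(np.random.random())
            ix = _voxel_of(px, o0, s0)
            iy = _voxel_of(py, o1, s1)
            iz = _voxel_of(pz, o2, s2)
            interacted = False
            # DDA march, accumulating optical depth in attenuation lengths
            while True:
                if ix < 0 or iy < 0 or iz < 0 or ix >= nx or iy >= ny or iz >= nz:
                    esc_h += e
                    alive = False
                    break
                t = tissue[ix, iy, iz]
                rho_scale = density[ix, iy, iz] / rho_nom[t]
                mc = _table_interp(mu_c_tab, t, e, e0_log, de_log) * rho_scale
                mp = _table_interp(mu_pe_tab, t, e, e0_log, de_log) * rho_scale
                mu_tot = mc + mp
                # distance to next voxel boundary
                tbest = 1e30
                axis = 0
                for a in range(3):
                    if a == 0:
                        d_a, p_a, o_a, s_a, i_a = dx, px, o0, s0, ix
                    elif a == 1:
                        d_a, p_a, o_a, s_a, i_a = dy, py, o1, s1, iy
                    else:
                        d_a, p_a, o_a, s_a, i_a = dz, pz, o2, s2, iz
                    if d_a > 1e-14:
                        bnd = o_a + (i_a + 0.5) * s_a
                        t_a = (bnd - p_a) / d_a
                    elif d_a < -1e-14:
                        bnd = o_a + (i_a - 0.5) * s_a
                        t_a = (bnd - p_a) / d_a
                    else:
                        t_a = 1e30
                    if t_a < tbest:
                        tbest = t_a
                        axis = a
                if tbest < 0.0:
                    tbest = 0.0
                if mu_tot > 0.0 and mu_tot * tbest >= tau:
                    step = tau / mu_tot
                    px += step * dx
                    py += step * dy
                    pz += step * dz
                    interacted = True
                    break
                tau -= mu_tot * tbest
                px += tbest * dx
                py += tbest * dy
                pz += tbest * dz
                if axis == 0:
                    ix += 1 if dx > 0 else -1
                elif axis == 1:
                    iy += 1 if dy > 0 else -1
                else:
                    iz += 1 if dz > 0 else -1
            if not alive:
                break
            if not interacted:
                continue
            # interaction in voxel (ix, iy, iz)
            t = tissue[ix, iy, iz]
            rho_scale = density[ix, iy, iz] / rho_nom[t]
            mc = _table_interp(mu_c_tab, t, e, e0_log, de_log) * rho_scale
            mp = _table_interp(mu_pe_tab, t, e, e0_log, de_log) * rho_scale
            if np.random.random() < mp / (mc + mp):
                # photoelectric: full local absorption
                edep[ix, iy, iz] += e
                dep_h += e
                break
            # Compton scatter
            cost = _sample_kn_cost(e)
            k = e / ELECTRON_REST
            e_sc = e / (1.0 + k * (1.0 - cost))
            e_el = e - e_sc
            phi = 2.0 * np.pi * np.random.random()
            # electron polar angle from kinematics
            sint = np.sqrt(max(0.0, 1.0 - cost * cost))
            half_tan = sint / (1.0 + cost) if cost > -1.0 + 1e-12 else 1e30
            tan_el = 1.0 / ((1.0 + k) * half_tan) if half_tan > 1e-30 else 1e30
            cos_el = 1.0 / np.sqrt(1.0 + tan_el * tan_el)
            if e_el > 0.0:
                edx, edy, edz = _rotate(dx, dy, dz, cos_el, phi + np.pi)
                dep, esc = _transport_electron_one(
                    px, py, pz, edx, edy, edz, e_el,
                    tissue, density, o0, o1, o2, s0, s1, s2,
                    stop_tab, rho_nom, e0_log, de_log,
                    n_ref, ft_const, lam1, lam2,
                    e_step, e_cutoff, emission_fraction,
                    edep, emission,
                    bank_pos, bank_dir, bank_lam, bank_birth_tissue,
                    bank_count, bank_generated,
                    air_label,
                )
                dep_h += dep
                esc_h += esc
            dx, dy, dz = _rotate(dx, dy, dz, cost, phi)
            e = e_sc
        hist_dep[h] = dep_h
        hist_esc[h] = esc_h
        total_escaped += esc_h
    return bank_count[0], bank_generated[0], total_escaped


@njit(cache=True)
def run_electron_batch(
    seed,
    src_pos, src_dir, src_e,
    tissue, density, origin, spacing,
    stop_tab, rho_nom, e0_log, de_log,
    n_ref, ft_const, lam1, lam2,
    e_step, e_cutoff, emission_fraction,
    edep, emission,
    bank_pos, bank_dir, bank_lam, bank_birth_tissue,
    hist_dep, hist_esc,
    air_label,
):
    """Transport a batch of primary electrons (no parent X-ray)."""
    np.random.seed(seed)
    o0, o1, o2 = origin[0], origin[1], origin[2]
    s0, s1, s2 = spacing[0], spacing[1], spacing[2]
    bank_count = np.zeros(1, dtype=np.int64)
    bank_generated = np.zeros(1, dtype=np.int64)
    for h in range(src_pos.shape[0]):
        dep, esc = _transport_electron_one(
            src_pos[h, 0], src_pos[h, 1], src_pos[h, 2],
            src_dir[h, 0], src_dir[h, 1], src_dir[h, 2], src_e[h],
            tissue, density, o0, o1, o2, s0, s1, s2,
            stop_tab, rho_nom, e0_log, de_log,
            n_ref, ft_const, lam1, lam2,
            e_step, e_cutoff, emission_fraction,
            edep, emission,
            bank_pos, bank_dir, bank_lam, bank_birth_tissue,
            bank_count, bank_generated,
            air_label,
        )
        hist_dep[h] = dep
        hist_esc[h] = esc
    return bank_count[0], bank_generated[0]


@njit(cache=True)
def _fresnel_unpolarized(cosi, n1, n2):
    sini2 = 1.0 - cosi * cosi
    sint2 = (n1 / n2) * (n1 / n2) * sini2
    if sint2 >= 1.0:
        return 1.0  # total internal reflection
    cost = np.sqrt(1.0 - sint2)
    rs = (n1 * cosi - n2 * cost) / (n1 * cosi + n2 * cost)
    rp = (n1 * cost - n2 * cosi) / (n1 * cost + n2 * cosi)
    return 0.5 * (rs * rs + rp * rp)


@njit(cache=True)
def run_optics_batch(
    seed,
    pos, direction, lam,
    tissue, origin, spacing,
    mua_tab, mus_tab, g_tab, n_tab, lam0, dlam,
    use_fresnel, max_events,
    face_lookup,
    status, exit_elem, exit_pos, exit_dir, absorb_voxel,
    fluence, score_fluence,
    air_label,
):
    """Trace a bank of optical photons to absorption or surface exit.

    ``status`` receives ABSORBED/EXITED/CAPPED per photon; exit arrays are
    filled for exited photons; ``absorb_voxel`` for absorbed ones.
    ``fluence`` accumulates track length per voxel when ``score_fluence``.
    """
    np.random.seed(seed)
    nx, ny, nz = tissue.shape
    o0, o1, o2 = origin[0], origin[1], origin[2]
    s0, s1, s2 = spacing[0], spacing[1], spacing[2]

    for h in range(pos.shape[0]):
        px = pos[h, 0]
        py = pos[h, 1]
        pz = pos[h, 2]
        dx = direction[h, 0]
        dy = direction[h, 1]
        dz = direction[h, 2]
        lm = lam[h]
        ix = _voxel_of(px, o0, s0)
        iy = _voxel_of(py, o1, s1)
        iz = _voxel_of(pz, o2, s2)
        events = 0
        st = ALIVE
        tau = -np.log(np.random.random())
        while st == ALIVE:
            t = tissue[ix, iy, iz]
            mua = _lam_interp(mua_tab, t, lm, lam0, dlam)
            mus = _lam_interp(mus_tab, t, lm, lam0, dlam)
            mu_tot = mua + mus
            # distance to next voxel boundary
            tbest = 1e30
            axis = 0
            for a in range(3):
                if a == 0:
                    d_a, p_a, o_a, s_a, i_a = dx, px, o0, s0, ix
                elif a == 1:
                    d_a, p_a, o_a, s_a, i_a = dy, py, o1, s1, iy
                else:
                    d_a, p_a, o_a, s_a, i_a = dz, pz, o2, s2, iz
                if d_a > 1e-14:
                    bnd = o_a + (i_a + 0.5) * s_a
                    t_a = (bnd - p_a) / d_a
                elif d_a < -1e-14:
                    bnd = o_a + (i_a - 0.5) * s_a
                    t_a = (bnd - p_a) / d_a
                else:
                    t_a = 1e30
                if t_a < tbest:
                    tbest = t_a
                    axis = a
            if tbest < 0.0:
                tbest = 0.0
            if mu_tot > 0.0 and mu_tot * tbest >= tau:
                # interaction inside this voxel
                step = tau / mu_tot
                if score_fluence:
                    fluence[ix, iy, iz] += step
                px += step * dx
                py += step * dy
                pz += step * dz
                if np.random.random() < mua / mu_tot:
                    st = ABSORBED
                    absorb_voxel[h, 0] = ix
                    absorb_voxel[h, 1] = iy
                    absorb_voxel[h, 2] = iz
                    break
                g_loc = _lam_interp(g_tab, t, lm, lam0, dlam)
                if abs(g_loc) < 1e-9:
                    cost = 2.0 * np.random.random() - 1.0
                else:
                    frac = (1.0 - g_loc * g_loc) / (1.0 - g_loc + 2.0 * g_loc * np.random.random())
                    cost = (1.0 + g_loc * g_loc - frac * frac) / (2.0 * g_loc)
                    if cost > 1.0:
                        cost = 1.0
                    elif cost < -1.0:
                        cost = -1.0
                phi = 2.0 * np.pi * np.random.random()
                dx, dy, dz = _rotate(dx, dy, dz, cost, phi)
                events += 1
                if events >= max_events:
                    st = CAPPED
                    absorb_voxel[h, 0] = ix
                    absorb_voxel[h, 1] = iy
                    absorb_voxel[h, 2] = iz
                    break
                tau = -np.log(np.random.random())
                continue
            # reach the boundary of the current voxel
            if score_fluence:
                fluence[ix, iy, iz] += tbest
            tau -= mu_tot * tbest
            px += tbest * dx
            py += tbest * dy
            pz += tbest * dz
            if axis == 0:
                nix, niy, niz = ix + (1 if dx > 0 else -1), iy, iz
                d_axis = dx
            elif axis == 1:
                nix, niy, niz = ix, iy + (1 if dy > 0 else -1), iz
                d_axis = dy
            else:
                nix, niy, niz = ix, iy, iz + (1 if dz > 0 else -1)
                d_axis = dz
            outside = nix < 0 or niy < 0 or niz < 0 or nix >= nx or niy >= ny or niz >= nz
            next_air = outside or tissue[nix, niy, niz] == air_label
            if not next_air:
                ix, iy, iz = nix, niy, niz
                continue
            # tissue-air (or domain) boundary: Fresnel or free escape
            side = 1 if d_axis > 0 else -1
            cosi = abs(d_axis)
            n1 = _lam_interp(n_tab, t, lm, lam0, dlam)
            n2 = 1.0
            refl = _fresnel_unpolarized(cosi, n1, n2) if use_fresnel else 0.0
            if np.random.random() < refl:
                # specular reflection: flip the axis component, stay inside
                if axis == 0:
                    dx = -dx
                elif axis == 1:
                    dy = -dy
                else:
                    dz = -dz
                events += 1
                if events >= max_events:
                    st = CAPPED
                    absorb_voxel[h, 0] = ix
                    absorb_voxel[h, 1] = iy
                    absorb_voxel[h, 2] = iz
                    break
                continue
            # refract and exit; face_lookup rows are (axis*2 + (0 for -, 1 for +))
            elem = face_lookup[axis * 2 + (1 if side > 0 else 0), ix, iy, iz]
            if use_fresnel and cosi < 1.0 - 1e-12:
                sini = np.sqrt(1.0 - cosi * cosi)
                sint = n1 / n2 * sini
                cost = np.sqrt(max(0.0, 1.0 - sint * sint))
                # tangential part scales by n1/n2, axis part set to cost
                scale = n1 / n2
                if axis == 0:
                    ty, tz = dy * scale, dz * scale
                    dx = side * cost
                    dy, dz = ty, tz
                elif axis == 1:
                    tx, tz = dx * scale, dz * scale
                    dy = side * cost
                    dx, dz = tx, tz
                else:
                    tx, ty = dx * scale, dy * scale
                    dz = side * cost
                    dx, dy = tx, ty
                nrm = np.sqrt(dx * dx + dy * dy + dz * dz)
                dx /= nrm
                dy /= nrm
                dz /= nrm
            st = EXITED
            exit_elem[h] = elem
            exit_pos[h, 0] = px
            exit_pos[h, 1] = py
            exit_pos[h, 2] = pz
            exit_dir[h, 0] = dx
            exit_dir[h, 1] = dy
            exit_dir[h, 2] = dz
        status[h] = st
    return 0
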