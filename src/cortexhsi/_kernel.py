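"""Numba kernels for weighted-photon Monte Carlo transport in the voxel slab.

Single-threaded, per-photon loop.  Every photon owns a splitmix64 substream
derived from the stream seed and its launch index, so results are independent
of batch size and identical for identical seeds.

Weight bookkeeping uses continuous absorption: along every straight segment
the packet weight decays by exp(−μa·ℓ) per traversed medium, and ℓ is accrued
to that medium's partial-pathlength tally.  Detection happens on Fresnel
transmission through the top surface; the lateral and bottom faces absorb
(the enlarged slab keeps boundary effects small) unless the mirror-walls test
flag is set.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

# splitmix64 constants
_GOLDEN = np.uint64(0x9E3779B97F4A7C15)
_MIX1 = np.uint64(0xBF58476D1CE4E5B9)
_MIX2 = np.uint64(0x94D049BB133111EB)
_S30 = np.uint64(30)
_S27 = np.uint64(27)
_S31 = np.uint64(31)
_S11 = np.uint64(11)
_ONE = np.uint64(1)
_INV53 = 1.0 / 9007199254740992.0  # 2^-53

# accounting slots
ACC_DETECTED = 0
ACC_ABSORBED = 1
ACC_ESCAPED_SIDE = 2
ACC_ESCAPED_BOTTOM = 3
ACC_SPECULAR = 4
ACC_ROULETTE = 5
ACC_STEPCAP = 6
ACC_SLOTS = 7

_EPS = 1e-12
_BIG = 1e30


@njit(cache=True, inline="always")
def _mix64(z):
    z = (z ^ (z >> _S30)) * _MIX1
    z = (z ^ (z >> _S27)) * _MIX2
    return z ^ (z >> _S31)


@njit(cache=True, inline="always")
def _uniform(state):
    """Advance the splitmix64 state; return (state, u) with u in (0, 1]."""
    state = state + _GOLDEN
    z = _mix64(state)
    return state, ((z >> _S11) + _ONE) * _INV53


@njit(cache=True, inline="always")
def _photon_state(seed, index):
    return _mix64(np.uint64(seed) ^ (np.uint64(index) * _MIX1) + _GOLDEN)


@njit(cache=True, inline="always")
def _sample_hg(state, g):
    """Henyey–Greenstein cosine of the deflection angle."""
    state, u = _uniform(state)
    if abs(g) < 1e-9:
        ct = 1.0 - 2.0 * u
    else:
        tmp = (1.0 - g * g) / (1.0 - g + 2.0 * g * u)
        ct = (1.0 + g * g - tmp * tmp) / (2.0 * g)
        if ct > 1.0:
            ct = 1.0
        elif ct < -1.0:
            ct = -1.0
    return state, ct


@njit(cache=True, inline="always")
def _fresnel(n1, n2, cos_i):
    """Unpolarized Fresnel reflectance and transmitted cosine for n1 → n2."""
    if cos_i > 1.0:
        cos_i = 1.0
    if n1 == n2:
        return 0.0, cos_i
    sin_i2 = 1.0 - cos_i * cos_i
    if sin_i2 < 0.0:
        sin_i2 = 0.0
    sin_t = n1 / n2 * math.sqrt(sin_i2)
    if sin_t >= 1.0:
        return 1.0, 0.0
    cos_t = math.sqrt(1.0 - sin_t * sin_t)
    rs = (n1 * cos_i - n2 * cos_t) / (n1 * cos_i + n2 * cos_t)
    rp = (n1 * cos_t - n2 * cos_i) / (n1 * cos_t + n2 * cos_i)
    return 0.5 * (rs * rs + rp * rp), cos_t


@njit(cache=True, inline="always")
def _spin(ux, uy, uz, ct, phi):
    """Rotate a unit direction by deflection cosine ct and azimuth phi."""
    st = math.sqrt(max(1.0 - ct * ct, 0.0))
    cp = math.cos(phi)
    sp = math.sin(phi)
    if abs(uz) > 0.99999:
        nx = st * cp
        ny = st * sp
        nz = ct if uz >= 0.0 else -ct
    else:
        den = math.sqrt(1.0 - uz * uz)
        nx = st * (ux * uz * cp - uy * sp) / den + ux * ct
        ny = st * (uy * uz * cp + ux * sp) / den + uy * ct
        nz = -st * cp * den + uz * ct
    norm = math.sqrt(nx * nx + ny * ny + nz * nz)
    return nx / norm, ny / norm, nz / norm


@njit(cache=True)
def _vessel_length(vox, h, x0g, y0g, px, py, pz, dx, dy, dz, ta, tb):
    """Path length inside vessel voxels along segment t ∈ [ta, tb].

    The caller guarantees z(t) lies within the vessel-layer depth for the
    whole interval.  3-D DDA; sub-segments leaving the grid count as gray.
    """
    nx, ny, nzl = vox.shape
    x = px + ta * dx
    y = py + ta * dy
    z = pz + ta * dz
    ix = int(math.floor((x - x0g) / h))
    iy = int(math.floor((y - y0g) / h))
    iz = int(math.floor(z / h))
    if ix < 0:
        ix = 0
    elif ix >= nx:
        ix = nx - 1
    if iy < 0:
        iy = 0
    elif iy >= ny:
        iy = ny - 1
    if iz < 0:
        iz = 0
    elif iz >= nzl:
        iz = nzl - 1

    if dx > 0.0:
        step_x = 1
        tmax_x = ta + ((ix + 1) * h + x0g - x) / dx
        tdel_x = h / dx
    elif dx < 0.0:
        step_x = -1
        tmax_x = ta + (ix * h + x0g - x) / dx
        tdel_x = -h / dx
    else:
        step_x = 0
        tmax_x = _BIG
        tdel_x = _BIG
    if dy > 0.0:
        step_y = 1
        tmax_y = ta + ((iy + 1) * h + y0g - y) / dy
        tdel_y = h / dy
    elif dy < 0.0:
        step_y = -1
        tmax_y = ta + (iy * h + y0g - y) / dy
        tdel_y = -h / dy
    else:
        step_y = 0
        tmax_y = _BIG
        tdel_y = _BIG
    if dz > 0.0:
        step_z = 1
        tmax_z = ta + ((iz + 1) * h) / dz - z / dz
        tdel_z = h / dz
    elif dz < 0.0:
        step_z = -1
        tmax_z = ta + (iz * h - z) / dz
        tdel_z = -h / dz
    else:
        step_z = 0
        tmax_z = _BIG
        tdel_z = _BIG

    lv = 0.0
    t = ta
    while t < tb - _EPS:
        tnext = tmax_x
        if tmax_y < tnext:
            tnext = tmax_y
        if tmax_z < tnext:
            tnext = tmax_z
        if tb < tnext:
            tnext = tb
        if vox[ix, iy, iz] == 1:
            lv += tnext - t
        t = tnext
        if t >= tb - _EPS:
            break
        if tmax_x <= tmax_y and tmax_x <= tmax_z:
            ix += step_x
            tmax_x += tdel_x
            if ix < 0 or ix >= nx:
                break
        elif tmax_y <= tmax_z:
            iy += step_y
            tmax_y += tdel_y
            if iy < 0 or iy >= ny:
                break
        else:
            iz += step_z
            tmax_z += tdel_z
            if iz < 0 or iz >= nzl:
                break
    return lv


@njit(cache=True, inline="always")
def _launch_one(state, collimated, reach, standoff,
                scx, scy, shx, shy, icx, icy, ihx, ihy):
    """Sample one launch: entry point uniform over the illuminated section,
    direction from a uniformly sampled source point within the divergence
    cone (rejection over source points).  Returns
    (state, ok, xe, ye, ux, uy, uz, attempts)."""
    xe = 0.0
    ye = 0.0
    ux = 0.0
    uy = 0.0
    uz = 1.0
    attempts = 0
    if collimated:
        for _ in range(10000):
            attempts += 1
            state, u1 = _uniform(state)
            state, u2 = _uniform(state)
            xe = scx + (2.0 * u1 - 1.0) * shx
            ye = scy + (2.0 * u2 - 1.0) * shy
            if abs(xe - icx) <= ihx and abs(ye - icy) <= ihy:
                return state, True, xe, ye, 0.0, 0.0, 1.0, attempts
        return state, False, xe, ye, ux, uy, uz, attempts
    state, u1 = _uniform(state)
    state, u2 = _uniform(state)
    xe = icx + (2.0 * u1 - 1.0) * ihx
    ye = icy + (2.0 * u2 - 1.0) * ihy
    for _ in range(10000):
        attempts += 1
        state, u1 = _uniform(state)
        state, u2 = _uniform(state)
        x0 = scx + (2.0 * u1 - 1.0) * shx
        y0 = scy + (2.0 * u2 - 1.0) * shy
        ddx = xe - x0
        ddy = ye - y0
        horiz2 = ddx * ddx + ddy * ddy
        if horiz2 <= reach * reach:
            norm = math.sqrt(horiz2 + standoff * standoff)
            return state, True, xe, ye, ddx / norm, ddy / norm, standoff / norm, attempts
    return state, False, xe, ye, ux, uy, uz, attempts


@njit(cache=True)
def sample_entry_points(n, seed, collimated, reach, standoff,
                        scx, scy, shx, shy, icx, icy, ihx, ihy,
                        out_x, out_y, out_uz):
    """Entry points and direction cosines of n launches (statistical tests)."""
    for i in range(n):
        state = _photon_state(seed, i)
        state, ok, xe, ye, ux, uy, uz, att = _launch_one(
            state, collimated, reach, standoff,
            scx, scy, shx, shy, icx, icy, ihx, ihy)
        out_x[i] = xe if ok else np.nan
        out_y[i] = ye if ok else np.nan
        out_uz[i] = uz if ok else np.nan


@njit(cache=True)
def run_photons(n_photons, seed, vox, voxel_h, hx, hy, zmax,
                scx, scy, shx, shy, standoff, cos_min,
                icx, icy, ihx, ihy,
                mua_v, mua_g, mus, g, n_rel,
                rr_threshold, rr_survive, max_steps, reflect_walls,
                out_x, out_y, out_w, out_pv, out_pg,
                acc, counters):
    """Trace n_photons; fill detection arrays, accounting and launch counters.

    Returns the number of detected photons.  ``acc`` collects weight by fate
    (see ACC_* slots); ``counters[0]`` counts launch attempts (rejection
    sampling of the source) and ``counters[1]`` failed launches.
    """
    nx, ny, nzl = vox.shape
    zlayer = nzl * voxel_h
    x0g = -hx
    y0g = -hy

    has_vessel = False
    vx_lo = _BIG
    vx_hi = -_BIG
    vy_lo = _BIG
    vy_hi = -_BIG
    for i in range(nx):
        for j in range(ny):
            any_v = False
            for k in range(nzl):
                if vox[i, j, k] == 1:
                    any_v = True
                    break
            if any_v:
                has_vessel = True
                xlo = x0g + i * voxel_h
                ylo = y0g + j * voxel_h
                if xlo < vx_lo:
                    vx_lo = xlo
                if xlo + voxel_h > vx_hi:
                    vx_hi = xlo + voxel_h
                if ylo < vy_lo:
                    vy_lo = ylo
                if ylo + voxel_h > vy_hi:
                    vy_hi = ylo + voxel_h

    collimated = cos_min >= 1.0 - 1e-12
    tan_max = 0.0
    if not collimated:
        tan_max = math.sqrt(1.0 / (cos_min * cos_min) - 1.0)
    reach = standoff * tan_max

    n_det = 0
    for i in range(n_photons):
        state = _photon_state(seed, i)

        # ---- launch: uniform coverage of the illuminated section ----
        state, ok, xe, ye, ux, uy, uz, attempts = _launch_one(
            state, collimated, reach, standoff,
            scx, scy, shx, shy, icx, icy, ihx, ihy)
        counters[0] += attempts
        if not ok:
            counters[1] += 1
            continue

        # ---- entry refraction / specular reflection at air→tissue ----
        refl, cos_t = _fresnel(1.0, n_rel, uz)
        state, u = _uniform(state)
        if u < refl:
            acc[ACC_SPECULAR] += 1.0
            continue
        if n_rel != 1.0:
            # tangential components scale by 1/n (Snell), normal becomes cos_t
            ux /= n_rel
            uy /= n_rel
            uz = cos_t
            norm = math.sqrt(ux * ux + uy * uy + uz * uz)
            ux /= norm
            uy /= norm
            uz /= norm

        px = xe
        py = ye
        pz = 0.0
        w = 1.0
        pv = 0.0
        pg = 0.0
        alive = True
        steps = 0

        while alive:
            state, u = _uniform(state)
            if mus > 0.0:
                s = -math.log(u) / mus
            else:
                s = _BIG

            while s > _EPS and alive:
                # distance to the nearest boundary along the direction
                t_b = s
                hit = 0
                if uz < 0.0:
                    tt = -pz / uz
                    if tt < t_b:
                        t_b = tt
                        hit = 1
                elif uz > 0.0:
                    tt = (zmax - pz) / uz
                    if tt < t_b:
                        t_b = tt
                        hit = 2
                if ux > 0.0:
                    tt = (hx - px) / ux
                    if tt < t_b:
                        t_b = tt
                        hit = 3
                elif ux < 0.0:
                    tt = (-hx - px) / ux
                    if tt < t_b:
                        t_b = tt
                        hit = 3
                if uy > 0.0:
                    tt = (hy - py) / uy
                    if tt < t_b:
                        t_b = tt
                        hit = 4
                elif uy < 0.0:
                    tt = (-hy - py) / uy
                    if tt < t_b:
                        t_b = tt
                        hit = 4

                seg = t_b
                # vessel portion of this segment (vessels live at z < zlayer)
                lv = 0.0
                if has_vessel:
                    if uz > 0.0:
                        if pz < zlayer:
                            ta = 0.0
                            tb = (zlayer - pz) / uz
                            if tb > seg:
                                tb = seg
                        else:
                            ta = 0.0
                            tb = -1.0
                    elif uz < 0.0:
                        if pz <= zlayer:
                            ta = 0.0
                        else:
                            ta = (zlayer - pz) / uz
                        tb = seg
                    else:
                        if pz < zlayer:
                            ta = 0.0
                            tb = seg
                        else:
                            ta = 0.0
                            tb = -1.0
                    if tb > ta:
                        # bounding-box reject against the vessel footprint
                        xa = px + ta * ux
                        xb = px + tb * ux
                        ya = py + ta * uy
                        yb = py + tb * uy
                        xmin = xa if xa < xb else xb
                        xmax = xa if xa > xb else xb
                        ymin = ya if ya < yb else yb
                        ymax = ya if ya > yb else yb
                        if xmax >= vx_lo and xmin <= vx_hi and ymax >= vy_lo and ymin <= vy_hi:
                            lv = _vessel_length(vox, voxel_h, x0g, y0g,
                                                px, py, pz, ux, uy, uz, ta, tb)
                lg = seg - lv
                if lg < 0.0:
                    lg = 0.0
                att = math.exp(-(mua_v * lv + mua_g * lg))
                acc[ACC_ABSORBED] += w * (1.0 - att)
                w *= att
                pv += lv
                pg += lg
                px += seg * ux
                py += seg * uy
                pz += seg * uz
                s -= seg

                if hit == 1:
                    pz = 0.0
                    cos_i = -uz
                    refl, cos_t = _fresnel(n_rel, 1.0, cos_i)
                    state, u = _uniform(state)
                    if u < refl:
                        uz = -uz
                    else:
                        out_x[n_det] = px
                        out_y[n_det] = py
                        out_w[n_det] = w
                        out_pv[n_det] = pv
                        out_pg[n_det] = pg
                        n_det += 1
                        acc[ACC_DETECTED] += w
                        alive = False
                elif hit == 2:
                    if reflect_walls:
                        pz = zmax
                        uz = -uz
                    else:
                        acc[ACC_ESCAPED_BOTTOM] += w
                        alive = False
                elif hit == 3:
                    if reflect_walls:
                        px = hx if ux > 0.0 else -hx
                        ux = -ux
                    else:
                        acc[ACC_ESCAPED_SIDE] += w
                        alive = False
                elif hit == 4:
                    if reflect_walls:
                        py = hy if uy > 0.0 else -hy
                        uy = -uy
                    else:
                        acc[ACC_ESCAPED_SIDE] += w
                        alive = False

            if not alive:
                break

            # scattering event
            state, ct = _sample_hg(state, g)
            state, u = _uniform(state)
            ux, uy, uz = _spin(ux, uy, uz, ct, 2.0 * math.pi * u)

            steps += 1
            if w < rr_threshold:
                state, u = _uniform(state)
                if u < rr_survive:
                    w /= rr_survive
                else:
                    acc[ACC_ROULETTE] += w
                    alive = False
            if alive and steps >= max_steps:
                acc[ACC_STEPCAP] += w
                alive = False

    return n_det


@njit(cache=True)
def sample_hg_many(n, seed, g, out):
    """Draw n Henyey–Greenstein deflection cosines (for statistical tests)."""
    state = _photon_state(seed, 0)
    for i in range(n):
        state, ct = _sample_hg(state, g)
        out[i] = ct


@njit(cache=True)
def hg_inverse(u, g):
    """Closed-form HG inversion for a given uniform variate (test hook)."""
    if abs(g) < 1e-9:
        return 1.0 - 2.0 * u
    tmp = (1.0 - g * g) / (1.0 - g + 2.0 * g * u)
    return (1.0 + g * g - tmp * tmp) / (2.0 * g)
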