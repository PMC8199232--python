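"""Numba photon-transport kernel for the slab + cylindrical-vessel geometry.

Weight bookkeeping is exact: every unit of launched weight ends up in exactly
one tally (specular R, diffuse R, T, absorption in background or vessel, side
escape), so the energy budget sums to one up to float rounding.
"""

import math

import numpy as np
from numba import njit

# tally indices
I_RSPEC = 0
I_RDIFF = 1
I_T = 2
I_ABS_BG = 3
I_ABS_V = 4
I_ESIDE = 5

_EPS = 1e-7  # mm, boundary nudge
_BIG = 1e30


@njit(cache=True, inline="always")
def _fresnel(n_i, n_t, cos_i):
    """Unpolarized Fresnel reflectance; 1.0 beyond the critical angle."""
    if n_i == n_t:
        return 0.0
    if cos_i > 1.0:
        cos_i = 1.0
    sin_i2 = 1.0 - cos_i * cos_i
    ratio = n_i / n_t
    sin_t2 = ratio * ratio * sin_i2
    if sin_t2 >= 1.0:
        return 1.0
    cos_t = math.sqrt(1.0 - sin_t2)
    rs = (n_i * cos_i - n_t * cos_t) / (n_i * cos_i + n_t * cos_t)
    rp = (n_i * cos_t - n_t * cos_i) / (n_i * cos_t + n_t * cos_i)
    return 0.5 * (rs * rs + rp * rp)


@njit(cache=True, inline="always")
def _hg_cos(g, u):
    """Sample cos(theta) from the Henyey-Greenstein phase function."""
    if abs(g) < 1e-6:
        return 2.0 * u - 1.0
    s = (1.0 - g * g) / (1.0 - g + 2.0 * g * u)
    c = (1.0 + g * g - s * s) / (2.0 * g)
    if c < -1.0:
        c = -1.0
    elif c > 1.0:
        c = 1.0
    return c


@njit(cache=True, inline="always")
def _cyl_hit(px, pz, ux, uz, cx, cz, r):
    """Smallest ray-parameter t > eps where the ray crosses the cylinder
    |(x,z) - (cx,cz)| = r (axis along y); _BIG if none."""
    a = ux * ux + uz * uz
    if a <= 0.0:
        return _BIG
    dx = px - cx
    dz = pz - cz
    b = dx * ux + dz * uz
    c = dx * dx + dz * dz - r * r
    disc = b * b - a * c
    if disc <= 0.0:
        return _BIG
    sq = math.sqrt(disc)
    t1 = (-b - sq) / a
    t2 = (-b + sq) / a
    if t1 > _EPS:
        return t1
    if t2 > _EPS:
        return t2
    return _BIG


@njit(cache=True)
def transport(
    n_photons,
    seed,
    spot_radius,
    thickness,
    lateral_radius,
    vessel_present,
    ves_z,
    ves_r,
    mua_bg,
    mus_bg,
    g_bg,
    mua_v,
    mus_v,
    g_v,
    n_above,
    n_slab,
    n_below,
    n_vessel,
    vessel_fresnel,
    roulette_threshold,
    roulette_survival,
    max_steps,
    grid,
    grid_on,
    pitch,
    ngx,
    ngy,
    ngz,
):
    np.random.seed(seed)
    tallies = np.zeros(6)
    lat2 = lateral_radius * lateral_radius
    mut_bg = mua_bg + mus_bg
    mut_v = mua_v + mus_v
    r_entry = _fresnel(n_above, n_slab, 1.0)

    for _ in range(n_photons):
        # launch on the flat-top spot, normal incidence
        rr = spot_radius * math.sqrt(np.random.random())
        phi = 2.0 * math.pi * np.random.random()
        x = rr * math.cos(phi)
        y = rr * math.sin(phi)
        z = 0.0
        ux = 0.0
        uy = 0.0
        uz = 1.0
        tallies[I_RSPEC] += r_entry
        w = 1.0 - r_entry
        tau = -math.log(1.0 - np.random.random())
        alive = True
        steps = 0

        while alive:
            steps += 1
            in_vessel = False
            if vessel_present:
                dxv = x
                dzv = z - ves_z
                in_vessel = dxv * dxv + dzv * dzv < ves_r * ves_r
            if in_vessel:
                mua = mua_v
                mus = mus_v
                mut = mut_v
                gg = g_v
                iabs = I_ABS_V
            else:
                mua = mua_bg
                mus = mus_bg
                mut = mut_bg
                gg = g_bg
                iabs = I_ABS_BG

            s_free = tau / mut if mut > 0.0 else _BIG

            # distances to boundaries
            d_top = _BIG
            d_bot = _BIG
            if uz < 0.0:
                d_top = -z / uz
            elif uz > 0.0:
                d_bot = (thickness - z) / uz
            # lateral disc
            d_lat = _BIG
            a2 = ux * ux + uy * uy
            if a2 > 0.0:
                b2 = x * ux + y * uy
                c2 = x * x + y * y - lat2
                disc = b2 * b2 - a2 * c2
                if disc > 0.0:
                    t = (-b2 + math.sqrt(disc)) / a2
                    if t > 0.0:
                        d_lat = t
            d_ves = _BIG
            if vessel_present:
                d_ves = _cyl_hit(x, z, ux, uz, 0.0, ves_z, ves_r)

            d_b = d_top
            which = 0  # 0 top, 1 bottom, 2 lateral, 3 vessel wall
            if d_bot < d_b:
                d_b = d_bot
                which = 1
            if d_lat < d_b:
                d_b = d_lat
                which = 2
            if d_ves < d_b:
                d_b = d_ves
                which = 3

            if s_free < d_b:
                # interaction inside the current region
                x += s_free * ux
                y += s_free * uy
                z += s_free * uz
                dw = w * (mua / mut)
                w -= dw
                tallies[iabs] += dw
                if grid_on and dw > 0.0:
                    ix = int((x + lateral_radius) / pitch)
                    iy = int((y + lateral_radius) / pitch)
                    iz = int(z / pitch)
                    if ix < 0:
                        ix = 0
                    elif ix >= ngx:
                        ix = ngx - 1
                    if iy < 0:
                        iy = 0
                    elif iy >= ngy:
                        iy = ngy - 1
                    if iz < 0:
                        iz = 0
                    elif iz >= ngz:
                        iz = ngz - 1
                    grid[(ix * ngy + iy) * ngz + iz] += dw
                killed = False
                if w < roulette_threshold:
                    if np.random.random() >= roulette_survival:
                        killed = True
                if steps >= max_steps:
                    killed = True
                if killed:
                    # residual weight absorbed at the termination site, so the
                    # energy ledger stays exact
                    tallies[iabs] += w
                    if grid_on and w > 0.0:
                        ix = int((x + lateral_radius) / pitch)
                        iy = int((y + lateral_radius) / pitch)
                        iz = int(z / pitch)
                        if ix < 0:
                            ix = 0
                        elif ix >= ngx:
                            ix = ngx - 1
                        if iy < 0:
                            iy = 0
                        elif iy >= ngy:
                            iy = ngy - 1
                        if iz < 0:
                            iz = 0
                        elif iz >= ngz:
                            iz = ngz - 1
                        grid[(ix * ngy + iy) * ngz + iz] += w
                    alive = False
                    continue
                # spin
                cost = _hg_cos(gg, np.random.random())
                sint = math.sqrt(max(0.0, 1.0 - cost * cost))
                phi = 2.0 * math.pi * np.random.random()
                cosp = math.cos(phi)
                sinp = math.sin(phi)
                if abs(uz) > 0.99999:
                    ux = sint * cosp
                    uy = sint * sinp
                    uz = cost if uz > 0.0 else -cost
                else:
                    temp = math.sqrt(1.0 - uz * uz)
                    uxn = sint * (ux * uz * cosp - uy * sinp) / temp + ux * cost
                    uyn = sint * (uy * uz * cosp + ux * sinp) / temp + uy * cost
                    uzn = -sint * cosp * temp + uz * cost
                    norm = math.sqrt(uxn * uxn + uyn * uyn + uzn * uzn)
                    ux = uxn / norm
                    uy = uyn / norm
                    uz = uzn / norm
                tau = -math.log(1.0 - np.random.random())
            else:
                # move to the boundary
                x += d_b * ux
                y += d_b * uy
                z += d_b * uz
                tau -= d_b * mut
                if tau < 0.0:
                    tau = 0.0
                if which == 0:
                    cos_i = -uz
                    if np.random.random() < _fresnel(n_slab, n_above, cos_i):
                        uz = -uz
                        z = _EPS
                    else:
                        tallies[I_RDIFF] += w
                        alive = False
                elif which == 1:
                    cos_i = uz
                    if np.random.random() < _fresnel(n_slab, n_below, cos_i):
                        uz = -uz
                        z = thickness - _EPS
                    else:
                        tallies[I_T] += w
                        alive = False
                elif which == 2:
                    tallies[I_ESIDE] += w
                    alive = False
                else:
                    # vessel wall
                    if vessel_fresnel:
                        nxw = x / ves_r
                        nzw = (z - ves_z) / ves_r
                        cos_i = abs(ux * nxw + uz * nzw)
                        if in_vessel:
                            n1 = n_vessel
                            n2 = n_slab
                        else:
                            n1 = n_slab
                            n2 = n_vessel
                        if np.random.random() < _fresnel(n1, n2, cos_i):
                            dot = ux * nxw + uz * nzw
                            ux -= 2.0 * dot * nxw
                            uz -= 2.0 * dot * nzw
                            x += _EPS * ux
                            y += _EPS * uy
                            z += _EPS * uz
                        else:
                            x += _EPS * ux
                            y += _EPS * uy
                            z += _EPS * uz
                    else:
                        x += _EPS * ux
                        y += _EPS * uy
                        z += _EPS * uz
                if alive and steps >= max_steps:
                    tallies[iabs] += w
                    if grid_on and w > 0.0:
                        ix = int((x + lateral_radius) / pitch)
                        iy = int((y + lateral_radius) / pitch)
                        iz = int(z / pitch)
                        if ix < 0:
                            ix = 0
                        elif ix >= ngx:
                            ix = ngx - 1
                        if iy < 0:
                            iy = 0
                        elif iy >= ngy:
                            iy = ngy - 1
                        if iz < 0:
                            iz = 0
                        elif iz >= ngz:
                            iz = ngz - 1
                        grid[(ix * ngy + iy) * ngz + iz] += w
                    alive = False

    return tallies
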