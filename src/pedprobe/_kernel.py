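"""Numba-compiled photon-packet transport kernel.

Scalar per-photon loop (MCML-style hop / drop / spin / roulette) consuming a
numpy ``Generator`` stream so that a pure-Python tracer sharing the same
stream reproduces identical trajectories. Random draws, in order per photon
step: step length, [HG deflection, azimuth] after each interaction, and one
roulette draw whenever the weight falls below the threshold.

All kernel lengths are cm. Layer edges are ``z_edges`` (len = n_layers + 1);
the photon's layer index is tracked explicitly so that edge crossings are
exact. Outer surfaces are absorbing (Dirichlet): a photon reaching z = 0 or
z = z_total is terminated and its weight logged as escaped. Detection is a
virtual-plane test at z = z_probe: crossing upward inside the detector disc
(centered ``det_x`` off-axis, squared radius ``det_r2``) with |uz| >=
``cos_min`` terminates the photon and scores its weight.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

#: Russian-roulette weight threshold and survival probability (MCML defaults).
ROULETTE_THRESHOLD = 1e-4
ROULETTE_SURVIVE = 0.1

#: Distance-based roulette: photons wandering far from the detector are
#: unlikely to contribute; once a photon first exceeds FAR_RADIUS_CM
#: (spherical distance from the detector-fiber centre) it plays roulette
#: with survival FAR_SURVIVE (survivor weight boosted accordingly, so the
#: estimator stays unbiased), and the triggering shell then grows by
#: FAR_GROWTH so oscillating photons are not repeatedly taxed.
FAR_RADIUS_CM = 0.3
FAR_SURVIVE = 0.2
FAR_GROWTH = 1.5


@njit(cache=True)
def _hg_cos(g: float, u: float) -> float:
    """Henyey-Greenstein deflection cosine from one uniform draw."""
    if g == 0.0:
        return 1.0 - 2.0 * u
    tmp = (1.0 - g * g) / (1.0 - g + 2.0 * g * u)
    ct = (1.0 + g * g - tmp * tmp) / (2.0 * g)
    if ct > 1.0:
        ct = 1.0
    elif ct < -1.0:
        ct = -1.0
    return ct


@njit(cache=True)
def _trace_one(
    z_edges,
    mu_t,
    albedo,
    g_arr,
    zp,
    det_x,
    det_r2,
    cos_min,
    li_start,
    gen,
):
    """Trace one photon packet; returns (detected, escaped, absorbed, roulette_net).

    detected + escaped + absorbed + roulette_net == 1 (launch weight) up to
    float rounding.
    """
    x = 0.0
    y = 0.0
    z = zp
    ux = 0.0
    uy = 0.0
    uz = 1.0
    li = li_start
    w = 1.0
    detected = 0.0
    escaped = 0.0
    absorbed = 0.0
    rnet = 0.0
    nlay = mu_t.shape[0]
    shell = FAR_RADIUS_CM

    while True:
        # --- hop (possibly across index-matched layer edges) ---
        s = -math.log(1.0 - gen.random())
        while True:
            mt = mu_t[li]
            d_int = s / mt
            if uz > 0.0:
                d_b = (z_edges[li + 1] - z) / uz
            elif uz < 0.0:
                d_b = (z_edges[li] - z) / uz
            else:
                d_b = 1e30
            if d_b < 0.0:
                d_b = 0.0
            hit = d_b <= d_int
            d = d_b if hit else d_int
            if hit:
                zn = z_edges[li + 1] if uz > 0.0 else z_edges[li]
            else:
                zn = z + uz * d
            # detection-plane crossing, moving toward the probe (-z)
            if uz < 0.0 and z > zp and zn <= zp:
                t = (zp - z) / uz
                xc = x + ux * t - det_x
                yc = y + uy * t
                if xc * xc + yc * yc <= det_r2 and -uz >= cos_min:
                    detected = w
                    return detected, escaped, absorbed, rnet
            x += ux * d
            y += uy * d
            if hit:
                s -= d_b * mt
                if uz > 0.0:
                    z = z_edges[li + 1]
                    li += 1
                    if li >= nlay:
                        escaped = w
                        return detected, escaped, absorbed, rnet
                else:
                    z = z_edges[li]
                    li -= 1
                    if li < 0:
                        escaped = w
                        return detected, escaped, absorbed, rnet
            else:
                z = zn
                break
        # --- drop ---
        a = albedo[li]
        absorbed += w * (1.0 - a)
        w *= a
        # --- spin (Henyey-Greenstein deflection, uniform azimuth) ---
        ct = _hg_cos(g_arr[li], gen.random())
        st = math.sqrt(1.0 - ct * ct)
        phi = 2.0 * math.pi * gen.random()
        cp = math.cos(phi)
        sp = math.sin(phi)
        if abs(uz) > 0.99999:
            ux = st * cp
            uy = st * sp
            uz = ct if uz >= 0.0 else -ct
        else:
            den = math.sqrt(1.0 - uz * uz)
            nx = st * (ux * uz * cp - uy * sp) / den + ux * ct
            ny = st * (uy * uz * cp + ux * sp) / den + uy * ct
            nz = -st * cp * den + uz * ct
            ux = nx
            uy = ny
            uz = nz
        # --- roulette (low weight, then distance shells) ---
        if w < ROULETTE_THRESHOLD:
            if gen.random() <= ROULETTE_SURVIVE:
                rnet -= w * (1.0 / ROULETTE_SURVIVE - 1.0)
                w *= 1.0 / ROULETTE_SURVIVE
            else:
                rnet += w
                return detected, escaped, absorbed, rnet
        dx = x - det_x
        dz = z - zp
        if dx * dx + y * y + dz * dz > shell * shell:
            if gen.random() <= FAR_SURVIVE:
                rnet -= w * (1.0 / FAR_SURVIVE - 1.0)
                w *= 1.0 / FAR_SURVIVE
                shell *= FAR_GROWTH
            else:
                rnet += w
                return detected, escaped, absorbed, rnet


@njit(cache=True)
def _run_batch(
    n_photons,
    z_edges,
    mu_t,
    albedo,
    g_arr,
    zp,
    det_x,
    det_r2,
    cos_min,
    li_start,
    gen,
):
    """Launch ``n_photons`` sequentially on one stream.

    Returns (sum_detected, sum_detected_sq, sum_escaped, sum_absorbed,
    sum_roulette_net, n_detected).
    """
    sw = 0.0
    sw2 = 0.0
    se = 0.0
    sa = 0.0
    sr = 0.0
    nd = 0
    for _ in range(n_photons):
        det, esc, ab, rn = _trace_one(
            z_edges, mu_t, albedo, g_arr, zp, det_x, det_r2, cos_min, li_start, gen
        )
        sw += det
        sw2 += det * det
        se += esc
        sa += ab
        sr += rn
        if det > 0.0:
            nd += 1
    return sw, sw2, se, sa, sr, nd
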