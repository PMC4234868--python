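"""Independent scalar reference tracer for photon transport.

A deliberately plain pure-Python reimplementation of the layered-slab photon
walk used to cross-check the compiled kernel: same physics, same random-draw
order (step, deflection, azimuth, roulette), written directly from the
transport rules rather than from the kernel's code. Shares a numpy
``Generator`` stream with the implementation under test so trajectories can
be compared photon by photon.
"""

from __future__ import annotations

import math

ROULETTE_THRESHOLD = 1e-4
ROULETTE_SURVIVE = 0.1
FAR_RADIUS_CM = 0.3
FAR_SURVIVE = 0.2
FAR_GROWTH = 1.5


def reference_trace(model, probe, probe_depth_mm, gen):
    """Trace one photon; returns (detected, escaped, absorbed, roulette_net)."""
    edges = list(model.boundaries_cm())
    mu_t = [layer.props.mu_t for layer in model.layers]
    albedo = [layer.props.albedo for layer in model.layers]
    gs = [layer.props.g for layer in model.layers]
    zp = probe_depth_mm / 10.0
    det_x = probe.separation_cm
    det_r2 = probe.detector_radius_cm**2
    cos_min = probe.acceptance_cos_min
    li = model.layer_index_at(probe_depth_mm)
    nlay = len(model.layers)

    pos = [0.0, 0.0, zp]
    direction = [0.0, 0.0, 1.0]
    w = 1.0
    absorbed = 0.0
    roulette_net = 0.0
    shell = FAR_RADIUS_CM

    while True:
        s = -math.log(1.0 - gen.random())
        # propagate, possibly through several index-matched layers
        while True:
            d_interact = s / mu_t[li]
            uz = direction[2]
            if uz > 0.0:
                d_edge = (edges[li + 1] - pos[2]) / uz
            elif uz < 0.0:
                d_edge = (edges[li] - pos[2]) / uz
            else:
                d_edge = math.inf
            d_edge = max(d_edge, 0.0)
            crosses_edge = d_edge <= d_interact
            travel = d_edge if crosses_edge else d_interact
            if crosses_edge:
                z_end = edges[li + 1] if uz > 0.0 else edges[li]
            else:
                z_end = pos[2] + uz * travel
            # virtual detection plane at the probe tip
            if uz < 0.0 and pos[2] > zp and z_end <= zp:
                frac = (zp - pos[2]) / uz
                cx = pos[0] + direction[0] * frac - det_x
                cy = pos[1] + direction[1] * frac
                if cx * cx + cy * cy <= det_r2 and -uz >= cos_min:
                    return (w, 0.0, absorbed, roulette_net)
            pos[0] += direction[0] * travel
            pos[1] += direction[1] * travel
            if crosses_edge:
                s -= d_edge * mu_t[li]
                if uz > 0.0:
                    pos[2] = edges[li + 1]
                    li += 1
                    if li >= nlay:
                        return (0.0, w, absorbed, roulette_net)
                else:
                    pos[2] = edges[li]
                    li -= 1
                    if li < 0:
                        return (0.0, w, absorbed, roulette_net)
            else:
                pos[2] = z_end
                break
        # absorb part of the packet weight
        absorbed += w * (1.0 - albedo[li])
        w *= albedo[li]
        # Henyey-Greenstein deflection + uniform azimuth
        g = gs[li]
        u = gen.random()
        if g == 0.0:
            cos_t = 1.0 - 2.0 * u
        else:
            lever = (1.0 - g * g) / (1.0 - g + 2.0 * g * u)
            cos_t = (1.0 + g * g - lever * lever) / (2.0 * g)
            cos_t = min(1.0, max(-1.0, cos_t))
        sin_t = math.sqrt(1.0 - cos_t * cos_t)
        phi = 2.0 * math.pi * gen.random()
        cos_p, sin_p = math.cos(phi), math.sin(phi)
        ux, uy, uz = direction
        if abs(uz) > 0.99999:
            direction = [sin_t * cos_p, sin_t * sin_p, cos_t if uz >= 0.0 else -cos_t]
        else:
            root = math.sqrt(1.0 - uz * uz)
            direction = [
                sin_t * (ux * uz * cos_p - uy * sin_p) / root + ux * cos_t,
                sin_t * (uy * uz * cos_p + ux * sin_p) / root + uy * cos_t,
                -sin_t * cos_p * root + uz * cos_t,
            ]
        # Russian roulette on low-weight packets
        if w < ROULETTE_THRESHOLD:
            if gen.random() <= ROULETTE_SURVIVE:
                roulette_net -= w * (1.0 / ROULETTE_SURVIVE - 1.0)
                w *= 1.0 / ROULETTE_SURVIVE
            else:
                return (0.0, 0.0, absorbed, roulette_net + w)
        # distance roulette once per expanding shell around the detector
        off_x = pos[0] - det_x
        off_z = pos[2] - zp
        if off_x * off_x + pos[1] * pos[1] + off_z * off_z > shell * shell:
            if gen.random() <= FAR_SURVIVE:
                roulette_net -= w * (1.0 / FAR_SURVIVE - 1.0)
                w *= 1.0 / FAR_SURVIVE
                shell *= FAR_GROWTH
            else:
                return (0.0, 0.0, absorbed, roulette_net + w)
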