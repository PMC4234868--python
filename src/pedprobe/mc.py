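"""Photon Monte Carlo of fiber-probe reflectance in a layered slab.

The probe tip sits on the horizontal plane z = probe_depth inside the tissue;
each photon packet is launched at the source-fiber position on that plane,
directed straight ahead (+z, an infinitely narrow collimated beam normal to
the tip plane), and is collected if it re-crosses the tip plane moving back
toward the probe inside the detector-fiber footprint within the acceptance
cone. The probe body itself occupies no volume. Entry and internal
interfaces are refractive-index matched, so no Fresnel events occur; the
outer slab surfaces are absorbing (Dirichlet).
"""

from __future__ import annotations

import math
from typing import NamedTuple

import numpy as np

from . import _kernel
from .errors import InvalidParameterError
from .optics import (
    MM_PER_CM,
    DepthProfile,
    LayeredModel,
    ProbeGeometry,
    ScanSchedule,
)

MAX_SEED = 2**31


class PhotonLedger(NamedTuple):
    """Per-photon weight bookkeeping; entries sum to the launch weight 1."""

    detected: float
    escaped: float
    absorbed: float
    roulette_net: float


def sample_step(mu_t: float, u: float) -> float:
    """Exponential free-path length -ln(u)/mu_t in cm.

    ``u`` must lie in (0, 1]; ``mu_t`` is the total attenuation coefficient
    in cm^-1.
    """
    if not np.isfinite(mu_t) or mu_t <= 0:
        raise InvalidParameterError(f"mu_t must be > 0, got {mu_t}")
    if not 0.0 < u <= 1.0:
        raise InvalidParameterError(f"u must be in (0, 1], got {u}")
    return -math.log(u) / mu_t


def sample_scatter(
    g: float, u1: float, u2: float, incoming: np.ndarray
) -> np.ndarray:
    """New unit direction after one Henyey-Greenstein scattering event.

    The polar deflection cosine is drawn from the HG distribution with
    anisotropy ``g`` (isotropic for g = 0) via ``u1``; the azimuth is
    2*pi*``u2``. ``incoming`` must be a unit 3-vector.
    """
    if not 0.0 <= g < 1.0:
        raise InvalidParameterError(f"g must be in [0, 1), got {g}")
    v = np.asarray(incoming, dtype=float)
    if v.shape != (3,) or abs(float(v @ v) - 1.0) > 1e-9:
        raise InvalidParameterError("incoming direction must be a unit 3-vector")
    ct = _kernel._hg_cos(g, float(u1))
    st = math.sqrt(1.0 - ct * ct)
    phi = 2.0 * math.pi * float(u2)
    cp, sp = math.cos(phi), math.sin(phi)
    ux, uy, uz = v
    if abs(uz) > 0.99999:
        out = np.array([st * cp, st * sp, ct if uz >= 0 else -ct])
    else:
        den = math.sqrt(1.0 - uz * uz)
        out = np.array(
            [
                st * (ux * uz * cp - uy * sp) / den + ux * ct,
                st * (uy * uz * cp + ux * sp) / den + uy * ct,
                -st * cp * den + uz * ct,
            ]
        )
    return out


def _kernel_args(model: LayeredModel, probe: ProbeGeometry, probe_depth_mm: float):
    model.uniform_n()  # raises NotImplementedError on internal n mismatch
    if not 0.0 <= probe_depth_mm < model.total_thickness_mm:
        raise InvalidParameterError(
            f"probe depth {probe_depth_mm} mm outside model "
            f"[0, {model.total_thickness_mm}) mm"
        )
    z_edges = model.boundaries_cm()
    mu_t = np.array([l.props.mu_t for l in model.layers])
    albedo = np.array([l.props.albedo for l in model.layers])
    g_arr = np.array([l.props.g for l in model.layers])
    zp = probe_depth_mm / MM_PER_CM
    li = model.layer_index_at(probe_depth_mm)
    return (
        z_edges,
        mu_t,
        albedo,
        g_arr,
        zp,
        probe.separation_cm,
        probe.detector_radius_cm**2,
        probe.acceptance_cos_min,
        li,
    )


def trace_photon(
    model: LayeredModel,
    probe: ProbeGeometry,
    probe_depth_mm: float,
    rng: np.random.Generator,
) -> float:
    """Trace one photon packet; returns its detected weight (0 if lost)."""
    return trace_photon_detail(model, probe, probe_depth_mm, rng).detected


def trace_photon_detail(
    model: LayeredModel,
    probe: ProbeGeometry,
    probe_depth_mm: float,
    rng: np.random.Generator,
) -> PhotonLedger:
    """Trace one photon and return the full weight ledger."""
    args = _kernel_args(model, probe, probe_depth_mm)
    return PhotonLedger(*_kernel._trace_one(*args, rng))


def simulate_reflectance(
    model: LayeredModel,
    probe: ProbeGeometry,
    probe_depth_mm: float,
    n_photons: int,
    seed: int,
    return_stderr: bool = False,
):
    """Mean detected weight per launched photon at one probe depth.

    Reproducible for a given ``seed``. With ``return_stderr=True`` also
    returns the Monte Carlo standard error of the mean.
    """
    if n_photons < 1:
        raise InvalidParameterError("n_photons must be >= 1")
    args = _kernel_args(model, probe, probe_depth_mm)
    gen = np.random.default_rng(int(seed) % MAX_SEED)
    sw, sw2, _, _, _, _ = _kernel._run_batch(int(n_photons), *args, gen)
    mean = sw / n_photons
    if not return_stderr:
        return mean
    var = max(sw2 / n_photons - mean * mean, 0.0)
    return mean, math.sqrt(var / n_photons)


def depth_scan(
    model: LayeredModel,
    probe: ProbeGeometry,
    schedule: ScanSchedule,
    n_photons: int,
    seed: int,
) -> DepthProfile:
    """Reflectance profile over a schedule of probe depths.

    Each depth uses an independent substream seeded ``seed + depth_index``.
    The returned profile carries both the raw reflectance and the profile
    normalized to its first point, plus per-depth standard errors.
    """
    if len(schedule) == 0:
        raise InvalidParameterError("empty scan schedule")
    if schedule.depths_mm[-1] >= model.total_thickness_mm:
        raise InvalidParameterError("schedule extends beyond the model")
    raw = np.empty(len(schedule))
    se = np.empty(len(schedule))
    for i, depth in enumerate(schedule.depths_mm):
        raw[i], se[i] = simulate_reflectance(
            model, probe, float(depth), n_photons, (int(seed) + i) % MAX_SEED,
            return_stderr=True,
        )
    profile = DepthProfile(
        schedule.depths_mm.copy(), raw, None, se, int(n_photons), int(seed)
    )
    return profile.normalized()
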