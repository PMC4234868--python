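"""Domain types for layered-slab photon transport.

Geometry convention: the z axis points *down* into the tissue, with z = 0 at
the top surface. Internally all lengths are centimetres (optical coefficients
are conventionally quoted in cm^-1); every user-facing depth or thickness is
in millimetres.

The bundled two-layer vertebra model places spongy (trabecular) bone on top of
compact (cortical) bone, with the optical properties of each measured at
690 nm: spongy mu_s' = 17.23 cm^-1, mu_a = 0.41 cm^-1; compact
mu_s' = 12.02 cm^-1, mu_a = 0.21 cm^-1. Both layers share g = 0.9 and
n = 1.38, so all internal and entry interfaces are refractive-index matched.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import DegenerateProfileError, InvalidParameterError

MM_PER_CM = 10.0


@dataclass(frozen=True)
class OpticalProperties:
    """Bulk optical properties of one homogeneous layer.

    Parameters
    ----------
    mu_a : float
        Absorption coefficient, cm^-1.
    mu_s_reduced : float
        Reduced scattering coefficient mu_s' = mu_s * (1 - g), cm^-1.
    g : float
        Scattering anisotropy (mean cosine of the single-scattering
        deflection angle), in [0, 1).
    n : float
        Refractive index, >= 1.
    """

    mu_a: float
    mu_s_reduced: float
    g: float = 0.9
    n: float = 1.38

    def __post_init__(self) -> None:
        if not np.isfinite(self.mu_a) or self.mu_a < 0:
            raise InvalidParameterError(f"mu_a must be >= 0, got {self.mu_a}")
        if not np.isfinite(self.mu_s_reduced) or self.mu_s_reduced <= 0:
            raise InvalidParameterError(
                f"mu_s_reduced must be > 0, got {self.mu_s_reduced}"
            )
        if not 0.0 <= self.g < 1.0:
            raise InvalidParameterError(f"g must be in [0, 1), got {self.g}")
        if self.n < 1.0:
            raise InvalidParameterError(f"n must be >= 1, got {self.n}")

    @property
    def mu_s(self) -> float:
        """Scattering coefficient mu_s = mu_s' / (1 - g), cm^-1."""
        return self.mu_s_reduced / (1.0 - self.g)

    @property
    def mu_t(self) -> float:
        """Total attenuation coefficient mu_a + mu_s, cm^-1."""
        return self.mu_a + self.mu_s

    @property
    def albedo(self) -> float:
        """Single-scattering albedo mu_s / mu_t."""
        return self.mu_s / self.mu_t


@dataclass(frozen=True)
class Layer:
    """One slab layer: optical properties plus thickness in mm."""

    props: OpticalProperties
    thickness_mm: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.thickness_mm) or self.thickness_mm <= 0:
            raise InvalidParameterError(
                f"layer thickness must be > 0 mm, got {self.thickness_mm}"
            )


@dataclass(frozen=True)
class LayeredModel:
    """Ordered stack of layers, top (z = 0) to bottom."""

    layers: tuple[Layer, ...]

    def __post_init__(self) -> None:
        if len(self.layers) < 1:
            raise InvalidParameterError("model needs at least one layer")

    @property
    def total_thickness_mm(self) -> float:
        return float(sum(l.thickness_mm for l in self.layers))

    def boundaries_cm(self) -> np.ndarray:
        """Layer edge depths [0, t1, t1+t2, ...] in cm."""
        t = np.cumsum([0.0] + [l.thickness_mm for l in self.layers])
        return t / MM_PER_CM

    def layer_index_at(self, depth_mm: float) -> int:
        """Index of the layer that a downward-moving photon at ``depth_mm``
        is entering. A depth exactly on an internal edge belongs to the
        layer below it."""
        if not 0.0 <= depth_mm < self.total_thickness_mm:
            raise InvalidParameterError(
                f"depth {depth_mm} mm outside model [0, {self.total_thickness_mm})"
            )
        edges = self.boundaries_cm()
        idx = int(np.searchsorted(edges, depth_mm / MM_PER_CM, side="right")) - 1
        return min(max(idx, 0), len(self.layers) - 1)

    def uniform_n(self) -> float:
        """Common refractive index; raises if layers are mismatched.

        Mismatched internal interfaces (Fresnel events) are deliberately not
        implemented: the probe's operating configuration is index-matched
        everywhere.
        """
        ns = {l.props.n for l in self.layers}
        if len(ns) > 1:
            raise NotImplementedError(
                "refractive-index mismatch between layers is not supported"
            )
        return ns.pop()


@dataclass(frozen=True)
class ProbeGeometry:
    """Dual-fiber needle probe: one source and one detector fiber.

    separation_um is the center-to-center source-detector distance. A photon
    is collected when it re-crosses the probe-tip plane moving toward the
    probe, inside the detector-fiber disc, with |direction cosine| at least
    ``acceptance_cos_min`` (default 0.5; the physical fibers' numerical
    aperture is narrower, this is configurable).
    """

    fiber_diameter_um: float = 200.0
    separation_um: float = 200.0
    acceptance_cos_min: float = 0.5

    def __post_init__(self) -> None:
        if self.fiber_diameter_um <= 0:
            raise InvalidParameterError("fiber diameter must be > 0")
        if self.separation_um < self.fiber_diameter_um:
            raise InvalidParameterError(
                "separation must be >= fiber diameter (fibers cannot overlap)"
            )
        if not 0.0 < self.acceptance_cos_min <= 1.0:
            raise InvalidParameterError("acceptance_cos_min must be in (0, 1]")

    @property
    def separation_cm(self) -> float:
        return self.separation_um * 1e-4

    @property
    def detector_radius_cm(self) -> float:
        return 0.5 * self.fiber_diameter_um * 1e-4


@dataclass(frozen=True)
class ScanSchedule:
    """Ordered probe depths H (mm from the top surface) for a depth scan."""

    depths_mm: np.ndarray

    def __post_init__(self) -> None:
        d = np.asarray(self.depths_mm, dtype=float)
        object.__setattr__(self, "depths_mm", d)
        if d.ndim != 1 or d.size == 0:
            raise InvalidParameterError("schedule must be a non-empty 1-d sequence")
        if np.any(np.diff(d) <= 0):
            raise InvalidParameterError("schedule depths must be strictly increasing")
        if d[0] < 0:
            raise InvalidParameterError("schedule depths must be >= 0")

    def __len__(self) -> int:
        return int(self.depths_mm.size)

    @classmethod
    def two_step(
        cls,
        coarse_stop_mm: float = 4.0,
        fine_stop_mm: float = 6.0,
        coarse_step_mm: float = 0.2,
        fine_step_mm: float = 0.1,
    ) -> "ScanSchedule":
        """The bone-scan schedule: 0.2 mm steps on [0, 4] mm, then 0.1 mm
        steps up to 6 mm while the probe crosses the layer boundary."""
        coarse = np.arange(0.0, coarse_stop_mm + 1e-9, coarse_step_mm)
        fine = np.arange(
            coarse_stop_mm + fine_step_mm, fine_stop_mm + 1e-9, fine_step_mm
        )
        return cls(np.round(np.concatenate([coarse, fine]), 6))


@dataclass
class DepthProfile:
    """Detected reflectance versus probe depth.

    ``raw`` is mean detected photon weight per launched photon;
    ``norm`` is the same profile divided by its first point;
    ``stderr`` is the per-depth Monte Carlo standard error of ``raw``.
    """

    depths_mm: np.ndarray
    raw: np.ndarray
    norm: np.ndarray | None = None
    stderr: np.ndarray | None = None
    n_photons: int = 0
    seed: int | None = None

    def __post_init__(self) -> None:
        self.depths_mm = np.asarray(self.depths_mm, dtype=float)
        self.raw = np.asarray(self.raw, dtype=float)
        if self.depths_mm.shape != self.raw.shape:
            raise InvalidParameterError("depths and intensities differ in length")
        if np.any(self.raw < 0):
            raise InvalidParameterError("reflectance must be >= 0")
        for name in ("norm", "stderr"):
            v = getattr(self, name)
            if v is not None:
                v = np.asarray(v, dtype=float)
                if v.shape != self.depths_mm.shape:
                    raise InvalidParameterError(f"{name} length mismatch")
                setattr(self, name, v)

    def normalized(self) -> "DepthProfile":
        """Profile normalized to the reflectance of the first point."""
        first = self.raw[0]
        if first <= 0:
            raise DegenerateProfileError("first-point reflectance is not positive")
        se = None if self.stderr is None else self.stderr / first
        return DepthProfile(
            self.depths_mm, self.raw, self.raw / first, se, self.n_photons, self.seed
        )

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {"depth_mm": self.depths_mm, "reflectance_raw": self.raw}
        )
        df["reflectance_norm"] = (
            self.norm if self.norm is not None else np.full(len(df), np.nan)
        )
        if self.stderr is not None:
            df["reflectance_se"] = self.stderr
        df["n_photons"] = self.n_photons
        df["seed"] = self.seed if self.seed is not None else -1
        return df

    def write(self, path, header_lines: Sequence[str] = ()) -> None:
        with open(path, "w", encoding="utf-8", newline="\n") as fh:
            for line in header_lines:
                fh.write(f"# {line}\n")
            self.to_frame().to_csv(fh, index=False, lineterminator="\n")

    @classmethod
    def read(cls, path) -> "DepthProfile":
        with open(path, "r", encoding="utf-8") as fh:
            text = "\n".join(
                l for l in fh.read().splitlines() if not l.startswith("#")
            )
        df = pd.read_csv(io.StringIO(text))
        norm = df["reflectance_norm"].to_numpy() if "reflectance_norm" in df else None
        if norm is not None and np.all(np.isnan(norm)):
            norm = None
        se = df["reflectance_se"].to_numpy() if "reflectance_se" in df else None
        return cls(
            df["depth_mm"].to_numpy(),
            df["reflectance_raw"].to_numpy(),
            norm,
            se,
            int(df["n_photons"].iloc[0]) if "n_photons" in df else 0,
            int(df["seed"].iloc[0]) if "seed" in df else None,
        )


SPONGY_BONE_690NM = OpticalProperties(mu_a=0.41, mu_s_reduced=17.23, g=0.9, n=1.38)
COMPACT_BONE_690NM = OpticalProperties(mu_a=0.21, mu_s_reduced=12.02, g=0.9, n=1.38)


def two_layer_vertebra_model(
    spongy_thickness_mm: float = 5.0, compact_thickness_mm: float = 2.0
) -> LayeredModel:
    """The default vertebra geometry: 5 mm spongy over 2 mm compact bone."""
    return LayeredModel(
        (
            Layer(SPONGY_BONE_690NM, spongy_thickness_mm),
            Layer(COMPACT_BONE_690NM, compact_thickness_mm),
        )
    )
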