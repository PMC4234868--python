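"""Reflectance spectra and the three spectral pattern factors.

A probe spectrum spans 340-1020 nm. Raw spectrometer counts are converted to
reflectance by R = (signal - dark) / (reference - dark), where dark is the
source-off reading and reference the spectrum of a ~99.9% reflective white
standard. Three scalar *pattern factors* summarize a spectrum for tissue
classification:

* area  - trapezoidal integral of intensity over 340-1020 nm,
* peak  - maximum intensity (ties resolved to the shortest wavelength),
* slope - ordinary-least-squares slope over 500-550 nm, multiplied by a
  configurable reporting scale (default x1000; the printed slope values of
  the bone study are on this scale for count-valued spectra).

Factors are computed on whatever intensity scale is supplied (raw counts or
normalized R); the bone-study tables use count-scaled spectra.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import (
    GridMismatchError,
    InsufficientDataError,
    InvalidParameterError,
    RangeError,
)

AREA_RANGE_NM = (340.0, 1020.0)
SLOPE_RANGE_NM = (500.0, 550.0)
SLOPE_SCALE = 1000.0
EXPECTED_REPLICATES = 20

FACTOR_NAMES = ("mu_s_reduced", "peak", "area", "slope")


@dataclass(frozen=True)
class Spectrum:
    """Wavelength grid (nm, strictly increasing) with intensities."""

    wavelengths: np.ndarray
    intensities: np.ndarray

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelengths, dtype=float)
        it = np.asarray(self.intensities, dtype=float)
        object.__setattr__(self, "wavelengths", wl)
        object.__setattr__(self, "intensities", it)
        if wl.ndim != 1 or wl.shape != it.shape:
            raise InvalidParameterError("wavelengths/intensities length mismatch")
        if wl.size < 2:
            raise InvalidParameterError("spectrum needs at least two samples")
        if np.any(np.diff(wl) <= 0):
            raise InvalidParameterError("wavelengths must be strictly increasing")
        if not np.all(np.isfinite(it)):
            raise InvalidParameterError("intensities must be finite")

    def same_grid(self, other: "Spectrum") -> bool:
        return self.wavelengths.shape == other.wavelengths.shape and np.array_equal(
            self.wavelengths, other.wavelengths
        )

    def window(self, lo_nm: float, hi_nm: float) -> np.ndarray:
        """Boolean mask of grid points in [lo, hi], endpoints inclusive."""
        wl = self.wavelengths
        if lo_nm < wl[0] or hi_nm > wl[-1]:
            raise RangeError(
                f"window [{lo_nm}, {hi_nm}] nm not covered by grid "
                f"[{wl[0]}, {wl[-1]}] nm"
            )
        return (wl >= lo_nm) & (wl <= hi_nm)


@dataclass(frozen=True)
class PatternFactors:
    """The three spectral factors plus the externally measured mu_s'."""

    area: float
    peak: float
    slope: float
    mu_s_reduced: float

    def as_dict(self) -> dict:
        return {
            "area": self.area,
            "peak": self.peak,
            "slope": self.slope,
            "mu_s_reduced": self.mu_s_reduced,
        }


def normalize_reflectance(
    signal: Spectrum, dark: Spectrum, reference: Spectrum
) -> Spectrum:
    """R(lambda) = (signal - dark) / (reference - dark), elementwise."""
    if not (signal.same_grid(dark) and signal.same_grid(reference)):
        raise GridMismatchError("signal/dark/reference grids differ")
    denom = reference.intensities - dark.intensities
    if np.any(denom <= 0):
        raise InvalidParameterError(
            "reference - dark must be positive at every wavelength "
            "(saturated or underexposed reference)"
        )
    return Spectrum(signal.wavelengths, (signal.intensities - dark.intensities) / denom)


def average_replicates(
    spectra: Sequence[Spectrum], expected_count: int = EXPECTED_REPLICATES
) -> Spectrum:
    """Pointwise mean of replicate spectra (default protocol: 20 readings).

    Warns, but does not fail, when the replicate count differs from the
    protocol's expectation.
    """
    if len(spectra) == 0:
        raise InsufficientDataError("no replicate spectra to average")
    first = spectra[0]
    for s in spectra[1:]:
        if not first.same_grid(s):
            raise GridMismatchError("replicates are not on a common grid")
    if len(spectra) != expected_count:
        warnings.warn(
            f"averaging {len(spectra)} replicates (protocol expects "
            f"{expected_count})",
            stacklevel=2,
        )
    stack = np.stack([s.intensities for s in spectra])
    return Spectrum(first.wavelengths, stack.mean(axis=0))


def area_factor(
    spectrum: Spectrum,
    lo_nm: float = AREA_RANGE_NM[0],
    hi_nm: float = AREA_RANGE_NM[1],
) -> float:
    """Trapezoidal integral of intensity over [lo, hi] nm (intensity * nm)."""
    mask = spectrum.window(lo_nm, hi_nm)
    if mask.sum() < 2:
        raise InsufficientDataError("need >= 2 grid points to integrate")
    return float(
        np.trapezoid(spectrum.intensities[mask], spectrum.wavelengths[mask])
    )


def peak_factor(
    spectrum: Spectrum,
    lo_nm: float = AREA_RANGE_NM[0],
    hi_nm: float = AREA_RANGE_NM[1],
) -> float:
    """Maximum intensity within [lo, hi] nm."""
    mask = spectrum.window(lo_nm, hi_nm)
    return float(np.max(spectrum.intensities[mask]))


def peak_location(
    spectrum: Spectrum,
    lo_nm: float = AREA_RANGE_NM[0],
    hi_nm: float = AREA_RANGE_NM[1],
) -> float:
    """Wavelength of the maximum; ties go to the shortest wavelength."""
    mask = spectrum.window(lo_nm, hi_nm)
    wl = spectrum.wavelengths[mask]
    return float(wl[int(np.argmax(spectrum.intensities[mask]))])


def slope_factor(
    spectrum: Spectrum,
    lo_nm: float = SLOPE_RANGE_NM[0],
    hi_nm: float = SLOPE_RANGE_NM[1],
    scale: float = SLOPE_SCALE,
) -> float:
    """OLS slope of intensity vs wavelength over [lo, hi] nm, times ``scale``."""
    mask = spectrum.window(lo_nm, hi_nm)
    if mask.sum() < 2:
        raise InsufficientDataError("need >= 2 grid points for a slope")
    x = spectrum.wavelengths[mask]
    y = spectrum.intensities[mask]
    xc = x - x.mean()
    return float((xc @ (y - y.mean())) / (xc @ xc)) * scale


def extract_pattern_factors(
    spectrum: Spectrum,
    mu_s_reduced: float,
    area_range_nm: tuple[float, float] = AREA_RANGE_NM,
    slope_range_nm: tuple[float, float] = SLOPE_RANGE_NM,
    slope_scale: float = SLOPE_SCALE,
) -> PatternFactors:
    """Bundle area, peak and slope with the supplied mu_s' measurement.

    mu_s' comes from an external estimate (device firmware or the synthetic
    generator); its derivation from spectra is outside this package's scope.
    """
    return PatternFactors(
        area=area_factor(spectrum, *area_range_nm),
        peak=peak_factor(spectrum, *area_range_nm),
        slope=slope_factor(spectrum, *slope_range_nm, scale=slope_scale),
        mu_s_reduced=float(mu_s_reduced),
    )


def read_spectrum(path) -> Spectrum:
    """Read a two-column (wavelength_nm, intensity) delimited text file.

    Tolerates '#' comment lines and a single non-numeric header line.
    """
    rows = []
    with open(path, "r", encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.replace(",", " ").split()
            try:
                rows.append((float(parts[0]), float(parts[1])))
            except (ValueError, IndexError):
                if not rows:  # tolerate one header line
                    continue
                raise
    if len(rows) < 2:
        raise InsufficientDataError(f"no spectral data found in {path}")
    arr = np.array(rows)
    return Spectrum(arr[:, 0], arr[:, 1])


def write_spectrum(spectrum: Spectrum, path, header_lines: Iterable[str] = ()) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        fh.write("wavelength_nm,intensity\n")
        for wl, it in zip(spectrum.wavelengths, spectrum.intensities):
            fh.write(f"{wl:.6g},{float(it)!r}\n")


def factor_table(
    records: Iterable[tuple[float, str, PatternFactors]]
) -> pd.DataFrame:
    """Assemble (depth, region, factors) records into the standard labeled
    factor table with columns depth_mm, region, mu_s_reduced, peak, area,
    slope."""
    rows = [
        {"depth_mm": d, "region": r, **pf.as_dict()} for d, r, pf in records
    ]
    df = pd.DataFrame(rows, columns=["depth_mm", "region", *FACTOR_NAMES])
    return df.sort_values("depth_mm", ignore_index=True)
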