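"""Source/target system models and the spectral response matrix.

The target system illuminates the scene one narrow band at a time
through two liquid-crystal tunable filters (LCTFs): a VIS filter
covering 420-730 nm and an NIR filter covering 650-1100 nm.  The
per-band emission spectra, measured on a dense spectrometer grid, are
stitched across the 710 nm transition, arranged as a dense-wavelength x
band matrix, restricted to the 440-900 nm effective range of the source
sensor, and min-max scaled per band.  The result is the normalized
spectral response matrix SR used by the mapper.

The source system (a push-broom camera) has bands narrow enough to be
modelled as Dirac deltas at their nominal centres; its only spectral
characterization is the sensor quantum-efficiency curve.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import numpy as np

from .hsio import SpectralAxis, read_spectrum_csv, write_spectrum_csv

__all__ = [
    "QECurve",
    "BandEmission",
    "ResponseMatrix",
    "TargetSystemSpec",
    "SourceSystemSpec",
    "BandMode",
    "band_grid",
    "stitch_bands",
    "build_response_matrix",
    "write_emission_library",
    "read_emission_library",
    "source_band_grid",
]

BandMode = Literal["narrow", "medium", "wide", "nir"]


@dataclass(frozen=True)
class QECurve:
    """Sensor quantum efficiency vs wavelength, in (0, 1]."""

    axis: SpectralAxis
    efficiency: np.ndarray

    def __post_init__(self) -> None:
        eff = np.asarray(self.efficiency, dtype=float)
        if eff.shape != (len(self.axis),):
            raise ValueError("efficiency length does not match axis")
        if np.any(eff <= 0) or np.any(eff > 1):
            raise ValueError("quantum efficiency must lie in (0, 1]")
        object.__setattr__(self, "efficiency", eff)

    def at(self, wavelengths_nm: np.ndarray) -> np.ndarray:
        """Linearly interpolated efficiency at the requested wavelengths."""
        wl = np.asarray(wavelengths_nm, dtype=float)
        lo, hi = self.axis.span
        if np.any(wl < lo) or np.any(wl > hi):
            raise ValueError("requested wavelengths outside the QE curve support")
        return np.interp(wl, self.axis.wavelengths, self.efficiency)


@dataclass(frozen=True)
class BandEmission:
    """Measured emitted power density of one illumination band."""

    center_nm: float
    mode: BandMode
    axis: SpectralAxis
    spectrum: np.ndarray

    def __post_init__(self) -> None:
        sp = np.asarray(self.spectrum, dtype=float)
        if sp.shape != (len(self.axis),):
            raise ValueError("spectrum length does not match axis")
        if np.any(sp < 0):
            raise ValueError(f"band {self.center_nm} nm has negative emission values")
        step = np.diff(self.axis.wavelengths)
        if np.max(step) > 1.0 + 1e-9:
            raise ValueError("emission spectra must be sampled at <= 1 nm")
        object.__setattr__(self, "spectrum", sp)

    def resampled(self, dense_axis: SpectralAxis) -> np.ndarray:
        """Spectrum linearly interpolated onto ``dense_axis`` (no extrapolation)."""
        if dense_axis is self.axis or dense_axis == self.axis:
            return self.spectrum
        lo, hi = self.axis.span
        qlo, qhi = dense_axis.span
        if qlo < lo - 1e-9 or qhi > hi + 1e-9:
            raise ValueError(
                f"band {self.center_nm} nm: dense axis extends beyond the measured support"
            )
        return np.interp(dense_axis.wavelengths, self.axis.wavelengths, self.spectrum)


@dataclass
class ResponseMatrix:
    """Normalized spectral response: dense wavelengths x target bands.

    Every column is min-max scaled to [0, 1] over the dense samples,
    so each band's response attains both 0 and 1 exactly.
    """

    dense_axis: SpectralAxis
    band_centers: np.ndarray
    matrix: np.ndarray

    def __post_init__(self) -> None:
        bc = np.asarray(self.band_centers, dtype=float)
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (len(self.dense_axis), bc.size):
            raise ValueError("matrix shape does not match dense axis / band centers")
        if np.any(np.diff(bc) <= 0):
            raise ValueError("band centers must be strictly increasing")
        self.band_centers = bc
        self.matrix = m

    @property
    def n_bands(self) -> int:
        return int(self.band_centers.size)

    @property
    def band_axis(self) -> SpectralAxis:
        # _unchecked: a single-band response matrix is degenerate but legal
        return SpectralAxis._unchecked(self.band_centers)


@dataclass(frozen=True)
class TargetSystemSpec:
    """Band-grid geometry of the narrow-band-illumination target system."""

    vis_range_nm: tuple[float, float] = (420.0, 730.0)
    nir_range_nm: tuple[float, float] = (650.0, 1100.0)
    sampling_nm: float = 5.0
    transition_nm: float = 710.0
    effective_range_nm: tuple[float, float] = (440.0, 900.0)

    def __post_init__(self) -> None:
        overlap = (self.nir_range_nm[0], self.vis_range_nm[1])
        if not overlap[0] <= self.transition_nm <= overlap[1]:
            raise ValueError("transition band must lie in the VIS/NIR overlap")
        lo = min(self.vis_range_nm[0], self.nir_range_nm[0])
        hi = max(self.vis_range_nm[1], self.nir_range_nm[1])
        if not (lo <= self.effective_range_nm[0] < self.effective_range_nm[1] <= hi):
            raise ValueError("effective range must lie within the VIS+NIR union")

    @property
    def full_grid(self) -> SpectralAxis:
        lo = min(self.vis_range_nm[0], self.nir_range_nm[0])
        hi = max(self.vis_range_nm[1], self.nir_range_nm[1])
        return band_grid(lo, hi, self.sampling_nm)

    @property
    def vis_grid(self) -> SpectralAxis:
        return band_grid(*self.vis_range_nm, self.sampling_nm)

    @property
    def nir_grid(self) -> SpectralAxis:
        return band_grid(*self.nir_range_nm, self.sampling_nm)


@dataclass(frozen=True)
class SourceSystemSpec:
    """Dirac-response source system: band centres plus sensor QE."""

    band_centers: SpectralAxis
    qe: QECurve
    response_model: Literal["dirac"] = "dirac"

    def __post_init__(self) -> None:
        lo, hi = self.qe.axis.span
        blo, bhi = self.band_centers.span
        if blo < lo or bhi > hi:
            raise ValueError("source band centres fall outside the QE curve span")


def band_grid(start_nm: float, stop_nm: float, step_nm: float) -> SpectralAxis:
    """Inclusive arithmetic wavelength grid start, start+step, ... <= stop."""
    if step_nm <= 0:
        raise ValueError("step must be positive")
    if start_nm >= stop_nm:
        raise ValueError("start must be below stop")
    n = int(np.floor((stop_nm - start_nm) / step_nm + 1e-9)) + 1
    return SpectralAxis(start_nm + step_nm * np.arange(n))


def source_band_grid(kind: Literal["full", "selected"] = "full") -> SpectralAxis:
    """Band grids of the push-broom source system.

    ``full``: 826 bands spanning 400-1000 nm (~0.73 nm sampling).
    ``selected``: 128 bands spanning the 440-900 nm effective range
    (~3.6 nm sampling), the configuration used for the tissue benchmark.
    """
    if kind == "full":
        return SpectralAxis(np.linspace(400.0, 1000.0, 826))
    if kind == "selected":
        return SpectralAxis(np.linspace(440.0, 900.0, 128))
    raise ValueError(f"unknown source grid kind {kind!r}")


def stitch_bands(
    vis_bands: Sequence[BandEmission],
    nir_bands: Sequence[BandEmission],
    transition_nm: float = 710.0,
) -> list[BandEmission]:
    """Merge VIS and NIR band emissions across the transition wavelength.

    Centres below the transition come from the VIS filter, centres at or
    above it from the NIR filter (where the NIR path delivers more
    power).  Exactly one emission per centre is returned, sorted.
    """
    vis = {b.center_nm: b for b in vis_bands}
    nir = {b.center_nm: b for b in nir_bands}
    centers = sorted(set(vis) | set(nir))
    out: list[BandEmission] = []
    for c in centers:
        pool = vis if c < transition_nm else nir
        if c not in pool:
            side = "VIS" if c < transition_nm else "NIR"
            raise ValueError(f"band centre {c} nm not covered by the {side} emission set")
        out.append(pool[c])
    return out


def build_response_matrix(
    emissions: Sequence[BandEmission],
    dense_axis: SpectralAxis,
    effective_range_nm: tuple[float, float] = (440.0, 900.0),
) -> ResponseMatrix:
    """Assemble and normalize the spectral response matrix SR.

    Emissions are resampled onto ``dense_axis``, both rows (dense
    wavelengths) and columns (bands, by centre) are restricted to the
    inclusive effective range, and each retained column is min-max
    scaled to [0, 1].
    """
    lo, hi = effective_range_nm
    dlo, dhi = dense_axis.span
    if lo < dlo or hi > dhi:
        raise ValueError("effective range extends beyond the dense axis span")
    kept = [b for b in sorted(emissions, key=lambda b: b.center_nm) if lo <= b.center_nm <= hi]
    if not kept:
        raise ValueError("no band centres inside the effective range")
    row_mask = (dense_axis.wavelengths >= lo) & (dense_axis.wavelengths <= hi)
    rows_axis = SpectralAxis(dense_axis.wavelengths[row_mask])
    cols = []
    for b in kept:
        col = b.resampled(dense_axis)[row_mask]
        rng = col.max() - col.min()
        if rng <= 0:
            raise ValueError(f"band {b.center_nm} nm has a constant (degenerate) response")
        cols.append((col - col.min()) / rng)
    return ResponseMatrix(
        dense_axis=rows_axis,
        band_centers=np.array([b.center_nm for b in kept]),
        matrix=np.column_stack(cols),
    )


# ---------------------------------------------------------------------------
# Emission library on disk: one CSV per band, {mode}_{center}nm.csv


def write_emission_library(emissions: Sequence[BandEmission], path: str | Path) -> None:
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    for b in emissions:
        name = f"{b.mode}_{b.center_nm:g}nm.csv"
        write_spectrum_csv(path / name, b.axis.wavelengths, b.spectrum, "power_density")


def read_emission_library(path: str | Path) -> list[BandEmission]:
    path = Path(path)
    out: list[BandEmission] = []
    for csv in sorted(path.glob("*_*nm.csv")):
        mode, rest = csv.stem.split("_", 1)
        center = float(rest[:-2])
        wl, power = read_spectrum_csv(csv)
        out.append(BandEmission(center_nm=center, mode=mode, axis=SpectralAxis(wl), spectrum=power))  # type: ignore[arg-type]
    return sorted(out, key=lambda b: (b.center_nm, b.mode))
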