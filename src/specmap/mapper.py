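"""The five-step high-to-low spectral mapping engine.

Given a raw capture from a spectrally dense source system, the mapping

1. takes the raw cube A,
2. estimates the spectral irradiance SI = A / QE reaching the sensor,
3. linearly interpolates SI onto the dense spectrometer grid on which
   the target system's per-band emissions were measured,
4. contracts the dense spectral axis against the normalized response
   matrix SR (a mode-3 tensor-matrix product), and
5. collects the per-band results into a synthetic raw cube in the
   target system's band space.

The same transform is applied to the white and dark reference cubes so
that flat-field calibration (raw - dark)/(white - dark) can be applied
to the synthetic data exactly as to real captures; per-band scale
ambiguities introduced by the min-max normalization of SR cancel there.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .hsio import CaptureSet, HSCube, SpectralAxis
from .response import QECurve, ResponseMatrix, SourceSystemSpec

__all__ = [
    "IrradianceCube",
    "estimate_irradiance",
    "resample_to_dense",
    "project",
    "map_capture_set",
    "flat_field",
    "normalize_pixels",
    "QE_FLOOR",
]

log = logging.getLogger(__name__)

#: Quantum-efficiency values at or below this are treated as invalid to
#: avoid blow-up when dividing raw counts; inside the 440-900 nm
#: effective range a working sensor sits far above it.
QE_FLOOR = 0.01


@dataclass
class IrradianceCube:
    """QE-compensated spectral irradiance, on the source or dense grid."""

    values: np.ndarray
    axis: SpectralAxis
    provenance: str = "source"

    def __post_init__(self) -> None:
        v = np.asarray(self.values)
        if v.ndim != 3 or v.shape[2] != len(self.axis):
            raise ValueError("irradiance values do not match the spectral axis")
        self.values = v


def estimate_irradiance(cube: HSCube, qe: QECurve) -> IrradianceCube:
    """Compensate the sensor quantum efficiency: SI = A / QE per band."""
    eff = qe.at(cube.axis.wavelengths)
    bad = np.flatnonzero(eff <= QE_FLOOR)
    if bad.size:
        centers = ", ".join(f"{cube.axis.wavelengths[i]:g}" for i in bad[:10])
        raise ValueError(f"quantum efficiency at/below {QE_FLOOR} at band centres: {centers}")
    return IrradianceCube(values=cube.values / eff, axis=cube.axis)


def resample_to_dense(si: IrradianceCube, dense_axis: SpectralAxis) -> IrradianceCube:
    """Linearly interpolate each pixel spectrum onto the dense grid.

    Extrapolation beyond the source support is refused: the sensor
    carries no information there.
    """
    if dense_axis == si.axis:
        return IrradianceCube(values=si.values.copy(), axis=si.axis, provenance=si.provenance)
    slo, shi = si.axis.span
    qlo, qhi = dense_axis.span
    if qlo < slo - 1e-9 or qhi > shi + 1e-9:
        raise ValueError(
            f"dense axis [{qlo:g}, {qhi:g}] nm extends beyond the source span [{slo:g}, {shi:g}] nm"
        )
    rows, cols, _ = si.values.shape
    flat = si.values.reshape(rows * cols, -1)
    # np.interp is 1-D; vectorize the shared-knot interpolation by hand.
    x = si.axis.wavelengths
    xq = dense_axis.wavelengths
    idx = np.clip(np.searchsorted(x, xq, side="right") - 1, 0, x.size - 2)
    x0, x1 = x[idx], x[idx + 1]
    t = (xq - x0) / (x1 - x0)
    out = flat[:, idx] * (1.0 - t) + flat[:, idx + 1] * t
    return IrradianceCube(
        values=out.reshape(rows, cols, xq.size), axis=dense_axis, provenance=si.provenance
    )


def project(
    si_dense: IrradianceCube,
    sr: ResponseMatrix,
    weight_by_spacing: bool = False,
) -> HSCube:
    """Mode-3 tensor-matrix product of the dense irradiance with SR.

    Output band b at pixel (i, j) is the inner product of the pixel's
    dense spectrum with SR column b.  With ``weight_by_spacing`` the
    inner product is weighted by the dense-grid spacing (a Riemann-sum
    reading); on a uniform grid the two differ by a constant per-band
    factor that flat-field calibration divides out.
    """
    if not si_dense.axis.isclose(sr.dense_axis):
        raise ValueError("irradiance axis does not match the response matrix dense axis")
    m = sr.matrix
    if weight_by_spacing:
        w = np.gradient(sr.dense_axis.wavelengths)
        m = m * w[:, None]
    values = np.einsum("ijk,kb->ijb", si_dense.values, m, optimize=True)
    return HSCube(values=values, axis=sr.band_axis, state="raw")


def map_capture_set(
    cs: CaptureSet,
    source: SourceSystemSpec,
    sr: ResponseMatrix,
    target_system_id: str = "target-synthetic",
    weight_by_spacing: bool = False,
) -> CaptureSet:
    """Map a full capture set (raw + white + dark) into the target band space."""
    if not cs.raw.axis.isclose(source.band_centers):
        raise ValueError("capture axes do not match the source system band centres")

    def _map(cube: HSCube) -> HSCube:
        si = estimate_irradiance(cube, source.qe)
        si_dense = resample_to_dense(si, sr.dense_axis)
        return project(si_dense, sr, weight_by_spacing=weight_by_spacing)

    mapped = CaptureSet(
        raw=_map(cs.raw), white=_map(cs.white), dark=_map(cs.dark),
        system_id=target_system_id,
    )
    log.info("mapped capture set %s: %d -> %d bands", cs.system_id,
             cs.raw.n_bands, mapped.raw.n_bands)
    return mapped


def flat_field(
    cs: CaptureSet,
    guard_fraction: float = 0.01,
) -> HSCube:
    """Flat-field calibration (raw - dark) / (white - dark), clipped to [0, 1].

    Elements where the white and dark references are within a tiny
    guard band of each other (1e-6 of the white dynamic range) carry no
    calibration information and are set to 0; if more than
    ``guard_fraction`` of elements are degenerate the references are
    considered invalid and an error is raised.
    """
    num = cs.raw.values - cs.dark.values
    den = cs.white.values - cs.dark.values
    dynamic = float(np.max(cs.white.values) - np.min(cs.white.values))
    eps = 1e-6 * (dynamic if dynamic > 0 else 1.0)
    bad = den <= eps
    frac = bad.mean() if bad.size else 0.0
    if frac > guard_fraction:
        raise ValueError(
            f"white reference does not exceed dark over {frac:.1%} of elements "
            f"(allowed {guard_fraction:.1%}); references invalid"
        )
    if frac:
        log.warning("flat_field: %.3g%% of elements had degenerate references", 100 * frac)
    out = np.zeros_like(num, dtype=float)
    np.divide(num, den, out=out, where=~bad)
    out = np.clip(out, 0.0, 1.0)
    return HSCube(values=out, axis=cs.raw.axis, state="calibrated")


def normalize_pixels(cube: HSCube) -> tuple[HSCube, np.ndarray]:
    """Min-max scale each pixel spectrum independently to [0, 1].

    Returns the normalized cube and a boolean mask of degenerate
    (constant-spectrum) pixels, which are mapped to all-zero rather
    than raised on: flat spectra legitimately occur in background
    regions.
    """
    v = cube.values
    mn = v.min(axis=2, keepdims=True)
    mx = v.max(axis=2, keepdims=True)
    rng = mx - mn
    degenerate = (rng[..., 0] <= 0)
    out = np.zeros_like(v, dtype=float)
    np.divide(v - mn, rng, out=out, where=rng > 0)
    if degenerate.any():
        log.info("normalize_pixels: %d degenerate constant pixels set to zero",
                 int(degenerate.sum()))
    return HSCube(values=out, axis=cube.axis, state="normalized"), degenerate
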