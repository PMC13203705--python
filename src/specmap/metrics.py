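"""Pixel-level spectral-similarity metrics between hyperspectral cubes.

Cubes are flattened to pixel x wavelength matrices and compared with
Pearson correlation of the spectra (computed on the original spectra
and on their first and second spectral differences), mean squared error
aggregated per wavelength (MSEw, over pixels) and per pixel (MSEp, over
wavelengths), and the spectral angle mapper (SAM), the arccosine of the
cosine similarity -- a scale-invariant shape distance in radians.

Degenerate pixels (flat spectra after differencing, or all-zero spectra
in SAM) give undefined values; these are emitted as NaN, excluded from
the summary means and counted, because flat background pixels occur in
real scenes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .hsio import AnnotationMap, CLASS_NAMES, HSCube, SpectralAxis

__all__ = [
    "PixelMatrix",
    "MetricsReport",
    "flatten",
    "unflatten",
    "spectral_derivative",
    "correlation_per_pixel",
    "mse_per_wavelength",
    "mse_per_pixel",
    "sam_per_pixel",
    "sam_error_map",
    "per_class_msew",
    "compute_report",
]


@dataclass
class PixelMatrix:
    """Pixels x wavelengths matrix with a map back to cube coordinates."""

    values: np.ndarray
    axis: SpectralAxis
    pixel_index: np.ndarray  # (p, 2) array of (row, col)
    spatial_shape: tuple[int, int]

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[1] != len(self.axis):
            raise ValueError("pixel matrix width must equal the axis length")
        if self.pixel_index.shape != (v.shape[0], 2):
            raise ValueError("pixel_index must map every row to a (row, col) pair")
        self.values = v

    @property
    def n_pixels(self) -> int:
        return self.values.shape[0]


def flatten(cube: HSCube, mask: np.ndarray | None = None) -> PixelMatrix:
    """Flatten a cube to pixels x wavelengths in raster (row-major) order."""
    rows, cols, _ = cube.shape
    if mask is None:
        mask = np.ones((rows, cols), dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != (rows, cols):
        raise ValueError("mask shape does not match the cube spatially")
    if not mask.any():
        raise ValueError("mask selects no pixels")
    idx = np.argwhere(mask)  # argwhere is raster-ordered
    return PixelMatrix(
        values=cube.values[mask],
        axis=cube.axis,
        pixel_index=idx,
        spatial_shape=(rows, cols),
    )


def unflatten(m: PixelMatrix, fill: float = np.nan) -> HSCube:
    """Rebuild a cube from a pixel matrix (unselected pixels get ``fill``)."""
    out = np.full(m.spatial_shape + (len(m.axis),), fill, dtype=float)
    out[m.pixel_index[:, 0], m.pixel_index[:, 1]] = m.values
    return HSCube(values=out, axis=m.axis, state="normalized")


def spectral_derivative(m: PixelMatrix, order: int) -> PixelMatrix:
    """Adjacent differencing along the wavelength axis, applied ``order`` times.

    Unnormalized differences (no division by the wavelength step): on a
    uniform grid this differs from a true derivative only by a constant
    factor, to which Pearson correlation is invariant.
    """
    if order not in (0, 1, 2):
        raise ValueError("derivative order must be 0, 1 or 2")
    if m.values.shape[1] <= order:
        raise ValueError("too few wavelengths for the requested derivative order")
    if order == 0:
        return m
    vals = np.diff(m.values, n=order, axis=1)
    axis = SpectralAxis._unchecked(m.axis.wavelengths[order:])
    return PixelMatrix(vals, axis, m.pixel_index, m.spatial_shape)


def _check_congruent(a: PixelMatrix, b: PixelMatrix) -> None:
    if a.values.shape != b.values.shape:
        raise ValueError(f"pixel matrices differ in shape: {a.values.shape} vs {b.values.shape}")


def correlation_per_pixel(a: PixelMatrix, b: PixelMatrix, order: int = 0) -> np.ndarray:
    """Per-pixel Pearson correlation of the order-k differenced spectra.

    Rows that are constant after differencing have undefined
    correlation and yield NaN.
    """
    _check_congruent(a, b)
    da, db = spectral_derivative(a, order).values, spectral_derivative(b, order).values
    ca = da - da.mean(axis=1, keepdims=True)
    cb = db - db.mean(axis=1, keepdims=True)
    sa = np.sqrt((ca * ca).sum(axis=1))
    sb = np.sqrt((cb * cb).sum(axis=1))
    denom = sa * sb
    out = np.full(da.shape[0], np.nan)
    ok = denom > 0
    out[ok] = (ca * cb).sum(axis=1)[ok] / denom[ok]
    return np.clip(out, -1.0, 1.0, out=out)


def mse_per_wavelength(a: PixelMatrix, b: PixelMatrix) -> np.ndarray:
    """MSEw(j): mean over pixels of squared differences at wavelength j."""
    _check_congruent(a, b)
    return np.mean((a.values - b.values) ** 2, axis=0)


def mse_per_pixel(a: PixelMatrix, b: PixelMatrix) -> np.ndarray:
    """MSEp(i): mean over wavelengths of squared differences at pixel i."""
    _check_congruent(a, b)
    return np.mean((a.values - b.values) ** 2, axis=1)


def sam_per_pixel(a: PixelMatrix, b: PixelMatrix) -> np.ndarray:
    """Spectral angle per pixel in radians, in [0, pi].

    The cosine is clamped to [-1, 1] before arccos to absorb rounding;
    all-zero spectra have no direction and yield NaN.
    """
    _check_congruent(a, b)
    na = np.linalg.norm(a.values, axis=1)
    nb = np.linalg.norm(b.values, axis=1)
    denom = na * nb
    out = np.full(a.n_pixels, np.nan)
    ok = denom > 0
    cosine = np.clip((a.values * b.values).sum(axis=1)[ok] / denom[ok], -1.0, 1.0)
    out[ok] = np.arccos(cosine)
    return out


def sam_error_map(a: HSCube, b: HSCube) -> np.ndarray:
    """Spatial image of per-pixel SAM between two congruent cubes."""
    if a.shape != b.shape:
        raise ValueError("cubes are not congruent")
    fa, fb = flatten(a), flatten(b)
    return sam_per_pixel(fa, fb).reshape(a.spatial_shape)


def per_class_msew(
    a: HSCube, b: HSCube, ann: AnnotationMap
) -> dict[str, np.ndarray]:
    """MSEw profiles restricted to each annotated class.

    Returns one per-wavelength profile per class present in the
    annotation, plus ``unlabelled`` (if present) and ``all`` (every
    pixel).  Classes with zero pixels are omitted.
    """
    if ann.labels.shape != a.spatial_shape:
        raise ValueError("annotation is not aligned with the cubes")
    if a.shape != b.shape:
        raise ValueError("cubes are not congruent")
    out: dict[str, np.ndarray] = {}
    for name in CLASS_NAMES:
        m = ann.class_mask(name)
        if m.any():
            out[name] = mse_per_wavelength(flatten(a, m), flatten(b, m))
    out["all"] = mse_per_wavelength(flatten(a), flatten(b))
    return out


def _summary(vec: np.ndarray) -> dict[str, float]:
    ok = vec[~np.isnan(vec)]
    return {
        "mean": float(np.mean(ok)) if ok.size else float("nan"),
        "sd": float(np.std(ok)) if ok.size else float("nan"),
        "n": int(ok.size),
        "n_excluded": int(vec.size - ok.size),
    }


@dataclass
class MetricsReport:
    """The full mapping-metric suite between two congruent cubes.

    Per-pixel vectors: correlation at derivative orders 0/1/2, MSEp and
    SAM; one per-wavelength vector MSEw.  ``summary`` holds mean +/- sd
    over the defined (non-NaN) population per metric; MSEp is often
    displayed scaled by 1000 in comparison tables, which is left to the
    presentation layer.
    """

    correlation: Mapping[int, np.ndarray]
    mse_p: np.ndarray
    sam: np.ndarray
    mse_w: np.ndarray
    axis: SpectralAxis

    @property
    def summary(self) -> dict[str, dict[str, float]]:
        s = {f"correlation_order{k}": _summary(v) for k, v in self.correlation.items()}
        s["mse_p"] = _summary(self.mse_p)
        s["sam_rad"] = _summary(self.sam)
        s["mse_w"] = _summary(self.mse_w)
        return s

    def to_dict(self) -> dict:
        return {"summary": self.summary, "wavelengths_nm": self.axis.wavelengths.tolist(),
                "mse_w": self.mse_w.tolist()}


def compute_report(a: HSCube, b: HSCube, mask: np.ndarray | None = None) -> MetricsReport:
    """Compute every mapping metric between two congruent cubes."""
    fa, fb = flatten(a, mask), flatten(b, mask)
    return MetricsReport(
        correlation={k: correlation_per_pixel(fa, fb, order=k) for k in (0, 1, 2)},
        mse_p=mse_per_pixel(fa, fb),
        sam=sam_per_pixel(fa, fb),
        mse_w=mse_per_wavelength(fa, fb),
        axis=fa.axis,
    )
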