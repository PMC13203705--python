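"""Core hyperspectral data model and on-disk IO.

A hyperspectral (HS) cube is a rank-3 array of intensities indexed
``(row, col, band)`` together with a wavelength axis in nanometres.  A
capture set bundles a raw cube with its paired white and dark reference
cubes, the operands of flat-field calibration.  Cubes are stored on disk
in the de facto HSI interchange layout: an ENVI-style ``.hdr`` text
header plus a band-sequential (BSQ) binary payload of little-endian
32-bit floats.

Index convention, used everywhere in the package: 0-based
``(row, col, band)`` with the band axis last.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Mapping

import numpy as np

__all__ = [
    "SpectralAxis",
    "HSCube",
    "CaptureSet",
    "AnnotationMap",
    "CLASS_NAMES",
    "CLASS_CODES",
    "read_capture_set",
    "write_capture_set",
    "read_cube",
    "write_cube",
    "read_annotation_map",
    "write_annotation_map",
    "read_spectrum_csv",
    "write_spectrum_csv",
    "render_synthetic_rgb",
]

CubeState = Literal["raw", "irradiance", "calibrated", "normalized"]

#: Integer codes used in annotation images (0 = unlabelled).
CLASS_NAMES: tuple[str, ...] = ("unlabelled", "normal", "tumour", "blood_vessel", "background")
CLASS_CODES: Mapping[str, int] = {name: code for code, name in enumerate(CLASS_NAMES)}


@dataclass(frozen=True)
class SpectralAxis:
    """Strictly increasing grid of wavelengths in nm."""

    wavelengths: np.ndarray

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelengths, dtype=float)
        if wl.ndim != 1 or wl.size < 2:
            raise ValueError("spectral axis needs at least two wavelengths")
        if not np.all(np.isfinite(wl)) or np.any(wl <= 0):
            raise ValueError("wavelengths must be finite and positive")
        if np.any(np.diff(wl) <= 0):
            raise ValueError("wavelengths must be strictly increasing")
        object.__setattr__(self, "wavelengths", wl)

    def __len__(self) -> int:
        return int(self.wavelengths.size)

    @classmethod
    def _unchecked(cls, wavelengths: np.ndarray) -> "SpectralAxis":
        # internal: derived axes (e.g. after spectral differencing) may
        # legitimately shrink below the 2-wavelength minimum
        obj = object.__new__(cls)
        object.__setattr__(obj, "wavelengths", np.asarray(wavelengths, dtype=float))
        return obj

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SpectralAxis):
            return NotImplemented
        return self.wavelengths.shape == other.wavelengths.shape and bool(
            np.array_equal(self.wavelengths, other.wavelengths)
        )

    def __hash__(self) -> int:  # frozen dataclass with array field
        return hash(self.wavelengths.tobytes())

    @property
    def span(self) -> tuple[float, float]:
        return float(self.wavelengths[0]), float(self.wavelengths[-1])

    def isclose(self, other: "SpectralAxis", tol: float = 1e-6) -> bool:
        return len(self) == len(other) and bool(
            np.allclose(self.wavelengths, other.wavelengths, atol=tol)
        )


@dataclass
class HSCube:
    """Hyperspectral cube: intensities indexed (row, col, band) plus axis.

    ``state`` tracks where the cube sits in the processing chain:
    ``raw`` sensor counts, quantum-efficiency-compensated ``irradiance``,
    flat-field ``calibrated`` reflectance in [0, 1], or per-pixel
    min-max ``normalized`` spectra.
    """

    values: np.ndarray
    axis: SpectralAxis
    state: CubeState = "raw"

    def __post_init__(self) -> None:
        v = np.asarray(self.values)
        if v.ndim != 3:
            raise ValueError(f"cube values must be rank-3, got shape {v.shape}")
        if v.shape[2] != len(self.axis):
            raise ValueError(
                f"band count {v.shape[2]} does not match axis length {len(self.axis)}"
            )
        if self.state == "raw" and v.size and np.nanmin(v) < 0:
            raise ValueError("raw cube contains negative values")
        self.values = v

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]

    @property
    def spatial_shape(self) -> tuple[int, int]:
        return self.values.shape[0], self.values.shape[1]

    @property
    def n_bands(self) -> int:
        return self.values.shape[2]


@dataclass
class CaptureSet:
    """Raw cube plus paired white/dark reference cubes of one system.

    The white reference images a standard that reflects 95% of incident
    light; the dark reference is captured with the lens capped.  All
    three cubes share one spectral axis and spatial geometry
    (full-frame references).
    """

    raw: HSCube
    white: HSCube
    dark: HSCube
    system_id: str = "source"

    def __post_init__(self) -> None:
        for name, cube in (("white", self.white), ("dark", self.dark)):
            if not cube.axis.isclose(self.raw.axis):
                raise ValueError(f"{name} reference axis differs from raw axis")
            if cube.spatial_shape != self.raw.spatial_shape:
                raise ValueError(f"{name} reference spatial shape differs from raw")


@dataclass
class AnnotationMap:
    """Per-pixel class labels with patient/image provenance.

    ``labels`` holds the integer codes of :data:`CLASS_NAMES`
    (0 = unlabelled).  Patient identity drives grouped cross-validation.
    """

    labels: np.ndarray
    patient_id: str
    image_id: str

    def __post_init__(self) -> None:
        lab = np.asarray(self.labels)
        if lab.ndim != 2:
            raise ValueError("annotation labels must be a 2-D image")
        if lab.size and (lab.min() < 0 or lab.max() >= len(CLASS_NAMES)):
            raise ValueError("annotation labels outside the known class codes")
        self.labels = lab.astype(np.uint8)

    def class_mask(self, name: str) -> np.ndarray:
        return self.labels == CLASS_CODES[name]


# ---------------------------------------------------------------------------
# ENVI-style header + BSQ binary IO


def _write_envi(cube: HSCube, stem: Path, system_id: str | None = None) -> None:
    rows, cols, bands = cube.shape
    if rows == 0 or cols == 0:
        raise ValueError("refusing to write a cube with empty spatial extent")
    wl = ", ".join(f"{w:.6f}" for w in cube.axis.wavelengths)
    lines = [
        "ENVI",
        f"samples = {cols}",
        f"lines = {rows}",
        f"bands = {bands}",
        "header offset = 0",
        "file type = ENVI Standard",
        "data type = 4",
        "interleave = bsq",
        "byte order = 0",
        f"cube state = {cube.state}",
    ]
    if system_id is not None:
        lines.append(f"system id = {system_id}")
    lines.append("wavelength = {" + wl + "}")
    stem.with_suffix(".hdr").write_text("\n".join(lines) + "\n")
    # BSQ: band-major on disk
    payload = np.ascontiguousarray(np.moveaxis(cube.values, 2, 0), dtype="<f4")
    payload.tofile(stem.with_suffix(".bsq"))


def _parse_envi_header(text: str) -> dict[str, str]:
    fields: dict[str, str] = {}
    key = None
    buf: list[str] = []
    for line in text.splitlines():
        if key is None:
            if "=" not in line:
                continue
            k, v = line.split("=", 1)
            key, v = k.strip().lower(), v.strip()
            if v.startswith("{") and not v.endswith("}"):
                buf = [v]
                continue
            fields[key] = v.strip("{} ")
            key = None
        else:
            buf.append(line.strip())
            if line.strip().endswith("}"):
                fields[key] = " ".join(buf).strip("{} ")
                key, buf = None, []
    return fields


def _read_envi(stem: Path, state: CubeState) -> HSCube:
    hdr = stem.with_suffix(".hdr")
    bin_path = stem.with_suffix(".bsq")
    if not hdr.exists() or not bin_path.exists():
        raise FileNotFoundError(f"missing capture member {stem.name} (.hdr/.bsq)")
    fields = _parse_envi_header(hdr.read_text())
    rows = int(fields["lines"])
    cols = int(fields["samples"])
    bands = int(fields["bands"])
    if fields.get("interleave", "bsq").lower() != "bsq":
        raise ValueError("only BSQ interleave is supported")
    wl = np.array([float(x) for x in fields["wavelength"].split(",")])
    if wl.size != bands:
        raise ValueError(f"header declares {bands} bands but {wl.size} wavelengths")
    data = np.fromfile(bin_path, dtype="<f4")
    if data.size != rows * cols * bands:
        raise ValueError(
            f"payload of {bin_path.name} has {data.size} values, "
            f"header declares {rows * cols * bands}"
        )
    values = np.moveaxis(data.reshape(bands, rows, cols), 0, 2)
    declared = fields.get("cube state", state)
    return HSCube(values=values, axis=SpectralAxis(wl), state=declared)  # type: ignore[arg-type]


_MEMBERS = ("raw", "white", "dark")


def write_capture_set(cs: CaptureSet, path: str | Path) -> None:
    """Write a capture set as ``{raw,white,dark}.hdr/.bsq`` in ``path``."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    for name in _MEMBERS:
        _write_envi(getattr(cs, name), path / name, system_id=cs.system_id)


def read_capture_set(path: str | Path) -> CaptureSet:
    """Read a capture set written by :func:`write_capture_set`."""
    path = Path(path)
    cubes = {name: _read_envi(path / name, "raw") for name in _MEMBERS}
    hdr = _parse_envi_header((path / "raw.hdr").read_text())
    return CaptureSet(system_id=hdr.get("system id", "unknown"), **cubes)


def write_cube(cube: HSCube, stem: str | Path) -> None:
    _write_envi(cube, Path(stem))


def read_cube(stem: str | Path, state: CubeState = "raw") -> HSCube:
    return _read_envi(Path(stem), state)


# ---------------------------------------------------------------------------
# Annotation maps: single-band integer image + JSON sidecar


def write_annotation_map(ann: AnnotationMap, stem: str | Path) -> None:
    import imageio.v3 as iio

    stem = Path(stem)
    stem.parent.mkdir(parents=True, exist_ok=True)
    iio.imwrite(stem.with_suffix(".png"), ann.labels.astype(np.uint8))
    stem.with_suffix(".json").write_text(
        json.dumps({"patient_id": ann.patient_id, "image_id": ann.image_id})
    )


def read_annotation_map(stem: str | Path) -> AnnotationMap:
    import imageio.v3 as iio

    stem = Path(stem)
    labels = np.asarray(iio.imread(stem.with_suffix(".png")))
    meta = json.loads(stem.with_suffix(".json").read_text())
    return AnnotationMap(labels=labels, patient_id=meta["patient_id"], image_id=meta["image_id"])


# ---------------------------------------------------------------------------
# Spectrum CSVs (QE curves, emission measurements)


def write_spectrum_csv(path: str | Path, wavelengths: np.ndarray, values: np.ndarray,
                       value_name: str = "value") -> None:
    import pandas as pd

    pd.DataFrame({"wavelength_nm": wavelengths, value_name: values}).to_csv(path, index=False)


def read_spectrum_csv(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    import pandas as pd

    df = pd.read_csv(path)
    return df.iloc[:, 0].to_numpy(float), df.iloc[:, 1].to_numpy(float)


# ---------------------------------------------------------------------------
# Qualitative RGB rendering

#: Triangular channel weighting curves (centre, half-width), nm — a fixed
#: stand-in for human photopic sensitivity; qualitative output only.
_RGB_CENTERS = {"r": 610.0, "g": 540.0, "b": 470.0}
_RGB_HALFWIDTH = 60.0


def _triangle(wl: np.ndarray, center: float, halfwidth: float) -> np.ndarray:
    return np.clip(1.0 - np.abs(wl - center) / halfwidth, 0.0, None)


def render_synthetic_rgb(cube: HSCube, clip: bool = True) -> np.ndarray:
    """Collapse a calibrated cube into a synthetic RGB image.

    Channels are weighted averages of the bands under fixed triangular
    curves centred at 610/540/470 nm; values are clipped to [0, 1].
    """
    wl = cube.axis.wavelengths
    visible = (wl >= 400.0) & (wl <= 700.0)
    if not np.any(visible):
        raise ValueError("cube axis lies entirely outside the 400-700 nm visible range")
    out = np.zeros(cube.spatial_shape + (3,), dtype=float)
    for ch, name in enumerate("rgb"):
        w = _triangle(wl, _RGB_CENTERS[name], _RGB_HALFWIDTH) * visible
        if w.sum() <= 0:
            continue
        out[..., ch] = cube.values @ (w / w.sum())
    return np.clip(out, 0.0, 1.0) if clip else out
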