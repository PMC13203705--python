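"""Synthetic inputs for the whole pipeline: no downloads required.

This module generates every artefact the mapper, metrics and benchmark
need: a sensor quantum-efficiency curve, Gaussian narrow-band emission
spectra mimicking a liquid-crystal tunable filter (LCTF) illumination
system, reflectance phantoms (a rare-earth-style multi-peak calibration
standard, a tiled plastic board, and four-class brain-like scenes with
patient structure), and simulated capture sets for both the dense
push-broom source system and the sparse LCTF target system.

The forward model is deliberately simple and invertible: raw counts are
reflectance x illumination x sensor response plus additive Gaussian
read noise (clipped at zero), the white reference images a standard
reflecting 95% of incident light, and the dark reference is read noise
alone.  Under zero noise, flat-field calibration recovers the phantom
reflectance divided by 0.95 exactly, which anchors the round-trip tests
of the mapping method.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Literal, Sequence

import numpy as np

from .hsio import AnnotationMap, CLASS_CODES, CaptureSet, HSCube, SpectralAxis
from .mapper import project, resample_to_dense, IrradianceCube
from .response import (
    BandEmission,
    BandMode,
    QECurve,
    ResponseMatrix,
    SourceSystemSpec,
    TargetSystemSpec,
    band_grid,
    build_response_matrix,
    source_band_grid,
    stitch_bands,
)

__all__ = [
    "ReflectancePhantom",
    "SimulationConfig",
    "WHITE_REFLECTANCE",
    "FWHM_ENDPOINTS",
    "default_qe",
    "default_illumination",
    "default_dense_axis",
    "default_source_system",
    "gaussian_emission",
    "fwhm_for_mode",
    "make_target_emissions",
    "build_target_response",
    "make_phantom",
    "make_brain_cohort",
    "simulate_source_capture",
    "simulate_target_capture",
]

#: Reflectance of the white reference standard (reflects 95% of light).
WHITE_REFLECTANCE = 0.95

#: Signal-independent read-noise floor, as a fraction of the
#: signal-proportional noise coefficient evaluated at the white level.
READ_NOISE_FRACTION = 0.1

#: FWHM endpoints (nm) of each illumination mode, linearly interpolated
#: across the mode's wavelength range: the bandwidth is
#: wavelength-dependent, widening toward longer wavelengths.
FWHM_ENDPOINTS: dict[str, tuple[tuple[float, float], tuple[float, float]]] = {
    # mode: ((range_lo, range_hi), (fwhm_lo, fwhm_hi))
    "narrow": ((420.0, 730.0), (7.1, 14.4)),
    "medium": ((420.0, 730.0), (10.0, 26.9)),
    "wide": ((420.0, 730.0), (14.6, 49.8)),
    "nir": ((650.0, 1100.0), (13.26, 24.11)),
}

_FWHM_TO_SIGMA = 1.0 / (2.0 * math.sqrt(2.0 * math.log(2.0)))


def default_dense_axis(step_nm: float = 1.0) -> SpectralAxis:
    """Dense spectrometer-style grid covering both LCTF ranges."""
    return band_grid(400.0, 1100.0, step_nm)


def default_qe(axis: SpectralAxis | None = None) -> QECurve:
    """Smooth unimodal quantum-efficiency curve in [0.1, 0.6] over 400-1000 nm."""
    if axis is None:
        axis = band_grid(400.0, 1000.0, 2.0)
    wl = axis.wavelengths
    eff = 0.1 + 0.5 * np.exp(-(((wl - 650.0) / 180.0) ** 2))
    return QECurve(axis=axis, efficiency=eff)


def default_illumination(wavelengths_nm: np.ndarray) -> np.ndarray:
    """Smooth broadband source spectrum peaking mid-range (arbitrary units)."""
    wl = np.asarray(wavelengths_nm, dtype=float)
    return 0.25 + 0.75 * np.exp(-(((wl - 680.0) / 220.0) ** 2))


def default_source_system(kind: Literal["full", "selected"] = "full") -> SourceSystemSpec:
    return SourceSystemSpec(band_centers=source_band_grid(kind), qe=default_qe())


# ---------------------------------------------------------------------------
# Emission synthesis


def gaussian_emission(center_nm: float, fwhm_nm: float, dense_axis: SpectralAxis,
                      mode: BandMode = "medium") -> BandEmission:
    """Gaussian band profile with unit peak at its centre."""
    if fwhm_nm <= 0:
        raise ValueError("FWHM must be positive")
    lo, hi = dense_axis.span
    if not lo <= center_nm <= hi:
        raise ValueError(f"band centre {center_nm} nm outside the dense axis [{lo}, {hi}]")
    sigma = fwhm_nm * _FWHM_TO_SIGMA
    spectrum = np.exp(-0.5 * ((dense_axis.wavelengths - center_nm) / sigma) ** 2)
    return BandEmission(center_nm=center_nm, mode=mode, axis=dense_axis, spectrum=spectrum)


def fwhm_for_mode(center_nm: float, mode: BandMode) -> float:
    """Wavelength-dependent FWHM of a mode, by linear interpolation."""
    (lo, hi), (flo, fhi) = FWHM_ENDPOINTS[mode]
    if not lo <= center_nm <= hi:
        raise ValueError(f"centre {center_nm} nm outside the {mode} mode range [{lo}, {hi}]")
    t = (center_nm - lo) / (hi - lo)
    return flo + t * (fhi - flo)


def make_target_emissions(
    spec: TargetSystemSpec,
    mode: BandMode = "medium",
    dense_axis: SpectralAxis | None = None,
) -> tuple[list[BandEmission], list[BandEmission]]:
    """One Gaussian emission per VIS band (chosen mode) and per NIR band.

    Returned before stitching, as the two filters measure their ranges
    independently.
    """
    if dense_axis is None:
        dense_axis = default_dense_axis()
    vis = [gaussian_emission(c, fwhm_for_mode(c, mode), dense_axis, mode)
           for c in spec.vis_grid.wavelengths]
    nir = [gaussian_emission(c, fwhm_for_mode(c, "nir"), dense_axis, "nir")
           for c in spec.nir_grid.wavelengths]
    return vis, nir


def build_target_response(
    spec: TargetSystemSpec | None = None,
    mode: BandMode = "medium",
    dense_axis: SpectralAxis | None = None,
) -> ResponseMatrix:
    """Convenience: emissions -> stitch -> normalized response matrix."""
    if spec is None:
        spec = TargetSystemSpec()
    if dense_axis is None:
        dense_axis = default_dense_axis()
    vis, nir = make_target_emissions(spec, mode, dense_axis)
    stitched = stitch_bands(vis, nir, spec.transition_nm)
    return build_response_matrix(stitched, dense_axis, spec.effective_range_nm)


# ---------------------------------------------------------------------------
# Reflectance phantoms


@dataclass
class ReflectancePhantom:
    """Spatial label grid plus one reflectance spectrum per label."""

    labels: np.ndarray                       # (rows, cols) int grid
    spectra: dict[int, np.ndarray]           # label -> reflectance on axis
    axis: SpectralAxis
    label_names: dict[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for lab in np.unique(self.labels):
            if int(lab) not in self.spectra:
                raise ValueError(f"label {lab} has no reflectance spectrum")
        for lab, sp in self.spectra.items():
            sp = np.asarray(sp, dtype=float)
            if sp.shape != (len(self.axis),):
                raise ValueError(f"label {lab}: spectrum length mismatch")
            if sp.min() < 0 or sp.max() > 1:
                raise ValueError(f"label {lab}: reflectance outside [0, 1]")
            self.spectra[lab] = sp

    @property
    def spatial_shape(self) -> tuple[int, int]:
        return self.labels.shape  # type: ignore[return-value]

    def reflectance_at(self, wavelengths_nm: np.ndarray) -> np.ndarray:
        """Per-pixel reflectance cube sampled at the given wavelengths."""
        wl = np.asarray(wavelengths_nm, dtype=float)
        lo, hi = self.axis.span
        if wl.min() < lo - 1e-9 or wl.max() > hi + 1e-9:
            raise ValueError("phantom spectra do not cover the requested wavelengths")
        table = {lab: np.interp(wl, self.axis.wavelengths, sp)
                 for lab, sp in self.spectra.items()}
        out = np.empty(self.labels.shape + (wl.size,))
        for lab, sp in table.items():
            out[self.labels == lab] = sp
        return out


@dataclass
class SimulationConfig:
    """Acquisition-simulation settings.

    ``noise_sd`` scales additive Gaussian noise proportional to the
    local signal (shot-noise-like): an element with clean value x gets
    noise of sd ``noise_sd * x`` plus a small signal-independent read
    floor (``READ_NOISE_FRACTION`` of the coefficient at the white
    level).  "1% noise" therefore means 1% relative noise regardless of
    albedo, and means the same thing for the dense source system and
    the band-integrating target system.  ``illumination`` maps
    wavelengths (nm) to source power.
    """

    noise_sd: float = 0.0
    seed: int = 0
    geometry: tuple[int, int] = (22, 22)
    cohort: tuple[int, int] = (34, 61)   # patients, images
    illumination: Callable[[np.ndarray], np.ndarray] = default_illumination

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        n_patients, n_images = self.cohort
        if n_images < n_patients:
            raise ValueError("cohort needs at least one image per patient")


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def _gauss(wl: np.ndarray, center: float, width: float) -> np.ndarray:
    return np.exp(-0.5 * ((wl - center) / width) ** 2)


def _zenith_phantom(geometry, rng, axis) -> tuple[ReflectancePhantom, AnnotationMap]:
    """Uniform rare-earth-style standard: smooth baseline + narrow dips."""
    wl = axis.wavelengths
    base = 0.88 + 0.04 * _sigmoid((wl - 600.0) / 150.0)
    n_peaks = int(rng.integers(6, 11))
    centers = np.sort(rng.uniform(455.0, 885.0, n_peaks))
    spectrum = base.copy()
    for c in centers:
        depth = rng.uniform(0.12, 0.45)
        width = rng.uniform(5.0, 11.0)  # fwhm 12-26 nm
        spectrum -= depth * _gauss(wl, c, width)
    spectrum = np.clip(spectrum, 0.02, 0.93)
    labels = np.zeros(geometry, dtype=int)
    ph = ReflectancePhantom(labels=labels, spectra={0: spectrum}, axis=axis,
                            label_names={0: "zenith"})
    ann = AnnotationMap(labels=np.zeros(geometry, dtype=np.uint8),
                        patient_id="standard", image_id="zenith-0")
    return ph, ann


_PLASTIC_COLOURS = [
    ("red", 620.0), ("green", 540.0), ("blue", 465.0), ("yellow", 580.0),
    ("magenta", 650.0), ("orange", 600.0),
]


def _plastic_phantom(geometry, rng, axis) -> tuple[ReflectancePhantom, AnnotationMap]:
    """4x4 board of plastic tiles: flat dark/bright plus coloured spectra."""
    wl = axis.wavelengths
    spectra: dict[int, np.ndarray] = {}
    names: dict[int, str] = {}
    for lab in range(16):
        kind = lab % 4
        if kind == 0:      # near-flat dark (black-ish)
            sp = rng.uniform(0.03, 0.07) + 0.01 * _sigmoid((wl - 700) / 100)
        elif kind == 1:    # near-flat bright (white-ish)
            sp = rng.uniform(0.80, 0.90) - 0.03 * _sigmoid((wl - 800) / 120)
        elif kind == 2:    # sloped coloured: reflectance rises past an edge
            name, edge = _PLASTIC_COLOURS[(lab // 4) % len(_PLASTIC_COLOURS)]
            sp = 0.08 + rng.uniform(0.5, 0.75) * _sigmoid((wl - edge) / rng.uniform(15, 30))
        else:              # banded coloured: reflectance peak
            name, peak = _PLASTIC_COLOURS[(lab // 4 + 2) % len(_PLASTIC_COLOURS)]
            sp = 0.08 + rng.uniform(0.4, 0.6) * _gauss(wl, peak, rng.uniform(30, 60)) \
                + 0.3 * _sigmoid((wl - 850) / 40)
        spectra[lab] = np.clip(sp, 0.01, 0.93)
        names[lab] = f"plastic_{lab}"
    rows, cols = geometry
    rr = (np.arange(rows)[:, None] * 4 // max(rows, 1)).clip(0, 3)
    cc = (np.arange(cols)[None, :] * 4 // max(cols, 1)).clip(0, 3)
    labels = rr * 4 + cc
    ph = ReflectancePhantom(labels=labels, spectra=spectra, axis=axis, label_names=names)
    ann = AnnotationMap(labels=np.zeros(geometry, dtype=np.uint8),
                        patient_id="board", image_id="plastic-0")
    return ph, ann


def _brain_templates(wl: np.ndarray, rng: np.random.Generator,
                     separation: float = 1.0) -> dict[int, np.ndarray]:
    """Four smooth tissue-like reflectance templates with random effects.

    Normal and tumour tissue share the haemoglobin-like double dip near
    540/575 nm and a reflectance rise into the NIR; ``separation``
    scales how far the tumour template departs from normal.  Vessels
    absorb strongly below the ~640 nm edge; background is dark and
    nearly flat.  ``rng`` injects the patient-level variability.
    """
    def jitter(scale):  # multiplicative patient/image effect
        return float(np.exp(rng.normal(0.0, scale)))

    # Patient-level random effects: oxygenation/vascularization proxies.
    # The edge shift sd is deliberately comparable to the normal/tumour
    # template separation, so classes overlap across patients and
    # patient-held-out classification is realistically imperfect.
    shift = float(rng.normal(0.0, 9.0))
    dip1 = 0.10 * jitter(0.30)
    dip2 = 0.08 * jitter(0.30)
    slope = 38.0 * jitter(0.15)
    normal = (0.30 + 0.32 * _sigmoid((wl - 600.0 - shift) / slope)
              - dip1 * _gauss(wl, 542.0, 12.0) - dip2 * _gauss(wl, 577.0, 12.0))
    normal = normal * jitter(0.08) + rng.normal(0.0, 0.015)

    t_shift = float(rng.normal(0.0, 9.0))
    d_edge = 10.0 * separation
    tumour = (0.30 + 0.02 * separation
              + 0.32 * _sigmoid((wl - 600.0 - d_edge - t_shift) / (slope * (1 + 0.2 * separation)))
              - (dip1 - 0.03 * separation) * _gauss(wl, 542.0, 12.0)
              - (dip2 + 0.015 * separation) * _gauss(wl, 577.0, 12.0))
    tumour = tumour * jitter(0.08) + rng.normal(0.0, 0.015)

    vessel = (0.06 + 0.40 * _sigmoid((wl - 640.0 - float(rng.normal(0.0, 7.0))) / 22.0)
              - 0.02 * _gauss(wl, 555.0, 25.0))
    vessel = vessel * jitter(0.10) + rng.normal(0.0, 0.01)

    background = 0.05 + 0.04 * (wl - wl[0]) / (wl[-1] - wl[0]) + rng.normal(0.0, 0.008)

    return {
        CLASS_CODES["normal"]: np.clip(normal, 0.01, 0.93),
        CLASS_CODES["tumour"]: np.clip(tumour, 0.01, 0.93),
        CLASS_CODES["blood_vessel"]: np.clip(vessel, 0.01, 0.93),
        CLASS_CODES["background"]: np.clip(background, 0.01, 0.93),
    }


def _brain_scene_layout(geometry, rng) -> np.ndarray:
    """Region grid: background frame, vessel stripes, tumour blob, normal bulk."""
    rows, cols = geometry
    labels = np.full(geometry, CLASS_CODES["normal"], dtype=int)
    border = max(2, min(rows, cols) // 8)
    labels[:border, :] = CLASS_CODES["background"]
    labels[-border:, :] = CLASS_CODES["background"]
    labels[:, :border] = CLASS_CODES["background"]
    labels[:, -border:] = CLASS_CODES["background"]
    interior = slice(border, rows - border)
    # two wiggly vertical vessel stripes
    rr = np.arange(rows)
    for frac in (0.3, 0.7):
        c0 = border + frac * (cols - 2 * border)
        wobble = 1.5 * np.sin(2 * np.pi * rr / rows + rng.uniform(0, 2 * np.pi))
        for r in range(border, rows - border):
            c = int(round(c0 + wobble[r]))
            lo, hi = max(border, c - 1), min(cols - border, c + 2)
            labels[r, lo:hi] = CLASS_CODES["blood_vessel"]
    # tumour ellipse somewhere in the interior
    cy = rng.uniform(rows * 0.35, rows * 0.65)
    cx = rng.uniform(cols * 0.35, cols * 0.65)
    ry, rx = rng.uniform(3.5, 5.0), rng.uniform(4.0, 5.5)
    yy, xx = np.mgrid[0:rows, 0:cols]
    blob = ((yy - cy) / ry) ** 2 + ((xx - cx) / rx) ** 2 <= 1.0
    frame = np.zeros(geometry, dtype=bool)
    frame[interior, border:cols - border] = True
    labels[blob & frame] = CLASS_CODES["tumour"]
    return labels


def _brain_phantom(geometry, rng, axis, separation: float = 1.0,
                   labelled_per_class: int = 64,
                   patient_id: str = "patient-000", image_id: str = "image-000",
                   ) -> tuple[ReflectancePhantom, AnnotationMap]:
    labels = _brain_scene_layout(geometry, rng)
    spectra = _brain_templates(axis.wavelengths, rng, separation)
    ph = ReflectancePhantom(
        labels=labels, spectra=spectra, axis=axis,
        label_names={v: k for k, v in CLASS_CODES.items() if v in spectra},
    )
    ann_labels = np.zeros(geometry, dtype=np.uint8)
    for code in spectra:
        where = np.argwhere(labels == code)
        take = min(labelled_per_class, where.shape[0])
        pick = where[rng.choice(where.shape[0], size=take, replace=False)]
        ann_labels[pick[:, 0], pick[:, 1]] = code
    ann = AnnotationMap(labels=ann_labels, patient_id=patient_id, image_id=image_id)
    return ph, ann


def make_phantom(
    kind: Literal["zenith", "plastic", "brain"],
    geometry: tuple[int, int] = (22, 22),
    seed: int = 0,
    axis: SpectralAxis | None = None,
    **kwargs,
) -> tuple[ReflectancePhantom, AnnotationMap]:
    """Generate a seeded reflectance phantom plus its annotation map."""
    if axis is None:
        axis = band_grid(400.0, 1000.0, 1.0)
    rng = np.random.default_rng(seed)
    if kind == "zenith":
        return _zenith_phantom(geometry, rng, axis)
    if kind == "plastic":
        return _plastic_phantom(geometry, rng, axis)
    if kind == "brain":
        return _brain_phantom(geometry, rng, axis, **kwargs)
    raise ValueError(f"unknown phantom kind {kind!r}")


def make_brain_cohort(
    n_patients: int = 34,
    n_images: int = 61,
    geometry: tuple[int, int] = (22, 22),
    seed: int = 0,
    separation: float = 1.0,
    labelled_per_class: int = 64,
    axis: SpectralAxis | None = None,
) -> list[tuple[ReflectancePhantom, AnnotationMap]]:
    """Brain-like scenes with patient structure.

    Every patient gets at least one image; the remaining images are
    assigned to random patients.  Patient-level spectral variability is
    drawn once per patient, with a smaller per-image jitter on top, so
    pixels of one patient are correlated across that patient's images.
    """
    if n_images < n_patients:
        raise ValueError("need at least one image per patient")
    if axis is None:
        axis = band_grid(400.0, 1000.0, 1.0)
    rng = np.random.default_rng(seed)
    owners = list(range(n_patients)) + list(rng.integers(0, n_patients, n_images - n_patients))
    rng.shuffle(owners)
    patient_seeds = rng.integers(0, 2**31 - 1, n_patients)
    scenes = []
    for img_idx, patient in enumerate(owners):
        # patient RNG restarted per image, advanced by an image offset:
        # patient-level draws coincide, image-level draws differ
        p_rng = np.random.default_rng(int(patient_seeds[patient]))
        image_jitter_seed = int(rng.integers(0, 2**31 - 1))
        ph, ann = _brain_phantom(
            geometry, p_rng, axis, separation=separation,
            labelled_per_class=labelled_per_class,
            patient_id=f"patient-{patient:03d}", image_id=f"image-{img_idx:03d}",
        )
        # per-image multiplicative jitter, common to all tissue classes
        j_rng = np.random.default_rng(image_jitter_seed)
        factor = float(np.exp(j_rng.normal(0.0, 0.03)))
        ph.spectra = {lab: np.clip(sp * factor, 0.01, 0.93) for lab, sp in ph.spectra.items()}
        # layout should differ between images of one patient
        ph.labels = _brain_scene_layout(geometry, j_rng)
        ann_labels = np.zeros(geometry, dtype=np.uint8)
        for code in ph.spectra:
            where = np.argwhere(ph.labels == code)
            take = min(labelled_per_class, where.shape[0])
            pick = where[j_rng.choice(where.shape[0], size=take, replace=False)]
            ann_labels[pick[:, 0], pick[:, 1]] = code
        ann = AnnotationMap(labels=ann_labels, patient_id=ann.patient_id, image_id=ann.image_id)
        scenes.append((ph, ann))
    return scenes


# ---------------------------------------------------------------------------
# Capture simulation


def _noisy(rng: np.random.Generator, clean: np.ndarray, white_level: np.ndarray,
           noise_sd: float) -> np.ndarray:
    if noise_sd == 0:
        return clean.copy()
    sd = noise_sd * (clean + READ_NOISE_FRACTION * white_level)
    noise = rng.normal(0.0, 1.0, clean.shape) * sd
    return np.clip(clean + noise, 0.0, None)


def simulate_source_capture(
    ph: ReflectancePhantom,
    src: SourceSystemSpec | None = None,
    cfg: SimulationConfig | None = None,
) -> CaptureSet:
    """Simulate a capture by the Dirac-response source system.

    raw(i, j, b) = reflectance(i, j, lambda_b) * illumination(lambda_b)
    * QE(lambda_b) + noise; the white reference uses the 0.95 standard,
    the dark reference is read noise alone.
    """
    src = src or default_source_system()
    cfg = cfg or SimulationConfig()
    wl = src.band_centers.wavelengths
    refl = ph.reflectance_at(wl)
    gain = cfg.illumination(wl) * src.qe.at(wl)
    rng = np.random.default_rng(cfg.seed)
    white_level = WHITE_REFLECTANCE * gain
    raw = _noisy(rng, refl * gain, white_level, cfg.noise_sd)
    white = _noisy(rng, np.broadcast_to(white_level, refl.shape).copy(),
                   white_level, cfg.noise_sd)
    dark = _noisy(rng, np.zeros_like(refl), white_level, cfg.noise_sd)
    axis = src.band_centers
    return CaptureSet(
        raw=HSCube(raw, axis, "raw"),
        white=HSCube(white, axis, "raw"),
        dark=HSCube(dark, axis, "raw"),
        system_id="source-pushbroom",
    )


def simulate_target_capture(
    ph: ReflectancePhantom,
    sr: ResponseMatrix,
    cfg: SimulationConfig | None = None,
) -> CaptureSet:
    """Simulate a direct capture by the narrow-band target system.

    Band b integrates reflectance x illumination against SR column b
    over the dense grid (the band-limited forward model); white and
    dark references follow the same conventions as the source system.
    """
    cfg = cfg or SimulationConfig()
    wl = sr.dense_axis.wavelengths
    illum = cfg.illumination(wl)
    refl = ph.reflectance_at(wl)
    scene = IrradianceCube(values=refl * illum, axis=sr.dense_axis, provenance="phantom")
    clean_raw = project(scene, sr).values
    white_level = WHITE_REFLECTANCE * (illum @ sr.matrix)
    rng = np.random.default_rng(cfg.seed + 1)
    raw = _noisy(rng, clean_raw, white_level, cfg.noise_sd)
    white = _noisy(rng, np.broadcast_to(white_level, clean_raw.shape).copy(),
                   white_level, cfg.noise_sd)
    dark = _noisy(rng, np.zeros_like(clean_raw), white_level, cfg.noise_sd)
    axis = sr.band_axis
    return CaptureSet(
        raw=HSCube(raw, axis, "raw"),
        white=HSCube(white, axis, "raw"),
        dark=HSCube(dark, axis, "raw"),
        system_id="target-lctf",
    )
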