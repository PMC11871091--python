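"""Synthetic proximal-hip CT phantom generator.

Each phantom is an axial cross-section built from nested elliptical regions:
background air, a subcutaneous fat ring, a fascial envelope containing muscle
with speckled intermuscular fat islands, and a bone with cortical shell,
trabecular zone and a marrow interior split into haematopoietic and adipose
subregions. Three calibration rods with linearly spaced densities sit outside
the body. Ground-truth labels and compartment masks are emitted alongside the
HU image, and a configurable second "scanner domain" applies an HU offset and
spacing change for cross-domain experiments.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .imaging_io import CTImage, LabelMask
from .refseg import AIR_CUTOFF_HU, CompartmentMasks, ThresholdScheme

__all__ = ["DomainShift", "PhantomConfig", "PhantomSample", "generate_phantom", "generate_cohort", "nominal_fractions"]

DEFAULT_TISSUE_HU = {
    "background": -1000.0,
    "cortical": 600.0,
    "trabecular": 220.0,
    "hbm": 100.0,
    "mat": 20.0,
    "muscle": 50.0,
    "imat": -80.0,
    "sat": -80.0,
}
_CODE_BY_NAME = {"cortical": 1, "trabecular": 2, "hbm": 3, "mat": 4, "muscle": 5, "imat": 6, "sat": 7}

# geometry in fractions of image size: (row, col) semi-axes / offsets
_BODY_AXES = (0.32, 0.40)
_FASCIA_SCALE = 0.82
_BONE_CENTER_OFF = (-0.02, 0.15)  # toward image-right = anatomical left
_BONE_AXES = (0.125, 0.145)
_CORTICAL_T = 0.025
_TRABECULAR_T = 0.025
_MAT_FRAC = 0.58  # MAT radius as a fraction of marrow minor semi-axis
_IMAT_OFFSETS = ((0.00, -0.26), (-0.14, -0.18), (0.14, -0.18), (-0.18, -0.10), (0.18, -0.10))
_IMAT_RADIUS = 0.022
_ROD_ROW = 0.92
_ROD_COLS = (0.30, 0.50, 0.70)
_ROD_RADIUS = 0.035
_SLICE_FALLOFF = 0.05  # bone scale decrease per slice away from the reference


@dataclass(frozen=True)
class DomainShift:
    """Acquisition difference applied to the second scanner domain."""

    hu_offset: float = 20.0
    spacing_multiplier: float = 1.0


@dataclass(frozen=True)
class PhantomConfig:
    image_size: int = 128
    pixel_spacing: float = 1.0  # mm per pixel, isotropic in-plane
    slice_thickness: float = 3.0
    n_slices: int = 5
    noise_sigma: float = 10.0
    domain_shift: DomainShift = field(default_factory=DomainShift)
    tissue_hu_means: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_TISSUE_HU))
    rod_concentrations: tuple[float, float, float] = (150.0, 75.0, 0.0)
    rod_hu_slope: float = 2.0  # HU per mg/cm3 when painting rods
    rod_hu_intercept: float = 0.0
    jitter: float = 0.07  # relative jitter of the per-subject anatomy scale
    seed: int = 0

    def validate(self, scheme: ThresholdScheme | None = None) -> None:
        scheme = scheme or ThresholdScheme()
        if not (0 < self.image_size <= 512):
            raise ValueError("image_size must be in 1..512")
        if self.pixel_spacing <= 0 or self.slice_thickness <= 0:
            raise ValueError("spacing and thickness must be positive")
        if self.n_slices < 1 or self.n_slices % 2 == 0:
            raise ValueError("n_slices must be odd so a central reference slice exists")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be non-negative")
        rods = self.rod_concentrations
        if len(rods) != 3 or not all(a > b for a, b in zip(rods, rods[1:])):
            raise ValueError("rod_concentrations must be 3 strictly decreasing values")
        means = dict(DEFAULT_TISSUE_HU, **self.tissue_hu_means)
        if means["background"] >= AIR_CUTOFF_HU:
            raise ValueError("background mean must stay below the air cutoff")
        for name, code in _CODE_BY_NAME.items():
            lo, hi = scheme.interval_for(code)
            if not (lo < means[name] < hi):
                raise ValueError(
                    f"tissue mean for {name} ({means[name]} HU) must lie strictly "
                    f"inside its threshold interval [{lo}, {hi})"
                )

    def hu_means(self) -> dict[str, float]:
        return dict(DEFAULT_TISSUE_HU, **self.tissue_hu_means)


@dataclass
class PhantomSample:
    """One synthetic subject: HU stack, labels, compartments and metadata."""

    image: CTImage
    labels: LabelMask
    compartments: CompartmentMasks  # of the reference (central) slice
    rod_masks: list[np.ndarray]  # one boolean mask per rod, densest first
    subject_id: str
    height_m: float
    domain: str = "A"

    @property
    def reference_index(self) -> int:
        return self.image.n_slices // 2


def _ellipse(shape: tuple[int, int], center: tuple[float, float], axes: tuple[float, float]) -> np.ndarray:
    rr, cc = np.ogrid[: shape[0], : shape[1]]
    return ((rr - center[0]) / axes[0]) ** 2 + ((cc - center[1]) / axes[1]) ** 2 <= 1.0


def _subject_rng(config: PhantomConfig, subject_id: str) -> np.random.Generator:
    return np.random.default_rng([config.seed, zlib.crc32(subject_id.encode())])


def _sample_geometry(config: PhantomConfig, rng: np.random.Generator) -> dict:
    """Per-subject geometry: one global anatomy scale plus position jitter.

    A single scale factor multiplies every structure so each class's pixel
    fraction varies with scale^2 (< 20% at the default jitter), while centers
    move independently for positional variety.
    """
    n = config.image_size
    j = config.jitter
    scale = 1.0 + j * rng.uniform(-1.0, 1.0)

    def wiggle(amount: float = 0.02) -> float:
        return n * amount * rng.uniform(-1.0, 1.0)

    center = (n * 0.48 + wiggle(), n * 0.50 + wiggle())
    body_axes = (n * _BODY_AXES[0] * scale, n * _BODY_AXES[1] * scale)
    bone_center = (
        center[0] + n * _BONE_CENTER_OFF[0] * scale + wiggle(),
        center[1] + n * _BONE_CENTER_OFF[1] * scale + wiggle(),
    )
    bone_axes = (n * _BONE_AXES[0] * scale, n * _BONE_AXES[1] * scale)
    imat_centers = [
        (center[0] + n * dr * scale + wiggle(), center[1] + n * dc * scale + wiggle())
        for dr, dc in _IMAT_OFFSETS
    ]
    return {
        "center": center,
        "body_axes": body_axes,
        "bone_center": bone_center,
        "bone_axes": bone_axes,
        "mat_frac": _MAT_FRAC,
        "ring_scale": scale,
        "imat_centers": imat_centers,
        "imat_radius": n * _IMAT_RADIUS * scale,
    }


def _nominal_geometry(config: PhantomConfig) -> dict:
    n = config.image_size
    center = (0.48 * n, 0.50 * n)
    return {
        "center": center,
        "body_axes": (n * _BODY_AXES[0], n * _BODY_AXES[1]),
        "bone_center": (center[0] + n * _BONE_CENTER_OFF[0], center[1] + n * _BONE_CENTER_OFF[1]),
        "bone_axes": (n * _BONE_AXES[0], n * _BONE_AXES[1]),
        "mat_frac": _MAT_FRAC,
        "ring_scale": 1.0,
        "imat_centers": [(center[0] + n * dr, center[1] + n * dc) for dr, dc in _IMAT_OFFSETS],
        "imat_radius": n * _IMAT_RADIUS,
    }


def _rasterize_slice(config: PhantomConfig, geom: dict, bone_scale: float = 1.0):
    """Paint one slice's label grid and compartments from ellipse geometry."""
    n = config.image_size
    shape = (n, n)
    body = _ellipse(shape, geom["center"], geom["body_axes"])
    fascia_env = _ellipse(shape, geom["center"], (geom["body_axes"][0] * _FASCIA_SCALE, geom["body_axes"][1] * _FASCIA_SCALE))

    ba = (geom["bone_axes"][0] * bone_scale, geom["bone_axes"][1] * bone_scale)
    t_c = _CORTICAL_T * n * geom["ring_scale"]
    t_t = _TRABECULAR_T * n * geom["ring_scale"]
    bone = _ellipse(shape, geom["bone_center"], ba)
    trab_outer = _ellipse(shape, geom["bone_center"], (ba[0] - t_c, ba[1] - t_c))
    marrow = _ellipse(shape, geom["bone_center"], (ba[0] - t_c - t_t, ba[1] - t_c - t_t))
    cortical = bone & ~trab_outer
    trabecular = trab_outer & ~marrow
    mat_r = geom["mat_frac"] * (ba[0] - t_c - t_t)
    mat = _ellipse(shape, (geom["bone_center"][0] + 0.2 * mat_r, geom["bone_center"][1]), (mat_r, mat_r)) & marrow
    hbm = marrow & ~mat

    imat = np.zeros(shape, dtype=bool)
    r = geom["imat_radius"]
    for c in geom["imat_centers"]:
        imat |= _ellipse(shape, c, (r, r))
    imat &= fascia_env & ~bone
    fascia = fascia_env & ~bone
    muscle = fascia & ~imat
    sat = body & ~fascia_env

    labels = np.zeros(shape, dtype=np.uint8)
    labels[sat] = 7
    labels[muscle] = 5
    labels[imat] = 6
    labels[cortical] = 1
    labels[trabecular] = 2
    labels[hbm] = 3
    labels[mat] = 4

    comps = CompartmentMasks(body=body, bone=bone, marrow=marrow, fascia=fascia, subcutaneous=sat)
    return labels, comps


def _rod_masks(config: PhantomConfig) -> list[np.ndarray]:
    n = config.image_size
    shape = (n, n)
    return [_ellipse(shape, (n * _ROD_ROW, n * col), (n * _ROD_RADIUS, n * _ROD_RADIUS)) for col in _ROD_COLS]


def _paint_hu(config: PhantomConfig, labels: np.ndarray, rods: Sequence[np.ndarray], rng: np.random.Generator) -> np.ndarray:
    means = config.hu_means()
    hu = np.full(labels.shape, means["background"], dtype=np.float64)
    for name, code in _CODE_BY_NAME.items():
        hu[labels == code] = means[name]
    for conc, rod in zip(config.rod_concentrations, rods):
        hu[rod] = config.rod_hu_slope * conc + config.rod_hu_intercept
    if config.noise_sigma > 0:
        hu += rng.normal(0.0, config.noise_sigma, size=labels.shape)
    return hu


def generate_phantom(
    config: PhantomConfig,
    subject_id: str,
    domain: str = "A",
    scheme: ThresholdScheme | None = None,
) -> PhantomSample:
    """Generate one subject's phantom stack, deterministic for a fixed seed.

    Domain ``"B"`` applies the configured HU offset and spacing multiplier;
    any other tag is rejected by :func:`generate_cohort`.
    """
    config.validate(scheme)
    rng = _subject_rng(config, subject_id)
    geom = _sample_geometry(config, rng)
    rods = _rod_masks(config)

    center = config.n_slices // 2
    label_slices, images = [], []
    ref_comps = None
    for k in range(config.n_slices):
        bone_scale = 1.0 - _SLICE_FALLOFF * abs(k - center)
        labels_k, comps_k = _rasterize_slice(config, geom, bone_scale)
        if k == center:
            ref_comps = comps_k
        label_slices.append(labels_k)
        images.append(_paint_hu(config, labels_k, rods, rng))

    height = float(np.clip(rng.normal(1.72, 0.07), 1.45, 2.05))

    spacing = config.pixel_spacing
    hu = np.stack(images) if config.n_slices > 1 else images[0]
    labels = np.stack(label_slices) if config.n_slices > 1 else label_slices[0]
    if domain == "B":
        hu = hu + config.domain_shift.hu_offset
        spacing = spacing * config.domain_shift.spacing_multiplier

    image = CTImage(hu, pixel_spacing=(spacing, spacing), slice_thickness=config.slice_thickness, origin=subject_id)
    mask = LabelMask(labels, pixel_spacing=(spacing, spacing), slice_thickness=config.slice_thickness)
    return PhantomSample(
        image=image,
        labels=mask,
        compartments=ref_comps,
        rod_masks=rods,
        subject_id=subject_id,
        height_m=height,
        domain=domain,
    )


def generate_cohort(
    config: PhantomConfig,
    n_subjects: int,
    domains: Sequence[str] = ("A",),
    scheme: ThresholdScheme | None = None,
) -> list[PhantomSample]:
    """Generate ``n_subjects`` phantoms split round-robin across domains."""
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    for d in domains:
        if d not in ("A", "B"):
            raise ValueError(f"unknown domain tag: {d!r} (expected 'A' or 'B')")
    return [
        generate_phantom(config, f"S{i:04d}", domain=domains[i % len(domains)], scheme=scheme)
        for i in range(n_subjects)
    ]


def nominal_fractions(config: PhantomConfig) -> dict[int, float]:
    """Per-class pixel fraction of the unjittered reference-slice geometry.

    These are the geometric targets that jittered subjects should stay
    within about +/-20% of (classes vary with the squared axis jitter).
    """
    labels, _ = _rasterize_slice(config, _nominal_geometry(config))
    counts = np.bincount(labels.ravel(), minlength=8)
    total = labels.size
    return {code: counts[code] / total for code in range(8)}
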