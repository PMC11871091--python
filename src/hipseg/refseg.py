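"""Reference (ground-truth protocol) segmentation.

Two stages, mirroring the manual protocol: anatomical compartments are
delineated first (body, bone shell, marrow cavity, fascial envelope,
subcutaneous ring), then Hounsfield-unit thresholds classify each
compartment's pixels into the seven tissues.

Interval convention is half-open ``[low, high)`` so touching ranges
partition the HU axis exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi
from skimage import morphology

from .imaging_io import CTImage, LabelMask

__all__ = ["ThresholdScheme", "CompartmentMasks", "derive_compartments", "classify_tissues", "reference_segment"]

AIR_CUTOFF_HU = -200.0  # body extraction cutoff
BASE_IMAGE_SIZE = 128  # disk radius below is stated at this scale
BASE_DISK_RADIUS = 2


@dataclass(frozen=True)
class ThresholdScheme:
    """Per-tissue HU intervals.

    Defaults: cortical bone above 300 HU, cancellous/trabecular bone
    150-300, HBM 50-150, MAT below 50 (all within the bone compartment);
    muscle -30 to 500 and fat below -30 in the soft-tissue compartments.
    """

    cortical_min: float = 300.0
    trabecular_range: tuple[float, float] = (150.0, 300.0)
    hbm_range: tuple[float, float] = (50.0, 150.0)
    mat_max: float = 50.0
    muscle_range: tuple[float, float] = (-30.0, 500.0)
    fat_max: float = -30.0

    def __post_init__(self) -> None:
        if not (self.mat_max <= self.hbm_range[0]):
            raise ValueError("MAT upper bound must not exceed HBM lower bound")
        if not (self.hbm_range[1] <= self.trabecular_range[0]):
            raise ValueError("HBM upper bound must not exceed trabecular lower bound")
        if not (self.trabecular_range[1] <= self.cortical_min):
            raise ValueError("trabecular upper bound must not exceed cortical minimum")
        if not (self.fat_max <= self.muscle_range[0]):
            raise ValueError("fat upper bound must not exceed muscle lower bound")
        for lo, hi in (self.trabecular_range, self.hbm_range, self.muscle_range):
            if lo >= hi:
                raise ValueError("interval bounds must be increasing")

    @classmethod
    def from_dict(cls, d: dict) -> "ThresholdScheme":
        kwargs = {}
        for key in ("cortical_min", "mat_max", "fat_max"):
            if key in d:
                kwargs[key] = float(d[key])
        for key in ("trabecular_range", "hbm_range", "muscle_range"):
            if key in d:
                kwargs[key] = tuple(float(v) for v in d[key])
        return cls(**kwargs)

    def to_dict(self) -> dict:
        return {
            "cortical_min": self.cortical_min,
            "trabecular_range": list(self.trabecular_range),
            "hbm_range": list(self.hbm_range),
            "mat_max": self.mat_max,
            "muscle_range": list(self.muscle_range),
            "fat_max": self.fat_max,
        }

    def interval_for(self, code: int) -> tuple[float, float]:
        """Half-open HU interval [low, high) for a tissue code."""
        return {
            1: (self.cortical_min, np.inf),
            2: self.trabecular_range,
            3: self.hbm_range,
            4: (-np.inf, self.mat_max),
            5: self.muscle_range,
            6: (-np.inf, self.fat_max),
            7: (-np.inf, self.fat_max),
        }[code]


@dataclass
class CompartmentMasks:
    """Binary anatomical compartments of one axial slice.

    ``bone`` is the cortical shell plus everything inside it; ``marrow`` its
    interior below the trabecular threshold; ``fascia`` the muscle compartment
    inside the fascial envelope excluding bone; ``subcutaneous`` the ring
    between skin and fascia; ``body`` the full cross-section.
    """

    body: np.ndarray
    bone: np.ndarray
    marrow: np.ndarray
    fascia: np.ndarray
    subcutaneous: np.ndarray

    def __post_init__(self) -> None:
        shapes = {m.shape for m in (self.body, self.bone, self.marrow, self.fascia, self.subcutaneous)}
        if len(shapes) != 1:
            raise ValueError("compartment masks must share one shape")
        for name in ("body", "bone", "marrow", "fascia", "subcutaneous"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=bool))

    def validate(self) -> None:
        if np.any(self.marrow & ~self.bone):
            raise ValueError("marrow must be contained in bone")
        if np.any(self.bone & self.fascia) or np.any(self.bone & self.subcutaneous) or np.any(self.fascia & self.subcutaneous):
            raise ValueError("bone, fascia and subcutaneous must be pairwise disjoint")
        union = self.bone | self.fascia | self.subcutaneous
        if np.any(union & ~self.body):
            raise ValueError("compartments must lie inside the body")


def _disk_radius(shape: tuple[int, ...]) -> int:
    return max(1, round(BASE_DISK_RADIUS * max(shape) / BASE_IMAGE_SIZE))


def derive_compartments(image: CTImage, scheme: ThresholdScheme | None = None) -> CompartmentMasks:
    """Delineate anatomical compartments of a 2-D slice.

    The body is the largest connected component above the air cutoff (which
    drops the calibration rods); bone is the morphologically closed,
    hole-filled envelope of the dense (>= trabecular low) pixels; marrow is
    the bone interior below that threshold; the fascial envelope is the
    hole-filled muscle region outside bone; subcutaneous is the remainder.
    """
    scheme = scheme or ThresholdScheme()
    if image.values.ndim != 2:
        raise ValueError("derive_compartments operates on single 2-D slices")
    hu = image.values

    above_air = hu > AIR_CUTOFF_HU
    labeled, n = ndi.label(above_air, structure=np.ones((3, 3), dtype=int))
    if n == 0:
        raise ValueError("empty body: no pixels above the air cutoff")
    sizes = ndi.sum_labels(np.ones_like(hu), labeled, index=np.arange(1, n + 1))
    body = labeled == (1 + int(np.argmax(sizes)))

    footprint = morphology.disk(_disk_radius(hu.shape))
    dense = (hu >= scheme.trabecular_range[0]) & body
    if not dense.any():
        raise ValueError("no bone component found")
    bone = ndi.binary_fill_holes(morphology.closing(dense, footprint))
    bone_labeled, nb = ndi.label(bone, structure=np.ones((3, 3), dtype=int))
    if nb > 1:  # keep largest bone component; specks from noise are dropped
        bsizes = ndi.sum_labels(np.ones_like(hu), bone_labeled, index=np.arange(1, nb + 1))
        bone = bone_labeled == (1 + int(np.argmax(bsizes)))
    marrow = bone & ~(hu >= scheme.trabecular_range[0])

    muscle_like = (hu >= scheme.muscle_range[0]) & body & ~bone
    fascia_env = ndi.binary_fill_holes(morphology.closing(muscle_like | bone, footprint))
    fascia = fascia_env & ~bone
    subcutaneous = body & ~fascia_env

    return CompartmentMasks(body=body, bone=bone, marrow=marrow, fascia=fascia, subcutaneous=subcutaneous)


def classify_tissues(
    image: CTImage,
    compartments: CompartmentMasks,
    scheme: ThresholdScheme | None = None,
) -> LabelMask:
    """Threshold each compartment's HU into the seven tissue classes.

    Within bone: cortical above ``cortical_min``, trabecular in its range
    (shell or residual marrow pixels alike); within marrow: HBM and MAT by
    their intervals. Within fascia: muscle in range, fat below ``fat_max`` is
    IMAT; the same fat interval in the subcutaneous ring is SAT. Muscle-range
    overshoot (>= 500 HU) in fascia and all unclassifiable pixels stay
    background.
    """
    scheme = scheme or ThresholdScheme()
    hu = image.values
    compartments.validate()
    out = np.zeros(hu.shape, dtype=np.uint8)

    bone, marrow = compartments.bone, compartments.marrow
    out[bone & (hu >= scheme.cortical_min)] = 1
    trab_lo, trab_hi = scheme.trabecular_range
    out[bone & (hu >= trab_lo) & (hu < trab_hi)] = 2
    hbm_lo, hbm_hi = scheme.hbm_range
    out[marrow & (hu >= hbm_lo) & (hu < hbm_hi)] = 3
    out[marrow & (hu < scheme.mat_max)] = 4
    # residual marrow pixels at/above the trabecular low bound already fell
    # into the trabecular assignment above

    fascia, subcut = compartments.fascia, compartments.subcutaneous
    mus_lo, mus_hi = scheme.muscle_range
    out[fascia & (hu >= mus_lo) & (hu < mus_hi)] = 5
    out[fascia & (hu < scheme.fat_max)] = 6
    out[subcut & (hu < scheme.fat_max)] = 7

    return LabelMask(out, pixel_spacing=image.pixel_spacing, slice_thickness=image.slice_thickness)


def reference_segment(image: CTImage, scheme: ThresholdScheme | None = None) -> LabelMask:
    """Convenience pipeline: compartments then tissue classification.

    Accepts 2-D slices or 3-D stacks (processed slice by slice).
    """
    scheme = scheme or ThresholdScheme()
    if image.values.ndim == 3:
        slices = [reference_segment(image.slice(i), scheme).classes for i in range(image.n_slices)]
        return LabelMask(np.stack(slices), image.pixel_spacing, image.slice_thickness)
    comps = derive_compartments(image, scheme)
    return classify_tissues(image, comps, scheme)
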