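"""Image and label-mask I/O with physical metadata, plus rod-based HU calibration.

Supported on-disk formats
-------------------------
* NIfTI (``.nii`` / ``.nii.gz``) via :mod:`nibabel`; pixel spacing and slice
  thickness are stored in the header zooms.
* 16-bit PNG (``.png``) with a JSON sidecar ``<name>.json`` holding
  ``pixel_spacing_mm``, ``slice_thickness_mm`` and ``hu_offset``.  HU values
  are stored as ``uint16`` after adding the offset (default +1024), which is
  lossless for the clinical HU range after rounding to integer HU.

Axial slice order for 3-D stacks is index-increasing superior to inferior;
the convention is recorded in the PNG sidecar.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

__all__ = [
    "CTImage",
    "LabelMask",
    "CalibrationFit",
    "read_image",
    "write_image",
    "read_mask",
    "write_mask",
    "fit_calibration",
    "apply_calibration",
]

#: uint16 storage offset so negative HU survive PNG round-trips.
PNG_HU_OFFSET = 1024
PNG_HU_MIN = -1024
PNG_HU_MAX = 65535 - PNG_HU_OFFSET

N_CLASSES = 8  #: background + 7 tissues

#: class codes, fixed across the toolkit
CLASS_NAMES = {
    0: "background",
    1: "cortical",
    2: "trabecular",
    3: "hbm",
    4: "mat",
    5: "muscle",
    6: "imat",
    7: "sat",
}
TISSUE_CODES = tuple(range(1, 8))


@dataclass
class CTImage:
    """A 2-D slice or 3-D axial stack of Hounsfield units with physical spacing.

    Parameters
    ----------
    values
        Float HU grid, shape ``(rows, cols)`` or ``(slices, rows, cols)``.
    pixel_spacing
        In-plane spacing ``(row_mm, col_mm)``.
    slice_thickness
        Axial thickness in mm.
    origin
        Free-form provenance tag (e.g. phantom subject id).
    """

    values: np.ndarray
    pixel_spacing: tuple[float, float] = (1.0, 1.0)
    slice_thickness: float = 3.0
    origin: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim not in (2, 3):
            raise ValueError(f"CTImage must be 2-D or 3-D, got ndim={self.values.ndim}")
        sp = tuple(float(s) for s in self.pixel_spacing)
        if len(sp) != 2 or any(s <= 0 for s in sp):
            raise ValueError(f"pixel_spacing must be two positive floats, got {self.pixel_spacing}")
        self.pixel_spacing = sp
        if self.slice_thickness <= 0:
            raise ValueError("slice_thickness must be positive")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("HU values must be finite")

    @property
    def is_stack(self) -> bool:
        return self.values.ndim == 3

    @property
    def n_slices(self) -> int:
        return self.values.shape[0] if self.is_stack else 1

    def slice(self, index: int) -> "CTImage":
        """Extract a single axial slice as a 2-D CTImage."""
        if not self.is_stack:
            raise ValueError("not a 3-D stack")
        return CTImage(
            self.values[index],
            pixel_spacing=self.pixel_spacing,
            slice_thickness=self.slice_thickness,
            origin=f"{self.origin}[{index}]",
        )


@dataclass
class LabelMask:
    """Integer tissue-class grid aligned to a :class:`CTImage`.

    Codes: 0 background, 1 cortical, 2 trabecular, 3 HBM, 4 MAT,
    5 muscle, 6 IMAT, 7 SAT.
    """

    classes: np.ndarray
    pixel_spacing: tuple[float, float] = (1.0, 1.0)
    slice_thickness: float = 3.0

    def __post_init__(self) -> None:
        self.classes = np.asarray(self.classes)
        if not np.issubdtype(self.classes.dtype, np.integer):
            raise ValueError("label mask must be integer-typed")
        self.classes = self.classes.astype(np.uint8, casting="safe" if self.classes.dtype == np.uint8 else "unsafe")
        if self.classes.ndim not in (2, 3):
            raise ValueError("LabelMask must be 2-D or 3-D")
        lo, hi = int(self.classes.min(initial=0)), int(self.classes.max(initial=0))
        if lo < 0 or hi >= N_CLASSES:
            raise ValueError(f"class codes must lie in 0..{N_CLASSES - 1}, found range [{lo}, {hi}]")
        self.pixel_spacing = tuple(float(s) for s in self.pixel_spacing)

    @property
    def is_stack(self) -> bool:
        return self.classes.ndim == 3

    def slice(self, index: int) -> "LabelMask":
        if not self.is_stack:
            raise ValueError("not a 3-D stack")
        return LabelMask(self.classes[index], self.pixel_spacing, self.slice_thickness)

    def histogram(self) -> np.ndarray:
        """Pixel count per class code (length 8)."""
        return np.bincount(self.classes.ravel(), minlength=N_CLASSES)


@dataclass
class CalibrationFit:
    """Least-squares line mapping measured HU to hydroxyapatite density."""

    slope: float  # (mg/cm3) per HU
    intercept: float  # mg/cm3
    r_squared: float
    rod_means: list[tuple[float, float]] = field(default_factory=list)  # (nominal, mean HU)

    def predict(self, hu: float | np.ndarray) -> float | np.ndarray:
        return self.slope * np.asarray(hu, dtype=float) + self.intercept


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(".json")


def write_image(image: CTImage, path: str | Path) -> None:
    """Write a CTImage as NIfTI or 16-bit PNG (+ JSON sidecar)."""
    path = Path(path)
    suffixes = "".join(path.suffixes)
    if suffixes.endswith((".nii", ".nii.gz")):
        _write_nifti(image.values, image.pixel_spacing, image.slice_thickness, path)
    elif path.suffix == ".png":
        if image.is_stack:
            raise ValueError("PNG supports 2-D slices only; write stacks as NIfTI")
        import imageio.v3 as iio

        stored = np.clip(np.rint(image.values), PNG_HU_MIN, PNG_HU_MAX) + PNG_HU_OFFSET
        iio.imwrite(path, stored.astype(np.uint16))
        sidecar = {
            "pixel_spacing_mm": list(image.pixel_spacing),
            "slice_thickness_mm": image.slice_thickness,
            "hu_offset": PNG_HU_OFFSET,
            "slice_order": "superior_to_inferior",
        }
        _sidecar_path(path).write_text(json.dumps(sidecar, indent=2))
    else:
        raise ValueError(f"unsupported image extension: {path.name}")


def read_image(path: str | Path) -> CTImage:
    """Read a CTImage; raises if spacing metadata is absent (no silent defaults)."""
    path = Path(path)
    suffixes = "".join(path.suffixes)
    if suffixes.endswith((".nii", ".nii.gz")):
        values, spacing, thickness = _read_nifti(path, dtype=np.float64)
        return CTImage(values, spacing, thickness, origin=path.name)
    if path.suffix == ".png":
        import imageio.v3 as iio

        side = _sidecar_path(path)
        if not side.exists():
            raise FileNotFoundError(f"missing JSON sidecar for {path.name}: {side.name}")
        meta = json.loads(side.read_text())
        if "pixel_spacing_mm" not in meta:
            raise ValueError(f"sidecar {side.name} lacks pixel_spacing_mm")
        stored = np.asarray(iio.imread(path), dtype=np.float64)
        hu = stored - float(meta.get("hu_offset", PNG_HU_OFFSET))
        return CTImage(
            hu,
            tuple(meta["pixel_spacing_mm"]),
            float(meta.get("slice_thickness_mm", 3.0)),
            origin=path.name,
        )
    raise ValueError(f"unsupported image extension: {path.name}")


def write_mask(mask: LabelMask, path: str | Path) -> None:
    """Write a LabelMask as NIfTI or indexed 8-bit PNG (+ sidecar)."""
    path = Path(path)
    suffixes = "".join(path.suffixes)
    if suffixes.endswith((".nii", ".nii.gz")):
        _write_nifti(mask.classes.astype(np.uint8), mask.pixel_spacing, mask.slice_thickness, path)
    elif path.suffix == ".png":
        if mask.is_stack:
            raise ValueError("PNG supports 2-D masks only")
        import imageio.v3 as iio

        iio.imwrite(path, mask.classes.astype(np.uint8))
        sidecar = {
            "pixel_spacing_mm": list(mask.pixel_spacing),
            "slice_thickness_mm": mask.slice_thickness,
            "kind": "label_mask",
        }
        _sidecar_path(path).write_text(json.dumps(sidecar, indent=2))
    else:
        raise ValueError(f"unsupported mask extension: {path.name}")


def read_mask(path: str | Path) -> LabelMask:
    path = Path(path)
    suffixes = "".join(path.suffixes)
    if suffixes.endswith((".nii", ".nii.gz")):
        values, spacing, thickness = _read_nifti(path, dtype=np.int64)
        return LabelMask(np.rint(values).astype(np.uint8), spacing, thickness)
    if path.suffix == ".png":
        import imageio.v3 as iio

        side = _sidecar_path(path)
        if not side.exists():
            raise FileNotFoundError(f"missing JSON sidecar for {path.name}")
        meta = json.loads(side.read_text())
        if "pixel_spacing_mm" not in meta:
            raise ValueError(f"sidecar {side.name} lacks pixel_spacing_mm")
        classes = np.asarray(iio.imread(path)).astype(np.uint8)
        return LabelMask(classes, tuple(meta["pixel_spacing_mm"]), float(meta.get("slice_thickness_mm", 3.0)))
    raise ValueError(f"unsupported mask extension: {path.name}")


def _write_nifti(values: np.ndarray, spacing: Sequence[float], thickness: float, path: Path) -> None:
    import nibabel as nib

    # nibabel axis order (i, j, k) = (col, row, slice); transpose our
    # (slice, row, col) / (row, col) grids accordingly.
    if values.ndim == 3:
        data = np.transpose(values, (2, 1, 0))
        zooms = (spacing[1], spacing[0], thickness)
    else:
        data = values.T[:, :, None]
        zooms = (spacing[1], spacing[0], thickness)
    affine = np.diag([zooms[0], zooms[1], zooms[2], 1.0])
    img = nib.Nifti1Image(np.ascontiguousarray(data), affine)
    img.header.set_zooms(zooms)
    nib.save(img, str(path))


def _read_nifti(path: Path, dtype) -> tuple[np.ndarray, tuple[float, float], float]:
    import nibabel as nib

    img = nib.load(str(path))
    zooms = img.header.get_zooms()[:3]
    if any(z <= 0 for z in zooms):
        raise ValueError(f"{path.name}: header lacks positive voxel spacing")
    data = np.asanyarray(img.dataobj).astype(dtype)
    if data.ndim != 3:
        raise ValueError(f"{path.name}: expected 3-D NIfTI data, got ndim={data.ndim}")
    if data.shape[2] == 1:
        values = data[:, :, 0].T
    else:
        values = np.transpose(data, (2, 1, 0))
    spacing = (float(zooms[1]), float(zooms[0]))
    return values, spacing, float(zooms[2])


# ---------------------------------------------------------------------------
# HU calibration against hydroxyapatite rods
# ---------------------------------------------------------------------------


def fit_calibration(
    image: CTImage,
    rod_rois: Sequence[np.ndarray],
    nominal: Sequence[float],
) -> CalibrationFit:
    """Fit the least-squares line mapping measured mean rod HU to nominal density.

    Parameters
    ----------
    image
        The CT slice/stack containing the calibration rods.
    rod_rois
        Boolean masks (same shape as ``image.values``), one per rod, pairwise
        disjoint and non-empty.
    nominal
        Known hydroxyapatite concentrations in mg/cm3, one per rod.
    """
    if len(rod_rois) != len(nominal):
        raise ValueError("one nominal concentration required per rod ROI")
    if len(rod_rois) < 2:
        raise ValueError("calibration needs at least 2 rods")
    rois = [np.asarray(r, dtype=bool) for r in rod_rois]
    for i, roi in enumerate(rois):
        if roi.shape != image.values.shape:
            raise ValueError(f"rod ROI {i} shape mismatch")
        if not roi.any():
            raise ValueError(f"rod ROI {i} is empty")
    for i in range(len(rois)):
        for j in range(i + 1, len(rois)):
            if np.any(rois[i] & rois[j]):
                raise ValueError(f"rod ROIs {i} and {j} overlap")

    hu_means = np.array([image.values[r].mean() for r in rois])
    conc = np.asarray(nominal, dtype=float)
    if np.ptp(hu_means) == 0:
        raise ValueError("degenerate calibration: identical rod mean HU")

    slope, intercept = np.polyfit(hu_means, conc, 1)
    pred = slope * hu_means + intercept
    ss_res = float(np.sum((conc - pred) ** 2))
    ss_tot = float(np.sum((conc - conc.mean()) ** 2))
    r2 = 1.0 if ss_tot == 0 else max(0.0, min(1.0, 1.0 - ss_res / ss_tot))
    return CalibrationFit(
        slope=float(slope),
        intercept=float(intercept),
        r_squared=r2,
        rod_means=[(float(c), float(h)) for c, h in zip(conc, hu_means)],
    )


def apply_calibration(image: CTImage, fit: CalibrationFit) -> np.ndarray:
    """Map every pixel's HU to mg/cm3 through the fitted affine line."""
    return fit.predict(image.values)
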