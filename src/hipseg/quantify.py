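"""Quantitative tissue measures from label masks.

Per-tissue cross-sectional area on the reference slice, volume over the
5-slice window, average HU for muscle (optionally adjusted for height
squared), and the haematopoietic/adipose marrow fractions of total bone
marrow.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .imaging_io import CTImage, LabelMask, CLASS_NAMES, TISSUE_CODES

__all__ = [
    "QuantReport",
    "select_reference_slice",
    "tissue_area",
    "tissue_volume",
    "ahu",
    "marrow_ratios",
    "quantify_subject",
    "cohort_table",
]

VOLUME_WINDOW = 5  # reference slice +/- 2


@dataclass
class QuantReport:
    """Quantitative measures for one subject."""

    subject_id: str
    reference_index: int
    area_cm2: dict[int, float] = field(default_factory=dict)  # class code -> cm2
    volume_cm3: dict[int, float] = field(default_factory=dict)  # class code -> cm3
    ahu_muscle: float | None = None
    ahu_muscle_per_h2: float | None = None
    height_m: float | None = None
    tbm_area_cm2: float = 0.0
    hbm_over_tbm: float | None = None
    mat_over_tbm: float | None = None

    def to_row(self) -> dict:
        row: dict = {"subject_id": self.subject_id, "reference_index": self.reference_index, "height_m": self.height_m}
        for code in TISSUE_CODES:
            row[f"area_{CLASS_NAMES[code]}_cm2"] = self.area_cm2.get(code)
            row[f"volume_{CLASS_NAMES[code]}_cm3"] = self.volume_cm3.get(code)
        row.update(
            ahu_muscle=self.ahu_muscle,
            ahu_muscle_per_h2=self.ahu_muscle_per_h2,
            tbm_area_cm2=self.tbm_area_cm2,
            hbm_over_tbm=self.hbm_over_tbm,
            mat_over_tbm=self.mat_over_tbm,
        )
        return row


def _bone_proxy_count(mask2d: np.ndarray, image_right_half: bool) -> int:
    """Cortical + trabecular pixels in the half-image holding the left
    femoral neck (image-right under radiological convention)."""
    _, w = mask2d.shape
    half = mask2d[:, w // 2 :] if image_right_half else mask2d[:, : w // 2]
    return int(np.isin(half, (1, 2)).sum())


def select_reference_slice(
    stack: CTImage | None,
    masks: LabelMask | Sequence[LabelMask],
    image_right_half: bool = True,
) -> int:
    """Index of the slice maximizing the femoral-neck thickness proxy
    (bone pixel count in the configured half-image); ties resolve to the
    inferior-most (highest index)."""
    if isinstance(masks, LabelMask):
        if not masks.is_stack:
            raise ValueError("need a 3-D mask stack or a list of slice masks")
        slices = [masks.classes[k] for k in range(masks.classes.shape[0])]
    else:
        slices = [m.classes for m in masks]
    counts = [_bone_proxy_count(s, image_right_half) for s in slices]
    if max(counts) == 0:
        raise ValueError("no bone found in any slice")
    best = max(counts)
    return max(i for i, c in enumerate(counts) if c == best)


def tissue_area(mask: LabelMask, class_code: int) -> float:
    """Cross-sectional area in cm2 (2-D mask): pixel count x pixel area."""
    if mask.classes.ndim != 2:
        raise ValueError("tissue_area expects a 2-D mask")
    if mask.pixel_spacing[0] <= 0 or mask.pixel_spacing[1] <= 0:
        raise ValueError("pixel spacing absent or non-positive")
    n = int((mask.classes == class_code).sum())
    mm2 = n * mask.pixel_spacing[0] * mask.pixel_spacing[1]
    return mm2 / 100.0


def tissue_volume(
    masks: LabelMask | Sequence[LabelMask],
    class_code: int,
    thickness_mm: float | None = None,
    reference_index: int | None = None,
    window: int = VOLUME_WINDOW,
) -> float:
    """Volume in cm3 over the ``window``-slice stack centred on the reference
    slice: sum of per-slice areas times slice thickness."""
    if isinstance(masks, LabelMask):
        if not masks.is_stack:
            raise ValueError("need a 3-D mask stack")
        thickness_mm = thickness_mm or masks.slice_thickness
        slice_masks = [masks.slice(k) for k in range(masks.classes.shape[0])]
    else:
        slice_masks = list(masks)
        if thickness_mm is None:
            thickness_mm = slice_masks[0].slice_thickness
    n = len(slice_masks)
    if reference_index is None:
        reference_index = n // 2
    half = window // 2
    lo, hi = reference_index - half, reference_index + half
    if lo < 0 or hi >= n:
        raise ValueError(f"{window}-slice window around slice {reference_index} exceeds the stack (n={n})")
    areas = [tissue_area(slice_masks[k], class_code) for k in range(lo, hi + 1)]
    return float(sum(areas) * thickness_mm / 10.0)  # mm -> cm


def ahu(
    image: CTImage,
    mask: LabelMask,
    class_code: int,
    height_m: float | None = None,
) -> tuple[float, float | None]:
    """Average HU over a class's pixels; with height, also AHU/h^2 (HU/m^2)."""
    sel = mask.classes == class_code
    if not sel.any():
        raise ValueError(f"class {class_code} is empty")
    mean_hu = float(image.values[sel].mean())
    if height_m is None:
        return mean_hu, None
    if height_m <= 0:
        raise ValueError("height must be positive")
    return mean_hu, mean_hu / (height_m**2)


def marrow_ratios(mask: LabelMask) -> tuple[float | None, float | None]:
    """(HBM/TBM, MAT/TBM) by pixel count; (None, None) when TBM is empty.
    The two fractions sum to one whenever defined."""
    hbm = int((mask.classes == 3).sum())
    mat = int((mask.classes == 4).sum())
    tbm = hbm + mat
    if tbm == 0:
        return None, None
    return hbm / tbm, mat / tbm


def quantify_subject(
    image: CTImage,
    masks: LabelMask,
    subject_id: str = "",
    height_m: float | None = None,
    image_right_half: bool = True,
) -> QuantReport:
    """Full quantitative report for one subject's stack (or single slice)."""
    if masks.is_stack:
        ref = select_reference_slice(image, masks, image_right_half=image_right_half)
        ref_mask = masks.slice(ref)
        ref_image = image.slice(ref)
    else:
        ref, ref_mask, ref_image = 0, masks, image

    report = QuantReport(subject_id=subject_id, reference_index=ref, height_m=height_m)
    for code in TISSUE_CODES:
        report.area_cm2[code] = tissue_area(ref_mask, code)
        if masks.is_stack and masks.classes.shape[0] >= VOLUME_WINDOW:
            report.volume_cm3[code] = tissue_volume(masks, code, reference_index=ref)
    if (ref_mask.classes == 5).any():
        report.ahu_muscle, report.ahu_muscle_per_h2 = ahu(ref_image, ref_mask, 5, height_m)
    report.tbm_area_cm2 = report.area_cm2.get(3, 0.0) + report.area_cm2.get(4, 0.0)
    report.hbm_over_tbm, report.mat_over_tbm = marrow_ratios(ref_mask)
    return report


def cohort_table(reports: Sequence[QuantReport]):
    """One row per subject, suitable for export to external statistics tools."""
    import pandas as pd

    return pd.DataFrame([r.to_row() for r in reports])
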