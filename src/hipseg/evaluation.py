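"""Segmentation metrics, k-fold cross-validation and cross-domain evaluation.

Per-class metrics operate one-vs-rest on label masks: Dice similarity
coefficient and sensitivity/specificity as percentages, and the average
symmetric surface distance in millimetres. Classes absent from both masks
(DSC) or from either mask (ASSD) yield ``None`` with a recorded flag and are
excluded from aggregation rather than defined away.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
from scipy.spatial import cKDTree

from .imaging_io import LabelMask, TISSUE_CODES, CLASS_NAMES

__all__ = [
    "dsc",
    "assd",
    "sensitivity_specificity",
    "per_class_metrics",
    "aggregate",
    "CVPlan",
    "plan_cv",
    "run_cv",
    "cross_domain_eval",
    "SegMetricsReport",
    "OracleModel",
]


def _binary(mask: LabelMask | np.ndarray, class_code: int) -> np.ndarray:
    arr = mask.classes if isinstance(mask, LabelMask) else np.asarray(mask)
    return arr == class_code


def dsc(a: LabelMask | np.ndarray, b: LabelMask | np.ndarray, class_code: int) -> float | None:
    """Dice similarity coefficient for one class, in percent.

    ``2|A∩B| / (|A|+|B|) * 100``; returns ``None`` (undefined) when the
    class is absent from both masks.
    """
    ba, bb = _binary(a, class_code), _binary(b, class_code)
    if ba.shape != bb.shape:
        raise ValueError("mask shapes differ")
    na, nb = int(ba.sum()), int(bb.sum())
    if na + nb == 0:
        return None
    inter = int(np.logical_and(ba, bb).sum())
    return 100.0 * 2.0 * inter / (na + nb)


def _boundary(mask: np.ndarray) -> np.ndarray:
    """Class pixels with at least one non-class 4-neighbour (image border
    counts as non-class)."""
    padded = np.pad(mask, 1, constant_values=False)
    interior = (
        padded[:-2, 1:-1] & padded[2:, 1:-1] & padded[1:-1, :-2] & padded[1:-1, 2:]
    )
    return mask & ~interior


def assd(
    a: LabelMask | np.ndarray,
    b: LabelMask | np.ndarray,
    class_code: int,
    spacing: tuple[float, float] | None = None,
) -> float | None:
    """Average symmetric surface distance in mm (2-D masks).

    Mean of both directed average Euclidean nearest-boundary distances;
    ``None`` when the class is missing from either mask.
    """
    if spacing is None:
        spacing = a.pixel_spacing if isinstance(a, LabelMask) else (1.0, 1.0)
    ba, bb = _binary(a, class_code), _binary(b, class_code)
    if ba.shape != bb.shape:
        raise ValueError("mask shapes differ")
    if not ba.any() or not bb.any():
        return None
    pa = np.argwhere(_boundary(ba)).astype(np.float64) * np.asarray(spacing)
    pb = np.argwhere(_boundary(bb)).astype(np.float64) * np.asarray(spacing)
    da = cKDTree(pb).query(pa)[0]
    db = cKDTree(pa).query(pb)[0]
    return float((da.mean() + db.mean()) / 2.0)


def sensitivity_specificity(
    truth: LabelMask | np.ndarray,
    pred: LabelMask | np.ndarray,
    class_code: int,
) -> tuple[float | None, float | None]:
    """One-vs-rest (sensitivity %, specificity %); ``None`` on a zero
    denominator."""
    bt, bp = _binary(truth, class_code), _binary(pred, class_code)
    if bt.shape != bp.shape:
        raise ValueError("mask shapes differ")
    tp = int((bt & bp).sum())
    fn = int((bt & ~bp).sum())
    tn = int((~bt & ~bp).sum())
    fp = int((~bt & bp).sum())
    sens = 100.0 * tp / (tp + fn) if (tp + fn) > 0 else None
    spec = 100.0 * tn / (tn + fp) if (tn + fp) > 0 else None
    return sens, spec


def per_class_metrics(
    truth: LabelMask,
    pred: LabelMask,
    classes: Sequence[int] = TISSUE_CODES,
    spacing: tuple[float, float] | None = None,
    with_assd: bool = True,
) -> dict[int, dict[str, float | None]]:
    """All four metrics for each requested class of one image."""
    out: dict[int, dict[str, float | None]] = {}
    for code in classes:
        sens, spec = sensitivity_specificity(truth, pred, code)
        row = {"dsc": dsc(truth, pred, code), "sensitivity": sens, "specificity": spec}
        if with_assd:
            t, p = truth.classes, pred.classes
            if t.ndim == 3:  # slice-wise mean for stacks
                vals = [assd(t[k], p[k], code, spacing or truth.pixel_spacing) for k in range(t.shape[0])]
                vals = [v for v in vals if v is not None]
                row["assd"] = float(np.mean(vals)) if vals else None
            else:
                row["assd"] = assd(t, p, code, spacing or truth.pixel_spacing)
        out[code] = row
    return out


@dataclass
class SegMetricsReport:
    """Per-image metric rows plus mean +/- sd aggregation.

    ``per_image`` maps image id -> class code -> metric -> value (or None).
    ``summary`` maps class code -> metric -> (mean, sd, n_defined).
    """

    per_image: dict[str, dict[int, dict[str, float | None]]] = field(default_factory=dict)
    summary: dict[int, dict[str, tuple[float, float, int]]] = field(default_factory=dict)
    timing_s_per_slice: list[float] = field(default_factory=list)
    undefined: list[tuple[str, int, str]] = field(default_factory=list)  # (image, class, metric)

    def mean_dsc(self, classes: Sequence[int] = TISSUE_CODES) -> float:
        vals = [self.summary[c]["dsc"][0] for c in classes if "dsc" in self.summary.get(c, {})]
        return float(np.mean(vals))

    def to_rows(self) -> list[dict]:
        rows = []
        for code, stats in sorted(self.summary.items()):
            for metric, (mean, sd, n) in stats.items():
                rows.append({"tissue": CLASS_NAMES[code], "metric": metric, "mean": mean, "sd": sd, "n": n})
        return rows


def aggregate(per_image: Mapping[str, Mapping[int, Mapping[str, float | None]]]) -> SegMetricsReport:
    """Aggregate per-image metric dicts into mean +/- sd per class/metric,
    excluding (and recording) undefined entries."""
    report = SegMetricsReport(per_image={k: {c: dict(m) for c, m in v.items()} for k, v in per_image.items()})
    by_key: dict[tuple[int, str], list[float]] = {}
    for image_id, classes in per_image.items():
        for code, metrics in classes.items():
            for metric, value in metrics.items():
                if value is None:
                    report.undefined.append((image_id, code, metric))
                else:
                    by_key.setdefault((code, metric), []).append(value)
    for (code, metric), vals in by_key.items():
        arr = np.asarray(vals, dtype=float)
        report.summary.setdefault(code, {})[metric] = (float(arr.mean()), float(arr.std(ddof=0)), len(vals))
    return report


# ---------------------------------------------------------------------------
# cross-validation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CVPlan:
    """Subject-level fold assignment; folds partition subjects, sizes differ
    by at most one."""

    k: int
    assignment: Mapping[str, int]
    seed: int

    def fold_subjects(self, fold: int) -> list[str]:
        return sorted(s for s, f in self.assignment.items() if f == fold)

    def validate(self) -> None:
        folds = np.asarray(sorted(self.assignment.values()))
        if set(folds.tolist()) != set(range(self.k)):
            raise ValueError("folds must cover 0..k-1")
        counts = np.bincount(folds, minlength=self.k)
        if counts.max() - counts.min() > 1:
            raise ValueError("fold sizes must differ by at most 1")


def plan_cv(subject_ids: Sequence[str], k: int = 10, seed: int = 0) -> CVPlan:
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > len(subject_ids):
        raise ValueError(f"k={k} exceeds number of subjects ({len(subject_ids)})")
    ids = list(subject_ids)
    if len(set(ids)) != len(ids):
        raise ValueError("subject ids must be unique")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(ids))
    assignment = {ids[idx]: int(i % k) for i, idx in enumerate(order)}
    plan = CVPlan(k=k, assignment=assignment, seed=seed)
    plan.validate()
    return plan


class OracleModel:
    """Truth-returning stand-in for a trained model (testing the harness)."""

    def fit(self, samples, tc=None) -> "OracleModel":
        return self

    def predict(self, sample) -> LabelMask:
        return sample.labels


def _predict_sample(model, sample) -> LabelMask:
    """Dispatch to an OracleModel-style ``predict(sample)`` or a network
    ``predict(image)``."""
    if isinstance(model, OracleModel):
        return model.predict(sample)
    from .model import predict as net_predict

    return net_predict(model, sample.image)[1]


def run_cv(
    samples: Sequence,
    k: int,
    model_factory: Callable[[], object],
    tc=None,
    classes: Sequence[int] = TISSUE_CODES,
    with_assd: bool = True,
    seed: int = 0,
) -> tuple[SegMetricsReport, list[SegMetricsReport], CVPlan]:
    """Subject-level k-fold cross-validation.

    ``model_factory()`` must return an object with ``fit(samples, tc)``
    returning a predictor usable by :func:`_predict_sample`. Returns the
    pooled report, one report per fold, and the fold plan.
    """
    ids = [s.subject_id for s in samples]
    plan = plan_cv(ids, k=k, seed=seed)
    by_id = {s.subject_id: s for s in samples}
    fold_reports: list[SegMetricsReport] = []
    pooled: dict[str, dict] = {}
    for fold in range(k):
        test_ids = plan.fold_subjects(fold)
        train_samples = [by_id[i] for i in ids if plan.assignment[i] != fold]
        model = model_factory().fit(train_samples, tc)
        per_image = {}
        for sid in test_ids:
            sample = by_id[sid]
            t0 = time.perf_counter()
            pred = _predict_sample(model, sample)
            elapsed = time.perf_counter() - t0
            per_image[sid] = per_class_metrics(sample.labels, pred, classes=classes, with_assd=with_assd)
            pooled[sid] = per_image[sid]
        rep = aggregate(per_image)
        rep.timing_s_per_slice.append(elapsed / max(1, sample.image.n_slices))
        fold_reports.append(rep)
    return aggregate(pooled), fold_reports, plan


def cross_domain_eval(
    model,
    samples: Sequence,
    classes: Sequence[int] = TISSUE_CODES,
    with_assd: bool = True,
) -> dict[str, SegMetricsReport | dict]:
    """Evaluate one model on every domain present in ``samples``.

    Returns per-domain reports plus per-class DSC deltas of each non-"A"
    domain against domain "A".
    """
    domains = sorted({s.domain for s in samples})
    if len(domains) < 2:
        raise ValueError("cross_domain_eval needs samples from at least two domains")
    reports: dict[str, SegMetricsReport] = {}
    for dom in domains:
        per_image = {}
        for s in samples:
            if s.domain != dom:
                continue
            pred = _predict_sample(model, s)
            per_image[s.subject_id] = per_class_metrics(s.labels, pred, classes=classes, with_assd=with_assd)
        reports[dom] = aggregate(per_image)
    base = domains[0]
    deltas: dict[str, dict[int, float]] = {}
    for dom in domains[1:]:
        deltas[dom] = {
            c: reports[dom].summary[c]["dsc"][0] - reports[base].summary[c]["dsc"][0]
            for c in classes
            if "dsc" in reports[dom].summary.get(c, {}) and "dsc" in reports[base].summary.get(c, {})
        }
    return {"reports": reports, "dsc_delta_vs_" + base: deltas}
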