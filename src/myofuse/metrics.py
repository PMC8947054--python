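"""Per-field and per-group fusion metrics.

Aggregates the mask-pipeline output into the quantities the fusion assay
reports: absolute MYH1E+ area per fluorophore class, the area relative to
the imaged field, myotube counts and mean/median object size, within-group
relative abundances of the three classes, and normalization of one
experimental group to a reference group (reference = 100%).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .masks import ClassMasks, MyotubeRecord

__all__ = [
    "ClassStats",
    "FusionMetrics",
    "NormalizedMetrics",
    "fusion_metrics",
    "subpopulation_summary",
    "normalize_to_reference",
    "metrics_table",
]

CLASSES = ("MT_GFP", "MT_RFP", "MT_DUAL")


@dataclass
class ClassStats:
    absolute_area_um2: float = 0.0
    relative_area: float = 0.0  # fraction of imaged field area
    myotube_count: int = 0
    count_per_mm2: float = 0.0
    mean_myotube_size_um2: float | None = None
    median_myotube_size_um2: float | None = None


@dataclass
class FusionMetrics:
    group_label: str
    field_area_um2: float
    per_class: dict[str, ClassStats]
    overall: ClassStats
    unclassified_area_um2: float = 0.0
    relative_abundance_area: dict[str, float] | None = None
    relative_abundance_count: dict[str, float] | None = None
    relative_abundance_size: dict[str, float] | None = None


@dataclass
class NormalizedMetrics:
    """Group metrics as a percentage of a reference group (reference = 100)."""

    group_label: str
    reference_label: str
    area_pct_of_reference: float
    count_pct_of_reference: float
    size_pct_of_reference: float


def _class_stats(records, field_area_um2, field_area_mm2):
    areas = [r.area_um2 for r in records]
    n = len(records)
    return ClassStats(
        absolute_area_um2=float(sum(areas)),
        relative_area=float(sum(areas)) / field_area_um2,
        myotube_count=n,
        count_per_mm2=n / field_area_mm2,
        mean_myotube_size_um2=float(np.mean(areas)) if n else None,
        median_myotube_size_um2=float(np.median(areas)) if n else None,
    )


def fusion_metrics(
    records: list[MyotubeRecord],
    class_masks: ClassMasks | None,
    field_shape: tuple[int, int],
    pixel_size: float,
    group_label: str = "",
) -> FusionMetrics:
    """Aggregate myotube records (and, if given, pixel masks) into metrics.

    Per-class pixel areas come from ``class_masks`` when provided (the
    pixel-level classification); counts and sizes always come from the
    object records. Relative area uses the imaged field area as
    denominator. With zero myotubes the sizes are absent (None), never 0.
    """
    n_px = int(field_shape[0]) * int(field_shape[1])
    if n_px == 0 or pixel_size <= 0:
        raise ValueError("field must have positive size and pixel_size")
    field_area_um2 = n_px * pixel_size**2
    field_area_mm2 = field_area_um2 / 1e6

    per_class: dict[str, ClassStats] = {}
    for cls in CLASSES:
        cls_records = [r for r in records if r.fusion_class == cls]
        stats = _class_stats(cls_records, field_area_um2, field_area_mm2)
        if class_masks is not None:
            # pixel-level class area supersedes the object-majority estimate
            area_um2 = class_masks.area(cls.lower()) * pixel_size**2
            stats.absolute_area_um2 = area_um2
            stats.relative_area = area_um2 / field_area_um2
        per_class[cls] = stats

    overall = _class_stats(records, field_area_um2, field_area_mm2)
    unclassified_area_um2 = 0.0
    if class_masks is not None:
        overall.absolute_area_um2 = int(class_masks.myh_total.sum()) * pixel_size**2
        overall.relative_area = overall.absolute_area_um2 / field_area_um2
        unclassified_area_um2 = int(class_masks.unclassified.sum()) * pixel_size**2

    metrics = FusionMetrics(
        group_label=group_label,
        field_area_um2=field_area_um2,
        per_class=per_class,
        overall=overall,
        unclassified_area_um2=unclassified_area_um2,
    )
    subpopulation_summary(metrics)
    return metrics


def _shares(values: dict[str, float | None]) -> dict[str, float] | None:
    clean = {k: (v if v is not None else 0.0) for k, v in values.items()}
    total = sum(clean.values())
    if total <= 0:
        return None
    return {k: v / total for k, v in clean.items()}


def subpopulation_summary(metrics: FusionMetrics) -> FusionMetrics:
    """Fill in each class's share of the within-group total for area,
    count and mean size; each triple sums to 1 when the total is nonzero,
    and is None when there is nothing to share."""
    metrics.relative_abundance_area = _shares(
        {c: metrics.per_class[c].absolute_area_um2 for c in CLASSES}
    )
    metrics.relative_abundance_count = _shares(
        {c: float(metrics.per_class[c].myotube_count) for c in CLASSES}
    )
    metrics.relative_abundance_size = _shares(
        {c: metrics.per_class[c].mean_myotube_size_um2 for c in CLASSES}
    )
    return metrics


def normalize_to_reference(group: FusionMetrics, reference: FusionMetrics) -> NormalizedMetrics:
    """Express a group's total area, count and mean size as percent of a
    reference group (the reference itself maps to exactly 100 on each axis)."""
    axes = {
        "area": (group.overall.absolute_area_um2, reference.overall.absolute_area_um2),
        "count": (float(group.overall.myotube_count), float(reference.overall.myotube_count)),
        "size": (
            group.overall.mean_myotube_size_um2,
            reference.overall.mean_myotube_size_um2,
        ),
    }
    pct = {}
    for axis, (g, ref) in axes.items():
        if ref is None or ref == 0:
            raise ValueError(f"reference group has zero {axis}; cannot normalize")
        if g is None:
            raise ValueError(f"group has undefined {axis} (no myotubes)")
        pct[axis] = 100.0 * g / ref
    return NormalizedMetrics(
        group_label=group.group_label,
        reference_label=reference.group_label,
        area_pct_of_reference=pct["area"],
        count_pct_of_reference=pct["count"],
        size_pct_of_reference=pct["size"],
    )


def metrics_table(all_metrics: list[FusionMetrics]) -> pd.DataFrame:
    """Tidy table: one row per field × class (plus an OVERALL row each)."""
    rows = []
    for m in all_metrics:
        entries = dict(m.per_class)
        entries["OVERALL"] = m.overall
        for cls, s in entries.items():
            rows.append(
                {
                    "group_label": m.group_label,
                    "fusion_class": cls,
                    "absolute_area_um2": s.absolute_area_um2,
                    "relative_area": s.relative_area,
                    "myotube_count": s.myotube_count,
                    "count_per_mm2": s.count_per_mm2,
                    "mean_myotube_size_um2": s.mean_myotube_size_um2,
                    "median_myotube_size_um2": s.median_myotube_size_um2,
                    "abundance_area": (m.relative_abundance_area or {}).get(cls, math.nan),
                    "abundance_count": (m.relative_abundance_count or {}).get(cls, math.nan),
                    "abundance_size": (m.relative_abundance_size or {}).get(cls, math.nan),
                }
            )
    return pd.DataFrame(rows)
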