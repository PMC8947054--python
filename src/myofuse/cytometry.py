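"""Cell morphology and proliferation kinetics.

Morphology: area and aspect ratio (major/minor axis of the ellipse with the
same second central moments as the cell mask — the fitted-ellipse AR
convention of standard image-analysis tools).

Proliferation: from a passage series of (day, seeded, harvested) counts,
population doublings PD = log2(harvested/seeded) per passage, cumulative PD
as their running sum, and population doubling time
PDT = Δt · ln 2 / ln(harvested/seeded), so PD × PDT = Δt exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from skimage.measure import regionprops

__all__ = [
    "CellShape",
    "PassageSeries",
    "cell_shape",
    "cumulative_population_doublings",
    "population_doubling_time",
]


@dataclass(frozen=True)
class CellShape:
    area_um2: float
    aspect_ratio: float  # major/minor, >= 1


@dataclass(frozen=True)
class PassageSeries:
    """Ordered passages: day since start, cells seeded, cells harvested."""

    days: tuple[float, ...]
    seeded: tuple[float, ...]
    harvested: tuple[float, ...]

    def __post_init__(self):
        if not (len(self.days) == len(self.seeded) == len(self.harvested)):
            raise ValueError("days, seeded, harvested must have equal length")
        if any(d1 <= d0 for d0, d1 in zip(self.days, self.days[1:])):
            raise ValueError("days must be strictly increasing")
        if any(x <= 0 for x in self.seeded) or any(x <= 0 for x in self.harvested):
            raise ValueError("counts must be > 0")

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "PassageSeries":
        return cls(
            days=tuple(float(x) for x in df["day"]),
            seeded=tuple(float(x) for x in df["seeded"]),
            harvested=tuple(float(x) for x in df["harvested"]),
        )

    @property
    def intervals(self) -> tuple[float, ...]:
        """Days in culture per passage: day[0] from 0, then successive diffs."""
        prev = (0.0,) + self.days[:-1]
        return tuple(d - p for d, p in zip(self.days, prev))


def cell_shape(object_mask: np.ndarray, pixel_size: float, method: str = "ellipse") -> CellShape:
    """Area and aspect ratio of a single-cell binary mask.

    ``method='ellipse'`` (default) uses the moments-equivalent ellipse;
    ``'bbox'`` uses the axis-aligned bounding box (long/short side).
    """
    mask = np.asarray(object_mask, dtype=bool)
    n = int(mask.sum())
    if n < 5:
        raise ValueError("mask too small for shape moments (need >= 5 pixels)")
    prop = regionprops(mask.astype(np.uint8))[0]
    if method == "ellipse":
        minor = prop.axis_minor_length
        if minor == 0:
            raise ValueError("degenerate mask: zero minor axis")
        ar = prop.axis_major_length / minor
    elif method == "bbox":
        r0, c0, r1, c1 = prop.bbox
        h, w = r1 - r0, c1 - c0
        ar = max(h, w) / min(h, w)
    else:
        raise ValueError(f"unknown method {method!r}")
    return CellShape(area_um2=n * pixel_size**2, aspect_ratio=max(ar, 1.0))


def cumulative_population_doublings(series: PassageSeries) -> pd.DataFrame:
    """Per-passage PD = log2(harvested/seeded) and its running sum (cumPD)."""
    pd_per_passage = [math.log2(h / s) for s, h in zip(series.seeded, series.harvested)]
    return pd.DataFrame(
        {
            "day": series.days,
            "pd": pd_per_passage,
            "cum_pd": np.cumsum(pd_per_passage),
        }
    )


def population_doubling_time(series: PassageSeries) -> pd.DataFrame:
    """Per-passage PDT = Δt · ln2 / ln(harvested/seeded), in days.

    A passage that did not grow (harvested <= seeded) has no finite
    doubling time; its PDT is reported as NaN and flagged, and the mean is
    taken over the finite passages only.
    """
    rows = []
    for dt, s, h in zip(series.intervals, series.seeded, series.harvested):
        if h > s:
            pdt = dt * math.log(2) / math.log(h / s)
            flagged = False
        else:
            pdt = math.nan
            flagged = True
        rows.append({"interval_days": dt, "pdt_days": pdt, "no_growth": flagged})
    out = pd.DataFrame(rows)
    out["day"] = series.days
    out.attrs["mean_pdt_days"] = float(out["pdt_days"].mean())
    return out
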