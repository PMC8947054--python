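"""Mask-level image pipeline for myotube fusion classification.

The classification assay labels two myoblast populations with GFP and RFP,
lets them differentiate, and asks of every MYH1E+ (myosin heavy chain
positive, i.e. fused) pixel whether it is green-only, red-only, or both.
Everything here operates on 8-bit grayscale channels and boolean masks:

1. each fluorescence channel is linearly rescaled to 8-bit,
2. denoised with a disc-shaped median filter,
3. thresholded to a binary mask (fixed value or Otsu),
4. combined by mask algebra: dual = GFP ∧ RFP ∧ MYH1E, and the
   single-color classes are the composites minus the dual overlap,
5. connected components of a mask become myotube records.

Masks are plain 2-D boolean numpy arrays throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.measure import label as cc_label, regionprops

__all__ = [
    "ClassMasks",
    "MyotubeRecord",
    "LabelingResult",
    "to_grayscale8",
    "denoise_median",
    "binarize",
    "mask_and",
    "mask_subtract",
    "classify_fusion_pixels",
    "label_myotubes",
    "quantify_field",
]


@dataclass(frozen=True)
class ClassMasks:
    """Disjoint per-class pixel masks inside the MYH1E+ area.

    ``mt_gfp``, ``mt_rfp`` and ``mt_dual`` are pairwise disjoint and each is
    a subset of ``myh_total``; MYH1E+ pixels in none of the three are
    unclassified (myosin signal with neither fluorophore above threshold).
    """

    mt_gfp: np.ndarray
    mt_rfp: np.ndarray
    mt_dual: np.ndarray
    myh_total: np.ndarray

    @property
    def unclassified(self) -> np.ndarray:
        return self.myh_total & ~(self.mt_gfp | self.mt_rfp | self.mt_dual)

    def area(self, cls: str) -> int:
        return int(getattr(self, cls).sum())


@dataclass
class MyotubeRecord:
    """One connected MYH1E+ object."""

    object_id: int
    fusion_class: str  # MT_GFP | MT_RFP | MT_DUAL | UNCLASSIFIED
    area_px: int
    area_um2: float
    centroid: tuple[float, float]
    bbox: tuple[int, int, int, int]


@dataclass
class LabelingResult:
    records: list[MyotubeRecord]
    n_discarded: int  # components below min_area


def _check_shape(*arrays: np.ndarray) -> None:
    shapes = {a.shape for a in arrays}
    if len(shapes) != 1:
        raise ValueError(f"shape mismatch among masks: {sorted(shapes)}")


def to_grayscale8(channel: np.ndarray) -> np.ndarray:
    """Linearly rescale an intensity image to uint8 [0, 255].

    A constant image maps to all zeros (the min–max range is degenerate, so
    there is nothing to stretch).
    """
    channel = np.asarray(channel, dtype=np.float64)
    if channel.size == 0:
        raise ValueError("empty image")
    if not np.all(np.isfinite(channel)) or channel.min() < 0:
        raise ValueError("intensities must be finite and non-negative")
    lo, hi = channel.min(), channel.max()
    if hi == lo:
        return np.zeros(channel.shape, dtype=np.uint8)
    scaled = (channel - lo) * (255.0 / (hi - lo))
    return np.rint(scaled).astype(np.uint8)


def _disc_footprint(radius: int) -> np.ndarray:
    yy, xx = np.mgrid[-radius : radius + 1, -radius : radius + 1]
    return (yy * yy + xx * xx) <= radius * radius


def denoise_median(channel: np.ndarray, radius: int = 2, square: bool = False) -> np.ndarray:
    """Median filter with a disc neighborhood of the given pixel radius.

    ``radius=0`` is the identity. ``square=True`` switches to a
    (2r+1)×(2r+1) square footprint, matching tools whose "r-pixel median"
    means a square kernel.
    """
    if radius < 0:
        raise ValueError("radius must be >= 0")
    channel = np.asarray(channel)
    if radius == 0:
        return channel.copy()
    if square:
        footprint = np.ones((2 * radius + 1, 2 * radius + 1), dtype=bool)
    else:
        footprint = _disc_footprint(radius)
    return ndimage.median_filter(channel, footprint=footprint, mode="reflect")


def binarize(
    channel: np.ndarray, method: str = "otsu", threshold: float | None = None
) -> tuple[np.ndarray, float]:
    """Threshold an 8-bit image; returns ``(mask, threshold_used)``.

    The comparison is inclusive: a pixel is foreground iff its intensity is
    ``>= threshold``. With ``method='otsu'`` the threshold is chosen by
    Otsu's criterion; a constant image yields an all-false mask.
    """
    channel = np.asarray(channel)
    if method == "fixed":
        if threshold is None or not (0 <= threshold <= 255):
            raise ValueError("fixed method requires a threshold in [0, 255]")
        t = float(threshold)
    elif method == "otsu":
        if channel.min() == channel.max():
            return np.zeros(channel.shape, dtype=bool), float(channel.max()) + 1.0
        # skimage's otsu is exclusive-upper (fg > t); shift to our >= rule.
        t = float(threshold_otsu(channel)) + 1.0
    else:
        raise ValueError(f"unknown method {method!r}")
    return channel >= t, t


def mask_and(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Pixelwise conjunction (the image-calculator AND of two binary masks)."""
    _check_shape(a, b)
    return np.logical_and(a, b)


def mask_subtract(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Pixelwise a ∧ ¬b: remove b's pixels from a."""
    _check_shape(a, b)
    return np.logical_and(a, np.logical_not(b))


def classify_fusion_pixels(
    gfp: np.ndarray, rfp: np.ndarray, myh: np.ndarray
) -> ClassMasks:
    """Partition the MYH1E+ area by fluorophore content.

    ``mt_dual = gfp ∧ rfp ∧ myh``; the single-color masks are the
    channel∧MYH composites with the dual overlap subtracted, so the three
    class masks are disjoint by construction and every class pixel is
    MYH1E+.
    """
    _check_shape(gfp, rfp, myh)
    gfp_myh = mask_and(gfp, myh)
    rfp_myh = mask_and(rfp, myh)
    dual = mask_and(gfp_myh, rfp)
    return ClassMasks(
        mt_gfp=mask_subtract(gfp_myh, dual),
        mt_rfp=mask_subtract(rfp_myh, dual),
        mt_dual=dual,
        myh_total=np.asarray(myh, dtype=bool),
    )


def _majority_class(component: np.ndarray, masks: ClassMasks) -> str:
    """Assign a component the class holding the most of its pixels."""
    counts = {
        "MT_GFP": int((component & masks.mt_gfp).sum()),
        "MT_RFP": int((component & masks.mt_rfp).sum()),
        "MT_DUAL": int((component & masks.mt_dual).sum()),
    }
    best = max(counts, key=lambda k: counts[k])
    if counts[best] == 0:
        return "UNCLASSIFIED"
    return best


def label_myotubes(
    mask: np.ndarray,
    min_area: int = 50,
    connectivity: int = 8,
    pixel_size: float = 1.0,
    class_masks: ClassMasks | None = None,
    exclude_border: bool = False,
) -> LabelingResult:
    """Connected components of a binary mask as myotube records.

    ``connectivity`` is 4 (edge-adjacent) or 8 (edge- or corner-adjacent,
    the default: diagonally touching myotube branches belong together).
    Components smaller than ``min_area`` pixels are discarded and counted.
    When ``class_masks`` is given each record carries the fusion class
    holding the majority of its pixels, else UNCLASSIFIED.
    """
    if min_area < 1:
        raise ValueError("min_area must be >= 1")
    if connectivity not in (4, 8):
        raise ValueError("connectivity must be 4 or 8")
    mask = np.asarray(mask, dtype=bool)
    labeled = cc_label(mask, connectivity=1 if connectivity == 4 else 2)
    records: list[MyotubeRecord] = []
    n_discarded = 0
    next_id = 1
    for prop in regionprops(labeled):
        if prop.area < min_area:
            n_discarded += 1
            continue
        if exclude_border:
            r0, c0, r1, c1 = prop.bbox
            if r0 == 0 or c0 == 0 or r1 == mask.shape[0] or c1 == mask.shape[1]:
                continue
        component = labeled == prop.label
        cls = (
            _majority_class(component, class_masks)
            if class_masks is not None
            else "UNCLASSIFIED"
        )
        records.append(
            MyotubeRecord(
                object_id=next_id,
                fusion_class=cls,
                area_px=int(prop.area),
                area_um2=float(prop.area) * pixel_size**2,
                centroid=tuple(map(float, prop.centroid)),
                bbox=tuple(map(int, prop.bbox)),
            )
        )
        next_id += 1
    return LabelingResult(records=records, n_discarded=n_discarded)


@dataclass
class QuantifyConfig:
    """Per-field pipeline settings.

    ``thresholds`` maps channel name to a fixed 8-bit threshold; channels
    absent from the map are thresholded by Otsu's method.
    """

    median_radius: int = 2
    median_square: bool = False
    thresholds: dict[str, float] = field(default_factory=dict)
    min_area: int = 50
    connectivity: int = 8
    exclude_border: bool = False


@dataclass
class FieldQuantification:
    class_masks: ClassMasks
    records: list[MyotubeRecord]
    n_discarded: int
    thresholds_used: dict[str, float]
    pixel_size: float
    field_shape: tuple[int, int]


def quantify_field(
    channels: dict[str, np.ndarray],
    pixel_size: float,
    config: QuantifyConfig | None = None,
) -> FieldQuantification:
    """Run the full per-field pipeline on raw intensity channels.

    Requires GFP, RFP and MYH1E channels; each is 8-bit rescaled, median
    filtered, thresholded, then combined by :func:`classify_fusion_pixels`,
    and the MYH1E+ mask is segmented into myotube records.
    """
    if config is None:
        config = QuantifyConfig()
    needed = {"GFP", "RFP", "MYH1E"}
    missing = needed - channels.keys()
    if missing:
        raise ValueError(f"missing channels: {sorted(missing)}")
    masks: dict[str, np.ndarray] = {}
    thresholds_used: dict[str, float] = {}
    for name in ("GFP", "RFP", "MYH1E"):
        img = denoise_median(
            to_grayscale8(channels[name]), config.median_radius, config.median_square
        )
        if name in config.thresholds:
            m, t = binarize(img, "fixed", config.thresholds[name])
        else:
            m, t = binarize(img, "otsu")
        masks[name] = m
        thresholds_used[name] = t
    class_masks = classify_fusion_pixels(masks["GFP"], masks["RFP"], masks["MYH1E"])
    labeling = label_myotubes(
        class_masks.myh_total,
        min_area=config.min_area,
        connectivity=config.connectivity,
        pixel_size=pixel_size,
        class_masks=class_masks,
        exclude_border=config.exclude_border,
    )
    return FieldQuantification(
        class_masks=class_masks,
        records=labeling.records,
        n_discarded=labeling.n_discarded,
        thresholds_used=thresholds_used,
        pixel_size=pixel_size,
        field_shape=tuple(channels["MYH1E"].shape),
    )
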