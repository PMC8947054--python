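"""Synthetic multi-channel fluorescence fields with known myotube composition.

The generator emulates the co-culture fusion assay: two myoblast
populations, one expressing GFP and one RFP, differentiate into myotubes
that contain green-only, red-only, or both lineages. A simulated field
consists of

* elongated myotubes (rotated capsules) that are MYH1E+ and fluoresce in
  GFP and/or RFP according to their class — dual-lineage myotubes carry
  both fluorophores at elevated intensity (fluorescence accumulates when
  two labeled populations fuse),
* small elliptical mononuclear myoblasts that never exceed background in
  the fluorescence channels (they only matter as MYH1E− distractors), and
* a DAPI channel with at least two nuclei per myotube and one per myoblast.

Every field comes with pixel-exact ground truth (label map + object table)
taken before noise is added, so the downstream mask pipeline can be
validated against known class areas.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
from scipy.ndimage import binary_dilation

__all__ = [
    "SimulationConfig",
    "FusionImageSet",
    "GroundTruth",
    "PlacementError",
    "simulate_field",
    "write_field",
    "read_field",
]

MYOTUBE_CLASSES = ("MT_GFP", "MT_RFP", "MT_DUAL")


class PlacementError(RuntimeError):
    """Raised when an object of the named class cannot be placed within the
    overlap budget after the retry limit."""

    def __init__(self, object_class: str, n_placed: int):
        self.object_class = object_class
        super().__init__(
            f"could not place a {object_class} object after retries "
            f"({n_placed} already placed); reduce counts or sizes"
        )


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one simulated field.

    Lengths and areas are in micrometres; intensities are arbitrary units
    on the scale of a 16-bit camera. ``dual_intensity_gain`` multiplies the
    GFP and RFP foreground inside dual-lineage myotubes (≥ 1; fusion of two
    labeled populations accumulates fluorophore).
    """

    field_shape: tuple[int, int] = (1024, 1024)
    pixel_size: float = 0.65  # µm per pixel
    n_myotubes_per_class: dict[str, int] = dc_field(
        default_factory=lambda: {"MT_GFP": 7, "MT_RFP": 5, "MT_DUAL": 5}
    )
    myotube_length_range: tuple[float, float] = (100.0, 300.0)  # µm
    myotube_width_range: tuple[float, float] = (12.0, 25.0)  # µm
    n_myoblasts: int = 120
    myoblast_area_mean: float = 400.0  # µm²
    myoblast_aspect_ratio_mean: float = 2.0
    fluor_intensity: dict[str, float] = dc_field(
        default_factory=lambda: {"GFP": 9000.0, "RFP": 9000.0, "MYH1E": 11000.0, "DAPI": 13000.0}
    )
    dual_intensity_gain: float = 1.8
    background_mean: float = 1500.0
    noise_sd: float = 400.0
    noise_model: str = "gaussian"  # or "poisson"
    max_overlap_px: int = 0
    placement_margin_px: int = 3  # min gap between objects, px
    max_retries: int = 300
    seed: int = 0

    def __post_init__(self):
        if any(n < 0 for n in self.n_myotubes_per_class.values()) or self.n_myoblasts < 0:
            raise ValueError("object counts must be >= 0")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be > 0")
        for rng_ in (self.myotube_length_range, self.myotube_width_range):
            if rng_[0] <= 0 or rng_[1] < rng_[0]:
                raise ValueError("length/width ranges must be positive and ordered")
        if self.dual_intensity_gain < 1:
            raise ValueError("dual_intensity_gain must be >= 1")
        if self.noise_sd < 0 or self.background_mean < 0:
            raise ValueError("background_mean and noise_sd must be >= 0")
        if self.noise_model not in ("gaussian", "poisson"):
            raise ValueError("noise_model must be 'gaussian' or 'poisson'")


@dataclass
class FusionImageSet:
    """One experiment field: named intensity channels plus calibration."""

    channels: dict[str, np.ndarray]
    pixel_size: float
    group_label: str = ""

    def __post_init__(self):
        shapes = {c.shape for c in self.channels.values()}
        if len(shapes) > 1:
            raise ValueError("all channels must share one shape")
        for name, c in self.channels.items():
            if not np.all(np.isfinite(c)) or c.min() < 0:
                raise ValueError(f"channel {name} has non-finite or negative intensities")


@dataclass
class GroundTruth:
    """Pixel-exact simulator truth: label map plus per-object table.

    ``object_table`` columns: object_id, object_class, true_area_px,
    centroid_row, centroid_col. ``true_area_px`` of id k equals the number
    of pixels labeled k in ``label_map``.
    """

    label_map: np.ndarray
    object_table: pd.DataFrame

    def class_area_px(self, object_class: str) -> int:
        t = self.object_table
        return int(t.loc[t.object_class == object_class, "true_area_px"].sum())


def _capsule_pixels(shape, center, angle, length_px, width_px):
    """Pixel coordinates of a rotated capsule (segment dilated by width/2)."""
    half = max(length_px / 2 - width_px / 2, 0.0)
    d = np.array([np.cos(angle), np.sin(angle)])
    p0 = np.asarray(center) - half * d
    p1 = np.asarray(center) + half * d
    r = width_px / 2
    lo = np.floor(np.minimum(p0, p1) - r - 1).astype(int)
    hi = np.ceil(np.maximum(p0, p1) + r + 1).astype(int)
    lo = np.maximum(lo, 0)
    hi = np.minimum(hi, np.asarray(shape) - 1)
    if np.any(hi < lo):
        return np.empty(0, int), np.empty(0, int)
    rows, cols = np.mgrid[lo[0] : hi[0] + 1, lo[1] : hi[1] + 1]
    pts = np.stack([rows, cols], axis=-1).astype(float)
    seg = p1 - p0
    seg_len2 = float(seg @ seg)
    if seg_len2 == 0:
        dist = np.linalg.norm(pts - p0, axis=-1)
    else:
        t = np.clip(((pts - p0) @ seg) / seg_len2, 0.0, 1.0)
        proj = p0 + t[..., None] * seg
        dist = np.linalg.norm(pts - proj, axis=-1)
    inside = dist <= r
    return rows[inside], cols[inside]


def _ellipse_pixels(shape, center, angle, semi_major, semi_minor):
    a, b = semi_major, semi_minor
    lo = np.floor(np.asarray(center) - a - 1).astype(int)
    hi = np.ceil(np.asarray(center) + a + 1).astype(int)
    lo = np.maximum(lo, 0)
    hi = np.minimum(hi, np.asarray(shape) - 1)
    if np.any(hi < lo):
        return np.empty(0, int), np.empty(0, int)
    rows, cols = np.mgrid[lo[0] : hi[0] + 1, lo[1] : hi[1] + 1]
    dr = rows - center[0]
    dc = cols - center[1]
    u = dr * np.cos(angle) + dc * np.sin(angle)
    v = -dr * np.sin(angle) + dc * np.cos(angle)
    inside = (u / a) ** 2 + (v / b) ** 2 <= 1.0
    return rows[inside], cols[inside]


def _try_place(blocked, rr, cc, budget):
    if rr.size == 0:
        return False
    return int(blocked[rr, cc].sum()) <= budget


def _block_halo(blocked, rr, cc, margin):
    """Mark object pixels plus a dilated halo so later objects keep a gap
    (touching objects would merge under connected-component labeling)."""
    blocked[rr, cc] = True
    if margin <= 0:
        return
    r0, r1 = rr.min(), rr.max()
    c0, c1 = cc.min(), cc.max()
    r0m = max(r0 - margin, 0)
    c0m = max(c0 - margin, 0)
    r1m = min(r1 + margin, blocked.shape[0] - 1)
    c1m = min(c1 + margin, blocked.shape[1] - 1)
    local = np.zeros((r1m - r0m + 1, c1m - c0m + 1), dtype=bool)
    local[rr - r0m, cc - c0m] = True
    yy, xx = np.mgrid[-margin : margin + 1, -margin : margin + 1]
    local = binary_dilation(local, structure=(yy * yy + xx * xx) <= margin * margin)
    blocked[r0m : r1m + 1, c0m : c1m + 1] |= local


def simulate_field(config: SimulationConfig, group_label: str = "") -> tuple[FusionImageSet, GroundTruth]:
    """Render one field; identical config (incl. seed) gives bit-identical output.

    Myotubes are rotated capsules with MYH1E foreground for every class,
    GFP foreground for MT_GFP/MT_DUAL and RFP foreground for
    MT_RFP/MT_DUAL; the dual class gets both fluorophores scaled by
    ``dual_intensity_gain``. Ground truth reflects the rendered geometry
    before noise. Raises :class:`PlacementError` if an object cannot be
    placed within the overlap budget.
    """
    rng = np.random.default_rng(config.seed)
    shape = tuple(config.field_shape)
    px = config.pixel_size
    label_map = np.zeros(shape, dtype=np.int32)
    blocked = np.zeros(shape, dtype=bool)
    objects: list[dict] = []
    nuclei: list[tuple[float, float]] = []
    next_id = 1

    def place(object_class, sampler):
        nonlocal next_id
        for _ in range(config.max_retries):
            rr, cc, obj_nuclei = sampler()
            if _try_place(blocked, rr, cc, config.max_overlap_px):
                label_map[rr, cc] = next_id
                _block_halo(blocked, rr, cc, config.placement_margin_px)
                objects.append(
                    {
                        "object_id": next_id,
                        "object_class": object_class,
                        "centroid_row": float(rr.mean()),
                        "centroid_col": float(cc.mean()),
                    }
                )
                nuclei.extend(obj_nuclei)
                next_id += 1
                return
        raise PlacementError(object_class, len(objects))

    for cls in MYOTUBE_CLASSES:
        for _ in range(config.n_myotubes_per_class.get(cls, 0)):

            def sample_myotube():
                length = rng.uniform(*config.myotube_length_range) / px
                width = rng.uniform(*config.myotube_width_range) / px
                angle = rng.uniform(0, np.pi)
                center = rng.uniform([0, 0], shape)
                rr, cc = _capsule_pixels(shape, center, angle, length, width)
                # >= 2 nuclei spaced along the long axis
                n_nuc = max(2, int(length * px // 60))
                ts = np.linspace(-0.35, 0.35, n_nuc)
                d = np.array([np.cos(angle), np.sin(angle)])
                nuc = [tuple(center + t * length * d) for t in ts]
                return rr, cc, nuc

            place(cls, sample_myotube)

    for _ in range(config.n_myoblasts):

        def sample_myoblast():
            area_px = max(rng.gamma(9.0, config.myoblast_area_mean / 9.0) / px**2, 12.0)
            ar = max(rng.normal(config.myoblast_aspect_ratio_mean, 0.3), 1.0)
            b = np.sqrt(area_px / (np.pi * ar))
            a = ar * b
            angle = rng.uniform(0, np.pi)
            center = rng.uniform([0, 0], shape)
            rr, cc = _ellipse_pixels(shape, center, angle, a, b)
            return rr, cc, [tuple(center)]

        place("MYOBLAST", sample_myoblast)

    # object table from the final label map (areas are pixel-exact)
    if objects:
        table = pd.DataFrame(objects)
        ids, counts = np.unique(label_map[label_map > 0], return_counts=True)
        area_by_id = dict(zip(ids.tolist(), counts.tolist()))
        table["true_area_px"] = table["object_id"].map(area_by_id).fillna(0).astype(int)
        table = table[["object_id", "object_class", "true_area_px", "centroid_row", "centroid_col"]]
    else:
        table = pd.DataFrame(
            columns=["object_id", "object_class", "true_area_px", "centroid_row", "centroid_col"]
        )
    truth = GroundTruth(label_map=label_map, object_table=table)

    # render channels
    fg = config.fluor_intensity
    channels = {
        name: np.full(shape, config.background_mean, dtype=np.float64)
        for name in ("GFP", "RFP", "MYH1E", "DAPI")
    }
    for obj in objects:
        sel = label_map == obj["object_id"]
        cls = obj["object_class"]
        if cls == "MYOBLAST":
            continue
        channels["MYH1E"][sel] = fg["MYH1E"]
        gain = config.dual_intensity_gain if cls == "MT_DUAL" else 1.0
        if cls in ("MT_GFP", "MT_DUAL"):
            channels["GFP"][sel] = fg["GFP"] * gain
        if cls in ("MT_RFP", "MT_DUAL"):
            channels["RFP"][sel] = fg["RFP"] * gain
    nuc_radius = 4.0 / px  # ~4 µm nuclear radius
    for center in nuclei:
        rr, cc = _ellipse_pixels(shape, center, 0.0, nuc_radius, nuc_radius)
        channels["DAPI"][rr, cc] = fg["DAPI"]

    if config.noise_model == "gaussian":
        if config.noise_sd > 0:
            for name in channels:
                channels[name] = np.clip(
                    channels[name] + rng.normal(0.0, config.noise_sd, shape), 0.0, None
                )
    else:
        for name in channels:
            channels[name] = rng.poisson(channels[name]).astype(np.float64)

    images = FusionImageSet(channels=channels, pixel_size=px, group_label=group_label)
    return images, truth


def write_field(images: FusionImageSet, truth: GroundTruth, out_dir: str | Path) -> None:
    """Write one 16-bit TIFF per channel, a 32-bit label-map TIFF, and the
    ground-truth object table as CSV."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for name, channel in images.channels.items():
        tifffile.imwrite(out / f"{name}.tif", np.clip(channel, 0, 65535).astype(np.uint16))
    tifffile.imwrite(out / "label_map.tif", truth.label_map.astype(np.int32))
    truth.object_table.to_csv(out / "ground_truth.csv", index=False)
    meta = {"pixel_size": images.pixel_size, "group_label": images.group_label}
    pd.Series(meta).to_csv(out / "field_meta.csv", header=False)


def read_field(field_dir: str | Path) -> tuple[FusionImageSet, GroundTruth | None]:
    """Read a field written by :func:`write_field` (ground truth optional)."""
    d = Path(field_dir)
    channels = {
        p.stem: tifffile.imread(p).astype(np.float64)
        for p in sorted(d.glob("*.tif"))
        if p.stem != "label_map"
    }
    meta = pd.read_csv(d / "field_meta.csv", header=None, index_col=0)[1]
    images = FusionImageSet(
        channels=channels,
        pixel_size=float(meta["pixel_size"]),
        group_label=str(meta.get("group_label", "")),
    )
    truth = None
    if (d / "label_map.tif").exists() and (d / "ground_truth.csv").exists():
        truth = GroundTruth(
            label_map=tifffile.imread(d / "label_map.tif"),
            object_table=pd.read_csv(d / "ground_truth.csv"),
        )
    return images, truth


def config_with(config: SimulationConfig, **updates) -> SimulationConfig:
    """A copy of ``config`` with the given fields replaced."""
    return dataclasses.replace(config, **updates)
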