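"""Reading/writing pipeline artifacts: YAML config, per-field JSON, CSV."""

from __future__ import annotations

import json
import logging
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .masks import FieldQuantification, QuantifyConfig

log = logging.getLogger("myofuse")

__all__ = [
    "load_quantify_config",
    "read_channel_tiff",
    "field_to_json",
    "write_field_json",
    "read_field_json",
]


def load_quantify_config(path: str | Path) -> tuple[QuantifyConfig, float]:
    """Read pipeline settings from YAML; returns (config, pixel_size)."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    pixel_size = float(raw.pop("pixel_size", 1.0))
    known = {k: raw[k] for k in raw if k in QuantifyConfig.__dataclass_fields__}
    unknown = set(raw) - set(known)
    if unknown:
        log.warning("ignoring unknown config keys: %s", sorted(unknown))
    return QuantifyConfig(**known), pixel_size


def read_channel_tiff(path: str | Path) -> np.ndarray:
    img = tifffile.imread(path).astype(np.float64)
    if img.ndim != 2:
        raise ValueError(f"{path}: expected a single-channel 2D TIFF, got shape {img.shape}")
    return img


def field_to_json(fq: FieldQuantification, group_label: str = "") -> dict:
    px2 = fq.pixel_size**2
    return {
        "group_label": group_label,
        "field_shape": list(fq.field_shape),
        "pixel_size": fq.pixel_size,
        "thresholds_used": fq.thresholds_used,
        "n_discarded_components": fq.n_discarded,
        "class_areas_px": {
            cls: fq.class_masks.area(cls.lower()) for cls in ("MT_GFP", "MT_RFP", "MT_DUAL")
        }
        | {"UNCLASSIFIED": int(fq.class_masks.unclassified.sum()),
           "MYH_TOTAL": int(fq.class_masks.myh_total.sum())},
        "class_areas_um2": {
            cls: fq.class_masks.area(cls.lower()) * px2 for cls in ("MT_GFP", "MT_RFP", "MT_DUAL")
        },
        "records": [asdict(r) for r in fq.records],
    }


def write_field_json(fq: FieldQuantification, path: str | Path, group_label: str = "") -> None:
    Path(path).write_text(json.dumps(field_to_json(fq, group_label), indent=1))


def read_field_json(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())
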