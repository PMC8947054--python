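#!/usr/bin/env python
"""Aggregate per-field classification into fusion metrics per condition.

Builds the tidy per-field × class metrics table, within-group relative
abundances, and normalizes the hypoxia-like condition to the reference
(reference = 100%), writing results/fusion_metrics.csv and
results/normalized_to_reference.csv.
"""

from pathlib import Path

import pandas as pd

from myofuse.io import read_field_json
from myofuse.masks import MyotubeRecord
from myofuse.metrics import fusion_metrics, metrics_table, normalize_to_reference

ROOT = Path(__file__).resolve().parents[1]


def metrics_from_json(doc):
    records = [MyotubeRecord(**r) for r in doc["records"]]

    class StoredMasks:
        def area(self, cls):
            return doc["class_areas_px"][cls.upper()]

        @property
        def unclassified(self):
            import numpy as np

            return np.array([doc["class_areas_px"]["UNCLASSIFIED"]])

        @property
        def myh_total(self):
            import numpy as np

            return np.array([doc["class_areas_px"]["MYH_TOTAL"]])

    return fusion_metrics(
        records, StoredMasks(), tuple(doc["field_shape"]), doc["pixel_size"],
        group_label=doc["group_label"],
    )


def main():
    field_docs = [read_field_json(p) for p in sorted((ROOT / "results" / "fields").glob("*.json"))]
    all_metrics = [metrics_from_json(doc) for doc in field_docs]
    table = metrics_table(all_metrics)
    table.to_csv(ROOT / "results" / "fusion_metrics.csv", index=False)

    by_group = table[table.fusion_class == "OVERALL"].groupby("group_label")
    print("per-condition means over fields:")
    print(
        by_group[["absolute_area_um2", "myotube_count", "mean_myotube_size_um2"]]
        .mean()
        .round(1)
    )

    # pool each condition's fields and normalize hypoxia-like to reference
    pooled = {}
    for label in ("reference", "hypoxia_like"):
        recs = [r for m, d in zip(all_metrics, field_docs) if d["group_label"] == label
                for r in [MyotubeRecord(**x) for x in d["records"]]]
        shape = field_docs[0]["field_shape"]
        n = sum(d["group_label"] == label for d in field_docs)
        pooled[label] = fusion_metrics(
            recs, None, (shape[0] * n, shape[1]), field_docs[0]["pixel_size"], group_label=label
        )
    norm = normalize_to_reference(pooled["hypoxia_like"], pooled["reference"])
    pd.DataFrame([norm.__dict__]).to_csv(
        ROOT / "results" / "normalized_to_reference.csv", index=False
    )
    print(
        f"\nhypoxia-like vs reference: area {norm.area_pct_of_reference:.0f}%, "
        f"count {norm.count_pct_of_reference:.0f}%, size {norm.size_pct_of_reference:.0f}%"
    )


if __name__ == "__main__":
    main()
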