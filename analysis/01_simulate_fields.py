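#!/usr/bin/env python
"""Simulate a small panel of fusion-assay fields for two conditions.

Generates three synthetic fields per condition — a reference
("normoxia-like") condition and a fusion-suppressed ("hypoxia-like")
condition with 40% fewer, 30% smaller myotubes — and writes each field's
channel TIFFs, label map and ground-truth table under scratch/fields/.
The per-field ground-truth class areas are also tabulated to
results/simulated_ground_truth.csv so later steps can be checked.

Fields here are 512×512 px (a quarter of the validation-study size) to
keep this walkthrough fast; the studies in myofuse.experiments use the
full 1024×1024 conditions.
"""

import dataclasses
from pathlib import Path

import pandas as pd

from myofuse.experiments import hypoxia_like_config, reference_config
from myofuse.simulate import simulate_field, write_field

ROOT = Path(__file__).resolve().parents[1]
N_FIELDS = 3


def shrink(cfg):
    # quarter-area field with proportionally fewer objects
    return dataclasses.replace(
        cfg,
        field_shape=(512, 512),
        n_myotubes_per_class={k: max(1, v // 2) for k, v in cfg.n_myotubes_per_class.items()},
        n_myoblasts=cfg.n_myoblasts // 4,
    )


def main():
    out_root = ROOT / "scratch" / "fields"
    rows = []
    for group, make in (("reference", reference_config), ("hypoxia_like", hypoxia_like_config)):
        for i in range(N_FIELDS):
            cfg = shrink(make(seed=100 + i))
            images, truth = simulate_field(cfg, group_label=group)
            field_dir = out_root / f"{group}_{i}"
            write_field(images, truth, field_dir)
            for cls, sub in truth.object_table.groupby("object_class"):
                rows.append(
                    {
                        "group": group,
                        "field": i,
                        "object_class": cls,
                        "n_objects": len(sub),
                        "true_area_px": int(sub.true_area_px.sum()),
                    }
                )
            print(f"{group} field {i}: {len(truth.object_table)} objects -> {field_dir}")
    table = pd.DataFrame(rows)
    out_csv = ROOT / "results" / "simulated_ground_truth.csv"
    out_csv.parent.mkdir(exist_ok=True)
    table.to_csv(out_csv, index=False)
    myotubes = table[table.object_class != "MYOBLAST"]
    print(
        f"\nwrote {out_csv}; mean planted myotube area per field: "
        f"{myotubes.groupby('group').true_area_px.sum().div(N_FIELDS).to_dict()}"
    )


if __name__ == "__main__":
    main()
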