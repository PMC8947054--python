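"""End-to-end validation studies over the synthetic assay.

Each study simulates fields under stated conditions, runs the full mask
pipeline on the rendered channels, and compares the pipeline's estimates to
the simulator's ground truth. These are the package's own benchmarks; the
analysis drivers, the test suite and the acceptance script all call them.

Conditions (fixed; they define the benchmark, not knobs to tune):

* recovery study — fields planted with class-area fractions of roughly
  0.4 / 0.3 / 0.3 (GFP / RFP / dual) of the myotube area, realized by
  7/5/5 myotubes per class drawn from one size distribution (the uneven
  ratio intentionally breaks symmetry between green-only and the others);
* direction-of-effect study — a "hypoxia-like" condition with 40% fewer
  and 30% smaller myotubes than reference, mirroring the qualitative
  finding that low oxygen suppresses both fusion extent and myotube size.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .masks import QuantifyConfig, quantify_field
from .metrics import fusion_metrics
from .simulate import MYOTUBE_CLASSES, SimulationConfig, simulate_field
from .stats import compare_groups

__all__ = [
    "reference_config",
    "hypoxia_like_config",
    "RecoveryResult",
    "recovery_study",
    "direction_of_effect_study",
    "type_i_error_study",
]


def reference_config(seed: int = 0, noise_sd: float = 400.0) -> SimulationConfig:
    """Reference ("normoxia-like") condition: 7/5/5 myotubes per class
    (expected class-area split 0.41/0.29/0.29) in a 1024² field."""
    return SimulationConfig(
        n_myotubes_per_class={"MT_GFP": 7, "MT_RFP": 5, "MT_DUAL": 5},
        noise_sd=noise_sd,
        seed=seed,
    )


def hypoxia_like_config(seed: int = 0, noise_sd: float = 400.0) -> SimulationConfig:
    """40% fewer and 30% smaller (by area) myotubes than reference."""
    ref = reference_config(seed, noise_sd)
    s = np.sqrt(0.7)  # scale both axes so object area shrinks by 30%
    return dataclasses.replace(
        ref,
        n_myotubes_per_class={"MT_GFP": 4, "MT_RFP": 3, "MT_DUAL": 3},
        myotube_length_range=tuple(x * s for x in ref.myotube_length_range),
        myotube_width_range=tuple(x * s for x in ref.myotube_width_range),
    )


def _pipeline_config(noise_sd: float) -> QuantifyConfig:
    # denoising is pointless (and boundary-biased) on noise-free renders
    return QuantifyConfig(median_radius=0 if noise_sd == 0 else 2)


@dataclass
class RecoveryResult:
    """Per-field comparison of pipeline class areas vs ground truth."""

    table: pd.DataFrame  # field, class, true_area_px, est_area_px, rel_error
    count_matches: int
    n_fields: int

    @property
    def max_rel_error(self) -> float:
        return float(self.table.rel_error.abs().max())


def recovery_study(
    n_fields: int = 20, base_seed: int = 1000, noise_sd: float = 400.0
) -> RecoveryResult:
    """Simulate ``n_fields`` reference fields and measure how well the mask
    pipeline recovers each field's true per-class pixel areas and myotube
    count."""
    qc = _pipeline_config(noise_sd)
    rows = []
    count_matches = 0
    for i in range(n_fields):
        cfg = reference_config(seed=base_seed + i, noise_sd=noise_sd)
        images, truth = simulate_field(cfg)
        fq = quantify_field(images.channels, images.pixel_size, qc)
        true_count = int((truth.object_table.object_class != "MYOBLAST").sum())
        count_matches += len(fq.records) == true_count
        for cls in MYOTUBE_CLASSES:
            true_px = truth.class_area_px(cls)
            est_px = fq.class_masks.area(cls.lower())
            rows.append(
                {
                    "field": i,
                    "fusion_class": cls,
                    "true_area_px": true_px,
                    "est_area_px": est_px,
                    "rel_error": (est_px - true_px) / true_px if true_px else np.nan,
                }
            )
    return RecoveryResult(table=pd.DataFrame(rows), count_matches=count_matches, n_fields=n_fields)


def direction_of_effect_study(
    n_pairs: int = 20, base_seed: int = 5000, noise_sd: float = 400.0
) -> pd.DataFrame:
    """Paired reference vs hypoxia-like fields at matched seeds.

    Returns one row per seed pair with both conditions' pipeline estimates
    of total MYH1E+ area, myotube count and mean myotube size, plus the
    win flags (hypoxia-like lower on every axis)."""
    qc = _pipeline_config(noise_sd)
    rows = []
    for i in range(n_pairs):
        est = {}
        for name, make in (("ref", reference_config), ("hyp", hypoxia_like_config)):
            cfg = make(seed=base_seed + i, noise_sd=noise_sd)
            images, _ = simulate_field(cfg)
            fq = quantify_field(images.channels, images.pixel_size, qc)
            m = fusion_metrics(
                fq.records, fq.class_masks, fq.field_shape, fq.pixel_size, group_label=name
            )
            est[name] = m.overall
        rows.append(
            {
                "pair": i,
                "ref_area_um2": est["ref"].absolute_area_um2,
                "hyp_area_um2": est["hyp"].absolute_area_um2,
                "ref_count": est["ref"].myotube_count,
                "hyp_count": est["hyp"].myotube_count,
                "ref_mean_size_um2": est["ref"].mean_myotube_size_um2,
                "hyp_mean_size_um2": est["hyp"].mean_myotube_size_um2,
            }
        )
    out = pd.DataFrame(rows)
    out["area_lower"] = out.hyp_area_um2 < out.ref_area_um2
    out["count_lower"] = out.hyp_count < out.ref_count
    out["size_lower"] = out.hyp_mean_size_um2 < out.ref_mean_size_um2
    out["all_lower"] = out.area_lower & out.count_lower & out.size_lower
    return out


def type_i_error_study(
    n_replicates: int = 1000, n_per_group: int = 10, n_groups: int = 3, seed: int = 0
) -> float:
    """Empirical type-I error of the parametric ANOVA route at alpha 0.05:
    groups drawn from one normal distribution, fraction of replicates where
    the omnibus test rejects."""
    rng = np.random.default_rng(seed)
    labels = [f"g{i}" for i in range(n_groups)]
    n_reject = 0
    for _ in range(n_replicates):
        groups = {g: rng.normal(0.0, 1.0, n_per_group) for g in labels}
        res = compare_groups(groups, force_parametric=True)
        n_reject += res.p_value <= 0.05
    return n_reject / n_replicates
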