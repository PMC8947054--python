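"""Group comparison statistics for assay read-outs.

Route selection follows the usual two-step convention: each group is first
checked for normality (Shapiro–Wilk at alpha 0.05). If every group looks
Gaussian, two groups are compared with a two-sided t-test (Welch by
default) and three or more with a one-way ANOVA followed by Tukey's HSD.
If any group fails normality, the rank-based alternatives are used instead
(Mann–Whitney U, or Kruskal–Wallis with Dunn's posthoc under Holm
adjustment). The route actually taken is recorded in the result.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as ss
from statsmodels.stats.multitest import multipletests
from statsmodels.stats.multicomp import pairwise_tukeyhsd

__all__ = ["ComparisonResult", "compare_groups", "dunn_posthoc"]


@dataclass
class ComparisonResult:
    test_name: str
    group_labels: list[str]
    statistic: float
    p_value: float
    parametric_route: bool
    normality_p: dict[str, float]
    posthoc_table: pd.DataFrame | None  # pairwise adjusted p, iff > 2 groups
    summary: pd.DataFrame  # per-group median, quartiles, mean, SD, n

    @property
    def significant(self) -> bool:
        return self.p_value <= self.alpha

    alpha: float = 0.05


def _summary(samples: dict[str, np.ndarray]) -> pd.DataFrame:
    rows = []
    for label, x in samples.items():
        q1, med, q3 = np.percentile(x, [25, 50, 75])
        rows.append(
            {
                "group": label,
                "n": len(x),
                "median": med,
                "q1": q1,
                "q3": q3,
                "min": x.min(),
                "max": x.max(),
                "mean": x.mean(),
                "sd": x.std(ddof=1),
            }
        )
    return pd.DataFrame(rows)


def dunn_posthoc(samples: dict[str, np.ndarray], adjust: str = "holm") -> pd.DataFrame:
    """Dunn's pairwise rank comparisons after Kruskal–Wallis.

    Z for groups i, j is the difference of mean joint ranks over the pooled
    standard error with the usual tie correction; p-values are two-sided
    and adjusted across all pairs.
    """
    labels = list(samples)
    pooled = np.concatenate([samples[g] for g in labels])
    ranks = ss.rankdata(pooled)
    n = len(pooled)
    mean_ranks, sizes, start = {}, {}, 0
    for g in labels:
        k = len(samples[g])
        mean_ranks[g] = ranks[start : start + k].mean()
        sizes[g] = k
        start += k
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = (tie_counts**3 - tie_counts).sum() / (12.0 * (n - 1))
    rows = []
    for i, a in enumerate(labels):
        for b in labels[i + 1 :]:
            se = np.sqrt((n * (n + 1) / 12.0 - tie_term) * (1.0 / sizes[a] + 1.0 / sizes[b]))
            z = (mean_ranks[a] - mean_ranks[b]) / se
            rows.append({"group_a": a, "group_b": b, "z": z, "p_raw": 2 * ss.norm.sf(abs(z))})
    out = pd.DataFrame(rows)
    out["p_adj"] = multipletests(out["p_raw"], method=adjust)[1]
    return out


def compare_groups(
    samples: dict[str, list[float] | np.ndarray],
    alpha: float = 0.05,
    welch: bool = True,
    force_parametric: bool = False,
) -> ComparisonResult:
    """Compare two or more groups of measurements.

    Every group needs n >= 3. ``force_parametric=True`` skips the
    normality gate (useful when the route is fixed by design).
    """
    arrays = {str(k): np.asarray(v, dtype=float) for k, v in samples.items()}
    if len(arrays) < 2:
        raise ValueError("need at least two groups")
    for label, x in arrays.items():
        if len(x) < 3:
            raise ValueError(f"group {label!r} has n={len(x)} < 3")
    labels = list(arrays)

    normality_p = {}
    for label, x in arrays.items():
        if np.ptp(x) == 0:  # Shapiro is undefined for constant samples
            normality_p[label] = 0.0
        else:
            normality_p[label] = float(ss.shapiro(x).pvalue)
    parametric = force_parametric or all(p > alpha for p in normality_p.values())

    posthoc = None
    values = list(arrays.values())
    if len(arrays) == 2:
        a, b = values
        if parametric:
            if np.ptp(np.concatenate(values)) == 0:
                stat, p = 0.0, 1.0  # identical constant groups
            else:
                stat, p = ss.ttest_ind(a, b, equal_var=not welch)
            name = "welch_t" if welch else "student_t"
        else:
            stat, p = ss.mannwhitneyu(a, b, alternative="two-sided")
            name = "mann_whitney_u"
    else:
        if parametric:
            stat, p = ss.f_oneway(*values)
            name = "one_way_anova"
            flat = np.concatenate(values)
            groups = np.concatenate([[lbl] * len(arrays[lbl]) for lbl in labels])
            tk = pairwise_tukeyhsd(flat, groups, alpha=alpha)
            posthoc = pd.DataFrame(
                tk.summary().data[1:], columns=[str(c) for c in tk.summary().data[0]]
            ).rename(columns={"group1": "group_a", "group2": "group_b", "p-adj": "p_adj"})
        else:
            stat, p = ss.kruskal(*values)
            name = "kruskal_wallis"
            posthoc = dunn_posthoc(arrays)

    return ComparisonResult(
        test_name=name,
        group_labels=labels,
        statistic=float(stat),
        p_value=float(p),
        parametric_route=parametric,
        normality_p=normality_p,
        posthoc_table=posthoc,
        summary=_summary(arrays),
        alpha=alpha,
    )
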