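"""Cohort statistics: rank-sum tests, correlations, summaries, agreement.

The group comparison of record is the two-sided Wilcoxon rank-sum test
under the normal approximation with tie-averaged ranks and *no* continuity
correction; exact-distribution and continuity-corrected variants are
available by flag.  Associations between continuous variables use
Pearson's correlation coefficient.  Inter-grader segmentation agreement
passes when the two delineated areas differ by less than 10% of the larger
one.

``REFERENCE_CLOT_INDICES`` holds the published perfusion indices of a
five-lesion cohort of partially clotted microaneurysms (SRMD and WSSMD
evaluated separately over the perfused and clotted body sub-regions); it
serves as the fixed input for the headline group comparison.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np
import pandas as pd
from scipy import stats as sps

#: Published perfused/clotted SRMD and WSSMD for five partially clotted
#: microaneurysms (rows: lesion id).
REFERENCE_CLOT_INDICES = pd.DataFrame(
    {
        "ma_id": ["MA1", "MA6", "MA7", "MA14", "MA20"],
        "srmd_perfused": [34.93, 125.94, 33.09, 43.51, 79.35],
        "srmd_clotted": [321.68, 352.52, 173.48, 112.18, 99.41],
        "wssmd_perfused": [16.82, 56.72, 14.91, 26.87, 29.80],
        "wssmd_clotted": [93.13, 132.08, 58.41, 72.41, 58.66],
    }
).set_index("ma_id")

#: significance level for rejecting the null hypothesis
ALPHA = 0.05


@dataclasses.dataclass
class RankSumResult:
    z: float
    p: float
    method: str

    @property
    def significant(self) -> bool:
        return self.p < ALPHA


def ranksum_test(x, y, method: str = "normal") -> RankSumResult:
    """Two-sided Wilcoxon rank-sum test.

    ``normal``
        rank-sum z statistic with average ranks for ties and no
        continuity correction (the default reading of the group
        comparisons here), p from the normal tail.
    ``normal_cc``
        as above with the 0.5 continuity correction.
    ``exact``
        exact Mann-Whitney null distribution (no ties supported by the
        exact enumeration; scipy falls back as needed).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("each sample needs at least 2 observations")
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        raise ValueError("all observations identical; rank-sum undefined")

    if method == "exact":
        res = sps.mannwhitneyu(x, y, alternative="two-sided", method="exact")
        # report the z-equivalent for uniformity
        z = sps.norm.isf(res.pvalue / 2.0) * math.copysign(1.0, np.median(x) - np.median(y))
        return RankSumResult(z=float(z), p=float(res.pvalue), method=method)
    if method not in ("normal", "normal_cc"):
        raise ValueError(f"unknown method {method!r}")

    n1, n2 = len(x), len(y)
    ranks = sps.rankdata(pooled)  # average ranks for ties
    w = ranks[:n1].sum()
    mu = n1 * (n1 + n2 + 1) / 2.0
    # tie-corrected variance
    _, counts = np.unique(pooled, return_counts=True)
    tie = (counts**3 - counts).sum()
    n = n1 + n2
    var = n1 * n2 / 12.0 * ((n + 1) - tie / (n * (n - 1)))
    if var <= 0:
        raise ValueError("zero variance in rank-sum test")
    d = w - mu
    if method == "normal_cc":
        d -= 0.5 * math.copysign(1.0, d)
    z = d / math.sqrt(var)
    p = 2.0 * sps.norm.sf(abs(z))
    return RankSumResult(z=float(z), p=float(p), method=method)


def pearson_r(x, y) -> float:
    """Sample Pearson product-moment correlation coefficient."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need equal-length samples of size >= 3")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance in a sample")
    return float(sps.pearsonr(x, y).statistic)


def group_summary(
    table: pd.DataFrame, group_field: str, value_field: str
) -> pd.DataFrame:
    """mean ± sample SD (n−1) per group; SD is NaN for single-value groups."""
    grouped = table.groupby(group_field)[value_field]
    out = grouped.agg(n="count", mean="mean", sd=lambda v: v.std(ddof=1))
    if (out["n"] < 1).any():
        raise ValueError("empty group in summary")
    return out


def grader_agreement(area_a: float, area_b: float, tolerance: float = 0.10) -> bool:
    """True when the two areas differ by less than 10% of the larger."""
    if area_a <= 0 or area_b <= 0:
        raise ValueError("areas must be positive")
    return abs(area_a - area_b) / max(area_a, area_b) < tolerance


def clot_region_comparison(
    table: pd.DataFrame = REFERENCE_CLOT_INDICES, method: str = "normal"
) -> dict:
    """Headline comparison: perfused vs clotted SRMD and WSSMD.

    Returns group means/SDs and the two-sided rank-sum p-values for both
    indices, computed from the per-lesion sub-region values.
    """
    out: dict = {}
    for index in ("srmd", "wssmd"):
        perf = table[f"{index}_perfused"].to_numpy()
        clot = table[f"{index}_clotted"].to_numpy()
        res = ranksum_test(perf, clot, method=method)
        out[index] = {
            "perfused_mean": float(perf.mean()),
            "perfused_sd": float(perf.std(ddof=1)),
            "clotted_mean": float(clot.mean()),
            "clotted_sd": float(clot.std(ddof=1)),
            "z": res.z,
            "p": res.p,
        }
    return out


def render_report(cohort: pd.DataFrame) -> str:
    """Plain-text cohort report mirroring the standard comparisons.

    Expects columns: classification, body_area_um2, ar, bnr, srmd, wssmd,
    and optionally the clot sub-region index columns.
    """
    lines = ["Cohort report", "=" * 13, ""]
    if "classification" in cohort and cohort["classification"].nunique() > 1:
        for field, label in (
            ("ar", "asymmetry ratio"),
            ("body_area_um2", "body area (um^2)"),
        ):
            if field not in cohort:
                continue
            summ = group_summary(cohort, "classification", field)
            lines.append(f"{label} by class:")
            for cls, row in summ.iterrows():
                sd = "NA" if np.isnan(row["sd"]) else f"{row['sd']:.2f}"
                lines.append(f"  {cls}: {row['mean']:.2f} +/- {sd} (n={int(row['n'])})")
            groups = [g for _, g in cohort.groupby("classification")[field] if len(g) >= 2]
            if len(groups) == 2:
                res = ranksum_test(groups[0], groups[1])
                lines.append(f"  rank-sum p = {res.p:.3g}")
            lines.append("")
    for a, b in (("bnr", "srmd"), ("bnr", "wssmd")):
        if a in cohort and b in cohort and cohort[[a, b]].dropna().shape[0] >= 3:
            sub = cohort[[a, b]].dropna()
            lines.append(f"Pearson r ({a.upper()} vs {b.upper()}): "
                         f"{pearson_r(sub[a], sub[b]):.2f}")
    sub_cols = [c for c in cohort.columns if c.endswith("_clotted")]
    if sub_cols:
        lines.append("")
        lines.append("clotted vs perfused sub-region indices:")
        for c in sub_cols:
            base = c[: -len("_clotted")]
            pair = cohort[[f"{base}_perfused", c]].dropna()
            if len(pair) >= 2:
                res = ranksum_test(pair[f"{base}_perfused"], pair[c])
                lines.append(
                    f"  {base}: perfused {pair[f'{base}_perfused'].mean():.2f} vs "
                    f"clotted {pair[c].mean():.2f}, p = {res.p:.3g}"
                )
    return "\n".join(lines) + "\n"
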