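"""Non-phylogenetic clade comparisons: one-way ANOVA and Tukey's HSD.

Genus-level characteristics are compared across the four angiosperm major
clades (Magnoliids, Monocots, Rosids, Asterids) ignoring phylogenetic
structure below the clade level: a one-way analysis of variance with clade
as the grouping factor, the effect size R² = SSB/SST, and Tukey's honestly
significant difference tests (Tukey–Kramer for the very unequal clade
sizes) to locate which pairs of clades drive a significant F.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DegenerateGroupError

__all__ = ["AnovaResult", "one_way_anova", "tukey_hsd", "load_clade_table"]


@dataclass
class AnovaResult:
    F: float
    df_between: int
    df_within: int
    p_value: float
    r_squared: float
    group_means: dict[str, float]
    group_sizes: dict[str, int]
    tukey: pd.DataFrame


def _split_groups(values, groups) -> dict[str, np.ndarray]:
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    if values.shape != groups.shape:
        raise ValueError("values and groups must have equal length")
    keep = np.isfinite(values)
    values, groups = values[keep], groups[keep]
    out = {g: values[groups == g] for g in pd.unique(groups)}
    if len(out) < 2:
        raise DegenerateGroupError("need at least 2 groups")
    small = [g for g, v in out.items() if len(v) < 2]
    if small:
        raise DegenerateGroupError(f"groups with fewer than 2 observations: {small}")
    return out


def one_way_anova(values, groups) -> AnovaResult:
    """Standard one-way ANOVA decomposition with R² and a Tukey table.

    F = (SSB/df_b) / (SSW/df_w); the p-value comes from the F distribution
    and R² = SSB/SST measures the share of variance between groups.
    """
    by_group = _split_groups(values, groups)
    all_vals = np.concatenate(list(by_group.values()))
    n, k = len(all_vals), len(by_group)
    grand = all_vals.mean()
    ssb = sum(len(v) * (v.mean() - grand) ** 2 for v in by_group.values())
    ssw = sum(((v - v.mean()) ** 2).sum() for v in by_group.values())
    sst = ssb + ssw
    if ssw == 0:
        raise DegenerateGroupError("zero within-group variance everywhere: F undefined")
    df_b, df_w = k - 1, n - k
    F = (ssb / df_b) / (ssw / df_w)
    p = float(stats.f.sf(F, df_b, df_w))
    return AnovaResult(
        F=float(F),
        df_between=df_b,
        df_within=df_w,
        p_value=p,
        r_squared=float(ssb / sst) if sst > 0 else 0.0,
        group_means={g: float(v.mean()) for g, v in by_group.items()},
        group_sizes={g: len(v) for g, v in by_group.items()},
        tukey=tukey_hsd(values, groups),
    )


def tukey_hsd(values, groups) -> pd.DataFrame:
    """Pairwise Tukey(-Kramer) comparisons from the studentized-range
    distribution; one row per unordered group pair with the mean difference
    and family-wise adjusted p-value."""
    by_group = _split_groups(values, groups)
    names = list(by_group)
    res = stats.tukey_hsd(*by_group.values())
    rows = []
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            rows.append(
                {
                    "group1": names[i],
                    "group2": names[j],
                    "mean_difference": float(res.statistic[i, j]),
                    "p_adjusted": float(res.pvalue[i, j]),
                }
            )
    return pd.DataFrame(rows)


def load_clade_table(path) -> pd.Series:
    """Read a genus→clade classification CSV/TSV (columns genus, clade)."""
    sep = "\t" if str(path).endswith((".tsv", ".tab", ".txt")) else ","
    df = pd.read_csv(path, sep=sep)
    if not {"genus", "clade"} <= set(df.columns):
        raise ValueError("clade table needs 'genus' and 'clade' columns")
    if df["genus"].duplicated().any():
        dupes = df["genus"][df["genus"].duplicated()].tolist()
        raise ValueError(f"genus assigned to more than one clade: {dupes[:5]}")
    return df.set_index("genus")["clade"]
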