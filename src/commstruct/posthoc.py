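"""Biome-wise comparison of site means with a variance-homogeneity gate.

Species richness (or any per-site value) is compared across biomes with
pairwise post hoc tests.  The test family is chosen by a Fligner-Killeen
homogeneity-of-variances gate: Tukey's HSD (pooled variance, studentised
range) when variances are homogeneous, Games-Howell (Welch-type SE and
Welch-Satterthwaite df) when they are not.  Biomes with too few sites are
excluded before testing.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats


def fligner_killeen(groups: list[np.ndarray]) -> tuple[float, float]:
    """Fligner-Killeen test of variance homogeneity.

    Rank-based normal scores of |x - group median|, chi-squared with
    g - 1 df.  Identical groups (zero spread everywhere) return
    (0.0, 1.0) rather than NaN.
    """
    if len(groups) < 2 or any(len(g) < 2 for g in groups):
        raise ValueError("need >= 2 groups with n >= 2 each")
    if all(np.ptp(np.abs(np.asarray(g, float)
                         - np.median(g))) == 0 for g in groups):
        return 0.0, 1.0
    stat, p = stats.fligner(*groups)
    return float(stat), float(p)


@dataclass
class PosthocTable:
    """Pairwise post hoc results: one row per unordered biome pair."""

    test: str                    # "tukey" | "games_howell"
    table: pd.DataFrame          # group_i, group_j, mean_diff, stat, df, p_adj
    gate: dict | None = None     # Fligner-Killeen stat/p and the decision


def tukey_hsd(groups: dict[str, np.ndarray]) -> PosthocTable:
    """Tukey's honestly-significant-difference pairwise comparisons."""
    names = list(groups)
    if len(names) < 2:
        raise ValueError("need >= 2 groups")
    arrays = [np.asarray(groups[g], float) for g in names]
    res = stats.tukey_hsd(*arrays)
    ns = np.array([len(a) for a in arrays])
    df_pool = int(ns.sum() - len(ns))
    rows = []
    for i, j in combinations(range(len(names)), 2):
        rows.append({
            "group_i": names[i], "group_j": names[j],
            "mean_diff": float(arrays[i].mean() - arrays[j].mean()),
            "stat": float(res.statistic[i, j]),
            "df": df_pool,
            "p_adj": float(np.clip(res.pvalue[i, j], 0, 1)),
        })
    return PosthocTable("tukey", pd.DataFrame(rows))


def games_howell(groups: dict[str, np.ndarray]) -> PosthocTable:
    """Games-Howell pairwise comparisons for unequal variances.

    Per pair: Welch standard error, Welch-Satterthwaite df, and a
    studentised-range p-value with q = |diff| / SE * sqrt(2).
    """
    names = list(groups)
    if len(names) < 2:
        raise ValueError("need >= 2 groups")
    if any(len(groups[g]) < 2 for g in names):
        raise ValueError("each group needs n >= 2")
    k = len(names)
    means = {g: float(np.mean(groups[g])) for g in names}
    varn = {g: float(np.var(groups[g], ddof=1)) / len(groups[g])
            for g in names}
    ns = {g: len(groups[g]) for g in names}
    rows = []
    for gi, gj in combinations(names, 2):
        se2 = varn[gi] + varn[gj]
        se = np.sqrt(se2)
        diff = means[gi] - means[gj]
        df = se2 ** 2 / (varn[gi] ** 2 / (ns[gi] - 1)
                         + varn[gj] ** 2 / (ns[gj] - 1))
        if se == 0:
            q, p = 0.0, 1.0
        else:
            q = abs(diff) / se * np.sqrt(2.0)
            p = float(stats.studentized_range.sf(q, k, df))
        rows.append({"group_i": gi, "group_j": gj, "mean_diff": diff,
                     "stat": float(q), "df": float(df),
                     "p_adj": float(np.clip(p, 0, 1))})
    return PosthocTable("games_howell", pd.DataFrame(rows))


def compare_biomes(values: pd.Series, biomes: pd.Series,
                   min_sites: int = 3, gate_alpha: float = 0.05
                   ) -> PosthocTable:
    """Gate on variance homogeneity, then run the appropriate post hoc.

    Biomes with fewer than ``min_sites`` sites are excluded (one or two
    localities cannot support a variance estimate worth testing).
    Fligner-Killeen p >= ``gate_alpha`` selects Tukey, otherwise
    Games-Howell.
    """
    df = pd.DataFrame({"value": values, "biome": biomes}).dropna()
    counts = df["biome"].value_counts()
    keep = counts.index[counts >= min_sites]
    df = df[df["biome"].isin(keep)]
    if df["biome"].nunique() < 2:
        raise ValueError("fewer than 2 biomes remain after exclusion")
    groups = {str(b): g["value"].to_numpy(float)
              for b, g in df.groupby("biome")}
    stat, p = fligner_killeen(list(groups.values()))
    use_tukey = p >= gate_alpha
    out = tukey_hsd(groups) if use_tukey else games_howell(groups)
    out.gate = {"fligner_stat": stat, "fligner_p": p,
                "homogeneous": bool(use_tukey),
                "excluded_biomes": {str(b): int(counts[b])
                                    for b in counts.index
                                    if counts[b] < min_sites}}
    return out
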