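"""ROI summarization, histotype group comparisons, and perfusion correlation.

Per-subject parameter maps are reduced to ROI medians (tumour core and
periphery), compared between groups with a normality-gated test battery
(Shapiro–Wilk per group; one-way ANOVA with Tukey's HSD when every group is
normal, otherwise Kruskal–Wallis with Dunn's pairwise comparisons,
Holm-adjusted), and the vascular fraction is correlated against
perfusion-MRI metrics (plasma volume Vp from DCE, relative blood volume rBV
from DSC) with one core-median point per lesion.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multicomp import pairwise_tukeyhsd

__all__ = [
    "roi_medians",
    "stack_roi_tables",
    "GroupComparisonResult",
    "compare_groups",
    "dunn_test",
    "correlate_with_pwi",
]

ALPHA = 0.05


def roi_medians(
    maps: dict, masks: dict, subject: str, group: str
) -> pd.DataFrame:
    """Median of each parameter map over each ROI for one subject.

    ``maps`` is name -> 3D array; ``masks`` is region -> binary 3D array.
    Medians are taken over finite voxels only.
    """
    rows = []
    for region, mask in masks.items():
        mask = np.asarray(mask, dtype=bool)
        if not mask.any():
            raise ValueError(f"empty ROI mask: subject {subject!r}, region {region!r}")
        row = {"subject": subject, "group": group, "region": region}
        for name, arr in maps.items():
            vals = np.asarray(arr, dtype=float)[mask]
            vals = vals[np.isfinite(vals)]
            if vals.size == 0:
                raise ValueError(
                    f"no finite voxels: subject {subject!r}, region {region!r}, map {name!r}"
                )
            row[name] = float(np.median(vals))
        rows.append(row)
    return pd.DataFrame(rows)


def stack_roi_tables(tables) -> pd.DataFrame:
    return pd.concat(list(tables), ignore_index=True)


@dataclass
class GroupComparisonResult:
    metric: str
    normality_p: dict
    all_normal: bool
    test: str  # "anova_tukey" | "kruskal_dunn"
    omnibus_p: float
    pairwise: pd.DataFrame  # symmetric p-value table
    significant: dict  # (group_a, group_b) -> bool at p < 0.05


def compare_groups(
    table: pd.DataFrame, metric: str, grouping: str = "group",
    region: str | None = None, alpha: float = ALPHA,
) -> GroupComparisonResult:
    """Compare a metric between groups.

    All groups must pass Shapiro–Wilk (per group, at ``alpha``) for the
    parametric branch; otherwise the rank-based branch runs.  Requires >= 2
    groups with >= 3 observations each.
    """
    data = table if region is None else table[table["region"] == region]
    groups = {
        str(g): np.asarray(sub[metric], dtype=float)
        for g, sub in data.groupby(grouping)
    }
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    for g, vals in groups.items():
        if len(vals) < 3:
            raise ValueError(f"group {g!r} has {len(vals)} observations; need >= 3")
    normality = {g: float(stats.shapiro(v).pvalue) for g, v in groups.items()}
    all_normal = all(p > alpha for p in normality.values())
    names = sorted(groups)
    if all_normal:
        omnibus = float(stats.f_oneway(*[groups[g] for g in names]).pvalue)
        flat_vals = np.concatenate([groups[g] for g in names])
        flat_grp = np.concatenate([[g] * len(groups[g]) for g in names])
        tuk = pairwise_tukeyhsd(flat_vals, flat_grp, alpha=alpha)
        pair_p = {}
        for (a, b), p in zip(
            combinations(tuk.groupsunique, 2), np.atleast_1d(tuk.pvalues)
        ):
            pair_p[(str(a), str(b))] = float(p)
        test = "anova_tukey"
    else:
        omnibus = float(stats.kruskal(*[groups[g] for g in names]).pvalue)
        pair_p = dunn_test(groups)
        test = "kruskal_dunn"
    pairwise = pd.DataFrame(np.nan, index=names, columns=names)
    significant = {}
    for (a, b), p in pair_p.items():
        pairwise.loc[a, b] = pairwise.loc[b, a] = p
        significant[(a, b)] = bool(p < alpha)
    return GroupComparisonResult(
        metric=metric, normality_p=normality, all_normal=all_normal,
        test=test, omnibus_p=omnibus, pairwise=pairwise, significant=significant,
    )


def dunn_test(groups: dict, adjust: str = "holm") -> dict:
    """Dunn's pairwise rank comparisons after Kruskal–Wallis.

    Two-sided z tests on mean ranks with a tie correction; p-values are
    Holm-adjusted by default (set ``adjust=None`` for raw p).
    """
    names = sorted(groups)
    pooled = np.concatenate([groups[g] for g in names])
    n_total = len(pooled)
    ranks = stats.rankdata(pooled)
    mean_ranks, sizes, start = {}, {}, 0
    for g in names:
        n = len(groups[g])
        mean_ranks[g] = ranks[start:start + n].mean()
        sizes[g] = n
        start += n
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = np.sum(tie_counts**3 - tie_counts) / (12.0 * (n_total - 1))
    var_base = n_total * (n_total + 1) / 12.0 - tie_term
    raw = {}
    for a, b in combinations(names, 2):
        se = np.sqrt(var_base * (1.0 / sizes[a] + 1.0 / sizes[b]))
        z = (mean_ranks[a] - mean_ranks[b]) / se
        raw[(a, b)] = 2.0 * stats.norm.sf(abs(z))
    if adjust is None:
        return {k: float(v) for k, v in raw.items()}
    # Holm step-down
    items = sorted(raw.items(), key=lambda kv: kv[1])
    m = len(items)
    out, running_max = {}, 0.0
    for i, (pair, p) in enumerate(items):
        adj = min((m - i) * p, 1.0)
        running_max = max(running_max, adj)
        out[pair] = float(running_max)
    return out


def correlate_with_pwi(
    fvasc_maps, perfusion_maps, core_masks, subjects=None
):
    """Pearson correlation between fvasc and a perfusion metric across lesions.

    One observation per subject: the median of each map inside the tumour
    core.  Returns (r, p, medians DataFrame).  Requires >= 3 subjects.
    """
    fvasc_maps = list(fvasc_maps)
    perfusion_maps = list(perfusion_maps)
    core_masks = list(core_masks)
    n = len(fvasc_maps)
    if not (len(perfusion_maps) == len(core_masks) == n):
        raise ValueError("per-subject inputs have mismatched lengths")
    if n < 3:
        raise ValueError(f"need >= 3 subjects for correlation, got {n}")
    subjects = list(subjects) if subjects is not None else [str(i) for i in range(n)]
    rows = []
    for sid, fv, pf, mask in zip(subjects, fvasc_maps, perfusion_maps, core_masks):
        fv = np.asarray(fv, dtype=float)
        pf = np.asarray(pf, dtype=float)
        mask = np.asarray(mask, dtype=bool)
        if fv.shape != pf.shape or fv.shape != mask.shape:
            raise ValueError(f"subject {sid!r}: map/mask grids do not match")
        if np.any(pf[np.isfinite(pf)] < 0):
            raise ValueError(f"subject {sid!r}: negative perfusion values")
        sel = mask & np.isfinite(fv) & np.isfinite(pf)
        if not sel.any():
            raise ValueError(f"subject {sid!r}: empty core overlap")
        rows.append(
            {"subject": sid, "fvasc": float(np.median(fv[sel])),
             "perfusion": float(np.median(pf[sel]))}
        )
    med = pd.DataFrame(rows)
    res = stats.pearsonr(med["fvasc"], med["perfusion"])
    return float(res.statistic), float(res.pvalue), med
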