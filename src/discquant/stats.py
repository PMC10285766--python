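"""The cohort statistical battery: assumptions, paired tests, group comparisons.

Classic formulations throughout — Shapiro-Wilk and Levene for assumptions,
paired t for intact-vs-post changes, one-way ANOVA with post-hoc Tukey HSD
for between-technique effects, Pearson r for associations — delegated to
scipy.stats.  Raw p-values are always reported alongside the test name so
significance markers can be derived, never hard-coded.
"""

from __future__ import annotations

import numpy as np
from scipy import stats


def check_assumptions(groups: dict[str, np.ndarray]) -> dict:
    """Per-group Shapiro-Wilk normality p and across-group Levene p.

    Groups with (numerically) constant values are degenerate for
    Shapiro-Wilk and are flagged instead of tested.
    """
    if len(groups) < 1:
        raise ValueError("need at least one group")
    shapiro_p: dict[str, float] = {}
    degenerate: list[str] = []
    arrays = []
    for name, values in groups.items():
        v = np.asarray(values, dtype=float)
        if v.size < 3:
            raise ValueError(f"group {name!r} has n={v.size} < 3")
        arrays.append(v)
        if np.ptp(v) == 0:
            shapiro_p[name] = float("nan")
            degenerate.append(name)
        else:
            shapiro_p[name] = float(stats.shapiro(v).pvalue)
    levene_p = (
        float(stats.levene(*arrays).pvalue)
        if len(arrays) >= 2 and not degenerate
        else float("nan")
    )
    return {"shapiro_p": shapiro_p, "levene_p": levene_p, "degenerate": degenerate}


def paired_change_test(intact: np.ndarray, post: np.ndarray) -> dict:
    """Two-sided paired t-test on intact-vs-post values."""
    a = np.asarray(intact, dtype=float)
    b = np.asarray(post, dtype=float)
    if a.size != b.size:
        raise ValueError(f"paired samples differ in length: {a.size} vs {b.size}")
    if a.size < 2:
        raise ValueError("paired t-test needs n >= 2")
    if np.ptp(a - b) == 0 and (a - b)[0] == 0:
        # identical pairs: t = 0 by convention, no evidence of change
        return {"t": 0.0, "p": 1.0, "mean_change": 0.0, "n": int(a.size), "test": "paired t"}
    res = stats.ttest_rel(a, b)
    return {
        "t": float(res.statistic),
        "p": float(res.pvalue),
        "mean_change": float(np.mean(a - b)),
        "n": int(a.size),
        "test": "paired t",
    }


def group_comparison(groups: dict[str, np.ndarray]) -> dict:
    """One-way ANOVA across groups plus Tukey HSD adjusted pairwise p-values."""
    if len(groups) < 2:
        raise ValueError("group comparison needs at least two groups")
    names = list(groups)
    arrays = [np.asarray(groups[n], dtype=float) for n in names]
    for name, v in zip(names, arrays):
        if v.size < 2:
            raise ValueError(f"group {name!r} has n={v.size} < 2")
    if all(np.ptp(np.concatenate(arrays)) == 0 for _ in (0,)):
        f_stat, p = 0.0, 1.0
    else:
        res = stats.f_oneway(*arrays)
        f_stat, p = float(res.statistic), float(res.pvalue)
        if np.isnan(f_stat):  # all groups identical
            f_stat, p = 0.0, 1.0
    out = {
        "anova_F": f_stat,
        "anova_p": p,
        "groups": {n: int(v.size) for n, v in zip(names, arrays)},
        "test": "one-way ANOVA + Tukey HSD",
        "tukey": {},
    }
    if np.ptp(np.concatenate(arrays)) > 0:
        tk = stats.tukey_hsd(*arrays)
        for i in range(len(names)):
            for j in range(i + 1, len(names)):
                out["tukey"][f"{names[i]} vs {names[j]}"] = float(tk.pvalue[i, j])
    else:
        for i in range(len(names)):
            for j in range(i + 1, len(names)):
                out["tukey"][f"{names[i]} vs {names[j]}"] = 1.0
    return out


def correlate(x: np.ndarray, y: np.ndarray) -> dict:
    """Sample Pearson correlation with a two-sided p-value."""
    a = np.asarray(x, dtype=float)
    b = np.asarray(y, dtype=float)
    if a.size != b.size:
        raise ValueError("x and y must have equal length")
    if a.size < 3:
        raise ValueError("Pearson correlation needs n >= 3")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ValueError("zero variance in x or y: correlation undefined")
    res = stats.pearsonr(a, b)
    return {"r": float(res.statistic), "p": float(res.pvalue), "n": int(a.size)}
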