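"""Group aggregation and statistical comparisons.

Bounded similarity-type quantities (correlations, VAF fractions,
diagonality) are standardized with the Fisher z-transform (arctanh)
before averaging; means and t-based confidence intervals are computed
in z-space and back-transformed.  Quantities bounded on [0, 1] are
mapped affinely onto (-1, 1) (x -> 2x - 1) before the transform and
mapped back after.
"""
from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats as sps

CLIP = 1.0 - 1e-10


def fisher_aggregate(
    values, domain: str = "correlation", ci: float = 0.95
) -> dict:
    """Fisher-z mean and CI of bounded values.

    domain="correlation": values in (-1, 1); domain="unit": values in
    [0, 1], mapped through x -> 2x - 1 and back.  Values at the closed
    boundary are clipped just inside it.
    """
    x = np.asarray(values, float)
    if x.size == 0:
        raise ValueError("no values to aggregate")
    if domain == "unit":
        x = 2.0 * x - 1.0
    elif domain != "correlation":
        raise ValueError(f"unknown domain {domain!r}")
    x = np.clip(x, -CLIP, CLIP)
    z = np.arctanh(x)
    zm = z.mean()
    if x.size > 1 and z.std(ddof=1) > 0:
        half = sps.t.ppf(0.5 + ci / 2, x.size - 1) * z.std(ddof=1) / np.sqrt(x.size)
    else:
        half = 0.0
    back = np.tanh([zm - half, zm, zm + half])
    if domain == "unit":
        back = (back + 1.0) / 2.0
    return {
        "mean": float(back[1]),
        "ci": (float(back[0]), float(back[2])),
        "z_mean": float(zm),
        "n": int(x.size),
    }


def rank_sum_test(a, b) -> dict:
    """Wilcoxon rank-sum (two independent groups); p = 1 for identical samples."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    if a.size == 0 or b.size == 0:
        raise ValueError("insufficient data: empty group")
    if a.size == b.size and np.array_equal(np.sort(a), np.sort(b)):
        return {"statistic": 0.0, "p": 1.0, "method": "wilcoxon-ranksum"}
    stat, p = sps.ranksums(a, b)
    return {"statistic": float(stat), "p": float(p), "method": "wilcoxon-ranksum"}


def kruskal_tukey(groups: dict) -> dict:
    """Kruskal-Wallis across named groups plus Tukey HSD post-hoc pairs."""
    labels = list(groups)
    samples = [np.asarray(groups[g], float) for g in labels]
    if any(s.size == 0 for s in samples):
        raise ValueError("insufficient data: empty group")
    H, p = sps.kruskal(*samples)
    tk = sps.tukey_hsd(*samples)
    pairs = {}
    for i in range(len(labels)):
        for j in range(i + 1, len(labels)):
            pairs[(labels[i], labels[j])] = float(tk.pvalue[i, j])
    return {"statistic": float(H), "p": float(p), "method": "kruskal-wallis",
            "tukey_p": pairs}


def two_way_anova(
    values, group_labels, n_modules, fisher_domain: str | None = "unit"
) -> dict:
    """Two-way ANOVA (group x module count + interaction) on z-values."""
    import statsmodels.api as sm
    from statsmodels.formula.api import ols

    y = np.asarray(values, float)
    if fisher_domain == "unit":
        y = np.arctanh(np.clip(2.0 * y - 1.0, -CLIP, CLIP))
    elif fisher_domain == "correlation":
        y = np.arctanh(np.clip(y, -CLIP, CLIP))
    df = pd.DataFrame(
        {"y": y, "group": list(group_labels), "n_modules": list(map(str, n_modules))}
    )
    model = ols("y ~ C(group) * C(n_modules)", data=df).fit()
    table = sm.stats.anova_lm(model, typ=2)
    out = {"method": "two-way-anova"}
    for term, key in [
        ("C(group)", "group"),
        ("C(n_modules)", "n_modules"),
        ("C(group):C(n_modules)", "interaction"),
    ]:
        if term in table.index:
            out[key] = {
                "F": float(table.loc[term, "F"]),
                "p": float(table.loc[term, "PR(>F)"]),
            }
    return out


def compare_groups(data_by_group: dict, design: str = "ranksum", **kw) -> dict:
    """Dispatch to the configured test.

    design="ranksum" (two groups), "kruskal" (>= 2 groups with Tukey
    post-hoc), or "anova2" (requires ``group_labels`` and ``n_modules``
    aligned with ``values`` in ``data_by_group``).
    """
    if design == "ranksum":
        labels = list(data_by_group)
        if len(labels) != 2:
            raise ValueError("insufficient data: rank-sum design needs two groups")
        return rank_sum_test(data_by_group[labels[0]], data_by_group[labels[1]])
    if design == "kruskal":
        return kruskal_tukey(data_by_group)
    if design == "anova2":
        return two_way_anova(
            data_by_group["values"],
            data_by_group["group_labels"],
            data_by_group["n_modules"],
            **kw,
        )
    raise ValueError(f"unknown design {design!r}")


def normality_screen(values) -> dict:
    """Kolmogorov-Smirnov test against a fitted normal (reported, never gating)."""
    x = np.asarray(values, float)
    stat, p = sps.kstest((x - x.mean()) / max(x.std(ddof=1), 1e-30), "norm")
    return {"statistic": float(stat), "p": float(p), "method": "ks-normality"}
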