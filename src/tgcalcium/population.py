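"""Population-level summaries and group statistics.

Soma-diameter classes follow the standard rodent sensory-neuron
convention: small (SD) < 20 um, medium (MD) 20-25 um (both boundaries
included), large (LD) > 25 um. The subtype active-fraction estimator
scales the overall percentage of spontaneously firing neurons by how
over- or under-represented a size class is among the firing neurons:

    est_active_pct(class) = overall_active_pct
                            * share_active_pct(class) / share_all_pct(class)

e.g. with 12.3% of all neurons firing, an SD share of 17.1% among firing
neurons and 67.3% among all neurons, about 3% of SD neurons fire.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "SIZE_CLASSES",
    "classify_soma",
    "subtype_composition",
    "estimate_subtype_activity",
    "percent_active",
    "significance_stars",
    "compare_groups",
    "before_after_summary",
]

SIZE_CLASSES = ("SD", "MD", "LD")
_SD_MAX_UM = 20.0  # exclusive upper bound of SD
_MD_MAX_UM = 25.0  # inclusive upper bound of MD


def classify_soma(diameter_um: float) -> str:
    """Size class of a soma: SD (< 20 um), MD (20-25 um, inclusive),
    LD (> 25 um). Every positive diameter maps to exactly one class."""
    if not diameter_um > 0:
        raise ValueError("diameter must be positive")
    if diameter_um < _SD_MAX_UM:
        return "SD"
    if diameter_um <= _MD_MAX_UM:
        return "MD"
    return "LD"


def subtype_composition(diameters_um, active_flags) -> pd.DataFrame:
    """Size-class shares among all neurons and among active neurons.

    Returns a DataFrame indexed by class with columns ``share_all_pct``
    and ``share_active_pct``, each rounded to 1 decimal (shares sum to
    ~100 within rounding).
    """
    d = np.asarray(diameters_um, dtype=float)
    a = np.asarray(active_flags, dtype=bool)
    if d.size < 1:
        raise ValueError("need at least one neuron")
    if d.shape != a.shape:
        raise ValueError("diameters and active flags must align")
    classes = np.array([classify_soma(x) for x in d])
    rows = {}
    n_all = d.size
    n_act = int(a.sum())
    for cls in SIZE_CLASSES:
        in_cls = classes == cls
        share_all = 100.0 * in_cls.sum() / n_all
        share_act = 100.0 * (in_cls & a).sum() / n_act if n_act else np.nan
        rows[cls] = (round(share_all, 1), round(share_act, 1))
    return pd.DataFrame.from_dict(rows, orient="index",
                                  columns=["share_all_pct", "share_active_pct"])


def estimate_subtype_activity(overall_active_pct: float,
                              share_active_pct: float,
                              share_all_pct: float) -> float:
    """Estimated percentage of one size class firing spontaneously.

    ``overall_active_pct * share_active_pct / share_all_pct``; the
    reporting layer rounds to the nearest integer.
    """
    if share_all_pct <= 0:
        raise ValueError("share_all_pct must be positive")
    return overall_active_pct * share_active_pct / share_all_pct


def percent_active(n_active: float, n_total: float) -> float:
    """Percentage of neurons firing: 100 * n_active / n_total."""
    if n_total <= 0:
        raise ValueError("n_total must be positive")
    return 100.0 * n_active / n_total


def significance_stars(p: float) -> str:
    """Star convention: * p<0.05, ** p<0.005, *** p<0.001, **** p<0.0001."""
    if p < 0.0001:
        return "****"
    if p < 0.001:
        return "***"
    if p < 0.005:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


def compare_groups(samples: dict[str, np.ndarray], design: str) -> dict:
    """Group comparison under one of the study designs.

    ``anova_tukey``: one-way ANOVA plus Tukey HSD pairwise adjusted
    p-values. ``kruskal_wallis``: Kruskal-Wallis H. ``mann_whitney``:
    two-sided Mann-Whitney U (two groups). ``paired_t``: paired
    two-tailed t test (two equal-length groups).

    A Shapiro-Wilk normality diagnostic is reported per group but never
    switches the design. Degenerate (zero-variance) inputs are reported
    in the result, not raised.
    """
    names = list(samples)
    groups = [np.asarray(samples[k], dtype=float) for k in names]
    if design == "paired_t":
        if len(groups) != 2 or len(groups[0]) != len(groups[1]) or len(groups[0]) < 1:
            raise ValueError("paired_t needs two equal-length groups")
    elif any(len(g) < 2 for g in groups):
        raise ValueError("each group needs at least 2 observations")

    shapiro = {}
    for k, g in zip(names, groups):
        if len(g) >= 3 and np.std(g) > 0:
            shapiro[k] = float(stats.shapiro(g).pvalue)
        else:
            shapiro[k] = np.nan

    report: dict = {"design": design, "groups": names, "shapiro_p": shapiro,
                    "degenerate": any(np.std(g) == 0 for g in groups)}
    if design == "anova_tukey":
        if len(groups) < 2:
            raise ValueError("need at least 2 groups")
        if report["degenerate"] and all(np.std(g) == 0 for g in groups):
            report.update(statistic=np.nan, p_value=np.nan, pairwise={})
            return report
        f, p = stats.f_oneway(*groups)
        tk = stats.tukey_hsd(*groups)
        pairwise = {}
        for i in range(len(groups)):
            for j in range(i + 1, len(groups)):
                pp = float(tk.pvalue[i, j])
                pairwise[(names[i], names[j])] = {
                    "p_adj": pp, "stars": significance_stars(pp)}
        report.update(statistic=float(f), p_value=float(p), pairwise=pairwise)
    elif design == "kruskal_wallis":
        h, p = stats.kruskal(*groups)
        report.update(statistic=float(h), p_value=float(p))
    elif design == "mann_whitney":
        if len(groups) != 2:
            raise ValueError("mann_whitney needs exactly 2 groups")
        from .correlation import mann_whitney_u

        u, p = mann_whitney_u(groups[0], groups[1])
        report.update(statistic=u, p_value=float(p))
    elif design == "paired_t":
        diff = groups[0] - groups[1]
        if np.std(diff) == 0:
            report.update(statistic=np.nan, p_value=1.0 if np.all(diff == 0) else 0.0)
        else:
            t, p = stats.ttest_rel(groups[0], groups[1])
            report.update(statistic=float(t), p_value=float(p))
    else:
        raise ValueError(f"unknown design: {design}")
    report["stars"] = significance_stars(report["p_value"]) \
        if np.isfinite(report.get("p_value", np.nan)) else "na"
    return report


def before_after_summary(events_by_roi: dict[int, list], pre_block: tuple[int, int],
                         post_block: tuple[int, int]) -> dict:
    """Active-neuron counts before and after a treatment.

    ``pre_block`` and ``post_block`` are frame ranges ``[start, stop)``;
    a neuron is active in a block iff it has an event peak inside it.
    Returns pre/post counts and their difference (pre - post). Group-level
    paired testing across sessions goes through :func:`compare_groups`
    with ``design='paired_t'``.
    """
    from .events import count_active

    for name, block in (("pre", pre_block), ("post", post_block)):
        if block is None or block[1] <= block[0]:
            raise ValueError(f"missing or empty {name} block")
    counts, _ = count_active(events_by_roi, [pre_block, post_block])
    pre, post = counts
    return {"pre_active": pre, "post_active": post, "difference": pre - post}
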