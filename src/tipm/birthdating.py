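"""Birthdate-cohort analyses.

Optical birthdating (whole-embryo photoconversion of Kaede at a chosen
hour post-fertilization) splits a population into neurons born before the
conversion time (converted) and after (unconverted only).  These analyses
quantify how the fraction of tagged neurons accumulates over development,
how directional subtype identity depends on birth cohort, and when each
axis's spatial organization reaches its mature (control) distribution.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests
from statsmodels.stats.proportion import proportion_confint

from .core import AXES, Population
from .topography import compare_groups  # re-exported convenience

__all__ = [
    "assign_cohorts",
    "cumulative_birth_curve",
    "subtype_by_birthdate",
    "emergence_stats",
    "dunn_test",
    "compare_groups",
]


def assign_cohorts(pop: Population, conversion_time_hpf: float) -> pd.DataFrame:
    """Label each neuron born_before / born_after a conversion time.

    born_before iff birth_hpf <= conversion time.  Records with missing
    birth times are flagged (``membership = "unknown"``), not dropped.
    """
    df = pop.to_frame()
    membership = np.where(
        df["birth_hpf"].isna(),
        "unknown",
        np.where(df["birth_hpf"] <= conversion_time_hpf, "born_before", "born_after"),
    )
    return df.assign(conversion_hpf=conversion_time_hpf, membership=membership)


@dataclass
class BirthCurve:
    timepoints: np.ndarray
    fraction_mean: np.ndarray  # mean per-fish fraction labeled at each timepoint
    per_fish: pd.DataFrame  # columns: conversion_hpf, fish_id, fraction
    slope: float  # fraction / hpf
    intercept: float
    r_squared: float


def cumulative_birth_curve(pop: Population, conversion_times) -> BirthCurve:
    """Per-fish born-before fractions vs conversion time + linear fit.

    Mirrors the converted-to-total ratio measured per hemisphere: for each
    conversion time the fraction of neurons with birth_hpf at or below it,
    computed per fish, then averaged; a least-squares line through the
    per-fish points summarizes the accumulation rate.
    """
    conversion_times = np.asarray(sorted(conversion_times), dtype=float)
    if len(conversion_times) < 2:
        raise ValueError("need >= 2 conversion timepoints")
    df = pop.to_frame()
    rows = []
    for t in conversion_times:
        for fish, sub in df.groupby("fish_id"):
            if len(sub) == 0:
                continue
            rows.append(
                {
                    "conversion_hpf": t,
                    "fish_id": fish,
                    "fraction": float((sub["birth_hpf"] <= t).mean()),
                }
            )
    per_fish = pd.DataFrame(rows)
    means = per_fish.groupby("conversion_hpf")["fraction"].mean()
    res = stats.linregress(per_fish["conversion_hpf"], per_fish["fraction"])
    return BirthCurve(
        conversion_times,
        means.reindex(conversion_times).to_numpy(),
        per_fish,
        float(res.slope),
        float(res.intercept),
        float(res.rvalue**2),
    )


def subtype_by_birthdate(
    pop: Population,
    conversion_time_hpf: float,
    side: str = "before",
    *,
    ci_alpha: float = 0.05,
) -> pd.DataFrame:
    """Subtype proportions within the born-before (or born-after) cohort.

    Returns one row per subtype with counts, proportions (summing to 1 over
    {nose_up, nose_down, none}) and Wilson binomial confidence intervals.
    """
    if side not in ("before", "after"):
        raise ValueError("side must be 'before' or 'after'")
    labeled = assign_cohorts(pop, conversion_time_hpf)
    cohort = labeled[labeled["membership"] == f"born_{side}"]
    if len(cohort) == 0:
        raise ValueError(f"empty born_{side} cohort at {conversion_time_hpf} hpf")
    n = len(cohort)
    rows = []
    for subtype in ("nose_up", "nose_down", "none"):
        k = int((cohort["subtype"] == subtype).sum())
        lo, hi = proportion_confint(k, n, alpha=ci_alpha, method="wilson")
        rows.append(
            {
                "subtype": subtype,
                "count": k,
                "n": n,
                "proportion": k / n,
                "ci_low": float(lo),
                "ci_high": float(hi),
            }
        )
    return pd.DataFrame(rows)


def dunn_test(groups: dict, *, control: str | None = None, method: str = "holm") -> pd.DataFrame:
    """Dunn's rank-based multiple-comparison test after Kruskal–Wallis.

    z-statistics from mean ranks of the pooled sample with tie correction;
    p-values adjusted by ``method`` (Holm by default).  With ``control``
    set, only comparisons against that group are made.
    """
    names = list(groups)
    sizes = {k: len(np.asarray(v)) for k, v in groups.items()}
    pooled = np.concatenate([np.asarray(groups[k], dtype=float) for k in names])
    ranks = stats.rankdata(pooled)
    n = len(pooled)
    mean_ranks = {}
    i = 0
    for k in names:
        mean_ranks[k] = ranks[i : i + sizes[k]].mean()
        i += sizes[k]
    # tie correction term
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = (counts**3 - counts).sum() / (12.0 * (n - 1)) if n > 1 else 0.0
    pairs = (
        [(g, control) for g in names if g != control]
        if control is not None
        else [(a, b) for i, a in enumerate(names) for b in names[i + 1 :]]
    )
    rows = []
    for a, b in pairs:
        se = math.sqrt((n * (n + 1) / 12.0 - tie_term) * (1.0 / sizes[a] + 1.0 / sizes[b]))
        z = (mean_ranks[a] - mean_ranks[b]) / se if se > 0 else 0.0
        p = 2.0 * stats.norm.sf(abs(z))
        rows.append({"group_a": a, "group_b": b, "z": z, "p_raw": p})
    out = pd.DataFrame(rows)
    out["p_adj"] = multipletests(out["p_raw"], method=method)[1] if len(out) else []
    return out


@dataclass
class EmergenceStats:
    H: float
    p: float
    pairwise: pd.DataFrame  # Dunn vs control, Holm-adjusted
    metadata: dict


def emergence_stats(
    populations_by_timepoint: dict, control: Population | np.ndarray, axis: str
) -> EmergenceStats:
    """When does one axis's organization match the mature control?

    Kruskal–Wallis H (tie-corrected) across per-timepoint coordinate
    samples plus the control, followed by Dunn comparisons of each
    timepoint against the control with Holm correction.  All-tied data
    yields H = 0, p = 1.
    """
    if axis not in AXES:
        raise ValueError(f"axis must be one of {AXES}")
    idx = AXES.index(axis)

    def axis_values(p) -> np.ndarray:
        return p.coords()[:, idx] if isinstance(p, Population) else np.asarray(p, dtype=float)

    groups = {str(k): axis_values(v) for k, v in populations_by_timepoint.items()}
    groups["control"] = axis_values(control)
    if len(groups) < 2 or any(len(v) < 2 for v in groups.values()):
        raise ValueError("need >= 2 groups with >= 2 neurons each")
    samples = list(groups.values())
    if all(np.ptp(np.concatenate(samples)) == 0 for _ in (0,)):
        return EmergenceStats(0.0, 1.0, pd.DataFrame(), {"axis": axis, "note": "all tied"})
    H, p = stats.kruskal(*samples)
    pairwise = dunn_test(groups, control="control")
    return EmergenceStats(
        float(H),
        float(p),
        pairwise,
        {"axis": axis, "posthoc": "dunn", "correction": "holm"},
    )
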