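"""Varicosity growth quantification.

Axo-somatic varicosities are a morphological proxy for synapses from
projection neurons onto extraocular motor neurons.  Counts are normalized
to the 90-hpf reference within each motor-neuron class (dorsal motor
neurons carry ~3× the varicosities of ventral ones), growth is summarized
by a three-phase piecewise model (flat at 0 → linear → plateau), and
timepoints are compared by one-way ANOVA with Tukey HSD follow-ups.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .simulate import VaricositySeries, piecewise_growth

__all__ = [
    "GrowthFit",
    "normalize_varicosities",
    "fit_growth_phases",
    "compare_timepoints",
]


def normalize_varicosities(series: VaricositySeries, *, anchor: str = "mean") -> VaricositySeries:
    """Express counts as percent of the 90-hpf reference for the class.

    ``anchor`` is the mean count at 90 hpf by default (``"max"``
    selectable).  Idempotent: renormalizing an already-normalized series
    against its own 90-hpf mean returns it unchanged.
    """
    obs = series.observations
    at90 = obs.loc[obs["age_hpf"] == 90.0, "varicosity_count"]
    if len(at90) == 0:
        raise ValueError("no 90-hpf observations to anchor the normalization")
    ref = float(at90.mean() if anchor == "mean" else at90.max())
    if ref <= 0:
        raise ValueError("90-hpf reference count must be positive")
    out = obs.copy()
    out["varicosity_count"] = 100.0 * out["varicosity_count"] / ref
    return VaricositySeries(series.motor_neuron_class, out)


@dataclass
class GrowthFit:
    """Least-squares three-phase growth model estimate."""

    onset_hpf: float
    plateau_hpf: float
    plateau_level: float  # percent (or count units of the input)
    growth_rate: float  # level units per hpf during the linear phase
    rss: float

    def predict(self, t) -> np.ndarray:
        return piecewise_growth(t, self.onset_hpf, self.plateau_hpf, self.plateau_level)


def fit_growth_phases(
    series: VaricositySeries, *, grid_step_hpf: float = 1.0
) -> GrowthFit:
    """Fit onset/linear/plateau breakpoints by grid least squares.

    The model is 0 before onset, linear to the plateau level at the second
    breakpoint, then flat.  Breakpoint pairs are scanned on a grid (1-hpf
    resolution by default); for each pair the plateau level has the
    closed-form least-squares solution L = Σ y·g / Σ g², where g is the
    unit-plateau template.  Global best by residual sum of squares; ties
    break toward the earliest onset.
    """
    obs = series.observations
    t = obs["age_hpf"].to_numpy(dtype=float)
    y = obs["varicosity_count"].to_numpy(dtype=float)
    if len(np.unique(t)) < 6:
        raise ValueError("need >= 6 distinct timepoints to identify three phases")
    lo, hi = float(t.min()), float(t.max())
    grid = np.arange(lo, hi + grid_step_hpf / 2, grid_step_hpf)
    best: GrowthFit | None = None
    for onset, plateau in itertools.combinations(grid, 2):
        g = np.clip((t - onset) / (plateau - onset), 0.0, 1.0)
        denom = float(g @ g)
        level = float(g @ y) / denom if denom > 0 else 0.0
        rss = float(((y - level * g) ** 2).sum())
        if best is None or rss < best.rss - 1e-12:
            rate = level / (plateau - onset)
            best = GrowthFit(float(onset), float(plateau), level, rate, rss)
    assert best is not None
    return best


@dataclass
class TimepointComparison:
    F: float
    p: float
    pairwise: pd.DataFrame  # Tukey HSD, one row per timepoint pair
    metadata: dict


def compare_timepoints(series: VaricositySeries) -> TimepointComparison:
    """One-way ANOVA across ages within one motor-neuron class.

    Tukey HSD supplies the pairwise follow-ups.  Degenerate input (zero
    within-group variance everywhere) is flagged rather than raised.
    """
    obs = series.observations
    groups = {
        age: sub["varicosity_count"].to_numpy(dtype=float)
        for age, sub in obs.groupby("age_hpf")
    }
    ages = sorted(groups)
    if len(ages) < 2 or any(len(groups[a]) < 2 for a in ages):
        raise ValueError("need >= 2 timepoints with >= 2 fish each")
    samples = [groups[a] for a in ages]
    if all(s.var() == 0 for s in samples):
        return TimepointComparison(
            float("nan"), float("nan"), pd.DataFrame(), {"degenerate": True}
        )
    F, p = stats.f_oneway(*samples)
    tk = stats.tukey_hsd(*samples)
    rows = []
    for i, j in itertools.combinations(range(len(ages)), 2):
        rows.append(
            {
                "age_a": ages[i],
                "age_b": ages[j],
                "mean_diff": float(samples[i].mean() - samples[j].mean()),
                "p_adj": float(tk.pvalue[i, j]),
            }
        )
    return TimepointComparison(
        float(F), float(p), pd.DataFrame(rows), {"posthoc": "tukey_hsd", "degenerate": False}
    )
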