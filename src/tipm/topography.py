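"""Spatial registration and topography statistics of neuron somata.

Coordinates live in a common reference frame (4.8 px/μm, origin at the
upper-left corner of the nucleus bounding box) and are subdivided into
5-μm dorsoventral planes.  Organization is tested globally (one-way MANOVA
on the 3-D coordinates, Wilks Λ with Rao's F) and per axis (two-sample
Kolmogorov–Smirnov), against a chance null built by permuting labels while
preserving label counts and coordinates.  A grid search over azimuth/
elevation finds the sagittal view that best separates subtypes — the
transformed coordinates are display-only; every statistic is computed on
raw coordinates.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .core import AXES, Population

__all__ = [
    "ReferenceFrame",
    "TopographyResult",
    "ViewSearchResult",
    "register_neurons",
    "axis_distribution",
    "ks_two_sample",
    "manova_one_way",
    "permutation_null",
    "compare_groups",
    "optimal_sagittal_view",
    "rotation_matrix",
]


@dataclass(frozen=True)
class ReferenceFrame:
    """Scaling/origin of the common anatomical reference stacks."""

    pixels_per_um: float = 4.8
    origin_px: tuple[float, float] = (0.0, 0.0)  # upper-left corner of bounding box
    plane_thickness_um: float = 5.0
    n_planes: int = 8

    def __post_init__(self) -> None:
        if self.pixels_per_um <= 0 or self.plane_thickness_um <= 0:
            raise ValueError("pixels_per_um and plane_thickness_um must be positive")


def register_neurons(
    raw: pd.DataFrame, frame: ReferenceFrame, *, stack_depth_um: float | None = None
) -> pd.DataFrame:
    """Normalize raw pixel coordinates into the μm reference frame.

    Input columns: ``x_px``, ``y_px`` (Illustrator-style coordinates within
    the nucleus bounding box) and ``z_um`` (dorsoventral position).  Output
    adds ``x_rc_um``, ``y_ml_um`` (origin-subtracted, scaled), the
    dorsoventral ``subdivision`` index = floor(z / plane thickness), and an
    ``out_of_bounds`` flag for records outside the box (flagged, kept).
    """
    depth = stack_depth_um if stack_depth_um is not None else (
        frame.n_planes * frame.plane_thickness_um
    )
    n_planes = int(math.floor(depth / frame.plane_thickness_um + 1e-9))
    out = raw.copy()
    ox, oy = frame.origin_px
    out["x_rc_um"] = (out["x_px"] - ox) / frame.pixels_per_um
    out["y_ml_um"] = (out["y_px"] - oy) / frame.pixels_per_um
    out["subdivision"] = np.floor(out["z_um"] / frame.plane_thickness_um + 1e-9).astype(int)
    out["out_of_bounds"] = (
        (out["x_rc_um"] < 0)
        | (out["y_ml_um"] < 0)
        | (out["z_um"] < 0)
        | (out["subdivision"] >= n_planes)
    )
    out.attrs["n_planes"] = n_planes
    return out


def n_subdivisions(stack_depth_um: float, plane_thickness_um: float = 5.0) -> int:
    """Number of dorsoventral planes a stack subdivides into (40 μm → 8)."""
    return int(math.floor(stack_depth_um / plane_thickness_um + 1e-9))


# ---------------------------------------------------------------------------
# densities
# ---------------------------------------------------------------------------

@dataclass
class AxisDensity:
    bin_edges: np.ndarray
    mean: dict  # group -> per-bin mean density (sums to 1)
    sd: dict  # group -> per-bin jackknife sd
    medians: dict  # group -> median position


def axis_distribution(
    pop: Population,
    axis: str,
    group_labels: np.ndarray | str,
    *,
    bin_width_um: float = 2.0,
    bounds: tuple[float, float] | None = None,
) -> AxisDensity:
    """Jackknifed per-group densities along one anatomical axis.

    Leave-one-neuron-out histogram densities (each summing to 1 over bins)
    give the pointwise mean and standard deviation; 2-μm bins sit below the
    ~5-μm soma diameter and are stable under the jackknife.
    """
    if axis not in AXES:
        raise ValueError(f"axis must be one of {AXES}")
    values = pop.coords()[:, AXES.index(axis)]
    labels = pop.labels(group_labels) if isinstance(group_labels, str) else np.asarray(group_labels)
    if bounds is None:
        bounds = (float(np.floor(values.min())), float(np.ceil(values.max()) + 1e-9))
    edges = np.arange(bounds[0], bounds[1] + bin_width_um, bin_width_um)
    mean, sd, medians = {}, {}, {}
    for g in np.unique(labels):
        x = values[labels == g]
        if len(x) < 3:
            raise ValueError(f"group {g!r} needs >= 3 neurons for the jackknife")
        reps = np.empty((len(x), len(edges) - 1))
        for i in range(len(x)):
            h, _ = np.histogram(np.delete(x, i), bins=edges)
            reps[i] = h / h.sum()
        mean[g] = reps.mean(axis=0)
        sd[g] = reps.std(axis=0, ddof=0)
        medians[g] = float(np.median(x))
    return AxisDensity(edges, mean, sd, medians)


# ---------------------------------------------------------------------------
# hypothesis tests
# ---------------------------------------------------------------------------

def _exact_one_sided_ks_p(n_x: int, n_y: int, d: float) -> float:
    """Exact P(sup_t F_x(t) − F_y(t) >= d) under exchangeability.

    Lattice-path count: interleavings of the pooled sample are paths from
    (0, 0) to (n_x, n_y); the supremum reaches d iff the path touches the
    region i/n_x − j/n_y >= d.  Counting the complement by dynamic
    programming gives the exact permutation p for continuous data.
    """
    if d <= 0:
        return 1.0
    ways = np.zeros((n_x + 1, n_y + 1))
    ways[0, 0] = 1.0
    for i in range(n_x + 1):
        for j in range(n_y + 1):
            if i == 0 and j == 0:
                continue
            if i / n_x - j / n_y >= d - 1e-12:
                continue  # path already crossed; contributes to the tail
            ways[i, j] = (ways[i - 1, j] if i > 0 else 0.0) + (
                ways[i, j - 1] if j > 0 else 0.0
            )
    return float(1.0 - ways[n_x, n_y] / math.comb(n_x + n_y, n_x))


def ks_two_sample(a, b, tail: str = "two") -> tuple[float, float]:
    """Two-sample Kolmogorov–Smirnov test.

    ``two``: D = sup|F_a − F_b| with scipy's p-value.  One-sided
    (``greater``/``less``): D⁺ = sup(F_a − F_b) (resp. D⁻) with the
    asymptotic Smirnov p = exp(−2 n_eff D²), n_eff = n_a n_b/(n_a + n_b),
    replaced by the exact permutation distribution (lattice-path count)
    when the pooled sample is small.  ``greater`` tests whether ``a`` is
    stochastically larger than ``b`` (its empirical CDF falls below b's;
    D⁻ is the evidence).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("both samples need >= 2 observations")
    if tail == "two":
        res = stats.ks_2samp(a, b, alternative="two-sided")
        return float(res.statistic), float(res.pvalue)
    if tail not in ("greater", "less"):
        raise ValueError("tail must be 'two', 'greater' or 'less'")
    # signed ECDF difference over the pooled support
    grid = np.sort(np.concatenate([a, b]))
    fa = np.searchsorted(np.sort(a), grid, side="right") / len(a)
    fb = np.searchsorted(np.sort(b), grid, side="right") / len(b)
    diff = fa - fb
    d = float(max(-diff.min(), 0.0)) if tail == "greater" else float(max(diff.max(), 0.0))
    if len(a) + len(b) <= 30:
        # statistic is sup(F_b − F_a) for "greater", sup(F_a − F_b) for "less"
        n_x, n_y = (len(b), len(a)) if tail == "greater" else (len(a), len(b))
        return d, _exact_one_sided_ks_p(n_x, n_y, d)
    n_eff = len(a) * len(b) / (len(a) + len(b))
    p = float(min(1.0, math.exp(-2.0 * n_eff * d * d)))
    return d, p


@dataclass
class ManovaResult:
    wilks_lambda: float
    F: float
    df1: float
    df2: float
    p: float


def manova_one_way(coords: np.ndarray, labels) -> ManovaResult:
    """One-way MANOVA: Wilks Λ with Rao's F approximation.

    Λ = det(W)/det(W + B) from the within/between scatter matrices; the F
    approximation is exact for two groups, where it coincides with
    Hotelling's T².  Requires each group to have more observations than
    dimensions and a non-singular pooled within-group scatter.
    """
    X = np.asarray(coords, dtype=float)
    labels = np.asarray(labels)
    groups = np.unique(labels)
    n, p = X.shape
    g = len(groups)
    if g < 2:
        raise ValueError("need at least two groups")
    grand = X.mean(axis=0)
    W = np.zeros((p, p))
    B = np.zeros((p, p))
    for grp in groups:
        Xi = X[labels == grp]
        if len(Xi) < p + 1:
            raise ValueError(f"group {grp!r} needs >= {p + 1} observations")
        mi = Xi.mean(axis=0)
        C = Xi - mi
        W += C.T @ C
        d = (mi - grand)[:, None]
        B += len(Xi) * (d @ d.T)
    sign, logdet_w = np.linalg.slogdet(W)
    if sign <= 0:
        raise np.linalg.LinAlgError("within-group scatter is rank deficient")
    _, logdet_t = np.linalg.slogdet(W + B)
    lam = float(np.exp(logdet_w - logdet_t))

    # Rao's F approximation
    q = g - 1
    m = n - 1 - (p + g) / 2.0
    denom = p * p + q * q - 5
    s = math.sqrt((p * p * q * q - 4) / denom) if denom > 0 else 1.0
    df1 = p * q
    df2 = m * s - p * q / 2.0 + 1.0
    lam_s = lam ** (1.0 / s)
    F = (1.0 - lam_s) / lam_s * df2 / df1
    pval = float(stats.f.sf(F, df1, df2))
    return ManovaResult(lam, float(F), float(df1), float(df2), pval)


@dataclass
class TopographyResult:
    ks_per_axis: dict  # axis -> (D, p)
    manova: ManovaResult
    medians: dict  # group -> axis -> median


def topography_battery(pop: Population, labels, *, tail: str = "two") -> TopographyResult:
    """Full battery: per-axis KS + 3-D MANOVA + per-group medians."""
    labels = np.asarray(labels)
    coords = pop.coords()
    groups = np.unique(labels)
    if len(groups) != 2:
        raise ValueError("the per-axis KS battery expects exactly two groups")
    ks = {}
    for i, axis in enumerate(AXES):
        a = coords[labels == groups[0], i]
        b = coords[labels == groups[1], i]
        ks[axis] = ks_two_sample(a, b, tail=tail)
    manova = manova_one_way(coords, labels)
    medians = {
        str(g): {axis: float(np.median(coords[labels == g, i])) for i, axis in enumerate(AXES)}
        for g in groups
    }
    return TopographyResult(ks, manova, medians)


@dataclass
class PermutationNull:
    p_values: np.ndarray  # per-permutation MANOVA p
    mean_p: float
    sd_p: float
    ks_p_values: dict  # axis -> array of per-permutation KS p
    observed: TopographyResult


def permutation_null(
    pop: Population,
    feature: str | np.ndarray,
    n_perm: int = 100,
    seed: int = 0,
    rng: np.random.Generator | None = None,
) -> PermutationNull:
    """Chance null for the topography battery.

    Each permutation reassigns the feature labels uniformly at random while
    preserving the observed label counts and leaving coordinates untouched;
    the full battery is rerun per permutation.
    """
    labels = pop.labels(feature) if isinstance(feature, str) else np.asarray(feature)
    if len(np.unique(labels)) < 2:
        raise ValueError("feature needs >= 2 levels")
    rng = rng if rng is not None else np.random.default_rng(seed)
    observed = topography_battery(pop, labels)
    ps = np.empty(n_perm)
    ks_ps = {axis: np.empty(n_perm) for axis in AXES}
    for i in range(n_perm):
        perm = rng.permutation(labels)
        res = topography_battery(pop, perm)
        ps[i] = res.manova.p
        for axis in AXES:
            ks_ps[axis][i] = res.ks_per_axis[axis][1]
    return PermutationNull(ps, float(ps.mean()), float(ps.std(ddof=0)), ks_ps, observed)


def compare_groups(a, b) -> tuple[float, tuple[float, float]]:
    """Cohen's d (pooled sd, n−1 denominators) plus a one-tailed KS test.

    d = (mean_a − mean_b)/s_pooled; NaN (flagged) when the pooled sd is 0.
    The KS tail tests ``a`` stochastically greater than ``b``.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("both samples need >= 2 observations")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    pooled = math.sqrt(((len(a) - 1) * va + (len(b) - 1) * vb) / (len(a) + len(b) - 2))
    d = (a.mean() - b.mean()) / pooled if pooled > 0 else float("nan")
    ks = ks_two_sample(a, b, tail="greater")
    return float(d), ks


# ---------------------------------------------------------------------------
# optimal sagittal view
# ---------------------------------------------------------------------------

def rotation_matrix(azimuth_deg: float, elevation_deg: float) -> np.ndarray:
    """View rotation: azimuth about the dorsoventral (z) axis, then
    elevation about the mediolateral (y) axis."""
    az = math.radians(azimuth_deg)
    el = math.radians(elevation_deg)
    rz = np.array(
        [[math.cos(az), -math.sin(az), 0.0], [math.sin(az), math.cos(az), 0.0], [0.0, 0.0, 1.0]]
    )
    ry = np.array(
        [[math.cos(el), 0.0, math.sin(el)], [0.0, 1.0, 0.0], [-math.sin(el), 0.0, math.cos(el)]]
    )
    return ry @ rz


@dataclass
class ViewSearchResult:
    azimuth_deg: float
    elevation_deg: float
    score: float
    score_grid: np.ndarray  # (n_azimuth, n_elevation)
    azimuth_grid: np.ndarray
    elevation_grid: np.ndarray
    transformed_coords: np.ndarray  # display only — never feeds statistics


def optimal_sagittal_view(
    pop: Population,
    azimuth_grid=None,
    elevation_grid=None,
    *,
    labels: str | np.ndarray = "subtype",
    score: str = "sum_d",
) -> ViewSearchResult:
    """Grid-search the view rotation maximizing subtype separation.

    For each (azimuth, elevation) the coordinate cloud is rotated and the
    per-axis two-sample KS statistics between the two subtype groups are
    aggregated — by default the sum of the three D statistics (monotone and
    scale-free); ``score="fisher"`` combines the three one-axis p-values
    with Fisher's method instead.  The returned transformed coordinates are
    for display only; all statistics elsewhere use raw coordinates.
    """
    azimuth_grid = np.asarray(
        azimuth_grid if azimuth_grid is not None else np.arange(-90.0, 91.0, 1.0)
    )
    elevation_grid = np.asarray(
        elevation_grid if elevation_grid is not None else np.arange(-90.0, 91.0, 1.0)
    )
    if azimuth_grid.size == 0 or elevation_grid.size == 0:
        raise ValueError("grids must be non-empty")
    lab = pop.labels(labels) if isinstance(labels, str) else np.asarray(labels)
    groups = [g for g in np.unique(lab) if g != "none"]
    if len(groups) != 2:
        raise ValueError("need exactly two subtype groups present")
    coords = pop.coords()
    mask_a = lab == groups[0]
    mask_b = lab == groups[1]

    grid = np.empty((len(azimuth_grid), len(elevation_grid)))
    for i, az in enumerate(azimuth_grid):
        for j, el in enumerate(elevation_grid):
            R = rotation_matrix(az, el)
            rc = coords @ R.T
            total = 0.0
            for k in range(3):
                d, p = ks_two_sample(rc[mask_a, k], rc[mask_b, k])
                if score == "fisher":
                    total += -2.0 * math.log(max(p, 1e-300))
                else:
                    total += d
            grid[i, j] = total
    i, j = np.unravel_index(np.argmax(grid), grid.shape)
    best_r = rotation_matrix(azimuth_grid[i], elevation_grid[j])
    return ViewSearchResult(
        float(azimuth_grid[i]),
        float(elevation_grid[j]),
        float(grid[i, j]),
        grid,
        azimuth_grid,
        elevation_grid,
        coords @ best_r.T,
    )
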