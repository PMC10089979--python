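"""ΔF/F extraction and directional classification of tilt responses.

The readout logic of tilt-in-place microscopy: the restoration step back to
horizontal is orders of magnitude faster than the calcium indicator's decay,
so fluorescence in the first second back at horizontal reports activity at
the preceding eccentric posture.  Each phase of the protocol gets its own
baseline window:

* nose-down: mean F of the initial 5-s horizontal baseline;
* nose-up:   mean F of the last 3 s of the nose-down response window
  (responses can stay elevated, so the immediately preceding window is the
  fair reference);
* impulse:   mean F of the 5 s immediately preceding the rotation.

Responsiveness is decided on *raw* fluorescence (first-second mean at least
2 baseline standard deviations above baseline, in at least two trials);
directional selectivity is quantified on ΔF/F via the directionality index
DI = (up − down)/(up + down) ∈ [−1, +1], with a selectivity threshold of
0.1 (≈22% difference in response magnitude).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .core import TrialSet
from .protocols import StimulusProtocol

__all__ = [
    "DffResponse",
    "NeuronClassification",
    "NonPositiveBaselineError",
    "phase_windows",
    "compute_dff",
    "classify_responsiveness",
    "directionality_index",
    "assign_subtype",
    "response_metrics",
    "impulse_residual",
    "classify_neuron",
    "classify_population",
    "DI_THRESHOLD",
]

DI_THRESHOLD = 0.1

TONIC_PHASES = ("nose_down", "nose_up")
IMPULSE_PHASES = ("impulse_1", "impulse_2")


class NonPositiveBaselineError(ValueError):
    """Baseline mean fluorescence is not positive; ΔF/F undefined."""


def first_second_frames(frame_rate: float) -> int:
    """Frames making up the 'first second' window: ``ceil(frame_rate)``."""
    return int(math.ceil(frame_rate - 1e-9))


def phase_windows(protocol: StimulusProtocol, phase: str) -> tuple[tuple[int, int], tuple[int, int]]:
    """(baseline, response) frame windows (half-open) for a phase.

    Tonic response windows are the 15-s horizontal segment following the
    eccentric hold (the restoration step opens the segment); impulse
    response windows are the 30 s following the restoration.
    """
    if phase in TONIC_PHASES:
        hold_hold = protocol.epoch(f"{phase}_hold")
        horiz_step = protocol.epoch(f"horizontal_after_{phase}_step")
        horiz_hold = protocol.epoch(f"horizontal_after_{phase}_hold")
        response = protocol.frame_window(horiz_step.start_s, horiz_hold.end_s)
        first = protocol.epochs[1].label.removesuffix("_step")  # first eccentric direction
        if phase == first:
            base_ep = protocol.epoch("baseline")
            baseline = protocol.frame_window(base_ep.start_s, base_ep.end_s)
        else:
            # last 3 s of the *previous* direction's response window
            prev_horiz = protocol.epoch(f"horizontal_after_{first}_hold")
            baseline = protocol.frame_window(prev_horiz.end_s - 3.0, prev_horiz.end_s)
        return baseline, response
    if phase in IMPULSE_PHASES:
        rot = protocol.epoch(f"{phase}_rotation")
        rest = protocol.epoch(f"{phase}_restoration")
        baseline = protocol.frame_window(rot.start_s - 5.0, rot.start_s)
        response = protocol.frame_window(rest.end_s, rest.end_s + 30.0)
        return baseline, response
    raise KeyError(f"unknown phase {phase!r}")


@dataclass
class DffResponse:
    """ΔF/F of one phase: per-trial series plus the trial-mean series."""

    phase: str
    baseline_value: float
    dff_trials: np.ndarray  # (n_trials, n_window_frames)
    frame_rate: float

    @property
    def dff_series(self) -> np.ndarray:
        """Mean ΔF/F across trials (the unit of all downstream analysis)."""
        return self.dff_trials.mean(axis=0)

    @property
    def mean_first_second(self) -> float:
        k = first_second_frames(self.frame_rate)
        return float(self.dff_series[:k].mean())

    @property
    def peak(self) -> float:
        return float(self.dff_series.max())

    @property
    def integral(self) -> float:
        """Trapezoidal integral of the first-second window, unit frame spacing."""
        k = first_second_frames(self.frame_rate)
        return float(np.trapezoid(self.dff_series[:k]))


def compute_dff(
    trials: TrialSet, protocol: StimulusProtocol, phase: str
) -> DffResponse:
    """ΔF/F(t) = (F(t) − B)/B over the phase's response window.

    Raises :class:`NonPositiveBaselineError` when any trial's baseline mean
    is ≤ 0 (the neuron is flagged upstream, never silently dropped).
    """
    (b_lo, b_hi), (r_lo, r_hi) = phase_windows(protocol, phase)
    if b_hi <= b_lo:
        raise NonPositiveBaselineError(f"empty baseline window for phase {phase!r}")
    F = trials.trials
    B = F[:, b_lo:b_hi].mean(axis=1)
    if np.any(B <= 0):
        raise NonPositiveBaselineError(
            f"non-positive baseline for neuron {trials.neuron_id}, phase {phase!r}"
        )
    dff = (F[:, r_lo:r_hi] - B[:, None]) / B[:, None]
    return DffResponse(phase, float(B.mean()), dff, trials.frame_rate)


def classify_responsiveness(
    trials: TrialSet,
    protocol: StimulusProtocol,
    phase: str,
    *,
    n_sd: float = 2.0,
    min_trials: int = 2,
) -> tuple[bool, str]:
    """Responsiveness on raw fluorescence + response-pattern label.

    Responsive iff, in at least ``min_trials`` trials, the mean raw F over
    the first second of the response window is at least ``n_sd`` baseline
    standard deviations above the baseline mean.  Patterns (on the
    trial-mean ΔF/F): ``excitation`` — first-second criterion met and peak
    within the first 3 s; ``suppression_recovery`` — an early dip at least
    ``n_sd`` baseline sd below baseline followed by an above-baseline final
    5-s mean; else ``none``.
    """
    if trials.n_trials < min_trials:
        raise ValueError(f"need >= {min_trials} trials")
    (b_lo, b_hi), (r_lo, r_hi) = phase_windows(protocol, phase)
    F = trials.trials
    k = first_second_frames(trials.frame_rate)
    base = F[:, b_lo:b_hi]
    mu, sd = base.mean(axis=1), base.std(axis=1, ddof=0)
    first_sec = F[:, r_lo : r_lo + k].mean(axis=1)
    n_exc = int(np.sum(first_sec > mu + n_sd * sd))  # strictly greater: a flat
    # trace with zero baseline variance is unresponsive, not an error
    responsive = n_exc >= min_trials

    # pattern on trial means (raw F, same units as the criterion)
    resp_mean = F[:, r_lo:r_hi].mean(axis=0)
    mu_m, sd_m = float(base.mean()), float(base.std(ddof=0))
    fr = trials.frame_rate
    k3 = int(math.ceil(3 * fr - 1e-9))
    k5 = int(math.ceil(5 * fr - 1e-9))
    if responsive:
        # the 2-sd first-second criterion is excitatory by construction;
        # peaks essentially always fall in the first 3 s for this indicator
        return True, "excitation"
    dip = resp_mean[:k3].min() <= mu_m - n_sd * sd_m
    recovered = resp_mean[-k5:].mean() > mu_m
    if dip and recovered:
        return False, "suppression_recovery"
    return False, "none"


def directionality_index(dff_up: float, dff_down: float) -> float:
    """DI = (up − down)/(up + down) on excitatory ΔF/F magnitudes.

    Inputs are floored at 0 (suppression contributes no excitatory
    magnitude), keeping DI within [−1, +1]: −1 is exclusive nose-down
    selectivity, +1 exclusive nose-up, 0 equal responses.  Returns NaN when
    both magnitudes are zero (DI undefined; subtype is then ``none``).
    """
    up = max(float(dff_up), 0.0)
    down = max(float(dff_down), 0.0)
    total = up + down
    if total == 0.0:
        return float("nan")
    return (up - down) / total


def assign_subtype(di: float, threshold: float = DI_THRESHOLD) -> str:
    """nose_up if DI > threshold, nose_down if DI < −threshold, else none."""
    if threshold < 0:
        raise ValueError("threshold must be non-negative")
    if not np.isfinite(di):
        return "none"
    if di > threshold:
        return "nose_up"
    if di < -threshold:
        return "nose_down"
    return "none"


@dataclass
class ResponseMetrics:
    mean_first_second: float
    integral: float
    cv: float  # NaN when undefined
    consistent: bool


def response_metrics(
    dff_trials: np.ndarray, frame_rate: float, *, literal_cv: bool = False
) -> ResponseMetrics:
    """Per-phase summary over stimulus repeats.

    ``cv`` is the coefficient of variation of per-trial first-second mean
    ΔF/F across repeats, sd/mean by default (``literal_cv`` flips to
    mean/sd).  ``consistent`` is True when every repeat's first-second mean
    has the same sign.
    """
    dff_trials = np.asarray(dff_trials, dtype=float)
    if dff_trials.ndim != 2 or dff_trials.shape[0] < 2:
        raise ValueError("need >= 2 trials")
    k = first_second_frames(frame_rate)
    per_trial = dff_trials[:, :k].mean(axis=1)
    mean_fs = float(per_trial.mean())
    integral = float(np.trapezoid(dff_trials.mean(axis=0)[:k]))
    sd = float(per_trial.std(ddof=0))  # population sd over the few repeats
    if literal_cv:
        cv = mean_fs / sd if sd != 0 else float("nan")
    else:
        cv = sd / mean_fs if mean_fs != 0 else float("nan")
    signs = np.sign(per_trial)
    consistent = bool(np.all(signs == signs[0]))
    return ResponseMetrics(mean_fs, integral, cv, consistent)


def impulse_residual(
    tonic_dff: np.ndarray, impulse_dff: np.ndarray, frame_rate: float
) -> tuple[np.ndarray, float]:
    """residual(t) = tonic(t) − impulse(t) on a common window.

    The fraction is the ratio of the residual's first-second mean to the
    tonic first-second mean: the share of the tonic response *not*
    explained by the rapid restoration step.  NaN when the tonic mean is 0.
    """
    tonic = np.asarray(tonic_dff, dtype=float)
    imp = np.asarray(impulse_dff, dtype=float)
    n = min(tonic.shape[-1], imp.shape[-1])
    residual = tonic[..., :n] - imp[..., :n]
    k = first_second_frames(frame_rate)
    tonic_mean = float(tonic[..., :k].mean())
    if tonic_mean == 0:
        return residual, float("nan")
    return residual, float(residual[..., :k].mean()) / tonic_mean


@dataclass
class NeuronClassification:
    """Full classification record for one neuron."""

    neuron_id: int
    responsive_per_phase: dict = field(default_factory=dict)
    pattern_per_phase: dict = field(default_factory=dict)
    cv_per_phase: dict = field(default_factory=dict)
    mean_dff_per_phase: dict = field(default_factory=dict)
    directionality_index: float = float("nan")
    subtype: str = "none"
    consistent: bool = True
    impulse_responsive: bool = False
    exclusion_code: str = ""  # "" = retained


def classify_neuron(
    tonic: TrialSet,
    tonic_protocol: StimulusProtocol,
    impulse: Optional[TrialSet] = None,
    impulse_protocol: Optional[StimulusProtocol] = None,
    *,
    threshold: float = DI_THRESHOLD,
    literal_cv: bool = False,
) -> NeuronClassification:
    """Run the full per-neuron classification chain.

    Neurons failing baseline positivity or repeat-consistency are retained
    with an ``exclusion_code`` rather than dropped.
    """
    out = NeuronClassification(neuron_id=tonic.neuron_id)
    dff: dict[str, DffResponse] = {}
    try:
        for phase in TONIC_PHASES:
            resp, pattern = classify_responsiveness(tonic, tonic_protocol, phase)
            out.responsive_per_phase[phase] = resp
            out.pattern_per_phase[phase] = pattern
            dff[phase] = compute_dff(tonic, tonic_protocol, phase)
            m = response_metrics(dff[phase].dff_trials, tonic.frame_rate, literal_cv=literal_cv)
            out.cv_per_phase[phase] = m.cv
            out.mean_dff_per_phase[phase] = m.mean_first_second
    except NonPositiveBaselineError:
        out.exclusion_code = "non_positive_baseline"
        return out

    # DI on excitatory magnitudes: unresponsive phases contribute 0
    up = out.mean_dff_per_phase["nose_up"] if out.responsive_per_phase["nose_up"] else 0.0
    down = out.mean_dff_per_phase["nose_down"] if out.responsive_per_phase["nose_down"] else 0.0
    out.directionality_index = directionality_index(up, down)
    out.subtype = assign_subtype(out.directionality_index, threshold)

    # consistency: per-trial DI sign stable across repeats
    k = first_second_frames(tonic.frame_rate)
    per_up = np.maximum(dff["nose_up"].dff_trials[:, :k].mean(axis=1), 0.0)
    per_down = np.maximum(dff["nose_down"].dff_trials[:, :k].mean(axis=1), 0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        per_di = (per_up - per_down) / (per_up + per_down)
    finite = np.isfinite(per_di)
    if out.subtype != "none" and finite.sum() >= 2:
        signs = np.sign(per_di[finite])
        out.consistent = bool(np.all(signs == signs[0]))
        if not out.consistent:
            out.exclusion_code = "inconsistent_direction"

    if impulse is not None and impulse_protocol is not None:
        for phase in IMPULSE_PHASES:
            resp, pattern = classify_responsiveness(impulse, impulse_protocol, phase)
            out.responsive_per_phase[phase] = resp
            out.pattern_per_phase[phase] = pattern
            try:
                d = compute_dff(impulse, impulse_protocol, phase)
                out.mean_dff_per_phase[phase] = d.mean_first_second
            except NonPositiveBaselineError:
                out.mean_dff_per_phase[phase] = float("nan")
        out.impulse_responsive = any(
            out.responsive_per_phase[p] for p in IMPULSE_PHASES
        )
    return out


def classify_population(
    trialsets: list[TrialSet],
    tonic_protocol: StimulusProtocol,
    impulse_sets: Optional[list[TrialSet]] = None,
    impulse_protocol: Optional[StimulusProtocol] = None,
    *,
    threshold: float = DI_THRESHOLD,
) -> pd.DataFrame:
    """Classification table for a list of neurons (one row per neuron)."""
    impulse_by_id = {t.neuron_id: t for t in impulse_sets} if impulse_sets else {}
    rows = []
    for ts in trialsets:
        c = classify_neuron(
            ts,
            tonic_protocol,
            impulse_by_id.get(ts.neuron_id),
            impulse_protocol,
            threshold=threshold,
        )
        rows.append(
            {
                "neuron_id": c.neuron_id,
                "DI": c.directionality_index,
                "subtype": c.subtype,
                "pattern_down": c.pattern_per_phase.get("nose_down", "none"),
                "pattern_up": c.pattern_per_phase.get("nose_up", "none"),
                "cv_down": c.cv_per_phase.get("nose_down", float("nan")),
                "cv_up": c.cv_per_phase.get("nose_up", float("nan")),
                "mean_dff_down": c.mean_dff_per_phase.get("nose_down", float("nan")),
                "mean_dff_up": c.mean_dff_per_phase.get("nose_up", float("nan")),
                "impulse_responsive": c.impulse_responsive,
                "exclusion_code": c.exclusion_code,
            }
        )
    return pd.DataFrame(rows)
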