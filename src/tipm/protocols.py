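"""Pitch-tilt stimulus protocols.

Two paradigms drive the whole pipeline:

* the *tonic* protocol — hold the larva at an eccentric pitch angle for
  15 s, restore to horizontal in a 4 ms galvanometer step, and read out
  calcium fluorescence in the 15 s horizontal window that follows;
* the *impulse* protocol — 10 ms there-and-back rotations (4 ms step,
  2 ms eccentric hold, 4 ms restoration) that isolate the contribution of
  the rapid step itself from the tonic posture response.

Epochs tile the protocol with no gaps or overlaps.  Epoch boundaries map to
frame indices by ``floor(time * frame_rate)`` so that window extraction is
reproducible at any acquisition rate (3 frames/s two-photon, 5 volumes/s
volumetric).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from typing import Sequence

__all__ = [
    "Epoch",
    "StimulusProtocol",
    "build_tonic_protocol",
    "build_impulse_protocol",
    "STEP_DURATION_S",
]

#: Duration of one "instantaneous" galvanometer step.
STEP_DURATION_S = 0.004

#: Default eccentric pitch angle (degrees); positive = nose-up.
DEFAULT_ANGLE_DEG = 19.0

MAX_ANGLE_DEG = 19.0  # galvanometer mechanical limit is +/-20 deg; stimuli use 19


class ProtocolError(ValueError):
    """Invalid protocol configuration."""


@dataclass(frozen=True)
class Epoch:
    """One contiguous protocol segment.

    ``angle_deg`` is the platform angle held (or reached, for step epochs)
    during the segment.
    """

    label: str
    start_s: float
    duration_s: float
    angle_deg: float

    @property
    def end_s(self) -> float:
        return self.start_s + self.duration_s


@dataclass(frozen=True)
class StimulusProtocol:
    """An ordered, gap-free tiling of labelled epochs."""

    name: str
    epochs: tuple[Epoch, ...]
    frame_rate: float = 3.0
    repeats: int = 3

    def __post_init__(self) -> None:
        if self.frame_rate <= 0:
            raise ProtocolError("frame_rate must be positive")
        t = 0.0
        for ep in self.epochs:
            if ep.duration_s < 0:
                raise ProtocolError(f"negative duration in epoch {ep.label!r}")
            if abs(ep.angle_deg) > MAX_ANGLE_DEG + 1e-9:
                raise ProtocolError(
                    f"epoch {ep.label!r} angle {ep.angle_deg} exceeds +/-{MAX_ANGLE_DEG} deg"
                )
            if abs(ep.start_s - t) > 1e-9:
                raise ProtocolError(f"epoch {ep.label!r} does not tile (gap/overlap at {t} s)")
            t = ep.end_s

    @property
    def duration_s(self) -> float:
        return self.epochs[-1].end_s if self.epochs else 0.0

    @property
    def n_frames(self) -> int:
        """Total frame count: ``floor(duration * frame_rate)``."""
        return int(math.floor(self.duration_s * self.frame_rate + 1e-9))

    def epoch(self, label: str) -> Epoch:
        for ep in self.epochs:
            if ep.label == label:
                return ep
        raise KeyError(label)

    def frame_window(self, start_s: float, end_s: float) -> tuple[int, int]:
        """Half-open frame-index window for the time interval [start, end)."""
        lo = int(math.floor(start_s * self.frame_rate + 1e-9))
        hi = int(math.floor(end_s * self.frame_rate + 1e-9))
        return lo, hi

    def angle_at(self, t: float) -> float:
        """Platform angle at time ``t`` (last epoch wins at boundaries)."""
        for ep in self.epochs:
            if ep.start_s <= t < ep.end_s:
                return ep.angle_deg
        return self.epochs[-1].angle_deg if self.epochs else 0.0

    # -- serialization -----------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "frame_rate": self.frame_rate,
            "repeats": self.repeats,
            "epochs": [asdict(ep) for ep in self.epochs],
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def from_dict(cls, d: dict) -> "StimulusProtocol":
        return cls(
            name=d["name"],
            epochs=tuple(Epoch(**e) for e in d["epochs"]),
            frame_rate=d.get("frame_rate", 3.0),
            repeats=d.get("repeats", 3),
        )

    @classmethod
    def from_json(cls, path) -> "StimulusProtocol":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def build_tonic_protocol(
    angle: float = DEFAULT_ANGLE_DEG,
    hold: float = 15.0,
    baseline: float = 5.0,
    *,
    frame_rate: float = 3.0,
    repeats: int = 3,
    invert_order: bool = False,
    step: float = STEP_DURATION_S,
    validate: bool = True,
) -> StimulusProtocol:
    """Tonic pitch-tilt protocol.

    Layout (defaults): 5 s horizontal baseline, then four 15-s segments —
    nose-down hold, horizontal, nose-up hold, horizontal — each opened by a
    4 ms galvanometer step (the step occupies the first 4 ms of its
    segment, so the total is exactly ``baseline + 4*hold`` = 65 s).
    Nose-down is presented first unless ``invert_order``.
    """
    if validate and (hold <= 0 or baseline <= 0):
        raise ProtocolError("hold and baseline durations must be positive")
    if not (0 < angle <= MAX_ANGLE_DEG + 1e-9):
        raise ProtocolError(f"angle must lie in (0, {MAX_ANGLE_DEG}]")
    first, second = ("nose_down", "nose_up") if not invert_order else ("nose_up", "nose_down")
    sign = {"nose_down": -1.0, "nose_up": +1.0}

    epochs: list[Epoch] = [Epoch("baseline", 0.0, baseline, 0.0)]
    t = baseline

    def segment(label: str, target: float, total: float) -> None:
        nonlocal t
        if total <= 0:
            return
        s = min(step, total)
        epochs.append(Epoch(f"{label}_step", t, s, target))
        if total - s > 0:
            epochs.append(Epoch(f"{label}_hold", t + s, total - s, target))
        t += total

    segment(first, sign[first] * angle, hold)
    segment(f"horizontal_after_{first}", 0.0, hold)
    segment(second, sign[second] * angle, hold)
    segment(f"horizontal_after_{second}", 0.0, hold)

    return StimulusProtocol("tonic", tuple(epochs), frame_rate=frame_rate, repeats=repeats)


def build_impulse_protocol(
    angle: float = DEFAULT_ANGLE_DEG,
    *,
    frame_rate: float = 3.0,
    repeats: int = 3,
    onsets: Sequence[float] = (20.0, 50.0),
    window: float = 30.0,
    step: float = STEP_DURATION_S,
    hold: float = 0.002,
) -> StimulusProtocol:
    """Impulse protocol: two 10 ms there-and-back rotations.

    Impulse 1 (down-then-up) at 20 s and impulse 2 (up-then-down) at 50 s,
    each 4 ms rotation + 2 ms eccentric hold + 4 ms restoration and each
    followed by a 30-s horizontal imaging window.  ``angle == 0`` gives a
    null (flat) stimulus for control analyses.
    """
    if len(onsets) != 2 or onsets[1] <= onsets[0]:
        raise ProtocolError("expected two increasing impulse onsets")
    directions = (-1.0, +1.0)  # down-first, then up-first
    epochs: list[Epoch] = []
    t = 0.0
    for i, (onset, sgn) in enumerate(zip(onsets, directions), start=1):
        if onset > t:
            label = "baseline" if i == 1 else f"horizontal_after_impulse_{i - 1}"
            epochs.append(Epoch(label, t, onset - t, 0.0))
            t = onset
        epochs.append(Epoch(f"impulse_{i}_rotation", t, step, sgn * angle))
        epochs.append(Epoch(f"impulse_{i}_hold", t + step, hold, sgn * angle))
        epochs.append(Epoch(f"impulse_{i}_restoration", t + step + hold, step, 0.0))
        t += 2 * step + hold
    epochs.append(Epoch("horizontal_after_impulse_2", t, window, 0.0))
    return StimulusProtocol("impulse", tuple(epochs), frame_rate=frame_rate, repeats=repeats)


def impulse_duration_s(protocol: StimulusProtocol, which: int = 1) -> float:
    """Total duration of one impulse (rotation + hold + restoration)."""
    labels = [f"impulse_{which}_{part}" for part in ("rotation", "hold", "restoration")]
    return sum(protocol.epoch(lbl).duration_s for lbl in labels)
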