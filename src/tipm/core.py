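"""Core domain containers shared across the pipeline.

Coordinate convention (used by every reader/writer):

* ``x_rc_um`` — rostrocaudal, rostral = 0, increasing caudal (μm);
* ``y_ml_um`` — mediolateral distance from the midline, non-negative so
  the two hemispheres pool without mirroring (μm);
* ``z_dv_um`` — dorsoventral, ventral = 0, increasing dorsal (μm).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .protocols import StimulusProtocol

__all__ = ["NeuronRecord", "Population", "TrialSet", "POPULATION_COLUMNS", "AXES"]

AXES = ("x_rc_um", "y_ml_um", "z_dv_um")

POPULATION_COLUMNS = [
    "neuron_id",
    "fish_id",
    "hemisphere",
    "x_rc_um",
    "y_ml_um",
    "z_dv_um",
    "birth_hpf",
    "cohort",
    "subtype",
]


@dataclass
class NeuronRecord:
    """One projection neuron: soma position, birthdate and tuning labels."""

    neuron_id: int
    fish_id: int
    hemisphere: str
    x_rc_um: float
    y_ml_um: float
    z_dv_um: float
    birth_hpf: float
    cohort: str  # "early" | "late"
    subtype: str  # "nose_up" | "nose_down" | "none"
    impulse_responsive: bool = False
    response_pattern: str = "excitation"  # or "suppression_recovery" / "none"
    true_di: float = 0.0  # generator ground truth, used by recovery tests

    @property
    def xyz(self) -> np.ndarray:
        return np.array([self.x_rc_um, self.y_ml_um, self.z_dv_um])


@dataclass
class Population:
    """A collection of neurons plus reference-frame metadata.

    The canonical tabular form is :meth:`to_frame`; all topography
    statistics operate on that table.
    """

    neurons: list[NeuronRecord]
    frame_metadata: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.neurons)

    def coords(self) -> np.ndarray:
        """(n, 3) array of soma coordinates in μm."""
        return np.array([[n.x_rc_um, n.y_ml_um, n.z_dv_um] for n in self.neurons])

    def labels(self, field_name: str) -> np.ndarray:
        return np.array([getattr(n, field_name) for n in self.neurons])

    def subset(self, mask) -> "Population":
        mask = np.asarray(mask)
        return Population(
            [n for n, keep in zip(self.neurons, mask) if keep], dict(self.frame_metadata)
        )

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "neuron_id": n.neuron_id,
                "fish_id": n.fish_id,
                "hemisphere": n.hemisphere,
                "x_rc_um": n.x_rc_um,
                "y_ml_um": n.y_ml_um,
                "z_dv_um": n.z_dv_um,
                "birth_hpf": n.birth_hpf,
                "cohort": n.cohort,
                "subtype": n.subtype,
            }
            for n in self.neurons
        ]
        return pd.DataFrame(rows, columns=POPULATION_COLUMNS)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, frame_metadata: Optional[dict] = None) -> "Population":
        neurons = [
            NeuronRecord(
                neuron_id=int(r.neuron_id),
                fish_id=int(r.fish_id),
                hemisphere=str(r.hemisphere),
                x_rc_um=float(r.x_rc_um),
                y_ml_um=float(r.y_ml_um),
                z_dv_um=float(r.z_dv_um),
                birth_hpf=float(r.birth_hpf),
                cohort=str(r.cohort),
                subtype=str(r.subtype),
            )
            for r in df.itertuples()
        ]
        return cls(neurons, frame_metadata or {})


@dataclass
class TrialSet:
    """Raw fluorescence trials for one neuron under one protocol.

    ``trials`` has shape (n_trials, n_frames); fluorescence is in arbitrary
    units and non-negative.  All trials share the protocol's frame count.
    """

    neuron_id: int
    protocol: StimulusProtocol
    trials: np.ndarray
    frame_rate: float

    def __post_init__(self) -> None:
        self.trials = np.asarray(self.trials, dtype=float)
        if self.trials.ndim != 2:
            raise ValueError("trials must be a 2-D (n_trials, n_frames) array")
        expected = self.protocol.n_frames
        if self.trials.shape[1] != expected:
            raise ValueError(
                f"trial length {self.trials.shape[1]} != protocol frames {expected}"
            )
        if (self.trials < 0).any():
            raise ValueError("fluorescence must be non-negative")

    @property
    def n_trials(self) -> int:
        return self.trials.shape[0]

    def to_frame(self) -> pd.DataFrame:
        n_tr, n_fr = self.trials.shape
        return pd.DataFrame(
            {
                "neuron_id": np.repeat(self.neuron_id, n_tr * n_fr),
                "trial": np.repeat(np.arange(n_tr), n_fr),
                "frame": np.tile(np.arange(n_fr), n_tr),
                "F": self.trials.ravel(),
            }
        )
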