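"""Afferent tuning from a traced synapse graph.

The graph has three layers: utricular hair cells (each with a unit
orientation vector for its preferred deflection), vestibular afferents
(utricular, or semicircular-canal afferents identified by end organ), and
projection neurons.  Utricular afferent tuning is the synapse-count-
weighted vector sum of the hair cells it receives ribbon synapses from;
canal afferent tuning follows from canal identity.  The direction-match
audit asks whether the canal and utricular routes onto each projection
neuron agree on vertical direction.

The anterior/posterior-canal ↔ nose-up/nose-down mapping is stated in two
mutually incompatible ways in the literature this models; both conventions
are exposed (``"results"``: anterior → nose-up, the default;
``"methods"``: anterior → nose-down) and neither is hard-coded as correct.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd

__all__ = [
    "HairCell",
    "Afferent",
    "ProjectionNeuronNode",
    "ConnectomeGraph",
    "TuningVector",
    "afferent_tuning",
    "canal_direction_map",
    "projection_inputs",
    "tuning_match",
    "CANAL_CONVENTIONS",
]

END_ORGANS = ("utricle", "anterior_canal", "posterior_canal", "horizontal_canal")

CANAL_CONVENTIONS = {
    "results": {"anterior_canal": "nose_up", "posterior_canal": "nose_down"},
    "methods": {"anterior_canal": "nose_down", "posterior_canal": "nose_up"},
}

#: |vertical component| must exceed this fraction of the vector norm to
#: classify; below it the class is indeterminate (configurable guard
#: against sign flips from near-horizontal tuning).
VERTICAL_THRESHOLD = 0.1


@dataclass(frozen=True)
class HairCell:
    id: str
    orientation: np.ndarray  # 3-D unit vector

    def __post_init__(self) -> None:
        v = np.asarray(self.orientation, dtype=float)
        object.__setattr__(self, "orientation", v)
        if abs(np.linalg.norm(v) - 1.0) > 1e-9:
            raise ValueError(f"hair cell {self.id}: orientation must be unit norm")


@dataclass(frozen=True)
class Afferent:
    id: str
    end_organ: str

    def __post_init__(self) -> None:
        if self.end_organ not in END_ORGANS:
            raise ValueError(f"unknown end organ {self.end_organ!r}")


@dataclass(frozen=True)
class ProjectionNeuronNode:
    id: str
    xyz_um: np.ndarray


@dataclass
class ConnectomeGraph:
    """Bipartite-layered synapse graph with count-weighted edges.

    Edges run hair_cell → afferent or afferent → projection_neuron only;
    every synapse count is >= 1.
    """

    hair_cells: list[HairCell]
    afferents: list[Afferent]
    projection_neurons: list[ProjectionNeuronNode]
    edges: list[tuple[str, str, int]]  # (pre, post, synapse_count)

    def __post_init__(self) -> None:
        hc = {h.id for h in self.hair_cells}
        aff = {a.id for a in self.afferents}
        pn = {n.id for n in self.projection_neurons}
        for pre, post, count in self.edges:
            if count < 1:
                raise ValueError(f"edge {pre}->{post}: synapse_count must be >= 1")
            ok = (pre in hc and post in aff) or (pre in aff and post in pn)
            if not ok:
                raise ValueError(
                    f"edge {pre}->{post}: only hair_cell->afferent and "
                    "afferent->projection_neuron edges are allowed"
                )

    # -- lookups -----------------------------------------------------------

    def hair_cell(self, hc_id: str) -> HairCell:
        return next(h for h in self.hair_cells if h.id == hc_id)

    def afferent(self, aff_id: str) -> Afferent:
        return next(a for a in self.afferents if a.id == aff_id)

    def edges_onto(self, post_id: str) -> list[tuple[str, int]]:
        return [(pre, c) for pre, post, c in self.edges if post == post_id]

    def to_networkx(self):
        import networkx as nx

        g = nx.DiGraph()
        for h in self.hair_cells:
            g.add_node(h.id, kind="hair_cell", orientation=tuple(h.orientation))
        for a in self.afferents:
            g.add_node(a.id, kind="afferent", end_organ=a.end_organ)
        for n in self.projection_neurons:
            g.add_node(n.id, kind="projection_neuron", xyz=tuple(np.asarray(n.xyz_um)))
        for pre, post, c in self.edges:
            g.add_edge(pre, post, synapse_count=c)
        return g

    # -- serialization -----------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "hair_cells": [
                {"id": h.id, "orientation": [float(x) for x in h.orientation]}
                for h in self.hair_cells
            ],
            "afferents": [{"id": a.id, "end_organ": a.end_organ} for a in self.afferents],
            "neurons": [
                {"id": n.id, "xyz": [float(x) for x in np.asarray(n.xyz_um)]}
                for n in self.projection_neurons
            ],
            "edges": [{"pre": p, "post": q, "count": c} for p, q, c in self.edges],
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def from_dict(cls, d: dict) -> "ConnectomeGraph":
        return cls(
            [HairCell(h["id"], np.asarray(h["orientation"], float)) for h in d["hair_cells"]],
            [Afferent(a["id"], a["end_organ"]) for a in d["afferents"]],
            [ProjectionNeuronNode(n["id"], np.asarray(n["xyz"], float)) for n in d["neurons"]],
            [(e["pre"], e["post"], int(e["count"])) for e in d["edges"]],
        )

    @classmethod
    def from_json(cls, path) -> "ConnectomeGraph":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))

    def edge_list_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.edges, columns=["pre", "post", "synapse_count"])


@dataclass
class TuningVector:
    """Weighted-vector-sum tuning of one afferent."""

    direction: np.ndarray | None  # unit vector, or None for a zero-norm sum
    magnitude: float  # summed synapse weight
    vertical_class: str  # "nose_up" | "nose_down" | "indeterminate"


def canal_direction_map(end_organ: str, convention: str = "results") -> str:
    """Vertical class implied by canal identity under a naming convention.

    The horizontal canal makes no contacts onto these neurons and is
    mapped to ``indeterminate``.
    """
    if end_organ not in END_ORGANS or end_organ == "utricle":
        raise ValueError(f"not a canal end organ: {end_organ!r}")
    if end_organ == "horizontal_canal":
        return "indeterminate"
    try:
        return CANAL_CONVENTIONS[convention][end_organ]
    except KeyError:
        raise ValueError(f"unknown convention {convention!r}") from None


def _classify_vertical(v: np.ndarray, threshold: float = VERTICAL_THRESHOLD) -> str:
    n = np.linalg.norm(v)
    if n == 0 or abs(v[2]) < threshold * n:
        return "indeterminate"
    return "nose_up" if v[2] > 0 else "nose_down"


def afferent_tuning(
    afferent_id: str,
    graph: ConnectomeGraph,
    *,
    convention: str = "results",
    vertical_threshold: float = VERTICAL_THRESHOLD,
) -> TuningVector:
    """Tuning of one afferent.

    Utricular: synapse-count-weighted vector sum of its hair cells'
    orientation vectors, normalized (invariant to uniform count scaling).
    Canal: class from end-organ identity; no direction vector.
    """
    aff = graph.afferent(afferent_id)
    if aff.end_organ != "utricle":
        cls = canal_direction_map(aff.end_organ, convention)
        total = float(sum(c for _, c in graph.edges_onto(afferent_id)))
        return TuningVector(None, total, cls)
    contacts = graph.edges_onto(afferent_id)
    if not contacts:
        raise ValueError(f"utricular afferent {afferent_id} has no hair-cell contacts")
    vec = np.zeros(3)
    total = 0.0
    for hc_id, count in contacts:
        vec += count * graph.hair_cell(hc_id).orientation
        total += count
    norm = np.linalg.norm(vec)
    if norm < 1e-12:
        return TuningVector(None, total, "indeterminate")
    unit = vec / norm
    return TuningVector(unit, total, _classify_vertical(unit, vertical_threshold))


def projection_inputs(
    graph: ConnectomeGraph, *, convention: str = "results"
) -> pd.DataFrame:
    """Per-projection-neuron input summary.

    Columns: canal/utricular synapse counts (weights summed over edges) and
    the vertical class carried by each input route.  A route's class is the
    count-weighted consensus of its afferents (ties → indeterminate).
    """
    tunings = {a.id: afferent_tuning(a.id, graph, convention=convention) for a in graph.afferents}
    organs = {a.id: a.end_organ for a in graph.afferents}
    rows = []
    for pn in graph.projection_neurons:
        counts = {"canal": 0, "utricle": 0}
        votes: dict[str, dict[str, float]] = {
            "canal": {"nose_up": 0.0, "nose_down": 0.0},
            "utricle": {"nose_up": 0.0, "nose_down": 0.0},
        }
        for aff_id, count in graph.edges_onto(pn.id):
            route = "utricle" if organs[aff_id] == "utricle" else "canal"
            counts[route] += count
            cls = tunings[aff_id].vertical_class
            if cls in votes[route]:
                votes[route][cls] += count

        def consensus(route: str) -> str:
            up, down = votes[route]["nose_up"], votes[route]["nose_down"]
            if up == down == 0:
                return "none"
            if up == down:
                return "indeterminate"
            return "nose_up" if up > down else "nose_down"

        rows.append(
            {
                "neuron_id": pn.id,
                "canal_synapses": counts["canal"],
                "utricular_synapses": counts["utricle"],
                "canal_class": consensus("canal"),
                "utricular_class": consensus("utricle"),
            }
        )
    return pd.DataFrame(rows)


def tuning_match(
    graph: ConnectomeGraph, *, convention: str = "results"
) -> tuple[pd.DataFrame, float]:
    """Audit canal-vs-utricular direction agreement per projection neuron.

    Only neurons receiving both canal and utricular input enter the
    matched fraction; indeterminate classes exclude a neuron with a flag.
    The audit is symmetric in which modality is treated as reference.
    """
    summary = projection_inputs(graph, convention=convention)
    matches = []
    flags = []
    for r in summary.itertuples():
        if r.canal_synapses == 0 or r.utricular_synapses == 0:
            matches.append(None)
            flags.append("missing_modality")
        elif "indeterminate" in (r.canal_class, r.utricular_class) or "none" in (
            r.canal_class,
            r.utricular_class,
        ):
            matches.append(None)
            flags.append("indeterminate")
        else:
            matches.append(r.canal_class == r.utricular_class)
            flags.append("")
    summary = summary.assign(match=matches, flag=flags)
    valid = summary["match"].dropna()
    fraction = float(valid.mean()) if len(valid) else float("nan")
    return summary, fraction
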