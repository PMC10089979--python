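"""Seedable generators for every input the pipeline consumes.

The generators emulate the statistical structure the downstream analyses
assume: 3-D soma positions whose distributions depend on directional
subtype and birthdate (early/nose-up somata dorsomedial, late/nose-down
ventrolateral, partially overlapping), slow-indicator calcium trial traces
under the tonic and impulse protocols, hair-cell → afferent → projection-
neuron synapse graphs with orientation vectors and synapse counts, and
three-phase varicosity growth series.  Every generator draws from a
:func:`substream` of a single run seed, so fixed seed ⇒ bit-identical
outputs and per-stage reruns reproduce in isolation.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .core import NeuronRecord, Population, TrialSet
from .connectome import Afferent, ConnectomeGraph, HairCell, ProjectionNeuronNode
from .protocols import StimulusProtocol

__all__ = [
    "SimConfig",
    "ConnectomeConfig",
    "VaricosityConfig",
    "VaricositySeries",
    "InvalidConfigError",
    "substream",
    "simulate_population",
    "simulate_trials",
    "simulate_connectome",
    "simulate_varicosity_series",
]


class InvalidConfigError(ValueError):
    """Generator configuration violates an invariant."""


def substream(seed: int, name: str) -> np.random.Generator:
    """Named, independent RNG substream derived from the single run seed."""
    key = zlib.crc32(name.encode())
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(key,)))


# ---------------------------------------------------------------------------
# population / trials
# ---------------------------------------------------------------------------

def _default_spatial_model() -> dict:
    """Per-subtype 3-D Gaussians (μm), partially overlapping.

    The nucleus spans ~40 μm per axis.  Nose-up (early-born) somata cluster
    dorsomedially; nose-down (late-born) ventrolaterally; untuned neurons
    sit in between.
    """
    sd = 6.0
    cov = (sd**2) * np.eye(3)
    return {
        "nose_up": {"mean": np.array([16.0, 10.0, 28.0]), "cov": cov.copy()},
        "nose_down": {"mean": np.array([24.0, 18.0, 12.0]), "cov": cov.copy()},
        "none": {"mean": np.array([20.0, 14.0, 20.0]), "cov": cov.copy()},
    }


@dataclass
class SimConfig:
    """Study-condition parameters for the population/trial generators.

    Defaults mirror the imaged preparation: 37 ± 7 projection neurons per
    hemisphere; subtype mix 49% nose-up / 44% nose-down / 7% untuned;
    birthdate cohorts early (≤30 hpf, 65%) vs late (≥48 hpf, 35%) with
    subtype-given-cohort splits of 96/4 (early) and 25/75 (late); GCaMP6s-
    like kernel with 0.18 s rise and 1.8 s decay.
    """

    n_fish: int = 5
    n_neurons_mean: float = 37.0
    n_neurons_sd: float = 7.0
    cohort_fractions: dict = field(default_factory=lambda: {"early": 0.65, "late": 0.35})
    cohort_birth_windows: dict = field(
        default_factory=lambda: {"early": (22.0, 30.0), "late": (48.0, 60.0)}
    )
    subtype_given_cohort: dict = field(
        default_factory=lambda: {
            "early": {"nose_up": 0.96, "nose_down": 0.04},
            "late": {"nose_up": 0.25, "nose_down": 0.75},
        }
    )
    none_fraction: float = 0.07
    spatial_model: dict = field(default_factory=_default_spatial_model)
    # response model
    gain: float = 1.0  # peak ΔF/F drive at the preferred posture
    rise_tau_s: float = 0.18
    decay_tau_s: float = 1.8
    noise_sd: float = 0.05  # additive Gaussian, units of baseline F fractions
    baseline_f: float = 100.0
    impulse_fraction: float = 0.3
    suppression_fraction: float = 0.2
    di_by_subtype: dict = field(
        default_factory=lambda: {
            "nose_up": (0.84, 0.28),
            "nose_down": (-0.73, 0.30),
            "none": (0.0, 0.05),
        }
    )
    seed: int = 0

    def validate(self) -> None:
        if self.n_neurons_sd < 0 or self.noise_sd < 0 or self.gain < 0:
            raise InvalidConfigError("standard deviations and gain must be >= 0")
        if abs(sum(self.cohort_fractions.values()) - 1.0) > 1e-9:
            raise InvalidConfigError("cohort fractions must sum to 1")
        if not (0 <= self.none_fraction < 1):
            raise InvalidConfigError("none_fraction must lie in [0, 1)")
        for cohort, probs in self.subtype_given_cohort.items():
            if abs(sum(probs.values()) - 1.0) > 1e-9:
                raise InvalidConfigError(f"subtype probabilities for {cohort!r} must sum to 1")
        for name, m in self.spatial_model.items():
            cov = np.asarray(m["cov"], dtype=float)
            if cov.shape != (3, 3):
                raise InvalidConfigError(f"covariance for {name!r} must be 3x3")
            w = np.linalg.eigvalsh((cov + cov.T) / 2)
            if w.min() < -1e-9:
                raise InvalidConfigError(f"covariance for {name!r} is not positive semidefinite")


def _psd_factor(cov: np.ndarray) -> np.ndarray:
    """Square root of a PSD matrix (handles the degenerate zero-cov case)."""
    cov = np.asarray(cov, dtype=float)
    w, v = np.linalg.eigh((cov + cov.T) / 2)
    return v @ np.diag(np.sqrt(np.clip(w, 0.0, None)))


def simulate_population(config: SimConfig, rng: np.random.Generator | None = None) -> Population:
    """Draw a multi-fish population with ground-truth labels retained."""
    config.validate()
    rng = rng if rng is not None else substream(config.seed, "population")
    cohorts = list(config.cohort_fractions)
    cohort_p = np.array([config.cohort_fractions[c] for c in cohorts])
    neurons: list[NeuronRecord] = []
    nid = 0
    for fish in range(config.n_fish):
        for hemi in ("left", "right"):
            n = max(1, int(round(rng.normal(config.n_neurons_mean, config.n_neurons_sd))))
            for _ in range(n):
                cohort = cohorts[rng.choice(len(cohorts), p=cohort_p)]
                lo, hi = config.cohort_birth_windows[cohort]
                birth = float(rng.uniform(lo, hi))
                if rng.uniform() < config.none_fraction:
                    subtype = "none"
                else:
                    probs = config.subtype_given_cohort[cohort]
                    keys = list(probs)
                    subtype = keys[rng.choice(len(keys), p=np.array([probs[k] for k in keys]))]
                m = config.spatial_model[subtype]
                xyz = np.asarray(m["mean"], float) + _psd_factor(m["cov"]) @ rng.standard_normal(3)
                mu_di, sd_di = config.di_by_subtype[subtype]
                true_di = float(np.clip(rng.normal(mu_di, sd_di), -1.0, 1.0))
                neurons.append(
                    NeuronRecord(
                        neuron_id=nid,
                        fish_id=fish,
                        hemisphere=hemi,
                        x_rc_um=float(xyz[0]),
                        y_ml_um=float(max(xyz[1], 0.0)),
                        z_dv_um=float(xyz[2]),
                        birth_hpf=birth,
                        cohort=cohort,
                        subtype=subtype,
                        impulse_responsive=bool(rng.uniform() < config.impulse_fraction),
                        response_pattern=(
                            "suppression_recovery"
                            if rng.uniform() < config.suppression_fraction
                            else "excitation"
                        ),
                        true_di=true_di,
                    )
                )
                nid += 1
    return Population(neurons, {"generator": "simulate_population", "seed": config.seed})


def _doe_kernel(frame_rate: float, rise: float, decay: float, horizon_s: float = 15.0) -> np.ndarray:
    """Difference-of-exponentials indicator kernel, peak-normalized to 1."""
    t = np.arange(0.0, horizon_s, 1.0 / frame_rate)
    k = np.exp(-t / decay) - np.exp(-t / rise)
    peak = k.max()
    return k / peak if peak > 0 else k


def simulate_trials(
    neuron: NeuronRecord,
    protocol: StimulusProtocol,
    config: SimConfig,
    rng: np.random.Generator | None = None,
    n_trials: int | None = None,
) -> TrialSet:
    """Forward model of one neuron's fluorescence under a protocol.

    A firing-rate drive — tuned to the preferred direction during eccentric
    holds, impulse-locked transients for impulse-responsive neurons, and an
    optional suppression/recovery pattern in the non-preferred direction —
    is convolved with a difference-of-exponentials kernel, scaled by
    ``baseline_f``, offset, and corrupted with additive Gaussian noise;
    non-negativity is enforced by flooring at 0.  Because the indicator
    decays slowly relative to the 4 ms restoration step, the convolved
    trace peaks at (and persists just after) the return to horizontal — the
    premise that lets the horizontal window report the eccentric posture.
    """
    rng = rng if rng is not None else substream(config.seed, f"trials:{neuron.neuron_id}")
    n_trials = n_trials if n_trials is not None else protocol.repeats
    fr = protocol.frame_rate
    n_frames = protocol.n_frames
    t_frames = np.arange(n_frames) / fr

    di = neuron.true_di if neuron.subtype != "none" else neuron.true_di
    a_up = config.gain * max(0.0, (1.0 + di) / 2.0)
    a_down = config.gain * max(0.0, (1.0 - di) / 2.0)
    preferred = "nose_up" if di >= 0 else "nose_down"
    nonpreferred = "nose_down" if preferred == "nose_up" else "nose_up"

    drive = np.zeros(n_frames)
    for ep in protocol.epochs:
        amp = None
        if ep.label.startswith("nose_up") and ep.angle_deg > 0:
            amp = a_up
        elif ep.label.startswith("nose_down") and ep.angle_deg < 0:
            amp = a_down
        if amp is None:
            continue
        lo, hi = protocol.frame_window(ep.start_s, ep.end_s)
        direction = "nose_up" if ep.angle_deg > 0 else "nose_down"
        if neuron.response_pattern == "suppression_recovery" and direction == nonpreferred:
            drive[lo:hi] = -0.5 * config.gain  # dip during the hold ...
            rb_lo, rb_hi = protocol.frame_window(ep.end_s, ep.end_s + 3.0)
            drive[rb_lo : min(rb_hi, n_frames)] += 0.75 * config.gain  # ... rebound after
        else:
            drive[lo:hi] = amp

    if neuron.impulse_responsive:
        for ep in protocol.epochs:
            if ep.label.endswith("_rotation") and ep.label.startswith("impulse"):
                idx = min(int(np.floor(ep.start_s * fr + 1e-9)), n_frames - 1)
                direction = "nose_down" if ep.angle_deg < 0 else "nose_up"
                amp = a_down if direction == "nose_down" else a_up
                drive[idx] += amp * fr * config.decay_tau_s  # ~matched transient area

    kernel = _doe_kernel(fr, config.rise_tau_s, config.decay_tau_s)
    # normalize so a sustained unit drive saturates near 1 (steady-state gain)
    gain_ss = kernel.sum()
    calcium = np.convolve(drive, kernel / gain_ss)[:n_frames]

    trials = np.empty((n_trials, n_frames))
    for i in range(n_trials):
        noise = rng.normal(0.0, config.noise_sd, n_frames)
        trials[i] = np.maximum(config.baseline_f * (1.0 + calcium + noise), 0.0)
    return TrialSet(neuron.neuron_id, protocol, trials, fr)


def simulate_volumes(
    config: SimConfig,
    protocol: StimulusProtocol,
    rng: np.random.Generator | None = None,
    *,
    shape_zyx: tuple[int, int, int] = (6, 24, 24),
    n_sources: int = 6,
    n_trials: int = 2,
    soma_sigma_vox: float = 1.2,
) -> tuple[list, "np.ndarray"]:
    """Volumetric trial series: Gaussian somata breathing with tilt tuning.

    Point sources with subtype-dependent tuning are placed in the volume;
    each source's fluorescence follows the same forward model as
    :func:`simulate_trials`, deposited as a Gaussian blob.  Direction
    presentation order is randomized per trial.  Returns the trial list
    (``scape.VolumeSeries``) plus the (n_sources, 3) source voxel centers
    for ground-truth checks.
    """
    from .scape import VolumeSeries

    rng = rng if rng is not None else substream(config.seed, "volumes")
    nz, ny, nx = shape_zyx
    centers = np.column_stack(
        [
            rng.uniform(1, nz - 1, n_sources),
            rng.uniform(2, ny - 2, n_sources),
            rng.uniform(2, nx - 2, n_sources),
        ]
    )
    subtypes = ["nose_up" if i % 2 == 0 else "nose_down" for i in range(n_sources)]
    zz, yy, xx = np.meshgrid(np.arange(nz), np.arange(ny), np.arange(nx), indexing="ij")
    blobs = []
    for c in centers:
        d2 = (zz - c[0]) ** 2 + (yy - c[1]) ** 2 + (xx - c[2]) ** 2
        blobs.append(np.exp(-d2 / (2 * soma_sigma_vox**2)))

    trials = []
    for t in range(n_trials):
        inverted = bool(rng.integers(0, 2))
        order = ("nose_up", "nose_down") if inverted else ("nose_down", "nose_up")
        frames = np.zeros((protocol.n_frames, nz, ny, nx))
        for blob, subtype, c in zip(blobs, subtypes, centers):
            mu_di, sd_di = config.di_by_subtype[subtype]
            neuron = NeuronRecord(
                neuron_id=0,
                fish_id=0,
                hemisphere="left",
                x_rc_um=0.0,
                y_ml_um=0.0,
                z_dv_um=0.0,
                birth_hpf=30.0,
                cohort="early",
                subtype=subtype,
                impulse_responsive=False,
                true_di=float(np.clip(mu_di, -1, 1)),
            )
            # physical direction order differs per trial: swap the drive by
            # building against a protocol whose first eccentric direction
            # matches the trial's presentation order
            from .protocols import build_tonic_protocol

            base_ep = protocol.epoch("baseline")
            phys = build_tonic_protocol(
                baseline=base_ep.duration_s,
                frame_rate=protocol.frame_rate,
                invert_order=inverted,
            )
            ts = simulate_trials(neuron, phys, config, rng=rng, n_trials=1)
            trace = ts.trials[0] / config.baseline_f  # back to 1 + ΔF/F units
            frames += trace[: protocol.n_frames, None, None, None] * blob[None]
        background = np.maximum(
            10.0 * (1.0 + rng.normal(0, config.noise_sd, frames.shape)), 0.0
        )
        data = np.maximum(frames * 50.0 + background, 0.0)
        trials.append(
            VolumeSeries(data, protocol.frame_rate, direction_order=order)
        )
    return trials, centers


# ---------------------------------------------------------------------------
# connectome
# ---------------------------------------------------------------------------

@dataclass
class ConnectomeConfig:
    n_projection: int = 19
    n_utricular: int = 6
    n_canal: int = 4
    hair_cells_per_afferent: tuple[int, int] = (3, 6)
    synapse_count_range: tuple[int, int] = (1, 12)
    inconsistency_rate: float = 0.0
    #: construction uses the results-convention (anterior → nose_up)
    convention: str = "results"
    seed: int = 0


def _unit(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v)
    if n == 0:
        raise ValueError("zero vector")
    return v / n


def simulate_connectome(
    config: ConnectomeConfig, rng: np.random.Generator | None = None
) -> ConnectomeGraph:
    """Hair-cell → afferent → projection-neuron graph with coherent wiring.

    Canal and utricular afferents converging on a projection neuron share a
    vertical direction unless ``inconsistency_rate`` requests mismatches
    for negative tests.  Hair-cell orientation vectors are unit-norm, with
    the vertical component dominating according to the afferent's class.
    """
    if min(config.n_projection, config.n_utricular, config.n_canal) < 1:
        raise InvalidConfigError("all node counts must be >= 1")
    rng = rng if rng is not None else substream(config.seed, "connectome")
    from .connectome import canal_direction_map  # local import to avoid cycle at load

    hair_cells: list[HairCell] = []
    afferents: list[Afferent] = []
    neurons: list[ProjectionNeuronNode] = []
    edges: list[tuple[str, str, int]] = []

    classes = ["nose_up", "nose_down"]
    utr_class: dict[str, str] = {}
    for i in range(config.n_utricular):
        cls = classes[i % 2]
        aff_id = f"utr_{i}"
        afferents.append(Afferent(aff_id, "utricle"))
        utr_class[aff_id] = cls
        n_hc = rng.integers(config.hair_cells_per_afferent[0], config.hair_cells_per_afferent[1] + 1)
        for j in range(n_hc):
            z = rng.uniform(0.6, 1.0) * (1.0 if cls == "nose_up" else -1.0)
            xy = rng.normal(0.0, 0.2, 2)
            vec = _unit(np.array([xy[0], xy[1], z]))
            hc_id = f"hc_{i}_{j}"
            hair_cells.append(HairCell(hc_id, vec))
            edges.append((hc_id, aff_id, int(rng.integers(*config.synapse_count_range))))

    canal_organ = {"nose_up": None, "nose_down": None}
    for cls in classes:
        for organ in ("anterior_canal", "posterior_canal"):
            if canal_direction_map(organ, config.convention) == cls:
                canal_organ[cls] = organ
    canal_ids: dict[str, list[str]] = {c: [] for c in classes}
    for i in range(config.n_canal):
        cls = classes[i % 2]
        aff_id = f"canal_{i}"
        afferents.append(Afferent(aff_id, canal_organ[cls]))
        canal_ids[cls].append(aff_id)

    utr_ids = {c: [a for a, k in utr_class.items() if k == c] for c in classes}
    for i in range(config.n_projection):
        cls = classes[i % 2]
        nid = f"pn_{i}"
        pos = rng.uniform(0.0, 40.0, 3)
        neurons.append(ProjectionNeuronNode(nid, pos))
        canal_cls = cls
        if rng.uniform() < config.inconsistency_rate:
            canal_cls = "nose_down" if cls == "nose_up" else "nose_up"
        edges.append(
            (str(rng.choice(canal_ids[canal_cls])), nid, int(rng.integers(*config.synapse_count_range)))
        )
        for aff in rng.choice(utr_ids[cls], size=min(2, len(utr_ids[cls])), replace=False):
            edges.append((str(aff), nid, int(rng.integers(*config.synapse_count_range))))

    return ConnectomeGraph(hair_cells, afferents, neurons, edges)


# ---------------------------------------------------------------------------
# varicosities
# ---------------------------------------------------------------------------

@dataclass
class VaricositySeries:
    """Varicosity counts onto one motor-neuron class across development."""

    motor_neuron_class: str  # "dorsal" | "ventral"
    observations: pd.DataFrame  # columns: age_hpf, fish_id, varicosity_count

    def __post_init__(self) -> None:
        obs = self.observations
        if (obs["varicosity_count"] < 0).any():
            raise ValueError("varicosity counts must be >= 0")
        if ((obs["age_hpf"] < 50) | (obs["age_hpf"] > 90)).any():
            raise ValueError("ages must lie within [50, 90] hpf")


@dataclass
class VaricosityConfig:
    """Three-phase growth: onset → linear growth → plateau.

    Dorsal motor neurons carry ~3× the varicosities of ventral ones, so the
    plateau levels default to 30 vs 10 counts.
    """

    onset_hpf: float = 55.0
    plateau_hpf: float = 78.0
    plateau_counts: dict = field(default_factory=lambda: {"dorsal": 30.0, "ventral": 10.0})
    ages: tuple = (50, 55, 62, 70, 78, 85, 90)
    n_fish: int = 5
    poisson_noise: bool = True
    seed: int = 0

    def validate(self) -> None:
        if not (50 <= self.onset_hpf < self.plateau_hpf <= 90):
            raise InvalidConfigError("breakpoints must be ordered within [50, 90] hpf")


def piecewise_growth(t, onset: float, plateau: float, level: float) -> np.ndarray:
    """0 before onset, linear to ``level`` at ``plateau``, flat after."""
    t = np.asarray(t, dtype=float)
    frac = np.clip((t - onset) / (plateau - onset), 0.0, 1.0)
    return level * frac


def simulate_varicosity_series(
    config: VaricosityConfig, rng: np.random.Generator | None = None
) -> dict[str, VaricositySeries]:
    """Per-class growth series with optional Poisson count noise."""
    config.validate()
    rng = rng if rng is not None else substream(config.seed, "varicosities")
    out = {}
    for cls, level in config.plateau_counts.items():
        rows = []
        for age in config.ages:
            mean = float(piecewise_growth(age, config.onset_hpf, config.plateau_hpf, level))
            for fish in range(config.n_fish):
                count = float(rng.poisson(mean)) if config.poisson_noise else mean
                rows.append({"age_hpf": float(age), "fish_id": fish, "varicosity_count": count})
        out[cls] = VaricositySeries(cls, pd.DataFrame(rows))
    return out
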