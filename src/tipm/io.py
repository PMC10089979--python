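"""Shared readers/writers, run configuration and the end-to-end pipeline.

Formats: CSV for tables, JSON for protocols/graphs/reports, YAML for run
configuration, TIFF for volumes and maps.  Every run writes its resolved
configuration beside its outputs, and every random draw flows from the
single run seed through named substreams, so per-stage reruns reproduce in
isolation.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .core import POPULATION_COLUMNS, Population
from .protocols import build_impulse_protocol, build_tonic_protocol
from .simulate import (
    ConnectomeConfig,
    SimConfig,
    VaricosityConfig,
    simulate_connectome,
    simulate_population,
    simulate_trials,
    simulate_varicosity_series,
    substream,
)

log = logging.getLogger("tipm")

__all__ = [
    "SchemaError",
    "load_table",
    "write_population_csv",
    "read_population_csv",
    "write_trials_csv",
    "read_trials_csv",
    "RunConfig",
    "run_pipeline",
]


class SchemaError(ValueError):
    """A required column is missing from an input table."""


def load_table(path, required_columns) -> pd.DataFrame:
    """Read a CSV and validate its schema.

    Unknown columns are preserved; a missing required column raises
    :class:`SchemaError` naming the column.  An empty file with a header
    yields zero records without error.
    """
    df = pd.read_csv(path)
    for col in required_columns:
        if col not in df.columns:
            raise SchemaError(f"missing required column {col!r} in {path}")
    log.info("loaded %d records from %s", len(df), path)
    return df


def write_population_csv(pop: Population, path) -> None:
    pop.to_frame().to_csv(path, index=False)


def read_population_csv(path) -> Population:
    return Population.from_frame(load_table(path, POPULATION_COLUMNS))


def write_trials_csv(trialsets, path) -> None:
    pd.concat([ts.to_frame() for ts in trialsets]).to_csv(path, index=False)


def read_trials_csv(path, protocol):
    """Rebuild TrialSets from the long-form (neuron_id, trial, frame, F) CSV."""
    from .core import TrialSet

    df = load_table(path, ["neuron_id", "trial", "frame", "F"])
    out = []
    for nid, sub in df.groupby("neuron_id"):
        n_tr = int(sub["trial"].max()) + 1
        n_fr = int(sub["frame"].max()) + 1
        arr = np.empty((n_tr, n_fr))
        arr[sub["trial"].to_numpy(), sub["frame"].to_numpy()] = sub["F"].to_numpy()
        out.append(TrialSet(int(nid), protocol, arr, protocol.frame_rate))
    return out


def _jsonable(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return _jsonable(dataclasses.asdict(obj))
    if isinstance(obj, pd.DataFrame):
        return _jsonable(obj.to_dict(orient="records"))
    return obj


@dataclass
class RunConfig:
    """Resolved configuration for one reproducible pipeline run."""

    seed: int = 0
    out_dir: str = "tipm_run"
    stages: dict = field(
        default_factory=lambda: {
            "population": True,
            "classify": True,
            "topography": True,
            "birthdating": True,
            "connectome": True,
            "varicosities": True,
        }
    )
    di_threshold: float = 0.1
    n_permutations: int = 100
    conversion_time_hpf: float = 30.0
    canal_convention: str = "results"
    n_trial_neurons: int = 40  # neurons simulated through the trace model

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)


def run_pipeline(config: RunConfig) -> dict:
    """simulate → classify → topography → birthdate → connectome → growth.

    Runs the stages toggled in ``config`` on synthetic data and aggregates
    every statistic into a single JSON-serializable report with provenance
    (seed, version, resolved configuration).  A stage failure is recorded
    in the report and re-raised as a nonzero-exit condition by the CLI.
    """
    from . import birthdating, responses, synaptogenesis, topography

    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "schema_version": 1,
        "provenance": {
            "seed": config.seed,
            "tipm_version": __version__,
            "config": dataclasses.asdict(config),
        },
        "stages": {},
        "failures": {},
    }
    sim = SimConfig(seed=config.seed)
    pop = None
    classes = None

    def stage(name):
        return config.stages.get(name, False)

    try:
        if stage("population"):
            pop = simulate_population(sim)
            write_population_csv(pop, out_dir / "population.csv")
            frac = {
                s: float((pop.labels("subtype") == s).mean())
                for s in ("nose_up", "nose_down", "none")
            }
            report["stages"]["population"] = {"n_neurons": len(pop), "subtype_fractions": frac}

        if stage("classify") and pop is not None:
            tonic = build_tonic_protocol()
            impulse = build_impulse_protocol()
            rng = substream(config.seed, "pipeline-trials")
            neurons = pop.neurons[: config.n_trial_neurons]
            tonic_sets = [simulate_trials(n, tonic, sim, rng=rng) for n in neurons]
            imp_sets = [simulate_trials(n, impulse, sim, rng=rng) for n in neurons]
            classes = responses.classify_population(
                tonic_sets, tonic, imp_sets, impulse, threshold=config.di_threshold
            )
            classes.to_csv(out_dir / "classification.csv", index=False)
            recovered = [
                c.subtype == n.subtype
                for c, n in zip(classes.itertuples(), neurons)
                if n.subtype != "none"
            ]
            report["stages"]["classify"] = {
                "n_classified": len(classes),
                "subtype_recovery": float(np.mean(recovered)) if recovered else float("nan"),
                "mean_abs_di": float(np.nanmean(np.abs(classes["DI"]))),
            }

        if stage("topography") and pop is not None:
            tuned = pop.subset(pop.labels("subtype") != "none")
            battery = topography.topography_battery(tuned, tuned.labels("subtype"))
            null = topography.permutation_null(
                tuned, "subtype", n_perm=config.n_permutations,
                rng=substream(config.seed, "pipeline-permutation"),
            )
            report["stages"]["topography"] = _jsonable(
                {
                    "manova": battery.manova,
                    "ks_per_axis": battery.ks_per_axis,
                    "medians": battery.medians,
                    "permutation_mean_p": null.mean_p,
                    "permutation_sd_p": null.sd_p,
                }
            )

        if stage("birthdating") and pop is not None:
            curve = birthdating.cumulative_birth_curve(pop, [24, 30, 36, 42, 48])
            props = birthdating.subtype_by_birthdate(pop, config.conversion_time_hpf, "before")
            report["stages"]["birthdating"] = _jsonable(
                {
                    "birth_curve_slope_per_hpf": curve.slope,
                    "birth_curve_r_squared": curve.r_squared,
                    "born_before_proportions": props,
                }
            )

        if stage("connectome"):
            from .connectome import tuning_match

            graph = simulate_connectome(ConnectomeConfig(seed=config.seed))
            graph.to_json(out_dir / "connectome.json")
            summary, fraction = tuning_match(graph, convention=config.canal_convention)
            summary.to_csv(out_dir / "connectome_summary.csv", index=False)
            report["stages"]["connectome"] = {
                "n_projection_neurons": len(graph.projection_neurons),
                "tuning_match_fraction": fraction,
            }

        if stage("varicosities"):
            series = simulate_varicosity_series(VaricosityConfig(seed=config.seed))
            out = {}
            for cls, s in series.items():
                norm = synaptogenesis.normalize_varicosities(s)
                fit = synaptogenesis.fit_growth_phases(norm)
                comparison = synaptogenesis.compare_timepoints(norm)
                out[cls] = {
                    "fit": _jsonable(fit),
                    "anova_F": comparison.F,
                    "anova_p": comparison.p,
                }
            report["stages"]["varicosities"] = _jsonable(out)
    except Exception as exc:  # partial report with the failure recorded
        report["failures"][type(exc).__name__] = str(exc)

    config.to_yaml(out_dir / "resolved_config.yaml")
    with open(out_dir / "report.json", "w") as fh:
        json.dump(_jsonable(report), fh, indent=2)
    return report
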