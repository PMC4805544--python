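"""End-to-end orchestration: generate -> normalize -> classify -> analyze -> agents.

``run_pipeline`` runs every stage on a synthetic population, writes each
stage's inputs and outputs to disk (CSV/JSON), and records a manifest
with the seed, package version and a hash of the configuration so a run
is reproducible and each stage re-runnable from its on-disk inputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from ._version import __version__
from .auroc import AnalysisConfig, auroc_matrix
from .classify import WaveformCriteria, classify_population, classify_waveform
from .errors import ConfigError
from .io import Dataset, write_dataset
from .synth import (
    BehaviorParams,
    PopulationSpec,
    SimulationResult,
    simulate_behavior,
    simulate_population,
)
from .task import TaskSpec
from . import agents as agents_mod
from . import signals as signals_mod


@dataclass(frozen=True)
class RunConfig:
    """Single configuration covering every stage."""

    seed: int = 0
    task: TaskSpec = field(default_factory=TaskSpec)
    population: PopulationSpec = field(default_factory=PopulationSpec)
    behavior: BehaviorParams = field(default_factory=BehaviorParams)
    analysis: AnalysisConfig = field(default_factory=AnalysisConfig)
    waveform: WaveformCriteria = field(default_factory=WaveformCriteria)
    agent_alpha: float = 0.1
    agent_gamma: float = 0.95

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        kwargs = dict(d)
        for key, sub in (("task", TaskSpec), ("population", PopulationSpec),
                         ("behavior", BehaviorParams), ("analysis", AnalysisConfig),
                         ("waveform", WaveformCriteria)):
            if key in kwargs and isinstance(kwargs[key], dict):
                section = dict(kwargs[key])
                for f in dataclasses.fields(sub):
                    if f.name in section and isinstance(section[f.name], list):
                        section[f.name] = tuple(section[f.name])
                kwargs[key] = sub(**section)
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def config_hash(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _seeded(config: RunConfig) -> tuple[PopulationSpec, int]:
    pop = dataclasses.replace(config.population, seed=int(config.seed))
    return pop, int(config.seed)


def generate(config: RunConfig) -> tuple[SimulationResult, Dataset]:
    """Simulate the population and behavior under the run seed."""
    if config.population.n_total <= 0:
        raise ConfigError("population is empty")
    pop, seed = _seeded(config)
    sim = simulate_population(pop, config.task)
    behavior = simulate_behavior(config.task, config.behavior, seed)
    ds = Dataset(spikes=sim.spikes, events=sim.events,
                 waveforms=sim.waveforms, behavior=behavior).validate()
    return sim, ds


def _contrast_dict(c) -> dict:
    return {"cue_pos": c.cue_pos, "cue_neg": c.cue_neg, "window": list(c.window),
            "measure": c.measure, "mean_diff": c.mean_diff, "t": c.t,
            "df": c.df, "p": c.p, "n": int(len(c.per_neuron))}


def _corr_dict(c) -> dict:
    return {"r": c.r, "n": c.n, "df": c.df, "p": c.p}


def analyze(ds: Dataset, config: RunConfig) -> dict:
    """All statistics panels from a validated dataset.

    Returns a JSON-serializable report keyed by analysis, plus the label
    tables and matrices needed to re-create the figure-ready outputs.
    """
    cfg = config.analysis
    spec = config.task
    report: dict = {}
    extras: dict = {}

    # Conditioning classification and peak migration.
    cond_sessions = list(spec.conditioning_sessions)
    m_cond = auroc_matrix(ds.spikes, ds.events, "B", cfg, sessions=cond_sessions)
    labels_cond = classify_population(m_cond, cfg)
    phasic_cond = labels_cond.loc[labels_cond.archetype == "phasic", "neuron_id"].to_numpy()
    diffs = signals_mod.onset_reward_difference(
        ds.spikes, ds.events, cfg, sessions=cond_sessions, neurons=phasic_cond)
    mig = signals_mod.migration_correlation(diffs)
    report["peak_migration"] = _corr_dict(mig)

    # Probe classification and value contrasts.
    probe_sessions = [spec.probe_session]
    m_probe = auroc_matrix(ds.spikes, ds.events, "B", cfg, sessions=probe_sessions)
    labels_probe = classify_population(m_probe, cfg)
    wide = classify_waveform(ds.waveforms.set_index("neuron_id"), config.waveform)
    labels_probe = labels_probe.merge(
        wide.rename("wide_waveform").reset_index(), on="neuron_id", how="left")
    phasic_probe = labels_probe.loc[labels_probe.archetype == "phasic", "neuron_id"].to_numpy()

    bd = signals_mod.phasic_contrast(ds.spikes, ds.events, cfg, "B", "D",
                                     neurons=phasic_probe, sessions=probe_sessions)
    ac = signals_mod.phasic_contrast(ds.spikes, ds.events, cfg, "A", "C",
                                     neurons=phasic_probe, sessions=probe_sessions)
    bd_sus = signals_mod.sustained_contrast(ds.spikes, ds.events, cfg, "B", "D",
                                            neurons=phasic_probe, sessions=probe_sessions)
    ac_sus = signals_mod.sustained_contrast(ds.spikes, ds.events, cfg, "A", "C",
                                            neurons=phasic_probe, sessions=probe_sessions)
    corr = signals_mod.inferred_vs_cached_correlation(bd, ac)
    report["cached_value_contrast"] = _contrast_dict(bd)
    report["inferred_value_contrast"] = _contrast_dict(ac)
    report["sustained_cached_contrast"] = _contrast_dict(bd_sus)
    report["sustained_inferred_contrast"] = _contrast_dict(ac_sus)
    report["inferred_vs_cached_correlation"] = _corr_dict(corr)
    report["archetype_counts_conditioning"] = labels_cond.archetype.value_counts().to_dict()
    report["archetype_counts_probe"] = labels_probe.archetype.value_counts().to_dict()
    report["n_wide_waveform"] = int(labels_probe.wide_waveform.fillna(False).sum())

    # Behavior panels.
    behavior = {}
    for phase in ("preconditioning", "conditioning", "probe"):
        st = signals_mod.behavior_stats(ds.behavior, phase, alpha=cfg.alpha)
        behavior[phase] = {
            "degenerate": st.degenerate,
            "effects": st.anova.to_dict(orient="records"),
            "means": st.means.to_dict(orient="records"),
        }
    report["behavior"] = behavior

    extras.update(matrix_conditioning=m_cond, matrix_probe=m_probe,
                  labels_conditioning=labels_cond, labels_probe=labels_probe,
                  migration=diffs, contrasts={"B-D": bd, "A-C": ac})
    return {"report": report, "extras": extras}


def run_pipeline(config: RunConfig, outdir: str | Path) -> dict:
    """Run every stage, write all outputs under ``outdir``, return the report."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if config.population.n_total <= 0:
        raise ConfigError("population is empty")

    sim, ds = generate(config)
    write_dataset(ds, outdir / "dataset")
    sim.truth.to_csv(outdir / "dataset" / "ground_truth.csv", index=False,
                     lineterminator="\n")

    result = analyze(ds, config)
    report, extras = result["report"], result["extras"]

    extras["matrix_conditioning"].to_frame().to_csv(
        outdir / "auroc_conditioning_B.csv", index=False, lineterminator="\n")
    extras["matrix_probe"].to_frame().to_csv(
        outdir / "auroc_probe_B.csv", index=False, lineterminator="\n")
    extras["labels_probe"].to_csv(outdir / "labels.csv", index=False, lineterminator="\n")
    extras["migration"].to_csv(outdir / "migration.csv", index=False, lineterminator="\n")

    agent_table = agents_mod.compare_agents(
        config.task,
        agents_mod.AgentConfig(alpha=config.agent_alpha, gamma=config.agent_gamma),
        agents_mod.AgentConfig(alpha=config.agent_alpha, gamma=config.agent_gamma,
                               model_based=True),
    )
    agent_table.to_csv(outdir / "agents.csv", index=False, lineterminator="\n")
    report["agents"] = agent_table.to_dict(orient="records")
    report["seed"] = int(config.seed)

    with open(outdir / "stats.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True, default=_jsonable)
        fh.write("\n")
    manifest = {
        "seed": int(config.seed),
        "config_hash": config.config_hash(),
        "package_version": __version__,
        "timestamp": datetime.now(timezone.utc).isoformat(),
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return report


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, pd.DataFrame):
        return obj.to_dict(orient="records")
    raise TypeError(f"not JSON serializable: {type(obj)}")
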