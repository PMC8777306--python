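"""End-to-end simulation study: simulate, fit both models, evaluate, report.

:func:`run_study` reproduces the whole pipeline from a YAML-loadable
:class:`StudyConfig`: for every prevalence x scenario it simulates a batch
of replicate datasets, fits the full hierarchical model and all single-drug
models to each (paired on the same datasets), and writes estimate records,
the performance table, the detection summary and a per-class relative-
precision table as CSVs, plus a JSON manifest that fully determines the run
(config hash, seeds, package version).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .models import InferenceSettings, PriorSpec, fit_full_batch, fit_singles_batch
from .network import TrialNetwork, default_network, read_network
from .performance import (
    detection_classes,
    estimate_records,
    per_class_relative_precision,
    performance_table,
)
from .scenarios import standard_scenarios, simulate_batch

__all__ = ["StudyConfig", "StudyResult", "load_config", "run_study"]

logger = logging.getLogger("ontopool")


@dataclass
class StudyConfig:
    """Configuration of one simulation study run.

    Defaults mirror the main analysis: all nine scenarios, 1000 replicates,
    prevalence 20% (add 0.1 and 0.5 for the sensitivity runs).
    """

    network: str = "default"  # "default" or a CSV path
    scenarios: Sequence[str] = field(
        default_factory=lambda: list(standard_scenarios())
    )
    n_reps: int = 1000
    prevalences: Sequence[float] = (0.2,)
    base_seed: int = 20210818
    out_dir: str = "study_output"
    n_chains: int = 1
    n_draws: int = 1250
    n_warmup: int = 350
    location_prior_sd: float = 2.0
    scale_prior_sd: float = 1.0
    detection_threshold: float | None = -0.10
    max_fail_fraction: float = 0.05

    def __post_init__(self) -> None:
        if self.n_reps < 1:
            raise ValueError("n_reps must be >= 1")
        known = set(standard_scenarios())
        unknown = set(self.scenarios) - known
        if unknown:
            raise ValueError(f"unknown scenario names: {sorted(unknown)}")
        if any(not 0.0 < p < 1.0 for p in self.prevalences):
            raise ValueError("prevalence values must be in (0, 1)")

    def resolve_network(self) -> TrialNetwork:
        if self.network == "default":
            return default_network()
        return read_network(self.network)

    def canonical(self) -> dict:
        d = asdict(self)
        d["scenarios"] = list(d["scenarios"])
        d["prevalences"] = list(d["prevalences"])
        return d

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.canonical(), sort_keys=True).encode()
        ).hexdigest()[:16]


def load_config(path: str | Path) -> StudyConfig:
    """Load a :class:`StudyConfig` from YAML (unknown keys rejected)."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    return StudyConfig(**raw)


@dataclass
class StudyResult:
    """Paths of the artifacts written by :func:`run_study`."""

    out_dir: Path
    records_path: Path
    performance_path: Path
    detection_path: Path
    class_precision_path: Path
    manifest_path: Path
    records: pd.DataFrame
    performance: pd.DataFrame


def run_study(config: StudyConfig) -> StudyResult:
    """Execute the configured study and write all artifacts.

    Replicate ``i`` of every scenario always uses the same child seed of
    ``base_seed``, so results are reproducible and independent of batching;
    both models are fitted to the same replicates (paired comparison).
    """
    network = config.resolve_network()
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    priors = PriorSpec(config.location_prior_sd, config.scale_prior_sd)
    scenario_grid = standard_scenarios()

    all_records: list[pd.DataFrame] = []
    detection_frames: list[pd.DataFrame] = []
    class_prec_frames: list[pd.DataFrame] = []
    for prevalence in config.prevalences:
        for k, name in enumerate(config.scenarios):
            scenario = scenario_grid[name].with_prevalence(prevalence)
            logger.info(
                "scenario %s (prevalence %.2f): simulating %d replicates",
                name, prevalence, config.n_reps,
            )
            datasets = simulate_batch(
                network, scenario, config.n_reps, config.base_seed
            )
            Y = np.stack([ds.y for ds in datasets])
            s = datasets[0].s
            fit_seed = int(
                np.random.SeedSequence(
                    entropy=config.base_seed, spawn_key=(4, k)
                ).generate_state(1)[0] % (2**31)
            )
            settings = InferenceSettings(
                n_chains=config.n_chains,
                n_draws=config.n_draws,
                n_warmup=config.n_warmup,
                seed=fit_seed,
                store="beta",
                compute_diagnostics=False,
            )
            logger.info("fitting full model (%d replicates jointly)", config.n_reps)
            full = fit_full_batch(network, Y, s, priors, settings)
            logger.info("fitting %d single-drug models", network.n_drugs)
            single = fit_singles_batch(network, Y, s, priors, settings)

            bad = ~np.isfinite(full.est).all(axis=1) | ~np.isfinite(single.est).all(
                axis=1
            )
            if bad.mean() > config.max_fail_fraction:
                raise RuntimeError(
                    f"{bad.sum()} of {config.n_reps} fits failed in scenario "
                    f"{name!r} (> {config.max_fail_fraction:.0%})"
                )

            rec_f = estimate_records(datasets, full, "full")
            rec_s = estimate_records(datasets, single, "single")
            for rec in (rec_f, rec_s):
                rec.insert(0, "scenario", name)
                rec.insert(1, "prevalence", prevalence)
            all_records += [rec_s, rec_f]

            det = detection_classes(
                rec_s, rec_f, effect_threshold=config.detection_threshold
            ).to_frame()
            det.insert(0, "scenario", name)
            det.insert(1, "prevalence", prevalence)
            detection_frames.append(det)

            cls_prec = per_class_relative_precision(rec_s, rec_f, network)
            cls_prec.insert(0, "scenario", name)
            cls_prec.insert(1, "prevalence", prevalence)
            class_prec_frames.append(cls_prec)

    records = pd.concat(all_records, ignore_index=True)
    perf_frames = []
    for prevalence in config.prevalences:
        sub = records[records["prevalence"] == prevalence]
        perf = performance_table(sub, scenarios=config.scenarios)
        perf.insert(1, "prevalence", prevalence)
        perf_frames.append(perf)
    performance = pd.concat(perf_frames, ignore_index=True)

    records_path = out_dir / "estimate_records.csv"
    performance_path = out_dir / "performance.csv"
    detection_path = out_dir / "detection.csv"
    class_precision_path = out_dir / "class_relative_precision.csv"
    manifest_path = out_dir / "manifest.json"

    records.to_csv(records_path, index=False, float_format="%.10g")
    performance.to_csv(performance_path, index=False, float_format="%.10g")
    pd.concat(detection_frames, ignore_index=True).to_csv(
        detection_path, index=False, float_format="%.10g"
    )
    pd.concat(class_prec_frames, ignore_index=True).to_csv(
        class_precision_path, index=False, float_format="%.10g"
    )
    manifest = {
        "version": __version__,
        "config": config.canonical(),
        "config_hash": config.config_hash(),
        "network": {
            "n_trials": network.n_trials,
            "n_drugs": network.n_drugs,
            "n_classes": network.n_classes,
            "total_enrollment": network.total_enrollment,
        },
        "fits_per_replicate": 1 + network.n_drugs,
    }
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    logger.info("study complete: artifacts in %s", out_dir)
    return StudyResult(
        out_dir=out_dir,
        records_path=records_path,
        performance_path=performance_path,
        detection_path=detection_path,
        class_precision_path=class_precision_path,
        manifest_path=manifest_path,
        records=records,
        performance=performance,
    )
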