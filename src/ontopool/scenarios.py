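"""Scenario definitions and the hierarchical data-generating process.

Each simulated dataset draws latent true interaction effects down the
ontology: a class effect around the overall effect, a drug effect around its
class, a trial effect around its drug, and finally an observed trial-level
estimate around the trial effect with sampling SD given by
:func:`ontopool.network.interaction_se`.

The nine standard scenarios vary the between-class, between-drug and
between-trial SDs over {0.05, 0.15, 0.25}: three "all levels" scenarios with
equal SDs, and six in which one level is raised to 0.15 or 0.25 while the
others stay at 0.05.  All scenarios use an overall effect of -0.1
standardized units and a comorbidity prevalence of 20% (10% and 50% are the
standard sensitivity settings).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path


import numpy as np
import pandas as pd
import yaml

from .network import TrialNetwork, interaction_se

__all__ = [
    "ScenarioSpec",
    "SimulatedDataset",
    "standard_scenarios",
    "get_scenario",
    "simulate_dataset",
    "simulate_batch",
    "write_dataset",
    "read_dataset",
    "child_seed",
]

DEFAULT_OVERALL_EFFECT = -0.1
DEFAULT_PREVALENCE = 0.2
SENSITIVITY_PREVALENCES = (0.1, 0.5)


@dataclass(frozen=True)
class ScenarioSpec:
    """Data-generating configuration for one simulation scenario.

    SDs are on the standardized outcome scale; ``overall_effect`` is the
    top-of-hierarchy mean interaction; ``prevalence`` is the comorbid
    subgroup proportion and enters only through the trial-level SE.
    """

    name: str
    sd_class: float
    sd_drug: float
    sd_trial: float
    overall_effect: float = DEFAULT_OVERALL_EFFECT
    prevalence: float = DEFAULT_PREVALENCE

    def __post_init__(self) -> None:
        if min(self.sd_class, self.sd_drug, self.sd_trial) < 0:
            raise ValueError("scenario SDs must be non-negative")
        if not 0.0 < self.prevalence < 1.0:
            raise ValueError(f"prevalence must be in (0, 1), got {self.prevalence}")

    def with_prevalence(self, prevalence: float) -> "ScenarioSpec":
        return replace(self, prevalence=prevalence)


def standard_scenarios(
    overall_effect: float = DEFAULT_OVERALL_EFFECT,
    prevalence: float = DEFAULT_PREVALENCE,
) -> dict[str, ScenarioSpec]:
    """The nine standard scenarios, keyed by name."""
    grid = {
        "all-low": (0.05, 0.05, 0.05),
        "all-medium": (0.15, 0.15, 0.15),
        "all-high": (0.25, 0.25, 0.25),
        "trial-medium": (0.05, 0.05, 0.15),
        "trial-high": (0.05, 0.05, 0.25),
        "drug-medium": (0.05, 0.15, 0.05),
        "drug-high": (0.05, 0.25, 0.05),
        "class-medium": (0.15, 0.05, 0.05),
        "class-high": (0.25, 0.05, 0.05),
    }
    return {
        name: ScenarioSpec(name, sc, sd, st, overall_effect, prevalence)
        for name, (sc, sd, st) in grid.items()
    }


def get_scenario(name: str, prevalence: float = DEFAULT_PREVALENCE) -> ScenarioSpec:
    scenarios = standard_scenarios(prevalence=prevalence)
    try:
        return scenarios[name]
    except KeyError:
        raise KeyError(
            f"unknown scenario {name!r}; available: {sorted(scenarios)}"
        ) from None


@dataclass
class SimulatedDataset:
    """One simulated realization of trial-level interaction estimates.

    ``y``/``s``/``mu_true`` align with the network's trials, ``beta_true``
    with its drugs, ``gamma_true`` with its classes.
    """

    network: TrialNetwork
    scenario: ScenarioSpec
    seed: int
    y: np.ndarray
    s: np.ndarray
    mu_true: np.ndarray
    beta_true: np.ndarray
    gamma_true: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        net = self.network
        return pd.DataFrame(
            {
                "trial_id": [r.trial_id for r in net.records],
                "drug_code": [r.drug_code for r in net.records],
                "class_code": [r.class_code for r in net.records],
                "y": self.y,
                "s": self.s,
                "mu_true": self.mu_true,
                "beta_true": self.beta_true[net.trial_drug_idx],
                "gamma_true": self.gamma_true[
                    net.drug_class_idx[net.trial_drug_idx]
                ],
            }
        )


def child_seed(base_seed: int, *key: int) -> np.random.SeedSequence:
    """Deterministic child seed for stream ``key`` of ``base_seed``.

    The (base_seed, key) pair fully determines the stream, so replicate i of
    a batch can be regenerated in isolation (resumable runs).
    """
    return np.random.SeedSequence(entropy=int(base_seed), spawn_key=tuple(key))


def trial_ses(network: TrialNetwork, prevalence: float) -> np.ndarray:
    """Per-trial interaction SEs for a network at a given prevalence."""
    return np.array(
        [interaction_se(r.enrollment, prevalence) for r in network.records]
    )


def simulate_dataset(
    network: TrialNetwork,
    scenario: ScenarioSpec,
    seed: int | np.random.SeedSequence,
) -> SimulatedDataset:
    """Draw one dataset from the hierarchical data-generating process.

    gamma_c = alpha + N(0, sd_class^2); beta_d = gamma_c(d) + N(0, sd_drug^2);
    mu_z = beta_d(z) + N(0, sd_trial^2); y_z = mu_z + N(0, s_z^2) with s_z the
    enrollment/prevalence-based interaction SE.  The same seed yields a
    bit-identical dataset.
    """
    seq = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(int(seed))
    rng = np.random.default_rng(seq)
    s = trial_ses(network, scenario.prevalence)
    gamma = scenario.overall_effect + scenario.sd_class * rng.standard_normal(
        network.n_classes
    )
    beta = gamma[network.drug_class_idx] + scenario.sd_drug * rng.standard_normal(
        network.n_drugs
    )
    mu = beta[network.trial_drug_idx] + scenario.sd_trial * rng.standard_normal(
        network.n_trials
    )
    y = mu + s * rng.standard_normal(network.n_trials)
    seed_int = int(seq.entropy) if not seq.spawn_key else -1
    return SimulatedDataset(
        network=network,
        scenario=scenario,
        seed=seed_int,
        y=y,
        s=s,
        mu_true=mu,
        beta_true=beta,
        gamma_true=gamma,
    )


def simulate_batch(
    network: TrialNetwork,
    scenario: ScenarioSpec,
    n_reps: int,
    base_seed: int,
    start_rep: int = 0,
) -> list[SimulatedDataset]:
    """Simulate ``n_reps`` independent datasets with deterministic child seeds.

    Replicate ``i`` always uses ``child_seed(base_seed, 0, i)`` regardless of
    batch boundaries, so batches can be split and resumed without changing
    any replicate.  The same batch should be fitted by every model under
    comparison so that performance contrasts are paired.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    return [
        simulate_dataset(network, scenario, child_seed(base_seed, 0, i))
        for i in range(start_rep, start_rep + n_reps)
    ]


def write_dataset(dataset: SimulatedDataset, path: str | Path) -> None:
    """Write a dataset CSV plus a YAML sidecar with scenario and seed."""
    path = Path(path)
    dataset.to_frame().to_csv(path, index=False)
    sidecar = {
        "scenario": {
            "name": dataset.scenario.name,
            "sd_class": dataset.scenario.sd_class,
            "sd_drug": dataset.scenario.sd_drug,
            "sd_trial": dataset.scenario.sd_trial,
            "overall_effect": dataset.scenario.overall_effect,
            "prevalence": dataset.scenario.prevalence,
        },
        "seed": dataset.seed,
    }
    path.with_suffix(".yaml").write_text(yaml.safe_dump(sidecar, sort_keys=False))


def read_dataset(path: str | Path, network: TrialNetwork) -> SimulatedDataset:
    """Read a dataset written by :func:`write_dataset` (against its network)."""
    path = Path(path)
    frame = pd.read_csv(path)
    meta = yaml.safe_load(path.with_suffix(".yaml").read_text())
    scenario = ScenarioSpec(**meta["scenario"])
    ids = [r.trial_id for r in network.records]
    frame = frame.set_index("trial_id").loc[ids]
    drug_first = frame.reset_index().drop_duplicates("drug_code", keep="first")
    class_first = drug_first.drop_duplicates("class_code", keep="first")
    return SimulatedDataset(
        network=network,
        scenario=scenario,
        seed=int(meta["seed"]),
        y=frame["y"].to_numpy(),
        s=frame["s"].to_numpy(),
        mu_true=frame["mu_true"].to_numpy(),
        beta_true=drug_first["beta_true"].to_numpy(),
        gamma_true=class_first["gamma_true"].to_numpy(),
    )
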