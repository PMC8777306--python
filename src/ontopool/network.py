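"""Trial networks: the trial-drug-class hierarchy underlying the meta-analysis.

A :class:`TrialNetwork` holds trials of drugs classified by the WHO-ATC
ontology: each trial belongs to one drug (ATC level-7 code) and each drug to
one level-5 class whose code is a prefix of the drug code.  The network
supplies the nesting structure for the hierarchical model and, together with
a comorbidity prevalence, the standard error of each trial's
comorbidity-treatment interaction estimate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "TrialRecord",
    "TrialNetwork",
    "NetworkValidationError",
    "SmallTrialWarning",
    "read_network",
    "write_network",
    "default_network",
    "interaction_se",
]

#: minimum enrollment used when screening real trials; smaller values are
#: legal inputs but trigger a warning.
ENROLLMENT_SCREEN = 300

NETWORK_COLUMNS = ["trial_id", "drug_code", "drug_name", "class_code", "enrollment"]


class NetworkValidationError(ValueError):
    """Raised when a trial network violates a structural invariant."""


class SmallTrialWarning(UserWarning):
    """A trial enrolls fewer participants than the selection screen."""


@dataclass(frozen=True)
class TrialRecord:
    """One randomized trial of one drug.

    ``class_code`` must be a prefix of ``drug_code`` (ATC level-5 vs level-7);
    ``enrollment`` is the number of randomized participants.
    """

    trial_id: str
    drug_code: str
    class_code: str
    enrollment: int
    drug_name: str = ""

    def __post_init__(self) -> None:
        if int(self.enrollment) < 1:
            raise NetworkValidationError(
                f"trial {self.trial_id!r}: enrollment must be >= 1, "
                f"got {self.enrollment}"
            )
        if not self.drug_code.startswith(self.class_code):
            raise NetworkValidationError(
                f"trial {self.trial_id!r}: class code {self.class_code!r} is not "
                f"a prefix of drug code {self.drug_code!r}"
            )


class TrialNetwork:
    """An ordered, validated collection of :class:`TrialRecord`.

    Derived indices (stable, in order of first appearance):

    - ``drug_codes`` / ``class_codes``: unique drugs and classes;
    - ``trial_drug_idx``: for each trial, the position of its drug;
    - ``drug_class_idx``: for each drug, the position of its class.
    """

    def __init__(self, records: Iterable[TrialRecord]):
        self.records: tuple[TrialRecord, ...] = tuple(records)
        if not self.records:
            raise NetworkValidationError("a trial network needs at least one trial")
        self._validate()
        self._build_indices()

    def _validate(self) -> None:
        seen: set[str] = set()
        drug_class: dict[str, str] = {}
        for rec in self.records:
            if rec.trial_id in seen:
                raise NetworkValidationError(f"duplicate trial id {rec.trial_id!r}")
            seen.add(rec.trial_id)
            prev = drug_class.setdefault(rec.drug_code, rec.class_code)
            if prev != rec.class_code:
                raise NetworkValidationError(
                    f"drug {rec.drug_code!r} assigned to two classes: "
                    f"{prev!r} and {rec.class_code!r}"
                )
            if rec.enrollment < ENROLLMENT_SCREEN:
                warnings.warn(
                    f"trial {rec.trial_id!r} enrolls {rec.enrollment} participants "
                    f"(< {ENROLLMENT_SCREEN}, the usual selection screen)",
                    SmallTrialWarning,
                    stacklevel=3,
                )

    def _build_indices(self) -> None:
        drug_codes: list[str] = []
        class_codes: list[str] = []
        drug_pos: dict[str, int] = {}
        class_pos: dict[str, int] = {}
        trial_drug = np.empty(len(self.records), dtype=np.intp)
        drug_class: list[int] = []
        for i, rec in enumerate(self.records):
            if rec.drug_code not in drug_pos:
                drug_pos[rec.drug_code] = len(drug_codes)
                drug_codes.append(rec.drug_code)
                if rec.class_code not in class_pos:
                    class_pos[rec.class_code] = len(class_codes)
                    class_codes.append(rec.class_code)
                drug_class.append(class_pos[rec.class_code])
            trial_drug[i] = drug_pos[rec.drug_code]
        self.drug_codes: tuple[str, ...] = tuple(drug_codes)
        self.class_codes: tuple[str, ...] = tuple(class_codes)
        self.trial_drug_idx: np.ndarray = trial_drug
        self.drug_class_idx: np.ndarray = np.asarray(drug_class, dtype=np.intp)

    # -- aggregates ---------------------------------------------------------

    @property
    def n_trials(self) -> int:
        return len(self.records)

    @property
    def n_drugs(self) -> int:
        return len(self.drug_codes)

    @property
    def n_classes(self) -> int:
        return len(self.class_codes)

    @property
    def total_enrollment(self) -> int:
        return int(sum(rec.enrollment for rec in self.records))

    @property
    def enrollments(self) -> np.ndarray:
        return np.array([rec.enrollment for rec in self.records], dtype=float)

    def class_of_drug(self, drug_code: str) -> str:
        return self.class_codes[self.drug_class_idx[self.drug_codes.index(drug_code)]]

    def trials_per_drug(self) -> np.ndarray:
        return np.bincount(self.trial_drug_idx, minlength=self.n_drugs)

    def enrollment_per_drug(self) -> np.ndarray:
        return np.bincount(
            self.trial_drug_idx, weights=self.enrollments, minlength=self.n_drugs
        )

    def subset_drug(self, drug_code: str) -> "TrialNetwork":
        """Network restricted to the trials of one drug."""
        if drug_code not in self.drug_codes:
            raise KeyError(f"unknown drug code {drug_code!r}")
        return TrialNetwork(r for r in self.records if r.drug_code == drug_code)

    # -- conversion ---------------------------------------------------------

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "trial_id": [r.trial_id for r in self.records],
                "drug_code": [r.drug_code for r in self.records],
                "drug_name": [r.drug_name for r in self.records],
                "class_code": [r.class_code for r in self.records],
                "enrollment": [r.enrollment for r in self.records],
            }
        )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "TrialNetwork":
        missing = {"trial_id", "drug_code", "class_code", "enrollment"} - set(
            frame.columns
        )
        if missing:
            raise NetworkValidationError(
                f"missing required columns: {sorted(missing)}"
            )
        records = []
        for row in frame.itertuples(index=False):
            name = getattr(row, "drug_name", "")
            records.append(
                TrialRecord(
                    trial_id=str(row.trial_id),
                    drug_code=str(row.drug_code),
                    class_code=str(row.class_code),
                    enrollment=int(row.enrollment),
                    drug_name="" if pd.isna(name) else str(name),
                )
            )
        return cls(records)

    def __eq__(self, other: object) -> bool:
        return isinstance(other, TrialNetwork) and self.records == other.records

    def __repr__(self) -> str:
        return (
            f"TrialNetwork({self.n_trials} trials, {self.n_drugs} drugs, "
            f"{self.n_classes} classes, {self.total_enrollment} participants)"
        )


def read_network(
    path: str | Path, dialect: Mapping[str, str] | None = None
) -> TrialNetwork:
    """Read a trial network from CSV.

    ``dialect`` optionally maps canonical column names (``trial_id``,
    ``drug_code``, ``class_code``, ``enrollment``, ``drug_name``) to the
    column names used in the file.
    """
    frame = pd.read_csv(path, dtype=str)
    if dialect:
        frame = frame.rename(columns={v: k for k, v in dialect.items()})
    if "enrollment" in frame.columns:
        frame["enrollment"] = pd.to_numeric(frame["enrollment"])
    return TrialNetwork.from_frame(frame)


def write_network(network: TrialNetwork, path: str | Path) -> None:
    """Write a network to CSV in the canonical column order."""
    network.to_frame()[NETWORK_COLUMNS].to_csv(path, index=False)


def default_network() -> TrialNetwork:
    """The packaged stand-in network of non-insulin glucose-lowering drug trials.

    161 trials of 24 drugs in 7 WHO-ATC level-5 classes, 210,046 participants
    in total — matching the published aggregates of the real trial network,
    whose per-trial composition is not public.  The allocation is synthetic
    (frozen in ``data/default_network.csv``): trials-per-drug and enrollments
    are right-skewed, class sizes range from one to six drugs, and one drug
    (taspoglutide) has a single small trial, so that the qualitative features
    the hierarchical model exploits — drugs with few or small trials — are
    represented.
    """
    with resources.files("ontopool.data").joinpath("default_network.csv").open() as fh:
        frame = pd.read_csv(fh)
    return TrialNetwork.from_frame(frame)


def interaction_se(
    enrollment: float, prevalence: float, outcome_sd: float = 1.0
) -> float:
    """Standard error of a trial-level comorbidity-treatment interaction.

    For a two-arm trial with 1:1 allocation, a continuous outcome with
    standard deviation ``outcome_sd`` and a comorbid subgroup of proportion
    ``prevalence``, the difference-in-differences interaction estimate has

        se = 2 * outcome_sd / sqrt(n * p * (1 - p))

    which is the least-squares interaction SE under balanced allocation.
    Strictly decreasing in ``enrollment``; minimised over ``prevalence`` at
    0.5.
    """
    if not 0.0 < prevalence < 1.0:
        raise ValueError(f"prevalence must be in (0, 1), got {prevalence}")
    if enrollment < 1:
        raise ValueError(f"enrollment must be >= 1, got {enrollment}")
    if outcome_sd <= 0:
        raise ValueError(f"outcome_sd must be > 0, got {outcome_sd}")
    return 2.0 * outcome_sd / np.sqrt(enrollment * prevalence * (1.0 - prevalence))
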