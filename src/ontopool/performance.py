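"""Simulation-study performance measures with Monte Carlo standard errors.

Implements the standard repertoire for comparing estimators across simulated
replicates — bias, MSE, RMSE, empirical-SE-based relative precision, and
coverage — each with its Monte Carlo SE, plus the per-drug "detection class"
decomposition (which of the two models' 95% credible intervals exclude
zero).  Estimates are pooled over drugs and replicates with equal weight;
replicates must be paired between models (same simulated datasets) for the
comparative measures.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .models import BatchBetaFit
from .network import TrialNetwork
from .scenarios import SimulatedDataset

__all__ = [
    "estimate_records",
    "bias",
    "mse",
    "rmse",
    "empirical_se",
    "relative_precision",
    "coverage",
    "detection_classes",
    "performance_table",
    "per_class_relative_precision",
    "MEASURES",
]

MEASURES = ("bias", "mse", "rmse", "rel_precision", "coverage")

RECORD_COLUMNS = ["rep", "drug_code", "model", "est", "ci_low", "ci_high", "truth"]


def estimate_records(
    datasets: Sequence[SimulatedDataset],
    fit: BatchBetaFit,
    model: str,
) -> pd.DataFrame:
    """Long-format estimate records (one row per replicate x drug).

    Columns: ``rep, drug_code, model, est, ci_low, ci_high, truth`` where
    ``truth`` is the replicate's simulated drug-level effect.
    """
    R, D = fit.est.shape
    if len(datasets) != R:
        raise ValueError(f"{len(datasets)} datasets but {R} fitted replicates")
    truths = np.stack([ds.beta_true for ds in datasets])
    return pd.DataFrame(
        {
            "rep": np.repeat(np.arange(R), D),
            "drug_code": np.tile(np.asarray(fit.drug_codes), R),
            "model": model,
            "est": fit.est.ravel(),
            "ci_low": fit.ci_low.ravel(),
            "ci_high": fit.ci_high.ravel(),
            "truth": truths.ravel(),
        }
    )


def _errors(records: pd.DataFrame, min_rows: int = 2) -> np.ndarray:
    if len(records) < min_rows:
        raise ValueError(f"need at least {min_rows} estimate records")
    return (records["est"] - records["truth"]).to_numpy()


def bias(records: pd.DataFrame) -> tuple[float, float]:
    """Mean error, pooled over drugs and replicates; MCSE = sd(error)/sqrt(N)."""
    err = _errors(records)
    return float(err.mean()), float(err.std(ddof=1) / np.sqrt(len(err)))


def mse(records: pd.DataFrame) -> tuple[float, float]:
    """Mean squared error; MCSE = sd(squared error)/sqrt(N)."""
    sq = _errors(records) ** 2
    return float(sq.mean()), float(sq.std(ddof=1) / np.sqrt(len(sq)))


def rmse(records: pd.DataFrame) -> tuple[float, float]:
    """Root mean squared error; MCSE by the delta method, mcse_mse/(2*sqrt(mse))."""
    m, m_se = mse(records)
    if m == 0.0:
        return 0.0, 0.0
    return float(np.sqrt(m)), float(m_se / (2.0 * np.sqrt(m)))


def empirical_se(records: pd.DataFrame, center: str = "estimates") -> float:
    """SD of the point estimates across pooled records.

    ``center="estimates"`` (the rsimsum convention and the default here)
    takes the SD of the estimates themselves; ``center="errors"`` takes the
    SD of est - truth, which removes between-drug spread of the replicate
    truths.
    """
    if center == "estimates":
        x = records["est"].to_numpy()
    elif center == "errors":
        x = _errors(records)
    else:
        raise ValueError(f"unknown center {center!r}")
    return float(x.std(ddof=1))


def _paired(records_a: pd.DataFrame, records_b: pd.DataFrame) -> None:
    key_a = records_a[["rep", "drug_code"]].to_numpy()
    key_b = records_b[["rep", "drug_code"]].to_numpy()
    if key_a.shape != key_b.shape or not (key_a == key_b).all():
        raise ValueError(
            "records are not paired: both models must be fitted to the same "
            "replicates and drugs, in the same order"
        )


def relative_precision(
    records_single: pd.DataFrame,
    records_full: pd.DataFrame,
    center: str = "estimates",
) -> tuple[float, float]:
    """Percent precision gain of the full over the single-drug model.

    100 * ((empSE_single / empSE_full)^2 - 1), with the empirical SE taken
    over pooled (replicate, drug) point estimates; the MCSE is a leave-one-
    replicate-out jackknife, which respects the pairing of the two models on
    the same datasets.
    """
    _paired(records_single, records_full)
    xs = records_single["est"].to_numpy() if center == "estimates" else _errors(
        records_single
    )
    xf = records_full["est"].to_numpy() if center == "estimates" else _errors(
        records_full
    )
    vs, vf = xs.var(ddof=1), xf.var(ddof=1)
    if vf == 0.0:
        raise ValueError("full-model empirical SE is zero")
    est = 100.0 * (vs / vf - 1.0)

    reps = records_single["rep"].to_numpy()
    rep_ids, inv = np.unique(reps, return_inverse=True)
    R = len(rep_ids)
    n = len(xs)

    def loo_var(x: np.ndarray) -> np.ndarray:
        # leave-one-replicate-out variance via group sums
        gs = np.bincount(inv, weights=x, minlength=R)
        gss = np.bincount(inv, weights=x**2, minlength=R)
        gn = np.bincount(inv, minlength=R)
        tot, tot2 = x.sum(), (x**2).sum()
        m = n - gn
        with np.errstate(divide="ignore", invalid="ignore"):
            mean_ = (tot - gs) / m
            return ((tot2 - gss) - m * mean_**2) / (m - 1)

    with np.errstate(divide="ignore", invalid="ignore"):
        theta = 100.0 * (loo_var(xs) / loo_var(xf) - 1.0)
    mcse = float(np.sqrt((R - 1) / R * ((theta - theta.mean()) ** 2).sum()))
    return float(est), mcse


def coverage(records: pd.DataFrame) -> tuple[float, float]:
    """Proportion of 95% intervals containing the truth; binomial MCSE."""
    if len(records) < 1:
        raise ValueError("need at least one estimate record")
    inside = (
        (records["ci_low"] <= records["truth"])
        & (records["truth"] <= records["ci_high"])
    ).to_numpy()
    c = float(inside.mean())
    return c, float(np.sqrt(c * (1.0 - c) / len(inside)))


@dataclass
class DetectionSummary:
    """Per-drug proportions of replicates in which each model's 95% interval
    excluded zero: both, single only, full only, neither (summing to 1)."""

    table: pd.DataFrame  # columns drug_code, p_both, p_single_only, p_full_only, p_neither, n_reps

    def to_frame(self) -> pd.DataFrame:
        return self.table.copy()


def detection_classes(
    records_single: pd.DataFrame,
    records_full: pd.DataFrame,
    effect_threshold: float | None = -0.10,
) -> DetectionSummary:
    """Classify detections per drug across paired replicates.

    A model "detects" when its interval excludes zero.  When
    ``effect_threshold`` is set (default -0.10), only replicates whose true
    drug-level effect is at least that large in the simulated direction
    (truth <= threshold for a negative threshold, truth >= threshold
    otherwise) are counted; pass ``None`` to disable the conditioning.
    """
    _paired(records_single, records_full)
    det_s = ((records_single["ci_low"] > 0) | (records_single["ci_high"] < 0)).to_numpy()
    det_f = ((records_full["ci_low"] > 0) | (records_full["ci_high"] < 0)).to_numpy()
    truth = records_single["truth"].to_numpy()
    if effect_threshold is None:
        keep = np.ones(len(truth), dtype=bool)
    elif effect_threshold <= 0:
        keep = truth <= effect_threshold
    else:
        keep = truth >= effect_threshold

    frame = pd.DataFrame(
        {
            "drug_code": records_single["drug_code"].to_numpy(),
            "keep": keep,
            "both": det_s & det_f,
            "single_only": det_s & ~det_f,
            "full_only": ~det_s & det_f,
            "neither": ~det_s & ~det_f,
        }
    )
    frame = frame[frame["keep"]].drop(columns="keep")
    order = records_single["drug_code"].drop_duplicates().tolist()
    rows = []
    for drug in order:
        sub = frame[frame["drug_code"] == drug]
        n = len(sub)
        if n == 0:
            rows.append((drug, np.nan, np.nan, np.nan, np.nan, 0))
            continue
        rows.append(
            (
                drug,
                sub["both"].mean(),
                sub["single_only"].mean(),
                sub["full_only"].mean(),
                sub["neither"].mean(),
                n,
            )
        )
    return DetectionSummary(
        pd.DataFrame(
            rows,
            columns=[
                "drug_code",
                "p_both",
                "p_single_only",
                "p_full_only",
                "p_neither",
                "n_reps",
            ],
        )
    )


_SCENARIO_SPLIT = {
    "all-low": ("All", "Low"),
    "all-medium": ("All", "Medium"),
    "all-high": ("All", "High"),
    "trial-medium": ("Trial", "Medium"),
    "trial-high": ("Trial", "High"),
    "drug-medium": ("Drug", "Medium"),
    "drug-high": ("Drug", "High"),
    "class-medium": ("Class", "Medium"),
    "class-high": ("Class", "High"),
}


def performance_table(
    records: pd.DataFrame,
    scenarios: Iterable[str] | None = None,
    models: Sequence[str] = ("single", "full"),
    center: str = "estimates",
) -> pd.DataFrame:
    """Long-format performance table over scenario x model cells.

    ``records`` must carry a ``scenario`` column in addition to the estimate
    record columns.  Relative precision is reported for the full model only
    (it is defined against the single-drug comparator).  Raises if any
    requested scenario x model cell has no records.
    """
    if "scenario" not in records.columns:
        raise ValueError("records need a 'scenario' column")
    scenario_list = (
        list(scenarios)
        if scenarios is not None
        else list(records["scenario"].drop_duplicates())
    )
    rows = []
    for scen in scenario_list:
        level, variation = _SCENARIO_SPLIT.get(scen, (scen, ""))
        sub = records[records["scenario"] == scen]
        per_model = {}
        for model in models:
            cell = sub[sub["model"] == model].reset_index(drop=True)
            if cell.empty:
                raise ValueError(f"no records for cell scenario={scen!r} model={model!r}")
            per_model[model] = cell
        for model in models:
            cell = per_model[model]
            for measure, fn in (("bias", bias), ("mse", mse), ("rmse", rmse), ("coverage", coverage)):
                est, mcse_ = fn(cell)
                rows.append((scen, level, variation, measure, model, est, mcse_))
        if "single" in per_model and "full" in per_model:
            # the single-drug column carries a dash in the published layout
            rows.append(
                (scen, level, variation, "rel_precision", "single", np.nan, np.nan)
            )
            est, mcse_ = relative_precision(
                per_model["single"], per_model["full"], center=center
            )
            rows.append((scen, level, variation, "rel_precision", "full", est, mcse_))
    return pd.DataFrame(
        rows,
        columns=[
            "scenario",
            "scenario_level",
            "variation",
            "measure",
            "model",
            "estimate",
            "mcse",
        ],
    )


def per_class_relative_precision(
    records_single: pd.DataFrame,
    records_full: pd.DataFrame,
    network: TrialNetwork,
    center: str = "estimates",
) -> pd.DataFrame:
    """Relative precision computed within each ATC class (per-class rows)."""
    _paired(records_single, records_full)
    rows = []
    for class_code in network.class_codes:
        drugs = [
            d
            for d, c in zip(network.drug_codes, network.drug_class_idx)
            if network.class_codes[c] == class_code
        ]
        sel_s = records_single[records_single["drug_code"].isin(drugs)].reset_index(
            drop=True
        )
        sel_f = records_full[records_full["drug_code"].isin(drugs)].reset_index(
            drop=True
        )
        est, mcse_ = relative_precision(sel_s, sel_f, center=center)
        rows.append((class_code, len(drugs), est, mcse_))
    return pd.DataFrame(
        rows, columns=["class_code", "n_drugs", "rel_precision", "mcse"]
    )
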