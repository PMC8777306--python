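"""Bayesian hierarchical models for trial-level interaction estimates.

Two models are fitted to observed pairs (y_z, s_z):

- the **full model**, with trials nested in drugs nested in ATC classes:

      y_z ~ N(mu_z, s_z^2),   mu_z   ~ N(beta_d, tau_d^2),
      beta_d ~ N(gamma_c, sigma_c^2), gamma_c ~ N(alpha, zeta^2),
      alpha ~ N(0, 2^2),  tau_d, sigma_c, zeta ~ half-N(0, 1^2);

- the **single-drug model**, the lowest two levels only, fitted per drug,
  with beta_d ~ N(0, 2^2) replacing the upper hierarchy.

Inference is by blocked Gibbs sampling (conjugate normal updates for
locations, slice updates for the half-normal-prior scales); with all scale
parameters fixed, the model is jointly Gaussian and
:func:`fit_conjugate_oracle` computes the exact posterior by a single
precision-matrix solve — used both to validate the sampler and as a fast
deterministic approximation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from ._engine import GibbsStructure, run_gibbs_full, run_gibbs_single
from .network import TrialNetwork
from .scenarios import child_seed

__all__ = [
    "PriorSpec",
    "FixedScales",
    "InferenceSettings",
    "PosteriorSummary",
    "Diagnostics",
    "FullFit",
    "SingleFit",
    "BatchBetaFit",
    "ConvergenceWarning",
    "fit_full",
    "fit_single",
    "fit_full_batch",
    "fit_singles_batch",
    "fit_conjugate_oracle",
    "single_drug_conjugate_oracle",
    "check_convergence",
]


class ConvergenceWarning(UserWarning):
    """A fit's convergence diagnostics exceeded their thresholds."""


@dataclass(frozen=True)
class PriorSpec:
    """Priors: N(0, location_prior_sd^2) on the top-level location (alpha in
    the full model, beta_d in single-drug models) and half-N(0,
    scale_prior_sd^2) on every between-level SD."""

    location_prior_sd: float = 2.0
    scale_prior_sd: float = 1.0

    def __post_init__(self) -> None:
        if self.location_prior_sd <= 0 or self.scale_prior_sd <= 0:
            raise ValueError("prior SDs must be positive")


@dataclass(frozen=True)
class FixedScales:
    """Pinned values for the scale parameters (scalars broadcast)."""

    zeta: float = 0.1
    sigma: float | np.ndarray = 0.1
    tau: float | np.ndarray = 0.1


@dataclass(frozen=True)
class InferenceSettings:
    """Gibbs sampler configuration.

    Defaults follow common practice for this model size: 2 chains x (500
    warm-up + 2500 kept) = 6000 total sweeps, 1000 discarded.  ``batch()``
    is a lighter preset for simulation batches where only drug-level point
    estimates and intervals are consumed downstream.
    """

    n_chains: int = 2
    n_draws: int = 2500
    n_warmup: int = 500
    seed: int = 0
    slice_width: float = 0.25
    store: str = "all"  # "all" | "beta"
    compute_diagnostics: bool = True
    rhat_max: float = 1.01
    ess_min: float = 400.0

    @classmethod
    def batch(cls, seed: int = 0) -> "InferenceSettings":
        return cls(
            n_chains=1,
            n_draws=1250,
            n_warmup=350,
            seed=seed,
            store="beta",
            compute_diagnostics=False,
        )


@dataclass(frozen=True)
class PosteriorSummary:
    """Marginal posterior summary: mean, SD, equal-tailed 95% interval,
    median, Monte Carlo error of the mean, and effective sample size."""

    mean: float
    sd: float
    q025: float
    q50: float
    q975: float
    mc_error: float
    ess: float


@dataclass
class Diagnostics:
    """Convergence report: split-chain R-hat and bulk ESS per parameter."""

    converged: bool
    max_rhat: float
    min_ess: float
    flagged: list[str] = field(default_factory=list)


@dataclass
class FullFit:
    """Posterior summaries for all parameters of the full model."""

    alpha: PosteriorSummary
    gamma: dict[str, PosteriorSummary]
    beta: dict[str, PosteriorSummary]
    zeta: PosteriorSummary
    sigma: dict[str, PosteriorSummary]
    tau: dict[str, PosteriorSummary]
    diagnostics: Diagnostics
    draws: dict[str, np.ndarray] | None = None  # (chains, draws, ...) network order


@dataclass
class SingleFit:
    """Posterior summaries for one drug's two-level model."""

    drug_code: str
    beta: PosteriorSummary
    tau: PosteriorSummary
    diagnostics: Diagnostics
    draws: dict[str, np.ndarray] | None = None


@dataclass
class BatchBetaFit:
    """Drug-level posterior summaries for a batch of replicate datasets.

    Arrays have shape (n_reps, n_drugs), aligned with ``drug_codes``.
    """

    drug_codes: tuple[str, ...]
    est: np.ndarray
    sd: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray


def _check_observed(y: np.ndarray, s: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    y = np.atleast_2d(np.asarray(y, dtype=float))
    s = np.asarray(s, dtype=float)
    if not np.all(np.isfinite(y)):
        raise ValueError("observed estimates y must be finite")
    if np.any(s <= 0) or not np.all(np.isfinite(s)):
        raise ValueError("standard errors s must be finite and > 0")
    return y, s


def _summaries_from_draws(draws: np.ndarray, ess: np.ndarray | None) -> list[
    PosteriorSummary
]:
    """Summarise (chains, draws, k) or (chains, draws) arrays."""
    if draws.ndim == 2:
        draws = draws[:, :, None]
    flat = draws.reshape(-1, draws.shape[-1])
    mean = flat.mean(axis=0)
    sd = flat.std(axis=0, ddof=1)
    q025, q50, q975 = np.quantile(flat, [0.025, 0.5, 0.975], axis=0)
    n = flat.shape[0]
    ess_arr = np.full(flat.shape[-1], float(n)) if ess is None else np.asarray(ess)
    mc = sd / np.sqrt(np.maximum(ess_arr, 1.0))
    return [
        PosteriorSummary(
            mean=float(mean[k]),
            sd=float(sd[k]),
            q025=float(q025[k]),
            q50=float(q50[k]),
            q975=float(q975[k]),
            mc_error=float(mc[k]),
            ess=float(ess_arr[k]),
        )
        for k in range(flat.shape[-1])
    ]


def check_convergence(
    draws: dict[str, np.ndarray],
    rhat_max: float = 1.01,
    ess_min: float = 400.0,
) -> tuple[Diagnostics, dict[str, np.ndarray]]:
    """Split-chain R-hat / bulk-ESS diagnostics for (chains, draws, ...) arrays.

    Returns the overall report and per-parameter ESS arrays (used for Monte
    Carlo errors).  Single chains are split in two, so diagnostics remain
    defined for one-chain runs.
    """
    import arviz as az

    max_rhat, min_ess = 0.0, np.inf
    flagged: list[str] = []
    ess_out: dict[str, np.ndarray] = {}
    for name, arr in draws.items():
        a = arr if arr.ndim == 3 else arr[:, :, None]
        if a.shape[0] == 1:  # split the single chain for R-hat
            half = a.shape[1] // 2
            a = np.concatenate([a[:, :half], a[:, half : 2 * half]], axis=0)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            ds = az.convert_to_dataset(a)
            rhat = np.asarray(az.rhat(ds).to_array()).ravel()
            ess = np.asarray(az.ess(ds).to_array()).ravel()
        ess_out[name] = ess
        for k in range(a.shape[-1]):
            label = name if a.shape[-1] == 1 else f"{name}[{k}]"
            if rhat[k] > rhat_max or ess[k] < ess_min:
                flagged.append(label)
        max_rhat = max(max_rhat, float(np.nanmax(rhat)))
        min_ess = min(min_ess, float(np.nanmin(ess)))
    return Diagnostics(
        converged=not flagged, max_rhat=max_rhat, min_ess=min_ess, flagged=flagged
    ), ess_out


def _run_chains(kernel, n_chains: int, seed: int, **kwargs) -> dict[str, np.ndarray]:
    """Run chains sequentially; stack draws as (chains, draws, ...)."""
    chains: list[dict[str, np.ndarray]] = []
    for c in range(n_chains):
        rng = np.random.default_rng(child_seed(seed, 1, c))
        chains.append(kernel(rng=rng, **kwargs))
    return {
        name: np.stack([ch[name][0] for ch in chains], axis=0)
        for name in chains[0]
    }


def _fixed_dict(
    fixed: FixedScales | None, n_drugs: int, n_classes: int
) -> dict | None:
    if fixed is None:
        return None
    return {
        "zeta": np.broadcast_to(np.asarray(fixed.zeta, float), ()),
        "sigma": np.broadcast_to(np.asarray(fixed.sigma, float), (n_classes,)),
        "tau": np.broadcast_to(np.asarray(fixed.tau, float), (n_drugs,)),
    }


def fit_full(
    network: TrialNetwork,
    y: np.ndarray,
    s: np.ndarray,
    priors: PriorSpec = PriorSpec(),
    settings: InferenceSettings = InferenceSettings(),
    fixed_scales: FixedScales | None = None,
) -> FullFit:
    """Fit the full ontology-structured model to one dataset.

    ``y`` and ``s`` are in the network's trial order.  A result whose
    diagnostics exceed their thresholds is returned flagged (with a
    :class:`ConvergenceWarning`), never silently.
    """
    y, s = _check_observed(y, s)
    if y.shape != (1, network.n_trials):
        raise ValueError(
            f"expected one y per trial ({network.n_trials}), got shape {y.shape}"
        )
    struct = GibbsStructure.from_network(network)
    draws = _run_chains(
        run_gibbs_full,
        settings.n_chains,
        settings.seed,
        y=y[:, struct.t_perm],
        s2=np.square(s[struct.t_perm]),
        struct=struct,
        loc_prior_var=priors.location_prior_sd**2,
        scale_prior_var=priors.scale_prior_sd**2,
        n_warmup=settings.n_warmup,
        n_draws=settings.n_draws,
        slice_width=settings.slice_width,
        fixed=_fixed_dict(fixed_scales, network.n_drugs, network.n_classes),
        store="all",
    )
    # map engine drug order back to network order
    inv_d = np.argsort(struct.d_perm)
    for name in ("beta", "tau"):
        draws[name] = draws[name][:, :, inv_d]

    if settings.compute_diagnostics and fixed_scales is None:
        diag, ess = check_convergence(draws, settings.rhat_max, settings.ess_min)
    elif settings.compute_diagnostics:
        diag, ess = check_convergence(
            {k: draws[k] for k in ("alpha", "gamma", "beta")},
            settings.rhat_max,
            settings.ess_min,
        )
    else:
        diag, ess = Diagnostics(True, np.nan, np.nan), {}
    if not diag.converged:
        warnings.warn(
            f"fit flagged: max R-hat {diag.max_rhat:.3f}, min ESS "
            f"{diag.min_ess:.0f} ({len(diag.flagged)} parameter(s))",
            ConvergenceWarning,
            stacklevel=2,
        )

    def summ(name: str) -> list[PosteriorSummary]:
        return _summaries_from_draws(draws[name], ess.get(name))

    beta_s, tau_s = summ("beta"), summ("tau")
    gamma_s, sigma_s = summ("gamma"), summ("sigma")
    return FullFit(
        alpha=summ("alpha")[0],
        gamma=dict(zip(network.class_codes, gamma_s)),
        beta=dict(zip(network.drug_codes, beta_s)),
        zeta=summ("zeta")[0],
        sigma=dict(zip(network.class_codes, sigma_s)),
        tau=dict(zip(network.drug_codes, tau_s)),
        diagnostics=diag,
        draws=draws,
    )


def fit_single(
    y: np.ndarray,
    s: np.ndarray,
    priors: PriorSpec = PriorSpec(),
    settings: InferenceSettings = InferenceSettings(),
    drug_code: str = "drug",
    fixed_tau: float | None = None,
) -> SingleFit:
    """Fit the two-level single-drug model to one drug's trials."""
    y, s = _check_observed(y, s)
    n = y.shape[1]
    if n < 1:
        raise ValueError("at least one trial is required")
    struct = _single_drug_structure(n)
    draws = _run_chains(
        run_gibbs_single,
        settings.n_chains,
        settings.seed,
        y=y,
        s2=np.square(s),
        struct=struct,
        loc_prior_var=priors.location_prior_sd**2,
        scale_prior_var=priors.scale_prior_sd**2,
        n_warmup=settings.n_warmup,
        n_draws=settings.n_draws,
        slice_width=settings.slice_width,
        fixed_tau=None if fixed_tau is None else np.asarray([fixed_tau]),
        store="all",
    )
    if settings.compute_diagnostics:
        which = {"beta": draws["beta"]} if fixed_tau is not None else draws
        diag, ess = check_convergence(which, settings.rhat_max, settings.ess_min)
    else:
        diag, ess = Diagnostics(True, np.nan, np.nan), {}
    if not diag.converged:
        warnings.warn(
            f"fit flagged: max R-hat {diag.max_rhat:.3f}, min ESS "
            f"{diag.min_ess:.0f}",
            ConvergenceWarning,
            stacklevel=2,
        )
    return SingleFit(
        drug_code=drug_code,
        beta=_summaries_from_draws(draws["beta"], ess.get("beta"))[0],
        tau=_summaries_from_draws(draws["tau"], ess.get("tau"))[0],
        diagnostics=diag,
        draws=draws,
    )


def _single_drug_structure(n_trials: int) -> GibbsStructure:
    return GibbsStructure(
        n_trials=n_trials,
        n_drugs=1,
        n_classes=1,
        t_perm=np.arange(n_trials),
        d_perm=np.arange(1),
        d_idx=np.zeros(n_trials, dtype=np.intp),
        c_idx=np.zeros(1, dtype=np.intp),
        t_starts=np.array([0]),
        d_starts=np.array([0]),
        n_trials_per_drug=np.array([float(n_trials)]),
        n_drugs_per_class=np.array([1.0]),
    )


def _batch_beta_summary(
    beta_draws: np.ndarray, drug_codes: tuple[str, ...]
) -> BatchBetaFit:
    """Summarise (R, draws, D) beta draws into per-rep, per-drug summaries."""
    est = beta_draws.mean(axis=1)
    sd = beta_draws.std(axis=1, ddof=1)
    ci_low, ci_high = np.quantile(beta_draws, [0.025, 0.975], axis=1)
    return BatchBetaFit(
        drug_codes=drug_codes, est=est, sd=sd, ci_low=ci_low, ci_high=ci_high
    )


def fit_full_batch(
    network: TrialNetwork,
    Y: np.ndarray,
    s: np.ndarray,
    priors: PriorSpec = PriorSpec(),
    settings: InferenceSettings | None = None,
) -> BatchBetaFit:
    """Fit the full model to R replicate datasets sharing one network.

    ``Y`` is (R, n_trials); replicates are sampled jointly in one vectorised
    Gibbs pass (they are conditionally independent, so this is exact) and
    drug-level posterior summaries are returned per replicate.
    """
    settings = settings or InferenceSettings.batch()
    Y, s = _check_observed(Y, s)
    struct = GibbsStructure.from_network(network)
    rng = np.random.default_rng(child_seed(settings.seed, 2, 0))
    draws = run_gibbs_full(
        y=Y[:, struct.t_perm],
        s2=np.square(s[struct.t_perm]),
        struct=struct,
        loc_prior_var=priors.location_prior_sd**2,
        scale_prior_var=priors.scale_prior_sd**2,
        n_warmup=settings.n_warmup,
        n_draws=settings.n_draws * settings.n_chains,
        rng=rng,
        slice_width=settings.slice_width,
        store="beta",
    )
    beta = draws["beta"][:, :, np.argsort(struct.d_perm)]
    return _batch_beta_summary(beta, network.drug_codes)


def fit_singles_batch(
    network: TrialNetwork,
    Y: np.ndarray,
    s: np.ndarray,
    priors: PriorSpec = PriorSpec(),
    settings: InferenceSettings | None = None,
) -> BatchBetaFit:
    """Fit every drug's single-drug model to R replicate datasets.

    All drugs x replicates are sampled in one vectorised pass; the models
    are mutually independent, so results match per-drug :func:`fit_single`
    up to Monte Carlo error.
    """
    settings = settings or InferenceSettings.batch()
    Y, s = _check_observed(Y, s)
    struct = GibbsStructure.from_network(network)
    rng = np.random.default_rng(child_seed(settings.seed, 3, 0))
    draws = run_gibbs_single(
        y=Y[:, struct.t_perm],
        s2=np.square(s[struct.t_perm]),
        struct=struct,
        loc_prior_var=priors.location_prior_sd**2,
        scale_prior_var=priors.scale_prior_sd**2,
        n_warmup=settings.n_warmup,
        n_draws=settings.n_draws * settings.n_chains,
        rng=rng,
        slice_width=settings.slice_width,
        store="beta",
    )
    beta = draws["beta"][:, :, np.argsort(struct.d_perm)]
    return _batch_beta_summary(beta, network.drug_codes)


# ---------------------------------------------------------------------------
# conjugate oracle
# ---------------------------------------------------------------------------


@dataclass
class ConjugatePosterior:
    """Exact Gaussian posterior of all location parameters given fixed scales.

    Parameter order in ``mean``/``cov``: alpha, gamma (classes), beta
    (drugs), mu (trials), in network order.
    """

    network: TrialNetwork
    mean: np.ndarray
    cov: np.ndarray

    def _slice(self, kind: str) -> slice:
        C, D = self.network.n_classes, self.network.n_drugs
        return {
            "alpha": slice(0, 1),
            "gamma": slice(1, 1 + C),
            "beta": slice(1 + C, 1 + C + D),
            "mu": slice(1 + C + D, None),
        }[kind]

    def mean_of(self, kind: str) -> np.ndarray:
        return self.mean[self._slice(kind)]

    def sd_of(self, kind: str) -> np.ndarray:
        return np.sqrt(np.diag(self.cov)[self._slice(kind)])


def fit_conjugate_oracle(
    y: np.ndarray,
    s: np.ndarray,
    network: TrialNetwork,
    fixed_scales: FixedScales,
    priors: PriorSpec = PriorSpec(),
) -> ConjugatePosterior:
    """Exact posterior of (alpha, gamma, beta, mu) with scales pinned.

    With zeta, sigma_c, tau_d fixed, the full model is jointly Gaussian, so
    the posterior follows from one precision-matrix solve.  This is both the
    sampler-validation oracle and a fast deterministic approximate fitter.
    """
    y2d, s = _check_observed(y, s)
    y = y2d[0]
    C, D, n = network.n_classes, network.n_drugs, network.n_trials
    zeta = float(np.asarray(fixed_scales.zeta))
    sigma = np.broadcast_to(np.asarray(fixed_scales.sigma, float), (C,))
    tau = np.broadcast_to(np.asarray(fixed_scales.tau, float), (D,))
    if zeta < 0 or np.any(sigma < 0) or np.any(tau < 0):
        raise ValueError("fixed scales must be non-negative")

    dim = 1 + C + D + n
    lam = np.zeros((dim, dim))
    b = np.zeros(dim)
    i_gamma = 1 + np.arange(C)
    i_beta = 1 + C + np.arange(D)
    i_mu = 1 + C + D + np.arange(n)

    lam[0, 0] += 1.0 / priors.location_prior_sd**2

    def couple(i: int, j: int, prec: float) -> None:
        lam[i, i] += prec
        lam[j, j] += prec
        lam[i, j] -= prec
        lam[j, i] -= prec

    for c in range(C):
        couple(int(i_gamma[c]), 0, 1.0 / zeta**2)
    for d in range(D):
        c = int(network.drug_class_idx[d])
        couple(int(i_beta[d]), int(i_gamma[c]), 1.0 / sigma[c] ** 2)
    for z in range(n):
        d = int(network.trial_drug_idx[z])
        couple(int(i_mu[z]), int(i_beta[d]), 1.0 / tau[d] ** 2)
        lam[i_mu[z], i_mu[z]] += 1.0 / s[z] ** 2
        b[i_mu[z]] += y[z] / s[z] ** 2

    try:
        cov = np.linalg.inv(lam)
    except np.linalg.LinAlgError as exc:  # zero scales can degenerate
        raise np.linalg.LinAlgError(
            "singular precision matrix; check fixed scales"
        ) from exc
    return ConjugatePosterior(network=network, mean=cov @ b, cov=cov)


def single_drug_conjugate_oracle(
    y: np.ndarray,
    s: np.ndarray,
    tau: float,
    priors: PriorSpec = PriorSpec(),
) -> tuple[float, float]:
    """Exact (mean, sd) of beta in the single-drug model with tau fixed.

    Marginally y_z ~ N(beta, s_z^2 + tau^2) with beta ~ N(0,
    location_prior_sd^2): the classical normal-normal shrinkage estimator.
    """
    y = np.asarray(y, float)
    s = np.asarray(s, float)
    w = 1.0 / (s**2 + tau**2)
    prec = w.sum() + 1.0 / priors.location_prior_sd**2
    return float((w * y).sum() / prec), float(1.0 / np.sqrt(prec))
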