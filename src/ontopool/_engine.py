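"""Sampling engine: blocked Gibbs with conjugate location updates.

The three-level model

    y_z ~ N(mu_z, s_z^2),  mu_z ~ N(beta_d, tau_d^2),
    beta_d ~ N(gamma_c, sigma_c^2),  gamma_c ~ N(alpha, zeta^2)

is sampled with the trial means mu_z integrated out analytically
(y_z ~ N(beta_d, s_z^2 + tau_d^2)), which removes the slowest-mixing block.
Location parameters (beta, gamma, alpha) then have normal full conditionals;
the half-normal-prior scale parameters (tau, sigma, zeta) are updated with
univariate slice sampling, vectorised across drugs/classes.

Every kernel carries a leading replicate axis R, so a batch of independent
datasets sharing one network is sampled in a single pass — replicates are
conditionally independent, so this is exact, not an approximation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import special

_NEG_INF = -np.inf


def _truncnorm_positive(
    mean: np.ndarray, sd: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Draw from N(mean, sd^2) truncated to (0, inf), elementwise."""
    lo = special.ndtr(-mean / sd)  # P(X <= 0)
    u = lo + (1.0 - lo) * rng.uniform(size=np.shape(mean))
    x = mean + sd * special.ndtri(np.clip(u, 1e-15, 1.0 - 1e-16))
    return np.maximum(x, 1e-12)


# ---------------------------------------------------------------------------
# network structure in engine (class-sorted) order
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GibbsStructure:
    """Index arrays for reduceat-based per-drug / per-class sums.

    Trials are permuted so each drug's trials are contiguous and drugs are
    permuted so each class's drugs are contiguous.
    """

    n_trials: int
    n_drugs: int
    n_classes: int
    t_perm: np.ndarray  # engine trial order (indices into network order)
    d_perm: np.ndarray  # engine drug pos -> network drug pos
    d_idx: np.ndarray  # per engine trial: engine drug index (non-decreasing)
    c_idx: np.ndarray  # per engine drug: class index (non-decreasing)
    t_starts: np.ndarray  # reduceat starts per drug
    d_starts: np.ndarray  # reduceat starts per class
    n_trials_per_drug: np.ndarray
    n_drugs_per_class: np.ndarray

    @classmethod
    def from_network(cls, network) -> "GibbsStructure":
        cls_of_drug = network.drug_class_idx
        d_perm = np.argsort(cls_of_drug, kind="stable")
        drug_rank = np.empty(network.n_drugs, dtype=np.intp)
        drug_rank[d_perm] = np.arange(network.n_drugs)
        t_key = drug_rank[network.trial_drug_idx]
        t_perm = np.argsort(t_key, kind="stable")
        d_idx = t_key[t_perm]
        c_idx = cls_of_drug[d_perm]
        t_starts = np.searchsorted(d_idx, np.arange(network.n_drugs))
        d_starts = np.searchsorted(c_idx, np.arange(network.n_classes))
        return cls(
            n_trials=network.n_trials,
            n_drugs=network.n_drugs,
            n_classes=network.n_classes,
            t_perm=t_perm,
            d_perm=d_perm,
            d_idx=d_idx,
            c_idx=c_idx,
            t_starts=t_starts,
            d_starts=d_starts,
            n_trials_per_drug=np.bincount(d_idx, minlength=network.n_drugs).astype(
                float
            ),
            n_drugs_per_class=np.bincount(c_idx, minlength=network.n_classes).astype(
                float
            ),
        )


def _rsum(a: np.ndarray, starts: np.ndarray) -> np.ndarray:
    """Row-wise segment sums (segments defined by ``starts``) along axis 1."""
    return np.add.reduceat(a, starts, axis=1)


# ---------------------------------------------------------------------------
# vectorised slice sampler on [0, inf)
# ---------------------------------------------------------------------------


def slice_update_positive(
    x0: np.ndarray,
    logpdf,
    rng: np.random.Generator,
    width: float = 0.25,
    max_steps: int = 60,
    max_shrink: int = 100,
) -> np.ndarray:
    """One slice-sampling update of each element of ``x0`` (support x >= 0).

    ``logpdf`` maps an array like ``x0`` to elementwise log densities (up to
    a constant) and must return -inf outside the support.  Elements are
    conditionally independent, so the update is performed for all of them at
    once with stepping-out and shrinkage.
    """
    logy = logpdf(x0) - rng.exponential(size=x0.shape)
    u = rng.uniform(size=x0.shape)
    left = np.maximum(x0 - width * u, 0.0)
    right = x0 + width * (1.0 - u)
    for _ in range(max_steps):
        grow_l = (left > 0.0) & (logpdf(left) > logy)
        grow_r = logpdf(right) > logy
        if not (grow_l.any() or grow_r.any()):
            break
        left = np.where(grow_l, np.maximum(left - width, 0.0), left)
        right = np.where(grow_r, right + width, right)
    x1 = x0.copy()
    done = np.zeros(x0.shape, dtype=bool)
    for _ in range(max_shrink):
        prop = left + rng.uniform(size=x0.shape) * (right - left)
        accept = (logpdf(prop) >= logy) & ~done
        x1 = np.where(accept, prop, x1)
        done |= accept
        if done.all():
            break
        shrink_l = ~done & (prop < x0)
        left = np.where(shrink_l, prop, left)
        right = np.where(~done & ~shrink_l, prop, right)
    return x1


# ---------------------------------------------------------------------------
# Gibbs kernels
# ---------------------------------------------------------------------------


def _halfnormal_logprior(x2: np.ndarray, prior_var: float) -> np.ndarray:
    return -x2 / (2.0 * prior_var)


def run_gibbs_full(
    y: np.ndarray,
    s2: np.ndarray,
    struct: GibbsStructure,
    *,
    loc_prior_var: float,
    scale_prior_var: float,
    n_warmup: int,
    n_draws: int,
    rng: np.random.Generator,
    slice_width: float = 0.25,
    fixed: dict | None = None,
    store: str = "all",
) -> dict[str, np.ndarray]:
    """Run one chain of the full-model Gibbs sampler.

    ``y``: (R, n) observed estimates in *engine* trial order; ``s2``: (n,)
    sampling variances in engine order.  ``fixed`` may pin ``zeta`` (R,),
    ``sigma`` (R, C), ``tau`` (R, D) at given values (scale updates skipped).
    Returns draws keyed by parameter, each (R, n_draws, ...).
    """
    R = y.shape[0]
    D, C = struct.n_drugs, struct.n_classes
    d_idx, c_idx = struct.d_idx, struct.c_idx
    t_starts, d_starts = struct.t_starts, struct.d_starts
    n_dc = struct.n_drugs_per_class

    # moment-based start: per-drug means, jittered per chain by the rng
    w0 = 1.0 / s2
    beta = _rsum(np.broadcast_to(w0 * y, y.shape).copy(), t_starts) / _rsum(
        np.broadcast_to(w0, y.shape).copy(), t_starts
    )
    beta = beta + 0.05 * rng.standard_normal((R, D))
    gamma = _rsum(beta, d_starts) / n_dc
    alpha = gamma.mean(axis=1)
    if fixed is not None:
        tau = np.broadcast_to(np.asarray(fixed["tau"], float), (R, D)).copy()
        sigma = np.broadcast_to(np.asarray(fixed["sigma"], float), (R, C)).copy()
        zeta = np.broadcast_to(np.asarray(fixed["zeta"], float), (R,)).copy()
    else:
        tau = np.full((R, D), 0.2) * np.exp(0.2 * rng.standard_normal((R, D)))
        sigma = np.full((R, C), 0.2) * np.exp(0.2 * rng.standard_normal((R, C)))
        zeta = np.full(R, 0.2) * np.exp(0.2 * rng.standard_normal(R))

    out: dict[str, np.ndarray] = {"beta": np.empty((R, n_draws, D))}
    if store == "all":
        out.update(
            alpha=np.empty((R, n_draws)),
            gamma=np.empty((R, n_draws, C)),
            zeta=np.empty((R, n_draws)),
            sigma=np.empty((R, n_draws, C)),
            tau=np.empty((R, n_draws, D)),
        )

    with np.errstate(divide="ignore", invalid="ignore"):
        for it in range(n_warmup + n_draws):
            # exact joint draw of (alpha, gamma, beta) | scales, y:
            # collapse beta into per-drug Gaussian summaries (m_d, V_d), then
            # gamma into per-class summaries, sample top-down.
            w = 1.0 / (s2 + np.square(tau)[:, d_idx])
            sig2 = np.square(sigma)
            zeta2 = np.square(zeta)

            sw = _rsum(w, t_starts)
            m_d = _rsum(w * y, t_starts) / sw
            v_d = 1.0 / sw
            w_cls = 1.0 / (v_d + sig2[:, c_idx])  # weights for gamma level
            p_c = _rsum(w_cls, d_starts)
            mbar_c = _rsum(w_cls * m_d, d_starts) / p_c
            w_top = 1.0 / (1.0 / p_c + zeta2[:, None])  # weights for alpha level

            prec_a = w_top.sum(axis=1) + 1.0 / loc_prior_var
            mean_a = (w_top * mbar_c).sum(axis=1) / prec_a
            alpha = mean_a + rng.standard_normal(R) / np.sqrt(prec_a)

            prec_g = p_c + 1.0 / zeta2[:, None]
            mean_g = (p_c * mbar_c + alpha[:, None] / zeta2[:, None]) / prec_g
            gamma = mean_g + rng.standard_normal((R, C)) / np.sqrt(prec_g)

            prec_b = sw + 1.0 / sig2[:, c_idx]
            mean_b = (sw * m_d + gamma[:, c_idx] / sig2[:, c_idx]) / prec_b
            beta = mean_b + rng.standard_normal((R, D)) / np.sqrt(prec_b)

            if fixed is None:
                # tau | beta  (slice, vectorised over reps x drugs)
                resid2 = np.square(y - beta[:, d_idx])

                def lp_tau(t: np.ndarray) -> np.ndarray:
                    t2 = np.square(t)
                    v = s2 + t2[:, d_idx]
                    ss = _rsum(np.log(v) + resid2 / v, t_starts)
                    val = -0.5 * ss + _halfnormal_logprior(t2, scale_prior_var)
                    return np.where(t >= 0.0, val, _NEG_INF)

                tau = slice_update_positive(tau, lp_tau, rng, width=slice_width)

                # sigma | beta, gamma
                ssb = _rsum(np.square(beta - gamma[:, c_idx]), d_starts)

                def lp_sigma(sg: np.ndarray) -> np.ndarray:
                    sg2 = np.square(sg)
                    val = (
                        -0.5 * n_dc * np.log(sg2)
                        - 0.5 * ssb / sg2
                        + _halfnormal_logprior(sg2, scale_prior_var)
                    )
                    return np.where(sg > 0.0, val, _NEG_INF)

                sigma = slice_update_positive(sigma, lp_sigma, rng, width=slice_width)

                # zeta | gamma, alpha
                ssg = np.square(gamma - alpha[:, None]).sum(axis=1)

                def lp_zeta(z: np.ndarray) -> np.ndarray:
                    z2 = np.square(z)
                    val = (
                        -0.5 * C * np.log(z2)
                        - 0.5 * ssg / z2
                        + _halfnormal_logprior(z2, scale_prior_var)
                    )
                    return np.where(z > 0.0, val, _NEG_INF)

                zeta = slice_update_positive(zeta, lp_zeta, rng, width=slice_width)

                # interweaved (non-centered) re-updates of sigma and zeta:
                # with u_d = (beta_d - gamma_c)/sigma_c held fixed, the
                # conditional of sigma_c is a positive-truncated normal
                # (likewise zeta with v_c = (gamma_c - alpha)/zeta), which
                # breaks the scale-location funnel.  Exact draws, then the
                # locations are recomputed from the fixed standardized
                # deviations.
                w = 1.0 / (s2 + np.square(tau)[:, d_idx])
                u_d = (beta - gamma[:, c_idx]) / sigma[:, c_idx]
                e_t = y - gamma[:, c_idx][:, d_idx]
                uu_t = u_d[:, d_idx]
                c_starts_t = t_starts[d_starts]
                a1 = np.add.reduceat(w * e_t * uu_t, c_starts_t, axis=1)
                a2 = np.add.reduceat(w * np.square(uu_t), c_starts_t, axis=1)
                prec_s = a2 + 1.0 / scale_prior_var
                sigma = _truncnorm_positive(a1 / prec_s, 1.0 / np.sqrt(prec_s), rng)
                beta = gamma[:, c_idx] + sigma[:, c_idx] * u_d

                v_c = (gamma - alpha[:, None]) / zeta[:, None]
                sig2 = np.square(sigma)
                vv_d = v_c[:, c_idx]
                b_resid = (beta - alpha[:, None]) / sig2[:, c_idx]
                b1 = (b_resid * vv_d).sum(axis=1)
                b2 = (np.square(vv_d) / sig2[:, c_idx]).sum(axis=1)
                prec_z = b2 + 1.0 / scale_prior_var
                zeta = _truncnorm_positive(b1 / prec_z, 1.0 / np.sqrt(prec_z), rng)
                gamma = alpha[:, None] + zeta[:, None] * v_c

            k = it - n_warmup
            if k >= 0:
                out["beta"][:, k] = beta
                if store == "all":
                    out["alpha"][:, k] = alpha
                    out["gamma"][:, k] = gamma
                    out["zeta"][:, k] = zeta
                    out["sigma"][:, k] = sigma
                    out["tau"][:, k] = tau
    return out


def run_gibbs_single(
    y: np.ndarray,
    s2: np.ndarray,
    struct: GibbsStructure,
    *,
    loc_prior_var: float,
    scale_prior_var: float,
    n_warmup: int,
    n_draws: int,
    rng: np.random.Generator,
    slice_width: float = 0.25,
    fixed_tau: np.ndarray | None = None,
    store: str = "all",
) -> dict[str, np.ndarray]:
    """Gibbs for the two-level single-drug model, all drugs simultaneously.

    Each drug's model (beta_d ~ N(0, loc_prior_var), tau_d ~ half-normal)
    only involves its own trials, so the D independent single-drug fits run
    as one vectorised chain.  Returns draws for ``beta`` and (if ``store ==
    "all"``) ``tau``, each (R, n_draws, D).
    """
    R = y.shape[0]
    D = struct.n_drugs
    d_idx, t_starts = struct.d_idx, struct.t_starts

    w0 = 1.0 / s2
    beta = _rsum(np.broadcast_to(w0 * y, y.shape).copy(), t_starts) / _rsum(
        np.broadcast_to(w0, y.shape).copy(), t_starts
    )
    beta = beta + 0.05 * rng.standard_normal((R, D))
    if fixed_tau is not None:
        tau = np.broadcast_to(np.asarray(fixed_tau, float), (R, D)).copy()
    else:
        tau = np.full((R, D), 0.2) * np.exp(0.2 * rng.standard_normal((R, D)))

    out: dict[str, np.ndarray] = {"beta": np.empty((R, n_draws, D))}
    if store == "all":
        out["tau"] = np.empty((R, n_draws, D))

    with np.errstate(divide="ignore", invalid="ignore"):
        for it in range(n_warmup + n_draws):
            w = 1.0 / (s2 + np.square(tau)[:, d_idx])
            prec_b = _rsum(w, t_starts) + 1.0 / loc_prior_var
            mean_b = _rsum(w * y, t_starts) / prec_b
            beta = mean_b + rng.standard_normal((R, D)) / np.sqrt(prec_b)

            if fixed_tau is None:
                resid2 = np.square(y - beta[:, d_idx])

                def lp_tau(t: np.ndarray) -> np.ndarray:
                    t2 = np.square(t)
                    v = s2 + t2[:, d_idx]
                    ss = _rsum(np.log(v) + resid2 / v, t_starts)
                    val = -0.5 * ss + _halfnormal_logprior(t2, scale_prior_var)
                    return np.where(t >= 0.0, val, _NEG_INF)

                tau = slice_update_positive(tau, lp_tau, rng, width=slice_width)

            k = it - n_warmup
            if k >= 0:
                out["beta"][:, k] = beta
                if store == "all":
                    out["tau"][:, k] = tau
    return out
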