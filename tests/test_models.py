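"""Model fitting: conjugate oracle, Gibbs sampler, shrinkage behaviour."""

import numpy as np
import pytest

from ontopool.models import (
    ConvergenceWarning,
    FixedScales,
    InferenceSettings,
    PriorSpec,
    check_convergence,
    fit_conjugate_oracle,
    fit_full,
    fit_single,
    fit_full_batch,
    fit_singles_batch,
    single_drug_conjugate_oracle,
)
from ontopool.network import TrialNetwork, TrialRecord
from ontopool.scenarios import get_scenario, simulate_dataset

from conftest import make_network

FAST = InferenceSettings(
    n_chains=2, n_draws=1500, n_warmup=300, compute_diagnostics=False
)


class TestConjugateOracle:
    def test_single_trial_scalar_shrinkage(self):
        # one class/drug/trial with tau fixed: the scalar normal-normal
        # shrinkage formula, weights 1/(s^2+tau^2) vs prior precision 1/4
        net = make_network({"A10BH01": ("A10BH", 1)})
        y, s, tau = np.array([-0.1]), np.array([0.158]), 0.05
        post = fit_conjugate_oracle(
            y, s, net, FixedScales(zeta=1e-4, sigma=1e-4, tau=tau)
        )
        w = (1 / (s[0] ** 2 + tau**2)) / (1 / (s[0] ** 2 + tau**2) + 1 / 4)
        # alpha, gamma and beta coincide when zeta, sigma -> 0
        assert post.mean_of("beta")[0] == pytest.approx(y[0] * w, abs=1e-4)
        assert post.mean_of("beta")[0] == pytest.approx(-0.0993, abs=5e-4)

    def test_vague_prior_gives_inverse_variance_weighting(self):
        # one drug, flat top: beta posterior mean -> IVW mean with
        # weights 1/(s^2 + tau^2), the classical random-effects estimator
        net = make_network({"A10BH01": ("A10BH", 4)})
        rng = np.random.default_rng(3)
        y = rng.normal(-0.1, 0.1, size=4)
        s = np.array([0.05, 0.1, 0.2, 0.3])
        tau = 0.07
        post = fit_conjugate_oracle(
            y,
            s,
            net,
            FixedScales(zeta=1e-4, sigma=1e-4, tau=tau),
            priors=PriorSpec(location_prior_sd=1e3),
        )
        w = 1 / (s**2 + tau**2)
        assert post.mean_of("beta")[0] == pytest.approx(
            (w * y).sum() / w.sum(), abs=1e-5
        )

    def test_mirror_symmetry(self):
        # two drugs with y mirrored around 0 give mirrored beta posteriors
        net = make_network({"A10BH01": ("A10BH", 2), "A10BH02": ("A10BH", 2)})
        y = np.array([0.2, 0.3, -0.2, -0.3])
        s = np.array([0.1, 0.15, 0.1, 0.15])
        post = fit_conjugate_oracle(y, s, net, FixedScales(0.1, 0.1, 0.1))
        bm = post.mean_of("beta")
        assert bm[0] == pytest.approx(-bm[1], abs=1e-12)
        assert post.sd_of("beta")[0] == pytest.approx(post.sd_of("beta")[1])

    def test_rejects_nonpositive_se(self, tiny_network):
        y = np.zeros(tiny_network.n_trials)
        s = np.full(tiny_network.n_trials, 0.1)
        s[0] = 0.0
        with pytest.raises(ValueError, match="s must be"):
            fit_conjugate_oracle(y, s, tiny_network, FixedScales(0.1, 0.1, 0.1))


class TestGibbsAgainstOracle:
    def test_fixed_scale_fit_matches_oracle(self, medium_network):
        ds = simulate_dataset(medium_network, get_scenario("all-medium"), 5)
        fx = FixedScales(zeta=0.12, sigma=0.1, tau=0.08)
        fit = fit_full(
            medium_network,
            ds.y,
            ds.s,
            settings=InferenceSettings(
                n_chains=2, n_draws=4000, n_warmup=300, seed=2,
                compute_diagnostics=False,
            ),
            fixed_scales=fx,
        )
        oracle = fit_conjugate_oracle(ds.y, ds.s, medium_network, fx)
        bm = np.array([fit.beta[d].mean for d in medium_network.drug_codes])
        bs = np.array([fit.beta[d].sd for d in medium_network.drug_codes])
        assert np.abs(bm - oracle.mean_of("beta")).max() < 0.005
        assert np.abs(bs / oracle.sd_of("beta") - 1).max() < 0.02
        assert fit.alpha.mean == pytest.approx(
            float(oracle.mean_of("alpha")[0]), abs=0.005
        )


class TestFullFit:
    def test_no_information_limit_recovers_prior(self, tiny_network):
        # s -> huge: alpha posterior reverts to its N(0, 2^2) prior
        y = np.zeros(tiny_network.n_trials)
        s = np.full(tiny_network.n_trials, 1e6)
        fit = fit_full(tiny_network, y, s, settings=FAST)
        assert abs(fit.alpha.mean) < 0.05 * 2 + 0.05
        assert fit.alpha.sd == pytest.approx(2.0, rel=0.05)

    def test_shrinkage_direction(self, medium_network):
        # the drug most extreme relative to its class is pulled toward the
        # class mean, landing between its single-drug estimate and gamma
        ds = simulate_dataset(medium_network, get_scenario("drug-high"), 17)
        fit = fit_full(medium_network, ds.y, ds.s, settings=FAST)
        singles = {}
        for d in medium_network.drug_codes:
            mask = medium_network.trial_drug_idx == list(
                medium_network.drug_codes
            ).index(d)
            singles[d] = fit_single(ds.y[mask], ds.s[mask], settings=FAST).beta.mean
        cls = {
            d: medium_network.class_codes[
                medium_network.drug_class_idx[i]
            ]
            for i, d in enumerate(medium_network.drug_codes)
        }
        extreme = max(
            medium_network.drug_codes,
            key=lambda d: abs(singles[d] - fit.gamma[cls[d]].mean),
        )
        lo, hi = sorted([singles[extreme], fit.gamma[cls[extreme]].mean])
        assert lo - 0.01 <= fit.beta[extreme].mean <= hi + 0.01

    def test_monotone_pooling(self):
        # adding concordant trials moves beta toward the data and tightens it
        y3 = np.full(3, -0.3)
        s3 = np.full(3, 0.1)
        y12 = np.full(12, -0.3)
        s12 = np.full(12, 0.1)
        net3 = make_network({"A10BH01": ("A10BH", 3)})
        net12 = make_network({"A10BH01": ("A10BH", 12)})
        f3 = fit_full(net3, y3, s3, settings=FAST)
        f12 = fit_full(net12, y12, s12, settings=FAST)
        b3, b12 = f3.beta["A10BH01"], f12.beta["A10BH01"]
        assert abs(b12.mean - (-0.3)) < abs(b3.mean - (-0.3))
        assert b12.sd < b3.sd

    def test_relabeling_invariance(self, medium_network):
        ds = simulate_dataset(medium_network, get_scenario("all-medium"), 9)
        fit = fit_full(medium_network, ds.y, ds.s, settings=FAST)
        # rename every code (prefix-consistent) and permute trial order
        perm = np.random.default_rng(0).permutation(medium_network.n_trials)
        renamed = TrialNetwork(
            [
                TrialRecord(
                    trial_id=f"x-{r.trial_id}",
                    drug_code="B" + r.drug_code,
                    class_code="B" + r.class_code,
                    enrollment=r.enrollment,
                )
                for r in (medium_network.records[i] for i in perm)
            ]
        )
        fit2 = fit_full(renamed, ds.y[perm], ds.s[perm], settings=FAST)
        for d in medium_network.drug_codes:
            a, b = fit.beta[d], fit2.beta["B" + d]
            tol = 4 * np.hypot(a.sd, b.sd) / np.sqrt(1500)
            assert abs(a.mean - b.mean) < max(tol, 0.01)

    def test_rejects_bad_inputs(self, tiny_network):
        y = np.zeros(tiny_network.n_trials)
        s = np.full(tiny_network.n_trials, 0.1)
        with pytest.raises(ValueError):
            fit_full(tiny_network, y, -s)
        with pytest.raises(ValueError):
            fit_full(tiny_network, y[:-1], s[:-1])


class TestSingleFit:
    def test_single_trial_closed_form(self):
        fit = fit_single(
            np.array([-0.1]),
            np.array([0.158]),
            settings=InferenceSettings(
                n_chains=2, n_draws=4000, n_warmup=300, seed=4,
                compute_diagnostics=False,
            ),
            fixed_tau=0.05,
        )
        mean, sd = single_drug_conjugate_oracle(
            np.array([-0.1]), np.array([0.158]), tau=0.05
        )
        assert mean == pytest.approx(-0.0993, abs=1e-4)
        assert fit.beta.mean == pytest.approx(mean, abs=0.005)
        assert fit.beta.sd == pytest.approx(sd, rel=0.03)

    def test_no_information_limit(self):
        fit = fit_single(np.array([0.3]), np.array([1e6]), settings=FAST)
        assert abs(fit.beta.mean) < 0.15
        assert fit.beta.sd == pytest.approx(2.0, rel=0.05)

    def test_many_concordant_trials_recover_mean(self):
        k = 200
        fit = fit_single(np.full(k, -0.1), np.full(k, 0.05), settings=FAST)
        assert fit.beta.mean == pytest.approx(-0.1, abs=0.005)


class TestBatchedFits:
    def test_batch_matches_per_dataset_fit(self, medium_network):
        # the vectorised batch path and a one-dataset fit are the same model
        ds = simulate_dataset(medium_network, get_scenario("all-low"), 31)
        settings = InferenceSettings(
            n_chains=1, n_draws=4000, n_warmup=400, seed=8,
            compute_diagnostics=False, store="beta",
        )
        batch = fit_full_batch(
            medium_network, ds.y[None, :], ds.s, settings=settings
        )
        fit = fit_full(
            medium_network, ds.y, ds.s,
            settings=InferenceSettings(
                n_chains=2, n_draws=3000, n_warmup=400, seed=81,
                compute_diagnostics=False,
            ),
        )
        for j, d in enumerate(medium_network.drug_codes):
            tol = 5 * fit.beta[d].sd / np.sqrt(1000)
            assert abs(batch.est[0, j] - fit.beta[d].mean) < max(tol, 0.02)

    def test_singles_batch_matches_fit_single(self, tiny_network):
        ds = simulate_dataset(tiny_network, get_scenario("all-medium"), 13)
        settings = InferenceSettings(
            n_chains=1, n_draws=4000, n_warmup=400, seed=9,
            compute_diagnostics=False, store="beta",
        )
        batch = fit_singles_batch(
            tiny_network, ds.y[None, :], ds.s, settings=settings
        )
        for j, d in enumerate(tiny_network.drug_codes):
            mask = tiny_network.trial_drug_idx == j
            single = fit_single(ds.y[mask], ds.s[mask], settings=FAST)
            tol = 5 * single.beta.sd / np.sqrt(1000)
            assert abs(batch.est[0, j] - single.beta.mean) < max(tol, 0.02)


class TestDiagnostics:
    def test_iid_draws_pass(self):
        rng = np.random.default_rng(0)
        draws = {"x": rng.standard_normal((2, 2000))}
        diag, _ = check_convergence(draws)
        assert diag.converged
        assert diag.max_rhat < 1.01

    def test_stuck_chains_flagged(self):
        draws = {"x": np.stack([np.zeros(500), np.ones(500)])}
        diag, _ = check_convergence(draws)
        assert not diag.converged
        assert diag.max_rhat > 1.5
        assert "x" in diag.flagged

    def test_nonconverged_fit_warns(self, tiny_network):
        ds = simulate_dataset(tiny_network, get_scenario("all-low"), 2)
        tiny = InferenceSettings(n_chains=2, n_draws=60, n_warmup=10, seed=0)
        with pytest.warns(ConvergenceWarning):
            fit = fit_full(tiny_network, ds.y, ds.s, settings=tiny)
        assert not fit.diagnostics.converged
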