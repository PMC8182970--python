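"""Importance-sampling machinery: priors, likelihood, weighting, study table."""
import numpy as np
import pandas as pd
import pytest

from vocalfem.coupled_sim import ObservationSeries, SimulationConfig
from vocalfem.errors import (AlignmentError, ConfigurationError,
                             DegeneratePosteriorError, SimulationBlowupError)
from vocalfem.inference import (FlowPermutation, ParameterVector, PriorSpec,
                                bernoulli_sweep, default_priors,
                                importance_estimate, log_likelihood,
                                run_study, sample_prior)


def series(widths, dt=1.0, depth=1.0):
    w = np.asarray(widths, dtype=float)
    return ObservationSeries(t=np.arange(w.size) * dt, width=w, depth=depth)


class TestSamplePrior:
    def test_point_mass(self):
        s = sample_prior(PriorSpec({"a": ("delta", 3.0)}), 20, seed=0)
        assert np.all(s["a"] == 3.0)

    def test_uniform_clt_bound(self):
        a, b, n = 2.0, 5.0, 100_000
        s = sample_prior(PriorSpec({"x": ("uniform", a, b)}), n, seed=1)
        assert abs(s["x"].mean() - (a + b) / 2) < 3 * (b - a) / np.sqrt(12 * n)

    def test_seed_reproducibility(self):
        p = PriorSpec({"x": ("uniform", 0, 1), "y": ("normal", 0, 2)})
        s1 = sample_prior(p, 100, seed=7)
        s2 = sample_prior(p, 100, seed=7)
        pd.testing.assert_frame_equal(s1, s2)

    def test_invalid_descriptor(self):
        with pytest.raises(ConfigurationError):
            PriorSpec({"x": ("uniform", 2.0, 1.0)})
        with pytest.raises(ConfigurationError):
            PriorSpec({"x": ("cauchy", 0.0, 1.0)})


class TestDefaultPriors:
    def test_spec_ranges(self):
        p = default_priors(ParameterVector(), with_r_sep=True)
        assert p.dists["E_body"] == ("uniform", 11.8 * 0.5, 11.8 * 1.5)
        assert p.dists["p_sub"][1:] == (1.092 * 0.8, 1.092 * 1.2)
        assert p.dists["rho_b"][1:] == (900.0, 1200.0)
        assert p.dists["eta"][1:] == (0.0, 10.0)
        assert p.dists["m"][1:] == (0.2, 0.6)
        assert p.dists["r_sep"][1:] == (1.0, 1.6)


class TestLogLikelihood:
    def test_identical_series_is_zero(self):
        obs = series([0.1, 0.5, 0.2])
        assert log_likelihood(obs, obs, sigma_area=1.0) == 0.0

    def test_single_point_one_sigma(self):
        obs = series([1.0], depth=2.0)
        sim = series([1.5], depth=2.0)           # sigma_w = 1/2
        assert log_likelihood(sim, obs, sigma_area=1.0,
                              register=False) == pytest.approx(-0.5)

    def test_matches_naive_loop(self):
        rng = np.random.default_rng(3)
        w_obs = rng.uniform(0, 1, 40)
        w_sim = rng.uniform(0, 1, 40)
        obs, sim = series(w_obs, depth=14.0), series(w_sim, depth=14.0)
        sig_w = 2.5 / 14.0
        naive = sum(-0.5 * ((a - b) / sig_w) ** 2 for a, b in zip(w_obs, w_sim))
        got = log_likelihood(sim, obs, sigma_area=2.5, register=False)
        assert got == pytest.approx(naive, rel=1e-12)

    def test_registration_absorbs_phase(self):
        t = np.arange(200) * 0.25
        w = 0.5 + 0.5 * np.sin(2 * np.pi * t / 10.0)
        obs = series(w, dt=0.25, depth=14.0)
        sim = series(np.roll(w, 13), dt=0.25, depth=14.0)
        assert log_likelihood(sim, obs, 1.0) == pytest.approx(0.0, abs=1e-9)

    def test_grid_mismatch_raises(self):
        with pytest.raises(AlignmentError):
            log_likelihood(series([1, 2, 3], dt=0.5), series([1, 2, 3], dt=0.25), 1.0)
        with pytest.raises(AlignmentError):
            log_likelihood(series([1.0]), series([1, 2, 3]), 1.0)


class TestImportanceEstimate:
    def _identity_forward(self, name="x"):
        return lambda p: series([p[name]])

    def test_degenerate_likelihood_selects_generating_sample(self):
        prior = PriorSpec({"x": ("uniform", 0.0, 1.0)})
        samples = prior.sample(50, np.random.default_rng(
            np.random.SeedSequence(11).spawn(2)[0]))
        target = float(samples["x"].iloc[17])
        post = importance_estimate(prior, series([target]),
                                   self._identity_forward(), n=50, seed=11,
                                   sigma_area=1e-9, register=False)
        assert post.mean["x"] == pytest.approx(target, abs=1e-12)
        assert post.weights.max() == pytest.approx(1.0)

    def test_conjugate_gaussian_posterior(self):
        mu0, s0, sig, y = 2.0, 0.5, 0.3, 2.4
        prior = PriorSpec({"x": ("normal", mu0, s0)})
        post = importance_estimate(prior, series([y]), self._identity_forward(),
                                   n=2000, seed=3, sigma_area=sig, register=False)
        exact_mean = (s0 ** 2 * y + sig ** 2 * mu0) / (s0 ** 2 + sig ** 2)
        exact_sd = np.sqrt(1 / (1 / s0 ** 2 + 1 / sig ** 2))
        se = exact_sd / np.sqrt(post.n_eff)
        assert abs(post.mean["x"] - exact_mean) < 3 * se
        assert post.std["x"] == pytest.approx(exact_sd, rel=0.15)

    def test_uniform_weights_resample_mean(self):
        prior = PriorSpec({"x": ("uniform", 0.0, 1.0)})
        post = importance_estimate(prior, series([0.5]), lambda p: series([0.5]),
                                   n=4000, seed=5, sigma_area=1.0, register=False)
        assert np.allclose(post.weights, 1.0 / 4000)
        resampled_mean = post.resampled["x"].mean()
        assert abs(resampled_mean - post.samples["x"].mean()) < 3 * np.sqrt(1 / 12 / 4000) * 2

    def test_weights_invariant_to_constant_shift(self):
        prior = PriorSpec({"x": ("uniform", 0.0, 1.0)})
        c = 57.0
        p1 = importance_estimate(prior, series([0.3]), self._identity_forward(),
                                 n=300, seed=9, sigma_area=0.2, register=False)
        p2 = importance_estimate(prior, series([0.3 + c]),
                                 lambda p: series([p["x"] + c]),
                                 n=300, seed=9, sigma_area=0.2, register=False)
        assert np.allclose(p1.weights, p2.weights, atol=1e-12)

    def test_failed_forwards_zero_weighted(self):
        prior = PriorSpec({"x": ("uniform", 0.0, 1.0)})

        def flaky(p):
            if p["x"] > 0.5:
                raise SimulationBlowupError("boom", step=3)
            return series([p["x"]])

        post = importance_estimate(prior, series([0.2]), flaky, n=200, seed=2,
                                   sigma_area=0.5, register=False)
        assert post.n_failures > 0
        bad = post.samples["x"].to_numpy() > 0.5
        assert np.all(post.weights[bad] == 0.0)

    def test_all_failures_raise(self):
        prior = PriorSpec({"x": ("uniform", 0.0, 1.0)})

        def dead(p):
            raise SimulationBlowupError("boom")
        with pytest.raises(DegeneratePosteriorError):
            importance_estimate(prior, series([0.2]), dead, n=10, seed=0)

    def test_summaries_invariant_to_sample_order(self):
        prior = PriorSpec({"x": ("normal", 0.0, 1.0)})
        post = importance_estimate(prior, series([0.4]), self._identity_forward(),
                                   n=500, seed=1, sigma_area=0.5, register=False)
        perm = np.random.default_rng(0).permutation(500)
        w, x = post.weights[perm], post.samples["x"].to_numpy()[perm]
        assert np.sum(w * x) == pytest.approx(post.mean["x"], rel=1e-12)

    def test_toy_recovery_calibration_across_seeds(self):
        """Truth inside 2 posterior std in >= 90% of repeated noisy fits."""
        truth, sig = 0.6, 0.1
        prior = PriorSpec({"x": ("uniform", 0.0, 1.0)})
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(100 + seed)
            y = truth + rng.normal(0, sig)
            post = importance_estimate(prior, series([y]),
                                       self._identity_forward(), n=500,
                                       seed=seed, sigma_area=sig, register=False)
            hits += abs(post.mean["x"] - truth) <= 2 * post.std["x"]
        assert hits >= 18


class TestStudy:
    def test_bernoulli_sweep_has_seven_permutations(self):
        perms = bernoulli_sweep()
        assert len(perms) == 7
        assert [p.r_sep for p in perms] == pytest.approx(
            [1.0, 1.1, 1.2, 1.3, 1.4, 1.5, 1.6])

    def test_permutation_validation(self):
        with pytest.raises(ConfigurationError):
            FlowPermutation("bernoulli_fixed")
        assert FlowPermutation("viscous").label == "viscous"

    def test_single_cell_table(self, coarse_mesh):
        from vocalfem.synthetic_data import make_observation
        cfg = SimulationConfig(duration=6.0, transient_discard=2.0,
                               resolution=0.75, r_sep=1.2)
        truth = ParameterVector(p_sub=1.092)
        obs = make_observation(truth, "bernoulli_fixed", 0.5, seed=4,
                               config=cfg, mesh=coarse_mesh)
        prior = PriorSpec({
            "E_body": ("uniform", 10.0, 13.5), "m": ("uniform", 0.35, 0.45)})
        table = run_study({"case": obs}, [FlowPermutation("bernoulli_fixed", 1.2)],
                          coarse_mesh, cfg, prior=prior, n=4, seed=0,
                          sigma_area=4.0)
        assert set(table["parameter"]) == {"E_body", "m"}
        row = table[table["parameter"] == "E_body"].iloc[0]
        assert row["permutation"] == "bernoulli r_sep=1.2"
        assert np.isfinite(row["estimate"]) and np.isfinite(row["n_eff"])
        assert np.isfinite(row["normalized_estimate"])

    def test_estimated_r_sep_gets_prior_entry(self, coarse_mesh):
        from vocalfem.synthetic_data import make_observation
        cfg = SimulationConfig(duration=6.0, transient_discard=2.0,
                               resolution=0.75, flow_model="bernoulli_estimated")
        truth = ParameterVector(p_sub=1.092, r_sep=1.2)
        obs = make_observation(truth, "bernoulli_estimated", 0.5, seed=4,
                               config=cfg, mesh=coarse_mesh)
        prior = PriorSpec({"E_body": ("uniform", 10.0, 13.5)})
        table = run_study({"case": obs},
                          [FlowPermutation("bernoulli_estimated")],
                          coarse_mesh, cfg, prior=prior, n=3, seed=0,
                          sigma_area=4.0)
        assert "r_sep" in set(table["parameter"])


def test_parameter_vector_validation():
    with pytest.raises(ConfigurationError):
        ParameterVector(E_body=-1.0)
    with pytest.raises(ConfigurationError):
        ParameterVector(r_sep=0.8)
    pv = ParameterVector(r_sep=1.3)
    assert pv.to_dict()["r_sep"] == 1.3
    assert "r_sep" not in ParameterVector().to_dict()
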