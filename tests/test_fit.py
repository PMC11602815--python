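import numpy as np
import pandas as pd
import pytest

import kfp
from kfp.fit import _LogPosterior


def one_pool_model():
    g = kfp.PathwayGraph(nodes=["X1"], labeled_inputs=[("X1", "f1")],
                         unlabeled_inputs=[("X1", "f2")],
                         exits=[("X1", "f3")])
    return kfp.enrichment_model(g)


class TestLogPosterior:
    def test_outside_prior_box_is_minus_inf(self, model_irrev, truth_irrev):
        ds = kfp.generate_dataset(model_irrev, truth_irrev, n_timepoints=3,
                                  seed=1)
        bad = truth_irrev.updated(k_X1=5.0)  # above U(0, 3)
        assert kfp.log_posterior(bad, ds, model_irrev) == -np.inf

    def test_inadmissible_substitution_is_minus_inf(self, model_rev,
                                                    truth_rev):
        ds = kfp.generate_dataset(model_rev, truth_rev, n_timepoints=3, seed=1)
        # alpha + beta > 1 at the labeled node kills the labeled share
        bad = truth_rev.updated(alpha_X1=0.9, beta_X1_X2=0.4)
        assert kfp.log_posterior(bad, ds, model_rev) == -np.inf

    def test_truth_beats_perturbed_grid_on_noiseless_data(self, model_irrev,
                                                          truth_irrev):
        ds = kfp.generate_dataset(model_irrev, truth_irrev, n_timepoints=10,
                                  noise_frac=0.0, seed=1)
        ds = kfp.EnrichmentDataset(observations=ds.observations,
                                   noise_frac=0.025,  # fixed sigma policy
                                   n_timepoints=10, n_replicates=3, seed=1,
                                   regime="transient")
        at_truth = kfp.log_posterior(truth_irrev, ds, model_irrev)
        for name in model_irrev.free_params:
            for delta in (-0.05, 0.05):
                perturbed = truth_irrev.updated(
                    **{name: truth_irrev[name] + delta})
                assert kfp.log_posterior(perturbed, ds, model_irrev) < at_truth

    def test_likelihood_adds_over_concatenated_datasets(self, model_irrev,
                                                        truth_irrev):
        a = kfp.generate_dataset(model_irrev, truth_irrev, n_timepoints=3,
                                 seed=1)
        b = kfp.generate_dataset(model_irrev, truth_irrev, n_timepoints=5,
                                 seed=2)
        both = kfp.EnrichmentDataset(
            observations=pd.concat([a.observations, b.observations],
                                   ignore_index=True),
            noise_frac=a.noise_frac, n_timepoints=8, n_replicates=3,
            seed=0, regime="transient")
        la = kfp.log_posterior(truth_irrev, a, model_irrev)
        lb = kfp.log_posterior(truth_irrev, b, model_irrev)
        lab = kfp.log_posterior(truth_irrev, both, model_irrev)
        assert lab == pytest.approx(la + lb, rel=1e-12)

    def test_unknown_metabolite_rejected(self, model_irrev, truth_irrev):
        ds = kfp.generate_dataset(model_irrev, truth_irrev, n_timepoints=3,
                                  seed=1)
        obs = ds.observations.copy()
        obs.loc[0, "metabolite"] = "X9"
        bad = kfp.EnrichmentDataset(observations=obs, noise_frac=0.025,
                                    n_timepoints=3, n_replicates=3, seed=1,
                                    regime="transient")
        with pytest.raises(ValueError, match="X9"):
            _LogPosterior(bad, model_irrev, kfp.PriorSpec.default_for(model_irrev))


class TestSummarize:
    def test_constant_samples(self):
        df = pd.DataFrame({"a": [0.7] * 100})
        mode, ci = kfp.summarize_posterior(df)
        assert mode["a"] == 0.7
        assert ci["a"][1] == ci["a"][2] == 0.7

    def test_normal_draws_mode_near_mean(self):
        rng = np.random.default_rng(0)
        x = rng.normal(0.5, 0.15, 20000)
        x = x[(x > 0.0) & (x < 1.0)]  # truncate to the prior box
        mode, _ = kfp.summarize_posterior(pd.DataFrame({"a": x}))
        assert mode["a"] == pytest.approx(0.5, abs=0.03)

    def test_uniform_draws_interval_matches_order_statistics(self):
        rng = np.random.default_rng(1)
        x = rng.uniform(0.0, 2.0, 50000)
        _, ci = kfp.summarize_posterior(pd.DataFrame({"a": x}), level=0.95)
        level, lo, hi = ci["a"]
        assert lo == pytest.approx(0.05, abs=0.01)
        assert hi == pytest.approx(1.95, abs=0.01)


class TestSampling:
    def test_one_pool_posterior_mode_near_truth(self):
        # x(t) = alpha + (1 - alpha) exp(-k t): both parameters identifiable
        # from transient data, so a short chain recovers them
        model = one_pool_model()
        truth = kfp.ParameterSet({"k_X1": 0.5, "alpha_X1": 0.3})
        ds = kfp.generate_dataset(model, truth, n_timepoints=10,
                                  noise_frac=0.025, seed=12)
        cfg = kfp.FitConfig(nwalkers=16, nsteps=1500, n_retained=1000, seed=3)
        s = kfp.sample_posterior(ds, model, config=cfg)
        assert s.mode["alpha_X1"] == pytest.approx(0.3, abs=0.05)
        assert s.mode["k_X1"] == pytest.approx(0.5, rel=0.2)
        assert set(s.rhat) == {"k_X1", "alpha_X1"}

    def test_sampling_is_seed_deterministic(self):
        model = one_pool_model()
        truth = kfp.ParameterSet({"k_X1": 0.5, "alpha_X1": 0.3})
        ds = kfp.generate_dataset(model, truth, n_timepoints=5,
                                  noise_frac=0.05, seed=12)
        cfg = kfp.FitConfig(nwalkers=8, nsteps=400, n_retained=400, seed=3)
        a = kfp.sample_posterior(ds, model, config=cfg)
        b = kfp.sample_posterior(ds, model, config=cfg)
        assert a.samples.equals(b.samples)
        assert a.mode == b.mode


class TestRidge:
    def test_ridge_passes_through_truth(self, model_rev, truth_rev):
        ss = kfp.solve_steady_state(model_rev, truth_rev).xbar_ss
        ridge = kfp.steady_state_ridge(ss)
        assert float(ridge(0.25)) == pytest.approx(0.15, abs=1e-3)

    def test_intercept_at_first_steady_state(self, model_rev, truth_rev):
        ss = kfp.solve_steady_state(model_rev, truth_rev).xbar_ss
        ridge = kfp.steady_state_ridge(ss)
        assert float(ridge(ss[0])) == pytest.approx(0.0, abs=1e-15)

    def test_perpendicular_distance_zero_on_the_line(self, model_rev,
                                                     truth_rev):
        ss = kfp.solve_steady_state(model_rev, truth_rev).xbar_ss
        ridge = kfp.steady_state_ridge(ss)
        a1 = np.linspace(0.0, 0.3, 20)
        np.testing.assert_allclose(
            ridge.perpendicular_distance(a1, ridge(a1)), 0, atol=1e-14)

    def test_degenerate_steady_state_rejected(self):
        with pytest.raises(ZeroDivisionError):
            kfp.steady_state_ridge([0.5, 0.0])
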