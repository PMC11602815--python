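"""Bayesian recovery from steady-state-only data (irreversible chain).

Data sampled after the isotopic steady state is reached pin down the
unlabeled-input proportions alpha_1, alpha_2 tightly, while the turnover
rates k_1, k_2 — which only shape the transient — come back with posterior
intervals spanning most of their U(0, 3) prior: the method reports what
the data cannot know instead of guessing.
"""

import kfp
from kfp import pathways

g = pathways.two_pool_chain()
model = kfp.enrichment_model(g)
truth = pathways.irreversible_truth()

dataset = kfp.generate_dataset(model, truth, n_timepoints=10,
                               noise_frac=0.025, regime="steady_state_only",
                               seed=11)
print(f"simulated {len(dataset.observations)} observations "
      f"(10 time points x 2 metabolites x 3 replicates), 2.5% noise")

summary = kfp.sample_posterior(
    dataset, model,
    config=kfp.FitConfig(seed=5, nonidentifiable=("k_X1", "k_X2")),
)
print(f"acceptance fraction {summary.acceptance_fraction:.2f}, "
      f"converged (identifiable params): {summary.converged}\n")
for name in model.free_params:
    level, lo, hi = summary.ci[name]
    true_v = truth[name]
    print(f"{name:9s} truth {true_v:6.3f}  mode {summary.mode[name]:6.3f}  "
          f"{int(level*100)}% CI [{lo:6.3f}, {hi:6.3f}]  width {hi-lo:5.3f}")
print("\nalphas recovered to ~0.01; k intervals nearly as wide as the prior.")
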