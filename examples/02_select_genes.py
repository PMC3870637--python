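"""Rank genes by posterior inclusion probability on synthetic data.

Runs the three-block MCMC (latent-utility sweep, inclusion-indicator
sweep, Metropolis-Hastings update of the g-prior scale c) and prints
the top of the resulting ranking. With a sparse prior (pi = 0.01
per gene) the chain visits small models, and the draw frequency of
each gene estimates its posterior probability of belonging in the
model. True signal genes should float to the top.
"""

import gsgprobit as g

spec = g.SyntheticSpec(n_train=80, n_test=0, p=60,
                       true_support=(0, 1, 2), beta_true=(1.5, -1.5, 1.5),
                       seed=7)
train, _, truth = g.generate(spec)

cfg = g.ModelConfig(h=100.0, pi=0.01)
res = g.run_chain(train, cfg, n_iter=6000, burn_in=1000, thin=5, seed=1)
ranking = g.inclusion_probabilities(res)

print(f"retained draws: {res.M}, c-update acceptance rate: "
      f"{res.acceptance_rate_c:.2f}")
print(f"posterior mean model size: {res.p_gammas().mean():.1f} genes")
print("\ntop 8 genes by posterior inclusion probability:")
print(ranking.to_dataframe().head(8).to_string(index=False))
print(f"\ntrue support was genes {truth['support']} — these should lead "
      "the ranking with probabilities well above the null genes.")
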