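"""Two flavours of leave-one-out evaluation on one training set.

Internal LOOCV reuses a single chain: for each sample the predictive
probability of its observed label given the others comes from the
harmonic-mean identity over draws — cheap, but gene selection has
seen the held-out sample. External LOOCV redoes the prescreen and the
selection inside every split, so no information leaks from the
held-out sample into gene selection; it is slower but honest, and is
the protocol used for headline error rates.
"""

import gsgprobit as g

spec = g.SyntheticSpec(n_train=30, n_test=0, p=30, true_support=(0, 1, 2),
                       beta_true=(2.0, -2.0, 2.0), seed=5)
train, _, _ = g.generate(spec)
cfg = g.ModelConfig(h=100.0, pi=0.05)

res = g.run_chain(train, cfg, n_iter=3000, burn_in=1000, thin=5, seed=2)
int_err, int_acc, probs = g.internal_loocv(res, train, cfg)
print(f"internal LOOCV: accuracy {int_acc:.3f} (error {int_err:.3f})")
print("lowest per-sample predictive probabilities:",
      [float(x) for x in sorted(probs.round(3))[:3]],
      "— samples the model finds hardest")

ext_err, ext_acc, _ = g.external_loocv(
    train, cfg, p_star=3, prescreen_k=10, seed=4,
    chain_params=dict(n_iter=1200, burn_in=400, thin=4),
    refit_params=dict(n_iter=600, burn_in=200, thin=4))
print(f"external LOOCV: accuracy {ext_acc:.3f} (error {ext_err:.3f})")
print("only the external protocol keeps gene selection blind to the "
      "held-out sample; it is the one to quote.")
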