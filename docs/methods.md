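# Methods

## Model

For `n` tissue samples with expression values `X` (`n × p`, samples by
genes) and binary labels `Y` (1 = case, 0 = control), the package fits
the latent-variable probit regression

    Z_i = α + X_i^γ β^γ + ε_i,   ε_i ~ N(0, 1),   Y_i = 1{Z_i > 0},

with stochastic search variable selection: a binary indicator γ_j per
gene, independent Bernoulli(π_j) a priori, selects the columns that
enter the regression. The priors are

  * α ~ N(0, h) — a vague intercept prior; default `h = 100` on the
    standardized expression scale,
  * β^γ | γ, c ~ N(0, c (X^γᵀ X^γ)⁺) — the **generalized singular
    g-prior**: Zellner's g-prior with the Moore–Penrose pseudoinverse
    replacing the inverse, so collinear or p > n selections are legal
    (the prior lives on the column space of the selected design),
  * c ~ IG(1/2, n/2) — a heavy-tailed reference-style hyperprior on
    the g-prior scale (no finite mean; mode at n/3), instead of a
    fixed constant c,
  * γ_j ~ Bernoulli(π_j) — default π_j = 0.005 for every gene,
    encoding strong prior sparsity (a handful of influential genes).

`fixed_c` in `ModelConfig` pins c to a constant and disables its
update, for comparing the hyperprior against fixed-c analyses.

## Marginalization and the covariance operator

α and β^γ are conjugate and are integrated out analytically, leaving

    Z | γ, c ~ N(0, Σ_γ),   Σ_γ = I_n + h 11ᵀ + c X^γ (X^γᵀX^γ)⁺ X^γᵀ.

The key structural fact used throughout: `X (XᵀX)⁺ Xᵀ` is the
orthogonal projector `P_γ` onto the span of the selected columns, so
`Σ_γ = I + h 11ᵀ + c P_γ` is the identity plus a rank-(m_γ + 1)
perturbation, where m_γ = rank(X^γ). Writing `W = [√h·1, √c·U]` with
`U` an orthonormal basis of that span, the matrix determinant lemma
and the Woodbury identity give `log|Σ_γ|` and `Σ_γ⁻¹` from an
(m_γ+1)×(m_γ+1) Cholesky factor. Every determinant, inverse and
quadratic form costs O(n·m²) instead of O(n³); the dense route exists
only as a test oracle and agrees to 1e-8 relative on random designs,
including rank-deficient and duplicated-column cases.

Numerical rank: Gram-matrix eigenvalues at or below 1e-10 × (largest)
are treated as zero; the equivalent singular-value cutoff √1e-10 is
used when the basis is computed directly from `X^γ` by SVD. A
duplicated or exactly collinear selected gene therefore leaves Σ_γ
(and all densities) unchanged, which the tests pin down.

## The three-block sampler

Each iteration of `run_chain` performs, in fixed order and driven by
one seeded generator:

1. **Latent utilities.** A systematic Gibbs sweep over Z_1…Z_n. With
   precision `Λ = Σ_γ⁻¹ = I − AAᵀ` (A = W L⁻ᵀ from the small Cholesky
   factor), the conditional of Z_i given the rest is
   N(Z_i − (ΛZ)_i/Λ_ii, 1/Λ_ii), truncated to (0, ∞) if Y_i = 1 and
   (−∞, 0] if Y_i = 0. Truncated draws use the inverse-CDF method on
   the survival scale, switching to an exponential-rejection tail
   sampler when the truncation point is extreme.

2. **Inclusion indicators.** A systematic sweep over genes j = 1…p.
   The closed-form conditional is
   p(γ_j = 1 | ·) = (1 + ((1−π_j)/π_j)·ρ_j)⁻¹ with
   ρ_j = |Σ_{γ¹}Σ_{γ⁰}⁻¹|^{1/2} exp{Zᵀ(Σ_{γ¹}⁻¹−Σ_{γ⁰}⁻¹)Z/2},
   evaluated in log space. Because Σ_γ depends on γ only through the
   projector, ρ_j reduces to scalar functions of
   (m_γ, 1ᵀP Z, ZᵀP Z, 1ᵀP 1): an "add gene" proposal is a rank-one
   basis extension by the gene's normalized residual (cheap, no
   refactorization), a removal re-factorizes the remaining columns,
   and a flip of a linearly dependent gene leaves ρ_j = 1 so its
   conditional equals the prior π_j. The basis is rebuilt from
   scratch periodically to stop floating-point drift.

3. **g-prior scale.** A Metropolis–Hastings update of c. The full
   conditional log p(c | Z, γ) is maximized over log c on
   [1e-3, 1e6] by bounded scalar optimization; the proposal is
   c* = c_opt + ε with ε truncated normal (μ = 0, Laplace-based σ
   floored at 0.1·c_opt, support chosen so c* ∈ (1e-6, ∞)), and with
   probability 0.1 the proposal instead draws c* from the IG(1/2,
   n/2) hyperprior. The mixture component is a deliberate design
   choice: the full conditional inherits the hyperprior's polynomial
   right tail, so a purely Gaussian independence proposal has lighter
   tails than its target and can lodge in the tail for practically
   unbounded stretches. Mixing in the prior bounds the importance
   weights (the likelihood factor in c is bounded above), making the
   kernel uniformly ergodic; empirically the c-chain's law matches
   1-D quadrature of the full conditional to Kolmogorov–Smirnov
   distance ≈ 0.01. Setting `heavy_weight = 0` in `MHProposalConfig`
   recovers the pure truncated-normal scheme. c_opt is recomputed
   every iteration because it depends on the current (Z, γ).

Initialization: γ = all zeros, c = n, Z_i = ±0.5 matching Y_i; burn-in
absorbs it. Defaults follow the reference protocol: 12 000 burn-in
iterations, every 30th draw retained. Retained draws always satisfy
the sign invariant Z_i > 0 ⇔ Y_i = 1 by construction of block 1.

## Gene ranking

The posterior inclusion probability of gene j is its draw frequency
across the M retained states. Rankings sort by probability descending
with ties broken by original gene index, so output is reproducible;
`select_top` takes the first p* genes of that order.

## Prediction and cross-validation

For a new sample, (Z, Z_new) is jointly N(0, Σ_ext) under the
marginalized model, with Σ_ext built on the (n+1)-row stacked design
of the selected genes. Each retained draw contributes the exact
Gaussian conditional P(Z_new > 0 | Z) — computed from the same
low-rank algebra — and the posterior predictive P(Y_new = 1) is the
average over draws. A probability ≥ 0.5 classifies as 1 (the exact
tie goes to 1; any deterministic rule would do).

*Internal* leave-one-out reuses one chain: per draw, the conditional
of Z_i given Z_(−i) yields p(Y_i | Y_(−i), ·), and draws combine
through the harmonic-mean identity M / Σ_t p_t⁻¹ (computed in log
space; a zero probability returns 0 with a warning). *External*
leave-one-out redoes the |t| prescreen (top 50 by default, pooled
variance) and the selection chain inside every split, then classifies
the held-out sample with the p* selected genes, so selection never
sees the held-out label. Per-split chains default to burn-in 2000,
thin 10, 1000 retained draws — deliberately shorter than full-analysis
defaults because n splits multiply the cost; both are overridable.

After selection, held-out samples are classified by running a fresh
chain restricted to the p* selected genes and averaging the
per-draw conditional probabilities — the marginalized predictive
applied to the reduced gene set (not a maximum-likelihood refit). The
t-test + ML-probit baseline (`ttest_probit_baseline`) consumes
identical splits so comparisons are paired; perfect separation or
non-convergence falls back to a lightly L2-penalized probit fit.

## Preprocessing

`preprocess` implements the classical microarray recipe: optional
clipping to [floor, ceil] = [100, 16000] with the variation filter
"keep a gene iff max/min ≥ 5 or max − min ≥ 500" (all four constants
overridable — the mechanism, not the constants, is what the tests pin
down), then log10, then per-gene standardization to mean 0 and unit
variance using the n−1 denominator. Zero-variance genes are dropped
with a warning. The two-sample t statistic uses pooled variance by
default (`equal_var=False` gives Welch).

## Synthetic data

`generate` draws the model's own likelihood forward: X standard
normal (optionally equicorrelated in consecutive blocks of 10 genes),
Z = α + Xβ + ε, Y = 1{Z > 0}. The default recipe mirrors the
reference simulation design — 500 genes, 15 with signal, 200 training
and 40 test samples — with effect sizes ±1, alternating signs
(balanced strong signal; the reference design does not print effect
sizes, so these defaults are labeled as such, not as reproductions).
Label-degenerate draws are resampled up to 100 times before erroring.

What the generator does *not* emulate: array-level intensity
artifacts, heavy-tailed measurement noise, batch effects, or
realistic gene-gene correlation beyond block equicorrelation. Tests
passing on these data therefore demonstrate correctness of the
inferential machinery under the model's own assumptions and
robustness of the pipeline wiring — not performance claims about any
particular real microarray study.

## Problem sizes used by the test suite and acceptance script

Statistical checks run at sizes chosen to finish on a single desktop
core: enumeration checks at n = 5, p = 4 (5×10⁴ sweeps); c-chain
stationarity at n = 30 (10⁵ updates); parameter recovery at p = 100,
5 true genes, n = 100 with 10 replicate chains of 12 000 iterations;
the classification comparison on a scaled-down simulation design
(p = 200, 10 true genes, 120 training / 40 test samples, 10 seeded
replicates). `scripts/acceptance.py` reruns the full pipeline on the
scaled-down design and reports only quantities it computes at run
time.

## Known limitations

* The sampler sweeps γ one gene at a time; strongly correlated gene
  pairs can mix slowly (the classical SSVS limitation). Nothing here
  implements joint swap moves.
* The harmonic-mean LOOCV estimator is known to have heavy-tailed
  weights; it is provided as specified, with the external protocol as
  the preferred evaluation.
* With p* larger than the posterior model size, the tail of the
  ranking is ordered by near-zero probabilities and the index
  tie-break; selected sets beyond the signal genes are effectively
  arbitrary, which is inherent to fixed-p* protocols.
* Binary outcomes only; no multinomial extension, no gene-network
  priors on γ.
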