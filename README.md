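# nichefate

Population dynamics of normal and leukaemic stem cells competing for the
bone-marrow niche: ODE competition models, qualitative (behaviour-constrained)
ABC-SMC inference, and PCA-based robustness analysis of the resulting
posterior.

## The problem

Haematopoietic stem cells (HSCs, species *S*) and leukaemia stem/driving
cells (LSCs, *L*) occupy the same ecological niche, together with their
progeny — progenitors *A*, differentiated blood cells *D* and differentiated
leukaemia cells *T*. `nichefate` asks: **under which rate regimes does
normal haematopoiesis outcompete leukaemia** (stable positive *S*, *A*, *D*
with *L*, *T* driven out), and **which rate combinations does that outcome
constrain most tightly** — i.e. where should an intervention act?

Because reliable data on native HSC/LSC dynamics are scarce, the posterior
is conditioned on *declared behaviour* rather than data. Two models are
provided:

- **Model A** (8 free rates): linear feedback through a *hard* carrying
  capacity, e.g. dS/dt = a₁S(1 − Z/K) − b₁S with Z = S+A+D+L+T ≤ K exactly.
- **Model B** (13 free rates): explicit stem-cell fates — symmetric renewal
  (λ₁), asymmetric renewal (λ₂), symmetric differentiation (λ₃), loss (μ₄),
  and leukaemic analogues (κ₁…κ₃, ν₄) — under *soft* exponential sub-niche
  feedback Φ₁ = e^(−γ₁(S+L)), Φ₂/Φ₃ = e^(−γ(A+D+T)). Its progenitor pool is
  unstable exactly when λ₅ > μ₆.

The pipeline: uniform [0, 1] priors → ABC-SMC conditioned on the
suppression criterion (distance = 0 iff the trajectory reaches a
pseudo-steady state with S, A, D viable and L, T extinct) → weighted
posterior → PCA of the weighted covariance. The **smallest-eigenvalue
("stiff") principal components** are the directions the behaviour constrains
most; squared-loading shares (summing to 100 % per component) attribute them
to parameters. See `docs/methods.md` for the full model equations,
numerical choices and limitations.

## Worked example

Validate the ABC machinery on the bundled one-parameter decay model, whose
behavioural posterior is known exactly (uniform on [r\*, 1] with r\* = 0.5):

```bash
nichefate run toy_abc_validation --out toy_out --seed 11
```

prints (numbers from this exact command):

```json
{
  "r_star_analytic": 0.5,
  "min_accepted_rate": 0.46709893027286997,
  "ks_distance_vs_analytic_posterior": 0.05139533796876198,
  "final_epsilon": 0.002655355677506065
}
```

The sampler recovers the analytic cutoff: accepted decay rates undershoot
r\* = 0.5 only by the amount the final tolerance ε ≈ 0.0027 permits, and the
weighted ECDF of the posterior sits within KS ≈ 0.05 of the exact uniform
law.

Map the dynamical regimes of model A under 500 prior draws:

```bash
nichefate classify --model modelA --n 500 --seed 11
```

```json
{"HSC_WIN": 0.236, "LSC_WIN": 0.27, "NEITHER": 0.38,
 "NO_STEADY_STATE": 0.114, "UNBOUNDED": 0.0}
```

About a quarter of prior volume suppresses leukaemia outright, a quarter
loses the niche to it, and the rest coexist or fail to settle; model A never
diverges (hard capacity). The same command with `--model modelB` finds
roughly half the prior volume unbounded — the λ₅ > μ₆ instability
half-space.

The headline experiments run the full pipeline and write populations,
posterior histograms, PCA loadings and contribution tables plus a
reproducibility manifest:

```bash
nichefate run modelA_suppression --out runA --seed 11   # ~1-2 min
nichefate run modelB_suppression --out runB --seed 11   # ~3 min
```

In the resulting PCA, the stiffest component of model A is dominated by
{a₁, b₁, e₁} (HSC self-renewal, progenitor production, differentiation) and
that of model B by {λ₁, λ₃, μ₄} (HSC fate rates), while the leukaemia-rate
marginals stay close to the flat prior: **maintaining HSC-lineage dynamics
constrains the suppression behaviour far more than controlling the
leukaemic rates** — the leukaemia-suppressing region is characterised by
what the healthy lineage must do, not by what the malignant one must not.

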