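# Methods

## The biological setting

Haematopoietic stem cells (HSCs) and leukaemia stem/driving cells (LSCs)
compete for the same ecological resource: the bone-marrow niche. `nichefate`
asks under what parameter regimes normal haematopoiesis wins — healthy
species maintain stable positive populations while the leukaemic species are
driven out — and which rate combinations that outcome constrains most
tightly. Because reliable in-vivo data on native HSC/LSC dynamics are
scarce, the analysis conditions on *declared behaviour* instead of data:
qualitative ABC identifies the region of parameter space producing leukaemia
suppression, and PCA of the resulting posterior ranks parameter directions
by how tightly the behaviour constrains them.

## Models

All species are nonnegative concentrations; rates are per unit model time
and, for inference, share a uniform [0, 1] prior ("the parameters are
rates").

**Two-species competition (`lv2`).**
dX/dt = X(α − γ(X+Y)), dY/dt = Y(β − γ(X+Y)): both species feel one linear
feedback signal proportional to the combined population. Since
d/dt log(X/Y) = α − β, the species with the larger growth rate always
excludes the other (exact winner-by-growth-rate property, tested).

**Model A (hard niche).** Five species — HSC `S`, progenitors `A`,
differentiated blood cells `D`, leukaemia drivers `L`, differentiated
leukaemia cells `T` — with every growth term damped by the shared factor
(1 − Z/K), Z = S+A+D+L+T:

    dS/dt = a1·S·(1 − Z/K) − b1·S
    dA/dt = b1·S + c1·A·(1 − Z/K) − e1·A
    dD/dt = e1·A − f·D
    dL/dt = a2·L·(1 − Z/K) − b2·L
    dT/dt = b2·L − g·T

Transitions conserve mass and removal only subtracts, so dZ/dt ≤ 0 at
Z = K: the capacity is *hard* (Z(t) ≤ K exactly; tested along trajectories).
K = 1 throughout, so populations are niche fractions. The L and T equations
mirror S and D under (a1,b1,f) ↔ (a2,b2,g); the healthy arm additionally has
the progenitor compartment (c1, e1), which is why the two arms are *not*
globally exchangeable (see "Mirror symmetry" below).

**Model B (soft niche, explicit fates).** Stem-cell fates are resolved:
symmetric renewal (S → 2S, rate λ1), asymmetric renewal (S → S+A, λ2),
symmetric differentiation (S → 2A, λ3), loss (μ4), and the leukaemic
analogues (κ1, κ2, κ3, ν4). Feedback is exponential and split across two
sub-niches: Φ1 = exp(−γ1(S+L)) for the stem sub-niche, and
Φ2 = exp(−γ2(A+D+T)), Φ3 = exp(−γ3(A+D+T)) for the differentiated
sub-niche acting on healthy and leukaemic differentiation respectively:

    dS/dt = λ1·S·Φ1 − λ3·S·Φ2 − μ4·S
    dA/dt = (λ2 + 2λ3)·S·Φ2 + (λ5 − μ6)·A
    dD/dt = χ1·A·Φ2 − μ8·D
    dL/dt = κ1·L·Φ1 − κ3·L·Φ3 − ν4·L
    dT/dt = (κ2 + 2κ3)·L·Φ3 − ν8·T

γ1 = γ2 = γ3 = 0.01 are held fixed (their value only rescales the other
rates); the 13 remaining rates are free. Design choices that were genuinely
open, and how they were resolved:

- *Feedback placement.* Φ1 damps the self-renewal of the stem species (the
  stem sub-niche acting "on themselves"); Φ2/Φ3 damp the differentiation
  fates feeding the A/D/T sub-niche. Removal rates (μ4, μ8, ν4, ν8) are
  bare — crowding should not suppress death or migration.
- *Progenitor amplification is bare.* A's net self-dynamics are
  (λ5 − μ6)·A with no additional loss term: the A → D transition (χ1)
  produces D without depleting A (progenitor depletion by differentiation is
  lumped into the disappearance rate μ6). Consequence: the system diverges
  *exactly* when λ5 > μ6 — if the progenitor pool self-replicates faster
  than it disappears, no feedback can save it, because the feedbacks only
  regulate differentiation. This makes the model's known instability region
  a sharp, testable statement (divergence iff λ5 > μ6, with a margin large
  enough to reach the blow-up cap within the horizon), and it matches the
  interpretation of T as structurally "between" A and D: produced directly
  from its stem species, unable to self-replicate.
- With all γ = 0 the system reduces to a linear compartment model (tested
  via additivity of the vector field).

Note the soft capacity: equilibrium occupancies scale like
ln(rate ratios)/γ ≈ O(100), not O(1). The criteria thresholds below are
absolute (fractions of K = 1) and are easily cleared by viable species in
model B.

## Simulation

Stiff-capable adaptive integration (LSODA; near-extinction dynamics are
stiff), rel/abs tolerance 1e−8, horizon t_end = 1000 with 500 output points.
Rates in [0, 1] give characteristic times of O(1–100), so 1000 time units
comfortably reach a plateau. Tolerance-scale negative overshoots are clipped
to zero inside the vector field and on the output grid.

A trajectory is at *pseudo-steady state* when every component's relative
change over the trailing 20 % of the horizon is below 1e−4 (absolute change
for components below the extinction floor 1e−6, where relative change is
meaningless). The reported final state is the tail average at steady state
and the last sample otherwise (the tail average estimates an equilibrium; it
would misstate a moving endpoint). Integration halts early, flagged
`unbounded`, when any component crosses the blow-up cap 1e6·K; integrator
failures are returned as flagged results so batch screening never aborts.

Default initial condition: S = L = 0.01·K with A = D = T = 0 — an
established small leukaemic clone alongside a small HSC pool. The models can
be bistable, so the initial state is a first-class configuration item, not a
constant.

## Outcome classification

"S, A, D > 0 and L = T = 0 at steady state" is an infinite-time statement;
finite-time classification needs thresholds: a species is *extinct* below
extinct_eps = 1e−3 (fraction of K) and *viable* above viable_delta = 1e−2.
Labels: HSC_WIN, LSC_WIN (the mirrored condition), NEITHER (coexistence,
bistability, or anything else), UNBOUNDED, NO_STEADY_STATE. Bistability is
not resolved per parameter set (that would require scanning initial
conditions); NEITHER absorbs it.

## Qualitative ABC

The behavioural distance of a trajectory from the criteria is

    d = Σ_{Y ∈ extinct} max(0, Y_end/K − extinct_eps)
      + Σ_{X ∈ viable} max(0, viable_delta − X_end/K) / viable_delta,

with a fixed ceiling d_max = 10 for unbounded or non-stationary runs. The
hinge form makes d zero *exactly* on the target behaviour (at the
thresholds), strictly positive otherwise, monotone in each leukaemic excess
and each healthy shortfall — and it gives the accepted region positive
prior mass, which the samplers exploit.

**Rejection ABC** draws from the prior and keeps draws with d ≤ ε (uniform
weights); it aborts with a diagnostic if the acceptance rate falls below
1e−5.

**ABC-SMC** starts from prior rejection at ε0 (∞ under the adaptive
schedule), then per generation: resample the previous population by weight,
perturb with a component-wise uniform kernel (half-width = previous
weighted standard deviation per parameter, truncated to the prior box),
accept at the shrunk ε, and weight by prior density over the kernel mixture
density. Defaults: 1000 particles, up to 6 generations, ε_t = median of the
previous generation's accepted distances, stop when ε < 0.01. Because the
distance has an atom at d_max (≈ half of model B's prior volume is
unbounded), a plain median can stall; when it fails to decrease the median
is taken over sub-d_max distances, with a 0.9 geometric shrink as a last
resort. In practice the schedule collapses to ε = 0 within 4–5 generations
— the hinge distance has an atom at zero too — so the final population
samples the prior restricted to the exact behaviour region, the exact
qualitative posterior. Per-generation ε, acceptance rate and effective
sample size (ESS) are logged; acceptance-rate collapse is the main failure
mode and must be visible.

The end-to-end oracle is a one-parameter pure-decay model whose behavioural
criterion ("extinct by t_end") holds exactly for rates above
r\* = ln(X0/threshold)/t_end, making the true posterior uniform on [r\*, 1];
both samplers are checked against this closed form (KS distance), and
against each other.

## Robustness (posterior PCA)

PCA eigen-decomposes the *weighted covariance* of the final population on
the raw [0, 1] parameter scale (all free rates share the same prior, so no
standardization; covariance, not correlation). Components are sorted by
descending eigenvalue: the last component is the *stiff* direction — least
posterior variance, i.e. the combination the behaviour constrains most —
and the first components are *sloppy*. Per-parameter contributions to a
component are squared-loading shares (×100); loadings are unit vectors, so
shares sum to 100 % per component, which is the only convention under which
subset shares are well-defined percentages (absolute-value shares are
available behind a flag for sensitivity checks). An independent
explicit-loop covariance assembly plus symmetric eigensolver serves as the
test oracle (agreement to 1e−8). ESS < 50 triggers a warning.

Posterior marginals are summarized as weighted 20-bin histograms over the
prior support plus pairwise 2-D density grids; marginal Shannon entropy
operationalizes "less well inferred": leukaemia-arm marginals stay closer to
the flat prior (higher entropy) than HSC-arm marginals in both models.

## Mirror symmetry — what is literally true

At the equation level, the L equation of model A equals the S equation under
the renaming S↔L, (a1,b1)↔(a2,b2) (tested symbolically at random points).
At the outcome level, exact count-swap under arm exchange cannot hold in the
full model: the healthy chain S→A→D has a middle compartment (c1, e1) with
no leukaemic counterpart, so exchanged systems are not trajectory-conjugate.
The count-swap property is therefore tested on the sub-family where the
exchange *is* an exact conjugacy: b1 = b2 = 0 with empty progeny
compartments reduces the dynamics to pure two-species stem competition, and
swapping (a1↔a2, S0↔L0) maps each trajectory onto its mirror image, so
HSC_WIN and LSC_WIN counts swap exactly (asymmetric initial clones make both
classes reachable; note this sub-family has a line of equilibria, so wins
come from initial-condition asymmetry rather than exclusion).

## What the synthetic conditions do and do not show

The generator's conditions *are* the study conditions: uniform [0, 1]
priors, behavioural criteria, no external data. Passing tests demonstrate
the internal consistency and correctness of the machinery (equations,
integration, classification, samplers, PCA) and the qualitative robustness
findings under these conditions. They do not validate the models against
experimental haematopoiesis data, nor do the coarse-grained species map onto
specific measurable cell populations.

## Numerical choices and limitations

- Problem sizes: suppression runs use 1000 particles × ≤ 6 generations
  (model A ≈ 1–2 min, model B ≈ 3 min on one CPU); regime maps default to
  1000 draws; unit tests use shorter horizons where only mechanics are
  exercised.
- The exact-region posterior (final ε = 0) is sharper than any
  finite-tolerance ABC approximation of it. Contribution percentages of the
  dominant groups on stiff components are therefore systematically higher
  than a loose-tolerance run would report, and percentages on near-flat
  directions lower; the *composition* (which groups dominate which stiff
  components) is the stable, reproducible finding. Middle eigenvalues of
  the posterior spectrum are closely spaced, so the ordering of
  mid-spectrum components can vary between seeds; only the well-separated
  stiffest components are interpreted.
- Exact ties at classification thresholds are resolved toward satisfaction
  (d = 0 at the thresholds); boundary parameter sets are measure-zero.
- Model B trajectories barely above the instability boundary
  (0 < λ5 − μ6 ≪ ln(cap)/t_end) diverge too slowly to reach the blow-up cap
  within the horizon and are labelled by their finite-time behaviour
  instead; divergence tests use a margin ≥ 0.05.
- No bifurcation or basin-of-attraction analysis; no model selection
  between the two models; no stochastic (jump-process) dynamics; no
  six-species extensions or spatially explicit sub-niches.
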