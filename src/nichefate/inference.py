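"""Qualitative (behaviour-constrained) approximate Bayesian computation.

Instead of fitting the models to data, the posterior is conditioned on a
declared behaviour — here, leukaemia suppression: stable positive healthy
populations with vanishing leukaemic populations at (pseudo-)steady state.
The usual data distance of ABC is replaced by a behavioural distance that is
zero exactly when a trajectory satisfies the criteria and grows with the
degree of violation.  Both a plain rejection sampler and the sequential Monte
Carlo (SMC) sampler — resample, perturb, reweight under a shrinking tolerance
schedule — are provided.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .classify import CriteriaSpec
from .models import get_model
from .simulate import SolverSettings, Trajectory, integrate

__all__ = ["PriorSpec", "Particle", "Population", "ABCConfig", "sample_prior",
           "qualitative_distance", "abc_rejection", "abc_smc",
           "AcceptanceRateError"]

log = logging.getLogger(__name__)

#: distance assigned to unbounded or non-stationary trajectories
D_MAX = 10.0


class AcceptanceRateError(RuntimeError):
    """Raised when the rejection sampler's acceptance rate collapses."""


@dataclass(frozen=True)
class PriorSpec:
    """Independent uniform priors, one [low, high] interval per free rate.

    All model rates default to U[0, 1]; fixed parameters (the feedback
    constants γ, the capacity K) are excluded from the inference dimension.
    """

    names: tuple[str, ...]
    lows: np.ndarray
    highs: np.ndarray
    fixed: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        object.__setattr__(self, "names", tuple(self.names))
        object.__setattr__(self, "lows", np.asarray(self.lows, dtype=float))
        object.__setattr__(self, "highs", np.asarray(self.highs, dtype=float))
        if not (len(self.names) == self.lows.size == self.highs.size):
            raise ValueError("names/lows/highs length mismatch")
        if np.any(self.lows >= self.highs):
            raise ValueError("each prior lower bound must be < upper bound")

    @classmethod
    def for_model(cls, model_name: str, low: float = 0.0,
                  high: float = 1.0) -> "PriorSpec":
        model = get_model(model_name)
        names = model.free_param_names
        d = len(names)
        return cls(names, np.full(d, low), np.full(d, high),
                   fixed=dict(model.fixed))

    @property
    def dim(self) -> int:
        return len(self.names)

    def contains(self, theta: np.ndarray) -> np.ndarray:
        theta = np.atleast_2d(theta)
        return np.all((theta >= self.lows) & (theta <= self.highs), axis=1)

    def log_volume(self) -> float:
        return float(np.sum(np.log(self.highs - self.lows)))


@dataclass(frozen=True)
class Particle:
    theta: np.ndarray
    weight: float
    distance: float


@dataclass
class Population:
    """A weighted particle ensemble at one SMC tolerance level."""

    thetas: np.ndarray          # (n, dim)
    weights: np.ndarray         # (n,), normalized to sum 1
    distances: np.ndarray       # (n,)
    epsilon: float
    generation: int
    acceptance_rate: float
    param_names: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        s = self.weights.sum()
        if s <= 0:
            raise ValueError("weights must have positive sum")
        self.weights = self.weights / s

    @property
    def n(self) -> int:
        return len(self.weights)

    @property
    def ess(self) -> float:
        """Effective sample size 1 / Σ w²."""
        return float(1.0 / np.sum(self.weights ** 2))

    @property
    def particles(self) -> list[Particle]:
        return [Particle(t, w, d) for t, w, d
                in zip(self.thetas, self.weights, self.distances)]

    def to_frame(self) -> pd.DataFrame:
        cols = self.param_names or tuple(f"p{i}" for i in range(self.thetas.shape[1]))
        df = pd.DataFrame(self.thetas, columns=list(cols))
        df.insert(0, "distance", self.distances)
        df.insert(0, "weight", self.weights)
        df.insert(0, "generation", self.generation)
        return df


@dataclass(frozen=True)
class ABCConfig:
    """SMC sampler configuration.

    The tolerance schedule is adaptive by default: the next ε is the median of
    the previous generation's accepted distances (an explicit non-increasing
    list may be given instead).  The perturbation kernel is component-wise
    uniform with half-width equal to the previous population's weighted
    standard deviation per parameter (times ``kernel_scale``), truncated to
    the prior support.  Sampling stops after ``n_generations`` or once
    ε < ``eps_min``.
    """

    n_particles: int = 1000
    n_generations: int = 6
    epsilons: tuple[float, ...] | None = None   # explicit schedule (optional)
    eps_min: float = 0.01
    kernel_scale: float = 1.0
    max_trials_factor: int = 500
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_particles < 2:
            raise ValueError("n_particles must be >= 2")
        if self.epsilons is not None:
            eps = tuple(self.epsilons)
            if any(b > a for a, b in zip(eps, eps[1:])):
                raise ValueError("explicit epsilon schedule must be non-increasing")
            object.__setattr__(self, "epsilons", eps)


def sample_prior(prior: PriorSpec, n: int, seed: int) -> np.ndarray:
    """n i.i.d. draws from the uniform prior; deterministic under the seed."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    return rng.uniform(prior.lows, prior.highs, size=(n, prior.dim))


def qualitative_distance(traj: Trajectory, criteria: CriteriaSpec) -> float:
    """Behavioural distance of a trajectory from the declared target.

    Zero iff the trajectory satisfies the criteria at the thresholds: every
    required-extinct species ends at or below ``extinct_eps·K`` and every
    required-viable species at or above ``viable_delta·K``.  Violations add
    hinge penalties — the excess final population (in units of K) for each
    species that should vanish, and the relative shortfall below the
    viability threshold for each species that should persist.  Unbounded or
    non-stationary trajectories get the fixed ceiling ``D_MAX``.
    """
    if traj.unbounded or not traj.solver_ok:
        return D_MAX
    if criteria.require_steady_state and not traj.reached_steady_state:
        return D_MAX
    idx = {s: i for i, s in enumerate(traj.species)}
    K = criteria.K
    d = 0.0
    for s in criteria.extinct_species:
        d += max(0.0, traj.final_state[idx[s]] / K - criteria.extinct_eps)
    for s in criteria.viable_species:
        short = criteria.viable_delta - traj.final_state[idx[s]] / K
        if short > 0:
            d += short / criteria.viable_delta
    return min(d, D_MAX)


def _simulate_distance(model, theta, criteria, settings, init_state):
    params = model.make_params(theta)
    traj = integrate(model.name, params, init_state, settings)
    return qualitative_distance(traj, criteria)


def abc_rejection(model_name: str,
                  prior: PriorSpec,
                  criteria: CriteriaSpec,
                  settings: SolverSettings,
                  epsilon: float,
                  n_accept: int,
                  seed: int,
                  init_state=None,
                  rate_floor: float = 1e-5,
                  check_every: int = 2000) -> Population:
    """Plain rejection ABC: draw from the prior, keep draws with d ≤ ε.

    Particles carry uniform weights.  If the running acceptance rate drops
    below ``rate_floor`` (after at least ``check_every`` trials) the sampler
    aborts with a diagnostic instead of spinning forever.
    """
    if epsilon < 0:
        raise ValueError("epsilon must be >= 0")
    model = get_model(model_name)
    rng = np.random.default_rng(seed)
    accepted, dists = [], []
    trials = 0
    while len(accepted) < n_accept:
        theta = rng.uniform(prior.lows, prior.highs, size=prior.dim)
        trials += 1
        d = _simulate_distance(model, theta, criteria, settings, init_state)
        if d <= epsilon:
            accepted.append(theta)
            dists.append(d)
        if trials >= check_every and len(accepted) / trials < rate_floor:
            raise AcceptanceRateError(
                f"acceptance rate {len(accepted)}/{trials} below floor "
                f"{rate_floor}; epsilon={epsilon} may be unreachable")
    rate = n_accept / trials
    return Population(np.array(accepted), np.full(n_accept, 1.0 / n_accept),
                      np.array(dists), epsilon, 0, rate,
                      param_names=prior.names)


def _weighted_std(thetas: np.ndarray, weights: np.ndarray) -> np.ndarray:
    mean = np.average(thetas, axis=0, weights=weights)
    var = np.average((thetas - mean) ** 2, axis=0, weights=weights)
    return np.sqrt(var)


def _next_epsilon(pop: Population, eps_prev: float) -> float:
    """Median of accepted distances, guarded against stalling.

    The distance has an atom at D_MAX (divergent / non-stationary runs), so a
    plain median can fail to decrease; in that case fall back to the median of
    the sub-D_MAX distances, then to a geometric shrink.
    """
    eps = float(np.median(pop.distances))
    if eps >= eps_prev:
        below = pop.distances[pop.distances < D_MAX]
        if below.size:
            eps = float(np.median(below))
    if eps >= eps_prev:
        eps = 0.9 * eps_prev
    return eps


def abc_smc(model_name: str,
            prior: PriorSpec,
            criteria: CriteriaSpec,
            settings: SolverSettings,
            config: ABCConfig,
            init_state=None) -> list[Population]:
    """ABC-SMC: shrink the tolerance generation by generation.

    Generation 0 is rejection sampling from the prior at ε0 (the first
    explicit ε, or ∞ under the adaptive schedule).  Each later generation
    resamples the previous population by weight, perturbs with a truncated
    component-wise uniform kernel, rejects proposals outside the prior
    support, accepts at the shrunk ε, and weights accepted particles by
    prior density over the kernel mixture density.  Returns the list of
    populations; the last one approximates the behavioural posterior.

    If a generation cannot be filled within ``max_trials_factor × n_particles``
    simulations, the completed generations are returned with a warning.
    """
    model = get_model(model_name)
    n = config.n_particles
    rng = np.random.default_rng(config.seed)
    explicit = config.epsilons

    eps0 = explicit[0] if explicit else np.inf
    pops: list[Population] = []

    # --- generation 0: rejection from the prior -------------------------
    accepted, dists = [], []
    trials = 0
    max_trials = config.max_trials_factor * n
    while len(accepted) < n and trials < max_trials:
        theta = rng.uniform(prior.lows, prior.highs, size=prior.dim)
        trials += 1
        d = _simulate_distance(model, theta, criteria, settings, init_state)
        if d <= eps0:
            accepted.append(theta)
            dists.append(d)
    if len(accepted) < n:
        log.warning("generation 0 incomplete (%d/%d particles after %d trials)",
                    len(accepted), n, trials)
        if not accepted:
            return pops
    pop = Population(np.array(accepted), np.full(len(accepted), 1.0),
                     np.array(dists), float(eps0), 0, len(accepted) / trials,
                     param_names=prior.names)
    pops.append(pop)
    log.info("gen 0: eps=%g acc=%.3f ess=%.1f", eps0, pop.acceptance_rate, pop.ess)

    n_gens = len(explicit) if explicit else config.n_generations
    for t in range(1, n_gens):
        eps_prev = pops[-1].epsilon
        if explicit:
            eps = explicit[t]
        else:
            eps = _next_epsilon(pops[-1], eps_prev)
        prev = pops[-1]
        half = config.kernel_scale * _weighted_std(prev.thetas, prev.weights)
        half = np.maximum(half, 1e-9)       # degenerate (point-mass) guard
        kern_dens = 1.0 / np.prod(2.0 * half)  # uniform kernel box density

        acc_t, acc_d, acc_w = [], [], []
        trials = 0
        while len(acc_t) < n and trials < max_trials:
            i = rng.choice(prev.n, p=prev.weights)
            theta = prev.thetas[i] + rng.uniform(-half, half)
            trials += 1
            if not prior.contains(theta)[0]:
                continue
            d = _simulate_distance(model, theta, criteria, settings, init_state)
            if d > eps:
                continue
            # SMC importance weight: prior density / kernel mixture density
            inside = np.all(np.abs(theta - prev.thetas) <= half, axis=1)
            mix = float(np.sum(prev.weights[inside])) * kern_dens
            prior_dens = math.exp(-prior.log_volume())
            acc_t.append(theta)
            acc_d.append(d)
            acc_w.append(prior_dens / mix if mix > 0 else 0.0)
        if len(acc_t) < max(2, n // 10):
            log.warning("generation %d failed to fill (%d/%d); stopping early",
                        t, len(acc_t), n)
            break
        pop = Population(np.array(acc_t), np.array(acc_w), np.array(acc_d),
                         float(eps), t, len(acc_t) / trials,
                         param_names=prior.names)
        pops.append(pop)
        log.info("gen %d: eps=%g acc=%.3f ess=%.1f", t, eps,
                 pop.acceptance_rate, pop.ess)
        if not explicit and eps < config.eps_min:
            break
    return pops


def population_to_csv(pops: list[Population] | Population, path) -> None:
    """Serialize one or several populations to CSV (one row per particle)."""
    if isinstance(pops, Population):
        pops = [pops]
    pd.concat([p.to_frame() for p in pops], ignore_index=True).to_csv(
        path, index=False)


def population_from_csv(path, generation: int | None = None) -> Population:
    """Load the (last, by default) generation back from a populations CSV."""
    df = pd.read_csv(path)
    gen = generation if generation is not None else int(df["generation"].max())
    sub = df[df["generation"] == gen]
    names = tuple(c for c in df.columns
                  if c not in ("generation", "weight", "distance"))
    return Population(sub[list(names)].to_numpy(), sub["weight"].to_numpy(),
                      sub["distance"].to_numpy(), float("nan"), gen,
                      float("nan"), param_names=names)
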