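"""Synthetic inputs: space-filling designs, labelled regime fixtures and an
analytically solvable toy inference problem.

Nothing in this package consumes experimental data — the study conditions are
parameter draws from uniform [0, 1] priors and behavioural criteria — so this
module generates everything the pipeline and its tests need: Latin-hypercube /
Sobol designs over the prior box, brute-force-screened parameter sets labelled
by dynamical regime, and a one-parameter decay model whose behavioural
posterior is known in closed form.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import qmc

from .classify import CriteriaSpec, OutcomeLabel, classify_outcome
from .inference import PriorSpec, sample_prior
from .models import get_model
from .simulate import SolverSettings, integrate

__all__ = ["lhs_sample", "full_factorial_count", "generate_regime_fixtures",
           "write_regime_fixtures", "toy_abc_problem", "ToyABCProblem"]


def lhs_sample(prior: PriorSpec, n: int, seed: int,
               method: str = "lhs") -> np.ndarray:
    """Space-filling sample of the prior box.

    ``lhs`` (default): Latin hypercube — each parameter's n draws occupy n
    distinct equal-probability strata.  ``sobol``: a scrambled Sobol sequence,
    exposed through the same interface as an alternative global design.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if method == "lhs":
        engine = qmc.LatinHypercube(d=prior.dim, seed=seed)
    elif method == "sobol":
        engine = qmc.Sobol(d=prior.dim, scramble=True, seed=seed)
    else:
        raise ValueError(f"unknown design {method!r}")
    unit = engine.random(n)
    return qmc.scale(unit, prior.lows, prior.highs)


def full_factorial_count(levels: int, dims: int) -> int:
    """Size of a full-factorial grid: ``levels ** dims``.

    Illustrates why grid designs are hopeless in high dimension — four levels
    per dimension in ten dimensions already needs 4**10 = 1,048,576 runs.
    """
    if levels < 1 or dims < 1:
        raise ValueError("levels and dims must be >= 1")
    return levels ** dims


def generate_regime_fixtures(model_name: str,
                             seed: int,
                             n_per_label: int = 5,
                             max_draws: int = 3000,
                             criteria: CriteriaSpec | None = None,
                             settings: SolverSettings | None = None,
                             forced: dict | None = None) -> dict[str, pd.DataFrame]:
    """Brute-force screen random draws into labelled parameter fixtures.

    Samples the uniform prior, integrates each draw from the default initial
    condition and bins it by outcome label until every reachable label has at
    least ``n_per_label`` sets (labels still empty after ``max_draws`` are
    recorded as absent — e.g. UNBOUNDED never occurs for model A, whose hard
    capacity bounds every trajectory).  ``forced`` pins selected parameters
    after sampling (e.g. ``{"lam5": 0.8, "mu6": 0.3}`` to probe the unstable
    region).  Deterministic: the same seed reproduces identical tables.
    """
    model = get_model(model_name)
    criteria = criteria or CriteriaSpec()
    settings = settings or SolverSettings()
    prior = PriorSpec.for_model(model_name)
    thetas = sample_prior(prior, max_draws, seed)
    if forced:
        for name, value in forced.items():
            thetas[:, model.free_param_names.index(name)] = value

    buckets: dict[str, list[dict]] = {lab.value: [] for lab in OutcomeLabel}
    need = set(buckets)
    for theta in thetas:
        traj = integrate(model_name, model.make_params(theta), None, settings)
        label = classify_outcome(traj, criteria).value
        if len(buckets[label]) < n_per_label:
            row = dict(zip(model.free_param_names, theta))
            row.update({f"final_{s}": v
                        for s, v in zip(model.species, traj.final_state)})
            row["label"] = label
            buckets[label].append(row)
            if len(buckets[label]) >= n_per_label:
                need.discard(label)
        if not need:
            break
    return {lab: pd.DataFrame(rows) for lab, rows in buckets.items() if rows}


def write_regime_fixtures(fixture_dir, model_name: str, seed: int,
                          **kwargs) -> Path:
    """Persist regime fixtures as CSVs plus a JSON manifest; returns the dir."""
    out = Path(fixture_dir)
    out.mkdir(parents=True, exist_ok=True)
    tables = generate_regime_fixtures(model_name, seed, **kwargs)
    manifest = {"model": model_name, "seed": seed,
                "labels": sorted(tables), "version": 1}
    for label, df in tables.items():
        df.to_csv(out / f"{model_name}_{label}.csv", index=False)
    with open(out / f"{model_name}_manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return out


@dataclass(frozen=True)
class ToyABCProblem:
    """One-parameter pure-decay model with an analytic behavioural posterior.

    The species decays as ``X(t) = X0·exp(−r t)``; the behavioural criterion
    "X extinct (≤ threshold) by t_end" is met exactly for decay rates above
    ``r* = ln(X0/threshold)/t_end``, so under a U[0, 1] prior the true
    posterior is uniform on [r*, 1].  Used as an end-to-end oracle for the
    ABC samplers.
    """

    x0: float
    threshold: float
    t_end: float

    @property
    def r_star(self) -> float:
        return float(np.log(self.x0 / self.threshold) / self.t_end)

    @property
    def model_name(self) -> str:
        return "toy_decay"

    @property
    def prior(self) -> PriorSpec:
        return PriorSpec.for_model("toy_decay")

    @property
    def criteria(self) -> CriteriaSpec:
        # extinction-only criterion; the slow pre-extinction transient is not
        # stationary on this short horizon, so no steady state is required
        return CriteriaSpec(viable_species=frozenset(),
                            extinct_species=frozenset({"X"}),
                            extinct_eps=self.threshold,
                            viable_delta=2 * self.threshold,
                            require_steady_state=False)

    @property
    def settings(self) -> SolverSettings:
        return SolverSettings(t_end=self.t_end, n_points=200)

    @property
    def init_state(self) -> tuple[float, ...]:
        return (self.x0,)

    def posterior_cdf(self, r: np.ndarray) -> np.ndarray:
        """Closed-form posterior CDF: uniform on [r*, 1]."""
        r = np.asarray(r, dtype=float)
        return np.clip((r - self.r_star) / (1.0 - self.r_star), 0.0, 1.0)


def toy_abc_problem(x0: float = 1.0,
                    threshold: float = float(np.exp(-5)),
                    t_end: float = 10.0) -> ToyABCProblem:
    """The bundled toy problem; defaults give the cutoff r* = 0.5 exactly."""
    return ToyABCProblem(x0=x0, threshold=threshold, t_end=t_end)
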