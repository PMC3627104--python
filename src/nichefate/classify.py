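"""Dynamical-outcome labelling and regime maps over parameter space.

A trajectory is reduced to one of five labels: the healthy lineage wins
(``HSC_WIN``: S, A, D persist while L, T vanish), the leukaemic lineage wins
(``LSC_WIN``: the mirrored condition), neither wins (coexistence, bistability
or anything else), the run diverged (``UNBOUNDED``), or no pseudo-steady state
was reached on the horizon (``NO_STEADY_STATE``).  "Persist" and "vanish" are
exact-limit statements at infinite time; on a finite horizon they become
thresholds: a species is viable above ``viable_delta·K`` and extinct below
``extinct_eps·K``.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .models import get_model
from .simulate import SolverSettings, Trajectory, integrate

__all__ = ["OutcomeLabel", "CriteriaSpec", "classify_outcome",
           "classify_final_state", "regime_map"]


class OutcomeLabel(str, enum.Enum):
    HSC_WIN = "HSC_WIN"
    LSC_WIN = "LSC_WIN"
    NEITHER = "NEITHER"
    UNBOUNDED = "UNBOUNDED"
    NO_STEADY_STATE = "NO_STEADY_STATE"


@dataclass(frozen=True)
class CriteriaSpec:
    """Behavioural target: which species must persist and which must vanish.

    Defaults encode leukaemia suppression: stable positive populations of the
    healthy species and vanishing leukaemic populations at steady state.
    Thresholds are fractions of the carrying capacity K: ``extinct_eps=1e-3``
    (a species is "gone") and ``viable_delta=1e-2`` (a species has "a finite
    positive value above some threshold").
    """

    viable_species: frozenset = frozenset({"S", "A", "D"})
    extinct_species: frozenset = frozenset({"L", "T"})
    extinct_eps: float = 1e-3
    viable_delta: float = 1e-2
    require_steady_state: bool = True
    K: float = 1.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "viable_species", frozenset(self.viable_species))
        object.__setattr__(self, "extinct_species", frozenset(self.extinct_species))
        if self.viable_species & self.extinct_species:
            raise ValueError("viable and extinct species sets must be disjoint")
        if not 0 < self.extinct_eps < self.viable_delta < 1:
            raise ValueError("need 0 < extinct_eps < viable_delta < 1")

    def mirrored(self) -> "CriteriaSpec":
        """The same criteria with the winning and losing sides exchanged."""
        return CriteriaSpec(self.extinct_species, self.viable_species,
                            self.extinct_eps, self.viable_delta,
                            self.require_steady_state, self.K)


def _satisfies(final: np.ndarray, species: Sequence[str],
               criteria: CriteriaSpec) -> bool:
    idx = {s: i for i, s in enumerate(species)}
    for s in criteria.viable_species:
        if final[idx[s]] < criteria.viable_delta * criteria.K:
            return False
    for s in criteria.extinct_species:
        if final[idx[s]] > criteria.extinct_eps * criteria.K:
            return False
    return True


def classify_final_state(final: np.ndarray, species: Sequence[str],
                         criteria: CriteriaSpec) -> OutcomeLabel:
    """Label a (steady) final state: HSC_WIN / LSC_WIN / NEITHER."""
    if _satisfies(final, species, criteria):
        return OutcomeLabel.HSC_WIN
    if _satisfies(final, species, criteria.mirrored()):
        return OutcomeLabel.LSC_WIN
    return OutcomeLabel.NEITHER


def classify_outcome(traj: Trajectory, criteria: CriteriaSpec) -> OutcomeLabel:
    """Map a trajectory to exactly one outcome label."""
    if traj.unbounded:
        return OutcomeLabel.UNBOUNDED
    if not traj.solver_ok:
        return OutcomeLabel.NO_STEADY_STATE
    if criteria.require_steady_state and not traj.reached_steady_state:
        return OutcomeLabel.NO_STEADY_STATE
    return classify_final_state(traj.final_state, traj.species, criteria)


def regime_map(model_name: str,
               n_samples: int,
               criteria: CriteriaSpec | None = None,
               settings: SolverSettings | None = None,
               seed: int = 0,
               sampler: str = "uniform",
               prior=None,
               init_state=None) -> tuple[dict, pd.DataFrame]:
    """Sample parameter space, label every draw, and tabulate outcome
    frequencies.

    Draws ``n_samples`` parameter vectors from the prior (uniform or Latin
    hypercube), integrates each from the common initial condition and labels
    the trajectory.  Returns ``(frequencies, table)`` where ``frequencies``
    maps each label to its fraction (summing to 1) and ``table`` has one row
    per draw with parameter columns, the final state and the label.
    Reproducible under a fixed seed.
    """
    from .inference import PriorSpec, sample_prior  # local import: no cycle at module load
    from .fixtures import lhs_sample

    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    model = get_model(model_name)
    criteria = criteria or CriteriaSpec()
    settings = settings or SolverSettings()
    prior = prior or PriorSpec.for_model(model_name)

    if sampler == "uniform":
        thetas = sample_prior(prior, n_samples, seed)
    elif sampler in ("lhs", "sobol"):
        thetas = lhs_sample(prior, n_samples, seed, method=sampler)
    else:
        raise ValueError(f"unknown sampler {sampler!r}")

    rows = []
    for theta in thetas:
        params = model.make_params(theta)
        traj = integrate(model_name, params, init_state, settings)
        label = classify_outcome(traj, criteria)
        row = dict(zip(model.free_param_names, theta))
        row.update({f"final_{s}": v
                    for s, v in zip(model.species, traj.final_state)})
        row["label"] = label.value
        rows.append(row)
    table = pd.DataFrame(rows)
    counts = table["label"].value_counts()
    freqs = {lab.value: float(counts.get(lab.value, 0)) / n_samples
             for lab in OutcomeLabel}
    return freqs, table
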