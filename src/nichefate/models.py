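"""Right-hand sides of the niche-competition models.

Three dynamical systems are defined here:

``lv2``
    The canonical two-species Lotka–Volterra competition system with a single
    shared linear feedback signal,

    .. math::

        \\dot X = X(\\alpha - \\gamma(X+Y)), \\qquad
        \\dot Y = Y(\\beta - \\gamma(X+Y)).

    Both species feel feedback proportional to the combined population; for
    :math:`\\alpha \\ne \\beta` the species with the larger growth rate always
    excludes the other (``d/dt log(X/Y) = α − β``).

``modelA``
    Five species — HSCs ``S``, progenitors ``A``, differentiated blood cells
    ``D``, leukaemia-driving cells ``L`` and differentiated leukaemia cells
    ``T`` — competing through a *hard* carrying capacity ``K``: every growth /
    self-renewal term carries the shared factor ``(1 − Z/K)`` with
    ``Z = S+A+D+L+T``, so the total niche occupancy can never exceed ``K``.

``modelB``
    The same five species with stem-cell fates resolved explicitly (symmetric
    renewal, asymmetric renewal, symmetric differentiation, loss) and *soft*,
    exponential niche feedback split across two sub-niches: the stem sub-niche
    (occupancy ``S+L``, feedback ``Φ1``) and the differentiated sub-niche
    (occupancy ``A+D+T``, feedbacks ``Φ2`` for the healthy lineage and ``Φ3``
    for the leukaemic one).  The progenitor compartment ``A`` amplifies at the
    bare net rate ``λ5 − μ6``, which makes the system unbounded exactly in the
    region ``λ5 > μ6``.

All rates are nonnegative and dimensioned per unit model time; in the default
configuration ``K = 1`` so populations are niche fractions.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, fields
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SPECIES",
    "StateVector",
    "ParamsLV2",
    "ParamsModelA",
    "ParamsModelB",
    "FeedbackTerms",
    "rhs_lv2",
    "rhs_model_a",
    "rhs_model_b",
    "feedback_terms",
    "ModelDef",
    "get_model",
    "MODEL_REGISTRY",
    "params_to_csv",
    "params_from_csv",
]

#: Species order used throughout the package.
SPECIES = ("S", "A", "D", "L", "T")


class DomainError(ValueError):
    """Raised when a state or parameter violates its domain (e.g. negative)."""


def _check_nonneg(values: Iterable[float], what: str) -> None:
    for v in values:
        if v < 0:
            raise DomainError(f"negative {what}: {v!r}")


@dataclass(frozen=True)
class StateVector:
    """Populations of the five species at one time point.

    Components are niche concentrations (fractions of the carrying capacity
    ``K`` in model A; absolute abundances in model B, whose capacity is soft).
    """

    S: float
    A: float
    D: float
    L: float
    T: float

    def __post_init__(self) -> None:
        arr = self.to_array()
        _check_nonneg(arr, "population")
        if not np.all(np.isfinite(arr)):
            raise DomainError("non-finite population")

    def to_array(self) -> np.ndarray:
        return np.array([self.S, self.A, self.D, self.L, self.T], dtype=float)

    @classmethod
    def from_array(cls, arr: Sequence[float]) -> "StateVector":
        arr = np.asarray(arr, dtype=float)
        if arr.shape != (5,):
            raise ValueError(f"expected 5 species, got shape {arr.shape}")
        return cls(*arr)

    @property
    def total(self) -> float:
        """Total niche occupancy Z = S + A + D + L + T."""
        return float(self.S + self.A + self.D + self.L + self.T)


def _warn_if_above_one(params: "_ParamsBase") -> None:
    # Priors for inference live on [0,1]; the model itself only needs
    # nonnegativity, so larger user-supplied rates get a warning, not an error.
    big = [f.name for f in fields(params)
           if f.name in params.free_names() and getattr(params, f.name) > 1.0]
    if big:
        warnings.warn(
            f"rates above 1 (outside the default [0,1] prior support): {big}",
            stacklevel=3,
        )


@dataclass(frozen=True)
class _ParamsBase:
    @classmethod
    def free_names(cls) -> tuple[str, ...]:
        raise NotImplementedError

    @classmethod
    def fixed_names(cls) -> tuple[str, ...]:
        return tuple(f.name for f in fields(cls) if f.name not in cls.free_names())

    def to_array(self) -> np.ndarray:
        """Free parameters as a vector, in declaration order."""
        return np.array([getattr(self, n) for n in self.free_names()], dtype=float)

    @classmethod
    def from_array(cls, theta: Sequence[float], **fixed):
        theta = np.asarray(theta, dtype=float)
        names = cls.free_names()
        if theta.shape != (len(names),):
            raise ValueError(
                f"expected {len(names)} free parameters, got shape {theta.shape}"
            )
        return cls(**dict(zip(names, theta)), **fixed)


@dataclass(frozen=True)
class ParamsLV2(_ParamsBase):
    """Growth rates and shared feedback strength of the two-species system."""

    alpha: float
    beta: float
    gamma: float

    @classmethod
    def free_names(cls) -> tuple[str, ...]:
        return ("alpha", "beta", "gamma")

    def __post_init__(self) -> None:
        _check_nonneg(self.to_array(), "rate")


@dataclass(frozen=True)
class ParamsModelA(_ParamsBase):
    """Model A rates: phenotype of each species plus the hard capacity K.

    a1/a2 — self-renewal of S/L; b1/b2 — transitions S→A, L→T; c1 —
    self-renewal of A; e1 — transition A→D; f/g — removal (migration into the
    bloodstream or death) of D/T.
    """

    a1: float
    b1: float
    c1: float
    e1: float
    f: float
    a2: float
    b2: float
    g: float
    K: float = 1.0

    @classmethod
    def free_names(cls) -> tuple[str, ...]:
        return ("a1", "b1", "c1", "e1", "f", "a2", "b2", "g")

    def __post_init__(self) -> None:
        _check_nonneg(self.to_array(), "rate")
        if self.K <= 0:
            raise ValueError(f"carrying capacity K must be positive, got {self.K}")
        _warn_if_above_one(self)


@dataclass(frozen=True)
class ParamsModelB(_ParamsBase):
    """Model B rates: explicit stem-cell fates with exponential niche feedback.

    Healthy lineage: lam1 (S→2S), lam2 (S→S+A), lam3 (S→2A), mu4 (loss of S),
    lam5 (amplification of A), mu6 (disappearance of A), chi1 (A→D), mu8 (loss
    of D).  Leukaemic lineage: kap1 (L→2L), kap2 (L→L+T), kap3 (L→2T), nu4
    (loss of L), nu8 (loss of T).  gam1..gam3 set the feedback strengths and
    are held fixed (0.01 in the headline configuration).
    """

    lam1: float
    lam2: float
    lam3: float
    mu4: float
    lam5: float
    mu6: float
    chi1: float
    mu8: float
    kap1: float
    kap2: float
    kap3: float
    nu4: float
    nu8: float
    gam1: float = 0.01
    gam2: float = 0.01
    gam3: float = 0.01

    @classmethod
    def free_names(cls) -> tuple[str, ...]:
        return ("lam1", "lam2", "lam3", "mu4", "lam5", "mu6", "chi1", "mu8",
                "kap1", "kap2", "kap3", "nu4", "nu8")

    def __post_init__(self) -> None:
        _check_nonneg(self.to_array(), "rate")
        _check_nonneg((self.gam1, self.gam2, self.gam3), "feedback constant")
        _warn_if_above_one(self)


@dataclass(frozen=True)
class FeedbackTerms:
    """The three exponential feedback multipliers of model B, each in (0, 1]."""

    phi1: float
    phi2: float
    phi3: float


def feedback_terms(state: StateVector | Sequence[float],
                   gammas: Sequence[float] = (0.01, 0.01, 0.01)) -> FeedbackTerms:
    """Evaluate model B's niche feedback at a state.

    ``phi1 = exp(−γ1(S+L))`` carries the stem sub-niche's effect on the
    self-renewal of S and L; ``phi2 = exp(−γ2(A+D+T))`` and
    ``phi3 = exp(−γ3(A+D+T))`` carry the differentiated sub-niche's effect on
    healthy and leukaemic differentiation respectively.  Each multiplier is 1
    at zero occupancy and decays monotonically as its sub-niche fills.
    """
    if not isinstance(state, StateVector):
        state = StateVector.from_array(state)
    g1, g2, g3 = gammas
    _check_nonneg((g1, g2, g3), "feedback constant")
    stem = state.S + state.L
    diff = state.A + state.D + state.T
    return FeedbackTerms(
        phi1=math.exp(-g1 * stem),
        phi2=math.exp(-g2 * diff),
        phi3=math.exp(-g3 * diff),
    )


def rhs_lv2(state2: Sequence[float], params: ParamsLV2) -> tuple[float, float]:
    """Time derivatives of the two-species competition system."""
    X, Y = state2
    _check_nonneg((X, Y), "population")
    crowd = params.gamma * (X + Y)
    return (X * (params.alpha - crowd), Y * (params.beta - crowd))


def rhs_model_a(state: StateVector | Sequence[float],
                params: ParamsModelA) -> np.ndarray:
    """Time derivatives of model A (hard carrying capacity).

    Growth terms share the factor ``(1 − Z/K)`` and vanish at full occupancy,
    so at ``Z = K`` only the loss/exit terms ``−f·D`` and ``−g·T`` remain and
    ``Z`` cannot cross ``K``.
    """
    if not isinstance(state, StateVector):
        state = StateVector.from_array(state)
    S, A, D, L, T = state.to_array()
    p = params
    room = 1.0 - state.total / p.K
    return np.array([
        p.a1 * S * room - p.b1 * S,
        p.b1 * S + p.c1 * A * room - p.e1 * A,
        p.e1 * A - p.f * D,
        p.a2 * L * room - p.b2 * L,
        p.b2 * L - p.g * T,
    ])


def rhs_model_b(state: StateVector | Sequence[float],
                params: ParamsModelB) -> np.ndarray:
    """Time derivatives of model B (explicit fates, soft exponential feedback).

    Symmetric renewal of S and L is damped by the stem-sub-niche feedback Φ1;
    the differentiation fates (S→S+A, S→2A, A→D and their leukaemic analogues)
    are damped by the differentiated-sub-niche feedbacks Φ2/Φ3.  The
    progenitor pool A self-amplifies at the bare net rate ``lam5 − mu6`` —
    crowding regulates differentiation, not amplification — which is what
    makes the region ``lam5 > mu6`` dynamically unbounded.  Removal rates
    (mu4, mu8, nu4, nu8) are bare.  With all γ = 0 every Φ is 1 and the system
    is a linear compartment model.
    """
    if not isinstance(state, StateVector):
        state = StateVector.from_array(state)
    S, A, D, L, T = state.to_array()
    p = params
    fb = feedback_terms(state, (p.gam1, p.gam2, p.gam3))
    f1, f2, f3 = fb.phi1, fb.phi2, fb.phi3
    return np.array([
        p.lam1 * S * f1 - p.lam3 * S * f2 - p.mu4 * S,
        (p.lam2 + 2.0 * p.lam3) * S * f2 + (p.lam5 - p.mu6) * A,
        p.chi1 * A * f2 - p.mu8 * D,
        p.kap1 * L * f1 - p.kap3 * L * f3 - p.nu4 * L,
        (p.kap2 + 2.0 * p.kap3) * L * f3 - p.nu8 * T,
    ])


# ---------------------------------------------------------------------------
# Model registry
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ModelDef:
    """A registered dynamical system: metadata plus a fast ODE closure factory."""

    name: str
    species: tuple[str, ...]
    params_cls: type
    rhs: Callable
    default_init: tuple[float, ...]
    #: parameters never varied during inference (name -> default value)
    fixed: dict = field(default_factory=dict)

    @property
    def n_species(self) -> int:
        return len(self.species)

    @property
    def free_param_names(self) -> tuple[str, ...]:
        return self.params_cls.free_names()

    def make_params(self, theta: Sequence[float], **fixed):
        merged = {**self.fixed, **fixed}
        return self.params_cls.from_array(theta, **merged)

    def make_ode(self, params) -> Callable:
        """Return ``f(t, y)`` unpacked to plain floats for the integrator.

        The closure clips tolerance-scale negative components to zero before
        evaluating the vector field (stiff decay near extinction overshoots).
        """
        return _ODE_FACTORIES[self.name](params)


def _ode_lv2(p: ParamsLV2):
    alpha, beta, gamma = p.alpha, p.beta, p.gamma

    def f(t, y):
        X = y[0] if y[0] > 0.0 else 0.0
        Y = y[1] if y[1] > 0.0 else 0.0
        crowd = gamma * (X + Y)
        return (X * (alpha - crowd), Y * (beta - crowd))

    return f


def _ode_model_a(p: ParamsModelA):
    a1, b1, c1, e1, f_, a2, b2, g, K = (p.a1, p.b1, p.c1, p.e1, p.f,
                                        p.a2, p.b2, p.g, p.K)

    def f(t, y):
        S = y[0] if y[0] > 0.0 else 0.0
        A = y[1] if y[1] > 0.0 else 0.0
        D = y[2] if y[2] > 0.0 else 0.0
        L = y[3] if y[3] > 0.0 else 0.0
        T = y[4] if y[4] > 0.0 else 0.0
        room = 1.0 - (S + A + D + L + T) / K
        return (
            a1 * S * room - b1 * S,
            b1 * S + c1 * A * room - e1 * A,
            e1 * A - f_ * D,
            a2 * L * room - b2 * L,
            b2 * L - g * T,
        )

    return f


def _ode_model_b(p: ParamsModelB):
    (l1, l2, l3, m4, l5, m6, x1, m8, k1, k2, k3, n4, n8) = p.to_array()
    g1, g2, g3 = p.gam1, p.gam2, p.gam3
    prodSA = l2 + 2.0 * l3
    prodLT = k2 + 2.0 * k3
    netA = l5 - m6

    def f(t, y):
        S = y[0] if y[0] > 0.0 else 0.0
        A = y[1] if y[1] > 0.0 else 0.0
        D = y[2] if y[2] > 0.0 else 0.0
        L = y[3] if y[3] > 0.0 else 0.0
        T = y[4] if y[4] > 0.0 else 0.0
        diff = A + D + T
        f1 = math.exp(-g1 * (S + L))
        f2 = math.exp(-g2 * diff)
        f3 = math.exp(-g3 * diff) if g3 != g2 else f2
        return (
            l1 * S * f1 - l3 * S * f2 - m4 * S,
            prodSA * S * f2 + netA * A,
            x1 * A * f2 - m8 * D,
            k1 * L * f1 - k3 * L * f3 - n4 * L,
            prodLT * L * f3 - n8 * T,
        )

    return f


def _ode_toy_decay(p):
    (r,) = p.to_array()

    def f(t, y):
        X = y[0] if y[0] > 0.0 else 0.0
        return (-r * X,)

    return f


@dataclass(frozen=True)
class ParamsToyDecay(_ParamsBase):
    """Single decay rate of the one-species toy model used to validate ABC."""

    r: float

    @classmethod
    def free_names(cls) -> tuple[str, ...]:
        return ("r",)

    def __post_init__(self) -> None:
        _check_nonneg((self.r,), "rate")


_ODE_FACTORIES = {
    "lv2": _ode_lv2,
    "modelA": _ode_model_a,
    "modelB": _ode_model_b,
    "toy_decay": _ode_toy_decay,
}

#: Small established leukaemic clone alongside a small HSC pool (fractions of K).
DEFAULT_INIT_5 = (0.01, 0.0, 0.0, 0.01, 0.0)

MODEL_REGISTRY: dict[str, ModelDef] = {
    "lv2": ModelDef("lv2", ("X", "Y"), ParamsLV2, rhs_lv2, (0.01, 0.01)),
    "modelA": ModelDef("modelA", SPECIES, ParamsModelA,
                       rhs_model_a, DEFAULT_INIT_5, fixed={"K": 1.0}),
    "modelB": ModelDef("modelB", SPECIES, ParamsModelB,
                       rhs_model_b, DEFAULT_INIT_5,
                       fixed={"gam1": 0.01, "gam2": 0.01, "gam3": 0.01}),
    "toy_decay": ModelDef("toy_decay", ("X",), ParamsToyDecay,
                          lambda s, p: np.array([-p.r * max(s[0], 0.0)]),
                          (1.0,)),
}


def get_model(name: str) -> ModelDef:
    try:
        return MODEL_REGISTRY[name]
    except KeyError:
        raise KeyError(
            f"unknown model {name!r}; registered: {sorted(MODEL_REGISTRY)}"
        ) from None


# ---------------------------------------------------------------------------
# Parameter table I/O
# ---------------------------------------------------------------------------

def params_to_csv(params_list, path) -> None:
    """Write parameter vectors to flat CSV, one row per set, named columns."""
    if not params_list:
        raise ValueError("empty parameter list")
    cls = type(params_list[0])
    names = list(cls.free_names()) + list(cls.fixed_names())
    rows = [{n: getattr(p, n) for n in names} for p in params_list]
    pd.DataFrame(rows, columns=names).to_csv(path, index=False)


def params_from_csv(path, model_name: str):
    """Read parameter vectors for a model back from CSV (round-trips to_csv)."""
    model = get_model(model_name)
    df = pd.read_csv(path)
    cls = model.params_cls
    out = []
    for _, row in df.iterrows():
        kwargs = {n: float(row[n]) for n in cls.free_names()}
        for n in cls.fixed_names():
            if n in df.columns:
                kwargs[n] = float(row[n])
        out.append(cls(**kwargs))
    return out
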