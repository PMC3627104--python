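"""Numerical integration to a finite-time pseudo-steady state.

Steady states are assessed numerically rather than analytically: trajectories
are integrated on a finite horizon and the tail of the trajectory is tested
for stationarity, which matches the biological reading that any non-extinct,
non-metastatic cancer state is at best a *pseudo*-steady state.  Runs that
diverge (possible in model B, whose niche capacity is soft) are cut off at a
blow-up cap and flagged.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .models import get_model

__all__ = ["SolverSettings", "Trajectory", "integrate",
           "steady_state_reached", "detect_unbounded", "trajectory_to_csv"]


@dataclass(frozen=True)
class SolverSettings:
    """Integration horizon, tolerances and steady-state test parameters.

    With all rates on [0, 1] characteristic times are O(1–100), so the
    default horizon of 1000 time units comfortably reaches the pseudo-steady
    state.  ``ss_window`` is the trailing fraction of the trajectory over
    which stationarity is tested; a component counts as stationary if its
    relative change over that window stays below ``ss_tol`` (absolute change
    for components below ``ext_floor``, where relative change is meaningless).
    """

    t_end: float = 1000.0
    n_points: int = 500
    rel_tol: float = 1e-8
    abs_tol: float = 1e-8
    blowup_cap: float = 1e6
    ss_window: float = 0.2
    ss_tol: float = 1e-4
    ext_floor: float = 1e-6
    method: str = "LSODA"

    def __post_init__(self) -> None:
        if self.t_end <= 0:
            raise ValueError("t_end must be positive")
        if not 0 < self.ss_window < 1:
            raise ValueError("ss_window must lie in (0, 1)")
        if self.n_points < 2:
            raise ValueError("n_points must be at least 2")


@dataclass(frozen=True)
class Trajectory:
    """A solved trajectory: time grid, state matrix and outcome flags."""

    model_name: str
    times: np.ndarray            # (n,) strictly increasing
    states: np.ndarray           # (n, n_species), clipped to >= 0
    reached_steady_state: bool
    unbounded: bool
    solver_ok: bool              # False on integrator failure (step collapse)
    final_state: np.ndarray      # tail-averaged state (last state if unbounded)

    @property
    def species(self) -> tuple[str, ...]:
        return get_model(self.model_name).species


def _tail(traj_states: np.ndarray, times: np.ndarray, window: float):
    n = len(times)
    k = max(2, int(np.ceil(window * n)))
    return traj_states[n - k:], times[n - k:]


def steady_state_reached(traj: Trajectory,
                         settings: SolverSettings) -> tuple[bool, np.ndarray]:
    """Test the trajectory tail for stationarity; return (flag, final state).

    Every component must change by less than ``ss_tol`` (relative, over the
    tail window) for the trajectory to count as a pseudo-steady state.
    Components whose tail maximum is below ``ext_floor`` are treated as
    extinct and compared absolutely.  The returned final state is the tail
    average, a better equilibrium estimate than the last sample.
    """
    if traj.states.size == 0:
        raise ValueError("empty trajectory")
    tail, _ = _tail(traj.states, traj.times, settings.ss_window)
    hi = tail.max(axis=0)
    lo = tail.min(axis=0)
    span = hi - lo
    ok = True
    for j in range(tail.shape[1]):
        if hi[j] < settings.ext_floor:
            if span[j] > settings.ss_tol * settings.ext_floor:
                ok = False
        elif span[j] / hi[j] > settings.ss_tol:
            ok = False
    return ok, tail.mean(axis=0)


def detect_unbounded(traj: Trajectory, settings: SolverSettings) -> bool:
    """True iff any component exceeded the blow-up cap (or the run was cut)."""
    if traj.states.size == 0:
        raise ValueError("empty trajectory")
    return bool(traj.unbounded or np.any(traj.states >= settings.blowup_cap))


def integrate(model_name: str,
              params,
              init_state: Sequence[float] | None = None,
              settings: SolverSettings | None = None) -> Trajectory:
    """Integrate a registered model and flag steady state / divergence.

    Uses a stiff-capable adaptive integrator (LSODA by default; dynamics near
    extinction are stiff).  Integration halts early, with ``unbounded=True``,
    as soon as any component crosses ``blowup_cap``.  Integrator failures are
    returned as flagged trajectories (``solver_ok=False``) rather than raised,
    so batch screening never aborts.  Deterministic for identical inputs.
    """
    settings = settings or SolverSettings()
    model = get_model(model_name)
    if init_state is None:
        init_state = model.default_init
    y0 = np.asarray(init_state, dtype=float)
    if y0.shape != (model.n_species,):
        raise ValueError(f"initial state must have {model.n_species} components")
    if np.any(y0 < 0):
        raise ValueError("negative initial state")

    f = model.make_ode(params)
    cap = settings.blowup_cap

    def blowup(t, y):
        return cap - max(y)

    blowup.terminal = True
    blowup.direction = -1

    t_eval = np.linspace(0.0, settings.t_end, settings.n_points)
    try:
        sol = solve_ivp(f, (0.0, settings.t_end), y0, method=settings.method,
                        rtol=settings.rel_tol, atol=settings.abs_tol,
                        t_eval=t_eval, events=blowup)
    except Exception:
        return Trajectory(model_name, np.array([0.0]), y0[None, :].clip(min=0),
                          reached_steady_state=False, unbounded=False,
                          solver_ok=False, final_state=y0.clip(min=0))

    hit_cap = bool(sol.t_events and len(sol.t_events[0]) > 0)
    if sol.status == -1 and not hit_cap:
        # step-size collapse: keep what was computed, flag the failure
        times = sol.t if sol.t.size else np.array([0.0])
        states = (sol.y.T if sol.t.size else y0[None, :]).clip(min=0.0)
        return Trajectory(model_name, times, states, False, False,
                          solver_ok=False, final_state=states[-1])

    times = sol.t
    states = sol.y.T.clip(min=0.0)
    if times.size < 2:  # terminated almost immediately by the blow-up event
        times = np.array([0.0, sol.t_events[0][0] if hit_cap else settings.t_end])
        states = np.vstack([y0, sol.y_events[0][0] if hit_cap else y0]).clip(min=0.0)

    traj = Trajectory(model_name, times, states,
                      reached_steady_state=False, unbounded=hit_cap,
                      solver_ok=True, final_state=states[-1])
    if hit_cap:
        return traj
    ss, tail_avg = steady_state_reached(traj, settings)
    # the tail average estimates the equilibrium; off-equilibrium it would
    # misstate the endpoint, so keep the last sample there
    return replace(traj, reached_steady_state=ss,
                   final_state=tail_avg if ss else states[-1])


def trajectory_to_csv(traj: Trajectory, path) -> None:
    """Export a trajectory as tidy CSV: one time column plus one per species."""
    df = pd.DataFrame(traj.states, columns=list(traj.species))
    df.insert(0, "time", traj.times)
    df.to_csv(path, index=False)


def settings_to_dict(settings: SolverSettings) -> dict:
    return asdict(settings)
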