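"""Initialisation and stiff integration with an absorbing extinction rule.

Integration runs an implicit stiff solver from t=0 to ``t_end``. Whenever a
population's biomass density falls to the extinction threshold the solver is
stopped by a terminal root-finding event, the species is set to exactly zero
(permanently), and integration restarts from the modified state. The final
``eval_window`` time units are sampled on a regular grid for the
ecosystem-function averages.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import solve_ivp

from .community import Community, ParameterSet
from .dynamics import State, rhs_flat
from .rates import NutrientParameters, RateCache

__all__ = [
    "SimulationSettings",
    "Trajectory",
    "IntegrationError",
    "initialize_state",
    "integrate",
    "is_discarded",
]


class IntegrationError(RuntimeError):
    """Solver failure; carries the last valid packed state if available."""

    def __init__(self, message: str, t: float | None = None,
                 y: np.ndarray | None = None):
        super().__init__(message)
        self.t = t
        self.y = y


@dataclass(frozen=True)
class SimulationSettings:
    t_end: float = 150_000.0
    eval_window: float = 10_000.0
    rel_tol: float = 1e-10
    abs_tol: float = 1e-10
    extinction_threshold: float = 1e-6
    #: spacing of the evaluation-window output grid (model time units)
    window_dt: float = 1.0
    method: str = "BDF"
    #: solver restarts at most every this many time units, so the wall-clock
    #: budget can be polled between chunks
    checkpoint_interval: float = 25_000.0
    #: per-run wall-clock budget in seconds (None = unlimited)
    max_wall_time: float | None = None

    def __post_init__(self) -> None:
        if not (self.t_end > self.eval_window > 0):
            raise ValueError("require t_end > eval_window > 0")
        if self.rel_tol <= 0 or self.abs_tol <= 0:
            raise ValueError("tolerances must be positive")


@dataclass
class Trajectory:
    """Sampled output grid (covering the evaluation window) plus event log."""

    times: np.ndarray                 # (n_t,), strictly increasing
    A: np.ndarray                     # (n_t, S_A)
    P: np.ndarray                     # (n_t, S_P)
    N: np.ndarray                     # (n_t, 2)
    extinction_events: list[tuple[int, float]] = field(default_factory=list)
    # species index convention for events: 0..S_A-1 animals, then plants

    @property
    def final_state(self) -> State:
        return State(A=self.A[-1], P=self.P[-1], N=self.N[-1])

    def window_slice(self, t_start: float) -> slice:
        i0 = int(np.searchsorted(self.times, t_start - 1e-9))
        return slice(i0, len(self.times))


def initialize_state(
    community: Community,
    nutrients: NutrientParameters,
    rng: np.random.Generator,
) -> State:
    """Random start: biomasses uniform on (0, 10], nutrients on [S_l/2, S_l]."""
    # 10 - U[0,10) has support (0, 10]
    A0 = 10.0 - rng.uniform(0.0, 10.0, size=community.S_A)
    P0 = 10.0 - rng.uniform(0.0, 10.0, size=community.S_P)
    N0 = rng.uniform(nutrients.S / 2.0, nutrients.S)
    return State(A=A0, P=P0, N=N0)


def integrate(
    community: Community,
    cache: RateCache,
    p: ParameterSet,
    nutrients: NutrientParameters,
    settings: SimulationSettings,
    state0: State,
) -> Trajectory:
    S_A, S_P = community.S_A, community.S_P
    n_bio = S_A + S_P
    thr = settings.extinction_threshold

    y = np.concatenate([state0.A, state0.P, state0.N])
    events: list[tuple[int, float]] = []
    # populations already at/below threshold never enter the dynamics
    dead0 = y[:n_bio] <= thr
    y[:n_bio][dead0] = 0.0

    t_grid = np.arange(
        settings.t_end - settings.eval_window,
        settings.t_end + settings.window_dt / 2,
        settings.window_dt,
    )
    samples_t: list[np.ndarray] = []
    samples_y: list[np.ndarray] = []

    args = (community, cache, p, nutrients)
    t0 = 0.0
    deadline = (time.monotonic() + settings.max_wall_time
                if settings.max_wall_time else None)
    n_chunks = int(np.ceil(settings.t_end / settings.checkpoint_interval))
    max_restarts = n_bio + n_chunks + 8
    for _ in range(max_restarts):
        if deadline is not None and time.monotonic() > deadline:
            raise IntegrationError("wall-clock budget exceeded", t=t0, y=y)
        t1 = min(t0 + settings.checkpoint_interval, settings.t_end)
        alive = np.flatnonzero(y[:n_bio] > 0.0)

        if alive.size:
            def ext_event(t, yy, *a, _alive=alive):
                return np.min(yy[_alive]) - thr
            ext_event.terminal = True
            ext_event.direction = -1.0
            ev = [ext_event]
        else:
            ev = None

        pts = t_grid[(t_grid > t0) & (t_grid <= t1)]
        # the chunk endpoint is needed to restart; keep it even when it is
        # not a window grid node (duplicates are removed at assembly)
        t_eval = pts if pts.size and pts[-1] == t1 else np.append(pts, t1)
        sol = solve_ivp(
            rhs_flat, (t0, t1), y,
            method=settings.method,
            rtol=settings.rel_tol, atol=settings.abs_tol,
            t_eval=t_eval,
            events=ev, args=args,
        )
        sol_t = np.asarray(sol.t, dtype=float)
        sol_y = np.asarray(sol.y, dtype=float) if sol_t.size else None
        if sol.status == -1:
            raise IntegrationError(sol.message, t=sol_t[-1] if sol_t.size else t0,
                                   y=sol_y[:, -1] if sol_t.size else y)
        if sol_t.size:
            keep = sol_t <= (sol.t_events[0][0] if sol.status == 1 else np.inf)
            samples_t.append(sol_t[keep])
            samples_y.append(sol_y[:, keep].T)

        if sol.status == 1:  # extinction event hit
            t0 = float(sol.t_events[0][0])
            y = sol.y_events[0][0].copy()
            if not np.all(np.isfinite(y)):
                raise IntegrationError("non-finite state at event", t=t0, y=y)
            bio = y[:n_bio]
            crossing = np.flatnonzero((bio > 0.0) & (bio <= thr * (1 + 1e-9)))
            if crossing.size == 0:
                # root landed marginally above threshold: extinguish the minimum
                crossing = np.array([alive[np.argmin(bio[alive])]])
            for idx in crossing:
                bio[idx] = 0.0
                events.append((int(idx), t0))
            continue
        # status 0: reached the chunk end
        y = sol_y[:, -1].copy() if sol_t.size else y
        if t1 >= settings.t_end:
            y_final = y
            break
        t0 = t1
    else:
        raise IntegrationError("restart budget exhausted", t=t0, y=y)

    times = np.concatenate(samples_t) if samples_t else np.array([settings.t_end])
    ys = np.vstack(samples_y) if samples_y else y_final[None, :]
    # drop duplicate grid points created by restarts on a grid node
    times, uniq = np.unique(times, return_index=True)
    ys = ys[uniq]
    ys = np.clip(ys, 0.0, None)
    # extinct species are exactly zero from their event time onward
    for idx, t_ev in events:
        ys[times >= t_ev, idx] = 0.0

    return Trajectory(
        times=times,
        A=ys[:, :S_A],
        P=ys[:, S_A:S_A + S_P],
        N=ys[:, S_A + S_P:],
        extinction_events=events,
    )


def is_discarded(trajectory: Trajectory, community: Community) -> bool:
    """True iff a plant that survived to t_end has no surviving linked consumer.

    Such consumer-free basal species grow without top-down control and
    signal a structurally different ecosystem; the replicate is flagged and
    excluded from the statistics stage (it is still recorded).
    """
    A_end = trajectory.A[-1]
    P_end = trajectory.P[-1]
    L = community.link_efficiency
    for i in np.flatnonzero(P_end > 0.0):
        consumers = np.flatnonzero(L[:, i] > 0.0)
        if not np.any(A_end[consumers] > 0.0):
            return True
    return False
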