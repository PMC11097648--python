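"""Five-state co-growth dynamics of the binary cross-feeding consortium.

State vector: (x1, x2, s_minus, s1_plus, s2_plus) — two population densities
(OD), shared glucose (g/L) and the two cross-fed amino acids, tryptophan and
tyrosine (mg/L).  Each species grows with double-Monod kinetics on its
required amino acid and on glucose,

    mu_i = mu_max_i * s_i+/(K_i+ + s_i+) * s-/(K_i- + s-),

consumes glucose and its own amino acid proportionally to growth, and
secretes the partner's amino acid proportionally to growth:

    dx_i/dt  = (mu_i - kd_i) x_i
    ds-/dt   = -Y_shared_1 mu_1 x_1 - Y_shared_2 mu_2 x_2 + q(t)
    ds_i+/dt = -Y_self_i mu_i x_i + Y_partner_j mu_j x_j

q(t) is a piecewise-constant glucose supply (zero for batch).  Integration
uses a stiff-capable solver restarted at each feed event so the right-hand
side is smooth on every segment; half-saturation constants of order 1e-4
make the system moderately stiff near substrate depletion.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np
from scipy.integrate import solve_ivp

from .params import FeedSchedule, KineticParams, StoichiometryParams

STATE_NAMES = ("x1", "x2", "s_minus", "s1_plus", "s2_plus")

#: CSV column names of the trajectory dialect, in state-vector order after time.
TRAJECTORY_COLUMNS = (
    "time_h",
    "x1_od",
    "x2_od",
    "glucose_g_per_L",
    "trp_mg_per_L",
    "tyr_mg_per_L",
)

DEFAULT_RTOL = 1e-8
DEFAULT_ATOL = 1e-9


class IntegrationError(RuntimeError):
    """Raised when the ODE solver fails; carries the last valid state."""

    def __init__(self, message: str, t: float, state: np.ndarray):
        super().__init__(f"{message} (t={t:.6g}, state={state})")
        self.t = t
        self.state = state


@dataclass(frozen=True)
class CommunityState:
    """Instantaneous densities and substrate concentrations."""

    x1: float
    x2: float
    s_minus: float
    s1_plus: float
    s2_plus: float

    def __post_init__(self) -> None:
        for name in STATE_NAMES:
            if getattr(self, name) < 0:
                raise ValueError(f"state component {name} must be >= 0")

    def as_array(self) -> np.ndarray:
        return np.array(
            [self.x1, self.x2, self.s_minus, self.s1_plus, self.s2_plus], dtype=float
        )

    @classmethod
    def from_array(cls, y: np.ndarray) -> "CommunityState":
        return cls(*(float(v) for v in y))

    def s_plus(self, species: int) -> float:
        return self.s1_plus if species == 1 else self.s2_plus

    def x(self, species: int) -> float:
        return self.x1 if species == 1 else self.x2


@dataclass
class Trajectory:
    """Simulated time course on a fixed grid.

    ``states`` is an (n_times, 5) array in STATE_NAMES order; ``metadata``
    records the parameter set and feed schedule that produced it.
    """

    times: np.ndarray
    states: np.ndarray
    metadata: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.states = np.asarray(self.states, dtype=float)
        if self.states.ndim != 2 or self.states.shape != (self.times.size, 5):
            raise ValueError("states must have shape (len(times), 5)")
        if self.times.size and self.times[0] < 0:
            raise ValueError("times must start at >= 0")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")

    def __len__(self) -> int:
        return self.times.size

    def state_at(self, k: int) -> CommunityState:
        return CommunityState.from_array(self.states[k])

    def column(self, name: str) -> np.ndarray:
        return self.states[:, STATE_NAMES.index(name)]

    def to_frame(self):
        import pandas as pd

        data = {"time_h": self.times}
        for col, name in zip(TRAJECTORY_COLUMNS[1:], STATE_NAMES):
            data[col] = self.states[:, STATE_NAMES.index(name)]
        return pd.DataFrame(data)


def monod_growth_rate(
    state: CommunityState, kin: KineticParams, species: int
) -> float:
    """Specific growth rate mu_i (1/h) of one species at the given state.

    Product of two saturating terms, one per substrate; 0 <= mu <= mu_max.
    A zero half-saturation constant with zero substrate is treated as a
    vanishing Monod factor (no growth without substrate).
    """
    if species not in (1, 2):
        raise ValueError(f"species must be 1 or 2, got {species}")
    sp = state.s_plus(species)
    sm = state.s_minus
    return _mu(sp, sm, kin.mu_max(species), kin.K_plus(species), kin.K_minus(species))


def _monod_factor(s: float, K: float) -> float:
    if s <= 0.0:
        return 0.0
    return s / (K + s)


def _mu(s_plus: float, s_minus: float, mu_max: float, K_plus: float,
        K_minus: float) -> float:
    return mu_max * _monod_factor(s_plus, K_plus) * _monod_factor(s_minus, K_minus)


def feed_rate(t: float, feed: FeedSchedule) -> float:
    """Glucose supply rate q (g/L/h) at time t under a feed schedule."""
    if t < 0:
        raise ValueError("t must be >= 0")
    return feed.rate_at(t)


def ode_rhs(
    t: float,
    state: CommunityState | np.ndarray,
    kin: KineticParams,
    stoich: StoichiometryParams,
    feed: FeedSchedule,
) -> np.ndarray:
    """Time derivative of the five-component state.

    Accepts either a CommunityState or a raw array (solver path).  Negative
    components from solver overshoot are clamped to zero before evaluating
    the kinetics, which keeps the Monod terms well defined.
    """
    if isinstance(state, CommunityState):
        y = state.as_array()
    else:
        y = np.asarray(state, dtype=float)
    y = np.maximum(y, 0.0)
    x1, x2, sm, s1p, s2p = y

    mu1 = _mu(s1p, sm, kin.mu_max_1, kin.K_plus_1, kin.K_minus_1)
    mu2 = _mu(s2p, sm, kin.mu_max_2, kin.K_plus_2, kin.K_minus_2)

    g1 = mu1 * x1  # gross growth fluxes (OD/h)
    g2 = mu2 * x2

    dx1 = g1 - kin.kd_1 * x1
    dx2 = g2 - kin.kd_2 * x2
    dsm = -stoich.Y_shared_1 * g1 - stoich.Y_shared_2 * g2 + feed.rate_at(t)
    ds1p = -stoich.Y_self_1 * g1 + stoich.Y_partner_2 * g2
    ds2p = -stoich.Y_self_2 * g2 + stoich.Y_partner_1 * g1
    return np.array([dx1, dx2, dsm, ds1p, ds2p])


def _segment_edges(feed: FeedSchedule, t0: float, t1: float) -> list[float]:
    edges = [t0]
    for start, _ in feed.events:
        if t0 < start < t1:
            edges.append(start)
    edges.append(t1)
    return edges


def simulate(
    kin: KineticParams,
    stoich: StoichiometryParams,
    feed: FeedSchedule,
    initial: CommunityState,
    times: np.ndarray,
    solver_opts: dict | None = None,
) -> Trajectory:
    """Integrate the consortium dynamics over a strictly increasing grid.

    The integration is split at feed-event times so each segment has a
    continuous right-hand side.  States are clamped at zero on output; a
    dip below 10x the absolute tolerance raises, as that indicates solver
    failure rather than roundoff.
    """
    times = np.asarray(times, dtype=float)
    if times.ndim != 1 or times.size < 2 or np.any(np.diff(times) <= 0):
        raise ValueError("times must be a strictly increasing 1-D grid")

    opts = {"method": "LSODA", "rtol": DEFAULT_RTOL, "atol": DEFAULT_ATOL}
    if solver_opts:
        opts.update(solver_opts)
    method = opts.pop("method")
    rtol = opts.pop("rtol")
    atol = opts.pop("atol")

    def rhs(t, y):
        return ode_rhs(t, y, kin, stoich, feed)

    t0, t1 = float(times[0]), float(times[-1])
    edges = _segment_edges(feed, t0, t1)
    y = initial.as_array()
    out = np.empty((times.size, 5))
    filled = 0
    if times[0] == t0:
        out[0] = y
        filled = 1

    for a, b in zip(edges, edges[1:]):
        # grid points strictly inside (a, b]; always evaluate b to restart
        mask = (times > a) & (times <= b)
        t_grid = times[mask]
        t_eval = t_grid if (t_grid.size and t_grid[-1] == b) else np.append(t_grid, b)
        sol = solve_ivp(
            rhs, (a, b), y, method=method, rtol=rtol, atol=atol,
            t_eval=t_eval, **opts,
        )
        if not sol.success:
            raise IntegrationError(sol.message, float(sol.t[-1]), sol.y[:, -1])
        out[filled : filled + t_grid.size] = sol.y[:, : t_grid.size].T
        filled += t_grid.size
        y = sol.y[:, -1]

    if filled != times.size:
        raise IntegrationError("grid not fully covered", t1, y)

    undershoot = out.min()
    if undershoot < -10 * atol:
        raise IntegrationError(
            f"state dipped below -10*atol ({undershoot:.3e})", t1, out.min(axis=0)
        )
    out = np.maximum(out, 0.0)

    meta = {
        "kinetics": kin,
        "stoichiometry": stoich,
        "feed": feed,
        "solver": {"method": method, "rtol": rtol, "atol": atol},
    }
    return Trajectory(times=times, states=out, metadata=meta)


def default_grid(horizon: float = 30.0, dt: float = 0.05) -> np.ndarray:
    """Default output grid: 30 h horizon sampled every 0.05 h."""
    n = int(round(horizon / dt))
    return np.linspace(0.0, horizon, n + 1)
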