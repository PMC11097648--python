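"""Parameter identification from multi-condition growth datasets.

Kinetic and stoichiometric parameters are estimated by weighted least
squares: each candidate parameter set is simulated under every dataset's
culture scenario and compared against the observed per-species OD, total
OD and glucose series.  Optimization is a multistart, bound-constrained
trust-region least-squares run (finite-difference Jacobian) with
Latin-hypercube start points; half-saturation constants are searched in
log10 space because they span orders of magnitude below the substrate
scales, while rates and yields stay linear.

A qualitative auxotrophy constraint filters candidates: each strain alone
must show no net growth without its amino acid, while the pair must be
able to bootstrap co-growth from trace amino-acid carryover when glucose
is present.  The constraint is applied as a feasibility filter on
optimizer results rather than as a smooth penalty.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace, fields as dc_fields

import numpy as np
from scipy.optimize import least_squares
from scipy.stats import qmc

from .model import CommunityState, simulate, IntegrationError
from .params import FeedSchedule, KineticParams, StoichiometryParams, PARAM_NAMES
from .synthetic import ObservationSet, Scenario

log = logging.getLogger(__name__)

#: parameters searched in log10 space (they span 1e-4 .. 1e-2)
LOG_SCALE_PARAMS = frozenset({"K_plus_1", "K_plus_2", "K_minus_1", "K_minus_2"})

#: residual magnitude substituted when a candidate simulation fails
PENALTY_RESIDUAL = 1e6

#: trace amino-acid carryover (mg/L) used to seed the co-growth feasibility
#: check; with exactly zero amino acids the deterministic model can never
#: start growing, so a small inoculum carryover stands in for the real
#: culture's residual amino acids
COGROWTH_TRACE_MG = 1e-3

_KIN_NAMES = {f.name for f in dc_fields(KineticParams)}
_ST_NAMES = {f.name for f in dc_fields(StoichiometryParams)}

#: observables compared against the data, with the replicate column and the
#: simulated quantity they map to
OBSERVABLES = ("x1_od", "x2_od", "od_total", "glucose_g_per_L")


@dataclass(frozen=True)
class FitConfig:
    """Free parameters, bounds, datasets and optimizer settings."""

    free_parameters: tuple[str, ...]
    bounds: dict[str, tuple[float, float]]
    datasets: tuple[tuple[ObservationSet, Scenario], ...]
    weights: dict[str, float] | None = None
    base_kinetics: KineticParams = field(default_factory=KineticParams)
    base_stoichiometry: StoichiometryParams = field(default_factory=StoichiometryParams)
    multistart: int = 8
    max_iterations: int = 200
    tolerance: float = 1e-8
    seed: int = 0
    solver_opts: dict | None = None

    def __post_init__(self) -> None:
        for name in self.free_parameters:
            if name not in PARAM_NAMES:
                raise ValueError(f"unknown parameter {name!r}")
            lo, hi = self.bounds[name]
            if lo > hi:
                raise ValueError(f"bounds for {name} have lower > upper")
            if lo < 0:
                raise ValueError(f"parameters are non-negative; bad bound for {name}")


@dataclass
class FitResult:
    """Estimates with diagnostics from the best feasible start."""

    estimates: dict[str, float]
    sse: float
    per_dataset_sse: list[float]
    converged: bool
    constraint: "ConstraintReport"
    n_starts: int
    n_feasible: int
    flat_parameters: tuple[str, ...] = ()
    near_bound_parameters: tuple[str, ...] = ()


@dataclass(frozen=True)
class ConstraintReport:
    satisfied: bool
    axenic_margins: tuple[float, float]  # initial - final OD per strain (>=0 ok)
    cogrowth_margin: float  # final - initial total OD (>0 ok)


def _apply(
    names: tuple[str, ...],
    values: np.ndarray,
    kin: KineticParams,
    st: StoichiometryParams,
) -> tuple[KineticParams, StoichiometryParams]:
    kin_updates = {n: float(v) for n, v in zip(names, values) if n in _KIN_NAMES}
    st_updates = {n: float(v) for n, v in zip(names, values) if n in _ST_NAMES}
    if kin_updates:
        kin = replace(kin, **kin_updates)
    if st_updates:
        st = replace(st, **st_updates)
    return kin, st


def _default_weights(datasets) -> dict[str, float]:
    """Inverse-squared observable scale so OD and glucose compete fairly."""
    weights = {}
    for obs_name in OBSERVABLES:
        vals = []
        for obs_set, _ in datasets:
            for rep in obs_set.replicates:
                if obs_name in rep.columns:
                    vals.append(rep[obs_name].to_numpy())
        scale = float(np.mean(np.concatenate(vals))) if vals else 1.0
        weights[obs_name] = 1.0 / max(scale, 1e-6) ** 2
    return weights


def _residual_vector(
    kin: KineticParams,
    st: StoichiometryParams,
    datasets,
    weights: dict[str, float],
    solver_opts: dict | None,
) -> tuple[np.ndarray, list[float]]:
    chunks: list[np.ndarray] = []
    per_dataset: list[float] = []
    for obs_set, scenario in datasets:
        t_obs = obs_set.replicates[0]["time_h"].to_numpy()
        grid = np.unique(np.concatenate([[0.0], t_obs]))
        if grid.size < 2:
            raise ValueError("each dataset needs >= 2 time points")
        try:
            traj = simulate(kin, st, scenario.feed, scenario.initial, grid,
                            solver_opts)
        except (IntegrationError, ValueError) as exc:
            log.warning("simulation failed during fit (%s); penalizing", exc)
            n = sum(len(rep) * len(OBSERVABLES) for rep in obs_set.replicates)
            chunk = np.full(n, PENALTY_RESIDUAL)
            chunks.append(chunk)
            per_dataset.append(float(chunk @ chunk))
            continue
        idx = np.searchsorted(grid, t_obs)
        sim = {
            "x1_od": traj.column("x1")[idx],
            "x2_od": traj.column("x2")[idx],
            "od_total": (traj.column("x1") + traj.column("x2"))[idx],
            "glucose_g_per_L": traj.column("s_minus")[idx],
        }
        ds_chunks = []
        for rep in obs_set.replicates:
            for obs_name in OBSERVABLES:
                if obs_name not in rep.columns:
                    continue
                w = np.sqrt(weights[obs_name])
                ds_chunks.append(w * (sim[obs_name] - rep[obs_name].to_numpy()))
        chunk = np.concatenate(ds_chunks)
        chunks.append(chunk)
        per_dataset.append(float(chunk @ chunk))
    return np.concatenate(chunks), per_dataset


def sse_objective(
    params: dict[str, float],
    datasets,
    weights: dict[str, float] | None = None,
    base_kinetics: KineticParams | None = None,
    base_stoichiometry: StoichiometryParams | None = None,
    solver_opts: dict | None = None,
) -> float:
    """Weighted sum of squared simulation-vs-observation errors."""
    kin = base_kinetics or KineticParams()
    st = base_stoichiometry or StoichiometryParams()
    names = tuple(params)
    kin, st = _apply(names, np.array([params[n] for n in names]), kin, st)
    weights = weights or _default_weights(datasets)
    res, _ = _residual_vector(kin, st, datasets, weights, solver_opts)
    return float(res @ res)


def auxotrophy_constraint(
    kin: KineticParams,
    stoich: StoichiometryParams,
    glucose: float = 4.5,
    horizon: float = 30.0,
    solver_opts: dict | None = None,
) -> ConstraintReport:
    """Check the auxotrophy/cross-feeding phenotype of a parameter set.

    (a) each strain alone, amino acid absent: no net growth over the
        horizon; (b) both strains together with glucose and only trace
        amino-acid carryover: positive net total growth.

    Half-saturation constants are floored at 1e-6 inside these simulations:
    a zero K makes the kinetics discontinuous at zero substrate (the solver
    cannot cross the chattering boundary), while the floor changes the
    growth prediction negligibly for any realistic parameter set.
    """
    opts = solver_opts or {"rtol": 1e-7, "atol": 1e-10}
    k_floor = 1e-6
    kin = replace(
        kin,
        K_plus_1=max(kin.K_plus_1, k_floor),
        K_plus_2=max(kin.K_plus_2, k_floor),
        K_minus_1=max(kin.K_minus_1, k_floor),
        K_minus_2=max(kin.K_minus_2, k_floor),
    )
    grid = np.array([0.0, horizon])
    x0 = 0.02
    margins = []
    for sp in (1, 2):
        init = CommunityState(
            x0 if sp == 1 else 0.0, x0 if sp == 2 else 0.0, glucose, 0.0, 0.0
        )
        traj = simulate(kin, stoich, FeedSchedule(), init, grid, opts)
        xi = traj.column("x1" if sp == 1 else "x2")
        margins.append(float(xi[0] - xi[-1]))  # >= 0 means no net growth
    init = CommunityState(x0, x0, glucose, COGROWTH_TRACE_MG, COGROWTH_TRACE_MG)
    traj = simulate(kin, stoich, FeedSchedule(), init, grid, opts)
    total = traj.column("x1") + traj.column("x2")
    # growth the trace seed alone could support, without any cross-feeding
    trace_only = COGROWTH_TRACE_MG * (
        1.0 / max(stoich.Y_self_1, 1e-9) + 1.0 / max(stoich.Y_self_2, 1e-9)
    )
    cogrowth = float(total[-1] - total[0]) - 2.0 * trace_only
    satisfied = margins[0] >= -1e-9 and margins[1] >= -1e-9 and cogrowth > 0
    return ConstraintReport(satisfied, (margins[0], margins[1]), cogrowth)


def _to_internal(names, values):
    return np.array(
        [np.log10(max(v, 1e-300)) if n in LOG_SCALE_PARAMS else v
         for n, v in zip(names, values)]
    )


def _from_internal(names, z):
    return np.array(
        [10.0 ** v if n in LOG_SCALE_PARAMS else v for n, v in zip(names, z)]
    )


def fit_parameters(config: FitConfig) -> FitResult:
    """Multistart bound-constrained least squares with feasibility filtering."""
    if not config.datasets:
        raise ValueError("at least one dataset is required")
    names = config.free_parameters
    weights = config.weights or _default_weights(config.datasets)
    kin0, st0 = config.base_kinetics, config.base_stoichiometry

    if not names:
        res, per_ds = _residual_vector(kin0, st0, config.datasets, weights,
                                       config.solver_opts)
        report = auxotrophy_constraint(kin0, st0)
        return FitResult({}, float(res @ res), per_ds, True, report, 0, 1)

    lo = np.array([config.bounds[n][0] for n in names])
    hi = np.array([config.bounds[n][1] for n in names])
    z_lo = _to_internal(names, np.maximum(lo, 1e-12))
    z_hi = _to_internal(names, hi)

    def residuals(z):
        values = _from_internal(names, z)
        kin, st = _apply(names, values, kin0, st0)
        res, _ = _residual_vector(kin, st, config.datasets, weights,
                                  config.solver_opts)
        return res

    sampler = qmc.LatinHypercube(d=len(names), seed=config.seed)
    starts = qmc.scale(sampler.random(config.multistart), z_lo, z_hi)

    candidates = []
    for k, z0 in enumerate(starts):
        try:
            sol = least_squares(
                residuals,
                z0,
                bounds=(z_lo, z_hi),
                method="trf",
                xtol=config.tolerance,
                ftol=config.tolerance,
                max_nfev=config.max_iterations * max(len(names), 1),
            )
        except Exception as exc:  # keep the multistart alive
            log.warning("start %d failed: %s", k, exc)
            continue
        values = _from_internal(names, sol.x)
        kin, st = _apply(names, values, kin0, st0)
        report = auxotrophy_constraint(kin, st)
        candidates.append((float(sol.cost * 2), values, sol.status > 0, report))

    if not candidates:
        raise RuntimeError("all optimization starts failed")

    feasible = [c for c in candidates if c[3].satisfied]
    pool = feasible if feasible else candidates
    if not feasible:
        log.warning("no start satisfied the auxotrophy constraint; "
                    "returning best infeasible candidate")
    sse, values, ok, report = min(pool, key=lambda c: c[0])

    kin, st = _apply(names, values, kin0, st0)
    res, per_ds = _residual_vector(kin, st, config.datasets, weights,
                                   config.solver_opts)

    near_bound = tuple(
        n for n, v, a, b in zip(names, values, lo, hi)
        if (b > a) and (v - a <= 0.01 * (b - a) or b - v <= 0.01 * (b - a))
    )
    flat = _flat_directions(names, values, kin0, st0, config, weights, sse)

    return FitResult(
        estimates={n: float(v) for n, v in zip(names, values)},
        sse=sse,
        per_dataset_sse=per_ds,
        converged=ok,
        constraint=report,
        n_starts=len(candidates),
        n_feasible=len(feasible),
        flat_parameters=flat,
        near_bound_parameters=near_bound,
    )


def _flat_directions(names, values, kin0, st0, config, weights, sse_best,
                     rel_perturb: float = 0.2, rel_tol: float = 1e-3):
    """Flag parameters whose +/-20% perturbation barely moves the objective."""
    flat = []
    floor = max(sse_best, 1e-12)
    for k, n in enumerate(names):
        changes = []
        for sgn in (-1.0, 1.0):
            v = values.copy()
            v[k] = np.clip(values[k] * (1 + sgn * rel_perturb),
                           config.bounds[n][0], config.bounds[n][1])
            kin, st = _apply(names, v, kin0, st0)
            res, _ = _residual_vector(kin, st, config.datasets, weights,
                                      config.solver_opts)
            changes.append(abs(float(res @ res) - sse_best))
        if max(changes) < rel_tol * floor:
            flat.append(n)
    return tuple(flat)
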