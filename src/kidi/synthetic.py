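"""Scenario library and synthetic observation generator.

The library encodes the culture designs used to study the consortium:
batch co-cultures at three substrate regimes, semi-batch co-cultures
perturbed by slow-release glucose beads, and axenic cultures of each
auxotroph with its amino acid supplemented.  The observation generator
simulates a scenario and degrades the truth the way plate-reader /
qPCR / HPLC workflows do: multiplicative log-normal noise on total OD and
on glucose, compositional (Beta) noise on the species-1 fraction, and
per-species OD reconstructed as fraction x total.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .model import CommunityState, Trajectory, simulate, default_grid
from .params import (
    FEED_RATE_FIVE_BEADS,
    FEED_RATE_THREE_BEADS,
    FeedSchedule,
    KineticParams,
    StoichiometryParams,
)

#: default inoculum: total 0.04 OD split equally between the two strains
DEFAULT_X0_EACH = 0.02

#: amino-acid supplementation for axenic growth (mg/L); the axenic
#: experiments spanned 10-40 mg/L, we use the midpoint of that range
AXENIC_AMINO_MG_PER_L = 20.0

#: bead addition time (h) in the semi-batch co-culture designs
BEAD_TIME_H = 7.5


@dataclass(frozen=True)
class Scenario:
    """A culture condition: initial state, feed schedule, and sampling plan."""

    label: str
    initial: CommunityState
    feed: FeedSchedule = FeedSchedule()
    horizon: float = 30.0
    sampling_times: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        if not self.sampling_times:
            # hourly sampling by default
            times = tuple(float(t) for t in np.arange(0.0, self.horizon + 1e-9, 1.0))
            object.__setattr__(self, "sampling_times", times)
        ts = self.sampling_times
        if min(ts) < 0 or max(ts) > self.horizon:
            raise ValueError("sampling times must lie within [0, horizon]")

    def grid(self, dt: float = 0.05) -> np.ndarray:
        return default_grid(self.horizon, dt)


def _co(s_minus, s1, s2):
    return CommunityState(DEFAULT_X0_EACH, DEFAULT_X0_EACH, s_minus, s1, s2)


def _three_bead_feed() -> FeedSchedule:
    return FeedSchedule(((BEAD_TIME_H, FEED_RATE_THREE_BEADS),))


def scenario_library() -> dict[str, Scenario]:
    """All built-in culture scenarios keyed by label.

    fig3A/B/C   batch co-cultures at (2, 1, 1), (0.5, 1, 1), (0.5, 4, 4)
                [glucose g/L, trp mg/L, tyr mg/L]
    fig4A/B/C   the same three conditions with three glucose beads
                (q = 5.580e-2 g/L/h) added at 7.5 h
    fig4B_5fb   five-bead variant of fig4B (q = 9.300e-2 g/L/h)
    axenic1/2   single-strain batch at 4.5 g/L glucose with the strain's
                amino acid supplemented
    coculture_batch   binary batch at 4.5 g/L glucose, 1 mg/L each amino acid
    """
    lib = {
        "fig3A": Scenario("fig3A", _co(2.0, 1.0, 1.0)),
        "fig3B": Scenario("fig3B", _co(0.5, 1.0, 1.0)),
        "fig3C": Scenario("fig3C", _co(0.5, 4.0, 4.0)),
        "fig4A": Scenario("fig4A", _co(2.0, 1.0, 1.0), _three_bead_feed()),
        "fig4B": Scenario("fig4B", _co(0.5, 1.0, 1.0), _three_bead_feed()),
        "fig4C": Scenario("fig4C", _co(0.5, 4.0, 4.0), _three_bead_feed()),
        "fig4B_5fb": Scenario(
            "fig4B_5fb",
            _co(0.5, 1.0, 1.0),
            FeedSchedule(((BEAD_TIME_H, FEED_RATE_FIVE_BEADS),)),
        ),
        "axenic1": Scenario(
            "axenic1",
            CommunityState(2 * DEFAULT_X0_EACH, 0.0, 4.5, AXENIC_AMINO_MG_PER_L, 0.0),
        ),
        "axenic2": Scenario(
            "axenic2",
            CommunityState(0.0, 2 * DEFAULT_X0_EACH, 4.5, 0.0, AXENIC_AMINO_MG_PER_L),
        ),
        "coculture_batch": Scenario("coculture_batch", _co(4.5, 1.0, 1.0)),
    }
    return lib


def get_scenario(label: str) -> Scenario:
    lib = scenario_library()
    if label not in lib:
        raise KeyError(
            f"unknown scenario {label!r}; available: {sorted(lib)}"
        )
    return lib[label]


@dataclass(frozen=True)
class NoiseModel:
    """Measurement-noise description for synthetic observations.

    od_cv / glucose_cv   multiplicative coefficient of variation
    fraction_kappa       Beta concentration for qPCR-style fraction noise
                         (math.inf turns fraction noise off)
    detection_limit_mg   amino-acid floor; values below are censored
    """

    od_cv: float = 0.02
    glucose_cv: float = 0.02
    fraction_kappa: float = 500.0
    replicates: int = 3
    seed: int = 0
    amino_acids: bool = False
    detection_limit_mg: float = 0.05

    def __post_init__(self) -> None:
        if self.od_cv < 0 or self.glucose_cv < 0:
            raise ValueError("CVs must be >= 0")
        if not self.fraction_kappa > 0:
            raise ValueError("fraction_kappa must be > 0")
        if self.replicates < 1:
            raise ValueError("replicate count must be >= 1")


@dataclass
class ObservationSet:
    """Noisy replicate tables plus the noise-free truth trajectory.

    Each replicate is a DataFrame with columns time_h, od_total,
    fraction_1, x1_od, x2_od, glucose_g_per_L and, when amino-acid
    observation is enabled, trp_mg_per_L / tyr_mg_per_L with matching
    *_censored flags.
    """

    label: str
    replicates: list[pd.DataFrame]
    truth: Trajectory | None = None
    noise: NoiseModel = field(default_factory=NoiseModel)


def _lognormal_factor(rng: np.random.Generator, cv: float, size) -> np.ndarray:
    """Mean-one multiplicative noise with the requested CV."""
    if cv == 0:
        return np.ones(size)
    sigma = np.sqrt(np.log1p(cv**2))
    return rng.lognormal(mean=-0.5 * sigma**2, sigma=sigma, size=size)


def _beta_fraction(rng: np.random.Generator, f: np.ndarray, kappa: float) -> np.ndarray:
    """Beta(f*kappa, (1-f)*kappa) perturbation; exact at f in {0, 1}."""
    if not np.isfinite(kappa):
        return f.copy()
    out = np.empty_like(f)
    for k, fk in enumerate(f):
        if fk <= 0.0 or fk >= 1.0:
            out[k] = np.clip(fk, 0.0, 1.0)
        else:
            out[k] = rng.beta(fk * kappa, (1.0 - fk) * kappa)
    return out


def generate_observations(
    scenario: Scenario,
    kin: KineticParams | None = None,
    stoich: StoichiometryParams | None = None,
    noise: NoiseModel | None = None,
    solver_opts: dict | None = None,
) -> ObservationSet:
    """Simulate a scenario and emit seeded noisy replicate tables."""
    kin = kin or KineticParams()
    stoich = stoich or StoichiometryParams()
    noise = noise or NoiseModel()

    grid = np.unique(
        np.concatenate([scenario.grid(), np.asarray(scenario.sampling_times)])
    )
    truth = simulate(kin, stoich, scenario.feed, scenario.initial, grid, solver_opts)

    idx = np.searchsorted(grid, np.asarray(scenario.sampling_times))
    t = grid[idx]
    x1 = truth.column("x1")[idx]
    x2 = truth.column("x2")[idx]
    glc = truth.column("s_minus")[idx]
    trp = truth.column("s1_plus")[idx]
    tyr = truth.column("s2_plus")[idx]
    total = x1 + x2
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(total > 0, x1 / np.where(total > 0, total, 1.0), 0.0)

    rng = np.random.default_rng(noise.seed)
    reps: list[pd.DataFrame] = []
    for _ in range(noise.replicates):
        od_obs = total * _lognormal_factor(rng, noise.od_cv, total.shape)
        glc_obs = glc * _lognormal_factor(rng, noise.glucose_cv, glc.shape)
        frac_obs = _beta_fraction(rng, frac, noise.fraction_kappa)
        df = pd.DataFrame(
            {
                "time_h": t,
                "od_total": od_obs,
                "fraction_1": frac_obs,
                "x1_od": frac_obs * od_obs,
                "x2_od": (1.0 - frac_obs) * od_obs,
                "glucose_g_per_L": glc_obs,
            }
        )
        if noise.amino_acids:
            for name, series in (("trp_mg_per_L", trp), ("tyr_mg_per_L", tyr)):
                obs = series * _lognormal_factor(rng, noise.glucose_cv, series.shape)
                censored = obs < noise.detection_limit_mg
                df[name] = np.where(censored, noise.detection_limit_mg, obs)
                df[name + "_censored"] = censored
        reps.append(df)
    return ObservationSet(scenario.label, reps, truth, noise)


def with_seed(noise: NoiseModel, seed: int) -> NoiseModel:
    return replace(noise, seed=seed)
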