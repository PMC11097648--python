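"""Time-varying gLV interaction coefficients from kinetics and stoichiometry.

In a generalized Lotka-Volterra description the specific growth rate of
species i is linear in the partner density x_j with coefficient a_ij.  When
the growth rate is instead a known kinetic function of environmental
concentrations, mu_i(s_i+, s-), the chain rule turns a_ij into an explicit
function of those concentrations:

    a_ij = d mu_i / d x_j
         = (d mu_i/d s_i+) (d s_i+/d x_j) + (d mu_i/d s-) (d s-/d x_j)
         = a_ij^+ + a_ij^-

The first term is the cross-feeding (promotive) channel: partner growth
releases the amino acid species i needs, d s_i+/d x_j = +Y_partner_j.  The
second is the competition (inhibitive) channel: partner growth consumes the
shared glucose, d s-/d x_j = -Y_shared_j.  For double-Monod kinetics both
terms have closed forms:

    a_ij^+ = mu_max_i * K_i+/(K_i+ + s_i+)^2 * s-/(K_i- + s-) * Y_partner_j
    a_ij^- = -mu_max_i * s_i+/(K_i+ + s_i+) * K_i-/(K_i- + s-)^2 * Y_shared_j

The normalized interaction parameter

    gamma_ij = (a_ij^+ + a_ij^-) / (a_ij^+ - a_ij^-)   in [-1, 1]

measures the relative dominance of promotion (+1) versus inhibition (-1),
independently of the magnitude of the net coefficient.  The intraspecific
coefficient a_ii follows the same chain rule through species i's own
consumption of both substrates and is always <= 0.

Coefficients are derived from the kinetic growth rate mu_i only; the death
rate affects the population dynamics but not the interaction definition.

Beyond the double-Monod fast path, ``coefficients_from_growth_model``
accepts any growth-rate function of (s_plus, s_minus), differentiating it
analytically when partial derivatives are supplied and by central
differences otherwise, so arbitrary kinetic forms can be plugged in.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np

from .model import CommunityState, Trajectory, monod_growth_rate
from .params import KineticParams, StoichiometryParams

_PAIRS = ((1, 2), (2, 1))

#: relative step for internal finite differences (fraction of K + s scale)
DEFAULT_FD_STEP = 1e-6


def _check_pair(pair: tuple[int, int]) -> tuple[int, int]:
    if tuple(pair) not in _PAIRS:
        raise ValueError(f"pair must be (1,2) or (2,1), got {pair}")
    return tuple(pair)


@dataclass(frozen=True)
class InteractionCoefficients:
    """All interaction coefficients of the binary consortium at one state.

    Units: a-coefficients in 1/(h*OD); gamma dimensionless.  ``defined_ij``
    is False where gamma's denominator vanishes (both channels exactly
    zero); the gamma value is then reported as 0 and should not be
    interpreted.
    """

    a_plus_12: float
    a_minus_12: float
    a_plus_21: float
    a_minus_21: float
    a_11: float
    a_22: float
    gamma_12: float = 0.0
    gamma_21: float = 0.0
    defined_12: bool = True
    defined_21: bool = True

    @property
    def a_12(self) -> float:
        return self.a_plus_12 + self.a_minus_12

    @property
    def a_21(self) -> float:
        return self.a_plus_21 + self.a_minus_21


@dataclass
class InteractionProfile:
    """Interaction coefficients evaluated along a trajectory's time grid."""

    times: np.ndarray
    coefficients: list[InteractionCoefficients]

    def __post_init__(self) -> None:
        if len(self.coefficients) != np.asarray(self.times).size:
            raise ValueError("one coefficient set per time point required")

    def __len__(self) -> int:
        return len(self.coefficients)

    def series(self, attr: str) -> np.ndarray:
        return np.array([getattr(c, attr) for c in self.coefficients], dtype=float)

    def to_frame(self):
        import pandas as pd

        cols = {
            "time_h": np.asarray(self.times, dtype=float),
            "a12_plus": self.series("a_plus_12"),
            "a12_minus": self.series("a_minus_12"),
            "a12": self.series("a_12"),
            "gamma12": self.series("gamma_12"),
            "a21_plus": self.series("a_plus_21"),
            "a21_minus": self.series("a_minus_21"),
            "a21": self.series("a_21"),
            "gamma21": self.series("gamma_21"),
            "a11": self.series("a_11"),
            "a22": self.series("a_22"),
            "gamma12_defined": self.series("defined_12").astype(bool),
            "gamma21_defined": self.series("defined_21").astype(bool),
        }
        return pd.DataFrame(cols)


def positive_coefficient(
    state: CommunityState,
    kin: KineticParams,
    stoich: StoichiometryParams,
    pair: tuple[int, int],
) -> float:
    """Cross-feeding channel a_ij^+ >= 0 (closed form, double Monod)."""
    i, j = _check_pair(pair)
    sp = state.s_plus(i)
    sm = state.s_minus
    Kp = kin.K_plus(i)
    Km = kin.K_minus(i)
    glucose_factor = sm / (Km + sm) if sm > 0 else 0.0
    dfactor_dsp = Kp / (Kp + sp) ** 2 if (Kp + sp) > 0 else 0.0
    return kin.mu_max(i) * dfactor_dsp * glucose_factor * stoich.Y_partner(j)


def negative_coefficient(
    state: CommunityState,
    kin: KineticParams,
    stoich: StoichiometryParams,
    pair: tuple[int, int],
) -> float:
    """Competition channel a_ij^- <= 0 (closed form, double Monod)."""
    i, j = _check_pair(pair)
    sp = state.s_plus(i)
    sm = state.s_minus
    Kp = kin.K_plus(i)
    Km = kin.K_minus(i)
    amino_factor = sp / (Kp + sp) if sp > 0 else 0.0
    dfactor_dsm = Km / (Km + sm) ** 2 if (Km + sm) > 0 else 0.0
    return -kin.mu_max(i) * amino_factor * dfactor_dsm * stoich.Y_shared(j)


def net_coefficient(a_plus: float, a_minus: float) -> float:
    """Net interspecific coefficient a_ij = a_ij^+ + a_ij^-."""
    if a_plus < 0 or a_minus > 0:
        raise ValueError("expected a_plus >= 0 and a_minus <= 0")
    return a_plus + a_minus


def gamma(a_plus: float, a_minus: float) -> tuple[float, bool]:
    """Normalized interaction parameter and a definedness flag.

    Returns (0.0, False) in the degenerate case where both channels vanish
    (e.g. both substrates exhausted), rather than NaN.
    """
    if a_plus < 0 or a_minus > 0:
        raise ValueError("expected a_plus >= 0 and a_minus <= 0")
    denom = a_plus - a_minus
    if denom == 0.0:
        return 0.0, False
    g = (a_plus + a_minus) / denom
    return float(np.clip(g, -1.0, 1.0)), True


def intraspecific_coefficient(
    state: CommunityState,
    kin: KineticParams,
    stoich: StoichiometryParams,
    species: int,
) -> float:
    """Self-limitation coefficient a_ii <= 0.

    Species i consumes both its amino acid (Y_self_i) and glucose
    (Y_shared_i), so both chain-rule channels are non-positive.
    """
    if species not in (1, 2):
        raise ValueError(f"species must be 1 or 2, got {species}")
    i = species
    sp = state.s_plus(i)
    sm = state.s_minus
    Kp = kin.K_plus(i)
    Km = kin.K_minus(i)
    mumax = kin.mu_max(i)
    glucose_factor = sm / (Km + sm) if sm > 0 else 0.0
    amino_factor = sp / (Kp + sp) if sp > 0 else 0.0
    dmu_dsp = mumax * (Kp / (Kp + sp) ** 2 if (Kp + sp) > 0 else 0.0) * glucose_factor
    dmu_dsm = mumax * amino_factor * (Km / (Km + sm) ** 2 if (Km + sm) > 0 else 0.0)
    return dmu_dsp * (-stoich.Y_self(i)) + dmu_dsm * (-stoich.Y_shared(i))


def finite_difference_oracle(
    state: CommunityState,
    kin: KineticParams,
    stoich: StoichiometryParams,
    pair: tuple[int, int],
    step: float | None = None,
) -> float:
    """Net a_ij by central differences under a virtual partner perturbation.

    A virtual change dx_j shifts s_i+ by +Y_partner_j*dx_j and s- by
    -Y_shared_j*dx_j; the symmetric difference quotient of mu_i under that
    shift converges to the closed-form chain-rule coefficient as the step
    shrinks.  This path is deliberately independent of the closed forms and
    serves as their verification oracle.
    """
    i, j = _check_pair(pair)
    return _fd_net(
        state, kin, i,
        dsp=stoich.Y_partner(j), dsm=-stoich.Y_shared(j), step=step,
    )


def finite_difference_intraspecific(
    state: CommunityState,
    kin: KineticParams,
    stoich: StoichiometryParams,
    species: int,
    step: float | None = None,
) -> float:
    """Central-difference oracle for a_ii via the two self-consumption channels."""
    i = species
    return _fd_net(
        state, kin, i,
        dsp=-stoich.Y_self(i), dsm=-stoich.Y_shared(i), step=step,
    )


def _fd_net(
    state: CommunityState,
    kin: KineticParams,
    i: int,
    dsp: float,
    dsm: float,
    step: float | None,
) -> float:
    sp = state.s_plus(i)
    sm = state.s_minus
    # scale the virtual biomass step so both concentration shifts stay small
    # relative to their (K + s) scales
    rel = DEFAULT_FD_STEP if step is None else None
    if step is None:
        scales = []
        if dsp != 0:
            scales.append(rel * (kin.K_plus(i) + sp) / abs(dsp))
        if dsm != 0:
            scales.append(rel * (kin.K_minus(i) + sm) / abs(dsm))
        step = min(scales)
    if step <= 0:
        raise ValueError("step must be > 0")
    sp_hi, sp_lo = sp + dsp * step, sp - dsp * step
    sm_hi, sm_lo = sm + dsm * step, sm - dsm * step
    if min(sp_hi, sp_lo, sm_hi, sm_lo) < 0:
        raise ValueError("finite-difference step drives a concentration negative")
    mu_hi = _mu_at(kin, i, sp_hi, sm_hi)
    mu_lo = _mu_at(kin, i, sp_lo, sm_lo)
    return (mu_hi - mu_lo) / (2.0 * step)


def _mu_at(kin: KineticParams, i: int, sp: float, sm: float) -> float:
    st = CommunityState(0.0, 0.0, sm, sp if i == 1 else 0.0, sp if i == 2 else 0.0)
    return monod_growth_rate(st, kin, i)


def coefficients_at_state(
    state: CommunityState, kin: KineticParams, stoich: StoichiometryParams
) -> InteractionCoefficients:
    """Evaluate the full coefficient set (both pairs, both species) at a state."""
    ap12 = positive_coefficient(state, kin, stoich, (1, 2))
    am12 = negative_coefficient(state, kin, stoich, (1, 2))
    ap21 = positive_coefficient(state, kin, stoich, (2, 1))
    am21 = negative_coefficient(state, kin, stoich, (2, 1))
    g12, d12 = gamma(ap12, am12)
    g21, d21 = gamma(ap21, am21)
    return InteractionCoefficients(
        a_plus_12=ap12,
        a_minus_12=am12,
        a_plus_21=ap21,
        a_minus_21=am21,
        a_11=intraspecific_coefficient(state, kin, stoich, 1),
        a_22=intraspecific_coefficient(state, kin, stoich, 2),
        gamma_12=g12,
        gamma_21=g21,
        defined_12=d12,
        defined_21=d21,
    )


def interactions_along_trajectory(
    traj: Trajectory, kin: KineticParams, stoich: StoichiometryParams
) -> InteractionProfile:
    """Coefficient profile on the trajectory's grid (the inference step)."""
    coeffs = [
        coefficients_at_state(traj.state_at(k), kin, stoich) for k in range(len(traj))
    ]
    return InteractionProfile(times=traj.times, coefficients=coeffs)


GrowthRate = Callable[[float, float], float]


def coefficients_from_growth_model(
    s_plus: float,
    s_minus: float,
    mu: GrowthRate,
    d_splus_dx: float,
    d_sminus_dx: float,
    dmu_dsplus: GrowthRate | None = None,
    dmu_dsminus: GrowthRate | None = None,
    fd_rel_step: float = DEFAULT_FD_STEP,
) -> tuple[float, float]:
    """Chain-rule channels for an arbitrary growth-rate function.

    ``mu(s_plus, s_minus)`` may be any kinetic form.  Partial derivatives
    are used when supplied and otherwise approximated by central
    differences with a step of ``fd_rel_step`` times the local
    concentration scale.  Returns the two channel contributions
    (through s_plus, through s_minus); their sum is the coefficient.
    """

    def _partial(f_analytic, var):
        if f_analytic is not None:
            return f_analytic(s_plus, s_minus)
        if var == "plus":
            h = fd_rel_step * (abs(s_plus) + 1.0)
            lo = max(s_plus - h, 0.0)
            return (mu(s_plus + h, s_minus) - mu(lo, s_minus)) / (s_plus + h - lo)
        h = fd_rel_step * (abs(s_minus) + 1.0)
        lo = max(s_minus - h, 0.0)
        return (mu(s_plus, s_minus + h) - mu(s_plus, lo)) / (s_minus + h - lo)

    via_plus = _partial(dmu_dsplus, "plus") * d_splus_dx
    via_minus = _partial(dmu_dsminus, "minus") * d_sminus_dx
    return via_plus, via_minus
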