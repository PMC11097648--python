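"""Parameter containers for the two-member consortium model.

The consortium couples two amino-acid auxotrophs (species 1 requires
tryptophan, species 2 requires tyrosine) that compete for a shared carbon
source (glucose) while cross-feeding the amino acid the partner cannot
synthesize.  Units follow the bioreactor convention used throughout the
package: biomass in OD600 units, glucose in g/L, amino acids in mg/L, time
in hours.  Yields are therefore g/OD (glucose) and mg/OD (amino acids); no
internal unit conversion is ever performed.
"""

from __future__ import annotations

from dataclasses import dataclass, fields, asdict
from typing import Sequence


@dataclass(frozen=True)
class KineticParams:
    """Double-Monod growth kinetics and death rates for both species.

    mu_max_i   maximal specific growth rate (1/h)
    K_plus_i   half-saturation for the species' required amino acid (mg/L)
    K_minus_i  half-saturation for shared glucose (g/L)
    kd_i       specific death rate (1/h)

    Defaults are the fitted values for the ΔtrpC (species 1) / ΔtyrA
    (species 2) E. coli pair.
    """

    mu_max_1: float = 2.961e-1
    mu_max_2: float = 1.658e-1
    K_plus_1: float = 3.300e-3
    K_plus_2: float = 3.881e-4
    K_minus_1: float = 3.091e-4
    K_minus_2: float = 3.923e-4
    kd_1: float = 1.206e-4
    kd_2: float = 4.024e-7

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if v < 0:
                raise ValueError(f"{f.name} must be >= 0, got {v}")
        if self.mu_max_1 <= 0 or self.mu_max_2 <= 0:
            raise ValueError("maximal growth rates must be positive")

    def mu_max(self, species: int) -> float:
        return self.mu_max_1 if species == 1 else self.mu_max_2

    def K_plus(self, species: int) -> float:
        return self.K_plus_1 if species == 1 else self.K_plus_2

    def K_minus(self, species: int) -> float:
        return self.K_minus_1 if species == 1 else self.K_minus_2

    def kd(self, species: int) -> float:
        return self.kd_1 if species == 1 else self.kd_2


@dataclass(frozen=True)
class StoichiometryParams:
    """Yield/exchange coefficients tied to the growth reaction of each species.

    Y_shared_i   glucose consumed per unit biomass of species i (g/OD)
    Y_self_i     own required amino acid consumed per unit biomass (mg/OD)
    Y_partner_i  partner's required amino acid *produced* per unit biomass
                 of species i (mg/OD); species 1 secretes tyrosine, species 2
                 secretes tryptophan.
    """

    Y_shared_1: float = 1.372
    Y_shared_2: float = 1.773
    Y_self_1: float = 1.550
    Y_self_2: float = 2.994
    Y_partner_1: float = 1.365
    Y_partner_2: float = 2.961

    def __post_init__(self) -> None:
        for f in fields(self):
            if getattr(self, f.name) < 0:
                raise ValueError(f"{f.name} must be >= 0")

    def Y_shared(self, species: int) -> float:
        return self.Y_shared_1 if species == 1 else self.Y_shared_2

    def Y_self(self, species: int) -> float:
        return self.Y_self_1 if species == 1 else self.Y_self_2

    def Y_partner(self, species: int) -> float:
        return self.Y_partner_1 if species == 1 else self.Y_partner_2


@dataclass(frozen=True)
class FeedSchedule:
    """Piecewise-constant glucose supply rate q (g/L/h).

    ``events`` is an ordered list of (start_time_h, rate) pairs; each event
    switches the supply rate to ``rate`` from ``start_time`` onward.  An
    empty list is pure batch (q = 0).  Slow-release glucose beads are
    represented as a single constant-rate event that stays on until the end
    of the horizon.
    """

    events: tuple[tuple[float, float], ...] = ()

    def __post_init__(self) -> None:
        ev = tuple((float(t), float(r)) for t, r in self.events)
        object.__setattr__(self, "events", ev)
        starts = [t for t, _ in ev]
        if any(b <= a for a, b in zip(starts, starts[1:])):
            raise ValueError("feed event start times must be strictly increasing")
        if any(r < 0 for _, r in ev):
            raise ValueError("feed rates must be >= 0")

    @property
    def is_batch(self) -> bool:
        return len(self.events) == 0

    def rate_at(self, t: float) -> float:
        """Supply rate of the latest event with start_time <= t, else 0."""
        q = 0.0
        for start, rate in self.events:
            if t >= start:
                q = rate
            else:
                break
        return q


# Glucose release rates of the commercial slow-release beads used in the
# semi-batch cultures (g/L/h).
FEED_RATE_THREE_BEADS = 5.580e-2
FEED_RATE_FIVE_BEADS = 9.300e-2


def kinetics_to_dict(kin: KineticParams) -> dict:
    return asdict(kin)


def stoichiometry_to_dict(st: StoichiometryParams) -> dict:
    return asdict(st)


def params_from_dict(d: dict) -> tuple[KineticParams, StoichiometryParams]:
    """Split a flat mapping of parameter names into the two containers.

    Unknown keys are ignored so that scenario blocks can live in the same
    config file.
    """
    kin_names = {f.name for f in fields(KineticParams)}
    st_names = {f.name for f in fields(StoichiometryParams)}
    kin = KineticParams(**{k: float(v) for k, v in d.items() if k in kin_names})
    st = StoichiometryParams(**{k: float(v) for k, v in d.items() if k in st_names})
    return kin, st


PARAM_NAMES: tuple[str, ...] = tuple(
    f.name for f in fields(KineticParams)
) + tuple(f.name for f in fields(StoichiometryParams))


def feed_from_config(obj: Sequence | dict | None) -> FeedSchedule:
    """Build a FeedSchedule from config data.

    Accepts ``{"events": [[t, rate], ...]}`` or a bare list of pairs.
    """
    if obj is None:
        return FeedSchedule()
    if isinstance(obj, dict):
        obj = obj.get("events", [])
    return FeedSchedule(tuple((float(t), float(r)) for t, r in obj))
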