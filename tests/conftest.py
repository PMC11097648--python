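import pytest

from kidi import (
    KineticParams,
    StoichiometryParams,
    get_scenario,
    interactions_along_trajectory,
    simulate,
)


@pytest.fixture(scope="session")
def kin():
    return KineticParams()


@pytest.fixture(scope="session")
def stoich():
    return StoichiometryParams()


@pytest.fixture(scope="session")
def fig3a_traj(kin, stoich):
    """Reference 30 h batch co-culture (2 g/L glucose, 1 mg/L each amino acid)."""
    scen = get_scenario("fig3A")
    return simulate(kin, stoich, scen.feed, scen.initial, scen.grid())


@pytest.fixture(scope="session")
def fig3a_profile(fig3a_traj, kin, stoich):
    return interactions_along_trajectory(fig3a_traj, kin, stoich)


def random_state_and_params(rng):
    """One random (state, kinetics, stoichiometry) draw over realistic ranges."""
    from kidi import CommunityState

    kin = KineticParams(
        mu_max_1=rng.uniform(0.05, 1.0),
        mu_max_2=rng.uniform(0.05, 1.0),
        K_plus_1=10 ** rng.uniform(-4, -1),
        K_plus_2=10 ** rng.uniform(-4, -1),
        K_minus_1=10 ** rng.uniform(-4, -1),
        K_minus_2=10 ** rng.uniform(-4, -1),
        kd_1=10 ** rng.uniform(-7, -3),
        kd_2=10 ** rng.uniform(-7, -3),
    )
    st = StoichiometryParams(
        Y_shared_1=rng.uniform(0.5, 5.0),
        Y_shared_2=rng.uniform(0.5, 5.0),
        Y_self_1=rng.uniform(0.5, 5.0),
        Y_self_2=rng.uniform(0.5, 5.0),
        Y_partner_1=rng.uniform(0.5, 5.0),
        Y_partner_2=rng.uniform(0.5, 5.0),
    )
    state = CommunityState(
        x1=rng.uniform(0.0, 2.0),
        x2=rng.uniform(0.0, 2.0),
        s_minus=10 ** rng.uniform(-5, 0.7),
        s1_plus=10 ** rng.uniform(-5, 1.0),
        s2_plus=10 ** rng.uniform(-5, 1.0),
    )
    return state, kin, st
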