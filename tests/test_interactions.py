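"""Tests for the chain-rule interaction coefficients and their oracle."""

import numpy as np
import pytest

from kidi import (
    CommunityState,
    KineticParams,
    StoichiometryParams,
    Trajectory,
    coefficients_at_state,
    coefficients_from_growth_model,
    finite_difference_intraspecific,
    finite_difference_oracle,
    gamma,
    interactions_along_trajectory,
    intraspecific_coefficient,
    negative_coefficient,
    net_coefficient,
    positive_coefficient,
)
from conftest import random_state_and_params


def state(x1=0.02, x2=0.02, glc=2.0, trp=1.0, tyr=1.0):
    return CommunityState(x1, x2, glc, trp, tyr)


class TestClosedForms:
    def test_no_glucose_no_promotion(self, kin, stoich):
        assert positive_coefficient(state(glc=0.0), kin, stoich, (1, 2)) == 0.0

    def test_saturated_amino_acid_kills_promotion(self, kin, stoich):
        small = positive_coefficient(state(trp=1e6), kin, stoich, (1, 2))
        ref = positive_coefficient(state(trp=1.0), kin, stoich, (1, 2))
        assert small < 1e-9 * ref

    def test_no_amino_acid_no_competition_channel(self, kin, stoich):
        assert negative_coefficient(state(trp=0.0), kin, stoich, (1, 2)) == 0.0

    def test_saturated_glucose_kills_competition(self, kin, stoich):
        small = negative_coefficient(state(glc=1e6), kin, stoich, (1, 2))
        ref = negative_coefficient(state(glc=0.5), kin, stoich, (1, 2))
        assert abs(small) < 1e-9 * abs(ref)

    def test_positive_matches_partial_derivative_times_yield(self, kin, stoich):
        # finite difference of mu_1 in the tryptophan direction only
        s = state()
        h = 1e-6 * (kin.K_plus_1 + s.s1_plus)
        from kidi import monod_growth_rate

        hi = monod_growth_rate(state(trp=s.s1_plus + h), kin, 1)
        lo = monod_growth_rate(state(trp=s.s1_plus - h), kin, 1)
        expected = (hi - lo) / (2 * h) * stoich.Y_partner_2
        got = positive_coefficient(s, kin, stoich, (1, 2))
        assert got == pytest.approx(expected, rel=1e-7)

    def test_negative_matches_partial_derivative_times_yield(self, kin, stoich):
        s = state(glc=0.5)
        h = 1e-6 * (kin.K_minus_1 + s.s_minus)
        from kidi import monod_growth_rate

        hi = monod_growth_rate(state(glc=s.s_minus + h), kin, 1)
        lo = monod_growth_rate(state(glc=s.s_minus - h), kin, 1)
        expected = (hi - lo) / (2 * h) * (-stoich.Y_shared_2)
        got = negative_coefficient(s, kin, stoich, (1, 2))
        assert got == pytest.approx(expected, rel=1e-7)

    def test_invalid_pair_rejected(self, kin, stoich):
        with pytest.raises(ValueError):
            positive_coefficient(state(), kin, stoich, (1, 1))

    def test_promotion_ordering_at_reference_initial_state(self, kin, stoich):
        # the tryptophan auxotroph benefits more from its partner than the
        # reverse at the glucose-rich reference condition
        s = state()
        a12 = net_coefficient(
            positive_coefficient(s, kin, stoich, (1, 2)),
            negative_coefficient(s, kin, stoich, (1, 2)),
        )
        a21 = net_coefficient(
            positive_coefficient(s, kin, stoich, (2, 1)),
            negative_coefficient(s, kin, stoich, (2, 1)),
        )
        assert a12 > a21


class TestGamma:
    def test_pure_promotion(self):
        assert gamma(0.3, 0.0) == (1.0, True)

    def test_pure_inhibition(self):
        assert gamma(0.0, -0.7) == (-1.0, True)

    def test_exact_balance(self):
        val, defined = gamma(0.5, -0.5)
        assert defined and val == 0.0

    def test_degenerate_flagged_not_nan(self):
        val, defined = gamma(0.0, 0.0)
        assert not defined and val == 0.0

    def test_sign_contract_violations_rejected(self):
        with pytest.raises(ValueError):
            gamma(-0.1, 0.0)
        with pytest.raises(ValueError):
            net_coefficient(0.1, 0.1)

    def test_matches_sign_of_net_coefficient(self):
        rng = np.random.default_rng(11)
        for _ in range(200):
            ap = rng.uniform(0, 1)
            am = -rng.uniform(0, 1)
            val, defined = gamma(ap, am)
            if defined and ap + am != 0:
                assert np.sign(val) == np.sign(net_coefficient(ap, am))


class TestIntraspecific:
    def test_zero_at_fully_depleted_state(self, kin, stoich):
        s = CommunityState(0.1, 0.1, 0.0, 0.0, 0.0)
        assert intraspecific_coefficient(s, kin, stoich, 1) == 0.0

    def test_strictly_negative_with_both_substrates(self, kin, stoich):
        assert intraspecific_coefficient(state(), kin, stoich, 1) < 0.0
        assert intraspecific_coefficient(state(), kin, stoich, 2) < 0.0

    def test_matches_finite_difference(self, kin, stoich):
        s = state()
        for sp in (1, 2):
            closed = intraspecific_coefficient(s, kin, stoich, sp)
            oracle = finite_difference_intraspecific(s, kin, stoich, sp)
            assert closed == pytest.approx(oracle, rel=1e-7)


class TestOracle:
    def test_second_order_convergence(self, kin, stoich):
        s = state(glc=0.5)
        closed = net_coefficient(
            positive_coefficient(s, kin, stoich, (1, 2)),
            negative_coefficient(s, kin, stoich, (1, 2)),
        )
        errs = []
        for rel in (1e-2, 1e-3):
            step = rel * (kin.K_plus_1 + s.s1_plus) / stoich.Y_partner_2
            errs.append(abs(finite_difference_oracle(s, kin, stoich, (1, 2),
                                                     step) - closed))
        # halving order: error ~ step^2 -> factor ~100 between the steps
        assert errs[1] < errs[0] / 20

    def test_oversized_step_rejected(self, kin, stoich):
        s = state(glc=1e-4)
        with pytest.raises(ValueError):
            finite_difference_oracle(s, kin, stoich, (1, 2), step=10.0)

    def test_exchange_symmetry(self):
        kin = KineticParams(mu_max_1=0.3, mu_max_2=0.3, K_plus_1=1e-3,
                            K_plus_2=1e-3, K_minus_1=2e-4, K_minus_2=2e-4,
                            kd_1=0.0, kd_2=0.0)
        st = StoichiometryParams(Y_shared_1=1.5, Y_shared_2=1.5, Y_self_1=2.0,
                                 Y_self_2=2.0, Y_partner_1=1.0, Y_partner_2=1.0)
        s = CommunityState(0.1, 0.1, 1.0, 0.5, 0.5)
        a12 = finite_difference_oracle(s, kin, st, (1, 2))
        a21 = finite_difference_oracle(s, kin, st, (2, 1))
        assert a12 == pytest.approx(a21, rel=1e-9)

    def test_agreement_on_random_draws(self, ):
        rng = np.random.default_rng(2024)
        for _ in range(200):
            s, kin, st = random_state_and_params(rng)
            for pair in ((1, 2), (2, 1)):
                closed = net_coefficient(
                    positive_coefficient(s, kin, st, pair),
                    negative_coefficient(s, kin, st, pair),
                )
                oracle = finite_difference_oracle(s, kin, st, pair)
                span = (positive_coefficient(s, kin, st, pair)
                        - negative_coefficient(s, kin, st, pair))
                denom = max(abs(closed), 1e-8 * span, 1e-12)
                assert abs(closed - oracle) / denom < 1e-5


class TestSignAndDecompositionSweep:
    def test_contracts_hold_on_random_draws(self):
        rng = np.random.default_rng(99)
        for _ in range(300):
            s, kin, st = random_state_and_params(rng)
            c = coefficients_at_state(s, kin, st)
            assert c.a_plus_12 >= 0 and c.a_plus_21 >= 0
            assert c.a_minus_12 <= 0 and c.a_minus_21 <= 0
            assert c.a_11 <= 0 and c.a_22 <= 0
            assert c.a_12 == c.a_plus_12 + c.a_minus_12
            assert c.a_21 == c.a_plus_21 + c.a_minus_21
            if c.defined_12:
                assert -1.0 <= c.gamma_12 <= 1.0
            if c.defined_21:
                assert -1.0 <= c.gamma_21 <= 1.0


class TestProfile:
    def test_constant_state_gives_constant_profile(self, kin, stoich):
        s = state()
        times = np.linspace(0, 5, 11)
        traj = Trajectory(times, np.tile(s.as_array(), (11, 1)))
        prof = interactions_along_trajectory(traj, kin, stoich)
        g = prof.series("gamma_12")
        assert np.all(g == g[0])
        assert len(prof) == 11

    def test_reference_batch_gamma_ordering(self, fig3a_profile, fig3a_traj, kin):
        # promotion dominates more strongly for the tryptophan auxotroph
        # throughout active co-growth
        from kidi import monod_growth_rate

        mu1 = np.array([monod_growth_rate(fig3a_traj.state_at(k), kin, 1)
                        for k in range(len(fig3a_traj))])
        mu2 = np.array([monod_growth_rate(fig3a_traj.state_at(k), kin, 2)
                        for k in range(len(fig3a_traj))])
        co = (mu1 > 0.01 * kin.mu_max_1) & (mu2 > 0.01 * kin.mu_max_2)
        g12 = fig3a_profile.series("gamma_12")
        g21 = fig3a_profile.series("gamma_21")
        assert co.sum() > 100
        assert np.all(g12[co] > g21[co])

    def test_amino_rich_low_glucose_is_mutually_inhibitive(self, kin, stoich):
        from kidi import get_scenario, simulate

        scen = get_scenario("fig3C")
        traj = simulate(kin, stoich, scen.feed, scen.initial, scen.grid(0.1))
        prof = interactions_along_trajectory(traj, kin, stoich)
        d = prof.series("defined_12").astype(bool) & \
            prof.series("defined_21").astype(bool)
        assert np.all(prof.series("gamma_12")[d] < 0)
        assert np.all(prof.series("gamma_21")[d] < 0)


class TestLimits:
    def test_glucose_excess_drives_gamma_to_plus_one(self, kin, stoich):
        s = state(glc=1e3 * kin.K_minus_1, trp=kin.K_plus_1, tyr=kin.K_plus_2)
        for pair in ((1, 2), (2, 1)):
            val, defined = gamma(
                positive_coefficient(s, kin, stoich, pair),
                negative_coefficient(s, kin, stoich, pair),
            )
            assert defined and val >= 0.99

    def test_amino_excess_drives_gamma_to_minus_one(self, kin, stoich):
        s = state(glc=kin.K_minus_1, trp=1e3 * kin.K_plus_1,
                  tyr=1e3 * kin.K_plus_2)
        for pair in ((1, 2), (2, 1)):
            val, defined = gamma(
                positive_coefficient(s, kin, stoich, pair),
                negative_coefficient(s, kin, stoich, pair),
            )
            assert defined and val <= -0.99


class TestGrowthModelHook:
    def test_generic_hook_reproduces_double_monod(self, kin, stoich):
        # analytic partials supplied
        def mu(sp, sm):
            return kin.mu_max_1 * sp / (kin.K_plus_1 + sp) * sm / (kin.K_minus_1 + sm)

        def dmu_dsp(sp, sm):
            return kin.mu_max_1 * kin.K_plus_1 / (kin.K_plus_1 + sp) ** 2 \
                * sm / (kin.K_minus_1 + sm)

        def dmu_dsm(sp, sm):
            return kin.mu_max_1 * sp / (kin.K_plus_1 + sp) \
                * kin.K_minus_1 / (kin.K_minus_1 + sm) ** 2

        s = state(glc=0.8, trp=0.3)
        via_p, via_m = coefficients_from_growth_model(
            s.s1_plus, s.s_minus, mu,
            d_splus_dx=stoich.Y_partner_2, d_sminus_dx=-stoich.Y_shared_2,
            dmu_dsplus=dmu_dsp, dmu_dsminus=dmu_dsm,
        )
        assert via_p == pytest.approx(
            positive_coefficient(s, kin, stoich, (1, 2)), rel=1e-12)
        assert via_m == pytest.approx(
            negative_coefficient(s, kin, stoich, (1, 2)), rel=1e-12)
        # internal finite differences, no analytic partials
        via_p2, via_m2 = coefficients_from_growth_model(
            s.s1_plus, s.s_minus, mu,
            d_splus_dx=stoich.Y_partner_2, d_sminus_dx=-stoich.Y_shared_2,
        )
        assert via_p2 == pytest.approx(via_p, rel=1e-4)
        assert via_m2 == pytest.approx(via_m, rel=1e-4)
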