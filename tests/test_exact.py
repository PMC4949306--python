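import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from domhier import (
    GameParams,
    IMMEDIATE_RETREAT,
    PayoffKind,
    class_from_theta,
    d_value,
    expected_payoff,
    expected_payoff_bruteforce,
    make_fixtures,
    payoff_pair,
    stopping_distribution,
    stopping_support,
    theta_interval,
    theta_rep,
    win_prob_from_diff,
)
from domhier.evolve import play_group

STEP_01 = math.log(1.1) - math.log(0.9)  # log-ratio step at V = C = 0.1


class TestThresholdClassMapping:
    @pytest.mark.parametrize(
        "theta, expected_d",
        [
            (1.0, 0.0),
            (0.61, -math.log(0.61) / STEP_01),   # ~2.4633
            (0.91, -math.log(0.91) / STEP_01),   # ~0.4700
        ],
    )
    def test_d_value(self, theta, expected_d):
        assert d_value(theta, 0.1, 0.1) == pytest.approx(expected_d, abs=1e-12)

    def test_d_value_sentinels(self):
        assert d_value(0.0, 0.1, 0.1) == math.inf
        assert d_value(1.2, 0.1, 0.1) < 0
        with pytest.raises(ValueError):
            d_value(0.5, 0.0, 0.0)

    def test_class_examples(self):
        c = class_from_theta(0.61, 0.1, 0.1)
        assert c.k == 3
        assert class_from_theta(1.0, 0.1, 0.1).k == 1
        c55 = class_from_theta(0.55, 0.1, 0.1)
        assert c55.k == 3
        assert round(c55.theta_min, 2) == 0.55  # (0.9/1.1)^3 ~ 0.5477
        assert round(c55.theta_sup, 2) == 0.67

    def test_immediate_retreat_class(self):
        assert class_from_theta(1.1, 0.1, 0.1).k == IMMEDIATE_RETREAT

    @pytest.mark.parametrize("k, V, C, expected", [(1, 0.1, 0.1, 0.91),
                                                   (3, 0.1, 0.1, 0.61),
                                                   (2, 0.02, 0.04, 0.91)])
    def test_theta_rep(self, k, V, C, expected):
        assert round(theta_rep(k, V, C), 2) == expected

    def test_theta_rep_is_interval_midpoint(self):
        lo, hi = theta_interval(4, 0.07, 0.12)
        assert theta_rep(4, 0.07, 0.12) == pytest.approx((lo + hi) / 2, rel=1e-14)

    @settings(max_examples=150, derandomize=True)
    @given(
        k=st.integers(min_value=1, max_value=12),
        V=st.floats(min_value=0.01, max_value=0.3),
        C=st.floats(min_value=0.01, max_value=0.3),
    )
    def test_class_round_trip(self, k, V, C):
        """theta_rep lies strictly inside its interval and maps back to k."""
        assert class_from_theta(theta_rep(k, V, C), V, C).k == k


class TestWinProbFromDiff:
    def test_values(self):
        assert win_prob_from_diff(0, 0.1, 0.1) == 0.5
        assert win_prob_from_diff(1, 0.1, 0.1) == pytest.approx(11 / 20, abs=1e-15)

    def test_complement(self):
        w = win_prob_from_diff(5, 0.2, 0.05)
        assert w + win_prob_from_diff(-5, 0.2, 0.05) == pytest.approx(1.0, abs=1e-15)


class TestExpectedPayoff:
    def test_single_round_closed_form(self):
        """T = 1, both class 1: one fight, payoff (ln 11 + ln 9) / 2."""
        p = GameParams.from_vc(0.1, 0.1, T=1)
        expected = 0.5 * math.log(11) + 0.5 * math.log(9)
        assert expected_payoff(1, 1, p) == pytest.approx(expected, abs=1e-14)
        assert expected_payoff_bruteforce(1, 1, p) == pytest.approx(expected, abs=1e-14)

    def test_example_diagonal_closed_form(self, params_example):
        """k = 1 vs 1 at T = 20: the loser concedes after round one, the
        winner collects 19 further uncontested gains."""
        expected = 0.5 * math.log(10 * 1.1**20) + 0.5 * math.log(9)
        assert expected_payoff(1, 1, params_example) == pytest.approx(expected, abs=1e-12)

    def test_share_symmetric_pair_is_half(self, params_example):
        for k in (1, 3, 6):
            assert expected_payoff(k, k, params_example, PayoffKind.SHARE) == pytest.approx(
                0.5, abs=1e-12
            )

    def test_double_kowtow_payoff(self, params_example):
        assert expected_payoff(
            IMMEDIATE_RETREAT, IMMEDIATE_RETREAT, params_example
        ) == pytest.approx(math.log(10), abs=1e-14)

    def test_immediate_retreat_vs_fighter(self, params_example):
        """The lone fighter collects T uncontested gains; the conceder is
        frozen at the initial score."""
        ex, ey = payoff_pair(IMMEDIATE_RETREAT, 2, params_example)
        assert ex == pytest.approx(math.log(10), abs=1e-14)
        assert ey == pytest.approx(math.log(10) + 20 * math.log(1.1), abs=1e-12)

    def test_requires_default_preset(self):
        p = GameParams(V1=0.1, V2=0.05, C1=0.1, C2=0.0)
        with pytest.raises(ValueError, match="preset"):
            expected_payoff(1, 1, p)

    def test_bruteforce_refuses_long_horizons(self, params_example):
        with pytest.raises(ValueError, match="enumeration"):
            expected_payoff_bruteforce(1, 1, params_example)  # T = 20 > 14

    @pytest.mark.parametrize("kind", [PayoffKind.LOG_RHP, PayoffKind.SHARE])
    def test_dp_matches_bruteforce(self, kind):
        """The (t, d) dynamic programme agrees with exhaustive enumeration
        of the micro-rules to 1e-10 on random parameter sets."""
        for fix in make_fixtures(seed=101, n_random=6):
            p = GameParams.from_vc(fix.params.V, fix.params.C, T=min(fix.params.T, 9))
            for k_x in (1, 2, 3):
                for k_y in (1, 2, 3):
                    dp = expected_payoff(k_x, k_y, p, kind)
                    bf = expected_payoff_bruteforce(k_x, k_y, p, kind)
                    assert dp == pytest.approx(bf, abs=1e-10), (fix.name, k_x, k_y)

    def test_share_payoffs_sum_to_one(self):
        """Both players' resource shares sum to one path-wise, hence in
        expectation, for every strategy pairing."""
        for fix in make_fixtures(seed=7, n_random=4):
            for k_x, k_y in [(1, 1), (1, 4), (3, 2), (5, 5)]:
                ex, ey = payoff_pair(k_x, k_y, fix.params, PayoffKind.SHARE)
                assert ex + ey == pytest.approx(1.0, abs=1e-12)

    def test_no_loss_cost_rewards_maximal_aggression(self):
        """With C = 0 the payoff is non-decreasing in one's own class
        against every opponent: with no injury cost it is best to keep
        fighting to the end."""
        p = GameParams.from_vc(0.1, 0.0, T=20)
        for k_y in range(1, 9):
            col = [expected_payoff(k_x, k_y, p) for k_x in range(1, 9)]
            assert all(b >= a - 1e-12 for a, b in zip(col, col[1:]))

    def test_no_win_benefit_rewards_immediate_retreat(self):
        """With V = 0 fighting can only hurt: conceding at once weakly
        dominates every fighting class."""
        p = GameParams.from_vc(0.0, 0.1, T=20)
        for k_y in [IMMEDIATE_RETREAT] + list(range(1, 9)):
            ir = expected_payoff(IMMEDIATE_RETREAT, k_y, p)
            for k_x in range(1, 9):
                assert ir >= expected_payoff(k_x, k_y, p) - 1e-12

    def test_monte_carlo_agreement(self):
        """Seeded simulation of the raw contest rules agrees with the
        dynamic programme within four standard errors."""
        rng = np.random.default_rng(2024)
        cases = [(0.1, 0.1, 1, 2), (0.2, 0.05, 2, 2), (0.05, 0.15, 3, 1)]
        n = 40_000
        for V, C, k_x, k_y in cases:
            p = GameParams.from_vc(V, C, T=20)
            thetas = [theta_rep(k_x, V, C), theta_rep(k_y, V, C)]
            payoffs = np.array(
                [
                    _batch_play(thetas, p, n, rng)[:, 0],
                ]
            ).ravel()
            dp = expected_payoff(k_x, k_y, p)
            se = payoffs.std(ddof=1) / math.sqrt(n)
            assert abs(payoffs.mean() - dp) < 4 * se, (V, C, k_x, k_y)


def _batch_play(thetas, params, n, rng):
    """Vectorised n-replicate pair contest via the group engine."""
    from domhier.evolve import _simulate_groups

    log_theta = np.tile(np.log(np.asarray(thetas)), (n, 1))
    return _simulate_groups(log_theta, params, params.T, rng)


class TestStoppingTime:
    def test_both_hair_trigger_point_mass(self, params_example):
        """Both class 1: the very first fight settles the contest."""
        dist = stopping_distribution(1, 1, params_example)
        assert dist.mass == {1: pytest.approx(1.0, abs=1e-15)}
        assert dist.censored_mass == 0.0

    def test_symmetric_two_first_passage(self, params_example):
        """k = 2 vs 2: stopping at t = 2 requires two same-sign results,
        probability 0.5*0.55 + 0.5*0.55."""
        dist = stopping_distribution(2, 2, params_example)
        assert dist.mass[2] == pytest.approx(0.55, abs=1e-12)

    @pytest.mark.parametrize("k_x, k_y", [(1, 1), (2, 2), (3, 3), (1, 2), (2, 5), (3, 6), (1, 8)])
    def test_mass_sums_to_one_and_support_parity(self, params_example, k_x, k_y):
        dist = stopping_distribution(k_x, k_y, params_example)
        member = stopping_support(k_x, k_y)
        assert dist.total() == pytest.approx(1.0, abs=1e-12)
        assert all(member(t) for t in dist.mass)
        non_support = [t for t in range(1, params_example.T + 1) if not member(t)]
        assert all(t not in dist.mass for t in non_support)

    def test_support_closed_forms(self):
        only_one = stopping_support(1, 1)
        assert [t for t in range(1, 10) if only_one(t)] == [1]
        evens = stopping_support(2, 2)
        assert [t for t in range(1, 9) if evens(t)] == [2, 4, 6, 8]
        odds = stopping_support(3, 3)
        assert [t for t in range(1, 10) if odds(t)] == [3, 5, 7, 9]
        mixed = stopping_support(2, 5)  # union of 2+2n and 5+2n
        assert [t for t in range(1, 10) if mixed(t)] == [2, 4, 5, 6, 7, 8, 9]

    def test_censoring_appears_for_patient_fighters(self):
        p = GameParams.from_vc(0.1, 0.1, T=6)
        dist = stopping_distribution(4, 4, p)
        assert dist.censored_mass > 0
        assert dist.total() == pytest.approx(1.0, abs=1e-12)

    def test_rejects_immediate_retreat(self, params_example):
        with pytest.raises(ValueError):
            stopping_distribution(IMMEDIATE_RETREAT, 2, params_example)


class TestSimulationConsistency:
    def test_play_group_single_fight(self):
        """theta = 0 on both sides with a single contest: one fight, the
        winner at ln 11 and the loser at ln 9."""
        p = GameParams.from_vc(0.1, 0.1, T=1)
        rng = np.random.default_rng(0)
        out = play_group([0.0, 0.0], p, contests=1, rng=rng)
        assert sorted(round(v, 10) for v in out) == [
            round(math.log(9), 10), round(math.log(11), 10)
        ]
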