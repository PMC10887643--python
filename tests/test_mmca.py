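import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import sicspread as sic
from sicspread import (
    ConsistencyError,
    InteractionModel,
    ParameterError,
    RateParams,
    build_initial_distribution,
    generate_ba,
    generate_fixture,
    marginals,
    mmca_run,
    mmca_step,
    parse_state_label,
    reception_probabilities,
    state_table,
    three_contagion_preset,
)

S, I, C = 0, 1, 2


class TestReceptionProbabilities:
    def test_no_infectious_neighbours(self, path3):
        q = np.zeros((3, 1))
        f = reception_probabilities(path3, q, [0.7])
        assert np.array_equal(f, np.zeros((3, 1)))

    def test_single_certain_neighbour(self, path3):
        q = np.array([[1.0], [0.0], [0.0]])
        f = reception_probabilities(path3, q, [0.1])
        assert f[1, 0] == pytest.approx(0.1)
        assert f[2, 0] == 0.0

    def test_two_certain_neighbours_combine(self, path3):
        q = np.array([[1.0], [0.0], [1.0]])
        f = reception_probabilities(path3, q, [0.5])
        assert f[1, 0] == pytest.approx(0.75)  # 1 - 0.25

    def test_fractional_marginal(self, path3):
        q = np.array([[0.5], [0.0], [0.0]])
        f = reception_probabilities(path3, q, [0.4])
        assert f[1, 0] == pytest.approx(0.2)

    def test_certain_transmission_saturates(self, path3):
        q = np.array([[1.0], [0.0], [0.0]])
        f = reception_probabilities(path3, q, [1.0])
        assert f[1, 0] == 1.0

    def test_dimension_mismatch_rejected(self, path3):
        with pytest.raises(ParameterError):
            reception_probabilities(path3, np.zeros((2, 1)), [0.5])


class TestInitialDistribution:
    def test_single_seed(self):
        net = generate_fixture("path", 3)
        d = build_initial_distribution(net, {0: [0]}, M=3)
        assert d.P[0, parse_state_label("I1S2S3")] == 1.0
        assert d.P[1, parse_state_label("S1S2S3")] == 1.0

    def test_overlapping_seeds(self):
        net = generate_fixture("path", 3)
        d = build_initial_distribution(net, [[1], [], [1]])
        assert d.P[1, parse_state_label("I1S2I3")] == 1.0

    def test_empty_seed_lists_stay_all_susceptible(self, k5):
        rates = RateParams(beta=[0.9], gamma=[0.5])
        traj = mmca_run(k5, rates, InteractionModel(M=1), [[]], max_steps=10)
        assert traj.converged and traj.spread_size[0] == 0.0

    def test_invalid_node_rejected(self, path3):
        with pytest.raises(ParameterError):
            build_initial_distribution(path3, [[7]])


class TestMMCAStep:
    def test_single_contagion_hand_example(self):
        # 2-node path, node 0 infectious, beta=0.5, gamma=0.2
        net = generate_fixture("path", 2)
        d = build_initial_distribution(net, [[0]])
        d1 = mmca_step(d, net, RateParams(beta=[0.5], gamma=[0.2]), InteractionModel(M=1))
        assert d1.P[1] == pytest.approx([0.5, 0.5, 0.0])
        assert d1.P[0] == pytest.approx([0.0, 0.8, 0.2])

    def test_all_susceptible_is_fixed_point(self, ba_small):
        d = build_initial_distribution(ba_small, [[], [], []])
        im = three_contagion_preset(a1=0.5, a2=1.0)
        rates = RateParams(beta=(0.9, 0.9, 0.9), gamma=(0.1, 0.1, 0.1))
        d1 = mmca_step(d, ba_small, rates, im)
        assert np.array_equal(d1.P, d.P)

    def test_complete_competition_blocks_joint_engagement(self):
        # contagions 1 and 2 seeded on different nodes of K3, a1=1
        net = generate_fixture("complete", 3)
        im = three_contagion_preset(a1=1.0)
        rates = RateParams(beta=(0.6, 0.6, 0.6), gamma=(0.3, 0.3, 0.3))
        d = build_initial_distribution(net, [[0], [1], []])
        codes = state_table(3)
        joint = (codes[:, 0] > 0) & (codes[:, 1] > 0)  # engaged with both 1 and 2
        for _ in range(25):
            d = mmca_step(d, net, rates, im)
            assert d.P[:, joint].max() == 0.0

    def test_verbatim_requires_canonical_preset(self, path3):
        d = build_initial_distribution(path3, [[0], [], []])
        rates = RateParams(beta=(0.3, 0.3, 0.3), gamma=(0.5, 0.5, 0.5))
        with pytest.raises(ParameterError, match="verbatim"):
            mmca_step(d, path3, rates, InteractionModel(M=3), mode="verbatim")

    def test_verbatim_matches_consistent_for_single_active_contagion(self, path3):
        # with beta2=beta3=0 the printed system reduces to one clean SIC chain
        im = three_contagion_preset(a2=1.0)
        rates = RateParams(beta=(0.4, 0.0, 0.0), gamma=(0.3, 0.5, 0.5))
        dv = dc = build_initial_distribution(path3, [[0], [], []])
        for _ in range(6):
            dv = mmca_step(dv, path3, rates, im, mode="verbatim")
            dc = mmca_step(dc, path3, rates, im, mode="consistent")
            assert np.abs(dv.P - dc.P).max() < 1e-12

    def test_verbatim_negative_residual_diagnosed(self):
        # a large enhancement factor makes a printed transition weight exceed 1
        net = generate_fixture("complete", 3)
        im = three_contagion_preset(a2=4.0)
        rates = RateParams(beta=(0.9, 0.0, 0.9), gamma=(0.1, 0.5, 0.1))
        d = build_initial_distribution(net, [[0], [], [1]])
        with pytest.raises(ConsistencyError, match="residual"):
            for _ in range(10):
                d = mmca_step(d, net, rates, im, mode="verbatim")


def _coop_pair_oracle_step(P, net, f0, f1, gamma, a2):
    """Literal 9-state transcription of the two cooperating contagions.

    States encoded x0 + 3*x1. Adoption of one contagion while the other is
    held/completed carries the (1+a2) boost (clipped at probability 1);
    simultaneous reception from the fully susceptible state adopts both.
    """
    g = lambda f: np.minimum(1.0, f * (1 + a2))
    r0, r1 = gamma
    SS, IS, CS = 0, 1, 2
    SI, II, CI = 3, 4, 5
    SC, IC, CC = 6, 7, 8
    new = np.zeros_like(P)
    new[:, SS] = P[:, SS] * (1 - f0) * (1 - f1)
    new[:, IS] = P[:, SS] * f0 * (1 - f1) + P[:, IS] * (1 - r0) * (1 - g(f1))
    new[:, SI] = P[:, SS] * (1 - f0) * f1 + P[:, SI] * (1 - g(f0)) * (1 - r1)
    new[:, CS] = P[:, IS] * r0 * (1 - g(f1)) + P[:, CS] * (1 - g(f1))
    new[:, SC] = P[:, SI] * (1 - g(f0)) * r1 + P[:, SC] * (1 - g(f0))
    new[:, II] = (
        P[:, SS] * f0 * f1
        + P[:, IS] * (1 - r0) * g(f1)
        + P[:, SI] * g(f0) * (1 - r1)
        + P[:, II] * (1 - r0) * (1 - r1)
    )
    new[:, CI] = (
        P[:, IS] * r0 * g(f1)
        + P[:, CS] * g(f1)
        + P[:, II] * r0 * (1 - r1)
        + P[:, CI] * (1 - r1)
    )
    new[:, IC] = (
        P[:, SI] * g(f0) * r1
        + P[:, SC] * g(f0)
        + P[:, II] * (1 - r0) * r1
        + P[:, IC] * (1 - r0)
    )
    new[:, CC] = (
        P[:, II] * r0 * r1 + P[:, CI] * r1 + P[:, IC] * r0 + P[:, CC]
    )
    return new


class TestAgainstCoopPairOracle:
    def test_five_step_marginals_match_transcription(self, path3, coop_pair):
        rates = RateParams(beta=(0.3, 0.3), gamma=(0.5, 0.5))
        d = build_initial_distribution(path3, [[0], [2]])
        P_oracle = d.P.copy()
        for _ in range(5):
            q = d.infectious_marginal()
            f = reception_probabilities(path3, q, rates.beta_array())
            P_oracle = _coop_pair_oracle_step(
                P_oracle, path3, f[:, 0], f[:, 1], rates.gamma, coop_pair.a2
            )
            d = mmca_step(d, path3, rates, coop_pair)
            assert np.abs(d.P - P_oracle).max() < 1e-12


class TestMMCARun:
    def test_no_transmission_converges_to_seed_fraction(self, k5):
        rates = RateParams(beta=[0.0], gamma=[0.7])
        traj = mmca_run(k5, rates, InteractionModel(M=1), [[0, 3]])
        assert traj.converged
        assert traj.spread_size[0] == pytest.approx(2 / 5)

    def test_certain_rates_on_star_reach_everyone(self):
        net = generate_fixture("star", 6)
        rates = RateParams(beta=[1.0], gamma=[1.0])
        traj = mmca_run(net, rates, InteractionModel(M=1), [[0]])
        assert traj.spread_size[0] == pytest.approx(1.0)
        # centre infects all leaves in step 1, everything completed by step 2
        assert traj.fractions[1, 0, I] == pytest.approx(5 / 6)

    def test_marginal_triples_sum_to_one(self, ba_small):
        rates = RateParams(beta=(0.2, 0.3, 0.1), gamma=(0.4, 0.4, 0.4))
        traj = mmca_run(
            ba_small, rates, three_contagion_preset(0.5, 1.0), [[0], [1], [2]], max_steps=50, tol=0
        )
        assert np.abs(traj.fractions.sum(axis=2) - 1.0).max() < 1e-9

    def test_completed_fraction_nondecreasing(self, ba_small):
        rates = RateParams(beta=(0.2, 0.3, 0.1), gamma=(0.4, 0.4, 0.4))
        traj = mmca_run(
            ba_small, rates, three_contagion_preset(0.5, 1.0), [[0], [1], [2]], max_steps=60, tol=0
        )
        c = traj.fractions[:, :, C]
        assert (np.diff(c, axis=0) >= -1e-12).all()
        engaged = traj.fractions[:, :, I] + c
        assert (np.diff(engaged, axis=0) >= -1e-12).all()

    def test_absorbing_state_has_no_residual_infection(self, ba_small):
        rates = RateParams(beta=[0.05], gamma=[0.6])
        traj = mmca_run(ba_small, rates, InteractionModel(M=1), [[0]], tol=1e-9)
        assert traj.converged
        assert traj.fractions[-1, 0, I] < 1e-8

    def test_factorizes_when_interactions_neutral(self, ba_small):
        rates3 = RateParams(beta=(0.15, 0.25, 0.1), gamma=(0.3, 0.5, 0.4))
        seeds = [[0, 7], [3], [11, 20]]
        traj3 = mmca_run(
            ba_small, rates3, three_contagion_preset(0.0, 0.0), seeds, max_steps=50, tol=0
        )
        for k in range(3):
            rates1 = RateParams(beta=[rates3.beta[k]], gamma=[rates3.gamma[k]])
            traj1 = mmca_run(
                ba_small, rates1, InteractionModel(M=1), [seeds[k]], max_steps=50, tol=0
            )
            assert np.abs(traj3.fractions[:, k] - traj1.fractions[:, 0]).max() < 1e-12


@settings(deadline=None, derandomize=True, max_examples=25)
@given(
    beta=st.tuples(*[st.floats(0, 1)] * 3),
    gamma=st.tuples(*[st.floats(0, 1)] * 3),
    a1=st.floats(0, 1),
    a2=st.floats(0, 4),
)
def test_probability_mass_conserved_for_random_parameters(beta, gamma, a1, a2):
    """Row sums stay at 1 to machine precision for arbitrary valid rates."""
    net = generate_ba(40, 2, seed=8)
    d = build_initial_distribution(net, [[0], [1], [2]])
    rates = RateParams(beta=beta, gamma=gamma)
    im = three_contagion_preset(a1=a1, a2=a2)
    for _ in range(5):
        d = mmca_step(d, net, rates, im)
        assert np.abs(d.P.sum(axis=1) - 1.0).max() < 1e-12
        assert d.P.min() >= 0.0
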