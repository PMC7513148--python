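"""Chain container, entropy rate, and first-return trajectory machinery."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import trajent as tj
from trajent.markov import ChainStructureError, NotIrreducibleError

LN2 = math.log(2.0)

# Hand evaluation of the entropy-rate sum for [[0.9,0.1],[0.5,0.5]] with
# s = (5/6, 1/6), term by term (the independent oracle for the vectorized
# implementation).
H_TWO_STATE = -(
    5 / 6 * (0.9 * math.log(0.9) + 0.1 * math.log(0.1))
    + 1 / 6 * (0.5 * math.log(0.5) + 0.5 * math.log(0.5))
)


def uniform_two_state():
    return tj.FiniteMarkovProcess([1, 2], np.full((2, 2), 0.5))


def deterministic_two_cycle():
    return tj.FiniteMarkovProcess([1, 2], np.array([[0.0, 1.0], [1.0, 0.0]]))


class TestEntropyRate:
    @pytest.mark.parametrize(
        "chain,s,expected",
        [
            (uniform_two_state(), [0.5, 0.5], LN2),
            (deterministic_two_cycle(), [0.5, 0.5], 0.0),
        ],
    )
    def test_closed_forms(self, chain, s, expected):
        assert tj.entropy_rate(chain, s) == pytest.approx(expected, abs=1e-12)

    def test_hand_evaluated_two_state(self, two_state_chain):
        assert tj.entropy_rate(two_state_chain, [5 / 6, 1 / 6]) == pytest.approx(
            H_TWO_STATE, abs=1e-12
        )

    def test_accepts_mapping_and_result_objects(self, two_state_chain):
        s = tj.stationary_power_iteration(two_state_chain)
        by_map = tj.entropy_rate(two_state_chain, {0: 5 / 6, 1: 1 / 6})
        assert tj.entropy_rate(two_state_chain, s) == pytest.approx(by_map, abs=1e-9)

    def test_rejects_length_mismatch(self, two_state_chain):
        with pytest.raises(ValueError):
            tj.entropy_rate(two_state_chain, [1.0])

    def test_rejects_unnormalized(self, two_state_chain):
        with pytest.raises(ValueError):
            tj.entropy_rate(two_state_chain, [0.9, 0.5])


class TestTrajectoryProbability:
    def test_product_of_steps(self):
        chain = uniform_two_state()
        assert tj.trajectory_probability(chain, [1, 2, 1]) == pytest.approx(0.25)

    def test_forbidden_step_gives_zero(self):
        chain = deterministic_two_cycle()
        assert tj.trajectory_probability(chain, [1, 1]) == 0.0

    def test_neutral_moran_step(self):
        # N=2 neutral chain without mutation: from (1,1), birth of type 1 and
        # death of type 2 has probability p_1 * abar_2 = 0.5 * 0.5.
        land = tj.GameLandscape(np.ones((2, 2)), kernel="linear")
        chain = tj.build_moran_chain(2, land, tj.uniform_mutation_matrix(2, 0.0))
        assert tj.trajectory_probability(chain, [(1, 1), (2, 0)]) == pytest.approx(0.25)

    def test_too_short_path_rejected(self):
        with pytest.raises(ValueError):
            tj.trajectory_probability(uniform_two_state(), [1])


class TestFirstReturnEnumeration:
    def test_geometric_paths(self):
        chain = uniform_two_state()
        trajs = tj.enumerate_first_return_trajectories(chain, 1, 3)
        got = {t.path: t.probability for t in trajs}
        assert got == {
            (1, 1): pytest.approx(0.5),
            (1, 2, 1): pytest.approx(0.25),
            (1, 2, 2, 1): pytest.approx(0.125),
        }
        assert all(t.is_first_return for t in trajs)

    def test_deterministic_cycle_unique_path(self):
        trajs = tj.enumerate_first_return_trajectories(deterministic_two_cycle(), 1, 5)
        assert len(trajs) == 1
        assert trajs[0].path == (1, 2, 1)
        assert trajs[0].probability == 1.0

    def test_absorbing_sink_mass_below_one(self):
        # State 2 absorbs: the only return path to 1 is the self-loop.
        chain = tj.FiniteMarkovProcess(
            [1, 2], np.array([[0.5, 0.5], [0.0, 1.0]]), validate=True
        )
        trajs = tj.enumerate_first_return_trajectories(chain, 1, 20)
        mass = sum(t.probability for t in trajs)
        assert mass == pytest.approx(0.5)
        assert mass <= 1.0

    def test_unknown_state_rejected(self):
        with pytest.raises(KeyError):
            tj.enumerate_first_return_trajectories(uniform_two_state(), 99, 3)

    def test_probability_floor_prunes(self):
        chain = uniform_two_state()
        pruned = tj.enumerate_first_return_trajectories(chain, 1, 30, prob_floor=1e-3)
        assert max(len(t.path) for t in pruned) - 1 <= 10  # 2^-10 < 1e-3


class TestBruteForceRTE:
    def test_geometric_first_return_entropy(self):
        # Path lengths are geometric(1/2); the exact entropy is 2 log 2.
        out = tj.rte_brute_force(uniform_two_state(), 1, 30)
        assert out.mass == pytest.approx(1.0 - 2.0**-30, abs=1e-15)
        assert out.entropy == pytest.approx(2 * LN2, abs=1e-6)

    def test_deterministic_cycle(self):
        out = tj.rte_brute_force(deterministic_two_cycle(), 1, 10)
        assert out.entropy == 0.0
        assert out.mass == 1.0

    def test_matches_enumeration_exactly(self):
        # The layered accumulation must equal the explicit path sum.
        chain = tj.make_fixture_chain(3, seed=11)
        trajs = tj.enumerate_first_return_trajectories(chain, 0, 12, prob_floor=0.0)
        explicit = -sum(t.probability * math.log(t.probability) for t in trajs)
        mass = sum(t.probability for t in trajs)
        out = tj.rte_brute_force(chain, 0, 12)
        assert out.entropy == pytest.approx(explicit, abs=1e-12)
        assert out.mass == pytest.approx(mass, abs=1e-12)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_monotone_convergence_to_closed_form(self, seed):
        chain = tj.make_fixture_chain(3, seed=seed)
        s = tj.stationary_power_iteration(chain)
        h = tj.entropy_rate(chain, s)
        target = h / s[1]
        prev_entropy, prev_mass = -1.0, -1.0
        errors = []
        for max_len in (10, 20, 40):
            out = tj.rte_brute_force(chain, 1, max_len)
            assert out.entropy >= prev_entropy
            assert out.mass >= prev_mass
            prev_entropy, prev_mass = out.entropy, out.mass
            errors.append(abs(out.entropy - target))
        assert errors[-1] <= min(errors) + 1e-12  # error shrinks with horizon
        assert errors[-1] <= 1e-3 + tj.rte_brute_force(chain, 1, 40).tail_bound

    def test_requires_irreducible(self):
        chain = tj.FiniteMarkovProcess([1, 2], np.array([[0.5, 0.5], [0.0, 1.0]]))
        with pytest.raises(NotIrreducibleError):
            tj.rte_brute_force(chain, 1, 10)


class TestClosedFormRTE:
    def test_direct_quotient(self):
        assert tj.rte(LN2, 0.5) == pytest.approx(2 * LN2)

    def test_degenerate_single_state(self):
        assert tj.rte(0.0, 1.0) == 0.0

    def test_two_state_worked_value(self):
        assert tj.rte(H_TWO_STATE, 5 / 6) == pytest.approx(H_TWO_STATE * 6 / 5, rel=1e-12)

    @pytest.mark.parametrize("bad", [0.0, -0.2])
    def test_rejects_nonpositive_stationary(self, bad):
        with pytest.raises(ValueError):
            tj.rte(1.0, bad)


class TestFixtureChain:
    def test_seeded_reproducibility(self):
        a = tj.make_fixture_chain(3, seed=0)
        b = tj.make_fixture_chain(3, seed=0)
        assert np.array_equal(a.todense(), b.todense())

    @given(st.integers(2, 6), st.integers(0, 50))
    @settings(max_examples=25, derandomize=True, deadline=None)
    def test_rows_stochastic_and_irreducible(self, n, seed):
        chain = tj.make_fixture_chain(n, seed)
        rows = chain.todense().sum(axis=1)
        assert np.abs(rows - 1.0).max() <= 1e-12
        assert (chain.todense() > 0).all()
        assert chain.is_irreducible

    def test_too_small_rejected(self):
        with pytest.raises(ValueError):
            tj.make_fixture_chain(1, seed=0)


class TestRTELowerBound:
    @pytest.mark.parametrize("seed", range(5))
    def test_rte_at_least_entropy_rate(self, seed):
        chain = tj.make_fixture_chain(4, seed)
        s = tj.stationary_power_iteration(chain)
        h = tj.entropy_rate(chain, s)
        for v in chain.states:
            assert tj.rte(h, s[v]) >= h


class TestContainer:
    def test_rejects_bad_rows(self):
        with pytest.raises(ChainStructureError):
            tj.FiniteMarkovProcess([0, 1], np.array([[0.6, 0.6], [0.5, 0.5]]))

    def test_rejects_out_of_range_probability(self):
        with pytest.raises(ChainStructureError):
            tj.FiniteMarkovProcess([0, 1], np.array([[1.5, -0.5], [0.5, 0.5]]))

    def test_states_sorted_lexicographically(self):
        chain = tj.FiniteMarkovProcess(
            [(1, 1), (0, 2), (2, 0)],
            {
                ((0, 2), (1, 1)): 1.0,
                ((1, 1), (2, 0)): 1.0,
                ((2, 0), (0, 2)): 1.0,
            },
        )
        assert chain.states == ((0, 2), (1, 1), (2, 0))

    def test_edgelist_roundtrip_with_tuple_states(self):
        land = tj.GameLandscape(tj.hawk_dove_matrix(), beta=0.7)
        chain = tj.build_moran_chain(4, land, tj.uniform_mutation_matrix(2, 0.25))
        text = chain.to_edgelist()
        back = tj.FiniteMarkovProcess.from_edgelist(text)
        assert back.states == chain.states
        assert np.allclose(back.todense(), chain.todense(), atol=0)

    def test_edgelist_file_roundtrip(self, tmp_path):
        chain = tj.make_fixture_chain(3, seed=5)
        path = tmp_path / "chain.tsv"
        chain.to_edgelist(path)
        back = tj.FiniteMarkovProcess.from_edgelist(path)
        assert np.allclose(back.todense(), chain.todense(), atol=0)
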