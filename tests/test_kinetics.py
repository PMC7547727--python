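import numpy as np
import pytest
from scipy.stats import spearmanr

import trajlm.kinetics as kin
from trajlm.encoding import DiscretizationScheme
from trajlm.kinetics import (StateMap, assign_states, commit_curve,
                             commit_transitions, counted_commute_time,
                             embedding_transition_matrix, free_energy,
                             kinetic_distance, rescale_unit,
                             state_probabilities)
from trajlm.markov import mfpt_commute


def brute_force_commit_counts(states, commit_time, n_states):
    """Hand-rule oracle: run-length encode, keep runs >= commit_time,
    merge equal neighbours, count ordered consecutive pairs."""
    runs = []
    for s in states:
        if s < 0:
            continue
        if runs and runs[-1][0] == s:
            runs[-1][1] += 1
        else:
            runs.append([s, 1])
    committed = [s for s, n in runs if n >= commit_time]
    merged = [committed[0]] if committed else []
    for s in committed[1:]:
        if s != merged[-1]:
            merged.append(s)
    counts = {(l, m): 0 for l in range(n_states)
              for m in range(n_states) if l != m}
    for a, b in zip(merged[:-1], merged[1:]):
        counts[(a, b)] += 1
    return counts


@pytest.fixture
def identity_statemap():
    """3 labels, each its own state."""
    return StateMap(n_states=3, assignment=np.array([0, 1, 2]))


class TestAssignStates:
    def test_nearest_minimum_within_radius(self):
        scheme = DiscretizationScheme(10, -2.5, 2.5)
        sm = assign_states(scheme, [-2.0, 0.0, 2.0], 0.5)
        reps = scheme.representative_values
        # representative value 0.25 lies within 0.5 of minimum 0 -> state 1
        lab = np.argmin(np.abs(reps - 0.25))
        assert sm.assignment[lab] == 1

    def test_outside_all_radii_unassigned(self):
        scheme = DiscretizationScheme(5, 0.0, 5.0)
        sm = assign_states(scheme, [0.5, 4.5], 0.4)
        # middle bin (midpoint 2.5) is far from both minima
        assert sm.assignment[2] == kin.UNASSIGNED

    def test_each_minimum_claims_its_nearest_label(self):
        scheme = DiscretizationScheme(12, -3.0, 3.0)
        minima = [-2.0, 0.0, 2.0]
        sm = assign_states(scheme, minima, 0.6)
        reps = scheme.representative_values
        for s, m in enumerate(minima):
            assert sm.assignment[np.argmin(np.abs(reps - m))] == s


class TestStateProbabilities:
    def test_two_segment_hand_example(self):
        # each contiguous half visits both states equally -> SE exactly 0
        sm = StateMap(n_states=2, assignment=np.array([0, 1]))
        df = state_probabilities(np.array([0, 1, 0, 1]), sm, n_segments=2)
        assert np.allclose(df["probability"], [0.5, 0.5])
        assert np.allclose(df["se"], 0.0)

    def test_segment_variability_reflected_in_se(self):
        # halves (0,0) and (1,1) disagree maximally: SE = 0.5/sqrt(2)
        sm = StateMap(n_states=2, assignment=np.array([0, 1]))
        df = state_probabilities(np.array([0, 0, 1, 1]), sm, n_segments=2)
        assert np.allclose(df["se"], 0.5 / np.sqrt(2))

    def test_probabilities_sum_to_one(self, identity_statemap, tiny_rng):
        labels = tiny_rng.integers(0, 3, size=1000)
        df = state_probabilities(labels, identity_statemap, n_segments=10)
        assert df["probability"].sum() == pytest.approx(1.0, abs=1e-12)

    def test_recovers_chain_stationary_law(self, three_state_chain,
                                           identity_statemap):
        from trajlm.markov import stationary_distribution
        spec, labels = three_state_chain
        pi = stationary_distribution(spec.transition_matrix)
        df = state_probabilities(labels, identity_statemap, n_segments=20)
        assert np.all(np.abs(df["probability"] - pi) <= 3 * df["se"])

    def test_empty_segment_rejected(self):
        sm = StateMap(n_states=2, assignment=np.array([0, 1, kin.UNASSIGNED]))
        labels = np.array([0, 1, 2, 2, 2, 2])  # second half unassigned
        with pytest.raises(ValueError, match="segment"):
            state_probabilities(labels, sm, n_segments=2)


class TestFreeEnergy:
    def test_certain_state_has_zero_free_energy(self):
        assert free_energy(np.array([1.0]), beta=3.0)[0] == 0.0

    def test_closed_form(self):
        assert free_energy(np.array([np.exp(-2.0)]), beta=1.0)[0] == \
            pytest.approx(2.0, abs=1e-12)

    def test_differences_invariant_to_rescaling(self):
        p = np.array([0.2, 0.5, 0.3])
        f1 = free_energy(p, 2.0)
        f2 = free_energy(10 * p, 2.0)
        assert np.allclose(np.diff(f1), np.diff(f2), atol=1e-12)

    def test_zero_probability_flagged_infinite(self):
        f = free_energy(np.array([0.0, 1.0]), 1.0)
        assert np.isinf(f[0]) and not np.isnan(f[0])


class TestCommitTransitions:
    def test_worked_eight_symbol_example_commit_two(self):
        sm = StateMap(n_states=2, assignment=np.array([0, 1]))
        seq = np.array([0, 0, 0, 1, 0, 1, 1, 1])  # A A A B A B B B
        counts = commit_transitions(seq, sm, commit_time=2)
        assert counts[(0, 1)] == 1
        assert all(v == 0 for k, v in counts.items() if k != (0, 1))

    def test_worked_eight_symbol_example_commit_one(self):
        sm = StateMap(n_states=2, assignment=np.array([0, 1]))
        seq = np.array([0, 0, 0, 1, 0, 1, 1, 1])
        counts = commit_transitions(seq, sm, commit_time=1)
        assert counts[(0, 1)] == 2
        assert counts[(1, 0)] == 1

    def test_commit_time_exceeding_longest_run_zeroes_counts(self):
        sm = StateMap(n_states=2, assignment=np.array([0, 1]))
        seq = np.array([0, 0, 0, 1, 0, 1, 1, 1])
        counts = commit_transitions(seq, sm, commit_time=4)
        assert all(v == 0 for v in counts.values())

    def test_matches_brute_force_on_random_sequences(self, tiny_rng):
        sm = StateMap(n_states=3,
                      assignment=np.array([0, kin.UNASSIGNED, 1, 2]))
        for trial in range(10):
            labels = tiny_rng.integers(0, 4, size=200)
            states = sm.states_of(labels)
            for ct in (1, 2, 3, 5):
                assert commit_transitions(labels, sm, ct) == \
                    brute_force_commit_counts(states, ct, 3)


class TestCommitCurve:
    def test_counts_non_increasing_for_two_state_system(self, tiny_rng):
        # without a bridging third state, raising the commit time can only
        # remove committed visits, so every pair's curve decays
        sm = StateMap(n_states=2, assignment=np.array([0, 1]))
        labels = (tiny_rng.random(20_000) < 0.3).astype(int)
        curve = commit_curve(labels, sm, np.arange(1, 30), n_segments=5)
        for mean in curve.counts.values():
            assert np.all(np.diff(mean) <= 1e-12)

    def test_total_committed_transitions_non_increasing(self,
                                                        three_state_chain,
                                                        identity_statemap):
        # per-pair curves may rise when an intermediate state's visits drop
        # below the commit time (via-B paths become direct A->C), but the
        # total number of committed transitions can only shrink
        _, labels = three_state_chain
        curve = commit_curve(labels[:20_000], identity_statemap,
                             np.arange(1, 30), n_segments=5)
        total = np.sum([m for m in curve.counts.values()], axis=0)
        assert np.all(np.diff(total) <= 1e-12)

    def test_single_segment_flagged(self, identity_statemap):
        with pytest.raises(ValueError):
            commit_curve(np.array([0, 1, 2]), identity_statemap,
                         np.array([1]), n_segments=1)

    def test_commit_one_equals_raw_run_transitions(self, three_state_chain,
                                                   identity_statemap):
        _, labels = three_state_chain
        labels = labels[:10_000]
        curve = commit_curve(labels, identity_statemap, np.array([1]),
                             n_segments=2)
        halves = np.array_split(labels, 2)
        for pair, mean in curve.counts.items():
            direct = np.mean([
                np.sum((h[:-1] == pair[0]) & (h[1:] == pair[1]))
                for h in halves])
            assert mean[0] == pytest.approx(direct)

    def test_to_frame_is_tidy(self, three_state_chain, identity_statemap):
        _, labels = three_state_chain
        df = commit_curve(labels[:5000], identity_statemap,
                          np.array([1, 5]), n_segments=2).to_frame()
        assert set(df.columns) == {"pair", "commit_time", "count_mean",
                                   "count_se"}


class TestEmbeddingTransitionMatrix:
    def test_identical_columns_give_uniform_rows(self):
        emb = np.ones((4, 5))
        q = embedding_transition_matrix(emb)
        assert np.allclose(q, 0.2, atol=1e-12)

    def test_rows_sum_to_one(self, tiny_rng):
        emb = tiny_rng.standard_normal((8, 12))
        q = embedding_transition_matrix(emb)
        assert np.allclose(q.sum(axis=1), 1.0, atol=1e-12)

    def test_orthogonal_two_state_case(self):
        emb = np.array([[0.0, 1.0], [0.0, 0.0]])  # x0 = 0 => all dots 0
        q = embedding_transition_matrix(emb)
        assert np.allclose(q[0], [0.5, 0.5], atol=1e-12)


class TestKineticDistance:
    def test_interconversion_arithmetic(self):
        # k = Q_l Q_lm + Q_m Q_ml with Q_l = Q_m = 0.5, Q_lm = Q_ml = 0.2
        sm = StateMap(n_states=2, assignment=np.array([0, 1]))
        labels = np.array([0, 1] * 50)  # occupancies 0.5 / 0.5
        q = np.array([[0.8, 0.2], [0.2, 0.8]])
        pairs, t = kinetic_distance(q, labels, sm)
        assert pairs == [(0, 1)]
        assert t[0] == pytest.approx(5.0, abs=1e-12)

    def test_symmetry_under_pair_swap(self, tiny_rng):
        # t_lm uses Q_l Q_lm + Q_m Q_ml, symmetric by construction; check
        # the table is reported once per unordered pair with finite values
        sm = StateMap(n_states=3, assignment=np.array([0, 1, 2]))
        labels = tiny_rng.integers(0, 3, size=300)
        emb = tiny_rng.standard_normal((4, 3))
        q = embedding_transition_matrix(emb)
        pairs, t = kinetic_distance(q, labels, sm)
        assert pairs == [(0, 1), (0, 2), (1, 2)]
        assert np.all(np.isfinite(t))

    def test_doubling_both_rates_halves_time(self):
        sm = StateMap(n_states=2, assignment=np.array([0, 1]))
        labels = np.array([0, 1] * 50)
        q1 = np.array([[0.9, 0.1], [0.1, 0.9]])
        q2 = np.array([[0.8, 0.2], [0.2, 0.8]])
        _, t1 = kinetic_distance(q1, labels, sm)
        _, t2 = kinetic_distance(q2, labels, sm)
        assert t1[0] == pytest.approx(2 * t2[0], abs=1e-12)

    def test_weighted_aggregation_matches_modal_for_single_label_states(
            self, tiny_rng):
        sm = StateMap(n_states=2, assignment=np.array([0, 1]))
        labels = tiny_rng.integers(0, 2, size=500)
        q = embedding_transition_matrix(tiny_rng.standard_normal((3, 2)))
        _, tm = kinetic_distance(q, labels, sm, aggregate="modal")
        _, tw = kinetic_distance(q, labels, sm, aggregate="weighted")
        assert np.allclose(tm, tw, atol=1e-12)


class TestCountedCommuteTime:
    def test_tau_arithmetic(self):
        # T = 1000 samples, <N_lm> = 10 transitions => tau = 100
        sm = StateMap(n_states=2, assignment=np.array([0, 1]))
        period = 100  # 10 full alternations in 1000 samples
        labels = np.tile(np.repeat([0, 1], period // 2), 1000 // period)
        pairs, tau = counted_commute_time(labels, sm, np.array([1]))
        # 19 boundary crossings in both directions summed
        assert tau[0] == pytest.approx(1000 / 19)

    def test_tau_decreases_when_transitions_added(self):
        sm = StateMap(n_states=2, assignment=np.array([0, 1]))
        slow = np.repeat([0, 1, 0, 1], 100)
        fast = np.repeat([0, 1] * 20, 10)
        _, tau_slow = counted_commute_time(slow, sm, np.array([1, 2]))
        _, tau_fast = counted_commute_time(fast, sm, np.array([1, 2]))
        assert tau_fast[0] < tau_slow[0]

    def test_no_transitions_flagged_infinite(self):
        sm = StateMap(n_states=2, assignment=np.array([0, 1]))
        labels = np.zeros(100, dtype=int)
        labels[:1] = 1  # single boundary, committed only at ct=1
        _, tau = counted_commute_time(np.zeros(100, dtype=int) * 0 + 0,
                                      sm, np.array([5]))
        # all-zero series never visits state 1
        assert np.isinf(tau[0])

    def test_ranking_matches_mfpt_commute_oracle(self, three_state_chain,
                                                 identity_statemap):
        spec, labels = three_state_chain
        pairs, tau = counted_commute_time(labels, identity_statemap,
                                          np.array([1]))
        oracle = mfpt_commute(spec)
        tau_oracle = np.array([oracle[p] for p in pairs])
        rho = spearmanr(tau, tau_oracle).statistic
        assert rho == pytest.approx(1.0)


class TestRescaleUnit:
    def test_affine_map(self):
        assert np.allclose(rescale_unit([2, 4, 6]), [0, 0.5, 1])

    def test_order_preserved(self, tiny_rng):
        v = tiny_rng.standard_normal(10)
        r = rescale_unit(v)
        assert np.array_equal(np.argsort(v), np.argsort(r, kind="stable"))

    def test_idempotent_on_unit_spanning_input(self):
        v = np.array([0.0, 0.3, 1.0])
        assert np.allclose(rescale_unit(v), v)

    def test_all_equal_flagged_half(self):
        assert np.allclose(rescale_unit([3.0, 3.0, 3.0]), 0.5)

    def test_infinite_pairs_map_to_one(self):
        r = rescale_unit([1.0, 2.0, np.inf])
        assert r[2] == 1.0
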