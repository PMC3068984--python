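"""Event-history metrics: durations, transitions, episodes, day aggregation."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from srsleep.metrics import (
    INTERVALS,
    TRANSITION_PAIRS,
    TimeInterval,
    normed_durations,
    rems_episodes,
    summarize_animal,
    transition_frequencies,
)
from srsleep.states import Hypnogram, VigilanceState

W, N, R = VigilanceState.WAKE, VigilanceState.NREMS, VigilanceState.REMS


def hyp(states, zt_start=0.0):
    return Hypnogram(states=np.array(states, dtype=np.int8), zt_start=zt_start)


def interval_for(states):
    return TimeInterval("all", 0.0, len(states) * 4.0 / 3600.0)


def full_day_hypnogram(rng, n=20700):
    return Hypnogram(states=rng.choice(3, n, p=[0.4, 0.45, 0.15]).astype(np.int8))


class TestNormedDurations:
    def test_toy_example(self):
        h = hyp([W, W, N, N, R, W])
        d = normed_durations(h, interval_for(h.states))
        assert d[W] == pytest.approx(1 / 2)
        assert d[N] == pytest.approx(1 / 3)
        assert d[R] == pytest.approx(1 / 6)

    def test_all_wake(self):
        h = hyp([W] * 10)
        d = normed_durations(h, interval_for(h.states))
        assert d == {W: 1.0, N: 0.0, R: 0.0}

    def test_counting_oracle_full_day(self, rng):
        h = full_day_hypnogram(rng)
        for iv in INTERVALS.values():
            d = normed_durations(h, iv)
            lo, hi = int(iv.start * 900), int(iv.end * 900)
            sub = h.states[lo:hi]
            for s in VigilanceState:
                assert d[s] == sum(1 for x in sub if x == s) / len(sub)
            assert sum(d.values()) == pytest.approx(1.0, abs=1e-12)

    def test_interval_outside_recording_rejected(self):
        h = hyp([W] * 10)
        with pytest.raises(ValueError, match="outside"):
            normed_durations(h, TimeInterval("L2", 6.0, 12.0))


class TestTransitions:
    def test_toy_example(self):
        h = hyp([W, W, N, N, R, W])
        counts, normed = transition_frequencies(h, interval_for(h.states))
        assert counts[(W, N)] == 1 and counts[(N, R)] == 1 and counts[(R, W)] == 1
        assert sum(counts.values()) == 3
        for pair in [(W, N), (N, R), (R, W)]:
            assert normed[pair] == pytest.approx(1 / 3)
        assert normed[(N, W)] == 0.0

    def test_constant_hypnogram_undefined(self):
        counts, normed = transition_frequencies(hyp([N] * 20), interval_for([N] * 20))
        assert all(c == 0 for c in counts.values())
        assert normed is None

    def test_markov_long_run_matches_generator(self, presets):
        """Normed transition frequencies of a long single-phase chain match
        pi_i * P(i->j) renormalised over off-diagonal pairs within 2%."""
        from srsleep.simulate import SimConfig, simulate_hypnogram
        from test_simulate import single_phase_preset, stationary_oracle

        P = np.array([[0.90, 0.06, 0.04], [0.05, 0.90, 0.05], [0.06, 0.04, 0.90]])
        preset = single_phase_preset(P, presets["IR"])
        cfg = SimConfig(n_days=1, recording_hours=1110.0, lights_off_zt=1110.0, seed=1)
        h = simulate_hypnogram(preset, cfg, 3)
        _, normed = transition_frequencies(h, TimeInterval("all", 0.0, 1110.0))
        pi = stationary_oracle(P)
        expected = {p: pi[p[0]] * P[p[0], p[1]] for p in TRANSITION_PAIRS}
        tot = sum(expected.values())
        for p in TRANSITION_PAIRS:
            exp = expected[p] / tot
            if exp > 0:
                assert normed[p] == pytest.approx(exp, rel=0.02)
            else:
                assert normed[p] == 0.0

    def test_boundary_attribution_to_later_epoch(self):
        """A transition across an interval boundary belongs to the interval
        of the later epoch."""
        states = [W] * 5400 + [N] * 5400  # 6 h WAKE then 6 h NREMS
        h = hyp(states)
        c1, _ = transition_frequencies(h, TimeInterval("L1", 0.0, 6.0))
        c2, _ = transition_frequencies(h, TimeInterval("L2", 6.0, 12.0))
        assert c1[(W, N)] == 0
        assert c2[(W, N)] == 1

    def test_splitting_invariance(self, rng):
        h = full_day_hypnogram(rng)
        whole, _ = transition_frequencies(h, TimeInterval("all", 0.0, 23.0))
        summed = {p: 0 for p in TRANSITION_PAIRS}
        for iv in INTERVALS.values():
            c, _ = transition_frequencies(h, iv)
            for p in TRANSITION_PAIRS:
                summed[p] += c[p]
        assert whole == summed

    def test_entry_exit_balance(self, rng):
        h = full_day_hypnogram(rng)
        c, _ = transition_frequencies(h, TimeInterval("all", 0.0, 23.0))
        for s in VigilanceState:
            into = sum(c[(a, b)] for a, b in TRANSITION_PAIRS if b == s)
            out = sum(c[(a, b)] for a, b in TRANSITION_PAIRS if a == s)
            assert abs(into - out) <= 1


class TestRemsEpisodes:
    def test_toy_example(self):
        h = hyp([N, R, R, N, R])
        lengths = rems_episodes(h, interval_for(h.states))
        assert lengths == [8.0, 4.0]
        assert np.mean(lengths) == pytest.approx(6.0)

    def test_no_rems_empty(self):
        assert rems_episodes(hyp([W, N, N]), interval_for([W, N, N])) == []

    def test_run_length_oracle(self, rng):
        h = full_day_hypnogram(rng)
        got = sorted(
            length for iv in INTERVALS.values() for length in rems_episodes(h, iv)
        )
        # brute-force run-length encoding over the whole day
        oracle = []
        i = 0
        s = h.states
        while i < len(s):
            if s[i] == R:
                j = i
                while j < len(s) and s[j] == R:
                    j += 1
                if i * 4.0 / 3600.0 < 23.0:
                    oracle.append((j - i) * 4.0)
                i = j
            else:
                i += 1
        assert got == sorted(oracle)

    def test_episode_spanning_boundary_not_split(self):
        states = [N] * 5399 + [R, R, R] + [N] * 5398  # starts at ZT 5.9989
        h = hyp(states)
        l1 = rems_episodes(h, TimeInterval("L1", 0.0, 6.0))
        l2 = rems_episodes(h, TimeInterval("L2", 6.0, 12.0))
        assert l1 == [12.0]
        assert l2 == []


class TestSummarizeAnimal:
    def test_single_day_identity(self, rng):
        h = full_day_hypnogram(rng)
        h.animal_id = "X_01"
        s = summarize_animal([h])
        for name, iv in INTERVALS.items():
            assert s[name].normed_duration == normed_durations(h, iv)

    def test_two_identical_days(self, rng):
        h = full_day_hypnogram(rng)
        s1 = summarize_animal([h])
        s2 = summarize_animal([h, h.copy()])
        for name in INTERVALS:
            assert s2[name].normed_duration == pytest.approx(s1[name].normed_duration)
            assert s2[name].normed_transitions == pytest.approx(s1[name].normed_transitions)
            assert s2[name].mean_rems_episode_length == s1[name].mean_rems_episode_length

    def test_two_distinct_days_hand_average(self):
        """12-epoch toy: durations average across days; transition counts sum
        and normed transitions are recomputed from the sums."""
        iv = {"all": TimeInterval("all", 0.0, 12 * 4.0 / 3600.0)}
        d1 = hyp([W, W, W, W, W, W, N, N, N, N, R, R])   # W 1/2, N 1/3, R 1/6
        d2 = hyp([W, W, W, N, N, N, N, N, N, R, R, R])   # W 1/4, N 1/2, R 1/4
        s = summarize_animal([d1, d2], intervals=iv)["all"]
        assert s.normed_duration[W] == pytest.approx((1 / 2 + 1 / 4) / 2)
        assert s.normed_duration[N] == pytest.approx((1 / 3 + 1 / 2) / 2)
        assert s.normed_duration[R] == pytest.approx((1 / 6 + 1 / 4) / 2)
        # day1: W->N, N->R; day2: W->N, N->R -> counts 2 and 2 of 4 total
        assert s.transition_counts[(W, N)] == 2
        assert s.transition_counts[(N, R)] == 2
        assert s.normed_transitions[(W, N)] == pytest.approx(0.5)
        # day1 has one 2-epoch episode (8 s), day2 one 3-epoch episode (12 s)
        assert s.mean_rems_episode_length == pytest.approx(10.0)

    def test_unequal_day_lengths_rejected(self, rng):
        with pytest.raises(ValueError, match="unequal"):
            summarize_animal([full_day_hypnogram(rng),
                              Hypnogram(states=np.zeros(100, dtype=np.int8))])


class TestMechanism:
    def test_more_episodes_not_longer_ones_raise_rems_time(self):
        """Doubling the REMS episode COUNT at fixed episode length doubles
        normed REMS duration while the episode-length distribution is
        unchanged — the event-history signature of the high-reactivity line."""
        block = [N] * 8 + [R, R] + [N] * 8
        few = hyp(block * 25 + [N] * 450)
        many = hyp(block * 50)
        iv = TimeInterval("all", 0.0, 1.0)
        d_few = normed_durations(few, iv)[R]
        d_many = normed_durations(many, iv)[R]
        assert d_many == pytest.approx(2 * d_few)
        assert np.mean(rems_episodes(few, iv)) == np.mean(rems_episodes(many, iv)) == 8.0


@settings(max_examples=50, deadline=None, derandomize=True, database=None)
@given(st.lists(st.integers(min_value=0, max_value=2), min_size=2, max_size=400))
def test_conservation_properties(states):
    """Normed durations always sum to 1; normed transitions, when defined,
    sum to 1 and match the transition counts."""
    h = hyp(states)
    iv = interval_for(states)
    d = normed_durations(h, iv)
    assert sum(d.values()) == pytest.approx(1.0, abs=1e-12)
    counts, normed = transition_frequencies(h, iv)
    total = sum(counts.values())
    if total == 0:
        assert normed is None
    else:
        assert sum(normed.values()) == pytest.approx(1.0, abs=1e-12)
        for p in TRANSITION_PAIRS:
            assert normed[p] == counts[p] / total
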