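"""Exclusive labels, run-length encoding, transition counting and the
genotype comparison over the 132 ordered label pairs."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ethoquartet import AnalysisConfig
from ethoquartet.bruteforce import brute_force_exclusive_labels
from ethoquartet.detection import detect_all
from ethoquartet.transitions import (
    EXCLUSIVE_LABELS,
    assign_exclusive_labels,
    compare_transitions,
    count_transitions,
    merge_to_exclusive_events,
    n_ordered_label_pairs,
)


def _label_index(name):
    return EXCLUSIVE_LABELS.index(name)


class TestExclusiveLabels:
    def test_twelve_labels(self):
        assert len(EXCLUSIVE_LABELS) == 12
        assert len(set(EXCLUSIVE_LABELS)) == 12
        assert "undetected" in EXCLUSIVE_LABELS

    def test_partition_every_frame_exactly_once(
        self, config, quartet_sim, quartet_ethogram
    ):
        traj, _, _ = quartet_sim
        labels = assign_exclusive_labels(quartet_ethogram, traj, config)
        for aid in traj.animals:
            assert labels[aid].shape == (traj.n_frames,)
            assert ((labels[aid] >= 0) & (labels[aid] < 12)).all()
            events = merge_to_exclusive_events(labels[aid], actor=aid)
            assert sum(e.duration_frames for e in events) == traj.n_frames

    def test_matches_bruteforce_precedence_scan(
        self, config, quartet_sim, quartet_ethogram
    ):
        traj, _, _ = quartet_sim
        labels = assign_exclusive_labels(quartet_ethogram, traj, config)
        bf = brute_force_exclusive_labels(traj, config)
        for aid in traj.animals:
            mine = [EXCLUSIVE_LABELS[i] for i in labels[aid]]
            assert mine == bf[aid]

    def test_combined_and_other_contact_states_reachable(self, config):
        """A quartet simulation weighted towards combined poses produces the
        named combined labels, a plain contact frame maps to 'other
        contact', and dropout frames map to 'undetected'."""
        from ethoquartet.simulate import SimulationConfig, simulate_quartet

        sc = SimulationConfig(
            n_animals=4, duration_s=240, contact_rate_per_min=8.0,
            contact_mean_s=3.0, detection_dropout=0.01,
            pose_weights={
                "nose-nose & side-side": 5.0,
                "nose-anogenital & side-side head-to-tail": 5.0,
                "other contact": 5.0,
            },
        )
        traj, _, _ = simulate_quartet(sc, seed=21)
        eth = detect_all(traj, config)
        labels = assign_exclusive_labels(eth, traj, config)
        seen = set()
        for aid in traj.animals:
            seen |= {EXCLUSIVE_LABELS[i] for i in np.unique(labels[aid])}
        assert "nose-nose & side-side" in seen
        assert "nose-anogenital & side-side head-to-tail" in seen
        assert "passive nose-anogenital & side-side head-to-tail" in seen
        assert "other contact" in seen
        assert "undetected" in seen

    def test_isolated_detected_still_frame_is_idle(self, config):
        from conftest import make_static_pair

        traj = make_static_pair(n_frames=10)
        eth = detect_all(traj, config)
        labels = assign_exclusive_labels(eth, traj, config)
        assert all(
            EXCLUSIVE_LABELS[i] == "idle" for i in labels["a"]
        )


class TestRunLengthEncoding:
    def test_hand_example(self):
        seq = np.array([0, 0, 1, 0], dtype=np.int8)
        events = merge_to_exclusive_events(seq, actor="x")
        spans = [(e.start_frame, e.end_frame, e.event_type) for e in events]
        assert spans == [
            (0, 1, EXCLUSIVE_LABELS[0]),
            (2, 2, EXCLUSIVE_LABELS[1]),
            (3, 3, EXCLUSIVE_LABELS[0]),
        ]

    def test_constant_sequence_single_interval(self):
        events = merge_to_exclusive_events(np.full(50, 3, dtype=np.int8))
        assert len(events) == 1
        assert events[0].duration_frames == 50

    @settings(max_examples=50, deadline=None)
    @given(seq=st.lists(st.integers(0, 11), min_size=1, max_size=200))
    def test_decode_encode_round_trip(self, seq):
        arr = np.array(seq, dtype=np.int8)
        events = merge_to_exclusive_events(arr)
        decoded = np.concatenate(
            [
                np.full(e.duration_frames, _label_index(e.event_type))
                for e in events
            ]
        )
        np.testing.assert_array_equal(decoded, arr)
        # consecutive intervals never share a label
        for e1, e2 in zip(events, events[1:]):
            assert e1.event_type != e2.event_type


class TestTransitionCounting:
    def test_hand_counted_proportions(self):
        """Sequence A,B,A,C,A,B: n(A)=3 including the non-terminal final A,
        p(A->B)=2/3, p(A->C)=1/3, p(B->A)=1/2 (last B has no successor)."""
        A, B, C = 0, 1, 2
        seq = np.array([A, B, A, C, A, B], dtype=np.int8)
        m = count_transitions(seq)
        p = m.proportions()
        assert m.occurrences[A] == 3
        assert m.occurrences[B] == 2
        assert p[A, B] == pytest.approx(2 / 3)
        assert p[A, C] == pytest.approx(1 / 3)
        assert p[B, A] == pytest.approx(1 / 2)

    def test_two_event_sequence(self):
        m = count_transitions(np.array([4, 7], dtype=np.int8))
        assert m.proportions()[4, 7] == pytest.approx(1.0)

    def test_single_event_sequence_zero_matrix(self):
        m = count_transitions(np.array([5, 5, 5], dtype=np.int8))
        assert m.counts.sum() == 0
        assert m.occurrences[5] == 1

    def test_exclude_terminal_normalises_rows(self):
        seq = np.array([0, 1, 0, 2, 0], dtype=np.int8)  # terminal 0
        m = count_transitions(seq)
        p_incl = m.proportions(exclude_terminal=False)
        p_excl = m.proportions(exclude_terminal=True)
        assert np.nansum(p_incl[0]) == pytest.approx(2 / 3)
        assert np.nansum(p_excl[0]) == pytest.approx(1.0)

    def test_number_of_ordered_pairs_is_132(self):
        assert n_ordered_label_pairs() == 12 * 11

    def test_sum_rule_on_simulation(self, config, quartet_sim, quartet_ethogram):
        """For every label A: sum_B n(A->B) = n(A) - [final interval is A]."""
        traj, _, _ = quartet_sim
        labels = assign_exclusive_labels(quartet_ethogram, traj, config)
        for aid in traj.animals:
            m = count_transitions(labels[aid])
            for i in range(12):
                terminal = 1 if m.terminal == i else 0
                assert m.counts[i].sum() == m.occurrences[i] - terminal

    def test_counts_match_bruteforce_scan(self, config, quartet_sim, quartet_ethogram):
        traj, _, _ = quartet_sim
        labels = assign_exclusive_labels(quartet_ethogram, traj, config)
        for aid in traj.animals:
            seq = labels[aid]
            # brute-force: walk the per-frame sequence
            occ = np.zeros(12, int)
            counts = np.zeros((12, 12), int)
            prev = None
            for lab in seq:
                lab = int(lab)
                if prev is None or lab != prev:
                    occ[lab] += 1
                    if prev is not None:
                        counts[prev, lab] += 1
                    prev = lab
            m = count_transitions(seq)
            np.testing.assert_array_equal(m.counts, counts)
            np.testing.assert_array_equal(m.occurrences, occ)


def _random_matrix(rng, bias=0.0):
    """A plausible individual transition matrix for group comparisons."""
    seq = rng.integers(0, 12, size=120).astype(np.int8)
    m = count_transitions(seq)
    if bias:
        # shift p(idle -> move) by inflating the corresponding count
        i = _label_index("idle")
        j = _label_index("move")
        m.counts[i, j] += int(bias * m.occurrences[i])
    return m


class TestCompareTransitions:
    def test_emits_132_records(self):
        rng = np.random.default_rng(5)
        a = [_random_matrix(rng) for _ in range(8)]
        b = [_random_matrix(rng) for _ in range(8)]
        table = compare_transitions(a, b)
        assert len(table) == 132
        ok = table[~table["skipped"]]
        assert (ok["p_corrected"] <= 1.0).all()
        assert (ok["p_corrected"] >= ok["p_raw"] - 1e-12).all()
        assert set(ok["test"]) <= {"t", "mann-whitney"}

    def test_identical_groups_no_effect(self):
        rng = np.random.default_rng(6)
        mats = [_random_matrix(rng) for _ in range(10)]
        table = compare_transitions(mats, mats)
        ok = table[~table["skipped"]]
        assert (ok["cohens_d"].abs() < 1e-9).all()
        assert (ok["p_corrected"] > 0.9).all()

    def test_large_shift_detected_after_bonferroni(self):
        """A +3 pooled-SD shift in p(idle->move) survives the x132
        correction at n = 16 / 20."""
        rng = np.random.default_rng(7)
        a = [_random_matrix(rng) for _ in range(16)]
        b = [_random_matrix(rng, bias=0.5) for _ in range(20)]
        table = compare_transitions(a, b)
        row = table[(table["from"] == "idle") & (table["to"] == "move")].iloc[0]
        assert not row["skipped"]
        assert row["p_corrected"] < 0.05
        assert row["cohens_d"] < 0  # group b has the larger proportion

    def test_needs_two_individuals_per_group(self):
        rng = np.random.default_rng(8)
        with pytest.raises(ValueError):
            compare_transitions([_random_matrix(rng)], [_random_matrix(rng)])
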