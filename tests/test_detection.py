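"""Event detection: kinematics, dyadic/locomotor/group/dynamic events,
activity, and equivalence with the brute-force per-frame labeller."""

import numpy as np
import pytest

from ethoquartet import AnalysisConfig
from ethoquartet.bruteforce import compare_detector_to_bruteforce
from ethoquartet.detection import compute_activity, detect_all
from ethoquartet.kinematics import speed_cm_s
from ethoquartet.model import AnimalTrack, TrajectorySet
from ethoquartet.simulate import (
    PAIR_POSES,
    SimulationConfig,
    scripted_approach_pair,
    scripted_follow_pair,
    scripted_huddle,
    simulate_pair_with_usv,
    simulate_quartet,
)

from conftest import make_static_pair


def _line_track(n, step_cm, fps=30.0, y=25.0):
    x = 5.0 + step_cm * np.arange(n)
    center = np.column_stack([x, np.full(n, y)])
    return AnimalTrack(
        nose=center + [2.0, 0.0], center=center, tail=center - [2.0, 0.0],
        body_slope=np.full(n, 0.1), detected=np.ones(n, bool),
    )


class TestKinematics:
    def test_one_cm_per_frame_is_30_cm_s(self):
        track = _line_track(10, 1.0)
        speed = speed_cm_s(track, fps=30.0)
        np.testing.assert_allclose(speed, 30.0)

    def test_stationary_speed_zero(self):
        track = _line_track(10, 0.0)
        np.testing.assert_allclose(speed_cm_s(track, fps=30.0), 0.0)

    def test_centred_difference_matches_per_frame_recomputation(self):
        rng = np.random.default_rng(0)
        n = 200
        center = np.cumsum(rng.normal(0, 0.3, size=(n, 2)), axis=0) + 25.0
        track = AnimalTrack(
            nose=center + [2, 0], center=center, tail=center - [2, 0],
            body_slope=np.full(n, 0.1), detected=np.ones(n, bool),
        )
        speed = speed_cm_s(track, fps=30.0)
        for t in range(1, n - 1):
            expected = (
                np.hypot(*(center[t + 1] - center[t - 1])) / 2.0 * 30.0
            )
            assert speed[t] == pytest.approx(expected)

    def test_single_frame_rejected(self):
        track = _line_track(1, 0.0)
        with pytest.raises(ValueError):
            speed_cm_s(track, fps=30.0)


class TestDyadicContacts:
    def test_far_apart_no_events(self, config):
        traj = make_static_pair(separation=30.0)
        eth = detect_all(traj, config)
        for etype in ("contact", "nose-nose", "nose-anogenital",
                      "side-side", "side-side head-to-tail"):
            assert eth.count(etype) == 0

    @pytest.mark.parametrize("kind,expected", [
        ("nose-nose", {"contact", "nose-nose"}),
        ("nose-anogenital", {"contact", "nose-anogenital"}),
        ("side-side", {"contact", "side-side"}),
        ("side-side head-to-tail", {"contact", "side-side head-to-tail"}),
        ("nose-nose & side-side", {"contact", "nose-nose", "side-side"}),
        ("nose-anogenital & side-side head-to-tail",
         {"contact", "nose-anogenital", "side-side head-to-tail"}),
        ("other contact", {"contact"}),
    ])
    def test_pose_library_triggers_exactly_intended_predicates(
        self, config, kind, expected
    ):
        """Each scripted pose produces its intended contact types and no
        other, for the actor playing role A."""
        n = 10
        (ca, tha), (cb, thb), truth = PAIR_POSES[kind]
        assert truth == frozenset(expected)

        def mk(center, theta):
            u = np.array([np.cos(np.radians(theta)), np.sin(np.radians(theta))])
            c = np.tile(np.asarray(center, float) + 25.0, (n, 1))
            return AnimalTrack(
                nose=c + 2.0 * u, center=c, tail=c - 2.0 * u,
                body_slope=np.full(n, 0.1), detected=np.ones(n, bool),
            )

        traj = TrajectorySet(
            {"a": mk(ca, tha), "b": mk(cb, thb)}, fps=30.0,
            arena_size_cm=(50.0, 50.0),
        )
        eth = detect_all(traj, config)
        for etype in ("contact", "nose-nose", "side-side",
                      "side-side head-to-tail"):
            present = eth.count(etype, actor="a") > 0
            assert present == (etype in expected), etype
        assert (eth.count("nose-anogenital", actor="a") > 0) == (
            "nose-anogenital" in expected
        )
        # directionality: role B never actively sniffs A's tail base here
        assert eth.count("nose-anogenital", actor="b") == 0

    def test_threshold_crossing_yields_single_interval(self, config):
        """An approach crossing the contact threshold mid-recording gives
        one contact interval whose frames match the brute-force labels."""
        traj, contact_start = scripted_approach_pair(n_frames=90)
        eth = detect_all(traj, config)
        contacts = eth.by_type("contact", actor="approacher")
        assert len(contacts) == 1
        assert contacts[0].start_frame == contact_start
        assert contacts[0].end_frame == 89
        mism = compare_detector_to_bruteforce(traj, config, eth)
        assert all(v == 0 for v in mism.values()), mism

    def test_symmetric_events_identical_for_both_members(self, config, quartet_sim, quartet_ethogram):
        traj, _, _ = quartet_sim
        n = traj.n_frames
        for a, b in traj.pairs():
            for etype in ("contact", "nose-nose", "side-side",
                          "side-side head-to-tail"):
                np.testing.assert_array_equal(
                    quartet_ethogram.mask(n, etype, actor=a, partner=b),
                    quartet_ethogram.mask(n, etype, actor=b, partner=a),
                )


class TestLocomotorEvents:
    def test_isolated_stationary_animal_idles_throughout(self, config):
        traj = make_static_pair(n_frames=30)
        eth = detect_all(traj, config)
        idles = eth.by_type("single idle", actor="a")
        assert len(idles) == 1
        assert (idles[0].start_frame, idles[0].end_frame) == (0, 29)
        assert eth.count("single move", actor="a") == 0

    def test_constant_speed_animal_moves_throughout(self, config):
        n = 60
        traj = TrajectorySet(
            {"a": _line_track(n, 10.0 / 30.0), "b": _line_track(n, 0.0, y=45.0)},
            fps=30.0, arena_size_cm=(50.0, 50.0),
        )
        eth = detect_all(traj, config)
        moves = eth.by_type("single move", actor="a")
        assert len(moves) == 1
        assert moves[0].duration_frames == n

    def test_alternating_blocks_match_bruteforce_schedule(self, config):
        """5-frame move / still alternation recovers the block structure."""
        n = 60
        step = np.where((np.arange(n) // 5) % 2 == 0, 0.4, 0.0)
        x = 5.0 + np.concatenate([[0.0], np.cumsum(step[:-1])])
        center = np.column_stack([x, np.full(n, 25.0)])
        track = AnimalTrack(
            nose=center + [2, 0], center=center, tail=center - [2, 0],
            body_slope=np.full(n, 0.1), detected=np.ones(n, bool),
        )
        far = _line_track(n, 0.0, y=45.0)
        traj = TrajectorySet({"a": track, "b": far}, fps=30.0,
                             arena_size_cm=(50.0, 50.0))
        eth = detect_all(traj, config)
        mism = compare_detector_to_bruteforce(traj, config, eth)
        assert all(v == 0 for v in mism.values()), mism

    def test_rearing_split_by_contact(self, config, quartet_sim, quartet_ethogram):
        traj, _, truth = quartet_sim
        n = traj.n_frames
        for aid in traj.animals:
            rear = quartet_ethogram.mask(n, "rearing", actor=aid)
            rear_c = quartet_ethogram.mask(n, "rearing in contact", actor=aid)
            assert not np.any(rear & rear_c)
            slope = traj.track(aid).body_slope > config.slope_threshold
            det = traj.track(aid).detected
            np.testing.assert_array_equal(rear | rear_c, slope & det)


class TestGroupEvents:
    def test_pair_in_contact_is_group2_throughout(self, config):
        traj = make_static_pair(separation=1.0)  # overlapping bodies
        eth = detect_all(traj, config)
        for aid in ("a", "b"):
            g2 = eth.by_type("group of 2", actor=aid)
            assert len(g2) == 1
            assert g2[0].duration_frames == traj.n_frames

    def test_scripted_huddle_make_break_events(self, config):
        traj, expected = scripted_huddle()
        eth = detect_all(traj, config)
        for etype, actor, frame in expected:
            events = eth.by_type(etype)
            assert len(events) == 1, etype
            assert events[0].actor == actor
            assert events[0].start_frame == frame

    def test_group_frames_nest_inside_contact(self, config, quartet_sim, quartet_ethogram):
        """Every group-of-2/3 frame is a contact frame and per animal
        contact duration = sum over partner counts k = 1..3."""
        traj, _, _ = quartet_sim
        n = traj.n_frames
        for aid in traj.animals:
            any_contact = np.zeros(n, bool)
            for p in traj.animals:
                if p != aid:
                    any_contact |= quartet_ethogram.mask(
                        n, "contact", actor=aid, partner=p
                    )
            g2 = quartet_ethogram.mask(n, "group of 2", actor=aid)
            g3 = quartet_ethogram.mask(n, "group of 3", actor=aid)
            assert not np.any(g2 & ~any_contact)
            assert not np.any(g3 & ~any_contact)
            # k=3 frames: touching all three others
            k = sum(
                quartet_ethogram.mask(n, "contact", actor=aid, partner=p).astype(int)
                for p in traj.animals if p != aid
            )
            assert int(any_contact.sum()) == int(
                (k == 1).sum() + (k == 2).sum() + (k == 3).sum()
            )

    def test_group3_on_pair_recording_impossible(self, config):
        traj = make_static_pair()
        eth = detect_all(traj, config)
        assert eth.count("group of 3") == 0
        assert eth.count("make group3") == 0


class TestDynamicEvents:
    def test_follow_straight_line(self, config):
        traj = scripted_follow_pair()
        eth = detect_all(traj, config)
        follows = eth.by_type("follow", actor="follower")
        assert len(follows) == 1
        assert follows[0].duration_frames == traj.n_frames
        assert eth.count("follow", actor="leader") == 0

    def test_follow_requires_aligned_heading(self, config):
        traj = scripted_follow_pair(heading_offset_deg=90.0)
        eth = detect_all(traj, config)
        assert eth.count("follow", actor="follower") == 0

    def test_train2_subset_of_follow_and_nose_anogenital(self, config):
        traj = scripted_follow_pair(gap_cm=5.0)
        eth = detect_all(traj, config)
        n = traj.n_frames
        t2 = eth.mask(n, "train2", actor="follower")
        fol = eth.mask(n, "follow", actor="follower")
        ng = eth.mask(n, "nose-anogenital", actor="follower")
        assert t2.any()
        assert not np.any(t2 & ~(fol & ng))

    def test_approach_ends_at_contact_onset(self, config):
        traj, contact_start = scripted_approach_pair()
        eth = detect_all(traj, config)
        approaches = eth.by_type("approach contact", actor="approacher")
        assert len(approaches) == 1
        assert approaches[0].end_frame == contact_start
        contacts = eth.by_type("contact", actor="approacher")
        assert contacts[0].start_frame == approaches[0].end_frame


class TestActivity:
    def test_stationary_animal_zero_distance(self):
        traj = make_static_pair(n_frames=120)
        act = compute_activity(traj, [(0, 119)])
        assert (act["distance_cm"] == 0.0).all()

    def test_one_cm_per_frame_hundred_frame_night(self):
        n = 101
        traj = TrajectorySet(
            {"a": _line_track(n, 0.0), "b": _line_track(n, 0.0, y=45.0)},
            fps=30.0, arena_size_cm=(200.0, 50.0),
        )
        x = 5.0 + 1.0 * np.arange(n)
        center = np.column_stack([x, np.full(n, 25.0)])
        traj.tracks["a"] = AnimalTrack(
            nose=center + [2, 0], center=center, tail=center - [2, 0],
            body_slope=np.full(n, 0.1), detected=np.ones(n, bool),
        )
        act = compute_activity(traj, [(0, 100)])
        a_dist = act.set_index("animal_id").loc["a", "distance_cm"]
        assert a_dist == pytest.approx(100.0)

    def test_reversal_invariance(self, quartet_sim):
        traj, _, _ = quartet_sim
        act = compute_activity(traj, [(0, traj.n_frames - 1)])
        rev = TrajectorySet(
            {
                aid: AnimalTrack(
                    nose=t.nose[::-1].copy(), center=t.center[::-1].copy(),
                    tail=t.tail[::-1].copy(),
                    body_slope=t.body_slope[::-1].copy(),
                    detected=t.detected[::-1].copy(),
                )
                for aid, t in traj.tracks.items()
            },
            fps=traj.fps, arena_size_cm=traj.arena_size_cm,
        )
        act_rev = compute_activity(rev, [(0, traj.n_frames - 1)])
        np.testing.assert_allclose(
            act["distance_cm"].to_numpy(), act_rev["distance_cm"].to_numpy()
        )

    def test_empty_window_rejected(self, quartet_sim):
        traj, _, _ = quartet_sim
        with pytest.raises(ValueError):
            compute_activity(traj, [(10, 5)])


class TestOracleEquivalence:
    """The vectorised detector must equal the naive per-frame labeller."""

    @pytest.mark.parametrize("seed", range(4))
    def test_pair_simulations(self, config, seed):
        traj, _, _, _ = simulate_pair_with_usv(
            SimulationConfig(n_animals=2, duration_s=1000 / 30.0), seed=seed
        )
        mism = compare_detector_to_bruteforce(traj, config)
        assert all(v == 0 for v in mism.values()), mism

    @pytest.mark.parametrize("seed", [100, 101])
    def test_quartet_simulations_with_dropout(self, config, seed):
        traj, _, _ = simulate_quartet(
            SimulationConfig(
                n_animals=4, duration_s=1000 / 30.0, detection_dropout=0.02
            ),
            seed=seed,
        )
        mism = compare_detector_to_bruteforce(traj, config)
        assert all(v == 0 for v in mism.values()), mism
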