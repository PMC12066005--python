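"""Fall scoring: displacement/region criteria, movement, hourly summaries."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from flyfall.core import FlyfallError, HourlySummary, Trajectory, VialGeometry
from flyfall.scoring import (
    FallParams,
    detect_falls,
    hourly_summaries,
    normalize_falls,
    total_movement,
)
from flyfall.synthetic import SyntheticSpec, generate_trajectory, noiseless

from conftest import make_trajectory, random_trajectory


def brute_force_falls(traj, geometry, params):
    """Literal re-statement of the fall criteria, as the oracle."""
    out = []
    dets = traj.detections
    for i in range(len(dets) - 1):
        d0, d1 = dets[i], dets[i + 1]
        crit_a = (d1.time_s - d0.time_s) <= params.max_fall_duration_s
        crit_b = (d1.cy - d0.cy) >= params.y_threshold_px
        crit_c = d1.cy >= geometry.bottom_y - params.bottom_fraction * (
            geometry.bottom_y - geometry.top_y
        )
        crit_d = (not params.require_upper_start) or d0.cy < geometry.top_y + 0.5 * (
            geometry.bottom_y - geometry.top_y
        )
        if crit_a and crit_b and crit_c and crit_d:
            out.append((d0.time_s, d1.time_s, d0.cy, d1.cy))
    return out


def event_tuples(events):
    return [(e.start_time_s, e.end_time_s, e.start_y, e.end_y) for e in events]


class TestDetectFalls:
    def test_rapid_large_drop_is_one_fall(self, geometry):
        # high at 10.00 s, on the floor 0.30 s later: one fall of 280 px
        traj = make_trajectory([(300, 60, 80), (309, 62, 360)])
        events = detect_falls(traj, geometry, FallParams(y_threshold_px=160))
        assert len(events) == 1
        e = events[0]
        assert e.start_time_s == pytest.approx(10.0)
        assert e.delta_y_px == pytest.approx(280.0)
        assert e.delta_y_cm == pytest.approx(280 * 3.0 / 325.0)

    def test_upward_jump_never_scores(self, geometry):
        traj = make_trajectory([(300, 60, 360), (309, 62, 80)])
        for thr in (20, 60, 160):
            assert detect_falls(traj, geometry, FallParams(y_threshold_px=thr)) == []

    def test_threshold_reclassifies_medium_drop(self, geometry):
        # 100 px drop ending on the floor: a fall at 60 px, not at 160 px
        traj = make_trajectory([(0, 60, 260), (9, 60, 360)])
        assert len(detect_falls(traj, geometry, FallParams(y_threshold_px=60))) == 1
        assert detect_falls(traj, geometry, FallParams(y_threshold_px=160)) == []

    def test_slow_descent_not_a_fall(self, geometry):
        # same displacement but 2 s elapsed: not rapid
        traj = make_trajectory([(0, 60, 80), (60, 60, 360)])
        assert detect_falls(traj, geometry, FallParams()) == []

    def test_end_above_bottom_region_not_a_fall(self, geometry):
        # 100 px drop ending mid-vial (above the bottom quarter)
        traj = make_trajectory([(0, 60, 100), (9, 60, 200)])
        assert detect_falls(traj, geometry, FallParams(y_threshold_px=60)) == []

    def test_require_upper_start_filters_low_starts(self, geometry):
        # starts below the half-height line (212.5): scored only when the
        # upper-start requirement is off
        traj = make_trajectory([(0, 60, 250), (9, 60, 360)])
        loose = FallParams(y_threshold_px=60, require_upper_start=False)
        strict = FallParams(y_threshold_px=60, require_upper_start=True)
        assert len(detect_falls(traj, geometry, loose)) == 1
        assert detect_falls(traj, geometry, strict) == []

    def test_empty_trajectory_yields_no_events(self, geometry):
        traj = Trajectory(source_id="x", fps=30, detections=[])
        assert detect_falls(traj, geometry, FallParams()) == []

    @pytest.mark.parametrize("seed", range(12))
    def test_agrees_with_brute_force_on_random_trajectories(self, seed, geometry):
        rng = np.random.default_rng(seed)
        traj = random_trajectory(rng, geometry, n=80)
        params = FallParams(
            y_threshold_px=float(rng.choice([40, 60, 160])),
            require_upper_start=bool(rng.integers(2)),
        )
        assert event_tuples(detect_falls(traj, geometry, params)) == brute_force_falls(
            traj, geometry, params
        )

    def test_threshold_monotonicity(self, geometry):
        spec = SyntheticSpec(seed=21, duration_s=120.0, n_falls=6)
        traj, _ = generate_trajectory(spec)
        counts = [
            len(detect_falls(traj, geometry, FallParams(y_threshold_px=thr)))
            for thr in range(20, 321, 20)
        ]
        assert counts == sorted(counts, reverse=True)

    def test_programmed_falls_recovered_exactly(self, geometry):
        spec = noiseless(SyntheticSpec(seed=33, duration_s=180.0, n_falls=6))
        traj, truth = generate_trajectory(spec)
        for thr in (60.0, 160.0):
            events = detect_falls(traj, geometry, FallParams(y_threshold_px=thr))
            assert [e.start_time_s for e in events] == [
                t.start_time_s for t in truth
            ]


class TestTotalMovement:
    def test_three_four_five(self):
        assert total_movement(make_trajectory([(0, 0, 0), (1, 3, 4)])) == 5.0

    def test_single_detection_is_zero(self):
        assert total_movement(make_trajectory([(0, 10, 10)])) == 0.0

    def test_diagonal_steps(self):
        traj = make_trajectory([(0, 0, 0), (1, 1, 1), (2, 2, 2)])
        assert total_movement(traj) == pytest.approx(2 * np.sqrt(2), abs=1e-4)

    def test_gap_spanning_pairs_included(self):
        with_gap = make_trajectory([(0, 0, 0), (100, 3, 4)])
        assert total_movement(with_gap) == 5.0

    @settings(deadline=None, derandomize=True)
    @given(
        dx=st.floats(-1000, 1000),
        dy=st.floats(-1000, 1000),
        seed=st.integers(0, 100),
    )
    def test_translation_invariance(self, dx, dy, seed):
        rng = np.random.default_rng(seed)
        pts = [(i, float(x), float(y)) for i, (x, y) in
               enumerate(rng.uniform(0, 300, (10, 2)))]
        shifted = [(f, x + dx, y + dy) for f, x, y in pts]
        assert total_movement(make_trajectory(pts)) == pytest.approx(
            total_movement(make_trajectory(shifted)), rel=1e-9, abs=1e-6
        )


class TestHourlySummaries:
    def _traj_events(self, geometry):
        spec = noiseless(SyntheticSpec(seed=4, duration_s=30.0, n_falls=2))
        return generate_trajectory(spec)

    def test_events_bin_by_start_hour(self, geometry):
        traj = make_trajectory([(0, 10, 100)])
        events = [
            _event(3601.0, geometry),
            _event(7300.0, geometry),
        ]
        out = hourly_summaries(traj, events, hours={1, 2})
        assert [(s.hour_index, s.falls) for s in out] == [(1, 1), (2, 1)]

    def test_bins_are_half_open(self, geometry):
        out = hourly_summaries(
            make_trajectory([(0, 10, 100)]),
            [_event(7200.0, geometry)],
            hours={1, 2},
        )
        assert {s.hour_index: s.falls for s in out} == {1: 0, 2: 1}

    def test_empty_event_list(self, geometry):
        traj, _ = self._traj_events(geometry)
        out = hourly_summaries(traj, [], hours={0})
        assert out[0].falls == 0
        assert out[0].movement_px == pytest.approx(total_movement(traj))

    def test_movement_binned_by_earlier_member(self, geometry):
        fps = 30.0
        f_before = int(3600 * fps) - 1   # last frame of hour 0
        traj = make_trajectory(
            [(f_before, 0, 100), (f_before + 1, 3, 104)], fps=fps
        )
        out = hourly_summaries(traj, [], hours={0, 1})
        by_hour = {s.hour_index: s.movement_px for s in out}
        assert by_hour[0] == 5.0 and by_hour[1] == 0.0


def _event(t, geometry):
    from flyfall.core import make_fall_event

    return make_fall_event(t, t + 0.3, 100.0, 360.0, geometry)


class TestNormalizeFalls:
    def test_hand_example(self):
        out = normalize_falls(
            [
                HourlySummary(hour_index=0, falls=2, movement_px=100.0),
                HourlySummary(hour_index=1, falls=4, movement_px=200.0),
            ]
        )
        # relative units 100/150 and 200/150; both hours normalize to 3.0
        assert [s.normalized_falls for s in out] == pytest.approx([3.0, 3.0])

    def test_uniform_movement_keeps_raw_counts(self):
        out = normalize_falls(
            [HourlySummary(hour_index=h, falls=h + 1, movement_px=50.0) for h in range(3)]
        )
        assert [s.normalized_falls for s in out] == pytest.approx([1.0, 2.0, 3.0])

    def test_zero_falls_zero_movement_is_zero(self):
        out = normalize_falls([HourlySummary(hour_index=0, falls=0, movement_px=0.0)])
        assert out[0].normalized_falls == 0.0

    def test_falls_without_movement_is_inconsistent(self):
        with pytest.raises(FlyfallError):
            normalize_falls([HourlySummary(hour_index=0, falls=3, movement_px=0.0)])
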