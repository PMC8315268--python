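"""Lip-area formulas, epoch extraction, and maximum movement speed."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from prespeech.errors import (
    EpochRangeError,
    InsufficientDataError,
    ValidationError,
)
from prespeech.kinematics import (
    anchor_index,
    extract_epoch,
    lip_area,
    max_speed,
    shoelace_area,
)
from tests.conftest import make_track

DIAMOND = [(0.0, 0.0), (1.0, 1.0), (2.0, 0.0), (1.0, -1.0)]
LIPLIKE = [(0.0, 0.0), (2.0, 1.0), (4.0, 0.0), (2.0, -1.0)]


def random_extremal_quads(rng, n):
    """Quads whose corners are the x-extrema and top/bottom the y-extrema."""
    x0 = rng.uniform(-50, 50, n)
    x1 = x0 + rng.uniform(0.1, 60, n)
    y0 = rng.uniform(-50, 50, n)
    y1 = y0 + rng.uniform(0.1, 60, n)
    q = np.empty((n, 4, 2))
    q[:, 0] = np.column_stack([x0, rng.uniform(y0, y1)])
    q[:, 1] = np.column_stack([rng.uniform(x0, x1), y1])
    q[:, 2] = np.column_stack([x1, rng.uniform(y0, y1)])
    q[:, 3] = np.column_stack([rng.uniform(x0, x1), y0])
    return q


class TestLipArea:
    def test_coincident_points_give_zero(self):
        assert lip_area([(3.0, 4.0)] * 4) == 0.0

    def test_diamond_fixture(self):
        # four right triangles of 0.5 plus a 2x2... rectangle: 4*0.5 + 2*2
        assert lip_area(DIAMOND) == pytest.approx(6.0, abs=0)
        assert shoelace_area(DIAMOND) == pytest.approx(2.0, abs=0)

    def test_liplike_fixture(self):
        # 4 triangles of area 1 plus a 4x2 rectangle
        assert lip_area(LIPLIKE) == pytest.approx(12.0, abs=0)
        assert shoelace_area(LIPLIKE) == pytest.approx(4.0, abs=0)

    def test_box_identity_on_extremal_quads(self):
        rng = np.random.default_rng(7)
        q = random_extremal_quads(rng, 500)
        box = (q[:, 2, 0] - q[:, 0, 0]) * (q[:, 1, 1] - q[:, 3, 1])
        lhs = lip_area(q)
        rhs = 2.0 * box - shoelace_area(q)
        np.testing.assert_allclose(lhs, rhs, rtol=1e-9)
        assert np.all(lhs >= shoelace_area(q) - 1e-9)

    def test_translation_invariance(self):
        rng = np.random.default_rng(8)
        q = random_extremal_quads(rng, 50)
        shift = q + rng.uniform(-1000, 1000, (50, 1, 2))
        np.testing.assert_allclose(lip_area(q), lip_area(shift), rtol=1e-9)

    def test_shoelace_degenerate_collinear(self):
        assert shoelace_area([(0, 0), (1, 0), (2, 0), (3, 0)]) == 0.0

    def test_shoelace_against_direct_formula(self):
        rng = np.random.default_rng(9)
        q = random_extremal_quads(rng, 100)
        x, y = q[..., 0], q[..., 1]
        direct = 0.5 * np.abs(
            np.sum(x * (np.roll(y, -1, axis=-1) - np.roll(y, 1, axis=-1)), axis=-1)
        )
        np.testing.assert_allclose(shoelace_area(q), direct, rtol=1e-12)

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(
        x0=st.floats(-100, 100),
        dx=st.floats(0.1, 100),
        y0=st.floats(-100, 100),
        dy=st.floats(0.1, 100),
        fx=st.tuples(*[st.floats(0, 1)] * 4),
        shift=st.tuples(st.floats(-1e4, 1e4), st.floats(-1e4, 1e4)),
    )
    def test_identity_and_translation_hold_for_any_extremal_quad(
        self, x0, dx, y0, dy, fx, shift
    ):
        x1, y1 = x0 + dx, y0 + dy
        q = np.array(
            [
                [x0, y0 + fx[0] * dy],
                [x0 + fx[1] * dx, y1],
                [x1, y0 + fx[2] * dy],
                [x0 + fx[3] * dx, y0],
            ]
        )
        box = dx * dy
        assert lip_area(q) == pytest.approx(2 * box - shoelace_area(q), rel=1e-9, abs=1e-9)
        assert lip_area(q + np.asarray(shift)) == pytest.approx(
            lip_area(q), rel=1e-9, abs=1e-9
        )

    def test_non_finite_coordinate_rejected(self):
        q = np.array(DIAMOND)
        q[1, 0] = np.nan
        with pytest.raises(ValidationError):
            lip_area(q)


class TestExtractEpoch:
    def test_constant_track(self):
        track = make_track(areas=np.full(200, 150.0))
        ep = extract_epoch(track, onset_ms=5000.0, utterance_id="u")
        assert ep.n_frames == 90
        np.testing.assert_allclose(ep.areas, 150.0)
        assert not ep.missing_mask.any()

    def test_onset_at_3000_covers_frames_0_to_89(self):
        areas = np.arange(120.0) + 100.0  # area == 100 + frame index
        track = make_track(areas=areas)
        ep = extract_epoch(track, onset_ms=3000.0)
        # brute-force: the last frame strictly before 3000 ms is frame 89
        ts = track.timestamp_ms
        expect_anchor = max(i for i in range(len(ts)) if ts[i] < 3000.0 - 1e-9)
        assert expect_anchor == 89
        np.testing.assert_allclose(ep.areas, areas[:90])

    def test_anchor_index_boundary(self):
        ts = np.arange(100) * (1000.0 / 30.0)
        assert anchor_index(ts, 3000.0) == 89
        assert anchor_index(ts, 3000.02) == 90

    def test_interpolation_of_short_dropout(self):
        areas = np.linspace(100, 200, 120)
        success = np.ones(120, bool)
        success[50] = False
        track = make_track(areas=areas, success=success)
        ep = extract_epoch(track, onset_ms=4000.0, fill_policy="interpolate")
        ts_idx = 50 - (anchor_index(track.timestamp_ms, 4000.0) - 89)
        assert ep.missing_mask[ts_idx]
        # linear interpolation of a linear signal restores it exactly
        np.testing.assert_allclose(ep.areas[ts_idx], areas[50], rtol=1e-12)

    def test_long_dropout_stays_missing(self):
        success = np.ones(120, bool)
        success[40:46] = False  # 6 > max_fill
        track = make_track(areas=np.full(120, 100.0), success=success)
        ep = extract_epoch(track, onset_ms=4000.0)
        assert np.isnan(ep.areas).sum() == 6

    def test_exclude_policy_keeps_gaps(self):
        success = np.ones(120, bool)
        success[50] = False
        track = make_track(areas=np.full(120, 100.0), success=success)
        ep = extract_epoch(track, onset_ms=4000.0, fill_policy="exclude")
        assert np.isnan(ep.areas).sum() == 1

    def test_window_before_track_is_partial(self):
        track = make_track(areas=np.full(60, 100.0))
        ep = extract_epoch(track, onset_ms=1000.0)
        assert ep.missing_mask[:60].all()
        assert np.isfinite(ep.areas[-29:]).all()

    def test_onset_before_track_raises(self):
        track = make_track(areas=np.full(60, 100.0))
        with pytest.raises(EpochRangeError):
            extract_epoch(track, onset_ms=-5.0)


def _traj(areas):
    from prespeech.core import AreaTrajectory

    areas = np.asarray(areas, float)
    return AreaTrajectory("u", areas, np.zeros(areas.size, bool))


class TestMaxSpeed:
    def test_constant_trajectory(self):
        s = max_speed(_traj(np.full(90, 42.0)))
        assert s.max_speed == 0.0

    def test_unit_ramp_gives_30_per_second(self):
        areas = np.full(90, 100.0)
        areas[-16:] = 100.0 - np.arange(16)  # final 15 steps of -1 each
        s = max_speed(_traj(areas))
        assert s.max_speed == pytest.approx(30.0)

    def test_sawtooth_jump_located(self):
        areas = np.full(90, 50.0)
        areas[74:] = 50.0 + np.cumsum([(-1.0) ** k for k in range(16)])
        areas[82] = areas[81] + 2.0  # one +2 jump among +-1 steps
        s = max_speed(_traj(areas))
        assert s.max_speed == pytest.approx(60.0)
        assert s.argmax_frame == 82

    def test_offset_invariance_and_scaling(self):
        rng = np.random.default_rng(5)
        areas = rng.uniform(50, 150, 90)
        base = max_speed(_traj(areas)).max_speed
        assert max_speed(_traj(areas + 500.0)).max_speed == pytest.approx(base)
        assert max_speed(_traj(areas * 3.0)).max_speed == pytest.approx(3 * base)

    def test_missing_frames_in_window_rejected(self):
        areas = np.full(90, 10.0)
        areas[85] = np.nan
        from prespeech.core import AreaTrajectory

        traj = AreaTrajectory("u", areas, np.isnan(areas))
        with pytest.raises(InsufficientDataError):
            max_speed(traj)

    def test_short_trajectory_rejected(self):
        with pytest.raises(InsufficientDataError):
            max_speed(_traj(np.zeros(10)))
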