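"""Decision-layer unit suite: preprocessing, the 0.7/10-frame trigger and
histogram tie-breaks, line generation, well partitioning, pulse scheduling
and termination detection."""

import numpy as np
import pytest

from optoloop import control_loop as cl
from optoloop.errors import ConfigError, InvalidGeometryError


def prob_map(peak_yx=None, peak=0.9):
    m = np.zeros((86, 86), dtype=np.float32)
    if peak_yx is not None:
        m[peak_yx] = peak
    return m


class TestPreprocess:
    def test_constant_pack_equal_to_background_zeroes_out(self):
        pack = np.full((5, 100, 100), 3.7, np.float32)
        window, bg = cl.preprocess(pack, pack[-1].copy())
        assert np.abs(window).max() == 0.0
        assert np.array_equal(bg, pack[-1])

    def test_output_is_86_square(self):
        window, _ = cl.preprocess(np.random.rand(5, 100, 100).astype(np.float32), None)
        assert window.shape == (5, 86, 86)

    def test_gaussian_kernel_weights_on_impulse(self):
        pack = np.zeros((5, 100, 100), np.float32)
        pack[0, 50, 50] = 1.0
        window, _ = cl.preprocess(pack, np.zeros((100, 100), np.float32))
        o = cl.crop_offset()
        patch = window[0, 50 - o - 1 : 50 - o + 2, 50 - o - 1 : 50 - o + 2]
        np.testing.assert_allclose(patch, cl.GAUSS3, atol=1e-7)

    def test_wrong_shape_rejected(self):
        with pytest.raises(ConfigError):
            cl.preprocess(np.zeros((5, 90, 90), np.float32), None)


class TestTrigger:
    def test_ten_frames_above_threshold_fire(self):
        hist = cl.CoreHistogram()
        for _ in range(9):
            assert cl.update_and_decide(hist, prob_map((40, 41), 0.75)) is None
        assert cl.update_and_decide(hist, prob_map((40, 41), 0.75)) == (40, 41)

    def test_mean_at_069_does_not_fire(self):
        hist = cl.CoreHistogram()
        out = None
        for _ in range(10):
            out = cl.update_and_decide(hist, prob_map((40, 41), 0.69))
        assert out is None

    def test_exactly_07_does_not_fire(self):
        # threshold is strictly greater-than
        hist = cl.CoreHistogram()
        out = None
        for _ in range(10):
            out = cl.update_and_decide(hist, prob_map((40, 41), 0.7))
        assert out is None

    def test_nine_high_frames_insufficient(self):
        hist = cl.CoreHistogram()
        for _ in range(9):
            assert cl.update_and_decide(hist, prob_map((40, 41), 0.99)) is None

    def test_modal_tie_goes_to_most_recent(self):
        hist = cl.CoreHistogram()
        coords = [(10, 10)] * 5 + [(50, 50)] * 5
        out = None
        for c in coords:
            out = cl.update_and_decide(hist, prob_map(c, 0.9))
        assert out == (50, 50)

    def test_nan_frame_dropped(self):
        hist = cl.CoreHistogram()
        bad = prob_map((40, 41), 0.9)
        bad[0, 0] = np.nan
        assert cl.update_and_decide(hist, bad) is None
        assert len(hist.buffer) == 0

    def test_sliding_window_recovers_after_low_frames(self):
        hist = cl.CoreHistogram()
        for _ in range(10):
            cl.update_and_decide(hist, prob_map((40, 41), 0.2))
        out = None
        for _ in range(10):
            out = cl.update_and_decide(hist, prob_map((40, 41), 0.9))
        assert out == (40, 41)


def disc_mask(n=100, r=48.8):
    yy, xx = np.mgrid[:n, :n]
    return (yy - (n - 1) / 2) ** 2 + (xx - (n - 1) / 2) ** 2 <= r**2


class TestBorderLine:
    def test_center_core_path_length_is_radius(self):
        mask = disc_mask(101, 40.0)
        path = cl.nearest_border_line((50, 50), mask)
        length = np.hypot(*(path[-1] - path[0]))
        assert length == pytest.approx(40.0, abs=1.5)
        # the tie among all directions breaks toward the smallest angle from
        # the +x axis (the discrete tie set sits just off-axis)
        assert path[-1][1] > 50 and abs(int(path[-1][0]) - 50) <= 2

    def test_core_near_border_short_path(self):
        mask = disc_mask(101, 40.0)
        path = cl.nearest_border_line((50, 88), mask)
        assert len(path) <= 3

    def test_paths_connected_and_reach_border(self):
        mask = disc_mask(100)
        rng = np.random.default_rng(0)
        inside = np.argwhere(mask)
        for idx in rng.choice(len(inside), size=100, replace=False):
            cy, cx = inside[idx]
            path = cl.nearest_border_line((cy, cx), mask)
            assert (np.abs(np.diff(path, axis=0)) <= 1).all()  # 8-connected
            end = path[-1]
            nb = mask[max(0, end[0] - 1) : end[0] + 2, max(0, end[1] - 1) : end[1] + 2]
            assert (~nb).any()  # endpoint adjacent to a non-conducting pixel

    def test_dotted_line_pitch(self):
        mask = disc_mask(101, 40.0)
        solid = cl.nearest_border_line((50, 50), mask)
        dotted = cl.nearest_border_line((50, 50), mask, dot_pitch=3)
        assert len(dotted) == len(solid[::3])

    def test_core_outside_mask_rejected(self):
        with pytest.raises(InvalidGeometryError):
            cl.nearest_border_line((0, 0), disc_mask(101, 40.0))


class TestWells:
    def test_disabled_well_returns_none(self):
        layout = cl.quadrant_layout(86, disabled=(2,))
        dec = cl.MultiWellDecider(layout)
        m = np.zeros((86, 86), np.float32)
        for yx in [(10, 10), (10, 60), (60, 10), (60, 60)]:
            m[yx] = 0.9
        out = {}
        for _ in range(10):
            out = dec.update(m)
        assert out[0] == (10, 10) and out[1] == (10, 60) and out[3] == (60, 60)
        assert out[2] is None

    def test_empty_map_none_everywhere(self):
        dec = cl.MultiWellDecider(cl.quadrant_layout(86))
        out = {}
        for _ in range(10):
            out = dec.update(np.zeros((86, 86), np.float32))
        assert all(v is None for v in out.values())

    def test_four_simultaneous_detections(self):
        dec = cl.MultiWellDecider(cl.quadrant_layout(86))
        m = np.zeros((86, 86), np.float32)
        for yx in [(12, 12), (12, 70), (70, 12), (70, 70)]:
            m[yx] = 0.95
        out = {}
        for _ in range(10):
            out = dec.update(m)
        assert all(v is not None for v in out.values())

    def test_overlapping_zones_rejected(self):
        bad = [cl.Well(0, 0, 50, 0, 50), cl.Well(1, 40, 86, 40, 86)]
        with pytest.raises(ConfigError):
            cl.MultiWellDecider(bad)


class TestSchedule:
    def test_single_trigger_timing(self):
        ev = cl.schedule(cl.TimingPolicy(), [0.0])
        assert ev == [(3000.0, "pulse_on"), (3500.0, "pulse_off"), (6500.0, "re-arm")]

    def test_zero_pulse_duration_rejected(self):
        with pytest.raises(ConfigError):
            cl.TimingPolicy(pulse_ms=0.0)

    def test_trigger_inside_blanking_suppressed(self):
        ev = cl.schedule(cl.TimingPolicy(), [0.0, 4000.0, 7000.0])
        kinds = [k for _, k in ev]
        assert kinds.count("suppressed") == 1
        assert (4000.0, "suppressed") in ev
        # the third trigger lands after re-arm and schedules normally
        assert (10000.0, "pulse_on") in ev

    def test_non_monotone_triggers_rejected(self):
        with pytest.raises(ConfigError):
            cl.schedule(cl.TimingPolicy(), [100.0, 50.0])


class TestTermination:
    def test_all_zero_stream_terminates_after_hold(self):
        det = cl.TerminationDetector(hold_ms=1000.0)
        w = np.zeros((5, 86, 86), np.float32)
        fired = [det.update(t, w, None, armed=True) for t in np.arange(0, 2000, 40)]
        assert not fired[0] and fired[-1]

    def test_loud_stream_with_decisions_never_terminates(self):
        det = cl.TerminationDetector(hold_ms=1000.0)
        w = np.full((5, 86, 86), 0.5, np.float32)
        for t in np.arange(0, 5000, 40):
            assert not det.update(t, w, (40, 40), armed=True)

    def test_paced_rhythm_without_decisions_terminates(self):
        # planar-wave analogue: loud windows, armed detector, no decisions
        det = cl.TerminationDetector(hold_ms=1000.0)
        w = np.full((5, 86, 86), 0.5, np.float32)
        fired = [det.update(t, w, None, armed=True) for t in np.arange(0, 2000, 40)]
        assert fired[-1]

    def test_blanking_does_not_fake_termination(self):
        # loud spiral during blanking: not armed, no decisions -> no fire
        det = cl.TerminationDetector(hold_ms=1000.0)
        w = np.full((5, 86, 86), 0.5, np.float32)
        for t in np.arange(0, 3000, 40):
            assert not det.update(t, w, None, armed=False)
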