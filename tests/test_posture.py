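"""Epoch alignment, mounting correction, classification and summaries."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dualact import (
    EpochSeries,
    PipelineConfig,
    PostureScript,
    Segment,
    align_epochs,
    classify_epoch,
    classify_frame,
    correct_lowerleg_pitch,
    generate_pair,
    summarize,
    timeline_export,
)
from dualact.cli import run_pipeline
from dualact.errors import AlignmentError, CorrectionWarning
from dualact.posture import LABELS, LYING, MOVING, SITTING, STANDING, DualEpochFrame


def _series(site, n, start_time=0.0, pitch=-10.0, enmo=0.0, epoch_length=5.0):
    return EpochSeries(
        site=site,
        epoch_length=epoch_length,
        epoch_starts=np.arange(n) * epoch_length,
        mean_pitch=np.full(n, float(pitch)),
        mean_enmo=np.full(n, float(enmo)),
        start_time=start_time,
    )


def _frame(thigh_pitch, lowerleg_pitch, enmo=None, labels=None):
    n = len(thigh_pitch)
    return DualEpochFrame(
        epoch_starts=np.arange(n) * 5.0,
        epoch_length=5.0,
        thigh_pitch=np.asarray(thigh_pitch, dtype=float),
        lowerleg_pitch=np.asarray(lowerleg_pitch, dtype=float),
        lowerleg_enmo=np.zeros(n) if enmo is None else np.asarray(enmo, dtype=float),
        labels=None if labels is None else np.array(labels, dtype=object),
    )


class TestAlignEpochs:
    def test_identical_series_fully_paired(self):
        frame = align_epochs(_series("thigh", 100), _series("lower_leg", 100))
        assert frame.n_epochs == 100

    def test_late_lowerleg_drops_first_thigh_epoch(self):
        frame = align_epochs(
            _series("thigh", 100), _series("lower_leg", 99, start_time=5.0)
        )
        assert frame.n_epochs == 99
        assert frame.epoch_starts[0] == 5.0

    def test_fractional_offset_matches_brute_force(self):
        thigh = _series("thigh", 50)
        lower = _series("lower_leg", 50, start_time=2.4)
        frame = align_epochs(thigh, lower)
        # brute force: anchor on lower leg, pair nearest thigh epoch within 2.5 s
        expected = 0
        for s in lower.abs_starts():
            if np.min(np.abs(thigh.abs_starts() - s)) <= 2.5:
                expected += 1
        assert frame.n_epochs == expected > 0

    def test_disjoint_series_raise(self):
        with pytest.raises(AlignmentError):
            align_epochs(_series("thigh", 10), _series("lower_leg", 10, start_time=1000.0))

    def test_site_order_enforced(self):
        with pytest.raises(AlignmentError):
            align_epochs(_series("lower_leg", 10), _series("thigh", 10))


class TestCorrection:
    def test_already_anchored_is_fixed_point(self):
        f = _frame([-85, -85], [-90.0, -60.0])
        out = correct_lowerleg_pitch(f)
        assert out.correction_offset == 0.0
        assert np.array_equal(out.lowerleg_pitch, f.lowerleg_pitch)

    def test_ten_degree_offset_arithmetic(self):
        f = _frame([-85, -85, -85], [-80.0, -20.0, -70.0])
        out = correct_lowerleg_pitch(f)
        assert out.correction_offset == pytest.approx(10.0)
        assert out.lowerleg_pitch[0] == -90.0
        assert out.lowerleg_pitch[1] == pytest.approx(-30.0)

    def test_minimum_is_exactly_minus_90(self):
        rng = np.random.default_rng(4)
        f = _frame(np.full(40, -85.0), rng.uniform(-83.3, 10.7, 40))
        out = correct_lowerleg_pitch(f)
        assert float(np.min(out.lowerleg_pitch)) == -90.0

    def test_idempotent(self):
        f = _frame(np.full(10, -85.0), np.linspace(-77.7, 3.3, 10))
        once = correct_lowerleg_pitch(f)
        twice = correct_lowerleg_pitch(once)
        assert np.array_equal(once.lowerleg_pitch, twice.lowerleg_pitch)
        assert twice.correction_offset == once.correction_offset

    def test_injected_mounting_offset_recovered(self):
        script = PostureScript(
            segments=[
                Segment("lying", 60.0),
                Segment("sitting", 60.0),
                Segment("standing", 30.0),
                Segment("moving", 30.0),
            ],
            mounting_offset_lowerleg=12.0,
            seed=5,
        )
        thigh, lower, _ = generate_pair(script)
        frame, _ = run_pipeline(thigh, lower)
        assert frame.correction_offset == pytest.approx(12.0, abs=1.0)

    def test_no_upright_epoch_warns(self):
        f = _frame(np.full(8, -10.0), np.full(8, -20.0))
        with pytest.warns(CorrectionWarning):
            out = correct_lowerleg_pitch(f)
        assert out.warnings_log


class TestClassifyEpoch:
    @pytest.mark.parametrize(
        "theta_t,theta_l,enmo,expected",
        [
            (-5, -10, 2, LYING),
            (-10, -80, 3, SITTING),
            (-85, -88, 20, MOVING),
            (-85, -88, 13, STANDING),  # strict > 13 mg
            (-85, -88, 13.0001, MOVING),
            (-85, -10, 0, LYING),  # vertical thigh + horizontal shank -> lying
            (-45, -45, 0, STANDING),  # boundary: <= -a counts as upright
        ],
    )
    def test_rule_table(self, theta_t, theta_l, enmo, expected):
        assert classify_epoch(theta_t, theta_l, enmo) == expected

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError):
            classify_epoch(np.nan, -80, 0)

    @settings(derandomize=True, max_examples=100)
    @given(
        theta_t=st.floats(-90, 90),
        theta_l=st.floats(-90, 90),
        enmo=st.floats(0, 500),
    )
    def test_every_epoch_gets_exactly_one_label(self, theta_t, theta_l, enmo):
        assert classify_epoch(theta_t, theta_l, enmo) in LABELS

    def test_standing_flips_to_moving_exactly_once(self, config):
        labels = [classify_epoch(-85, -85, e / 10.0) for e in range(0, 400)]
        flips = sum(a != b for a, b in zip(labels, labels[1:]))
        assert flips == 1
        boundary = max(e / 10.0 for e in range(400)
                       if classify_epoch(-85, -85, e / 10.0) == STANDING)
        assert boundary == config.enmo_moving_threshold

    def test_vectorized_matches_scalar(self):
        rng = np.random.default_rng(8)
        f = _frame(
            rng.uniform(-90, 90, 200), rng.uniform(-90, 90, 200),
            enmo=rng.uniform(0, 40, 200),
        )
        out = classify_frame(f)
        scalar = [
            classify_epoch(a, b, c)
            for a, b, c in zip(f.thigh_pitch, f.lowerleg_pitch, f.lowerleg_enmo)
        ]
        assert list(out.labels) == scalar


class TestSummarize:
    def test_one_of_each_label(self):
        f = _frame([-5, -10, -85, -85], [-10, -80, -88, -88], enmo=[0, 0, 0, 20],
                   labels=list(LABELS))
        s = summarize(f)
        assert (s.pct_lying, s.pct_sitting, s.pct_standing, s.pct_moving) == (25, 25, 25, 25)
        assert s.total_hours == pytest.approx(20 / 3600)

    def test_all_lying(self):
        f = _frame([-5] * 8, [-10] * 8, labels=[LYING] * 8)
        s = summarize(f)
        assert s.pct_lying == 100.0
        assert s.pct_sitting == s.pct_standing == s.pct_moving == 0.0

    def test_percentages_sum_to_100(self):
        rng = np.random.default_rng(9)
        labels = rng.choice(LABELS, 97)
        f = _frame(np.zeros(97), np.zeros(97), labels=labels)
        s = summarize(f)
        assert s.pct_lying + s.pct_sitting + s.pct_standing + s.pct_moving == pytest.approx(
            100.0, abs=1e-9
        )

    def test_empty_or_unlabeled_rejected(self):
        with pytest.raises(ValueError):
            summarize(_frame([-5], [-10]))


class TestTimeline:
    def test_runs_from_short_sequence(self):
        f = _frame(np.zeros(5), np.zeros(5), labels=[LYING, LYING, SITTING, SITTING, SITTING])
        runs = timeline_export(f)
        assert runs == [(0.0, 10.0, LYING), (10.0, 25.0, SITTING)]

    def test_single_epoch_single_run(self):
        f = _frame([0.0], [0.0], labels=[STANDING])
        assert timeline_export(f) == [(0.0, 5.0, STANDING)]

    @settings(derandomize=True, max_examples=50)
    @given(st.lists(st.sampled_from(LABELS), min_size=1, max_size=60))
    def test_decode_inverts_encode(self, labels):
        f = _frame(np.zeros(len(labels)), np.zeros(len(labels)), labels=labels)
        runs = timeline_export(f)
        decoded = []
        for start, end, lab in runs:
            decoded += [lab] * int(round((end - start) / 5.0))
        assert decoded == labels
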