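"""Phase demarcation: smoothing, derivatives, threshold learning, segmentation."""

from datetime import date, timedelta

import numpy as np
import pytest

from tweetphases.io_ingest import DailySeries
from tweetphases.phase_detect import (
    DerivativeSeries,
    ThresholdPair,
    compute_derivatives,
    detect_phase_starts,
    detect_phases,
    identity_smooth,
    learn_thresholds,
    lowpass_smooth,
    segment_phases,
)

D0 = date(2020, 1, 1)


def day(i: int) -> date:
    return D0 + timedelta(days=i)


class TestLowpassSmooth:
    def test_constant_series_unchanged(self):
        s = DailySeries(D0, [5.0] * 8)
        out = lowpass_smooth(s)
        assert np.max(np.abs(out.values - 5.0)) < 1e-9

    def test_nyquist_component_attenuated_by_half(self):
        alt = np.tile([0.0, 10.0], 16)
        out = lowpass_smooth(DailySeries(D0, alt))
        fin = np.fft.rfft(alt)
        fout = np.fft.rfft(out.values)
        assert abs(fout[-1]) <= 0.5 * abs(fin[-1])

    def test_impulse_total_mass_preserved(self):
        imp = np.zeros(64)
        imp[32] = 100.0
        out = lowpass_smooth(DailySeries(D0, imp))
        assert out.values.sum() == pytest.approx(100.0, rel=1e-6)

    def test_short_series_raises_length_error(self):
        with pytest.raises(ValueError, match="length"):
            lowpass_smooth(DailySeries(D0, [1.0] * 6))

    def test_cutoff_outside_unit_interval_rejected(self):
        s = DailySeries(D0, [1.0] * 10)
        with pytest.raises(ValueError):
            lowpass_smooth(s, cutoff=1.5)


class TestDerivatives:
    def test_constant_series_all_zero(self):
        der = compute_derivatives(identity_smooth(DailySeries(D0, [4.0] * 6)))
        assert np.allclose(der.velocity[1:], 0)
        assert np.allclose(der.acceleration[2:], 0)
        assert np.isnan(der.velocity[0])
        assert np.isnan(der.acceleration[:2]).all()

    def test_linear_ramp(self):
        der = compute_derivatives(identity_smooth(DailySeries(D0, [0, 2, 4, 6])))
        assert list(der.velocity[1:]) == [2, 2, 2]
        assert list(der.acceleration[2:]) == [0, 0]

    def test_closed_form_three_points(self):
        der = compute_derivatives(identity_smooth(DailySeries(D0, [10, 30, 70])))
        assert der.velocity[1] == 20
        assert der.velocity[2] == 40
        assert der.acceleration[2] == 20

    def test_too_short_raises(self):
        with pytest.raises(ValueError):
            compute_derivatives(identity_smooth(DailySeries(D0, [1, 2])))


class TestLearnThresholds:
    def make_deriv(self, v_gt, a_gt, idx=3, n=6):
        v = np.full(n, np.nan)
        a = np.full(n, np.nan)
        v[1:] = 1.0
        a[2:] = 0.0
        v[idx] = v_gt
        a[idx] = a_gt
        return DerivativeSeries(D0, v, a)

    @pytest.mark.parametrize(
        "v_gt,a_gt,v_thr,a_thr",
        [
            (3.7, 2.9, 4, 2),
            (4.0, 4.0, 5, 4),  # floor of an integer still adds 1 to velocity
        ],
    )
    def test_floor_rules(self, v_gt, a_gt, v_thr, a_thr):
        thr = learn_thresholds(self.make_deriv(v_gt, a_gt), day(3))
        assert thr.v_thresh == v_thr
        assert thr.a_thresh == a_thr

    def test_hand_computed_toy_series(self):
        # jump to 20 on day 3: v = 20-12 = 8, a = 8-2 = 6
        series = DailySeries(D0, [10, 10, 12, 20, 21, 22])
        der = compute_derivatives(identity_smooth(series))
        thr = learn_thresholds(der, day(3))
        assert thr.v_gt == 8
        assert thr.a_gt == 6
        assert thr.v_thresh == 9
        assert thr.a_thresh == 6

    def test_gt_in_first_two_days_rejected(self):
        with pytest.raises(ValueError):
            learn_thresholds(self.make_deriv(1, 1), day(1))

    def test_gt_outside_series_rejected(self):
        with pytest.raises(KeyError):
            learn_thresholds(self.make_deriv(1, 1), day(99))

    def test_nonpositive_velocity_warns(self, caplog):
        import logging

        with caplog.at_level(logging.WARNING, logger="tweetphases.phase_detect"):
            learn_thresholds(self.make_deriv(-1.0, 2.0), day(3))
        assert any("vacuous" in m for m in caplog.messages)


class TestDetectPhaseStarts:
    def test_flat_series_gives_gt_only(self):
        series = DailySeries(D0, [10.0] * 10 + [10.0])
        der = compute_derivatives(identity_smooth(series))
        thr = ThresholdPair(5, 1, day(3), 4.0, 1.5)
        assert detect_phase_starts(der, thr) == [day(3)]

    def test_hand_computed_fixture(self):
        # v = [-,0,2,8,1,1,8,20,5]; a = [-,-,2,6,-7,0,7,12,-15]
        series = DailySeries(D0, [10, 10, 12, 20, 21, 22, 30, 50, 55])
        der = compute_derivatives(identity_smooth(series))
        thr = learn_thresholds(der, day(3))
        assert (thr.v_thresh, thr.a_thresh) == (9, 6)
        starts = detect_phase_starts(der, thr)
        assert starts == [day(3), day(6)]

    def test_consecutive_qualifying_days_collapse_to_first(self):
        v = np.full(10, np.nan)
        a = np.full(10, np.nan)
        v[1:] = 20.0  # above threshold: not qualifying
        a[2:] = 0.0
        v[6], a[6] = 3.0, 5.0  # qualifies
        v[7], a[7] = 4.0, 6.0  # qualifies, same run
        der = DerivativeSeries(D0, v, a)
        thr = ThresholdPair(v_thresh=9, a_thresh=2, gt_date=day(3),
                            v_gt=8.0, a_gt=2.5)
        assert detect_phase_starts(der, thr) == [day(3), day(6)]

    def test_strict_inequalities(self):
        v = np.full(8, np.nan)
        a = np.full(8, np.nan)
        v[1:] = 20.0
        a[2:] = 0.0
        v[5], a[5] = 9.0, 7.0  # v == v_thresh: excluded
        v[6], a[6] = 8.0, 6.0  # a == a_thresh: excluded
        der = DerivativeSeries(D0, v, a)
        thr = ThresholdPair(v_thresh=9, a_thresh=6, gt_date=day(3),
                            v_gt=8.5, a_gt=6.2)
        assert detect_phase_starts(der, thr) == [day(3)]

    def test_no_starts_before_gt_date(self):
        v = np.full(10, np.nan)
        a = np.full(10, np.nan)
        v[1:] = 3.0
        a[2:] = 5.0  # every day qualifies on its own
        der = DerivativeSeries(D0, v, a)
        thr = ThresholdPair(v_thresh=9, a_thresh=2, gt_date=day(5),
                            v_gt=8.0, a_gt=2.5)
        starts = detect_phase_starts(der, thr)
        assert starts[0] == day(5)
        assert all(s >= day(5) for s in starts)


class TestSegmentPhases:
    def test_table_style_window(self):
        # one start on Jan 20 splits January into Jan 1-19 and Jan 20-31
        seg = segment_phases([date(2020, 1, 20)],
                             (date(2020, 1, 1), date(2020, 1, 31)))
        assert [(p.phase_id, p.start, p.end) for p in seg] == [
            (0, date(2020, 1, 1), date(2020, 1, 19)),
            (1, date(2020, 1, 20), date(2020, 1, 31)),
        ]

    def test_no_starts_gives_single_phase(self):
        seg = segment_phases([], (day(0), day(9)))
        assert len(seg) == 1
        assert seg.phases[0].n_days == 10

    def test_two_starts_partition_lengths(self):
        # 9-day window, starts on the 3rd and 6th days: lengths 2, 3, 4
        seg = segment_phases([day(2), day(5)], (day(0), day(8)))
        assert [p.n_days for p in seg] == [2, 3, 4]

    def test_start_at_window_start_omits_empty_phase(self):
        seg = segment_phases([day(0), day(4)], (day(0), day(9)))
        assert [p.n_days for p in seg] == [4, 6]
        assert seg.phases[0].start == day(0)

    def test_start_outside_window_rejected(self):
        with pytest.raises(ValueError):
            segment_phases([day(50)], (day(0), day(9)))

    def test_partition_property(self):
        seg = segment_phases([day(3), day(7)], (day(0), day(20)))
        covered = [d for p in seg for d in
                   (p.start + timedelta(days=i) for i in range(p.n_days))]
        assert covered == [day(i) for i in range(21)]  # exact cover, in order


class TestEndToEnd:
    def test_monotone_robustness_constant_offset(self):
        rng = np.random.default_rng(3)
        counts = rng.poisson(50, size=40).astype(float)
        counts[20:] += 120  # a jump creating a detectable onset
        s1 = DailySeries(D0, counts)
        s2 = DailySeries(D0, counts + 37.0)
        seg1, thr1 = detect_phases(s1, day(10))
        seg2, thr2 = detect_phases(s2, day(10))
        assert seg1.to_dicts() == seg2.to_dicts()
        assert thr1.v_thresh == thr2.v_thresh
        assert thr1.a_thresh == thr2.a_thresh

    def test_same_inputs_same_segmentation(self):
        rng = np.random.default_rng(11)
        counts = rng.poisson(80, size=50).astype(float)
        s = DailySeries(D0, counts)
        a = detect_phases(s, day(12))[0].to_dicts()
        b = detect_phases(s, day(12))[0].to_dicts()
        assert a == b

    def test_phase0_starts_at_window_start_phase1_at_gt(self):
        rng = np.random.default_rng(5)
        s = DailySeries(D0, rng.poisson(60, size=30).astype(float))
        seg, thr = detect_phases(s, day(9))
        assert seg.phases[0].start == D0
        assert seg.phases[1].start == day(9)
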