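"""Process metrics: task time, path length, peaks, LDLJ, SPARC, flash ratio."""

import math

import numpy as np
import pytest

from cannuskill import (
    MINIMUM_JERK_LDLJ,
    compose_trial,
    compute_all,
    count_peaks,
    even_split_plan,
    flash_ratio,
    ldlj,
    min_jerk_trajectory,
    path_length,
    segment_task,
    sg_derivatives,
    sparc,
    time_metric,
)
from cannuskill.io import GRS_CATEGORIES, TrialMeta
from cannuskill.metrics import DegenerateTrialError, UndefinedMetricError
from cannuskill.segmentation import TaskSegment

from conftest import make_series


def _segment_with_entry(n_above=120, n_below=680, flash=None):
    z = np.concatenate([np.full(n_above, 5.0), np.full(n_below, -1.0)])
    return segment_task(make_series(z, flash=flash), 0.0)


def _meta():
    return TrialMeta(
        participant_id="P001", trial_id="T01", fistula_id=1, skin_z=0.0,
        fs=100.0, years_experience=2.0, grs={c: 4 for c in GRS_CATEGORIES},
    )


class TestTimeMetric:
    def test_subtraction(self):
        seg = _segment_with_entry()
        assert time_metric(seg) == pytest.approx(seg.t_end - seg.t_entry)

    def test_planned_duration_recovered(self):
        # 5 s trial that crosses the skin at its very first sample
        s = min_jerk_trajectory([0, 0, 1], [0, 0, -10], 5.0, 100.0)
        seg = segment_task(s, 1.5)
        assert time_metric(seg) == pytest.approx(5.0, abs=0.011)

    def test_invariant_to_spatial_scale(self):
        s1 = min_jerk_trajectory([0, 0, 1], [0, 0, -10], 5.0, 100.0)
        s2 = s1.replace(x=s1.x * 7, y=s1.y * 7, z=s1.z * 7)
        assert time_metric(segment_task(s2, 7 * 1.5)) == time_metric(
            segment_task(s1, 1.5)
        )


class TestPathLength:
    def test_straight_segment(self):
        s = min_jerk_trajectory([0, 0, 0], [10, 0, 0], 2.0, 100.0)
        assert path_length(sg_derivatives(s, 5)) == pytest.approx(10.0, rel=1e-3)

    def test_homogeneous_under_spatial_scale(self):
        s = min_jerk_trajectory([0, 0, 0], [3, 4, 0], 2.0, 100.0)
        pl1 = path_length(sg_derivatives(s, 5))
        s2 = s.replace(x=s.x * 2.5, y=s.y * 2.5, z=s.z * 2.5)
        assert path_length(sg_derivatives(s2, 5)) == pytest.approx(2.5 * pl1)

    def test_noise_lengthens_the_path(self):
        from cannuskill import add_sensor_noise

        clean = min_jerk_trajectory([0, 0, 0], [20, 0, 0], 4.0, 100.0)
        noisy = add_sensor_noise(clean, 0.06, 31)
        assert path_length(sg_derivatives(noisy, 5)) > path_length(
            sg_derivatives(clean, 5)
        )


class TestCountPeaks:
    def test_single_movement_is_unimodal(self):
        s = min_jerk_trajectory([0, 0, 0], [10, 0, 0], 2.0, 100.0)
        assert count_peaks(sg_derivatives(s, 5)) == 1

    def test_two_submovements(self):
        plan = even_split_plan([0, 0, 0], [10, 0, 0], 2, 3.0, pause_s=0.5)
        s = compose_trial(plan, 100.0)
        # prominence floor ignores junction ripple from the local cubic fits
        assert count_peaks(sg_derivatives(s, 5), prominence=0.01) == 2

    def test_constant_speed_has_no_strict_maxima(self):
        t = np.arange(200) / 100.0
        s = make_series(z=2.0 * t)
        assert count_peaks(sg_derivatives(s, 11)) == 0


class TestLDLJ:
    @pytest.mark.parametrize("A,T", [(10.0, 1.0), (35.0, 2.5)])
    def test_minimum_jerk_attains_minus_ln_720(self, A, T):
        s = min_jerk_trajectory([0, 0, 0], [A, 0, 0], T, 100.0)
        d = sg_derivatives(s, 5)
        value = ldlj(d, T, path_length(d))
        assert value == pytest.approx(MINIMUM_JERK_LDLJ, rel=0.01)

    def test_dimensionless_under_amplitude_and_duration(self):
        def _ldlj(A, T):
            s = min_jerk_trajectory([0, 0, 0], [A, 0, 0], T, 100.0)
            d = sg_derivatives(s, 5)
            return ldlj(d, T, path_length(d))

        base = _ldlj(10.0, 1.0)
        assert abs(_ldlj(20.0, 1.0) - base) / abs(base) < 0.005
        assert abs(_ldlj(10.0, 2.0) - base) / abs(base) < 0.005
        assert abs(_ldlj(20.0, 2.0) - base) / abs(base) < 0.005

    def test_fragmented_movement_scores_lower(self):
        def _ldlj_n(n):
            plan = even_split_plan([0, 0, 0], [40, 0, 0], n, 6.0,
                                   pause_s=0.25 if n > 1 else 0.0)
            s = compose_trial(plan, 100.0)
            d = sg_derivatives(s, 5)
            return ldlj(d, s.t[-1] - s.t[0], path_length(d))

        assert _ldlj_n(4) < _ldlj_n(1)

    def test_zero_jerk_is_undefined(self):
        t = np.arange(200) / 100.0
        s = make_series(z=3.0 * t)  # constant velocity
        d = sg_derivatives(s, 11)
        with pytest.raises(UndefinedMetricError):
            ldlj(d, 2.0, 6.0)


class TestSPARC:
    def test_amplitude_scaling_exact_invariance(self):
        s = min_jerk_trajectory([0, 0, 0], [10, 0, 0], 2.0, 100.0)
        d1 = sg_derivatives(s, 5)
        s2 = s.replace(x=s.x * 8, y=s.y * 8, z=s.z * 8)
        d2 = sg_derivatives(s2, 5)
        assert sparc(d2) == pytest.approx(sparc(d1), rel=1e-12)

    def test_never_exceeds_minus_one(self):
        # the normalised frequency axis alone contributes arc length 1
        for n in (1, 3, 8):
            plan = even_split_plan([0, 0, 0], [30, 0, 0], n, 5.0,
                                   pause_s=0.2 if n > 1 else 0.0)
            d = sg_derivatives(compose_trial(plan, 100.0), 5)
            assert sparc(d) <= -1.0

    def test_fragmented_movement_scores_lower(self):
        def _sparc_n(n):
            plan = even_split_plan([0, 0, 0], [40, 0, 0], n, 6.0,
                                   pause_s=0.25 if n > 1 else 0.0)
            return sparc(sg_derivatives(compose_trial(plan, 100.0), 5))

        assert _sparc_n(8) < _sparc_n(1)

    def test_zero_speed_is_undefined(self):
        s = make_series(np.zeros(100))
        d = sg_derivatives(s, 11)
        with pytest.raises(UndefinedMetricError):
            sparc(d)


class TestFlashRatio:
    def test_no_flash_scores_zero(self):
        assert flash_ratio(_segment_with_entry()) == 0.0

    def test_interval_arithmetic(self):
        # intervals [2,3] and [4,5] with onset 2 and end 6 → (1+1)/4
        seg = TaskSegment(
            t_entry=0.0, t_end=6.0, t_flash=2.0,
            flash_intervals=[(2.0, 3.0), (4.0, 5.0)],
            series=make_series(np.linspace(-1, -2, 601)),
        )
        assert flash_ratio(seg) == pytest.approx(0.5)

    def test_continuous_flash_scores_one_exactly(self):
        flash = np.zeros(800, dtype=int)
        flash[400:] = 1
        seg = _segment_with_entry(flash=flash)
        assert flash_ratio(seg) == 1.0

    def test_flash_on_final_sample_only_is_degenerate(self):
        flash = np.zeros(800, dtype=int)
        flash[-1] = 1
        seg = _segment_with_entry(flash=flash)
        with pytest.raises(DegenerateTrialError):
            flash_ratio(seg)


class TestComputeAll:
    def test_one_row_per_span_and_constant_fr(self):
        flash = np.zeros(800, dtype=int)
        flash[500:] = 1
        seg = _segment_with_entry(flash=flash)
        rows = compute_all(seg, _meta(), spans=(5, 25, 51, 101, 201))
        assert len(rows) == 5
        assert len({row.FR for row in rows}) == 1

    def test_span_longer_than_trial_flagged_missing(self):
        seg = _segment_with_entry(n_above=10, n_below=30)  # 0.3 s task
        rows = compute_all(seg, _meta(), spans=(5, 201))
        by_span = {row.window_span: row for row in rows}
        assert by_span[5].missing_reason is None
        assert by_span[201].missing_reason is not None
        assert math.isnan(by_span[201].LDLJ)


def _analytic_jerk_sq(plan, t):
    """Closed-form squared jerk of a composed plan at arbitrary times."""
    total = np.zeros((len(t), 3))
    for seg in plan.segments:
        tau = (t - seg.start_time) / seg.duration
        inside = (tau >= 0) & (tau <= 1)
        basis = np.where(
            inside, (60.0 - 360.0 * tau + 360.0 * tau**2) / seg.duration**3, 0.0
        )
        total += basis[:, None] * seg.displacement[None, :]
    return np.einsum("ij,ij->i", total, total)


def test_trapezoid_jerk_integral_against_riemann_oracle():
    # the integration rule used by LDLJ (trapezoid on the 100 Hz grid)
    # against a brute-force Riemann oracle on a 10x finer grid
    plan = even_split_plan([0, 0, 0], [40, 0, 0], 4, 6.0, pause_s=0.25)
    s = compose_trial(plan, 100.0)
    measured = np.trapezoid(_analytic_jerk_sq(plan, s.t), s.t)

    t_fine = np.arange(int(plan.total_time * 1000.0)) / 1000.0
    oracle = _analytic_jerk_sq(plan, t_fine).sum() / 1000.0
    assert measured == pytest.approx(oracle, rel=0.01)


def test_sg_jerk_integral_tracks_analytic_value_for_single_movement():
    # full pipeline: for a continuous-jerk record the SG estimate at span 5
    # reproduces the analytic squared-jerk integral to within 1%
    s = min_jerk_trajectory([0, 0, 0], [40, 0, 0], 6.0, 100.0)
    d = sg_derivatives(s, 5)
    measured = np.trapezoid(np.einsum("ij,ij->i", d.jerk, d.jerk), d.t)
    assert measured == pytest.approx(720 * 40**2 / 6.0**5, rel=0.01)
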