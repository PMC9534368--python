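"""Scoring operations: thresholds, T50, tonic means, TSP, CS mean, CPM."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cpmpheno.scoring import (
    classify_cpm,
    classify_tsp,
    cpm_efficiency,
    cs_mean_intensity,
    heat_pain_threshold,
    mean_trace_intensity,
    pretest_t50,
    score_session,
    temporal_summation,
)
from cpmpheno.types import (
    CpmClass,
    Phase,
    ThermalTrace,
    TspClass,
    UndefinedScoreError,
)
from conftest import make_cs, make_ramp, make_session, make_tonic


def densify(trace: ThermalTrace, rate_hz: float = 100.0) -> ThermalTrace:
    """Regenerate a trace on a dense grid from its linear interpolant (the
    grid-independence oracle)."""
    t = np.arange(trace.time_s[0], trace.time_s[-1] + 1e-9, 1.0 / rate_hz)
    return ThermalTrace(
        phase=trace.phase,
        time_s=t,
        covas=np.interp(t, trace.time_s, trace.covas),
        temperature_c=(
            np.interp(t, trace.time_s, trace.temperature_c)
            if trace.temperature_c is not None
            else None
        ),
    )


class TestThresholdAndT50:
    def test_threshold_at_known_onset_temperature(self):
        trials = [make_ramp(p, t50=43.0, threshold=38.0) for p in
                  (Phase.PRETEST_1, Phase.PRETEST_2, Phase.PRETEST_3)]
        assert heat_pain_threshold(trials) == pytest.approx(38.0, abs=0.05)

    def test_threshold_interpolates_between_samples(self):
        # covas 0 at (t=20 s, 38.0 °C), 10 at (t=21 s, 38.3 °C): the onset
        # lies strictly inside (38.0, 38.3) and agrees with a 100 Hz oracle
        t = np.array([0.0, 20.0, 21.0, 30.0])
        trace = ThermalTrace(
            phase=Phase.PRETEST_1,
            time_s=t,
            covas=np.array([0.0, 0.0, 10.0, 100.0]),
            temperature_c=np.array([32.0, 38.0, 38.3, 41.0]),
        )
        got = heat_pain_threshold([trace])
        assert 38.0 < got < 38.3
        dense = densify(trace)
        first_pos = dense.temperature_c[dense.covas > 0][0]
        assert got == pytest.approx(first_pos, abs=0.05)

    def test_all_zero_trace_is_undefined(self):
        trace = ThermalTrace(
            phase=Phase.PRETEST_1,
            time_s=np.arange(0.0, 30.0),
            covas=np.zeros(30),
            temperature_c=32.0 + 0.3 * np.arange(0.0, 30.0),
        )
        with pytest.raises(UndefinedScoreError):
            heat_pain_threshold([trace])

    def test_t50_is_mean_of_trial_crossings(self):
        trials = [
            make_ramp(Phase.PRETEST_1, t50=43.0),
            make_ramp(Phase.PRETEST_2, t50=43.2),
            make_ramp(Phase.PRETEST_3, t50=43.4),
        ]
        assert pretest_t50(trials) == pytest.approx(43.2, abs=0.02)

    def test_t50_excludes_trials_never_reaching_50(self):
        low = make_ramp(Phase.PRETEST_3, t50=43.0)
        low.covas = np.clip(low.covas, 0.0, 40.0)  # peaks at 40
        trials = [make_ramp(Phase.PRETEST_1, t50=43.0),
                  make_ramp(Phase.PRETEST_2, t50=43.4), low]
        assert pretest_t50(trials) == pytest.approx(43.2, abs=0.02)

    def test_t50_undefined_when_no_trial_reaches_50(self):
        low = make_ramp(Phase.PRETEST_1, t50=43.0)
        low.covas = np.clip(low.covas, 0.0, 40.0)
        with pytest.raises(UndefinedScoreError):
            pretest_t50([low])

    def test_t50_crossing_between_samples_matches_dense_oracle(self, rng):
        # coarse 0.5 Hz sampling forces interpolation between samples
        trace = make_ramp(Phase.PRETEST_1, t50=43.17, rate_hz=0.5)
        got = pretest_t50([trace])
        dense = densify(trace)
        t_cross = dense.time_s[dense.covas >= 50.0][0]
        expect = np.interp(t_cross, dense.time_s, dense.temperature_c)
        assert got == pytest.approx(expect, abs=0.05)


class TestTonicMeans:
    def test_constant_trace(self):
        assert mean_trace_intensity(make_tonic(plateau=50.0), (0, 120)) == pytest.approx(50.0)

    def test_linear_trace_symmetry(self):
        t = np.arange(0.0, 121.0)
        trace = ThermalTrace(Phase.TS1, t, 40.0 + 20.0 * t / 120.0)
        assert mean_trace_intensity(trace, (0, 120)) == pytest.approx(50.0)

    def test_irregular_grid_matches_riemann_oracle(self, rng):
        t = np.unique(np.concatenate([[0.0, 120.0], rng.uniform(0, 120, 40)]))
        trace = ThermalTrace(Phase.TS1, t, rng.uniform(0, 100, t.size))
        got = mean_trace_intensity(trace, (10.0, 110.0))
        n = 200_000
        h = 100.0 / n
        mid = 10.0 + (np.arange(n) + 0.5) * h
        oracle = np.interp(mid, trace.time_s, trace.covas).mean()  # midpoint Riemann sum
        assert got == pytest.approx(oracle, abs=1e-6)

    def test_window_outside_span_raises(self):
        with pytest.raises(ValueError):
            mean_trace_intensity(make_tonic(), (0, 130))


class TestTemporalSummation:
    @pytest.mark.parametrize(
        "plateau,tsp,expected",
        [(50.0, 0.0, 0.0), (50.0, 20.0, 20.0), (60.0, -20.0, -20.0)],
    )
    def test_signed_endpoint_difference(self, plateau, tsp, expected):
        assert temporal_summation(make_tonic(plateau=plateau, tsp=tsp)) == pytest.approx(expected)

    def test_short_trace_raises(self):
        t = np.arange(0.0, 100.0)
        with pytest.raises(ValueError):
            temporal_summation(ThermalTrace(Phase.TS1, t, np.full(t.size, 50.0)))


class TestClassification:
    @pytest.mark.parametrize(
        "tsp,expected",
        [
            (20.0, TspClass.INCREASE),
            (-19.9, TspClass.CONSTANT),
            (-20.0, TspClass.DECREASE),
            (0.0, TspClass.CONSTANT),
            (19.99, TspClass.CONSTANT),
        ],
    )
    def test_tsp_cutoffs_inclusive(self, tsp, expected):
        assert classify_tsp(tsp) is expected

    @pytest.mark.parametrize(
        "cpm,expected",
        [
            (-32.47, CpmClass.OPTIMAL),
            (0.0, CpmClass.INEFFICIENT),
            (-30.0, CpmClass.OPTIMAL),
            (-10.0, CpmClass.SUBOPTIMAL),
            (-29.99, CpmClass.SUBOPTIMAL),
            (-9.99, CpmClass.INEFFICIENT),
        ],
    )
    def test_cpm_cutoffs_to_more_inhibitory_class(self, cpm, expected):
        assert classify_cpm(cpm) is expected

    @given(st.floats(min_value=-100, max_value=100, allow_nan=False))
    @settings(max_examples=200, deadline=None)
    def test_cpm_classes_partition_the_range(self, cpm):
        assert classify_cpm(cpm) in set(CpmClass)


class TestColdPressor:
    def test_mean_of_ratings(self):
        assert cs_mean_intensity(make_cs([5, 6, 6, 7, 7, 8, 8, 8])) == pytest.approx(6.875)

    def test_withdrawal_imputed_as_ten(self):
        assert cs_mean_intensity(make_cs([7, 8, 9], withdrawal=45.0)) == 10.0

    def test_single_rating(self):
        assert cs_mean_intensity(make_cs([3])) == pytest.approx(3.0)

    def test_empty_without_withdrawal_raises(self):
        with pytest.raises(UndefinedScoreError):
            cs_mean_intensity(make_cs([]))

    @given(
        st.lists(st.floats(min_value=0, max_value=10), min_size=1, max_size=8),
        st.one_of(st.none(), st.floats(min_value=15, max_value=119)),
    )
    @settings(max_examples=100, deadline=None)
    def test_never_exceeds_ten_and_withdrawal_forces_ten(self, ratings, wt):
        ratings = [round(r * 2) / 2 for r in ratings]
        n = min(len(ratings), int(wt // 15) if wt else len(ratings))
        series = make_cs(ratings[: max(n, 0)] if wt else ratings, withdrawal=wt)
        if series.nrs.size == 0 and wt is None:
            return
        m = cs_mean_intensity(series)
        assert m <= 10.0
        if wt is not None:
            assert m == 10.0


class TestCpmEfficiency:
    @pytest.mark.parametrize(
        "m1,m2,expected", [(50, 35, -30.0), (50, 50, 0.0), (40, 60, 50.0)]
    )
    def test_percent_change(self, m1, m2, expected):
        assert cpm_efficiency(m1, m2) == pytest.approx(expected)

    def test_zero_baseline_is_undefined(self):
        with pytest.raises(UndefinedScoreError):
            cpm_efficiency(0.0, 10.0)

    def test_invariant_to_sampling_rate(self):
        """Re-sampling piecewise-linear traces (1 Hz vs 10 Hz) moves the CPM
        by less than 0.1."""
        vals = {}
        for rate in (1.0, 10.0):
            ts1 = make_tonic(Phase.TS1, 50.0, -12.0, rate_hz=rate)
            ts2 = make_tonic(Phase.TS2, 35.0, -6.0, rate_hz=rate)
            vals[rate] = cpm_efficiency(
                mean_trace_intensity(ts1, (0, 120)), mean_trace_intensity(ts2, (0, 120))
            )
        assert abs(vals[1.0] - vals[10.0]) < 0.1


class TestScoreSession:
    def test_constant_50_both_stimuli(self):
        rec = score_session(make_session(tsp1=0.0, tsp2=0.0, ts2_plateau=50.0))
        assert rec.cpm_pct == pytest.approx(0.0)
        assert rec.tsp1 == pytest.approx(0.0)
        assert rec.tsp2 == pytest.approx(0.0)
        assert rec.cpm_class is CpmClass.INEFFICIENT

    def test_withdrawal_session_scores_cs_ten(self):
        rec = score_session(make_session(ratings=[8, 9], withdrawal=40.0))
        assert rec.cs_mean == 10.0
        assert rec.withdrawal

    def test_t50_direct_without_pretest(self):
        rec = score_session(make_session(with_pretest=False, t50=44.2))
        assert rec.t50_c == pytest.approx(44.2)
        assert rec.threshold_c is None

    def test_incomplete_session_raises(self):
        s = make_session()
        s.ts2 = None
        with pytest.raises(ValueError):
            score_session(s)
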