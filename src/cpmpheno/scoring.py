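"""Psychophysical scoring of a conditioned pain modulation session.

Every quantity is defined on the piecewise-linear interpolant of the recorded
samples, so results do not depend on the (possibly irregular) sampling grid:

* heat pain threshold — ramp temperature at the first upward CoVAS crossing
  of a minimal pain level, averaged over pretest trials that report pain;
* T50 — ramp temperature at the first upward CoVAS crossing of 50/100,
  averaged over pretest trials that reach 50;
* tonic-stimulus mean pain — time-weighted (trapezoidal) CoVAS mean;
* temporal summation of pain (TSP) — signed CoVAS change over the last 60 s
  of a 120-s tonic stimulus, covas(120) − covas(60);
* conditioning-stimulus mean — arithmetic mean of the NRS ratings, imputed
  as 10/10 when the participant withdrew before 120 s;
* CPM efficiency — percent change in mean tonic pain after vs before
  conditioning, 100 × (mean_TS2 − mean_TS1) / mean_TS1.
"""

from __future__ import annotations

from typing import Iterable, Optional

import numpy as np

from .types import (
    ColdPressorSeries,
    CpmClass,
    ParticipantSession,
    ScoreRecord,
    ThermalTrace,
    TspClass,
    UndefinedScoreError,
)

__all__ = [
    "heat_pain_threshold",
    "pretest_t50",
    "mean_trace_intensity",
    "temporal_summation",
    "classify_tsp",
    "cs_mean_intensity",
    "cpm_efficiency",
    "classify_cpm",
    "score_session",
]

# Minimal CoVAS level treated as "first report of pain".  The cursor rests at
# exactly 0 until moved, so the first strictly positive excursion marks the
# threshold; a small level keeps the crossing well defined on the interpolant.
PAIN_ONSET_LEVEL = 0.1

TSP_CUTOFF = 20.0
CPM_OPTIMAL_CUTOFF = -30.0
CPM_SUBOPTIMAL_CUTOFF = -10.0


def _first_upward_crossing(time_s: np.ndarray, values: np.ndarray, level: float) -> Optional[float]:
    """Time of the first upward crossing of ``level`` by the piecewise-linear
    interpolant of (time, values); None if the level is never exceeded."""
    above = values >= level
    if values[0] >= level:
        return float(time_s[0])
    idx = np.nonzero(above)[0]
    if idx.size == 0:
        return None
    i = idx[0]
    t0, t1 = time_s[i - 1], time_s[i]
    v0, v1 = values[i - 1], values[i]
    if v1 == v0:
        return float(t1)
    return float(t0 + (level - v0) / (v1 - v0) * (t1 - t0))


def _ramp_temperature_at(trace: ThermalTrace, t: float) -> float:
    if trace.temperature_c is None:
        raise ValueError(f"{trace.phase.value}: no temperature channel")
    return float(np.interp(t, trace.time_s, trace.temperature_c))


def _crossing_temperature(trace: ThermalTrace, level: float) -> Optional[float]:
    t = _first_upward_crossing(trace.time_s, trace.covas, level)
    if t is None:
        return None
    return _ramp_temperature_at(trace, t)


def heat_pain_threshold(pretest: Iterable[ThermalTrace]) -> float:
    """Mean ramp temperature at the first report of pain, over trials in
    which any pain was reported.

    Raises
    ------
    UndefinedScoreError
        If no trial ever leaves CoVAS 0.
    """
    temps = [_crossing_temperature(tr, PAIN_ONSET_LEVEL) for tr in pretest]
    temps = [t for t in temps if t is not None]
    if not temps:
        raise UndefinedScoreError("heat pain threshold undefined: no trial reported pain")
    return float(np.mean(temps))


def pretest_t50(pretest: Iterable[ThermalTrace]) -> float:
    """Mean ramp temperature at the first upward CoVAS crossing of 50/100,
    over trials that reach 50; trials that never reach 50 are excluded.

    Raises
    ------
    UndefinedScoreError
        If no trial reaches 50.
    """
    temps = [_crossing_temperature(tr, 50.0) for tr in pretest]
    temps = [t for t in temps if t is not None]
    if not temps:
        raise UndefinedScoreError("T50 undefined: no pretest trial reached CoVAS 50")
    return float(np.mean(temps))


def mean_trace_intensity(trace: ThermalTrace, window: tuple[float, float]) -> float:
    """Time-weighted mean CoVAS over ``window`` — the trapezoidal integral of
    the piecewise-linear interpolant divided by the window length."""
    t_start, t_end = window
    lo, hi = trace.span
    if t_start < lo or t_end > hi or t_start >= t_end:
        raise ValueError(f"window {window} outside trace span ({lo:g}, {hi:g})")
    interior = trace.time_s[(trace.time_s > t_start) & (trace.time_s < t_end)]
    grid = np.concatenate(([t_start], interior, [t_end]))
    vals = np.interp(grid, trace.time_s, trace.covas)
    return float(np.trapezoid(vals, grid) / (t_end - t_start))


def temporal_summation(trace: ThermalTrace) -> float:
    """Signed CoVAS change over the temporal-summation phase (last 60 s):
    interpolated covas(120) − covas(60)."""
    lo, hi = trace.span
    if lo > 60.0 or hi < 120.0:
        raise ValueError("temporal summation requires a trace covering [60, 120] s")
    v60, v120 = np.interp([60.0, 120.0], trace.time_s, trace.covas)
    return float(v120 - v60)


def classify_tsp(tsp: float) -> TspClass:
    """Clinically significant change is |ΔCoVAS| ≥ 20/100 (cutoff inclusive)."""
    if tsp >= TSP_CUTOFF:
        return TspClass.INCREASE
    if tsp <= -TSP_CUTOFF:
        return TspClass.DECREASE
    return TspClass.CONSTANT


def cs_mean_intensity(cs: ColdPressorSeries) -> float:
    """Average cold-pressor pain; early withdrawal is imputed as 10/10."""
    if cs.withdrew:
        return 10.0
    if cs.nrs.size == 0:
        raise UndefinedScoreError("cold-pressor mean undefined: no ratings, no withdrawal")
    return float(np.mean(cs.nrs))


def cpm_efficiency(mean_ts1: float, mean_ts2: float) -> float:
    """CPM efficiency as percent change in mean tonic pain,
    100 × (mean_TS2 − mean_TS1) / mean_TS1; negative values indicate
    inhibition, positive values facilitation."""
    if mean_ts1 <= 0:
        raise UndefinedScoreError("CPM efficiency undefined: mean TS1 pain is zero")
    return float(100.0 * (mean_ts2 - mean_ts1) / mean_ts1)


def classify_cpm(cpm_pct: float) -> CpmClass:
    """Optimal ≤ −30 < suboptimal ≤ −10 < inefficient; each cutoff belongs to
    the more-inhibitory class."""
    if not np.isfinite(cpm_pct):
        raise ValueError("CPM efficiency must be finite")
    if cpm_pct <= CPM_OPTIMAL_CUTOFF:
        return CpmClass.OPTIMAL
    if cpm_pct <= CPM_SUBOPTIMAL_CUTOFF:
        return CpmClass.SUBOPTIMAL
    return CpmClass.INEFFICIENT


def clip_cpm_for_report(cpm_pct: float) -> float:
    """Reporting/plot range is −100..+100; the unclipped value feeds clustering."""
    return float(np.clip(cpm_pct, -100.0, 100.0))


def score_session(session: ParticipantSession) -> ScoreRecord:
    """Compute the full score record for a complete session.

    Raises
    ------
    UndefinedScoreError
        Propagated from T50 / threshold / CPM when undefined.
    ValueError
        If the session is incomplete.
    """
    if not session.is_complete:
        raise ValueError(f"session {session.participant_id} is incomplete")

    threshold_c: Optional[float] = None
    if session.pretest:
        try:
            threshold_c = heat_pain_threshold(session.pretest)
        except UndefinedScoreError:
            threshold_c = None

    if session.t50_c is not None:
        t50_c = float(session.t50_c)
    else:
        t50_c = pretest_t50(session.pretest)

    window = (0.0, 120.0)
    mean_ts1 = mean_trace_intensity(session.ts1, window)
    mean_ts2 = mean_trace_intensity(session.ts2, window)
    tsp1 = temporal_summation(session.ts1)
    tsp2 = temporal_summation(session.ts2)
    cs_mean = cs_mean_intensity(session.cs)
    cpm_pct = cpm_efficiency(mean_ts1, mean_ts2)

    return ScoreRecord(
        participant_id=session.participant_id,
        group=session.group,
        gender=session.gender,
        age_years=session.age_years,
        t50_c=t50_c,
        threshold_c=threshold_c,
        mean_ts1=mean_ts1,
        mean_ts2=mean_ts2,
        tsp1=tsp1,
        tsp2=tsp2,
        cs_mean=cs_mean,
        cpm_pct=cpm_pct,
        cpm_class=classify_cpm(cpm_pct),
        tsp1_class=classify_tsp(tsp1),
        tsp2_class=classify_tsp(tsp2),
        withdrawal=session.cs.withdrew,
    )
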