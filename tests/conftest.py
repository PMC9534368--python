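import numpy as np
import pytest

from cpmpheno.types import (
    ColdPressorSeries,
    Gender,
    Group,
    ParticipantSession,
    Phase,
    Recruitment,
    ThermalTrace,
)


def make_tonic(phase=Phase.TS1, plateau=50.0, tsp=0.0, rate_hz=1.0):
    """Plateau-then-drift tonic heat trace: constant over [0, 60] s, linear
    to plateau+tsp at 120 s."""
    t = np.arange(0.0, 121.0, 1.0 / rate_hz)
    if t[-1] != 120.0:
        t = np.append(t[t < 120.0], 120.0)
    covas = np.where(t <= 60.0, plateau, plateau + tsp * (t - 60.0) / 60.0)
    return ThermalTrace(phase=phase, time_s=t, covas=np.clip(covas, 0, 100))


def make_ramp(phase=Phase.PRETEST_1, t50=43.0, threshold=38.0, rate_hz=1.0, t_end=None):
    """Pretest ramp: 0.3 °C/s from 32 °C; CoVAS 0 below the threshold
    temperature, then linear reaching 50 at t50."""
    if t_end is None:
        t_end = t50 + 2.0
    duration = (t_end - 32.0) / 0.3
    t = np.arange(0.0, duration, 1.0 / rate_hz)
    t = np.append(t, duration)
    temp = np.minimum(32.0 + 0.3 * t, t_end)
    covas = np.clip(50.0 * (temp - threshold) / (t50 - threshold), 0.0, 100.0)
    return ThermalTrace(phase=phase, time_s=t, covas=covas, temperature_c=temp)


def make_cs(ratings=(5, 6, 6, 7, 7, 8, 8, 8), withdrawal=None):
    ratings = np.asarray(ratings, dtype=float)
    times = 15.0 * np.arange(1, ratings.size + 1)
    return ColdPressorSeries(time_s=times, nrs=ratings, withdrawal_time_s=withdrawal)


def make_session(pid="P0001", group=Group.PATIENT, tsp1=0.0, tsp2=0.0,
                 ts2_plateau=50.0, ratings=(5, 6, 6, 7, 7, 8, 8, 8),
                 withdrawal=None, t50=43.0, with_pretest=True):
    return ParticipantSession(
        participant_id=pid,
        group=group,
        gender=Gender.FEMALE,
        age_years=15.0,
        recruitment=Recruitment.OUTPATIENT if group == Group.PATIENT else Recruitment.COMMUNITY,
        pretest=[make_ramp(p, t50=t50) for p in
                 (Phase.PRETEST_1, Phase.PRETEST_2, Phase.PRETEST_3)] if with_pretest else [],
        ts1=make_tonic(Phase.TS1, 50.0, tsp1),
        ts2=make_tonic(Phase.TS2, ts2_plateau, tsp2),
        cs=make_cs(ratings, withdrawal),
        t50_c=None if with_pretest else t50,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
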