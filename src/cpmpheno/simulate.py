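"""Synthetic CPM-assessment cohorts with known latent phenotype structure.

The generator works by *inverse construction*: for each participant it first
draws the four latent indicator targets (TSP1, CS mean, TSP2, CPM %) from the
participant's phenotype distribution, then builds raw session time series
that score back to those targets —

* TS1 is canonically a CoVAS plateau at b1 = 50 (the protocol calibrates the
  test temperature to pain 50/100) for t ∈ [0, 60] s followed by a linear
  drift to b1 + TSP1 at t = 120 s, so the time-weighted 120-s mean is
  b1 + TSP1/4;
* TS2 must satisfy mean_TS2 = mean_TS1·(1 + CPM/100) with endpoint change
  TSP2, which makes the scored CPM efficiency equal the target; where the
  plateau shape cannot stay within the 0–100 scale (strong inhibition with a
  falling TS2, and the mirrored facilitation case) a 3-knot or dip-shaped
  piecewise-linear profile with the same mean and endpoint change is used
  instead, so the target distributions are preserved rather than truncated;
* the cold-pressor series is eight 0.5-resolution NRS ratings whose mean
  matches the CS target, or an early withdrawal (scored 10/10);
* pretest ramps (0.3 °C/s from 32 °C) are shaped so the CoVAS crosses 50 at
  the participant's T50.

Targets whose implied trace levels leave [0, 100] are redrawn from the
phenotype (logged); truncation to the indicator ranges is applied otherwise.
Withdrawal is coupled to latent pain: a participant withdraws when the
untruncated CS draw exceeds the phenotype's (1 − withdrawal_prob) quantile,
so the marginal withdrawal rate equals ``withdrawal_prob`` while withdrawal
remains driven by pain intensity. The latent-truth table records the
*effective* targets (CS = 10 for withdrawers).

Within a phenotype the four indicators are drawn independently; real
within-cluster covariance is unknown and not modelled.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
import yaml
from scipy.stats import norm

from .types import (
    Cohort,
    ColdPressorSeries,
    Gender,
    Group,
    PainDescriptors,
    ParticipantSession,
    Phase,
    Recruitment,
    ThermalTrace,
)

__all__ = [
    "PhenotypeSpec",
    "GeneratorConfig",
    "default_phenotypes",
    "generate_session",
    "generate_cohort",
    "write_latent_truth",
]

TS_PLATEAU = 50.0  # CoVAS level of the TS1 plateau (T50 calibration)
RAMP_RATE = 0.3
RAMP_BASELINE = 32.0
# mean gap between T50 and first-pain threshold on the ramp, °C
THRESHOLD_GAP_MEAN = 4.45
THRESHOLD_GAP_SD = 1.5


@dataclass(frozen=True)
class PhenotypeSpec:
    """Distributional description of one latent phenotype (or the control
    group): indicator means/SDs in their native units, withdrawal rate, and
    demographics."""

    name: str
    weight: float
    tsp1_mean: float
    tsp1_sd: float
    cs_mean: float
    cs_sd: float
    tsp2_mean: float
    tsp2_sd: float
    cpm_mean: float
    cpm_sd: float
    withdrawal_prob: float
    female_prob: float
    age_mean: float
    age_sd: float
    t50_mean: float
    t50_sd: float


def default_phenotypes() -> tuple[list[PhenotypeSpec], PhenotypeSpec]:
    """Three patient phenotypes plus a control spec.

    Phenotype 1 (44.6%): efficient inhibition, no summation, high cold pain.
    Phenotype 2 (30.6%): efficient inhibition, no summation, low cold pain.
    Phenotype 3 (24.8%): inefficient inhibition, temporal summation, high
    cold pain.
    """
    patients = [
        PhenotypeSpec(
            name="cluster1", weight=0.446,
            tsp1_mean=-10.62, tsp1_sd=20.17,
            cs_mean=8.16, cs_sd=1.47,
            tsp2_mean=-6.11, tsp2_sd=16.42,
            cpm_mean=-41.06, cpm_sd=34.19,
            withdrawal_prob=0.1053, female_prob=0.8092,
            age_mean=15.18, age_sd=2.14,
            t50_mean=42.70, t50_sd=2.45,
        ),
        PhenotypeSpec(
            name="cluster2", weight=0.306,
            tsp1_mean=6.89, tsp1_sd=17.72,
            cs_mean=4.04, cs_sd=1.70,
            tsp2_mean=2.10, tsp2_sd=14.11,
            cpm_mean=-33.10, cpm_sd=37.84,
            withdrawal_prob=0.0002, female_prob=0.8092,
            age_mean=15.18, age_sd=2.14,
            t50_mean=44.39, t50_sd=1.98,
        ),
        PhenotypeSpec(
            name="cluster3", weight=0.248,
            tsp1_mean=12.39, tsp1_sd=19.23,
            cs_mean=8.24, cs_sd=1.32,
            tsp2_mean=15.78, tsp2_sd=20.66,
            cpm_mean=9.25, cpm_sd=44.27,
            withdrawal_prob=0.0912, female_prob=0.8092,
            age_mean=15.18, age_sd=2.14,
            t50_mean=43.49, t50_sd=2.27,
        ),
    ]
    control = PhenotypeSpec(
        name="control", weight=1.0,
        tsp1_mean=6.46, tsp1_sd=19.05,
        cs_mean=6.31, cs_sd=2.41,
        tsp2_mean=5.16, tsp2_sd=14.49,
        cpm_mean=-32.67, cpm_sd=35.47,
        withdrawal_prob=0.0629, female_prob=0.4833,
        age_mean=15.06, age_sd=2.23,
        t50_mean=42.84, t50_sd=2.38,
    )
    return patients, control


# cohort-level descriptor frequencies (patients)
_P_PAIN_CLINIC = 259 / 608
_P_DURATION_SHORT = 40 / 608
_P_PERSISTENT = 329 / 552
_P_SECONDARY = 0.5099
_P_PAIN_BEFORE = 0.7023
_PAIN_BEFORE_MEAN, _PAIN_BEFORE_SD = 4.16, 2.16
_LOCATIONS = ("back", "head/neck", "abdomen", "groin", "thorax", "upper limbs", "lower limbs")
_LOCATION_P = np.array([410, 31, 24, 1, 14, 18, 109], dtype=float)
_LOCATION_P /= _LOCATION_P.sum()


@dataclass
class GeneratorConfig:
    """Study conditions for a synthetic cohort.

    ``noise_sd`` is the per-sample Gaussian CoVAS noise (NRS noise is scaled
    by 1/10); ``incomplete_fraction`` of patient sessions have one randomly
    deleted phase so downstream exclusion logic is exercised.
    """

    seed: int
    n_patients: int = 639
    n_controls: int = 60
    phenotypes: Optional[list[PhenotypeSpec]] = None
    control: Optional[PhenotypeSpec] = None
    noise_sd: float = 2.0
    sample_rate_hz: float = 1.0
    incomplete_fraction: float = 31 / 639

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        if self.phenotypes is None or self.control is None:
            patients, control = default_phenotypes()
            if self.phenotypes is None:
                self.phenotypes = patients
            if self.control is None:
                self.control = control
        w = sum(p.weight for p in self.phenotypes)
        if abs(w - 1.0) > 1e-9:
            raise ValueError(f"phenotype weights sum to {w}, not 1")

    @classmethod
    def from_yaml(cls, path) -> "GeneratorConfig":
        """Load the flat key-value config (n_patients, n_controls, seed,
        noise_sd, sample_rate_hz, incomplete_fraction)."""
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        allowed = {
            "seed", "n_patients", "n_controls", "noise_sd",
            "sample_rate_hz", "incomplete_fraction",
        }
        unknown = set(raw) - allowed
        if unknown:
            raise ValueError(f"unknown config key(s): {', '.join(sorted(unknown))}")
        if "seed" not in raw:
            raise ValueError("config must set a seed")
        return cls(**raw)


def _time_grid(duration: float, rate_hz: float, knots: tuple[float, ...] = ()) -> np.ndarray:
    step = 1.0 / rate_hz
    t = np.arange(0.0, duration, step)
    t = np.unique(np.concatenate([t, [duration], np.asarray(knots, dtype=float)]))
    return t[(t >= 0) & (t <= duration)]


def tonic_profile(
    mean_target: float, tsp: float, rate_hz: float
) -> Optional[tuple[np.ndarray, np.ndarray]]:
    """Piecewise-linear 120-s CoVAS profile with time-weighted mean equal to
    ``mean_target``, covas(120) − covas(60) equal to ``tsp``, and values in
    [0, 100]; all knots lie on the sampling grid so the sampled trace scores
    back exactly. Returns None when no such profile exists.

    Shapes, in order of preference: plateau + linear drift (the canonical
    tonic-stimulus shape); a 3-knot profile (free level at t = 0); a
    dip/spike profile for extreme inhibition or facilitation where the
    rating rests at a bound for part of the first 60 s.
    """
    m = mean_target
    if not 0.0 <= m <= 100.0:
        return None
    t = _time_grid(120.0, rate_hz, knots=(60.0,))

    b = m - tsp / 4.0
    if 0.0 <= b <= 100.0 and 0.0 <= b + tsp <= 100.0:
        return t, np.where(t <= 60.0, b, b + tsp * (t - 60.0) / 60.0)

    # 3-knot (a, v60, v60+tsp): mean = (a + 3 v60 + tsp)/4
    lo = max(0.0, -tsp, (4.0 * m - tsp - 100.0) / 3.0)
    hi = min(100.0, 100.0 - tsp, (4.0 * m - tsp) / 3.0)
    if lo <= hi:
        v60 = float(np.clip(m - tsp / 4.0, lo, hi))
        a = 4.0 * m - 3.0 * v60 - tsp
        return t, np.interp(t, [0.0, 60.0, 120.0], [a, v60, v60 + tsp])

    # late-drift: plateau h until a break point tg in (60, 120), then a
    # linear ramp to h + tsp; the break is placed on the grid
    vlo, vhi = max(0.0, -tsp), min(100.0, 100.0 - tsp)
    for tg in t[(t > 60.0) & (t < 120.0)]:
        h = m - tsp * (120.0 - tg) / 240.0
        if vlo <= h <= vhi:
            return t, np.interp(t, [0.0, tg, 120.0], [h, h, h + tsp])

    if tsp <= 0:
        res = _dip_profile(m, tsp, t)
        if res is not None:
            return t, res
    else:
        res = _dip_profile(100.0 - m, -tsp, t)
        if res is not None:
            return t, 100.0 - res
    return None


def _dip_profile(m: float, tsp: float, t: np.ndarray) -> Optional[np.ndarray]:
    """Profile (0 on [0, tg], rise to v60 at 60 s, fall to v60 + tsp) for
    strongly negative tsp with a small mean; tg is chosen on the grid so the
    sampled trapezoidal mean is exactly m."""
    for tg in t[t < 60.0]:
        denom = (60.0 - tg) / 240.0 + 0.5
        v60 = (m - tsp / 4.0) / denom
        if max(0.0, -tsp) <= v60 <= min(100.0, 100.0 - tsp):
            return np.interp(t, [0.0, tg, 60.0, 120.0], [0.0, 0.0, v60, v60 + tsp])
    return None


def _draw_targets(
    spec: PhenotypeSpec, rng: np.random.Generator, rate_hz: float,
    log: list[str], pid: str,
):
    """Draw (tsp1, cs_raw, tsp2, cpm) and build the matching TS profiles.
    TSP1 determines mean_TS1 = 50 + TSP1/4 (the T50-calibrated plateau);
    (cpm, tsp2) pairs whose implied TS2 profile cannot stay in [0, 100] are
    redrawn (rare, logged); tsp1 and cs are never redrawn."""
    cs_raw = float(rng.normal(spec.cs_mean, spec.cs_sd))
    tsp1 = float(np.clip(rng.normal(spec.tsp1_mean, spec.tsp1_sd), -100, 100))
    mean1 = TS_PLATEAU + tsp1 / 4.0
    prof1 = tonic_profile(mean1, tsp1, rate_hz)
    if prof1 is None:  # cannot happen for |tsp1| <= 100: kept as a guard
        raise RuntimeError(f"{pid}: no TS1 profile for tsp1={tsp1}")
    for attempt in range(100):
        tsp2 = float(np.clip(rng.normal(spec.tsp2_mean, spec.tsp2_sd), -100, 100))
        cpm = float(np.clip(rng.normal(spec.cpm_mean, spec.cpm_sd), -100, 100))
        if cpm <= -100.0 + 1e-12:
            # complete inhibition: TS2 is pinned at zero, which physically
            # forces TSP2 = 0; keeps the truncated-normal CPM mass at −100
            tsp2 = 0.0
            prof2 = tonic_profile(0.0, 0.0, rate_hz)
            log.append(f"{pid}: CPM at −100, TS2 pinned to zero (tsp2 set to 0)")
            return tsp1, cs_raw, tsp2, -100.0, prof1, prof2
        mean2 = mean1 * (1.0 + cpm / 100.0)
        prof2 = tonic_profile(mean2, tsp2, rate_hz)
        if prof2 is not None:
            if attempt:
                log.append(f"{pid}: redrew (tsp2, cpm) {attempt} time(s) for feasibility")
            return tsp1, cs_raw, tsp2, cpm, prof1, prof2
    raise RuntimeError(f"{pid}: could not draw a feasible (tsp2, cpm) in 100 attempts")


def _tonic_trace(
    phase: Phase, profile: tuple[np.ndarray, np.ndarray], config: GeneratorConfig,
    rng: np.random.Generator,
) -> ThermalTrace:
    t, base = profile
    if config.noise_sd > 0:
        base = base + rng.normal(0.0, config.noise_sd, size=t.size)
    return ThermalTrace(phase=phase, time_s=t, covas=np.clip(base, 0.0, 100.0))


def _pretest_trace(
    phase: Phase, t50_c: float, threshold_c: float, config: GeneratorConfig,
    rng: np.random.Generator,
) -> ThermalTrace:
    t_end = min(t50_c + 2.0, 49.7)
    duration = (t_end - RAMP_BASELINE) / RAMP_RATE
    t = _time_grid(duration, config.sample_rate_hz)
    temp = np.minimum(RAMP_BASELINE + RAMP_RATE * t, t_end)
    base = 50.0 * (temp - threshold_c) / (t50_c - threshold_c)
    base = np.clip(base, 0.0, 100.0)
    if config.noise_sd > 0:
        noise = rng.normal(0.0, config.noise_sd, size=t.size)
        base = np.where(base > 0, np.clip(base + noise, 0.0, 100.0), base)
    return ThermalTrace(phase=phase, time_s=t, covas=base, temperature_c=temp)


def _cs_ratings(
    target: float, config: GeneratorConfig, rng: np.random.Generator
) -> ColdPressorSeries:
    times = np.arange(15.0, 121.0, 15.0)
    if config.noise_sd > 0:
        shape = np.array([-1.0, -0.75, -0.5, -0.25, 0.25, 0.5, 0.75, 1.0])
        vals = target + shape + rng.normal(0.0, config.noise_sd / 10.0, size=8)
        nrs = np.clip(np.round(vals * 2.0) / 2.0, 0.0, 10.0)
        return ColdPressorSeries(time_s=times, nrs=nrs)
    # noise-free: build ratings on the 0.5 grid whose mean matches the target
    # to within 1/32 NRS units
    total_half = int(round(target * 16.0))  # total over 8 ratings, 0.5-units
    total_half = min(max(total_half, 0), 8 * 20)
    base = total_half // 8
    rem = total_half % 8
    half_units = np.full(8, base)
    if rem:
        half_units[-rem:] += 1
    nrs = half_units / 2.0
    return ColdPressorSeries(time_s=times, nrs=nrs)


def _withdrawal_series(config: GeneratorConfig, rng: np.random.Generator) -> ColdPressorSeries:
    wt = float(rng.uniform(20.0, 115.0))
    times = np.arange(15.0, 121.0, 15.0)
    times = times[times <= wt]
    vals = np.linspace(7.0, 10.0, max(times.size, 1))
    if config.noise_sd > 0:
        vals = vals + rng.normal(0.0, config.noise_sd / 10.0, size=vals.size)
    nrs = np.clip(np.round(vals * 2.0) / 2.0, 0.0, 10.0)
    return ColdPressorSeries(time_s=times, nrs=nrs, withdrawal_time_s=wt)


@dataclass
class _Demographics:
    gender: Gender
    age_years: float
    t50_c: float
    threshold_c: float
    recruitment: Recruitment
    pain_before_nrs: Optional[float]
    descriptors: PainDescriptors


def _draw_demographics(
    spec: PhenotypeSpec, group: Group, rng: np.random.Generator
) -> _Demographics:
    gender = Gender.FEMALE if rng.random() < spec.female_prob else Gender.MALE
    age = float(np.clip(rng.normal(spec.age_mean, spec.age_sd), 8.0, 21.4))
    t50 = float(np.clip(rng.normal(spec.t50_mean, spec.t50_sd), 36.0, 47.5))
    gap = float(np.clip(rng.normal(THRESHOLD_GAP_MEAN, THRESHOLD_GAP_SD), 1.0, 8.0))
    threshold = max(t50 - gap, RAMP_BASELINE + 1.0)
    if group == Group.PATIENT:
        recruitment = (
            Recruitment.PAIN_CLINIC if rng.random() < _P_PAIN_CLINIC else Recruitment.OUTPATIENT
        )
        duration = "3-6mo" if rng.random() < _P_DURATION_SHORT else ">6mo"
        pattern = "persistent" if rng.random() < _P_PERSISTENT else "recurrent"
        location = str(rng.choice(_LOCATIONS, p=_LOCATION_P))
        secondary = bool(rng.random() < _P_SECONDARY)
        if rng.random() < _P_PAIN_BEFORE:
            pain = float(
                np.clip(
                    np.round(rng.normal(_PAIN_BEFORE_MEAN, _PAIN_BEFORE_SD) * 2) / 2, 0.5, 10.0
                )
            )
        else:
            pain = 0.0
        descriptors = PainDescriptors(duration, pattern, location, secondary)
    else:
        recruitment = Recruitment.COMMUNITY
        pain = 0.0
        descriptors = PainDescriptors()
    return _Demographics(gender, age, t50, threshold, recruitment, pain, descriptors)


def generate_session(
    participant_id: str,
    spec: PhenotypeSpec,
    group: Group,
    config: GeneratorConfig,
    rng: np.random.Generator,
    log: Optional[list[str]] = None,
) -> tuple[ParticipantSession, dict]:
    """Generate one raw session plus its latent-truth row."""
    log = log if log is not None else []
    demo = _draw_demographics(spec, group, rng)
    tsp1, cs_raw, tsp2, cpm, prof1, prof2 = _draw_targets(
        spec, rng, config.sample_rate_hz, log, participant_id
    )

    # withdrawal: latent cold pain above the phenotype's upper quantile
    withdraw = False
    if spec.withdrawal_prob > 0:
        if spec.cs_sd > 0:
            q = norm.ppf(1.0 - spec.withdrawal_prob, loc=spec.cs_mean, scale=spec.cs_sd)
            withdraw = cs_raw > q
        else:  # degenerate spec: fall back to an independent draw
            withdraw = bool(rng.random() < spec.withdrawal_prob)
    cs_target = 10.0 if withdraw else float(np.clip(cs_raw, 0.0, 10.0))

    jitter_sd = 0.15 if config.noise_sd > 0 else 0.0
    pretest = []
    for phase in (Phase.PRETEST_1, Phase.PRETEST_2, Phase.PRETEST_3):
        t50_trial = demo.t50_c + (rng.normal(0.0, jitter_sd) if jitter_sd else 0.0)
        pretest.append(_pretest_trace(phase, t50_trial, demo.threshold_c, config, rng))

    ts1 = _tonic_trace(Phase.TS1, prof1, config, rng)
    ts2 = _tonic_trace(Phase.TS2, prof2, config, rng)
    cs = _withdrawal_series(config, rng) if withdraw else _cs_ratings(cs_target, config, rng)

    session = ParticipantSession(
        participant_id=participant_id,
        group=group,
        gender=demo.gender,
        age_years=demo.age_years,
        recruitment=demo.recruitment,
        pain_before_nrs=demo.pain_before_nrs,
        pain_descriptors=demo.descriptors,
        pretest=pretest,
        ts1=ts1,
        ts2=ts2,
        cs=cs,
        t50_c=demo.t50_c,
    )
    truth = {
        "participant_id": participant_id,
        "phenotype": spec.name,
        "tsp1_target": tsp1,
        "cs_target": cs_target,
        "tsp2_target": tsp2,
        "cpm_target": cpm,
        "withdrawal": withdraw,
        "incomplete": False,
    }
    return session, truth


def generate_cohort(config: GeneratorConfig) -> tuple[Cohort, pd.DataFrame]:
    """Generate the full cohort (patients + controls) and the latent-truth
    table. Deterministic given ``config.seed``; an ``incomplete_fraction`` of
    patient sessions have one phase deleted at random."""
    rng = np.random.default_rng(config.seed)
    log: list[str] = [f"generator seed {config.seed}"]
    weights = np.array([p.weight for p in config.phenotypes])
    weights = weights / weights.sum()

    sessions: list[ParticipantSession] = []
    truths: list[dict] = []
    assignments = rng.choice(len(config.phenotypes), size=config.n_patients, p=weights)
    for i in range(config.n_patients):
        pid = f"P{i + 1:04d}"
        spec = config.phenotypes[int(assignments[i])]
        session, truth = generate_session(pid, spec, Group.PATIENT, config, rng, log)
        sessions.append(session)
        truths.append(truth)
    for i in range(config.n_controls):
        pid = f"C{i + 1:04d}"
        session, truth = generate_session(
            pid, config.control, Group.CONTROL, config, rng, log
        )
        sessions.append(session)
        truths.append(truth)

    n_incomplete = int(round(config.incomplete_fraction * config.n_patients))
    if n_incomplete > 0:
        victims = rng.choice(config.n_patients, size=n_incomplete, replace=False)
        for v in sorted(victims):
            s = sessions[int(v)]
            part = str(rng.choice(["ts1", "ts2", "cs", "t50"]))
            if part == "ts1":
                s.ts1 = None
            elif part == "ts2":
                s.ts2 = None
            elif part == "cs":
                s.cs = None
            else:
                s.t50_c = None
                s.pretest = []
            truths[int(v)]["incomplete"] = True
            log.append(f"{s.participant_id}: deleted {part} (incomplete session)")

    cohort = Cohort(sessions=sessions, invalid={}, provenance=log)
    return cohort, pd.DataFrame(truths)


def write_latent_truth(truth: pd.DataFrame, path) -> None:
    truth.to_csv(path, index=False)
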