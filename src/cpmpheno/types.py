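"""Core domain containers for a conditioned pain modulation (CPM) assessment.

A session comprises up to three pretest thermode ramps (0.3 °C/s from 32 °C,
continuous 0–100 CoVAS rating), two 120-s tonic heat test stimuli (TS1 before
and TS2 after conditioning) at the individually calibrated T50 temperature,
and a 120-s cold-pressor conditioning stimulus (CS) rated verbally on a 0–10
NRS every 15 s, with optional early withdrawal.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "Phase",
    "Group",
    "Gender",
    "Recruitment",
    "CpmClass",
    "TspClass",
    "ThermalTrace",
    "ColdPressorSeries",
    "PainDescriptors",
    "ParticipantSession",
    "Cohort",
    "ScoreRecord",
    "UndefinedScoreError",
]

RAMP_RATE_C_PER_S = 0.3
RAMP_BASELINE_C = 32.0
TONIC_DURATION_S = 120.0
NRS_STEP = 0.5


class Phase(str, Enum):
    PRETEST_1 = "PRETEST_1"
    PRETEST_2 = "PRETEST_2"
    PRETEST_3 = "PRETEST_3"
    TS1 = "TS1"
    TS2 = "TS2"
    CS = "CS"


class Group(str, Enum):
    PATIENT = "PATIENT"
    CONTROL = "CONTROL"


class Gender(str, Enum):
    FEMALE = "FEMALE"
    MALE = "MALE"


class Recruitment(str, Enum):
    PAIN_CLINIC = "PAIN_CLINIC"
    OUTPATIENT = "OUTPATIENT"
    COMMUNITY = "COMMUNITY"


class CpmClass(str, Enum):
    OPTIMAL = "OPTIMAL"
    SUBOPTIMAL = "SUBOPTIMAL"
    INEFFICIENT = "INEFFICIENT"


class TspClass(str, Enum):
    DECREASE = "DECREASE"
    CONSTANT = "CONSTANT"
    INCREASE = "INCREASE"


class UndefinedScoreError(ValueError):
    """A psychophysical score is undefined for this session (e.g. no pain
    reported during any pretest ramp, or zero mean pain during TS1)."""


@dataclass
class ThermalTrace:
    """Time-stamped CoVAS samples (optionally with thermode temperature)
    for one heat stimulus phase; times are seconds from phase onset."""

    phase: Phase
    time_s: np.ndarray
    covas: np.ndarray
    temperature_c: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.covas = np.asarray(self.covas, dtype=float)
        if self.temperature_c is not None:
            self.temperature_c = np.asarray(self.temperature_c, dtype=float)

    def validate(self) -> list[str]:
        """Return a list of invariant violations (empty means valid)."""
        problems: list[str] = []
        if self.time_s.size < 2:
            problems.append(f"{self.phase.value}: fewer than 2 samples")
            return problems
        if not np.all(np.diff(self.time_s) > 0):
            problems.append(f"{self.phase.value}: times not strictly increasing")
        if np.any(self.covas < 0) or np.any(self.covas > 100):
            problems.append(f"{self.phase.value}: CoVAS outside [0, 100]")
        if self.phase in (Phase.TS1, Phase.TS2):
            if self.time_s[0] > 0 or self.time_s[-1] < TONIC_DURATION_S:
                problems.append(
                    f"{self.phase.value}: span does not cover [0, {TONIC_DURATION_S:g}] s"
                )
        if self.phase in (Phase.PRETEST_1, Phase.PRETEST_2, Phase.PRETEST_3):
            if self.temperature_c is None:
                problems.append(f"{self.phase.value}: pretest ramp lacks temperature")
            elif np.any(np.diff(self.temperature_c) < 0):
                problems.append(f"{self.phase.value}: ramp temperature decreasing")
        return problems

    @property
    def span(self) -> tuple[float, float]:
        return float(self.time_s[0]), float(self.time_s[-1])


@dataclass
class ColdPressorSeries:
    """Cold-pressor NRS ratings every 15 s over 120 s, with optional early
    withdrawal (arm removal); no ratings may follow a withdrawal."""

    time_s: np.ndarray
    nrs: np.ndarray
    withdrawal_time_s: Optional[float] = None

    def __post_init__(self) -> None:
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.nrs = np.asarray(self.nrs, dtype=float)

    def validate(self) -> list[str]:
        problems: list[str] = []
        t = self.time_s
        if np.any((t <= 0) | (t > TONIC_DURATION_S)) or np.any(np.mod(t, 15.0) != 0):
            problems.append("CS: rating times must be multiples of 15 in (0, 120]")
        if np.any(self.nrs < 0) or np.any(self.nrs > 10):
            problems.append("CS: NRS outside [0, 10]")
        if self.withdrawal_time_s is not None and np.any(t > self.withdrawal_time_s):
            problems.append("CS: ratings recorded after withdrawal")
        if self.nrs.size == 0 and self.withdrawal_time_s is None:
            problems.append("CS: no ratings and no withdrawal")
        return problems

    @property
    def withdrew(self) -> bool:
        return (
            self.withdrawal_time_s is not None
            and self.withdrawal_time_s < TONIC_DURATION_S
        )


@dataclass
class PainDescriptors:
    duration_class: Optional[str] = None        # "3-6mo" | ">6mo"
    pattern: Optional[str] = None               # "persistent" | "recurrent"
    primary_location: Optional[str] = None
    secondary_sites: Optional[bool] = None


@dataclass
class ParticipantSession:
    participant_id: str
    group: Group
    gender: Gender
    age_years: float
    recruitment: Recruitment
    pain_before_nrs: Optional[float] = None
    pain_descriptors: PainDescriptors = field(default_factory=PainDescriptors)
    pretest: list[ThermalTrace] = field(default_factory=list)
    ts1: Optional[ThermalTrace] = None
    ts2: Optional[ThermalTrace] = None
    cs: Optional[ColdPressorSeries] = None
    t50_c: Optional[float] = None

    @property
    def has_t50_source(self) -> bool:
        return self.t50_c is not None or len(self.pretest) > 0

    @property
    def is_complete(self) -> bool:
        return (
            self.ts1 is not None
            and self.ts2 is not None
            and self.cs is not None
            and self.has_t50_source
        )

    def validate(self) -> list[str]:
        problems: list[str] = []
        if not self.has_t50_source:
            problems.append("no T50 source (neither t50_c nor pretest traces)")
        for tr in self.pretest:
            problems.extend(tr.validate())
        for tr in (self.ts1, self.ts2):
            if tr is not None:
                problems.extend(tr.validate())
        if self.cs is not None:
            problems.extend(self.cs.validate())
        return problems


@dataclass
class Cohort:
    """A collection of sessions with unique participant ids.  Sessions that
    fail validation are kept but flagged, so exclusion counts stay reportable."""

    sessions: list[ParticipantSession] = field(default_factory=list)
    invalid: dict[str, str] = field(default_factory=dict)  # participant_id -> reason
    provenance: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [s.participant_id for s in self.sessions]
        if len(ids) != len(set(ids)):
            raise ValueError("duplicate participant_id in cohort")

    def __len__(self) -> int:
        return len(self.sessions)

    def valid_sessions(self) -> list[ParticipantSession]:
        return [s for s in self.sessions if s.participant_id not in self.invalid]


@dataclass
class ScoreRecord:
    """Per-participant psychophysical scores.

    The four cluster indicator variables are ``tsp1``, ``cs_mean``, ``tsp2``
    and ``cpm_pct``; ``cpm_pct`` is stored unclipped (clipping to the −100..100
    reporting range happens only at presentation time).
    """

    participant_id: str
    group: Group
    gender: Gender
    age_years: float
    t50_c: Optional[float]
    threshold_c: Optional[float]
    mean_ts1: float
    mean_ts2: float
    tsp1: float
    tsp2: float
    cs_mean: float
    cpm_pct: float
    cpm_class: CpmClass
    tsp1_class: TspClass
    tsp2_class: TspClass
    withdrawal: bool

    INDICATORS = ("tsp1", "cs_mean", "tsp2", "cpm_pct")

    def indicator_vector(self) -> np.ndarray:
        return np.array([self.tsp1, self.cs_mean, self.tsp2, self.cpm_pct])


def as_enum(cls, value, field_name: str):
    """Parse ``value`` into enum ``cls`` with a readable error."""
    try:
        return cls(str(value).strip().upper())
    except ValueError as exc:
        options = ", ".join(m.value for m in cls)
        raise ValueError(f"invalid {field_name} {value!r}; expected one of {options}") from exc
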