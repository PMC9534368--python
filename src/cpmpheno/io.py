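"""Reading and writing session time series, cohort metadata and score tables.

Two CSV schemas carry a cohort:

``cohort.csv`` (one row per participant)
    participant_id, group, gender, age_years, recruitment, pain_before_nrs,
    duration_class, pattern, primary_location, secondary_sites, t50_c,
    withdrawal_time_s

``traces.csv`` (long format, one row per sample)
    participant_id, phase, time_s, value, temperature_c, stimulus_kind

where ``phase`` is one of PRETEST_1..3, TS1, TS2, CS; ``value`` is CoVAS
(0–100) for heat phases and NRS (0–10) for CS; ``temperature_c`` is present
for pretest ramps. Missing values are empty strings; files are UTF-8 with a
header row.
"""

from __future__ import annotations

import math
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .types import (
    Cohort,
    ColdPressorSeries,
    CpmClass,
    Gender,
    Group,
    PainDescriptors,
    ParticipantSession,
    Phase,
    Recruitment,
    ScoreRecord,
    ThermalTrace,
    TspClass,
    as_enum,
)
from .scoring import pretest_t50
from .types import UndefinedScoreError

__all__ = [
    "read_cohort",
    "write_cohort",
    "filter_complete",
    "write_scores",
    "read_scores",
    "METADATA_COLUMNS",
    "TRACE_COLUMNS",
    "SCORE_COLUMNS",
]

PathLike = Union[str, Path]

METADATA_COLUMNS = [
    "participant_id",
    "group",
    "gender",
    "age_years",
    "recruitment",
    "pain_before_nrs",
    "duration_class",
    "pattern",
    "primary_location",
    "secondary_sites",
    "t50_c",
    "withdrawal_time_s",
]
METADATA_REQUIRED = ["participant_id", "group", "gender", "age_years", "recruitment"]

TRACE_COLUMNS = ["participant_id", "phase", "time_s", "value", "temperature_c", "stimulus_kind"]
TRACE_REQUIRED = ["participant_id", "phase", "time_s", "value"]

SCORE_COLUMNS = [
    "participant_id",
    "group",
    "gender",
    "age_years",
    "t50_c",
    "threshold_c",
    "mean_ts1",
    "mean_ts2",
    "tsp1",
    "tsp2",
    "cs_mean",
    "cpm_pct",
    "cpm_class",
    "tsp1_class",
    "tsp2_class",
    "withdrawal",
]

def _optional_float(value) -> Optional[float]:
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return None
    s = str(value).strip()
    if s == "":
        return None
    return float(s)


def _optional_bool(value) -> Optional[bool]:
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return None
    s = str(value).strip().lower()
    if s == "":
        return None
    if s in ("1", "true", "yes", "y"):
        return True
    if s in ("0", "false", "no", "n"):
        return False
    raise ValueError(f"cannot parse boolean {value!r}")


def _check_columns(df: pd.DataFrame, required: Sequence[str], what: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{what} is missing required column(s): {', '.join(missing)}")


def read_cohort(metadata_path: PathLike, traces_path: PathLike) -> Cohort:
    """Assemble a validated :class:`Cohort` from the two CSV schemas.

    Malformed trace rows are logged (with 1-based data line numbers) in the
    cohort provenance; a session with any out-of-range or inconsistent data
    is flagged invalid rather than dropped. Duplicate (participant, phase,
    time) rows and missing required columns are hard errors.
    """
    meta = pd.read_csv(metadata_path, dtype={"participant_id": str}, float_precision="round_trip")
    traces = pd.read_csv(
        traces_path, dtype={"participant_id": str, "phase": str}, float_precision="round_trip"
    )
    _check_columns(meta, METADATA_REQUIRED, f"metadata file {metadata_path}")
    _check_columns(traces, TRACE_REQUIRED, f"traces file {traces_path}")

    log: list[str] = [f"metadata: {metadata_path}", f"traces: {traces_path}"]
    invalid: dict[str, str] = {}

    dup = traces.duplicated(subset=["participant_id", "phase", "time_s"], keep=False)
    if dup.any():
        rows = (traces.index[dup] + 2).tolist()[:5]
        raise ValueError(
            f"duplicate (participant_id, phase, time_s) rows in traces file (lines {rows})"
        )

    # malformed numeric rows: logged with line number and removed before assembly
    bad_time = pd.to_numeric(traces["time_s"], errors="coerce").isna()
    bad_value = pd.to_numeric(traces["value"], errors="coerce").isna()
    bad = bad_time | bad_value
    for i in traces.index[bad]:
        log.append(f"traces line {i + 2}: unparseable time_s/value; row skipped")
        pid = traces.at[i, "participant_id"]
        invalid.setdefault(str(pid), f"malformed trace row at line {i + 2}")
    traces = traces[~bad].copy()
    traces["time_s"] = traces["time_s"].astype(float)
    traces["value"] = traces["value"].astype(float)
    if "temperature_c" in traces.columns:
        traces["temperature_c"] = pd.to_numeric(traces["temperature_c"], errors="coerce")

    grouped = {pid: g for pid, g in traces.groupby("participant_id", sort=False)}

    sessions: list[ParticipantSession] = []
    for _, row in meta.iterrows():
        pid = str(row["participant_id"])
        try:
            session = _build_session(pid, row, grouped.get(pid))
        except ValueError as exc:
            log.append(f"participant {pid}: {exc}")
            invalid[pid] = str(exc)
            session = _fallback_session(pid, row)
            if session is None:
                continue
        problems = session.validate()
        if problems:
            reason = "; ".join(problems)
            log.append(f"participant {pid}: {reason}")
            invalid.setdefault(pid, reason)
        sessions.append(session)

    return Cohort(sessions=sessions, invalid=invalid, provenance=log)


def _fallback_session(pid: str, row: pd.Series) -> Optional[ParticipantSession]:
    try:
        return ParticipantSession(
            participant_id=pid,
            group=as_enum(Group, row["group"], "group"),
            gender=as_enum(Gender, row["gender"], "gender"),
            age_years=float(row["age_years"]),
            recruitment=as_enum(Recruitment, row["recruitment"], "recruitment"),
        )
    except (ValueError, KeyError):
        return None


def _build_session(pid: str, row: pd.Series, tr: Optional[pd.DataFrame]) -> ParticipantSession:
    descriptors = PainDescriptors(
        duration_class=(str(row["duration_class"]) if _has(row, "duration_class") else None),
        pattern=(str(row["pattern"]) if _has(row, "pattern") else None),
        primary_location=(str(row["primary_location"]) if _has(row, "primary_location") else None),
        secondary_sites=_optional_bool(row.get("secondary_sites")),
    )
    session = ParticipantSession(
        participant_id=pid,
        group=as_enum(Group, row["group"], "group"),
        gender=as_enum(Gender, row["gender"], "gender"),
        age_years=float(row["age_years"]),
        recruitment=as_enum(Recruitment, row["recruitment"], "recruitment"),
        pain_before_nrs=_optional_float(row.get("pain_before_nrs")),
        pain_descriptors=descriptors,
        t50_c=_optional_float(row.get("t50_c")),
    )
    withdrawal_time = _optional_float(row.get("withdrawal_time_s"))

    if tr is not None:
        for phase_name, g in tr.groupby("phase", sort=False):
            phase = as_enum(Phase, phase_name, "phase")
            g = g.sort_values("time_s")
            if phase == Phase.CS:
                session.cs = ColdPressorSeries(
                    time_s=g["time_s"].to_numpy(),
                    nrs=g["value"].to_numpy(),
                    withdrawal_time_s=withdrawal_time,
                )
            else:
                temp = None
                if "temperature_c" in g.columns and g["temperature_c"].notna().all():
                    temp = g["temperature_c"].to_numpy()
                trace = ThermalTrace(
                    phase=phase, time_s=g["time_s"].to_numpy(),
                    covas=g["value"].to_numpy(), temperature_c=temp,
                )
                if phase in (Phase.PRETEST_1, Phase.PRETEST_2, Phase.PRETEST_3):
                    session.pretest.append(trace)
                elif phase == Phase.TS1:
                    session.ts1 = trace
                else:
                    session.ts2 = trace
    elif withdrawal_time is not None:
        session.cs = ColdPressorSeries(
            time_s=np.array([]), nrs=np.array([]), withdrawal_time_s=withdrawal_time
        )
    return session


def _has(row: pd.Series, key: str) -> bool:
    v = row.get(key)
    if v is None or (isinstance(v, float) and math.isnan(v)):
        return False
    return str(v).strip() != ""


def filter_complete(cohort: Cohort) -> tuple[Cohort, list[tuple[str, str]]]:
    """Retain sessions with TS1, TS2 and CS present, a determinable T50 and no
    validation flags; return the retained cohort and an exclusion report of
    (participant_id, reason) pairs. Retained sessions are passed through
    untouched."""
    retained: list[ParticipantSession] = []
    report: list[tuple[str, str]] = []
    for s in cohort.sessions:
        if s.participant_id in cohort.invalid:
            report.append((s.participant_id, cohort.invalid[s.participant_id]))
            continue
        missing = [
            name
            for name, part in (("TS1", s.ts1), ("TS2", s.ts2), ("CS", s.cs))
            if part is None
        ]
        if missing:
            report.append((s.participant_id, f"missing {'/'.join(missing)}"))
            continue
        if s.t50_c is None:
            if not s.pretest:
                report.append((s.participant_id, "no T50 source"))
                continue
            try:
                pretest_t50(s.pretest)
            except UndefinedScoreError:
                report.append((s.participant_id, "T50 undetermined (no pretest reached 50)"))
                continue
        retained.append(s)
    if not retained:
        raise ValueError("no complete sessions retained")
    kept = Cohort(
        sessions=retained,
        invalid={},
        provenance=cohort.provenance + [f"filter_complete: excluded {len(report)}"],
    )
    return kept, report


def write_cohort(cohort: Cohort, metadata_path: PathLike, traces_path: PathLike) -> None:
    """Serialize a cohort back to the two CSV schemas (inverse of read_cohort)."""
    meta_rows = []
    trace_rows: list[dict] = []
    for s in cohort.sessions:
        d = s.pain_descriptors
        meta_rows.append(
            {
                "participant_id": s.participant_id,
                "group": s.group.value,
                "gender": s.gender.value,
                "age_years": float(s.age_years),
                "recruitment": s.recruitment.value,
                "pain_before_nrs": None if s.pain_before_nrs is None else float(s.pain_before_nrs),
                "duration_class": d.duration_class,
                "pattern": d.pattern,
                "primary_location": d.primary_location,
                "secondary_sites": d.secondary_sites,
                "t50_c": None if s.t50_c is None else float(s.t50_c),
                "withdrawal_time_s": (
                    None
                    if s.cs is None or s.cs.withdrawal_time_s is None
                    else float(s.cs.withdrawal_time_s)
                ),
            }
        )
        for tr in list(s.pretest) + [t for t in (s.ts1, s.ts2) if t is not None]:
            kind = "RAMP" if tr.phase not in (Phase.TS1, Phase.TS2) else "TONIC_HEAT"
            for i in range(tr.time_s.size):
                trace_rows.append(
                    {
                        "participant_id": s.participant_id,
                        "phase": tr.phase.value,
                        "time_s": float(tr.time_s[i]),
                        "value": float(tr.covas[i]),
                        "temperature_c": (
                            float(tr.temperature_c[i]) if tr.temperature_c is not None else None
                        ),
                        "stimulus_kind": kind,
                    }
                )
        if s.cs is not None:
            for i in range(s.cs.time_s.size):
                trace_rows.append(
                    {
                        "participant_id": s.participant_id,
                        "phase": Phase.CS.value,
                        "time_s": float(s.cs.time_s[i]),
                        "value": float(s.cs.nrs[i]),
                        "temperature_c": None,
                        "stimulus_kind": "COLD_PRESSOR",
                    }
                )
    pd.DataFrame(meta_rows, columns=METADATA_COLUMNS).to_csv(metadata_path, index=False)
    pd.DataFrame(trace_rows, columns=TRACE_COLUMNS).to_csv(traces_path, index=False)


def write_scores(records: Sequence[ScoreRecord], path: PathLike) -> None:
    """Write score records as CSV with a stable column order; numeric fields
    round-trip losslessly through :func:`read_scores`."""
    if not records:
        raise ValueError("cannot write an empty score table")
    rows = []
    for r in records:
        rows.append(
            {
                "participant_id": r.participant_id,
                "group": r.group.value,
                "gender": r.gender.value,
                "age_years": repr(float(r.age_years)),
                "t50_c": "" if r.t50_c is None else repr(float(r.t50_c)),
                "threshold_c": "" if r.threshold_c is None else repr(float(r.threshold_c)),
                "mean_ts1": repr(float(r.mean_ts1)),
                "mean_ts2": repr(float(r.mean_ts2)),
                "tsp1": repr(float(r.tsp1)),
                "tsp2": repr(float(r.tsp2)),
                "cs_mean": repr(float(r.cs_mean)),
                "cpm_pct": repr(float(r.cpm_pct)),
                "cpm_class": r.cpm_class.value,
                "tsp1_class": r.tsp1_class.value,
                "tsp2_class": r.tsp2_class.value,
                "withdrawal": r.withdrawal,
            }
        )
    pd.DataFrame(rows, columns=SCORE_COLUMNS).to_csv(path, index=False)


def read_scores(path: PathLike) -> list[ScoreRecord]:
    df = pd.read_csv(path, dtype={"participant_id": str}, float_precision="round_trip")
    _check_columns(df, SCORE_COLUMNS, f"scores file {path}")
    records = []
    for _, row in df.iterrows():
        records.append(
            ScoreRecord(
                participant_id=str(row["participant_id"]),
                group=as_enum(Group, row["group"], "group"),
                gender=as_enum(Gender, row["gender"], "gender"),
                age_years=float(row["age_years"]),
                t50_c=_optional_float(row["t50_c"]),
                threshold_c=_optional_float(row["threshold_c"]),
                mean_ts1=float(row["mean_ts1"]),
                mean_ts2=float(row["mean_ts2"]),
                tsp1=float(row["tsp1"]),
                tsp2=float(row["tsp2"]),
                cs_mean=float(row["cs_mean"]),
                cpm_pct=float(row["cpm_pct"]),
                cpm_class=as_enum(CpmClass, row["cpm_class"], "cpm_class"),
                tsp1_class=as_enum(TspClass, row["tsp1_class"], "tsp1_class"),
                tsp2_class=as_enum(TspClass, row["tsp2_class"], "tsp2_class"),
                withdrawal=bool(_optional_bool(row["withdrawal"])),
            )
        )
    return records
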