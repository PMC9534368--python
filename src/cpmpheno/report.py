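"""Report tables: cluster demographics (χ² / gender-adjusted ANOVA) and
indicator-variable comparisons across clusters and controls.

Percentages and statistics in the report tables are rounded half-up at the
configured precision; machine-readable outputs keep full precision.
"""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .cluster import ClusterResult
from .stats import (
    ContingencyTable,
    anova_gender_controlled,
    pearson_chi2,
    scheffe_pairwise,
)
from .types import Group, ScoreRecord, CpmClass, TspClass

__all__ = [
    "round_half_up",
    "report_category_table",
    "demographics_table",
    "indicator_table",
]

_CPM_ORDER = [CpmClass.INEFFICIENT, CpmClass.SUBOPTIMAL, CpmClass.OPTIMAL]
_TSP_ORDER = [TspClass.DECREASE, TspClass.CONSTANT, TspClass.INCREASE]


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Decimal half-up rounding (the tables' convention, e.g. 271/608 → 44.57)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def _columns(
    patients: Sequence[ScoreRecord],
    assignment: dict[str, int],
    controls: Sequence[ScoreRecord],
) -> dict[str, list[ScoreRecord]]:
    ks = sorted(set(assignment.values()))
    cols: dict[str, list[ScoreRecord]] = {f"cluster{k}": [] for k in ks}
    for r in patients:
        cols[f"cluster{assignment[r.participant_id]}"].append(r)
    if controls:
        cols["controls"] = list(controls)
    return cols


def report_category_table(
    records: Sequence[ScoreRecord],
    result: ClusterResult,
    controls: Sequence[ScoreRecord] = (),
) -> dict[str, tuple[ContingencyTable, float, int, float]]:
    """Cross-tabulate the TSP1, TSP2 and CPM categories against cluster
    columns (plus a controls column when given) and run the Pearson χ² on
    each; returns {name: (table, statistic, df, p)}."""
    assignment = dict(zip(result.participant_ids, (int(l) for l in result.labels_consolidated)))
    patients = [r for r in records if r.participant_id in assignment]
    cols = _columns(patients, assignment, controls)

    out = {}
    for name, attr, order in (
        ("tsp1_class", "tsp1_class", _TSP_ORDER),
        ("tsp2_class", "tsp2_class", _TSP_ORDER),
        ("cpm_class", "cpm_class", _CPM_ORDER),
    ):
        counts = np.array(
            [
                [sum(1 for r in rs if getattr(r, attr) == cat) for rs in cols.values()]
                for cat in order
            ],
            dtype=int,
        )
        # drop all-zero category rows so the χ² marginal rule can run
        keep = counts.sum(axis=1) > 0
        table = ContingencyTable(
            row_labels=[c.value for c, k in zip(order, keep) if k],
            col_labels=list(cols.keys()),
            counts=counts[keep],
        )
        stat, df, p = pearson_chi2(table)
        out[name] = (table, stat, df, p)
    return out


def demographics_table(
    records: Sequence[ScoreRecord],
    result: ClusterResult,
    sessions_meta: Optional[pd.DataFrame] = None,
    precision: int = 2,
) -> pd.DataFrame:
    """Demographic characteristics per cluster: gender counts with χ², age
    summaries with the gender-adjusted ANOVA F."""
    assignment = dict(zip(result.participant_ids, (int(l) for l in result.labels_consolidated)))
    patients = [r for r in records if r.participant_id in assignment]
    cols = _columns(patients, assignment, ())

    rows = []
    # gender
    counts = np.array(
        [
            [sum(1 for r in rs if r.gender.value == gval) for rs in cols.values()]
            for gval in ("FEMALE", "MALE")
        ],
        dtype=int,
    )
    stat, df, p = pearson_chi2(
        ContingencyTable(["Female", "Male"], list(cols.keys()), counts)
    )
    rows.append({"variable": "Gender", "test": "chi2", "statistic": round_half_up(stat, precision), "p": round_half_up(p, 3)})
    for gi, gval in enumerate(("Female", "Male")):
        row = {"variable": f"  {gval}, n (%)", "test": "", "statistic": np.nan, "p": np.nan}
        for ci, (cname, rs) in enumerate(cols.items()):
            pct = round_half_up(100.0 * counts[gi, ci] / len(rs), precision)
            row[cname] = f"{counts[gi, ci]} ({pct})"
        rows.append(row)
    # age: gender-adjusted ANOVA across clusters
    values = [r.age_years for r in patients]
    groups = [f"cluster{assignment[r.participant_id]}" for r in patients]
    genders = [r.gender.value for r in patients]
    res = anova_gender_controlled(values, groups, genders)
    age_row = {
        "variable": "Age, mean ± SD",
        "test": "anova_gender_adj",
        "statistic": round_half_up(res.F_group, precision),
        "p": round_half_up(res.p_value, 3),
    }
    for cname, rs in cols.items():
        ages = np.array([r.age_years for r in rs])
        age_row[cname] = f"{round_half_up(ages.mean(), precision)} ± {round_half_up(ages.std(ddof=1), precision)}"
    rows.append(age_row)
    return pd.DataFrame(rows)


def indicator_table(
    records: Sequence[ScoreRecord],
    result: ClusterResult,
    controls: Sequence[ScoreRecord] = (),
    precision: int = 2,
) -> pd.DataFrame:
    """Indicator variables (plus T50/threshold) by cluster and controls:
    mean ± SD columns, gender-adjusted ANOVA F, ω², Scheffé letter codes, and
    the category-count rows with their χ²."""
    assignment = dict(zip(result.participant_ids, (int(l) for l in result.labels_consolidated)))
    patients = [r for r in records if r.participant_id in assignment]
    cols = _columns(patients, assignment, controls)

    def col_group(r: ScoreRecord) -> str:
        if r.participant_id in assignment:
            return f"cluster{assignment[r.participant_id]}"
        return "controls"

    everyone = patients + list(controls)
    rows = []
    numeric_vars = [
        ("Heat pain threshold (°C)", "threshold_c"),
        ("Test temperature T50 (°C)", "t50_c"),
        ("TSP1: ΔCoVAS last 60 s of TS1", "tsp1"),
        ("Average pain during CS (NRS)", "cs_mean"),
        ("TSP2: ΔCoVAS last 60 s of TS2", "tsp2"),
        ("CPM efficiency (%)", "cpm_pct"),
    ]
    for label, attr in numeric_vars:
        subset = [r for r in everyone if getattr(r, attr) is not None]
        values = [float(getattr(r, attr)) for r in subset]
        groups = [col_group(r) for r in subset]
        genders = [r.gender.value for r in subset]
        res = anova_gender_controlled(values, groups, genders)
        scheffe = scheffe_pairwise(values, groups, genders)
        letters = _letter_codes(sorted(set(groups)), scheffe)
        row = {
            "variable": label,
            "test": "anova_gender_adj",
            "statistic": round_half_up(res.F_group, precision),
            "p": round_half_up(res.p_value, 3),
            "omega_sq": round_half_up(res.omega_sq, precision),
            "magnitude": res.magnitude.value,
        }
        arr = {g: [] for g in set(groups)}
        for v, g in zip(values, groups):
            arr[g].append(v)
        for cname in cols:
            if cname in arr:
                a = np.array(arr[cname])
                row[cname] = (
                    f"{round_half_up(a.mean(), precision)} ± {round_half_up(a.std(ddof=1), precision)}"
                    + (f" [{letters[cname]}]" if letters.get(cname) else "")
                )
        rows.append(row)

    for name, (table, stat, df, p) in report_category_table(records, result, controls).items():
        rows.append(
            {
                "variable": f"{name} categories",
                "test": "chi2",
                "statistic": round_half_up(stat, precision),
                "p": round_half_up(p, 3),
            }
        )
        frame = table.to_frame()
        for cat in frame.index:
            row = {"variable": f"  {cat}, n (%)", "test": "", "statistic": np.nan, "p": np.nan}
            for cname in frame.columns:
                n_col = sum(frame[cname])
                pct = round_half_up(100.0 * frame.loc[cat, cname] / n_col, precision)
                row[cname] = f"{frame.loc[cat, cname]} ({pct})"
            rows.append(row)
    return pd.DataFrame(rows)


def _letter_codes(groups: list[str], pairwise, alpha: float = 0.05) -> dict[str, str]:
    """Compact letter display: each group is tagged with the letters of the
    *other* groups it differs from significantly (a = first group, ...)."""
    letter = {g: chr(ord("a") + i) for i, g in enumerate(groups)}
    codes = {}
    for g in groups:
        marks = []
        for h in groups:
            if h == g:
                continue
            try:
                if pairwise.p(g, h) < alpha:
                    marks.append(letter[h])
            except KeyError:
                pass
        codes[g] = "".join(sorted(marks))
    return codes
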