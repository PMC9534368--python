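"""Reference computations used by the acceptance checks.

The printed cross-tabulations of the study population (category counts by
cluster and control group, and demographic counts by cluster) serve as exact
inputs for the χ² reproductions; the remaining checks are property-based
computations on synthetic cohorts and random fixtures.
"""

from __future__ import annotations

import numpy as np

from .stats import ContingencyTable, pearson_chi2

# Cross-tabulations of the 608-patient / 60-control study population.
# Columns: cluster 1, cluster 2, cluster 3 (and control subjects where given).
PUBLISHED_TABLES: dict[str, dict] = {
    "gender_by_cluster": {
        "rows": ["Female", "Male"],
        "cols": ["cluster1", "cluster2", "cluster3"],
        "counts": [[218, 156, 118], [53, 30, 33]],
    },
    "recruitment_by_cluster": {
        "rows": ["Chronic pain clinic", "Orthopedic outpatient clinic"],
        "cols": ["cluster1", "cluster2", "cluster3"],
        "counts": [[106, 81, 72], [165, 105, 79]],
    },
    "duration_by_cluster": {
        "rows": ["3-6 mo", "More than 6 mo"],
        "cols": ["cluster1", "cluster2", "cluster3"],
        "counts": [[18, 9, 13], [253, 177, 138]],
    },
    "secondary_sites_by_cluster": {
        "rows": ["No", "Yes"],
        "cols": ["cluster1", "cluster2", "cluster3"],
        "counts": [[139, 94, 65], [132, 92, 86]],
    },
    "ts1_class_by_group": {
        "rows": ["Decrease", "Constant", "Increase"],
        "cols": ["cluster1", "cluster2", "cluster3", "controls"],
        "counts": [[73, 12, 6, 5], [189, 139, 102, 43], [9, 35, 43, 12]],
    },
    "ts2_class_by_group": {
        "rows": ["Decrease", "Constant", "Increase"],
        "cols": ["cluster1", "cluster2", "cluster3", "controls"],
        "counts": [[39, 11, 7, 4], [222, 157, 86, 47], [10, 18, 58, 9]],
    },
    "cpm_class_by_group": {
        "rows": ["Inefficient", "Suboptimal", "Optimal"],
        "cols": ["cluster1", "cluster2", "cluster3", "controls"],
        "counts": [[45, 44, 97, 14], [61, 44, 24, 12], [165, 98, 30, 34]],
    },
}

CLUSTER_SIZES = (271, 186, 151)
N_PATIENTS = 608


def published_chi2(name: str) -> tuple[float, int, float]:
    spec = PUBLISHED_TABLES[name]
    table = ContingencyTable(spec["rows"], spec["cols"], np.asarray(spec["counts"]))
    return pearson_chi2(table)
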