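"""Two-cluster hierarchical patient stratification and cluster summaries.

Patients are clustered per modality by hierarchical agglomerative
clustering (Ward linkage on Euclidean distances over z-scored features,
the common default — the choice is pinned in the run config) and the
dendrogram is cut into exactly two clusters.  Each cluster is then
characterised descriptively: size, patients with PFS > 12 months,
OS > 12 months, and CD8 strictly above the cohort median.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

__all__ = ["ClusterAssignment", "hac_cluster", "cluster_summary", "compare_assignments"]


@dataclass
class ClusterAssignment:
    modality: str
    labels: pd.Series          # patient_id -> {0, 1, ...}
    linkage: np.ndarray        # scipy linkage matrix (merge heights)
    method: str = "ward"
    metric: str = "euclidean"


def _canonicalize(labels: pd.Series) -> pd.Series:
    """Cluster 0 = larger cluster; size tie -> cluster holding the
    lexicographically smallest patient_id."""
    counts = labels.value_counts()
    order = sorted(
        counts.index,
        key=lambda lab: (-counts[lab], min(labels.index[labels == lab])),
    )
    remap = {old: new for new, old in enumerate(order)}
    return labels.map(remap)


def hac_cluster(
    features: pd.DataFrame,
    k: int = 2,
    method: str = "ward",
    metric: str = "euclidean",
    modality: str = "",
) -> ClusterAssignment:
    """Agglomerative clustering of patients, dendrogram cut at exactly k.

    Expects a z-scored patients x features table.  Labels are
    canonicalized so the output is independent of input row order.
    """
    n = len(features)
    if n < k:
        raise ValueError(f"cannot form {k} clusters from {n} patients")
    # sort rows so the linkage (and any tie-breaking inside it) is
    # independent of the caller's row order
    features = features.sort_index()
    Z = hierarchy.linkage(pdist(features.to_numpy(), metric=metric), method=method)
    raw = hierarchy.fcluster(Z, t=k, criterion="maxclust")
    labels = _canonicalize(pd.Series(raw, index=features.index, name="cluster"))
    return ClusterAssignment(modality=modality, labels=labels, linkage=Z,
                             method=method, metric=metric)


def cluster_summary(assignment: ClusterAssignment, clinical: pd.DataFrame) -> pd.DataFrame:
    """Descriptive per-cluster endpoint summary.

    Counts patients with observed PFS > 12 months, OS > 12 months, and
    CD8 strictly above the cohort median (median over all patients with
    non-missing CD8).  Patients missing an endpoint are excluded from
    that endpoint's denominator.  Display percentages are rounded to
    whole percent; exact fractions are kept alongside.
    """
    missing = assignment.labels.index.difference(clinical.index)
    if len(missing):
        raise ValueError(f"clinical table does not cover patients: {list(missing)}")
    clin = clinical.loc[assignment.labels.index]
    cd8_median = clin["cd8_pct"].median(skipna=True)
    rows = []
    for lab in sorted(assignment.labels.unique()):
        pids = assignment.labels.index[assignment.labels == lab]
        sub = clin.loc[pids]
        row = {"cluster": int(lab), "size": len(pids)}
        for col, key, thresh in (
            ("pfs_months", "pfs_gt12", 12.0),
            ("os_months", "os_gt12", 12.0),
            ("cd8_pct", "cd8_gt_median", cd8_median),
        ):
            obs = sub[col].dropna()
            n_missing = len(sub) - len(obs)
            if n_missing:
                warnings.warn(f"cluster {lab}: {n_missing} patient(s) missing {col}")
            cnt = int((obs > thresh).sum())
            row[f"n_{key}"] = cnt
            row[f"frac_{key}"] = cnt / len(obs) if len(obs) else np.nan
            row[f"pct_{key}"] = int(round(100.0 * cnt / len(obs))) if len(obs) else np.nan
        rows.append(row)
    return pd.DataFrame(rows)


def compare_assignments(a: ClusterAssignment, b: ClusterAssignment) -> dict[str, int]:
    """Patients switching clusters between two modalities.

    Reports both the raw label disagreement and the disagreement after
    aligning labels by the best of the two label permutations (cluster
    labels are arbitrary across independent clusterings).
    """
    if set(a.labels.index) != set(b.labels.index):
        raise ValueError("assignments cover different patient sets")
    la = a.labels.sort_index().to_numpy()
    lb = b.labels.sort_index().to_numpy()
    raw = int((la != lb).sum())
    flipped = int((la != (1 - lb)).sum())
    return {"raw_switches": raw, "aligned_switches": min(raw, flipped)}
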