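"""Two-way hierarchical clustering of the feature matrix and chi-square
association of patient clusters with clinical parameters."""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import dendrogram, fcluster, linkage
from scipy.stats import chi2_contingency


@dataclass
class ClusterAssignment:
    """Patient cluster labels plus both dendrograms (scipy linkage matrices)."""

    labels: pd.Series                 # patient -> cluster id in 1..k
    k: int
    patient_linkage: np.ndarray
    feature_linkage: np.ndarray
    patient_order: list[str]
    feature_order: list[str]


def two_way_cluster(matrix: pd.DataFrame, k_patients: int = 4) -> ClusterAssignment:
    """Average-linkage (UPGMA) Euclidean clustering of patients and features.

    ``matrix`` must be z-normalized and NaN-free (rows = patients).  The
    patient dendrogram is cut into ``k_patients`` flat clusters.
    """
    if matrix.isna().any().any():
        raise ValueError("matrix contains NaN; normalize and clean first")
    if k_patients < 2:
        raise ValueError("k_patients must be >= 2")
    Zp = linkage(matrix.to_numpy(), method="average", metric="euclidean")
    Zf = linkage(matrix.to_numpy().T, method="average", metric="euclidean")
    raw = fcluster(Zp, t=k_patients, criterion="maxclust")
    # relabel clusters 1..k by order of first appearance for determinism
    remap: dict[int, int] = {}
    labels = []
    for c in raw:
        if c not in remap:
            remap[c] = len(remap) + 1
        labels.append(remap[c])
    p_order = dendrogram(Zp, no_plot=True)["leaves"]
    f_order = dendrogram(Zf, no_plot=True)["leaves"]
    return ClusterAssignment(
        labels=pd.Series(labels, index=matrix.index, name="cluster"),
        k=int(max(labels)),
        patient_linkage=Zp,
        feature_linkage=Zf,
        patient_order=[matrix.index[i] for i in p_order],
        feature_order=[matrix.columns[i] for i in f_order],
    )


def chi_square_independence(table: np.ndarray) -> tuple[float, float, int]:
    """Pearson chi-square test of independence, no continuity correction.

    Returns (statistic, p, dof).  Zero-margin rows/columns are dropped first.
    """
    table = np.asarray(table, dtype=float)
    table = table[table.sum(axis=1) > 0][:, table.sum(axis=0) > 0]
    if table.shape[0] < 2 or table.shape[1] < 2:
        raise ValueError("degenerate contingency table")
    stat, p, dof, expected = chi2_contingency(table, correction=False)
    if (expected < 5).any():
        warnings.warn("chi-square expectation < 5 in some cells", stacklevel=2)
    return float(stat), float(p), int(dof)


def cluster_association(
    assignment: ClusterAssignment, clinical: pd.DataFrame
) -> pd.DataFrame:
    """Chi-square association of the patient clusters with each clinical
    parameter; degenerate tables are skipped with a warning."""
    rows = []
    labels = assignment.labels.loc[clinical.index]
    for col in clinical.columns:
        tab = pd.crosstab(labels, clinical[col]).to_numpy()
        try:
            stat, p, dof = chi_square_independence(tab)
        except ValueError:
            warnings.warn(f"skipping degenerate parameter {col!r}", stacklevel=2)
            continue
        rows.append({"parameter": col, "chi2": stat, "dof": dof, "p": p})
    return pd.DataFrame(rows).set_index("parameter")
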