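"""Correlation-based feature-space reduction.

Redundant radiomic features are grouped by agglomerative hierarchical
clustering with average linkage on the distance ``d = 1 - |rho|`` where
``rho`` is the Spearman rank correlation between feature columns (the
absolute value makes redundancy sign-agnostic; the signed variant
``1 - rho`` is available by option).  Clusters are the subtrees lying
entirely below a cut at ``f * h_max`` with ``h_max`` the maximum linkage
height; the default cut fraction is f = 0.6.

From each cluster one representative is kept: the feature with the lowest
univariable likelihood-ratio p-value against the outcome (ties broken by
feature name for reproducibility), and representatives with p >= 0.2 are
dropped before any multivariable selection.

The same machinery clusters patients (rows) on the per-feature Z-scored
table, which is how the patient-cluster vs covariate independence checks
are formed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .models import univariable_screen

__all__ = [
    "FeatureDendrogram",
    "ClusterAssignment",
    "spearman_distance",
    "cluster_features",
    "select_representatives",
    "cluster_patients",
    "reduce_features",
]


@dataclass
class FeatureDendrogram:
    linkage_matrix: np.ndarray
    labels: tuple[str, ...]
    distance: str

    @property
    def h_max(self) -> float:
        return float(self.linkage_matrix[-1, 2])


@dataclass
class ClusterAssignment:
    assignment: pd.Series  # feature -> cluster id (1..k)
    cut_height: float
    cut_fraction: float
    representatives: pd.DataFrame | None = None  # set by select_representatives
    flags: list[str] = field(default_factory=list)

    @property
    def n_clusters(self) -> int:
        return int(self.assignment.nunique())


def spearman_distance(features: pd.DataFrame, absolute: bool = True) -> pd.DataFrame:
    """Pairwise feature distance ``1 - |rho_spearman|`` (or ``1 - rho``).

    Constant columns carry no rank information and are excluded with a
    warning; an all-constant table is an error.
    """
    if len(features) < 2:
        raise ValueError("need at least 2 patients to correlate features")
    const = features.columns[features.nunique() <= 1]
    if len(const) == len(features.columns):
        raise ValueError("all feature columns are constant")
    if len(const):
        warnings.warn(f"excluding {len(const)} constant feature column(s): {list(const)[:5]}...")
        features = features.drop(columns=const)
    rho = stats.spearmanr(features.to_numpy()).statistic
    if np.ndim(rho) == 0:  # spearmanr collapses the 2-column case to a scalar
        rho = np.array([[1.0, float(rho)], [float(rho), 1.0]])
    d = 1.0 - (np.abs(rho) if absolute else rho)
    np.fill_diagonal(d, 0.0)
    d = np.clip((d + d.T) / 2.0, 0.0, None)  # symmetrize away float fuzz
    return pd.DataFrame(d, index=features.columns, columns=features.columns)


def cluster_features(
    distance: pd.DataFrame, cut_fraction: float = 0.6
) -> tuple[FeatureDendrogram, ClusterAssignment]:
    """Average-linkage tree over a feature distance matrix, cut at f * h_max."""
    if not 0.0 < cut_fraction < 1.0:
        raise ValueError(f"cut fraction must be in (0, 1), got {cut_fraction}")
    labels = tuple(distance.columns)
    z = linkage(squareform(distance.to_numpy(), checks=False), method="average")
    dendro = FeatureDendrogram(z, labels, "1-|spearman rho|")
    cut = cut_fraction * dendro.h_max
    ids = fcluster(z, t=cut, criterion="distance")
    assign = pd.Series(ids, index=labels, name="cluster")
    return dendro, ClusterAssignment(assign, cut, cut_fraction)


def select_representatives(
    assignment: ClusterAssignment,
    features: pd.DataFrame,
    labels,
    threshold: float = 0.2,
    outcome: str = "response",
) -> pd.DataFrame:
    """One representative per cluster (lowest univariable LRT p), screened.

    Returns a DataFrame indexed by cluster id with columns ``feature``,
    ``p`` and ``keep`` (p < threshold).  Ties in minimum p break by
    canonical feature-name order.  The result is also stored on
    ``assignment.representatives``.
    """
    y = np.asarray(labels)
    if len(np.unique(y)) < 2:
        raise ValueError("both outcome classes must be present")
    data = features.copy()
    data[outcome] = y
    screen = univariable_screen(data, assignment.assignment.index, outcome=outcome,
                                threshold=threshold)
    rows = []
    for cid in sorted(assignment.assignment.unique()):
        members = sorted(assignment.assignment.index[assignment.assignment == cid])
        ps = screen.loc[members, "p"].astype(float)
        best = ps.index[np.lexsort((ps.index, ps.to_numpy()))][0]
        rows.append(
            {
                "cluster": cid,
                "feature": best,
                "p": float(ps[best]),
                "keep": bool(ps[best] < threshold),
                "separation": bool(screen.loc[best, "separation"]),
            }
        )
    reps = pd.DataFrame(rows).set_index("cluster")
    assignment.representatives = reps
    return reps


def cluster_patients(
    features: pd.DataFrame, cut_fraction: float = 0.6
) -> tuple[FeatureDendrogram, ClusterAssignment]:
    """Cluster patients on the per-feature Z-scored, transposed table."""
    z = (features - features.mean()) / features.std(ddof=0).replace(0, 1.0)
    zt = z.T
    zt.columns = [str(c) for c in zt.columns]
    return cluster_features(spearman_distance(zt), cut_fraction)


def reduce_features(
    features: pd.DataFrame,
    labels,
    cut_fraction: float = 0.6,
    threshold: float = 0.2,
    absolute: bool = True,
) -> dict:
    """End-to-end reduction: distance → clusters → screened representatives.

    Returns a dict with the dendrogram, assignment, representative table and
    the final kept feature list, deterministic for a given table.
    """
    d = spearman_distance(features, absolute=absolute)
    dendro, assign = cluster_features(d, cut_fraction)
    reps = select_representatives(assign, features[list(d.columns)], labels, threshold)
    kept = sorted(reps.loc[reps["keep"], "feature"])
    return {
        "dendrogram": dendro,
        "assignment": assign,
        "representatives": reps,
        "selected": kept,
    }
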