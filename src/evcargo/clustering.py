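"""Feature clustering with the fixed-fraction dendrogram cut.

Features passing the expression filter are z-scored across samples and
clustered hierarchically (Euclidean distance, complete linkage). Flat
clusters are extracted by cutting the dendrogram at 1/1.25 of the maximal
merge height (= 0.8 * h_max). Cluster-level summaries attach the mean linear
and nonlinear age correlation, and cross-fraction cluster mapping counts
shared features between every (EV cluster, fc cluster) pair.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy

from .core_io import ExpressionMatrix, ValidationError, filter_expressed

__all__ = ["ClusterResult", "cluster_features", "summarize_and_map"]


@dataclass
class ClusterResult:
    """Cluster assignments plus optional summaries and cross-fraction overlap."""

    assignments: pd.Series  # feature_id -> cluster_id
    excluded: list[str] = field(default_factory=list)  # zero-variance features
    cut_height: float = float("nan")
    linkage_method: str = "complete"
    summary: pd.DataFrame | None = None
    overlap: pd.DataFrame | None = None

    @property
    def n_clusters(self) -> int:
        return int(self.assignments.nunique())


def cluster_features(
    x: ExpressionMatrix,
    min_rpm: float = 5.0,
    cut_factor: float = 1.25,
    method: str = "complete",
) -> ClusterResult:
    """Cluster filtered, z-scored features; cut the dendrogram at h_max/cut_factor.

    Features are standardized to mean 0 and population variance 1 across
    samples (ddof 0). Zero-variance features cannot be standardized and are
    excluded with a warning. Features are processed in sorted-id order so the
    partition does not depend on input order.
    """
    if x.unit == "rpm":
        x = filter_expressed(x, min_rpm=min_rpm)
    if x.shape[1] < 2:
        raise ValidationError("need at least 2 samples")
    data = x.data.sort_index()
    v = data.to_numpy(dtype=float)
    sd = v.std(axis=1, ddof=0)
    zero_var = sd == 0
    excluded = data.index[zero_var].tolist()
    if excluded:
        warnings.warn(f"excluding {len(excluded)} zero-variance feature(s)", stacklevel=2)
    data = data.loc[~zero_var]
    v = v[~zero_var]
    sd = sd[~zero_var]
    if len(data) < 2:
        raise ValidationError("need at least 2 features with non-zero variance")
    z = (v - v.mean(axis=1, keepdims=True)) / sd[:, None]
    Z = hierarchy.linkage(z, method=method, metric="euclidean")
    h_max = Z[-1, 2]
    cut = h_max / cut_factor
    labels = hierarchy.fcluster(Z, t=cut, criterion="distance")
    return ClusterResult(
        assignments=pd.Series(labels, index=data.index, name="cluster_id"),
        excluded=excluded,
        cut_height=float(cut),
        linkage_method=method,
    )


def _cluster_summary(res: ClusterResult, stats_df: pd.DataFrame) -> pd.DataFrame:
    rows = []
    for cid, members in res.assignments.groupby(res.assignments).groups.items():
        members = pd.Index(members)
        present = members.intersection(stats_df.index)
        if len(present) == 0:
            warnings.warn(f"cluster {cid}: no trajectory stats available", stacklevel=3)
            mean_r = mean_d = np.nan
        else:
            mean_r = float(stats_df.loc[present, "pearson_r"].mean())
            mean_d = float(stats_df.loc[present, "dcor"].mean())
        rows.append(
            {"cluster_id": cid, "size": len(members), "mean_pearson_r": mean_r, "mean_dcor": mean_d}
        )
    return pd.DataFrame(rows).set_index("cluster_id")


def summarize_and_map(
    clusters_ev: ClusterResult,
    clusters_fc: ClusterResult,
    stats_ev: pd.DataFrame,
    stats_fc: pd.DataFrame,
) -> tuple[ClusterResult, ClusterResult, pd.DataFrame]:
    """Fill per-cluster correlation summaries and the cross-fraction overlap.

    The overlap matrix entry (i, j) counts feature ids shared between EV
    cluster i and fc cluster j; its total equals the number of features
    clustered in both fractions.
    """
    clusters_ev.summary = _cluster_summary(clusters_ev, stats_ev)
    clusters_fc.summary = _cluster_summary(clusters_fc, stats_fc)
    ev_ids = sorted(clusters_ev.assignments.unique())
    fc_ids = sorted(clusters_fc.assignments.unique())
    overlap = pd.DataFrame(0, index=ev_ids, columns=fc_ids)
    shared = clusters_ev.assignments.index.intersection(clusters_fc.assignments.index)
    for feat in shared:
        overlap.loc[clusters_ev.assignments[feat], clusters_fc.assignments[feat]] += 1
    overlap.index.name = "ev_cluster"
    overlap.columns.name = "fc_cluster"
    clusters_ev.overlap = overlap
    clusters_fc.overlap = overlap
    return clusters_ev, clusters_fc, overlap
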