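"""Fundamental-battery selection: cluster methods by mutual similarity and
keep one representative per cluster.

Methods whose thresholded maps overlap heavily carry redundant information;
agglomerative clustering on the dissimilarity 1 − MS groups them, and the
method with the best Predictive Index summary (median by default) represents
each cluster in the reduced battery.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .metrics import SimilarityMatrix

LINKAGES = ("average", "complete", "single")


@dataclass
class MethodDendrogram:
    """Agglomerative merge tree over methods (distances = 1 − MS)."""

    leaves: list[str]
    linkage_matrix: np.ndarray  # scipy (n-1, 4) format
    method: str  # linkage rule

    @property
    def merges(self) -> list[tuple[int, int, float]]:
        return [(int(a), int(b), float(h)) for a, b, h, _ in self.linkage_matrix]

    @property
    def max_height(self) -> float:
        return float(self.linkage_matrix[:, 2].max())

    def to_json(self) -> str:
        return json.dumps(
            {"leaves": self.leaves, "linkage": self.method,
             "merges": [list(m) for m in self.merges]}
        )

    def to_newick(self) -> str:
        """Newick string; branch lengths are merge-height differences."""
        n = len(self.leaves)
        heights = {i: 0.0 for i in range(n)}
        reprs = {i: self.leaves[i] for i in range(n)}
        for k, (a, b, h, _) in enumerate(self.linkage_matrix):
            a, b = int(a), int(b)
            la = h - heights[a]
            lb = h - heights[b]
            node = n + k
            reprs[node] = f"({reprs[a]}:{la:g},{reprs[b]}:{lb:g})"
            heights[node] = float(h)
        return reprs[2 * n - 2] + ";"


@dataclass
class ClusterAssignment:
    labels: pd.Series  # method -> cluster id (1-based)
    cut: float | int
    mode: str  # "height" | "count"

    @property
    def n_clusters(self) -> int:
        return int(self.labels.nunique())

    def members(self, cluster_id: int) -> list[str]:
        return sorted(self.labels.index[self.labels == cluster_id])


@dataclass
class FundamentalBattery:
    """One representative method per similarity cluster."""

    selected: list[str]
    per_cluster: pd.DataFrame  # cluster, method, summary PI, n_obs
    summary: str  # "median" | "mean"


def method_distance_matrix(sim: SimilarityMatrix) -> pd.DataFrame:
    """D = 1 − S on the methods with fully observed pairwise similarity.

    Methods with any NaN pair are excluded with a warning (a pair never
    co-observed has no defined similarity).
    """
    values = sim.values
    if not np.allclose(values.values, values.values.T, equal_nan=True):
        raise ValueError("similarity matrix is not symmetric")
    keep = [m for m in values.index if not values.loc[m].isna().any()]
    dropped = [m for m in values.index if m not in keep]
    if dropped:
        warnings.warn(
            f"excluding methods with unobserved similarity pairs: {dropped}",
            stacklevel=2,
        )
    d = 1.0 - values.loc[keep, keep]
    np.fill_diagonal(d.values, 0.0)
    return d


def hierarchical_cluster(
    d: pd.DataFrame, linkage_method: str = "average"
) -> MethodDendrogram:
    """Agglomerative clustering of the method distance matrix (UPGMA default)."""
    if linkage_method not in LINKAGES:
        raise ValueError(f"linkage must be one of {LINKAGES}")
    if len(d) < 2:
        raise ValueError("need at least 2 methods to cluster")
    if not np.allclose(d.values, d.values.T):
        raise ValueError("distance matrix is not symmetric")
    condensed = squareform(d.values, checks=False)
    z = linkage(condensed, method=linkage_method)
    return MethodDendrogram(
        leaves=list(d.index), linkage_matrix=z, method=linkage_method
    )


def cut_dendrogram(
    dend: MethodDendrogram,
    height: float | None = None,
    n_clusters: int | None = None,
) -> ClusterAssignment:
    """Partition the tree at a height or into a target number of clusters."""
    n = len(dend.leaves)
    if (height is None) == (n_clusters is None):
        raise ValueError("give exactly one of height or n_clusters")
    if height is not None:
        if height < 0:
            raise ValueError("cut height must be >= 0")
        flat = fcluster(dend.linkage_matrix, t=height, criterion="distance")
        cut: float | int = height
        mode = "height"
    else:
        if not (1 <= n_clusters <= n):
            raise ValueError(f"cluster count must be in [1, {n}]")
        flat = fcluster(dend.linkage_matrix, t=n_clusters, criterion="maxclust")
        cut = n_clusters
        mode = "count"
    labels = pd.Series(flat, index=dend.leaves, name="cluster")
    return ClusterAssignment(labels=labels, cut=cut, mode=mode)


def select_representatives(
    assign: ClusterAssignment,
    pi_table: pd.DataFrame,
    summary: str = "median",
) -> FundamentalBattery:
    """Per cluster, keep the method with the highest PI summary.

    Ties go to the method with more observations, then to the
    lexicographically smaller name. A cluster whose methods all lack PI
    observations is an error.
    """
    if summary not in ("median", "mean"):
        raise ValueError("summary must be 'median' or 'mean'")
    rows = []
    selected = []
    for cid in sorted(assign.labels.unique()):
        members = assign.members(int(cid))
        candidates = []
        for m in members:
            if m not in pi_table.columns:
                continue
            obs = pi_table[m].dropna()
            if len(obs) == 0:
                continue
            stat = float(obs.median() if summary == "median" else obs.mean())
            candidates.append((m, stat, len(obs)))
        if not candidates:
            raise ValueError(
                f"cluster {cid} ({members}) has no PI observations"
            )
        candidates.sort(key=lambda c: (-c[1], -c[2], c[0]))
        best = candidates[0]
        selected.append(best[0])
        for m, stat, n in candidates:
            rows.append(
                {"cluster": int(cid), "method": m, f"{summary}_pi": stat,
                 "n_obs": n, "selected": m == best[0]}
            )
    table = pd.DataFrame(rows)
    return FundamentalBattery(selected=selected, per_cluster=table, summary=summary)
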