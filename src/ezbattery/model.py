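"""Model-object interface to the full battery comparison.

`BatteryAnalysis` wraps a cohort plus the analysis operating point
(threshold percentile, exact-test size K, clustering and ranking options);
`fit()` runs scoring → similarity → clustering/selection → ranking →
reverse-Helmert cutoff and returns a `BatteryResults` carrying every
intermediate table, a text `summary()` and simple plots.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import metrics, ranking, selection
from .metrics import DEFAULT_K, DEFAULT_PERCENTILE, SimilarityMatrix
from .volumes import Cohort, load_cohort


class BatteryAnalysis:
    """Comparison and selection of imaging methods on one cohort.

    Parameters
    ----------
    cohort : Cohort
        Per-subject statistical maps, resection masks and brain masks.
    percentile : float
        Threshold operating point; 90 keeps the strongest 10% of the brain.
    k : int
        Number of random surgery masks per exact test.
    n_clusters : int or None
        Similarity-cluster count; default ceil(n_methods / 2), mirroring
        the "about half of all methods" heuristic.
    linkage : {"average", "complete", "single"}
    summary : {"median", "mean"}
        PI summary used to pick each cluster's representative.
    alpha : float
        Significance level for the reverse-Helmert cutoff.
    seed : int
        Master seed for the exact tests.
    """

    def __init__(
        self,
        cohort: Cohort,
        percentile: float = DEFAULT_PERCENTILE,
        k: int = DEFAULT_K,
        n_clusters: int | None = None,
        linkage: str = "average",
        summary: str = "median",
        alpha: float = 0.05,
        seed: int = 0,
    ) -> None:
        self.cohort = cohort
        self.percentile = percentile
        self.k = k
        self.n_clusters = n_clusters
        self.linkage = linkage
        self.summary = summary
        self.alpha = alpha
        self.seed = seed

    @classmethod
    def from_directory(cls, cohort_dir: str | Path, **kwargs) -> "BatteryAnalysis":
        """Build from an on-disk cohort (directory with manifest.tsv)."""
        cohort_dir = Path(cohort_dir)
        manifest = cohort_dir / "manifest.tsv"
        return cls(load_cohort(manifest), **kwargs)

    def fit(self, keep_null: bool = False) -> "BatteryResults":
        pi = metrics.compute_pi_table(
            self.cohort, k=self.k, percentile=self.percentile, seed=self.seed,
            keep_null=keep_null,
        )
        null_details = None
        if keep_null:
            pi, null_details = pi
        sim = metrics.average_similarity_matrix(self.cohort, self.percentile)
        dist = selection.method_distance_matrix(sim)
        dend = selection.hierarchical_cluster(dist, self.linkage)
        n_clusters = self.n_clusters
        if n_clusters is None:
            n_clusters = int(np.ceil(len(dist) / 2))
        assign = selection.cut_dendrogram(dend, n_clusters=n_clusters)
        battery = selection.select_representatives(assign, pi, self.summary)
        omnibus = ranking.omnibus_kruskal_wallis(pi)
        rank = ranking.rank_by_mean_pi(pi)
        pairwise = ranking.pairwise_wilcoxon_fdr(pi)
        helmert = ranking.reverse_helmert_cutoff(pi, rank, alpha=self.alpha)
        return BatteryResults(
            model=self, pi_table=pi, similarity=sim, dendrogram=dend,
            clusters=assign, battery=battery, omnibus=omnibus, ranking=rank,
            pairwise=pairwise, helmert=helmert, null_details=null_details,
        )


@dataclass
class BatteryResults:
    """Fitted results: all stage outputs plus summary/plot helpers."""

    model: BatteryAnalysis
    pi_table: pd.DataFrame
    similarity: SimilarityMatrix
    dendrogram: selection.MethodDendrogram
    clusters: selection.ClusterAssignment
    battery: selection.FundamentalBattery
    omnibus: ranking.OmnibusResult
    ranking: ranking.RankingResult
    pairwise: ranking.PairwiseTestMatrix
    helmert: ranking.HelmertResult
    null_details: dict | None = None

    @property
    def recommended(self) -> list[str]:
        """Leading methods before the Helmert cutoff (battery to acquire)."""
        return self.helmert.recommended

    def summary(self) -> str:
        m = self.model
        lines = [
            "Battery comparison of EZ-localization methods",
            "=" * 46,
            f"subjects: {len(m.cohort.subjects)}   methods: {len(m.cohort.methods)}",
            f"percentile: {m.percentile}   K: {m.k}   alpha: {m.alpha}   seed: {m.seed}",
            "",
            f"Kruskal-Wallis omnibus: H = {self.omnibus.h:.3f}, "
            f"p = {self.omnibus.p_value:.4g}",
            "",
            "Ranking by mean PI:",
        ]
        for i, (meth, row) in enumerate(self.ranking.table.iterrows(), 1):
            lines.append(
                f"  {i:2d}. {meth:<16s} mean PI {row['mean_pi']:.3f}  "
                f"median {row['median_pi']:.3f}  (n={int(row['n_obs'])})"
            )
        lines += [
            "",
            f"Similarity clusters: {self.clusters.n_clusters}",
            f"Fundamental battery ({self.battery.summary} PI per cluster): "
            + ", ".join(self.battery.selected),
            "",
        ]
        if self.helmert.cutoff is not None:
            j = self.helmert.cutoff
            row = self.helmert.contrasts.set_index("position").loc[j]
            lines.append(
                f"Helmert cutoff at position {j} "
                f"(estimate {row['estimate']:.3f}, p = {row['p_value']:.4g}); "
                f"recommended battery: first {self.helmert.n_recommended} methods"
            )
        else:
            lines.append(
                "Helmert cutoff: none (no position significantly below its "
                "predecessors); recommended battery: full ranking"
            )
        lines.append("  " + ", ".join(self.recommended))
        return "\n".join(lines)

    # -- plotting -----------------------------------------------------------

    def plot_dendrogram(self, ax=None):
        """Dendrogram of method similarity (left-to-right merge heights)."""
        import matplotlib.pyplot as plt
        from scipy.cluster.hierarchy import dendrogram as scipy_dendrogram

        if ax is None:
            _, ax = plt.subplots(figsize=(6, 0.3 * len(self.dendrogram.leaves) + 1))
        scipy_dendrogram(
            self.dendrogram.linkage_matrix, labels=self.dendrogram.leaves,
            orientation="right", ax=ax,
        )
        ax.set_xlabel("1 − mean mutual similarity")
        return ax

    def plot_ranking(self, ax=None):
        """Mean PI per method with per-subject points, in ranked order."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(0.45 * len(self.ranking.order) + 1, 4))
        for i, meth in enumerate(self.ranking.order):
            obs = self.pi_table[meth].dropna()
            ax.plot([i] * len(obs), obs, "o", color="0.7", ms=3, zorder=1)
            ax.plot(i, obs.mean(), "o", color="crimson", zorder=2)
        ax.set_xticks(range(len(self.ranking.order)))
        ax.set_xticklabels(self.ranking.order, rotation=90)
        ax.set_ylabel("Predictive Index")
        if self.helmert.cutoff is not None:
            ax.axvline(self.helmert.cutoff - 1.5, ls="--", color="k")
        return ax
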