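"""Ranking and inferential comparison of method accuracies.

Given a subjects × methods Predictive Index table:

* a Kruskal–Wallis omnibus test asks whether methods differ at all;
* methods are ranked by mean PI;
* pairwise Wilcoxon signed-rank tests (paired on subjects, BH-FDR
  corrected) show which methods differ;
* a reverse-Helmert linear model on the ranked methods finds the first
  position significantly less accurate than the mean of all better-ranked
  methods — the natural cutoff for how many leading methods to recommend.

Missing cells are handled with the standard available-case conventions:
Kruskal–Wallis pools all available observations, the signed-rank tests use
pairwise-complete subjects, and the Helmert model fits the unbalanced long
table.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats as st
import statsmodels.api as sm
from statsmodels.stats.multitest import multipletests

MIN_PAIRS = 5  # fewer informative pairs than this -> NOT-TESTED cell
EXACT_WILCOXON_MAX_N = 25


@dataclass
class OmnibusResult:
    h: float
    p_value: float
    group_sizes: dict[str, int]


@dataclass
class RankingResult:
    """Methods ordered by decreasing mean PI (ties broken by name)."""

    table: pd.DataFrame  # index: method; columns mean_pi, median_pi, n_obs

    @property
    def order(self) -> list[str]:
        return list(self.table.index)


@dataclass
class PairwiseTestMatrix:
    p_raw: pd.DataFrame
    p_adjusted: pd.DataFrame
    effect_size: pd.DataFrame  # difference of mean PI (row − column)
    n_pairs: pd.DataFrame
    tested: pd.DataFrame  # boolean: cell had >= MIN_PAIRS informative pairs


@dataclass
class HelmertResult:
    """Ordered reverse-Helmert contrasts and the battery-size cutoff.

    `contrasts` has one row per position j = 2..m: the estimate of
    mean(method_j) − mean over methods 1..j−1, its SE and two-sided p.
    `cutoff` is the first position whose contrast is significantly
    negative at `alpha`, or None; the recommended battery is the first
    cutoff − 1 methods of the ordering (the full ordering when None).
    """

    ordering: list[str]
    contrasts: pd.DataFrame  # position, method, estimate, se, p_value
    alpha: float
    cutoff: int | None

    @property
    def n_recommended(self) -> int:
        return (self.cutoff - 1) if self.cutoff is not None else len(self.ordering)

    @property
    def recommended(self) -> list[str]:
        return self.ordering[: self.n_recommended]


def _long_format(pi_table: pd.DataFrame) -> pd.DataFrame:
    long = pi_table.stack().rename("pi").reset_index()
    long.columns = ["subject", "method", "pi"]
    return long


def omnibus_kruskal_wallis(pi_table: pd.DataFrame) -> OmnibusResult:
    """Kruskal–Wallis H over per-method PI samples (tie-corrected)."""
    groups = {m: pi_table[m].dropna().to_numpy() for m in pi_table.columns}
    groups = {m: g for m, g in groups.items() if len(g) >= 2}
    if len(groups) < 2:
        raise ValueError("need >= 2 methods with >= 2 observations each")
    samples = list(groups.values())
    if np.ptp(np.concatenate(samples)) == 0:
        # identical values everywhere: H = 0, p = 1 (scipy raises on all-ties)
        h, p = 0.0, 1.0
    else:
        h, p = st.kruskal(*samples)
    return OmnibusResult(
        h=float(h), p_value=float(p),
        group_sizes={m: len(g) for m, g in groups.items()},
    )


def rank_by_mean_pi(pi_table: pd.DataFrame) -> RankingResult:
    """Rank methods by mean PI over non-missing cells, descending."""
    rows = []
    for m in pi_table.columns:
        obs = pi_table[m].dropna()
        if len(obs) == 0:
            raise ValueError(f"method {m} has no PI observations")
        rows.append(
            {"method": m, "mean_pi": float(obs.mean()),
             "median_pi": float(obs.median()), "n_obs": int(len(obs))}
        )
    table = pd.DataFrame(rows).set_index("method")
    # descending mean PI, ties broken by ascending method name
    table = table.iloc[
        np.lexsort((table.index.to_numpy(), -table["mean_pi"].to_numpy()))
    ]
    return RankingResult(table=table)


def pairwise_wilcoxon_fdr(pi_table: pd.DataFrame) -> PairwiseTestMatrix:
    """All-pairs Wilcoxon signed-rank tests with BH-FDR correction.

    Pairs are formed within subjects (pairwise-complete); zero differences
    are discarded (classic signed-rank convention). The exact null
    distribution is used for up to 25 informative pairs, the normal
    approximation with continuity correction above. Cells with fewer than
    5 informative pairs are flagged NOT-TESTED (NaN p) rather than tested.
    """
    methods = list(pi_table.columns)
    nm = len(methods)
    p_raw = pd.DataFrame(np.nan, index=methods, columns=methods)
    eff = pd.DataFrame(np.nan, index=methods, columns=methods)
    npairs = pd.DataFrame(0, index=methods, columns=methods)
    tested = pd.DataFrame(False, index=methods, columns=methods)
    cells = []
    for i in range(nm):
        for j in range(i + 1, nm):
            a, b = methods[i], methods[j]
            both = pi_table[[a, b]].dropna()
            n_complete = len(both)
            diff = both[a].to_numpy() - both[b].to_numpy()
            informative = diff[diff != 0]
            npairs.loc[a, b] = npairs.loc[b, a] = n_complete
            if n_complete > 0:
                e = float(both[a].mean() - both[b].mean())
                eff.loc[a, b] = e
                eff.loc[b, a] = -e
            if informative.size < MIN_PAIRS:
                continue
            method = "exact" if informative.size <= EXACT_WILCOXON_MAX_N else "approx"
            try:
                res = st.wilcoxon(
                    informative, zero_method="wilcox", alternative="two-sided",
                    correction=True, method=method,
                )
                p = float(res.pvalue)
            except ValueError:
                # exact method unavailable (e.g. ties): fall back to approx
                res = st.wilcoxon(
                    informative, zero_method="wilcox", alternative="two-sided",
                    correction=True, method="approx",
                )
                p = float(res.pvalue)
            p_raw.loc[a, b] = p_raw.loc[b, a] = p
            tested.loc[a, b] = tested.loc[b, a] = True
            cells.append((a, b, p))
    p_adj = pd.DataFrame(np.nan, index=methods, columns=methods)
    if cells:
        raw = [c[2] for c in cells]
        adj = multipletests(raw, method="fdr_bh")[1]
        for (a, b, _), q in zip(cells, adj):
            p_adj.loc[a, b] = p_adj.loc[b, a] = float(q)
    return PairwiseTestMatrix(
        p_raw=p_raw, p_adjusted=p_adj, effect_size=eff,
        n_pairs=npairs, tested=tested,
    )


def reverse_helmert_coding(m: int) -> np.ndarray:
    """Coding matrix C (m × m, first column intercept) such that OLS
    coefficients equal [grand mean of level means, mean_2 − mean_1,
    mean_3 − mean(1,2), ..., mean_m − mean(1..m−1)].

    Built as the inverse of the hypothesis matrix L whose row j is the
    desired contrast on level means.
    """
    L = np.zeros((m, m))
    L[0, :] = 1.0 / m
    for j in range(1, m):
        L[j, j] = 1.0
        L[j, :j] = -1.0 / j
    return np.linalg.inv(L)


def reverse_helmert_cutoff(
    pi_table: pd.DataFrame,
    ordering: RankingResult | list[str],
    alpha: float = 0.05,
    block_subjects: bool = False,
) -> HelmertResult:
    """Least-squares fit of PI on the method factor in reverse-Helmert coding.

    Contrast j tests method j against the unweighted mean of methods
    1..j−1 in the given ordering; the cutoff is the first position with a
    negative estimate and two-sided p < alpha. `block_subjects` adds
    subject fixed effects (not the default: the basic model regresses PI
    on the method factor alone).
    """
    order = ordering.order if isinstance(ordering, RankingResult) else list(ordering)
    m = len(order)
    if m < 2:
        raise ValueError("ordering must cover >= 2 methods")
    long = _long_format(pi_table[order])
    for meth in order:
        if (long["method"] == meth).sum() == 0:
            raise ValueError(f"method {meth} has no observations; design is singular")
    level = long["method"].map({meth: i for i, meth in enumerate(order)}).to_numpy()
    coding = reverse_helmert_coding(m)
    X = coding[level, :]
    names = ["intercept"] + [f"pos{j + 1}_vs_prev" for j in range(1, m)]
    if block_subjects:
        subj = pd.get_dummies(long["subject"], drop_first=True, dtype=float)
        X = np.hstack([X, subj.to_numpy()])
        names = names + [f"subject_{c}" for c in subj.columns]
    fit = sm.OLS(long["pi"].to_numpy(), X).fit()
    rows = []
    cutoff: int | None = None
    for j in range(1, m):
        est = float(fit.params[j])
        se = float(fit.bse[j])
        p = float(fit.pvalues[j])
        rows.append(
            {"position": j + 1, "method": order[j], "estimate": est,
             "se": se, "p_value": p}
        )
        # -1e-9 guards against float-noise "negative" estimates on
        # degenerate (constant) tables, where se is also ~0
        if cutoff is None and est < -1e-9 and np.isfinite(p) and p < alpha:
            cutoff = j + 1
    contrasts = pd.DataFrame(rows)
    return HelmertResult(ordering=order, contrasts=contrasts, alpha=alpha,
                         cutoff=cutoff)
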