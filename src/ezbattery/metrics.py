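"""Core concordance statistics.

Four primitives quantify how well an imaging method's statistical map
localizes the epileptogenic zone, approximated by the surgical resection
mask:

* percentile thresholding — keep the strongest 10% of in-brain voxels
  (the 90th percentile is the default operating point);
* sensitivity — SEN = TP / P, the fraction of the resection covered by
  the suprathreshold set;
* the Predictive Index — an exact test against K random, size-matched,
  brain-constrained connected surgery masks:
  PI = 1 − (1/K) Σ_k 1(SEN_k > SEN0), in [0, 1], 1 = best localization;
* mutual similarity — MS(a, b) = |a90 ∩ b90| / N90 between two equally
  sized suprathreshold sets of the same subject.

PI tables (subjects × methods) and subject-averaged similarity matrices
feed the battery-selection and ranking stages.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._grow import flat_to_mask, grow_region
from ._rng import substream
from .volumes import BinaryVolume, Cohort, LabeledVolume

DEFAULT_PERCENTILE = 90.0
DEFAULT_K = 1000


@dataclass
class ThresholdedMap:
    """Binary suprathreshold map: the top (100 − p)% of in-brain voxels."""

    subject: str
    method: str
    percentile: float
    mask: np.ndarray  # boolean, grid-shaped
    grid: "object"

    @property
    def n90(self) -> int:
        return int(self.mask.sum())

    def member_flat(self) -> np.ndarray:
        return np.flatnonzero(self.mask.ravel())


@dataclass
class SensitivityResult:
    tp: int
    fp: int
    p: int

    @property
    def sen(self) -> float:
        return self.tp / self.p


@dataclass
class PIResult:
    """Exact-test result for one (subject, method) cell."""

    sen0: float
    null_sens: np.ndarray  # SEN_k, k = 1..K
    k: int

    @property
    def pi(self) -> float:
        return 1.0 - float(np.count_nonzero(self.null_sens > self.sen0)) / self.k


@dataclass
class SimilarityMatrix:
    """Methods × methods mean mutual similarity, averaged over subjects."""

    values: pd.DataFrame  # NaN where a pair was never co-observed
    counts: pd.DataFrame  # subjects contributing to each cell

    @property
    def methods(self) -> list[str]:
        return list(self.values.index)


def n_suprathreshold(n_brain: int, percentile: float) -> int:
    """Voxels retained at a percentile: round((1 − p/100) × |brain|),
    rounding half away from zero."""
    return int(np.floor((1.0 - percentile / 100.0) * n_brain + 0.5))


def threshold_map(
    vol: LabeledVolume,
    brain: BinaryVolume,
    percentile: float = DEFAULT_PERCENTILE,
) -> ThresholdedMap:
    """Keep exactly N90 = round((1 − p/100)·|brain|) highest in-brain voxels.

    Ties at the boundary are broken deterministically by linear voxel index
    (smaller index wins), so |a90| = |b90| = N90 holds exactly for every
    map — a requirement of the mutual-similarity statistic.
    """
    if not (0.0 < percentile < 100.0):
        raise ValueError("percentile must be in (0, 100)")
    vol.grid.require_compatible(brain.grid)
    n_brain = brain.n_members
    n_keep = n_suprathreshold(n_brain, percentile)
    flat = np.asarray(vol.values, dtype=np.float64).ravel()
    brain_flat = np.flatnonzero(brain.mask.ravel())
    vals = flat[brain_flat]
    finite = np.isfinite(vals)
    if int(finite.sum()) < n_keep:
        raise ValueError(
            f"only {int(finite.sum())} finite in-brain voxels; need {n_keep}"
        )
    brain_flat = brain_flat[finite]
    vals = vals[finite]
    # stable sort on index, then stable sort on descending value: ties keep
    # ascending linear index order
    order = np.argsort(-vals, kind="stable")
    keep = brain_flat[order[:n_keep]]
    mask = flat_to_mask(keep, tuple(vol.grid.dims))
    return ThresholdedMap(
        subject=vol.subject, method=vol.label, percentile=percentile,
        mask=mask, grid=vol.grid,
    )


def sensitivity(t: ThresholdedMap, resection: BinaryVolume) -> SensitivityResult:
    """SEN = TP/P: suprathreshold voxels inside the resection over its size."""
    p = resection.n_members
    if p == 0:
        raise ValueError("empty resection mask: sensitivity undefined")
    tp = int(np.count_nonzero(t.mask & resection.mask))
    return SensitivityResult(tp=tp, fp=t.n90 - tp, p=p)


def generate_random_mask(
    brain: BinaryVolume,
    size_voxels: int,
    rng: np.random.Generator,
) -> BinaryVolume:
    """A connected random surgery mask of exactly `size_voxels` voxels.

    The seed voxel is uniform over the brain; the region then grows by
    picking a frontier voxel uniformly at random each step (6-connectivity).
    """
    n_brain = brain.n_members
    if not (1 <= size_voxels <= n_brain):
        raise ValueError(f"mask size {size_voxels} outside [1, |brain|={n_brain}]")
    brain_flat = np.flatnonzero(brain.mask.ravel())
    seed = brain_flat[rng.integers(n_brain)]
    region = grow_region(brain.mask, np.array([seed]), size_voxels, rng)
    mask = flat_to_mask(region, tuple(brain.grid.dims))
    sv = np.unravel_index(seed, tuple(brain.grid.dims))
    return BinaryVolume(
        grid=brain.grid, mask=mask, role="random_mask",
        seed_voxel=tuple(int(i) for i in sv),
    )


def _null_sensitivities(
    t_flat_mask: np.ndarray,
    brain: BinaryVolume,
    sizes_voxels: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """SEN_k for K random masks; sizes resampled with replacement per draw."""
    brain_flat = np.flatnonzero(brain.mask.ravel())
    n_brain = brain_flat.size
    out = np.empty(sizes_voxels.size)
    for k, size in enumerate(sizes_voxels):
        seed = brain_flat[rng.integers(n_brain)]
        region = grow_region(brain.mask, np.array([seed]), int(size), rng)
        out[k] = np.count_nonzero(t_flat_mask[region]) / size
    return out


def predictive_index(
    t: ThresholdedMap,
    resection: BinaryVolume,
    brain: BinaryVolume,
    size_pool_cm3: list[float],
    k: int = DEFAULT_K,
    rng: np.random.Generator | None = None,
) -> PIResult:
    """PI = 1 − (1/K) Σ 1(SEN_k > SEN0), the exact-test Predictive Index.

    Null masks are connected random regions in the brain with sizes drawn
    with replacement from `size_pool_cm3` (the resection sizes observed
    over the surgery group), converted to voxels by rounding. The strict
    inequality means ties count in favour of the observed mask; when SEN0
    is 0 but most null masks also score 0, PI can still be large —
    `null_sens` is kept so such ties can be audited.
    """
    if k < 1:
        raise ValueError("K must be >= 1")
    if not size_pool_cm3:
        raise ValueError("size pool is empty")
    if rng is None:
        rng = np.random.default_rng()
    sen0 = sensitivity(t, resection).sen
    vv = brain.grid.voxel_volume_cm3
    n_brain = brain.n_members
    pool_vox = np.array(
        [min(max(1, round(s / vv)), n_brain) for s in size_pool_cm3], dtype=np.int64
    )
    sizes = pool_vox[rng.integers(pool_vox.size, size=k)]
    null = _null_sensitivities(t.mask.ravel(), brain, sizes, rng)
    return PIResult(sen0=sen0, null_sens=null, k=k)


def mutual_similarity(a: ThresholdedMap, b: ThresholdedMap) -> float:
    """MS(a, b) = |a90 ∩ b90| / N90; symmetric, in [0, 1].

    Requires equal percentiles on the same subject's grid so that
    N90 = |a90| = |b90|.
    """
    if a.n90 != b.n90:
        raise ValueError(
            f"thresholded sets differ in size ({a.n90} vs {b.n90}); "
            "mutual similarity requires a common N90"
        )
    inter = int(np.count_nonzero(a.mask & b.mask))
    return inter / a.n90


def threshold_cohort(
    cohort: Cohort, percentile: float = DEFAULT_PERCENTILE
) -> dict[tuple[str, str], ThresholdedMap]:
    return {
        (s, m): threshold_map(cohort.maps[(s, m)], cohort.brain[s], percentile)
        for s in cohort.subjects
        for m in cohort.methods
        if cohort.has(s, m)
    }


def average_similarity_matrix(
    cohort: Cohort,
    percentile: float = DEFAULT_PERCENTILE,
    thresholded: dict[tuple[str, str], ThresholdedMap] | None = None,
) -> SimilarityMatrix:
    """Mean MS per method pair over the subjects having both methods.

    Pairs never co-observed are NaN (explicitly missing, not zero); the
    diagonal is 1 wherever the method is observed at least once.
    """
    if thresholded is None:
        thresholded = threshold_cohort(cohort, percentile)
    methods = cohort.methods
    nm = len(methods)
    acc = np.zeros((nm, nm))
    cnt = np.zeros((nm, nm), dtype=int)
    for s in cohort.subjects:
        present = [m for m in methods if (s, m) in thresholded]
        masks = {m: thresholded[(s, m)] for m in present}
        for i, mi in enumerate(present):
            ii = methods.index(mi)
            for mj in present[i:]:
                jj = methods.index(mj)
                ms = 1.0 if ii == jj else mutual_similarity(masks[mi], masks[mj])
                acc[ii, jj] += ms
                acc[jj, ii] += ms if ii != jj else 0.0
                cnt[ii, jj] += 1
                if ii != jj:
                    cnt[jj, ii] += 1
    with np.errstate(invalid="ignore"):
        vals = np.where(cnt > 0, acc / np.maximum(cnt, 1), np.nan)
    values = pd.DataFrame(vals, index=methods, columns=methods)
    counts = pd.DataFrame(cnt, index=methods, columns=methods)
    for m in methods:
        if counts.loc[m, m] == 0:
            warnings.warn(f"method {m}: observed in no subject; similarity row is NaN",
                          stacklevel=2)
    return SimilarityMatrix(values=values, counts=counts)


def compute_pi_table(
    cohort: Cohort,
    k: int = DEFAULT_K,
    percentile: float = DEFAULT_PERCENTILE,
    seed: int = 0,
    size_pool_cm3: list[float] | None = None,
    keep_null: bool = False,
) -> pd.DataFrame | tuple[pd.DataFrame, dict[tuple[str, str], PIResult]]:
    """Predictive Index for every observed (subject, method) cell.

    The null-mask size pool defaults to the resection sizes observed over
    the whole cohort. Each cell draws from its own substream keyed by
    (seed, subject, method), so results are reproducible cell-by-cell and
    adding a method never perturbs the others.
    """
    if size_pool_cm3 is None:
        size_pool_cm3 = cohort.resection_sizes_cm3()
    table = pd.DataFrame(
        np.nan, index=list(cohort.subjects), columns=list(cohort.methods)
    )
    details: dict[tuple[str, str], PIResult] = {}
    for s in cohort.subjects:
        brain = cohort.brain[s]
        resection = cohort.resection[s]
        for m in cohort.methods:
            if not cohort.has(s, m):
                continue
            t = threshold_map(cohort.maps[(s, m)], brain, percentile)
            rng = substream(seed, "pi", s, m)
            res = predictive_index(t, resection, brain, size_pool_cm3, k=k, rng=rng)
            table.loc[s, m] = res.pi
            if keep_null:
                details[(s, m)] = res
    if keep_null:
        return table, details
    return table
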