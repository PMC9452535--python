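# Methods

## Problem and model

Given a cohort of operated epilepsy patients, each with a binary resection
mask (the proxy for the epileptogenic zone) and up to a few dozen 3-D
statistical maps from different imaging methods, the package quantifies
each method's localization value and reduces the battery. All volumes of a
subject must share one voxel grid; the package performs no resampling,
smoothing or registration — harmonizing native grids is the user's
preprocessing. Grid compatibility means identical dims and voxel sizes and
affines within 1e-3 (mm / per element).

### Thresholding

Each map is binarized at a brain-volume percentile `p` (default 90):
exactly `N₉₀ = round((1 − p/100)·|brain|)` voxels are kept, ranked by
value with ties broken by ascending linear voxel index. The exact-size
rule matters: the mutual-similarity statistic divides by a common `N₉₀`,
which a "≥ percentile value" rule violates under ties (e.g. constant
maps). The percentile is computed over in-brain voxels only; whether the
original analysis used the brain mask or the full image box is not
documented, so the brain-mask reading was chosen and the percentile is a
parameter for sensitivity analysis.

### Sensitivity and the Predictive Index

`SEN = TP/P` measures resection coverage but ignores specificity and
depends on resection size. The Predictive Index calibrates it by an exact
test: `K` random surgery masks (default 1000) are grown as connected
regions — seed voxel uniform over the brain, then a uniformly chosen
frontier voxel added per step (6-connectivity) — with sizes resampled with
replacement from the resection sizes observed across the cohort, and

PI = 1 − (1/K) Σₖ 1(SENₖ > SEN₀).

The strict inequality is kept exactly as defined; its consequence — ties
count for the observed mask, so PI can be large when SEN₀ = 0 but most
null masks also score 0 — is visible in the retained `null_sens` vector.
Under the null (map unrelated to resection location) PI is approximately
uniform on [0, 1] with mean ≈ 0.5 + 1/(2K); this calibration is verified
on 200 synthetic null subjects (mean in [0.45, 0.55], Kolmogorov–Smirnov
uniformity not rejected at α = 0.01) and, exactly, against a brute-force
enumeration of all size-2 mask placements on a 6×6×1 slab, where the
placement probability of a domino {u, v} under the growth process is
(1/|brain|)(1/deg u) + (1/|brain|)(1/deg v).

The region-growing sampler guarantees exact size and brain conformity;
its shape distribution is a modelling choice (only location and size
marginals are prescribed by the framework). The hot loop is numba-compiled.

### Similarity, clustering, selection

`MS(a,b) = |a₉₀ ∩ b₉₀|/N₉₀` per subject, averaged over the subjects with
both methods observed; never-co-observed pairs are missing, not zero.
Methods are clustered agglomeratively on `1 − MS` (UPGMA default;
complete/single available); merge-order ties follow scipy's deterministic
implementation. The cut is a cluster count (default ⌈n/2⌉, mirroring the
"about half of all methods" heuristic of the original battery) or a
height. Per cluster the method with the highest median PI is selected
(mean optional — the original description uses both wordings; median is
default), ties going to more observations, then lexicographic order.
`1 − MS` is a dissimilarity, not a metric; no triangle inequality is used.

### Ranking and the reverse-Helmert cutoff

Kruskal–Wallis (tie-corrected, χ² approximation) tests the omnibus
difference; methods are then sorted by mean PI. Pairwise Wilcoxon
signed-rank tests use pairwise-complete subjects, discard zero differences,
use the exact distribution up to 25 informative pairs (normal
approximation with continuity correction above), require ≥ 5 informative
pairs (otherwise NOT-TESTED), and are Benjamini–Hochberg adjusted across
tested cells.

The battery-size cutoff fits OLS of PI on the method factor coded so that
coefficient j equals mean(method j) − mean(methods 1..j−1) in the ranked
order (the coding matrix is the inverse of that hypothesis matrix, so the
identity holds exactly even on unbalanced data). The cutoff is the first
position with estimate < 0 and two-sided p < α (default 0.05); the
recommended battery is everything before it. Two caveats are deliberate
and documented rather than corrected: the ordering is estimated from the
same data (the stepwise first-significant rule mildly inflates type-I
error — on null synthetic cohorts the no-cutoff rate is verified ≥ 90%),
and subjects are not modelled as a blocking factor by default (matching
the simple `PI ~ method` formulation); `block_subjects=True` adds subject
fixed effects. A numerical guard treats estimates above −1e-9 as zero so
degenerate constant tables never yield a cutoff.

Missing cells use available-case conventions throughout: Kruskal–Wallis
pools all available observations (treating repeated measures as
independent — a documented limitation of the rank test, kept as
formulated), Wilcoxon uses pairwise-complete subjects, the Helmert model
fits the unbalanced long table.

## Synthetic cohorts

The generator emulates the statistical structure the analysis consumes,
not imaging physics.

* **Brain**: deterministic ellipsoid, semi-axes 0.45 × dims. Default grid
  20×20×20 at 3 mm (brain ≈ 82 cm³), chosen so the largest default
  resection (52 cm³) fits inside.
* **Resections**: connected regions grown from a uniform seed, sizes drawn
  uniformly with replacement from {4, 10, 15, 21, 27, 35, 52} cm³ — a
  7-point list whose median (21), minimum (4) and maximum (52) match the
  surgical cohort's reported order statistics, which are all that is
  known of the size distribution.
* **Maps**: `√ρ·family_noise + √(1−ρ)·private_noise + 4a·1[signal region]`.
  Noise fields are white Gaussian, smoothed with a separable Gaussian
  (default FWHM 8 mm) and re-standardized to unit variance, so the planted
  amplitude `4a` is in noise-SD units and the within-family correlation is
  exactly ρ (default 0.9). The signal region has the resection's size and
  overlaps it by exactly `round(a·P)` voxels: a connected in-resection
  core is grown first, then extended through the surrounding brain
  (partial growth is tolerated when a large resection disconnects the
  remaining brain). `a = 0` adds no signal. Thus the planted accuracy `a`
  controls both contrast and spatial overlap, and mean PI is monotone in
  `a` by construction (verified: Spearman ≥ 0.9 across a ∈ {0,…,1}).
* **Families**: same-family methods share the noise component *and* the
  signal-region growth stream (per subject), so their regions are nested
  and strongly overlapping. This models method families that err in the
  same spatial direction (e.g. perfusion methods mislocalizing to the same
  lobe) and is what makes family structure recoverable by MS clustering
  even when within-family accuracies differ.
* **Missingness**: each (subject, method) cell is dropped independently
  with the method's `missing_rate` (default 4%, matching ≈ 96% battery
  completeness).
* **Reproducibility**: every draw comes from a substream keyed by
  (master seed, stage tag, subject, method/family), so cohorts are
  bit-identical across runs and insensitive to generation order; adding a
  method never changes another method's maps or PI values.

What the generator does **not** emulate: realistic brain geometry and
tissue contrast, modality-specific noise (PET counts, EEG forward
models), spatially varying smoothness, registration error, or resections
correlated with map artefacts. Passing recovery tests therefore show the
*pipeline* is correct and well calibrated, not that any particular real
method ranking is reproduced.

## Problem sizes used in the test suite

Simulation-based checks run at deliberately desk-scale sizes: 25 subjects
per cohort (200 for the null-calibration check), 20×20×20 grids, K = 200
null masks in replicate studies (1000 where the default operating point
itself is under test, 10,000 against the enumeration oracle), and 5–20
replicates per recovery claim. Recovery thresholds (Spearman ≥ 0.9,
best-of-family ≥ 80%, cutoff recovery and null control ≥ 90%) are asserted
at these sizes.

## Known limitations

* PI values are Monte-Carlo estimates with SD ≤ 1/(2√K); rankings of
  near-tied methods at small K reflect that noise.
* The random-mask shape distribution (uniform-frontier growth) is one
  admissible choice; alternative connected samplers with the same
  location/size marginals would give slightly different null sets.
* The Helmert cutoff inherits the multiple-look caveat above; treat it as
  a heuristic decision aid, not a familywise-error-controlled test.
* Similarity averaging weights each subject equally regardless of how many
  method pairs it contributes.
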