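"""Synthetic cohorts with planted localization accuracy.

No public dataset accompanies the method-comparison framework, so testing
and calibration run on generated cohorts that emulate the statistical
structure the analysis consumes:

* an ellipsoidal brain mask on a small voxel grid;
* connected resection masks whose sizes are resampled from a 7-point
  list calibrated to the surgical cohort (median 21 cm³, range 4–52 cm³);
* per-method statistical maps = smoothed unit-variance Gaussian noise
  plus a signal bump of amplitude 4a (in noise-SD units) on a connected
  region the size of the resection whose overlap fraction with the
  resection equals the planted accuracy a (no signal at a = 0);
* correlated method families: same-family maps share a noise component
  (correlation rho) and a common signal-region displacement, emulating
  modalities that err in the same spatial direction;
* per-method missingness, emulating incomplete batteries (~96% complete).

Ground truth (planted accuracy, family, signal region) is recorded for
every generated map.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.ndimage import gaussian_filter

from ._grow import flat_to_mask, grow_region
from ._rng import substream
from .volumes import (
    BinaryVolume,
    Cohort,
    CohortManifest,
    LabeledVolume,
    MISSING,
    VolumeGrid,
    write_mask,
    write_volume,
)

#: 7-point resection-size list (cm³) matching the surgical cohort's order
#: statistics: median 21, min 4, max 52.
DEFAULT_RESECTION_SIZES_CM3: tuple[float, ...] = (4.0, 10.0, 15.0, 21.0, 27.0, 35.0, 52.0)

FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


@dataclass(frozen=True)
class MethodSpec:
    """One synthetic imaging method: name, planted accuracy, family."""

    name: str
    accuracy: float
    family: int = -1  # -1: no family (independent noise & displacement)
    missing_rate: float = 0.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.accuracy <= 1.0):
            raise ValueError(f"accuracy must be in [0,1], got {self.accuracy}")
        if not (0.0 <= self.missing_rate < 1.0):
            raise ValueError("missing_rate must be in [0,1)")


@dataclass
class CohortSpec:
    """Generation parameters for a synthetic cohort.

    Defaults emulate the surgical study: 25 subjects, resection sizes with
    median 21 cm³ and range 4–52 cm³, 8 mm smoothing, family share 0.9 and
    4% missingness. The default 20³ grid uses 3 mm voxels so the 82 cm³
    ellipsoidal brain can host the largest 52 cm³ resection.
    """

    n_subjects: int = 25
    methods: list[MethodSpec] = field(default_factory=list)
    brain_shape: tuple[int, int, int] = (20, 20, 20)
    voxel_size_mm: float = 3.0
    resection_sizes_cm3: tuple[float, ...] = DEFAULT_RESECTION_SIZES_CM3
    smoothness_fwhm_mm: float = 8.0
    family_share: float = 0.9
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        if any(s <= 0 for s in self.resection_sizes_cm3):
            raise ValueError("resection sizes must be positive")
        if not (0.0 <= self.family_share < 1.0):
            raise ValueError("family_share must be in [0,1)")

    @property
    def grid(self) -> VolumeGrid:
        return VolumeGrid.isotropic(self.brain_shape, self.voxel_size_mm)


def default_method_set(
    n_families: int = 4,
    per_family: int = 3,
    accuracies: tuple[float, ...] = (0.8, 0.5, 0.2),
    missing_rate: float = 0.04,
) -> list[MethodSpec]:
    """A family-structured method battery with graded within-family accuracy."""
    methods = []
    for f in range(n_families):
        for j in range(per_family):
            a = accuracies[j % len(accuracies)]
            methods.append(
                MethodSpec(name=f"fam{f}_m{j}", accuracy=a, family=f,
                           missing_rate=missing_rate)
            )
    return methods


@dataclass
class SyntheticCohort:
    """A generated cohort plus its ground truth."""

    cohort: Cohort
    spec: CohortSpec
    true_accuracy: dict[str, float]
    family: dict[str, int]
    signal_regions: dict[tuple[str, str], np.ndarray]  # flat voxel indices


def make_brain_mask(spec: CohortSpec) -> BinaryVolume:
    """Deterministic connected ellipsoidal brain with semi-axes 0.45×dims."""
    dims = spec.brain_shape
    if any(d < 8 for d in dims):
        raise ValueError("brain box must be at least 8 voxels per axis")
    grid = spec.grid
    semi = [0.45 * d for d in dims]
    center = [(d - 1) / 2.0 for d in dims]
    idx = np.indices(dims)
    r2 = sum(((idx[i] - center[i]) / semi[i]) ** 2 for i in range(3))
    mask = r2 <= 1.0
    brain = BinaryVolume(grid=grid, mask=mask, role="brain")
    vv = grid.voxel_volume_cm3
    largest = max(spec.resection_sizes_cm3)
    if round(largest / vv) > brain.n_members:
        raise ValueError(
            f"brain ({brain.size_cm3:.1f} cm³) cannot host the largest "
            f"requested resection ({largest} cm³)"
        )
    return brain


def sample_resection_size_cm3(
    rng: np.random.Generator,
    sizes: tuple[float, ...] = DEFAULT_RESECTION_SIZES_CM3,
) -> float:
    """Draw one resection size uniformly with replacement from the list."""
    return float(sizes[rng.integers(len(sizes))])


def sample_resection_mask(
    brain: BinaryVolume,
    target_size_cm3: float,
    rng: np.random.Generator,
) -> BinaryVolume:
    """Connected resection of exactly round(size/voxel volume) voxels ⊆ brain."""
    vv = brain.grid.voxel_volume_cm3
    size_vox = int(round(target_size_cm3 / vv))
    if size_vox < 1:
        size_vox = 1
    if size_vox > brain.n_members:
        raise ValueError(
            f"target {target_size_cm3} cm³ ({size_vox} voxels) exceeds brain "
            f"({brain.n_members} voxels)"
        )
    brain_flat = np.flatnonzero(brain.mask.ravel())
    seed = brain_flat[rng.integers(brain_flat.size)]
    region = grow_region(brain.mask, np.array([seed]), size_vox, rng)
    return BinaryVolume(
        grid=brain.grid,
        mask=flat_to_mask(region, tuple(brain.grid.dims)),
        role="resection",
        seed_voxel=tuple(int(i) for i in np.unravel_index(seed, brain.grid.dims)),
    )


def _smooth_unit_noise(
    shape: tuple[int, int, int], sigma_vox: float, rng: np.random.Generator
) -> np.ndarray:
    """Gaussian-smoothed white noise re-standardized to unit variance."""
    field = rng.standard_normal(shape)
    if sigma_vox > 0:
        field = gaussian_filter(field, sigma=sigma_vox, mode="nearest")
    sd = field.std()
    return field / sd if sd > 0 else field


def _signal_region(
    brain: BinaryVolume,
    resection: BinaryVolume,
    accuracy: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Connected region, same size as the resection, overlapping it by
    exactly round(a·P) voxels (clipped only if the brain runs out of room).

    Phase 1 grows the in-resection part from a random resection voxel;
    phase 2 grows the remainder outward through brain∖resection. Driving
    both phases from one substream means methods sharing that substream
    (a method family) get nested, strongly overlapping regions.
    """
    p = resection.n_members
    n_in = int(round(accuracy * p))
    if accuracy > 0 and n_in == 0:
        n_in = 1
    res_flat = np.flatnonzero(resection.mask.ravel())
    if n_in > 0:
        seed = res_flat[rng.integers(res_flat.size)]
        inside = grow_region(resection.mask, np.array([seed]), n_in, rng)
    else:
        # a = 0 in this helper: region fully outside the resection
        outside_mask = brain.mask & ~resection.mask
        out_flat = np.flatnonzero(outside_mask.ravel())
        seed = out_flat[rng.integers(out_flat.size)]
        inside = np.array([seed])
    allowed = brain.mask & ~resection.mask
    allowed.ravel()[inside] = True
    target = p if n_in > 0 else p
    capacity = int(allowed.sum())
    if target > capacity:
        target = capacity
    # allow_partial: a large resection can disconnect the remaining brain,
    # leaving the reachable component smaller than the nominal region size
    return grow_region(allowed, inside, target, rng, allow_partial=True)


def generate_method_map(
    brain: BinaryVolume,
    resection: BinaryVolume,
    method: MethodSpec,
    spec: CohortSpec,
    noise_rng: np.random.Generator,
    family_field: np.ndarray | None,
    region_rng: np.random.Generator,
) -> tuple[LabeledVolume, np.ndarray]:
    """One synthetic statistical map and its planted signal region.

    map = sqrt(rho)·family_noise + sqrt(1−rho)·private_noise + 4a·1[region];
    at a = 0 no signal is added and the region is empty.
    """
    sigma_vox = spec.smoothness_fwhm_mm * FWHM_TO_SIGMA / spec.voxel_size_mm
    private = _smooth_unit_noise(tuple(spec.brain_shape), sigma_vox, noise_rng)
    rho = spec.family_share
    if family_field is not None and method.family >= 0:
        noise = np.sqrt(rho) * family_field + np.sqrt(1.0 - rho) * private
    else:
        noise = private
    values = noise.copy()
    if method.accuracy > 0:
        region = _signal_region(brain, resection, method.accuracy, region_rng)
        values.ravel()[region] += 4.0 * method.accuracy
    else:
        region = np.empty(0, dtype=np.int64)
    values[~brain.mask] = 0.0
    vol = LabeledVolume(
        grid=brain.grid,
        values=values.astype(np.float32),
        label=method.name,
        subject="",
    )
    return vol, region


def generate_cohort(spec: CohortSpec) -> SyntheticCohort:
    """Generate a full cohort, reproducible from `spec.seed`.

    Per-subject and per-method substreams are derived deterministically
    from the master seed, so cohorts are identical regardless of the
    order in which pieces are generated.
    """
    if not spec.methods:
        raise ValueError("spec.methods is empty")
    brain = make_brain_mask(spec)
    subjects = [f"sub{i:03d}" for i in range(1, spec.n_subjects + 1)]
    sigma_vox = spec.smoothness_fwhm_mm * FWHM_TO_SIGMA / spec.voxel_size_mm

    maps: dict[tuple[str, str], LabeledVolume] = {}
    resections: dict[str, BinaryVolume] = {}
    brains: dict[str, BinaryVolume] = {}
    regions: dict[tuple[str, str], np.ndarray] = {}

    for s in subjects:
        rng_res = substream(spec.seed, "resection", s)
        size = sample_resection_size_cm3(rng_res, spec.resection_sizes_cm3)
        resections[s] = sample_resection_mask(brain, size, rng_res)
        brains[s] = brain
        family_fields: dict[int, np.ndarray] = {}
        for m in spec.methods:
            rng_miss = substream(spec.seed, "missing", s, m.name)
            if m.missing_rate > 0 and rng_miss.random() < m.missing_rate:
                continue
            if m.family >= 0 and m.family not in family_fields:
                rng_fam = substream(spec.seed, "family-noise", s, m.family)
                family_fields[m.family] = _smooth_unit_noise(
                    tuple(spec.brain_shape), sigma_vox, rng_fam
                )
            fam_field = family_fields.get(m.family) if m.family >= 0 else None
            noise_rng = substream(spec.seed, "noise", s, m.name)
            # family members share the displacement stream; independents get
            # their own
            region_key = ("region-fam", s, m.family) if m.family >= 0 else (
                "region", s, m.name)
            region_rng = substream(spec.seed, *region_key)
            vol, region = generate_method_map(
                brain, resections[s], m, spec, noise_rng, fam_field, region_rng
            )
            vol.subject = s
            maps[(s, m.name)] = vol
            regions[(s, m.name)] = region

    method_names = [m.name for m in spec.methods]
    for m in spec.methods:
        if not any((s, m.name) in maps for s in subjects):
            warnings.warn(f"method {m.name}: all observations missing", stacklevel=2)

    cohort = Cohort(subjects, method_names, maps, resections, brains)
    return SyntheticCohort(
        cohort=cohort,
        spec=spec,
        true_accuracy={m.name: m.accuracy for m in spec.methods},
        family={m.name: m.family for m in spec.methods},
        signal_regions=regions,
    )


def write_cohort(syn: SyntheticCohort, out_dir: str | Path) -> Path:
    """Write NIfTI volumes + manifest TSV + ground-truth JSON to a directory."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cohort = syn.cohort
    entries: dict[tuple[str, str], str] = {}
    resection_path: dict[str, str] = {}
    brain_path: dict[str, str] = {}
    for s in cohort.subjects:
        sdir = out / s
        sdir.mkdir(exist_ok=True)
        write_mask(cohort.brain[s], sdir / "brain.nii.gz")
        write_mask(cohort.resection[s], sdir / "resection.nii.gz")
        brain_path[s] = f"{s}/brain.nii.gz"
        resection_path[s] = f"{s}/resection.nii.gz"
        for m in cohort.methods:
            if cohort.has(s, m):
                write_volume(cohort.maps[(s, m)], sdir / f"{m}.nii.gz")
                entries[(s, m)] = f"{s}/{m}.nii.gz"
            else:
                entries[(s, m)] = MISSING
    manifest = CohortManifest(
        list(cohort.subjects), list(cohort.methods), entries,
        resection_path, brain_path,
    )
    manifest.to_tsv(out / "manifest.tsv")
    truth = {
        "accuracy": syn.true_accuracy,
        "family": syn.family,
        "seed": syn.spec.seed,
        "n_subjects": syn.spec.n_subjects,
    }
    (out / "ground_truth.json").write_text(json.dumps(truth, indent=2))
    return out / "manifest.tsv"
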