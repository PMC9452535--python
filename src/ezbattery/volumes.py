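"""Volumetric containers, NIfTI I/O and cohort manifests.

All volumes of a subject must live on one voxel grid; no resampling is
performed here — harmonizing heterogeneous native grids is preprocessing
that belongs upstream of this package.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import nibabel as nib
import numpy as np
import pandas as pd

#: reserved method names in the manifest
RESECTION = "RESECTION"
BRAIN = "BRAIN"
#: literal marking an absent (subject, method) entry in the manifest
MISSING = "NA"

GRID_ATOL = 1e-3  # mm / per-element tolerance for grid compatibility


class GridMismatchError(ValueError):
    """Two volumes do not share a compatible voxel grid."""


@dataclass(frozen=True)
class VolumeGrid:
    """A 3-D voxel grid: array dims, voxel size in mm and voxel→world affine."""

    dims: tuple[int, int, int]
    voxel_size: tuple[float, float, float]
    affine: np.ndarray  # 4x4 voxel-index -> world-mm map

    def __post_init__(self) -> None:
        if len(self.dims) != 3 or any(d < 1 for d in self.dims):
            raise ValueError(f"dims must be three integers >= 1, got {self.dims}")
        if len(self.voxel_size) != 3 or any(v <= 0 for v in self.voxel_size):
            raise ValueError(f"voxel sizes must be > 0, got {self.voxel_size}")
        object.__setattr__(self, "affine", np.asarray(self.affine, dtype=float))
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")

    @property
    def n_voxels(self) -> int:
        return int(np.prod(self.dims))

    @property
    def voxel_volume_cm3(self) -> float:
        """Volume of one voxel in cm³ (product of mm sizes / 1000)."""
        return float(np.prod(self.voxel_size)) / 1000.0

    def compatible(self, other: "VolumeGrid", atol: float = GRID_ATOL) -> bool:
        return (
            self.dims == other.dims
            and np.allclose(self.voxel_size, other.voxel_size, atol=atol, rtol=0)
            and np.allclose(self.affine, other.affine, atol=atol, rtol=0)
        )

    def require_compatible(self, other: "VolumeGrid") -> None:
        if not self.compatible(other):
            raise GridMismatchError(
                f"incompatible grids: dims {self.dims} voxel {self.voxel_size} vs "
                f"dims {other.dims} voxel {other.voxel_size}"
            )

    @staticmethod
    def isotropic(dims: tuple[int, int, int], voxel_mm: float) -> "VolumeGrid":
        aff = np.diag([voxel_mm, voxel_mm, voxel_mm, 1.0])
        return VolumeGrid(tuple(int(d) for d in dims), (voxel_mm,) * 3, aff)


@dataclass
class LabeledVolume:
    """One method's scalar statistical map for one subject."""

    grid: VolumeGrid
    values: np.ndarray
    label: str = ""
    subject: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if tuple(self.values.shape) != tuple(self.grid.dims):
            raise ValueError(
                f"value shape {self.values.shape} != grid dims {self.grid.dims}"
            )


@dataclass
class BinaryVolume:
    """A binary mask: brain, resection, thresholded map or random surgery mask."""

    grid: VolumeGrid
    mask: np.ndarray  # boolean, shape == grid.dims
    role: str = "brain"  # brain | resection | thresholded | random_mask
    seed_voxel: tuple[int, int, int] | None = None  # diagnostics for grown masks

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask).astype(bool)
        if tuple(self.mask.shape) != tuple(self.grid.dims):
            raise ValueError(
                f"mask shape {self.mask.shape} != grid dims {self.grid.dims}"
            )

    @property
    def n_members(self) -> int:
        return int(self.mask.sum())

    @property
    def size_cm3(self) -> float:
        return self.n_members * self.grid.voxel_volume_cm3

    def members(self) -> np.ndarray:
        """(n, 3) integer voxel indices of the mask, in C order."""
        return np.argwhere(self.mask)


def _grid_from_image(img: nib.Nifti1Image) -> VolumeGrid:
    shape = tuple(int(s) for s in img.shape[:3])
    zooms = tuple(float(z) for z in img.header.get_zooms()[:3])
    return VolumeGrid(shape, zooms, np.asarray(img.affine, dtype=float))


def read_volume(
    path: str | Path,
    expected_grid: VolumeGrid | None = None,
    label: str = "",
    subject: str = "",
) -> LabeledVolume:
    """Read a NIfTI-1 scalar volume; optionally enforce a grid.

    Raises ``OSError`` for unreadable files and :class:`GridMismatchError`
    when ``expected_grid`` is given and does not match the file's grid.
    """
    path = Path(path)
    if not path.exists():
        raise OSError(f"volume file not found: {path}")
    img = nib.load(str(path))
    grid = _grid_from_image(img)
    if expected_grid is not None:
        expected_grid.require_compatible(grid)
    data = np.asanyarray(img.dataobj)
    if data.ndim > 3:
        data = np.squeeze(data)
    return LabeledVolume(grid=grid, values=data, label=label, subject=subject)


def read_mask(
    path: str | Path,
    role: str,
    expected_grid: VolumeGrid | None = None,
) -> BinaryVolume:
    vol = read_volume(path, expected_grid=expected_grid)
    return BinaryVolume(grid=vol.grid, mask=vol.values > 0, role=role)


def write_volume(vol: LabeledVolume, path: str | Path) -> Path:
    """Write as float32 NIfTI (float32 data round-trips bit-exactly)."""
    path = Path(path)
    img = nib.Nifti1Image(np.asarray(vol.values, dtype=np.float32), vol.grid.affine)
    img.header.set_zooms(vol.grid.voxel_size)
    nib.save(img, str(path))
    return path


def write_mask(bv: BinaryVolume, path: str | Path) -> Path:
    """Masks are stored as 8-bit NIfTI with 0/1 values."""
    path = Path(path)
    img = nib.Nifti1Image(bv.mask.astype(np.uint8), bv.grid.affine)
    img.header.set_zooms(bv.grid.voxel_size)
    nib.save(img, str(path))
    return path


@dataclass
class CohortManifest:
    """Tabular index of a cohort: which file holds which (subject, method) map.

    Serialized as a TSV with columns ``subject``, ``method``, ``path``;
    the method names ``RESECTION`` and ``BRAIN`` are reserved for the masks
    and the literal path value ``NA`` marks an explicitly missing entry.
    """

    subjects: list[str]
    methods: list[str]
    entries: dict[tuple[str, str], str]  # (subject, method) -> path or MISSING
    resection_path: dict[str, str] = field(default_factory=dict)
    brain_path: dict[str, str] = field(default_factory=dict)

    def validate(self) -> None:
        for s in self.subjects:
            if s not in self.resection_path:
                raise ValueError(f"subject {s} has no RESECTION entry")
            if s not in self.brain_path:
                raise ValueError(f"subject {s} has no BRAIN entry")
        for (s, m) in self.entries:
            if s not in self.subjects or m not in self.methods:
                raise ValueError(f"entry ({s}, {m}) outside declared subjects/methods")

    def is_missing(self, subject: str, method: str) -> bool:
        return self.entries.get((subject, method), MISSING) == MISSING

    def to_tsv(self, path: str | Path) -> Path:
        rows = []
        for s in self.subjects:
            rows.append((s, RESECTION, self.resection_path[s]))
            rows.append((s, BRAIN, self.brain_path[s]))
            for m in self.methods:
                rows.append((s, m, self.entries.get((s, m), MISSING)))
        df = pd.DataFrame(rows, columns=["subject", "method", "path"])
        path = Path(path)
        df.to_csv(path, sep="\t", index=False)
        return path

    @staticmethod
    def from_tsv(path: str | Path) -> "CohortManifest":
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
        required = {"subject", "method", "path"}
        if not required.issubset(df.columns):
            raise ValueError(f"manifest must have columns {sorted(required)}")
        subjects: list[str] = []
        methods: list[str] = []
        entries: dict[tuple[str, str], str] = {}
        resection: dict[str, str] = {}
        brain: dict[str, str] = {}
        for _, row in df.iterrows():
            s, m, p = row["subject"], row["method"], row["path"]
            if s not in subjects:
                subjects.append(s)
            if m == RESECTION:
                resection[s] = p
            elif m == BRAIN:
                brain[s] = p
            else:
                if m not in methods:
                    methods.append(m)
                entries[(s, m)] = p
        man = CohortManifest(subjects, methods, entries, resection, brain)
        man.validate()
        return man


@dataclass
class Cohort:
    """In-memory cohort: per-subject maps, masks and explicit missingness."""

    subjects: list[str]
    methods: list[str]
    maps: dict[tuple[str, str], LabeledVolume]
    resection: dict[str, BinaryVolume]
    brain: dict[str, BinaryVolume]

    def __post_init__(self) -> None:
        for s in self.subjects:
            rs, br = self.resection[s], self.brain[s]
            br.grid.require_compatible(rs.grid)
            if np.any(rs.mask & ~br.mask):
                raise ValueError(f"subject {s}: resection extends outside brain mask")

    def has(self, subject: str, method: str) -> bool:
        return (subject, method) in self.maps

    def completeness(self) -> pd.Series:
        """Fraction of subjects with an observed map, per method."""
        frac = {
            m: sum(self.has(s, m) for s in self.subjects) / len(self.subjects)
            for m in self.methods
        }
        return pd.Series(frac, name="completeness")

    def resection_sizes_cm3(self) -> list[float]:
        """Observed resection sizes over the cohort — the random-mask size pool."""
        return [self.resection[s].size_cm3 for s in self.subjects]


def load_cohort(manifest: CohortManifest | str | Path, base_dir: str | Path | None = None) -> Cohort:
    """Load every non-missing entry of a manifest, grid-checking each volume
    against its subject's brain mask. Never silently drops a subject."""
    if not isinstance(manifest, CohortManifest):
        manifest_path = Path(manifest)
        if base_dir is None:
            base_dir = manifest_path.parent
        manifest = CohortManifest.from_tsv(manifest_path)
    base = Path(base_dir) if base_dir is not None else Path(".")

    def _resolve(p: str) -> Path:
        q = Path(p)
        return q if q.is_absolute() else base / q

    maps: dict[tuple[str, str], LabeledVolume] = {}
    resection: dict[str, BinaryVolume] = {}
    brain: dict[str, BinaryVolume] = {}
    for s in manifest.subjects:
        try:
            brain[s] = read_mask(_resolve(manifest.brain_path[s]), role="brain")
            resection[s] = read_mask(
                _resolve(manifest.resection_path[s]), role="resection",
                expected_grid=brain[s].grid,
            )
        except Exception as exc:  # noqa: BLE001 - annotate with subject
            raise type(exc)(f"subject {s}: {exc}") from exc
        for m in manifest.methods:
            p = manifest.entries.get((s, m), MISSING)
            if p == MISSING:
                continue
            try:
                maps[(s, m)] = read_volume(
                    _resolve(p), expected_grid=brain[s].grid, label=m, subject=s
                )
            except Exception as exc:  # noqa: BLE001
                raise type(exc)(f"subject {s}, method {m}: {exc}") from exc
    cohort = Cohort(list(manifest.subjects), list(manifest.methods), maps, resection, brain)
    comp = cohort.completeness()
    for m, f in comp.items():
        if f == 0:
            warnings.warn(f"method {m}: no observed maps in cohort", stacklevel=2)
    return cohort


def volume_cm3(n_voxels: int, grid: VolumeGrid) -> float:
    """|members| × voxel volume, in cm³."""
    return n_voxels * grid.voxel_volume_cm3
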