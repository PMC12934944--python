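"""Volumetric pattern handling: masks, searchlights, ROIs, reliability.

Patterns are condition-by-voxel beta matrices bound to a 3D voxel grid
through an analysis mask; voxel columns follow the lexicographic order of
the mask's member indices.  Searchlights are overlapping spheres (radius
in voxel units, inclusive boundary) centered on every in-mask voxel.
Functional ROIs are the top fraction of localizer-contrast voxels inside
an anatomical parcel.  Split-half reliability (even vs odd repeats)
provides both voxelwise inclusion masks and, via the Spearman-Brown
correction 2r/(1+r), the noise-ceiling estimate for ROI-level RSA.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass
from functools import lru_cache

import nibabel as nib
import numpy as np

from .rdm import RDM, DegenerateRepresentationError, correlation_distance_matrix

__all__ = [
    "VolumeGrid",
    "VoxelMask",
    "Searchlight",
    "PatternDataset",
    "normalize_and_average",
    "sphere_offsets",
    "define_searchlights",
    "neural_rdm",
    "split_half_voxel_reliability",
    "split_half_rsa_reliability",
    "spearman_brown",
    "split_repeats",
    "define_roi_top_percent",
    "dice",
    "remove_overlap",
    "save_mask_nifti",
    "load_mask_nifti",
    "save_map_nifti",
]

logger = logging.getLogger(__name__)

#: searchlights smaller than this are flagged, not dropped
MIN_SEARCHLIGHT_VOXELS = 10


@dataclass(frozen=True)
class VolumeGrid:
    """Voxel grid extents with physical voxel size in mm."""

    shape: tuple[int, int, int]
    voxel_size: tuple[float, float, float] = (3.0, 3.0, 3.0)
    affine: np.ndarray | None = None

    def __post_init__(self) -> None:
        shape = tuple(int(s) for s in self.shape)
        object.__setattr__(self, "shape", shape)
        if len(shape) != 3 or any(s <= 0 for s in shape):
            raise ValueError("grid shape must be three positive extents")
        if any(v <= 0 for v in self.voxel_size):
            raise ValueError("voxel size must be positive")

    @property
    def n_voxels(self) -> int:
        return int(np.prod(self.shape))

    def default_affine(self) -> np.ndarray:
        if self.affine is not None:
            return np.asarray(self.affine)
        aff = np.diag(list(self.voxel_size) + [1.0])
        return aff


class VoxelMask:
    """A set of voxel indices on a grid (boolean volume with set semantics)."""

    def __init__(self, grid: VolumeGrid, data: np.ndarray):
        data = np.asarray(data, dtype=bool)
        if data.shape != grid.shape:
            raise ValueError(
                f"mask shape {data.shape} does not match grid {grid.shape}"
            )
        self.grid = grid
        self.data = data
        self._members = np.argwhere(data)  # lexicographic order
        flat = np.full(grid.n_voxels, -1, dtype=np.int64)
        flat[np.ravel_multi_index(self._members.T, grid.shape)] = np.arange(
            len(self._members)
        )
        self._flat = flat

    @classmethod
    def from_indices(cls, grid: VolumeGrid, indices) -> "VoxelMask":
        indices = np.atleast_2d(np.asarray(indices, dtype=int))
        data = np.zeros(grid.shape, dtype=bool)
        if indices.size:
            if indices.min() < 0 or np.any(indices >= np.array(grid.shape)):
                raise ValueError("voxel indices outside grid extents")
            data[tuple(indices.T)] = True
        return cls(grid, data)

    @property
    def members(self) -> np.ndarray:
        """(N, 3) int array of member voxel indices, lexicographic order."""
        return self._members

    @property
    def size(self) -> int:
        return len(self._members)

    def __len__(self) -> int:
        return self.size

    def column_indices(self, indices: np.ndarray) -> np.ndarray:
        """Map voxel indices to column positions in this mask's ordering."""
        flat = np.ravel_multi_index(np.atleast_2d(indices).T, self.grid.shape)
        cols = self._flat[flat]
        if np.any(cols < 0):
            raise ValueError("some voxels are not members of the mask")
        return cols

    def intersect(self, other: "VoxelMask") -> "VoxelMask":
        self._check_grid(other)
        return VoxelMask(self.grid, self.data & other.data)

    def difference(self, other: "VoxelMask") -> "VoxelMask":
        self._check_grid(other)
        return VoxelMask(self.grid, self.data & ~other.data)

    def union(self, other: "VoxelMask") -> "VoxelMask":
        self._check_grid(other)
        return VoxelMask(self.grid, self.data | other.data)

    def _check_grid(self, other: "VoxelMask") -> None:
        if other.grid.shape != self.grid.shape:
            raise ValueError("masks live on different grids")

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, VoxelMask)
            and self.grid.shape == other.grid.shape
            and bool(np.array_equal(self.data, other.data))
        )


@dataclass(frozen=True)
class Searchlight:
    """A sphere of in-mask voxels around a center voxel."""

    center: tuple[int, int, int]
    members: np.ndarray  # (M, 3) voxel indices
    member_cols: np.ndarray  # columns into the analysis-mask ordering
    small: bool = False  # fewer than MIN_SEARCHLIGHT_VOXELS members

    @property
    def n_voxels(self) -> int:
        return len(self.member_cols)


@dataclass
class PatternDataset:
    """Per-subject, per-repeat condition-by-voxel response matrices.

    ``subjects`` maps a subject id to a list of repeat matrices, each of
    shape (n_conditions, mask.size); ragged repeat counts across subjects
    are allowed (e.g. participants missing late runs).
    """

    subjects: dict[str, list[np.ndarray]]
    condition_labels: tuple[str, ...]
    grid: VolumeGrid
    mask: VoxelMask

    def __post_init__(self) -> None:
        self.condition_labels = tuple(map(str, self.condition_labels))
        n_cond = len(self.condition_labels)
        for subj, repeats in self.subjects.items():
            if not repeats:
                raise ValueError(f"subject {subj} has no repeats")
            for rep in repeats:
                if rep.shape != (n_cond, self.mask.size):
                    raise ValueError(
                        f"subject {subj}: repeat shape {rep.shape} != "
                        f"({n_cond}, {self.mask.size})"
                    )

    @property
    def subject_ids(self) -> tuple[str, ...]:
        return tuple(self.subjects)

    @property
    def n_subjects(self) -> int:
        return len(self.subjects)

    def averaged(self, subject: str) -> np.ndarray:
        """Voxelwise-normalized, repeat-averaged patterns for one subject."""
        return normalize_and_average(self.subjects[subject])


def normalize_and_average(repeats: list[np.ndarray],
                          return_excluded: bool = False):
    """Standardize each voxel across conditions x repeats, then average repeats.

    Standardization is to zero mean and unit (population) variance within
    the subject; zero-variance voxels are zeroed and logged rather than
    raising.
    """
    if not repeats:
        raise ValueError("need at least one repeat")
    stacked = np.vstack([np.asarray(r, dtype=float) for r in repeats])
    mean = stacked.mean(axis=0)
    sd = stacked.std(axis=0)
    excluded = np.flatnonzero(sd == 0)
    if excluded.size:
        logger.warning(
            "normalize_and_average: %d zero-variance voxel(s) zeroed", excluded.size
        )
    safe_sd = np.where(sd == 0, 1.0, sd)
    n_cond = repeats[0].shape[0]
    z = (stacked - mean) / safe_sd
    avg = z.reshape(len(repeats), n_cond, -1).mean(axis=0)
    avg[:, excluded] = 0.0
    if return_excluded:
        return avg, excluded
    return avg


@lru_cache(maxsize=None)
def sphere_offsets(radius: float) -> np.ndarray:
    """Integer lattice offsets with squared Euclidean norm <= radius^2."""
    r = int(math.floor(radius))
    rng = np.arange(-r, r + 1)
    xx, yy, zz = np.meshgrid(rng, rng, rng, indexing="ij")
    keep = xx**2 + yy**2 + zz**2 <= radius**2 + 1e-12
    return np.column_stack([xx[keep], yy[keep], zz[keep]])


def define_searchlights(mask: VoxelMask, radius: float = 3.0) -> list[Searchlight]:
    """One searchlight per in-mask voxel; members restricted to the mask."""
    if radius <= 0:
        raise ValueError("searchlight radius must be positive")
    if mask.size == 0:
        warnings.warn("empty analysis mask: no searchlights defined")
        return []
    offsets = sphere_offsets(radius)
    shape = np.array(mask.grid.shape)
    out: list[Searchlight] = []
    for center in mask.members:
        cand = center + offsets
        inb = np.all((cand >= 0) & (cand < shape), axis=1)
        cand = cand[inb]
        inmask = mask.data[tuple(cand.T)]
        members = cand[inmask]
        cols = mask.column_indices(members)
        out.append(
            Searchlight(
                center=tuple(int(c) for c in center),
                members=members,
                member_cols=cols,
                small=len(cols) < MIN_SEARCHLIGHT_VOXELS,
            )
        )
    return out


def neural_rdm(patterns: np.ndarray, voxel_cols=None,
               labels: tuple[str, ...] | None = None) -> RDM:
    """Correlation-distance RDM over condition patterns at a voxel subset."""
    patterns = np.asarray(patterns, dtype=float)
    if voxel_cols is not None:
        patterns = patterns[:, np.asarray(voxel_cols, dtype=int)]
    n_cond, n_vox = patterns.shape
    if n_vox < 2:
        raise ValueError(f"need >= 2 voxels for a neural RDM, got {n_vox}")
    if n_cond < 3:
        raise ValueError("need >= 3 conditions for a neural RDM")
    if labels is None:
        labels = tuple(map(str, range(n_cond)))
    sd = patterns.std(axis=1)
    bad = np.flatnonzero(sd == 0)
    if bad.size:
        raise DegenerateRepresentationError(
            "zero-variance pattern for condition(s): "
            + ", ".join(labels[i] for i in bad)
        )
    return RDM(labels, correlation_distance_matrix(patterns))


def split_repeats(repeats: list[np.ndarray]) -> tuple[np.ndarray, np.ndarray]:
    """Average even-index and odd-index repeats (0-based; an odd count
    leaves the extra repeat in the even split)."""
    if len(repeats) < 2:
        raise ValueError("split-half needs >= 2 repeats")
    even = np.mean([r for i, r in enumerate(repeats) if i % 2 == 0], axis=0)
    odd = np.mean([r for i, r in enumerate(repeats) if i % 2 == 1], axis=0)
    return even, odd


def split_half_voxel_reliability(repeats: list[np.ndarray]):
    """Per-voxel Pearson r between even- and odd-repeat averages.

    Returns ``(r, mask)`` where ``r`` is a per-voxel correlation across
    conditions (NaN where a half has zero variance) and ``mask`` the
    liberal inclusion rule r > 0.
    """
    even, odd = split_repeats(repeats)
    a = even - even.mean(axis=0)
    b = odd - odd.mean(axis=0)
    denom = np.sqrt((a**2).sum(axis=0) * (b**2).sum(axis=0))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(denom > 0, (a * b).sum(axis=0) / np.where(denom > 0, denom, 1.0),
                     np.nan)
    mask = np.nan_to_num(r, nan=-1.0) > 0
    return r, mask


def spearman_brown(r: float) -> float:
    """Split-half correction 2r / (1 + r); undefined (NaN) at r = -1."""
    if r <= -1.0:
        return float("nan")
    return 2.0 * r / (1.0 + r)


def split_half_rsa_reliability(repeats: list[np.ndarray],
                               voxel_cols=None,
                               apply_reliability_mask: bool = True) -> float:
    """Spearman-Brown-corrected split-half RSA of the pattern geometry.

    Splits repeats into even/odd halves, optionally restricts to voxels
    passing the split-half reliability mask, builds an RDM per half, and
    corrects the Spearman correlation between them as 2r/(1+r).  Returns
    NaN when the correction is undefined or too few voxels survive.
    """
    if voxel_cols is not None:
        repeats = [np.asarray(r)[:, np.asarray(voxel_cols, int)] for r in repeats]
    even, odd = split_repeats(repeats)
    if apply_reliability_mask:
        _, keep = split_half_voxel_reliability(repeats)
        if keep.sum() < 2:
            return float("nan")
        even, odd = even[:, keep], odd[:, keep]
    try:
        rdm_even = neural_rdm(even)
        rdm_odd = neural_rdm(odd)
    except (ValueError, DegenerateRepresentationError):
        return float("nan")
    from .rdm import rdm_vector, spearman_rsa

    r = spearman_rsa(rdm_vector(rdm_even), rdm_vector(rdm_odd)).rho
    return spearman_brown(r)


def define_roi_top_percent(contrast: np.ndarray, parcel: VoxelMask,
                           pct: float = 0.10) -> VoxelMask:
    """Top ``pct`` fraction of contrast voxels inside a parcel.

    Takes the ceil(pct * |parcel|) parcel voxels with the largest contrast;
    ties at the threshold are broken by lexicographic voxel-index order.
    """
    if parcel.size == 0:
        raise ValueError("empty parcel")
    if not 0.0 < pct <= 1.0:
        raise ValueError("pct must lie in (0, 1]")
    contrast = np.asarray(contrast, dtype=float)
    if contrast.shape != parcel.grid.shape:
        raise ValueError("contrast map shape does not match the grid")
    values = contrast[tuple(parcel.members.T)]
    if np.any(~np.isfinite(values)):
        raise ValueError("contrast undefined (non-finite) inside the parcel")
    k = math.ceil(pct * parcel.size)
    # stable sort on descending value keeps lexicographic order within ties
    order = np.argsort(-values, kind="stable")[:k]
    return VoxelMask.from_indices(parcel.grid, parcel.members[order])


def dice(a: VoxelMask, b: VoxelMask) -> float:
    """DICE overlap 2|A n B| / (|A| + |B|)."""
    if a.grid.shape != b.grid.shape:
        raise ValueError("masks live on different grids")
    total = a.size + b.size
    if total == 0:
        raise ValueError("DICE undefined for two empty masks")
    return 2.0 * a.intersect(b).size / total


def remove_overlap(a: VoxelMask, b: VoxelMask) -> tuple[VoxelMask, VoxelMask]:
    """Strip shared voxels from both masks: returns (a \\ b, b \\ a)."""
    out_a, out_b = a.difference(b), b.difference(a)
    if out_a.size == 0 or out_b.size == 0:
        warnings.warn("overlap removal emptied a mask")
    return out_a, out_b


def save_mask_nifti(mask: VoxelMask, path) -> None:
    img = nib.Nifti1Image(mask.data.astype(np.uint8), mask.grid.default_affine())
    nib.save(img, str(path))


def load_mask_nifti(path, grid: VolumeGrid | None = None) -> VoxelMask:
    img = nib.load(str(path))
    data = np.asarray(img.dataobj) > 0.5
    if grid is None:
        zooms = img.header.get_zooms()[:3]
        grid = VolumeGrid(data.shape, tuple(float(z) for z in zooms),
                          affine=img.affine)
    return VoxelMask(grid, data)


def save_map_nifti(values: np.ndarray, mask: VoxelMask, path,
                   fill: float = 0.0) -> None:
    """Scatter per-mask-voxel values into a volume and write NIfTI-1."""
    vol = np.full(mask.grid.shape, fill, dtype=np.float32)
    vol[tuple(mask.members.T)] = values
    img = nib.Nifti1Image(vol, mask.grid.default_affine())
    nib.save(img, str(path))
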