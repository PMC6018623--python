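"""Voxel grids, binary lesion/region masks, and NIfTI input/output.

All spatial quantities downstream (mislocalisation vectors, cluster
centroids) are expressed in millimetres via the NIfTI affine; voxel indices
are 0-based ``(i, j, k)`` triples.  Masks are dense boolean volumes on a
shared :class:`VoxelGrid`.
"""

from __future__ import annotations

import os
import warnings
from dataclasses import dataclass, field

import nibabel as nib
import numpy as np

__all__ = [
    "VoxelGrid",
    "LesionStack",
    "RegionMask",
    "make_grid",
    "spherical_mask",
    "spherical_region",
    "read_mask_volume",
    "write_mask_volume",
    "stack_lesions",
    "read_manifest",
    "write_manifest",
    "read_atlas",
    "mirror_mask",
]


@dataclass(frozen=True)
class VoxelGrid:
    """A regular 3-D voxel grid with a world (mm) coordinate frame.

    Parameters
    ----------
    shape
        Number of voxels per axis.
    affine
        4x4 voxel-index -> mm transform (NIfTI convention, 0-based indices).
    brain_mask
        Boolean volume marking in-brain voxels; analyses are restricted to it.
    """

    shape: tuple[int, int, int]
    affine: np.ndarray
    brain_mask: np.ndarray

    def __post_init__(self) -> None:
        shape = tuple(int(s) for s in self.shape)
        object.__setattr__(self, "shape", shape)
        if any(s < 1 for s in shape):
            raise ValueError(f"grid shape must be >= 1 per axis, got {shape}")
        aff = np.asarray(self.affine, dtype=float)
        if aff.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        if abs(np.linalg.det(aff[:3, :3])) < 1e-12:
            raise ValueError("affine is singular")
        object.__setattr__(self, "affine", aff)
        bm = np.asarray(self.brain_mask, dtype=bool)
        if bm.shape != shape:
            raise ValueError(
                f"brain_mask shape {bm.shape} does not match grid shape {shape}"
            )
        object.__setattr__(self, "brain_mask", bm)

    @property
    def voxel_size(self) -> np.ndarray:
        """Voxel edge lengths in mm per axis."""
        return np.sqrt((self.affine[:3, :3] ** 2).sum(axis=0))

    @property
    def voxel_volume_mm3(self) -> float:
        return float(abs(np.linalg.det(self.affine[:3, :3])))

    @property
    def n_in_mask(self) -> int:
        return int(self.brain_mask.sum())

    def voxel_to_world(self, index) -> np.ndarray:
        """Map 0-based voxel indices to mm world coordinates.

        ``index`` may be a single triple or an (n, 3) array.
        """
        idx = np.atleast_2d(np.asarray(index, dtype=float))
        ints = np.round(idx).astype(int)
        if (ints < 0).any() or (ints >= np.asarray(self.shape)).any():
            raise IndexError(f"voxel index out of bounds for shape {self.shape}")
        world = idx @ self.affine[:3, :3].T + self.affine[:3, 3]
        return world[0] if np.asarray(index).ndim == 1 else world

    def world_to_voxel(self, coord) -> np.ndarray:
        """Inverse of :meth:`voxel_to_world`; returns nearest integer indices."""
        xyz = np.atleast_2d(np.asarray(coord, dtype=float))
        inv = np.linalg.inv(self.affine)
        idx = xyz @ inv[:3, :3].T + inv[:3, 3]
        idx = np.round(idx).astype(int)
        return idx[0] if np.asarray(coord).ndim == 1 else idx

    def mask_indices(self) -> np.ndarray:
        """(n_in_mask, 3) integer indices of in-brain voxels, C order."""
        return np.argwhere(self.brain_mask)

    def compatible_with(self, other: "VoxelGrid", atol: float = 1e-4) -> bool:
        return self.shape == other.shape and np.allclose(
            self.affine, other.affine, atol=atol
        )


def make_grid(
    shape: tuple[int, int, int],
    voxel_size: float | tuple[float, float, float] = 1.0,
    brain_mask: np.ndarray | None = None,
) -> VoxelGrid:
    """Build a grid with a diagonal affine (isotropic or per-axis mm)."""
    vs = np.broadcast_to(np.asarray(voxel_size, dtype=float), (3,))
    if (vs <= 0).any():
        raise ValueError("voxel_size must be positive")
    affine = np.diag(np.append(vs, 1.0))
    if brain_mask is None:
        brain_mask = np.ones(shape, dtype=bool)
    return VoxelGrid(shape=tuple(shape), affine=affine, brain_mask=brain_mask)


def spherical_mask(shape, radius: float, centre=None) -> np.ndarray:
    """Boolean ball of ``radius`` voxels, a convenient synthetic brain mask."""
    shape = tuple(int(s) for s in shape)
    if centre is None:
        centre = [(s - 1) / 2 for s in shape]
    grids = np.ogrid[tuple(slice(0, s) for s in shape)]
    d2 = sum((g - c) ** 2 for g, c in zip(grids, centre))
    return d2 <= radius**2


@dataclass(frozen=True)
class RegionMask:
    """A named anatomical region (e.g. a Brodmann area) on a grid."""

    name: str
    grid: VoxelGrid
    mask: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.mask, dtype=bool)
        if m.shape != self.grid.shape:
            raise ValueError("region mask shape does not match grid")
        if not m.any():
            raise ValueError(f"region {self.name!r} is empty")
        if (m & ~self.grid.brain_mask).any():
            raise ValueError(f"region {self.name!r} extends outside the brain mask")
        object.__setattr__(self, "mask", m)

    @property
    def volume_voxels(self) -> int:
        return int(self.mask.sum())


def spherical_region(
    grid: VoxelGrid, name: str, centre, radius: float
) -> RegionMask:
    """Spherical region clipped to the brain mask — a synthetic stand-in for
    an atlas label when no real atlas is available."""
    m = spherical_mask(grid.shape, radius, centre) & grid.brain_mask
    return RegionMask(name=name, grid=grid, mask=m)


@dataclass
class LesionStack:
    """N co-registered binary lesion masks on one grid.

    ``masks`` is an (N, nx, ny, nz) boolean array; ``volumes_mm3`` is derived
    (voxel count x voxel volume) and kept consistent by construction.
    """

    grid: VoxelGrid
    masks: np.ndarray
    lesion_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        m = np.asarray(self.masks, dtype=bool)
        if m.ndim != 4 or m.shape[1:] != self.grid.shape:
            raise ValueError(
                f"masks must be (N, {self.grid.shape}), got {m.shape}"
            )
        if m.shape[0] < 1:
            raise ValueError("a lesion stack needs at least one lesion")
        outside = m & ~self.grid.brain_mask[None]
        if outside.any():
            raise ValueError("lesion voxels fall outside the brain mask")
        self.masks = m
        if not self.lesion_ids:
            self.lesion_ids = [f"lesion_{i:04d}" for i in range(m.shape[0])]
        if len(self.lesion_ids) != m.shape[0]:
            raise ValueError("lesion_ids length does not match mask count")

    @property
    def n(self) -> int:
        return self.masks.shape[0]

    @property
    def voxel_counts(self) -> np.ndarray:
        return self.masks.reshape(self.n, -1).sum(axis=1)

    @property
    def volumes_mm3(self) -> np.ndarray:
        return self.voxel_counts * self.grid.voxel_volume_mm3

    def hit_counts(self) -> np.ndarray:
        """Per-voxel number of lesions covering that voxel."""
        return self.masks.sum(axis=0)

    def design_matrix(self, voxel_indices: np.ndarray) -> np.ndarray:
        """(N, V) binary damage matrix at the given (V, 3) voxel indices."""
        i, j, k = voxel_indices.T
        return self.masks[:, i, j, k]

    def subset(self, indices) -> "LesionStack":
        idx = np.asarray(indices)
        return LesionStack(
            grid=self.grid,
            masks=self.masks[idx],
            lesion_ids=[self.lesion_ids[i] for i in idx],
        )


# ---------------------------------------------------------------------------
# NIfTI and manifest I/O


def read_mask_volume(
    path: str | os.PathLike,
    grid: VoxelGrid | None = None,
    threshold: float = 0.5,
    on_nonbinary: str = "warn",
) -> tuple[np.ndarray, VoxelGrid]:
    """Read a binary mask from a NIfTI file.

    Values are thresholded at ``threshold``; data that is not already 0/1
    triggers a warning (``on_nonbinary='warn'``) or an error (``'raise'``).
    If a reference ``grid`` is supplied, shape and affine must match it.
    """
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=float)
    if data.ndim != 3:
        raise ValueError(f"{path}: expected a 3-D volume, got shape {data.shape}")
    binary_already = np.isin(np.unique(data), [0.0, 1.0]).all()
    mask = data > threshold
    if not binary_already:
        msg = f"{path}: non-binary data thresholded at {threshold}"
        if on_nonbinary == "raise":
            raise ValueError(msg)
        warnings.warn(msg, stacklevel=2)
    affine = np.asarray(img.affine, dtype=float)
    if grid is not None:
        if tuple(data.shape) != grid.shape:
            raise ValueError(
                f"{path}: shape {data.shape} does not match reference {grid.shape}"
            )
        if not np.allclose(affine, grid.affine, atol=1e-4):
            raise ValueError(f"{path}: affine does not match reference grid")
        out_grid = grid
    else:
        out_grid = VoxelGrid(
            shape=tuple(data.shape),
            affine=affine,
            brain_mask=np.ones(data.shape, dtype=bool),
        )
    return mask, out_grid


def write_mask_volume(path: str | os.PathLike, mask: np.ndarray, grid: VoxelGrid) -> None:
    img = nib.Nifti1Image(np.asarray(mask, dtype=np.uint8), grid.affine)
    nib.save(img, str(path))


def stack_lesions(
    paths: list[str | os.PathLike],
    grid: VoxelGrid | None = None,
    lesion_ids: list[str] | None = None,
    on_empty: str = "raise",
) -> LesionStack:
    """Load lesion NIfTI files sharing one grid into a :class:`LesionStack`.

    Empty (zero-voxel) lesions carry no information and break volume
    covariates; they raise by default (``on_empty='warn'`` keeps them).
    """
    if not paths:
        raise ValueError("no lesion paths given")
    masks = []
    for p in paths:
        mask, grid = read_mask_volume(p, grid=grid)
        if not mask.any():
            if on_empty == "raise":
                raise ValueError(f"{p}: lesion has zero voxels")
            warnings.warn(f"{p}: lesion has zero voxels", stacklevel=2)
        masks.append(mask)
    ids = lesion_ids or [os.path.splitext(os.path.basename(str(p)))[0] for p in paths]
    return LesionStack(grid=grid, masks=np.stack(masks), lesion_ids=ids)


def write_manifest(path: str | os.PathLike, paths: list[str], labels=None) -> None:
    """Plain-text cohort manifest: one ``path[\\t label]`` per line."""
    with open(path, "w") as fh:
        for i, p in enumerate(paths):
            if labels is not None:
                fh.write(f"{p}\t{labels[i]}\n")
            else:
                fh.write(f"{p}\n")


def read_manifest(path: str | os.PathLike) -> tuple[list[str], list[str] | None]:
    paths, labels = [], []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            paths.append(parts[0])
            labels.append(parts[1] if len(parts) > 1 else None)
    has_labels = any(l is not None for l in labels)
    return paths, (labels if has_labels else None)


def read_atlas(
    nifti_path: str | os.PathLike,
    label_table: str | os.PathLike | None = None,
    grid: VoxelGrid | None = None,
) -> list[RegionMask]:
    """Read regions from an integer-labelled NIfTI plus a name<->label TSV.

    Without a table, each distinct nonzero label becomes ``label_<k>``.
    """
    img = nib.load(str(nifti_path))
    data = np.asarray(img.dataobj)
    data = np.round(data).astype(int)
    affine = np.asarray(img.affine, dtype=float)
    if grid is None:
        grid = VoxelGrid(
            shape=tuple(data.shape),
            affine=affine,
            brain_mask=np.ones(data.shape, dtype=bool),
        )
    names: dict[int, str] = {}
    if label_table is not None:
        with open(label_table) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                name, lab = line.split("\t")[:2]
                names[int(lab)] = name
    regions = []
    for lab in np.unique(data):
        if lab == 0:
            continue
        regions.append(
            RegionMask(
                name=names.get(int(lab), f"label_{int(lab)}"),
                grid=grid,
                mask=data == lab,
            )
        )
    return regions


def mirror_mask(mask: np.ndarray, axis: int = 0) -> np.ndarray:
    """Reflect a mask about the grid's mid-plane along ``axis`` and take the
    union with the original (hemisphere mirroring; optional preprocessing)."""
    return mask | np.flip(mask, axis=axis)
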