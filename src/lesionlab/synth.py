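"""Synthetic lesion cohorts with controllable spatial structure.

Real focal brain lesions — above all ischaemic stroke — are not random
scatter: which voxels are damaged together is dictated by the branching
macrovascular architecture, so the voxel-voxel damage covariance is highly
structured and lesion volume varies systematically with anatomy.  This
module emulates three regimes:

``uniform_single_voxel``
    Each lesion is exactly one in-mask voxel, i.i.d. uniform over the brain
    mask — a lesion architecture that is random by construction and so
    introduces no spatial bias.
``tree_structured``
    Lesions seed on a stochastic bifurcating vascular tree and grow as
    connected regions preferentially within the seed segment's perfusion
    territory, with target volumes drawn from a depth-dependent log-normal
    (proximal occlusions -> large territories, distal -> small).
``gaussian_blob``
    Spherical blobs at uniform centres: spatially extended but tree-free,
    a structured-but-unbiased control.

The tree-growth algorithm is a modelling device, not a fit to any artery
atlas; its only contract is to induce territory-structured voxel covariance
and anatomically varying lesion volume.
"""

from __future__ import annotations

import heapq
import json
from dataclasses import dataclass

import numpy as np

from .grid import VoxelGrid, LesionStack

__all__ = [
    "VascularTree",
    "LesionGeneratorConfig",
    "grow_vascular_tree",
    "generate_lesions",
    "lesion_summary",
]

_MODES = ("uniform_single_voxel", "tree_structured", "gaussian_blob")


@dataclass
class LesionGeneratorConfig:
    """Parameters of the cohort generator.

    Tree parameters: ``tree_depth`` bifurcation levels; ``step_length_mm``
    root segment length with ``step_decay`` shrink per level;
    ``angle_jitter_deg`` random deviation of child directions.  Growth
    parameters: ``base_volume_voxels`` log-normal median at depth 0, scaled
    by ``volume_depth_decay**depth``; ``volume_sigma`` log-scale spread;
    ``territory_penalty`` growth-cost multiplier for leaving the seed
    territory (larger -> lesions hug their territory more tightly).
    """

    mode: str = "tree_structured"
    n_lesions: int = 100
    seed: int = 0
    # tree shape
    tree_depth: int = 5
    n_roots: int = 4
    step_length_mm: float = 12.0
    step_decay: float = 0.7
    angle_jitter_deg: float = 35.0
    # lesion growth
    base_volume_voxels: float = 400.0
    volume_depth_decay: float = 0.65
    volume_sigma: float = 0.5
    territory_penalty: float = 8.0
    connectivity: int = 6
    # gaussian_blob mode
    blob_radius_mean: float = 3.0
    blob_radius_sigma: float = 0.3

    def __post_init__(self) -> None:
        if self.mode not in _MODES:
            raise ValueError(f"unknown mode {self.mode!r}; expected one of {_MODES}")
        if self.n_lesions < 1:
            raise ValueError("n_lesions must be >= 1")
        for name in (
            "step_length_mm",
            "step_decay",
            "angle_jitter_deg",
            "base_volume_voxels",
            "volume_depth_decay",
            "volume_sigma",
            "territory_penalty",
            "blob_radius_mean",
            "blob_radius_sigma",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.connectivity not in (6, 26):
            raise ValueError("connectivity must be 6 or 26")


@dataclass
class VascularTree:
    """A stochastic bifurcating tree clipped to the brain mask.

    ``segments`` is a list of ``(start_mm, end_mm, depth, territory_id)``;
    ``territory_id`` equals the segment's own index (each segment perfuses
    the voxels nearer to it than to any other segment).
    ``territory_of_voxel`` assigns every in-mask voxel its nearest segment.
    """

    segments: list[tuple[np.ndarray, np.ndarray, int, int]]
    roots: list[np.ndarray]
    territory_of_voxel: np.ndarray  # int volume, -1 outside the mask

    @property
    def n_segments(self) -> int:
        return len(self.segments)

    def depths(self) -> np.ndarray:
        return np.array([s[2] for s in self.segments])

    def to_json(self, path: str) -> None:
        payload = {
            "roots": [r.tolist() for r in self.roots],
            "segments": [
                {
                    "start_mm": s.tolist(),
                    "end_mm": e.tolist(),
                    "depth": int(d),
                    "territory_id": int(t),
                }
                for s, e, d, t in self.segments
            ],
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)


def _point_segment_distance(points: np.ndarray, a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Euclidean distance from each point to segment ab (all in mm)."""
    ab = b - a
    denom = float(ab @ ab)
    if denom == 0.0:
        return np.linalg.norm(points - a, axis=1)
    t = np.clip((points - a) @ ab / denom, 0.0, 1.0)
    proj = a + t[:, None] * ab
    return np.linalg.norm(points - proj, axis=1)


def grow_vascular_tree(
    grid: VoxelGrid, config: LesionGeneratorConfig, seed: int | None = None
) -> VascularTree:
    """Grow a stochastic bifurcating tree inside the brain mask.

    From each root on the mask boundary, segments split into two children
    with random angular jitter and step length decaying per level, clipped
    to the mask bounding box.  Every in-mask voxel is then assigned the
    territory of its nearest segment.  Deterministic given ``seed``.
    """
    if not grid.brain_mask.any():
        raise ValueError("brain mask is empty")
    rng = np.random.default_rng(config.seed if seed is None else seed)
    mask_idx = grid.mask_indices()
    if len(mask_idx) < config.n_roots:
        raise ValueError("mask has fewer voxels than requested roots")
    mask_mm = grid.voxel_to_world(mask_idx)
    lo, hi = mask_mm.min(axis=0), mask_mm.max(axis=0)
    centre = (lo + hi) / 2.0

    segments: list[tuple[np.ndarray, np.ndarray, int, int]] = []
    roots: list[np.ndarray] = []

    for _ in range(config.n_roots):
        # root enters from a random point on the mask surface heading inward
        start = mask_mm[rng.integers(len(mask_mm))]
        direction = centre - start
        nrm = np.linalg.norm(direction)
        direction = direction / nrm if nrm > 0 else np.array([1.0, 0.0, 0.0])
        roots.append(start)
        frontier = [(start, direction, 0)]
        while frontier:
            pos, d, depth = frontier.pop()
            if depth >= config.tree_depth:
                continue
            step = config.step_length_mm * config.step_decay**depth
            end = np.clip(pos + d * step, lo, hi)
            segments.append((pos, end, depth, len(segments)))
            for _child in range(2):
                nd = _jitter_direction(rng, d, config.angle_jitter_deg)
                frontier.append((end, nd, depth + 1))

    territory = np.full(grid.shape, -1, dtype=np.int32)
    dists = np.empty((len(segments), len(mask_mm)))
    for si, (a, b, _, _) in enumerate(segments):
        dists[si] = _point_segment_distance(mask_mm, a, b)
    nearest = dists.argmin(axis=0).astype(np.int32)
    territory[tuple(mask_idx.T)] = nearest
    return VascularTree(segments=segments, roots=roots, territory_of_voxel=territory)


def _jitter_direction(rng: np.random.Generator, d: np.ndarray, jitter_deg: float) -> np.ndarray:
    """Rotate ``d`` by a random angle up to ``jitter_deg`` about a random axis."""
    angle = np.deg2rad(rng.uniform(0.25, 1.0) * jitter_deg)
    axis = rng.normal(size=3)
    axis /= np.linalg.norm(axis)
    # Rodrigues rotation
    cos, sin = np.cos(angle), np.sin(angle)
    rotated = d * cos + np.cross(axis, d) * sin + axis * (axis @ d) * (1 - cos)
    nrm = np.linalg.norm(rotated)
    return rotated / nrm if nrm > 0 else d


_NEIGHBOURS_6 = np.array(
    [[1, 0, 0], [-1, 0, 0], [0, 1, 0], [0, -1, 0], [0, 0, 1], [0, 0, -1]]
)


def _neighbour_offsets(connectivity: int) -> np.ndarray:
    if connectivity == 6:
        return _NEIGHBOURS_6
    offs = np.array(
        [[i, j, k] for i in (-1, 0, 1) for j in (-1, 0, 1) for k in (-1, 0, 1)]
    )
    return offs[(offs != 0).any(axis=1)]


def generate_lesions(
    grid: VoxelGrid,
    config: LesionGeneratorConfig,
    tree: VascularTree | None = None,
    seed: int | None = None,
) -> LesionStack:
    """Generate a lesion cohort under the configured regime.

    One master seed spawns an independent substream per lesion, so earlier
    lesions are unchanged when ``n_lesions`` grows.  In ``tree_structured``
    mode each lesion seeds on a random tree segment (weighted toward distal
    segments, which are more numerous), grows as a connected region that
    preferentially stays within the seed segment's territory, and targets a
    volume drawn from a log-normal whose median shrinks with branch depth.
    """
    if config.mode == "tree_structured" and tree is None:
        raise ValueError("tree_structured mode requires a VascularTree")
    master = np.random.SeedSequence(config.seed if seed is None else seed)
    substreams = master.spawn(config.n_lesions)
    mask_idx = grid.mask_indices()
    if len(mask_idx) == 0:
        raise ValueError("brain mask is empty")

    masks = np.zeros((config.n_lesions, *grid.shape), dtype=bool)
    truncated = 0
    for i, ss in enumerate(substreams):
        rng = np.random.default_rng(ss)
        if config.mode == "uniform_single_voxel":
            v = mask_idx[rng.integers(len(mask_idx))]
            masks[i, v[0], v[1], v[2]] = True
        elif config.mode == "gaussian_blob":
            masks[i] = _grow_blob(grid, mask_idx, config, rng)
        else:
            masks[i], trunc = _grow_tree_lesion(grid, tree, config, rng)
            truncated += trunc
    if truncated:
        import warnings

        warnings.warn(
            f"{truncated} lesion(s) truncated: target volume exceeded the "
            "reachable connected region",
            stacklevel=2,
        )
    return LesionStack(grid=grid, masks=masks)


def _grow_blob(grid, mask_idx, config, rng) -> np.ndarray:
    centre = mask_idx[rng.integers(len(mask_idx))]
    radius = rng.lognormal(np.log(config.blob_radius_mean), config.blob_radius_sigma)
    grids = np.ogrid[tuple(slice(0, s) for s in grid.shape)]
    d2 = sum((g - c) ** 2 for g, c in zip(grids, centre))
    blob = (d2 <= radius**2) & grid.brain_mask
    if not blob.any():
        blob[tuple(centre)] = True
    return blob


def _grow_tree_lesion(
    grid: VoxelGrid, tree: VascularTree, config: LesionGeneratorConfig, rng
) -> tuple[np.ndarray, bool]:
    depths = tree.depths()
    # distal segments are more numerous targets of occlusion; weight by count
    # is implicit (uniform over segments doubles weight per level)
    seg = int(rng.integers(tree.n_segments))
    depth = int(depths[seg])
    territory = tree.territory_of_voxel
    candidates = np.argwhere(territory == seg)
    if len(candidates) == 0:
        candidates = grid.mask_indices()
    seed_voxel = candidates[rng.integers(len(candidates))]

    median = config.base_volume_voxels * config.volume_depth_decay**depth
    target = max(1, int(round(rng.lognormal(np.log(median), config.volume_sigma))))

    offsets = _neighbour_offsets(config.connectivity)
    shape = grid.shape
    bm = grid.brain_mask
    visited = np.zeros(shape, dtype=bool)
    out = np.zeros(shape, dtype=bool)
    heap: list[tuple[float, int, int, int]] = [(0.0, *map(int, seed_voxel))]
    visited[tuple(seed_voxel)] = True
    n_set = 0
    while heap and n_set < target:
        cost, x, y, z = heapq.heappop(heap)
        out[x, y, z] = True
        n_set += 1
        for dx, dy, dz in offsets:
            nx, ny, nz = x + dx, y + dy, z + dz
            if not (0 <= nx < shape[0] and 0 <= ny < shape[1] and 0 <= nz < shape[2]):
                continue
            if visited[nx, ny, nz] or not bm[nx, ny, nz]:
                continue
            visited[nx, ny, nz] = True
            step = 1.0 if territory[nx, ny, nz] == seg else config.territory_penalty
            heapq.heappush(
                heap, (cost + step * (1.0 + rng.exponential(0.5)), nx, ny, nz)
            )
    return out, n_set < target


def regions_on_tree(
    grid: VoxelGrid,
    tree: VascularTree,
    radius_voxels: float = 3.5,
    depth: int = 1,
    n_regions: int = 2,
    name_prefix: str = "region",
    offset: int = 0,
):
    """Spherical regions centred on the midpoints of proximal tree segments.

    Ground-truth critical regions in real studies (e.g. Brodmann areas 39
    and 44) lie inside commonly infarcted vascular territory; placing
    synthetic regions on proximal branches reproduces that property.
    Segments are taken at the given ``depth``, spread across distinct
    subtrees where possible.
    """
    from .grid import spherical_region

    segs = [s for s in tree.segments if s[2] == depth]
    if len(segs) < n_regions:
        segs = sorted(tree.segments, key=lambda s: s[2])
    if len(segs) < n_regions:
        raise ValueError("tree has too few segments for the requested regions")
    step = max(1, len(segs) // n_regions)
    chosen = [segs[(offset + i * step) % len(segs)] for i in range(n_regions)]
    inv = np.linalg.inv(grid.affine)
    regions = []
    for i, (a, b, _, _) in enumerate(chosen):
        mid_mm = (a + b) / 2.0
        centre = mid_mm @ inv[:3, :3].T + inv[:3, 3]
        regions.append(
            spherical_region(grid, f"{name_prefix}_{i}", centre, radius_voxels)
        )
    return regions


def lesion_summary(stack: LesionStack) -> dict:
    """Per-voxel hit counts plus a histogram of lesion volumes.

    The hit-count volume drives eligibility downstream (voxels hit more than
    ``min_hits`` times are testable).
    """
    if stack.n < 1:
        raise ValueError("empty stack")
    hits = stack.hit_counts()
    vols = stack.volumes_mm3
    counts, edges = np.histogram(vols, bins="auto")
    return {
        "hit_counts": hits,
        "volume_hist_counts": counts,
        "volume_hist_edges": edges,
        "volumes_mm3": vols,
    }
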