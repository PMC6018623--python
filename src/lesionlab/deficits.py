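"""Ground-truth functional-anatomy models mapping lesions to deficit labels.

A deficit criterion is either dependence on a single critical voxel
(deficit iff that voxel is hit) or region logic: damage to at least a given
fraction of the volume of one (OR) or every (AND) region in a list.  A
third operator, XOR_REVERSAL, captures deficit reversal by a second lesion
(deficit iff region A is damaged AND region B intact), the pattern reported
for visuospatial neglect.  Labels are then drawn with probability
``p_deficit_given_criterion`` when the criterion is met and
``p_deficit_baseline`` otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .grid import LesionStack, RegionMask

__all__ = [
    "DeficitModel",
    "DeficitLabels",
    "damage_fraction",
    "criterion_met",
    "assign_deficits",
]

_OPERATORS = ("OR", "AND", "XOR_REVERSAL")


@dataclass
class DeficitModel:
    """Ground-truth rule assigning deficits from lesion geometry.

    ``kind='single_voxel'`` uses ``target_voxel``; ``kind='region_logic'``
    combines per-region damage fractions with ``operator`` at an inclusive
    ``damage_fraction_threshold`` ("at least" semantics: a fraction exactly
    at the threshold meets the criterion).
    """

    kind: str = "region_logic"
    target_voxel: tuple[int, int, int] | None = None
    regions: list[RegionMask] = field(default_factory=list)
    operator: str = "OR"
    damage_fraction_threshold: float = 0.20
    p_deficit_given_criterion: float = 0.9
    p_deficit_baseline: float = 0.0

    def __post_init__(self) -> None:
        if self.kind not in ("single_voxel", "region_logic"):
            raise ValueError(f"unknown model kind {self.kind!r}")
        if self.kind == "single_voxel":
            if self.target_voxel is None:
                raise ValueError("single_voxel model needs a target_voxel")
        else:
            if not self.regions:
                raise ValueError("region_logic model needs at least one region")
            if self.operator not in _OPERATORS:
                raise ValueError(f"operator must be one of {_OPERATORS}")
            if self.operator == "XOR_REVERSAL" and len(self.regions) != 2:
                raise ValueError("XOR_REVERSAL takes exactly two regions")
        if not 0.0 < self.damage_fraction_threshold <= 1.0:
            raise ValueError("damage_fraction_threshold must be in (0, 1]")
        for p in (self.p_deficit_given_criterion, self.p_deficit_baseline):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must be in [0, 1]")

    def validate_against(self, stack: LesionStack) -> None:
        if self.kind == "single_voxel":
            if not stack.grid.brain_mask[tuple(self.target_voxel)]:
                raise ValueError("target voxel is outside the brain mask")
        else:
            for r in self.regions:
                if not r.grid.compatible_with(stack.grid):
                    raise ValueError(f"region {r.name!r} is on a different grid")


@dataclass
class DeficitLabels:
    """Binary outcomes for a cohort, plus the pre-noise criterion flags."""

    labels: np.ndarray
    criterion_met: np.ndarray
    model: DeficitModel
    seed: int

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=bool)
        self.criterion_met = np.asarray(self.criterion_met, dtype=bool)
        if self.labels.shape != self.criterion_met.shape:
            raise ValueError("labels and criterion_met must have equal length")

    @property
    def n(self) -> int:
        return len(self.labels)


def damage_fraction(lesion: np.ndarray, region: RegionMask) -> float:
    """Fraction of the region's volume covered by the lesion,
    |lesion ∩ region| / |region| (voxel counts; identical to mm³ fractions
    on a uniform grid)."""
    if region.volume_voxels == 0:
        raise ValueError("empty region")
    lesion = np.asarray(lesion, dtype=bool)
    if lesion.shape != region.mask.shape:
        raise ValueError("lesion and region are on different grids")
    return float((lesion & region.mask).sum()) / region.volume_voxels


def criterion_met(lesion: np.ndarray, model: DeficitModel) -> bool:
    """Evaluate the deterministic damage criterion for one lesion."""
    lesion = np.asarray(lesion, dtype=bool)
    if model.kind == "single_voxel":
        return bool(lesion[tuple(model.target_voxel)])
    fracs = [damage_fraction(lesion, r) for r in model.regions]
    thr = model.damage_fraction_threshold
    hit = [f >= thr for f in fracs]
    if model.operator == "OR":
        return any(hit)
    if model.operator == "AND":
        return all(hit)
    # XOR_REVERSAL: deficit iff region A damaged and region B intact
    return hit[0] and not hit[1]


def _criteria_vector(stack: LesionStack, model: DeficitModel) -> np.ndarray:
    """Vectorized criterion evaluation over a whole stack."""
    flat = stack.masks.reshape(stack.n, -1)
    if model.kind == "single_voxel":
        i, j, k = model.target_voxel
        return stack.masks[:, i, j, k].astype(bool)
    thr = model.damage_fraction_threshold
    per_region = []
    for r in model.regions:
        rflat = r.mask.reshape(-1)
        overlap = flat[:, rflat].sum(axis=1)
        per_region.append(overlap / r.volume_voxels >= thr)
    hit = np.stack(per_region)
    if model.operator == "OR":
        return hit.any(axis=0)
    if model.operator == "AND":
        return hit.all(axis=0)
    return hit[0] & ~hit[1]


def assign_deficits(stack: LesionStack, model: DeficitModel, seed: int = 0) -> DeficitLabels:
    """Draw Bernoulli deficit labels for every lesion in the stack.

    ``label_i ~ Bernoulli(p_given)`` if the criterion is met, else
    ``Bernoulli(p_baseline)``; deterministic given ``seed``.  In the
    noiseless limit (p_given=1, p_baseline=0) labels equal the criterion.
    """
    model.validate_against(stack)
    crit = _criteria_vector(stack, model)
    rng = np.random.default_rng(seed)
    u = rng.random(stack.n)
    p = np.where(crit, model.p_deficit_given_criterion, model.p_deficit_baseline)
    labels = u < p
    return DeficitLabels(labels=labels, criterion_met=crit, model=model, seed=seed)


def write_labels_tsv(path, stack: LesionStack, labels: DeficitLabels) -> None:
    """Two-column TSV (lesion_id, label), plus the pre-noise criterion flag."""
    with open(path, "w") as fh:
        fh.write("lesion_id\tlabel\tcriterion_met\n")
        for lid, lab, crit in zip(stack.lesion_ids, labels.labels, labels.criterion_met):
            fh.write(f"{lid}\t{int(lab)}\t{int(crit)}\n")
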