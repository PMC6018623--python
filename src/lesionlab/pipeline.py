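"""End-to-end experiment orchestration from a single config.

An :class:`ExperimentConfig` (YAML/JSON on disk) specifies the grid, the
lesion generator, the ground-truth deficit model, and which analysis
stages to run (mislocalisation field, outcome prediction, volume-bias
map).  All randomness derives from one master seed through stage-name
hashing, so toggling a stage never perturbs another stage's draws.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
from dataclasses import dataclass, field, asdict

import numpy as np
import yaml

from . import __version__
from .grid import VoxelGrid, make_grid, spherical_mask, spherical_region, write_mask_volume
from .synth import LesionGeneratorConfig, grow_vascular_tree, generate_lesions
from .deficits import DeficitModel, assign_deficits, write_labels_tsv
from .vlsm import mislocalisation_field
from .predict import make_splits, run_experiment, MethodConfig, plot_roc_summaries
from .volume import volume_odds_map

logger = logging.getLogger("lesionlab")

__all__ = ["ExperimentConfig", "RunManifest", "run", "load_config", "save_config"]


@dataclass
class GridSpec:
    shape: tuple[int, int, int] = (32, 32, 32)
    voxel_size_mm: float = 2.0
    mask: str = "sphere"  # sphere | full
    mask_radius_voxels: float | None = None


@dataclass
class RegionSpec:
    name: str
    centre: tuple[float, float, float]
    radius_voxels: float


@dataclass
class DeficitSpec:
    kind: str = "region_logic"
    target_voxel: tuple[int, int, int] | None = None
    regions: list[RegionSpec] = field(default_factory=list)
    operator: str = "OR"
    damage_fraction_threshold: float = 0.20
    p_deficit_given_criterion: float = 0.9
    p_deficit_baseline: float = 0.0


@dataclass
class MislocSpec:
    enabled: bool = True
    alpha: float = 0.01
    correction: str = "bonferroni"
    min_hits: int = 3
    variant: str = "exact"


@dataclass
class PredictSpec:
    enabled: bool = False
    train_fraction: float = 0.70
    n_iterations: int = 200
    fisher_p_threshold: float = 1e-3
    svm_cost_exponent: float = -14.0


@dataclass
class VolumeBiasSpec:
    enabled: bool = False
    min_hits: int = 3
    prior_scale: float = 2.5


@dataclass
class ExperimentConfig:
    """Everything needed to reproduce a full synthetic experiment."""

    grid: GridSpec = field(default_factory=GridSpec)
    lesions: LesionGeneratorConfig = field(default_factory=LesionGeneratorConfig)
    deficit: DeficitSpec = field(default_factory=DeficitSpec)
    misloc: MislocSpec = field(default_factory=MislocSpec)
    predict: PredictSpec = field(default_factory=PredictSpec)
    volume_bias: VolumeBiasSpec = field(default_factory=VolumeBiasSpec)
    seed: int = 0
    out_dir: str = "lesionlab_out"
    write_nifti: bool = False  # per-lesion NIfTI output is opt-in (bulky)


@dataclass
class RunManifest:
    config_hash: str
    software_version: str
    seeds: dict
    outputs: dict
    failures: list

    def save(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1)


def _to_plain(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _to_plain(v) for k, v in asdict(obj).items()}
    if isinstance(obj, (list, tuple)):
        return [_to_plain(v) for v in obj]
    if isinstance(obj, dict):
        return {k: _to_plain(v) for k, v in obj.items()}
    if isinstance(obj, np.generic):
        return obj.item()
    return obj


def save_config(config: ExperimentConfig, path: str) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(_to_plain(config), fh, sort_keys=False)


def _build(cls, data):
    kwargs = {}
    for f in dataclasses.fields(cls):
        if f.name not in data:
            continue
        v = data[f.name]
        sub = {
            "grid": GridSpec,
            "lesions": LesionGeneratorConfig,
            "deficit": DeficitSpec,
            "misloc": MislocSpec,
            "predict": PredictSpec,
            "volume_bias": VolumeBiasSpec,
        }.get(f.name)
        if sub is not None and isinstance(v, dict):
            v = _build(sub, v)
        if f.name == "regions" and isinstance(v, list):
            v = [RegionSpec(**r) if isinstance(r, dict) else r for r in v]
        if isinstance(v, list) and f.name in ("shape", "target_voxel", "centre"):
            v = tuple(v)
        kwargs[f.name] = v
    return cls(**kwargs)


def load_config(path: str) -> ExperimentConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    return _build(ExperimentConfig, data or {})


def config_hash(config: ExperimentConfig) -> str:
    blob = json.dumps(_to_plain(config), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def stage_seed(master_seed: int, stage: str) -> int:
    """Independent per-stage seed: stable hash of (master seed, stage name),
    kept below 2^31."""
    digest = hashlib.sha256(f"{master_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def build_grid(spec: GridSpec) -> VoxelGrid:
    if spec.mask == "sphere":
        radius = spec.mask_radius_voxels or (min(spec.shape) / 2.0 - 1.0)
        mask = spherical_mask(spec.shape, radius)
    elif spec.mask == "full":
        mask = None
    else:
        raise ValueError(f"unknown mask spec {spec.mask!r}")
    return make_grid(spec.shape, spec.voxel_size_mm, brain_mask=mask)


def build_deficit_model(spec: DeficitSpec, grid: VoxelGrid) -> DeficitModel:
    regions = [
        spherical_region(grid, r.name, r.centre, r.radius_voxels)
        for r in spec.regions
    ]
    return DeficitModel(
        kind=spec.kind,
        target_voxel=spec.target_voxel,
        regions=regions,
        operator=spec.operator,
        damage_fraction_threshold=spec.damage_fraction_threshold,
        p_deficit_given_criterion=spec.p_deficit_given_criterion,
        p_deficit_baseline=spec.p_deficit_baseline,
    )


def run(config: ExperimentConfig) -> RunManifest:
    """Execute enabled stages in dependency order and write a manifest.

    Stage order: generate cohort -> assign labels -> {misloc, predict,
    volume_bias}.  A stage failure halts its dependents; the manifest
    records the partial state.
    """
    os.makedirs(config.out_dir, exist_ok=True)
    seeds = {
        s: stage_seed(config.seed, s)
        for s in ("tree", "lesions", "labels", "splits")
    }
    outputs: dict[str, str] = {}
    failures: list[str] = []

    grid = build_grid(config.grid)
    tree = None
    if config.lesions.mode == "tree_structured":
        logger.info("growing vascular tree")
        tree = grow_vascular_tree(grid, config.lesions, seed=seeds["tree"])
        tree_path = os.path.join(config.out_dir, "vascular_tree.json")
        tree.to_json(tree_path)
        outputs["tree"] = tree_path
    logger.info("generating %d lesions (%s)", config.lesions.n_lesions, config.lesions.mode)
    stack = generate_lesions(grid, config.lesions, tree=tree, seed=seeds["lesions"])
    if config.write_nifti:
        cohort_dir = os.path.join(config.out_dir, "lesions")
        os.makedirs(cohort_dir, exist_ok=True)
        paths = []
        for lid, mask in zip(stack.lesion_ids, stack.masks):
            p = os.path.join(cohort_dir, f"{lid}.nii.gz")
            write_mask_volume(p, mask, grid)
            paths.append(p)
        from .grid import write_manifest as _wm

        manifest_path = os.path.join(config.out_dir, "cohort_manifest.txt")
        _wm(manifest_path, paths)
        outputs["cohort_manifest"] = manifest_path

    model = None
    labels = None
    needs_labels = config.predict.enabled or config.deficit.kind == "single_voxel"
    if config.deficit.regions or config.deficit.target_voxel is not None:
        model = build_deficit_model(config.deficit, grid)
        labels = assign_deficits(stack, model, seed=seeds["labels"])
        lab_path = os.path.join(config.out_dir, "labels.tsv")
        write_labels_tsv(lab_path, stack, labels)
        outputs["labels"] = lab_path
    elif needs_labels:
        failures.append("labels: no deficit model configured")

    if config.misloc.enabled:
        logger.info("computing mislocalisation field")
        try:
            fld = mislocalisation_field(
                stack,
                alpha=config.misloc.alpha,
                correction=config.misloc.correction,
                min_hits=config.misloc.min_hits,
                variant=config.misloc.variant,
            )
            misloc_tsv = os.path.join(config.out_dir, "mislocalisation.tsv")
            fld.to_dataframe().to_csv(misloc_tsv, sep="\t", index=False)
            outputs["misloc_tsv"] = misloc_tsv
            import nibabel as nib

            nib.save(
                nib.Nifti1Image(fld.magnitude_mm.astype(np.float32), grid.affine),
                os.path.join(config.out_dir, "misloc_magnitude_mm.nii.gz"),
            )
            nib.save(
                nib.Nifti1Image(fld.vector_mm.astype(np.float32), grid.affine),
                os.path.join(config.out_dir, "misloc_vector_mm.nii.gz"),
            )
            outputs["misloc_magnitude"] = os.path.join(
                config.out_dir, "misloc_magnitude_mm.nii.gz"
            )
            outputs["misloc_vectors"] = os.path.join(
                config.out_dir, "misloc_vector_mm.nii.gz"
            )
        except Exception as exc:  # pragma: no cover - surfaced in manifest
            failures.append(f"misloc: {exc}")

    if config.predict.enabled and labels is not None:
        logger.info("running prediction experiment (%d iterations)", config.predict.n_iterations)
        try:
            plan = make_splits(
                stack.n,
                config.predict.train_fraction,
                config.predict.n_iterations,
                seed=seeds["splits"],
                labels=labels.labels,
            )
            res = run_experiment(
                stack,
                labels,
                plan,
                MethodConfig(
                    fisher_p_threshold=config.predict.fisher_p_threshold,
                    svm_cost_exponent=config.predict.svm_cost_exponent,
                ),
                collect_scores=True,
            )
            scores_tsv = os.path.join(config.out_dir, "prediction_scores.tsv")
            res["scores"].to_csv(scores_tsv, sep="\t", index=False)
            outputs["prediction_scores"] = scores_tsv
            summary = {
                m: {
                    "mean_auc": res[m].mean_auc,
                    "auc_ci": list(res[m].auc_ci),
                    "n_iterations": res[m].n_iterations,
                }
                for m in ("fisher", "svm")
            }
            roc_json = os.path.join(config.out_dir, "roc_summary.json")
            with open(roc_json, "w") as fh:
                json.dump(summary, fh, indent=1)
            outputs["roc_summary"] = roc_json
            roc_png = os.path.join(config.out_dir, "roc_curves.png")
            plot_roc_summaries({m: res[m] for m in ("fisher", "svm")}, roc_png)
            outputs["roc_plot"] = roc_png
        except Exception as exc:  # pragma: no cover
            failures.append(f"predict: {exc}")
    elif config.predict.enabled:
        failures.append("predict: skipped (no labels)")

    if config.volume_bias.enabled:
        logger.info("computing volume-bias odds map")
        try:
            omap = volume_odds_map(
                stack,
                min_hits=config.volume_bias.min_hits,
                prior_scale=config.volume_bias.prior_scale,
            )
            import nibabel as nib

            for name, vol in (
                ("or_hat", omap.or_hat),
                ("or_ci_low", omap.ci_low),
                ("or_ci_high", omap.ci_high),
            ):
                p = os.path.join(config.out_dir, f"volume_{name}.nii.gz")
                nib.save(nib.Nifti1Image(vol.astype(np.float32), grid.affine), p)
                outputs[f"volume_{name}"] = p
        except Exception as exc:  # pragma: no cover
            failures.append(f"volume_bias: {exc}")

    cfg_path = os.path.join(config.out_dir, "config.yaml")
    save_config(config, cfg_path)
    outputs["config"] = cfg_path
    manifest = RunManifest(
        config_hash=config_hash(config),
        software_version=__version__,
        seeds=seeds,
        outputs=outputs,
        failures=failures,
    )
    manifest.save(os.path.join(config.out_dir, "manifest.json"))
    return manifest
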