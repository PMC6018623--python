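"""High-dimensional multivariate lesion-deficit model: a linear SVM over
vectorized binary lesion masks.

Every voxel in the feature mask is one binary feature (damaged / intact);
the soft-margin linear classifier jointly weighs all of them, which is what
lets it separate truly critical voxels from parasitic ones that merely
co-occur with damage.  The cost parameter follows the grid-search
convention C = base**cost_exponent (base 2 by default): a cost exponent
of -14 means C = 2^-14.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
from sklearn.svm import SVC

from .grid import VoxelGrid, LesionStack
from .deficits import DeficitLabels

__all__ = ["WeightMap", "fit_linear_svm", "svm_score"]


@dataclass
class WeightMap:
    """Per-voxel linear-SVM weights plus bias over a feature mask."""

    grid: VoxelGrid
    weights: np.ndarray  # volume, 0 outside feature_mask
    bias: float
    cost_exponent: float
    feature_mask: np.ndarray
    cost_base: float = 2.0

    def __post_init__(self) -> None:
        if not np.isfinite(self.weights[self.feature_mask]).all():
            raise ValueError("non-finite weights")
        if (self.weights[~self.feature_mask] != 0).any():
            raise ValueError("weights must be zero outside the feature mask")

    @property
    def cost(self) -> float:
        return float(self.cost_base**self.cost_exponent)

    def save(self, nifti_path: str, sidecar_path: str) -> None:
        import nibabel as nib

        nib.save(nib.Nifti1Image(self.weights.astype(np.float32), self.grid.affine), nifti_path)
        with open(sidecar_path, "w") as fh:
            json.dump(
                {
                    "bias": self.bias,
                    "cost_exponent": self.cost_exponent,
                    "cost_base": self.cost_base,
                    "n_features": int(self.feature_mask.sum()),
                },
                fh,
                indent=1,
            )


def fit_linear_svm(
    stack: LesionStack,
    labels: DeficitLabels | np.ndarray,
    cost_exponent: float = -14.0,
    cost_base: float = 2.0,
    feature_mask: np.ndarray | None = None,
    tol: float = 1e-6,
    max_iter: int = 200_000,
) -> WeightMap:
    """Train a soft-margin linear SVM on the N x V binary damage matrix.

    Features are raw binary voxels with no scaling or smoothing, restricted
    by default to voxels hit at least once in the training stack (zero
    columns carry no information and are dropped for speed; their weight is
    exactly zero either way).  The problem is convex, so the fit is
    deterministic given the data.  Orientation: positive scores indicate
    deficit.
    """
    y = labels.labels if isinstance(labels, DeficitLabels) else np.asarray(labels, bool)
    if len(y) != stack.n:
        raise ValueError("labels and stack have different lengths")
    if y.all() or not y.any():
        raise ValueError("both classes must be present to fit the classifier")
    if feature_mask is None:
        feature_mask = (stack.hit_counts() >= 1) & stack.grid.brain_mask
    if not feature_mask.any():
        raise ValueError("feature mask is empty")
    idx = np.argwhere(feature_mask)
    X = stack.design_matrix(idx).astype(np.float64)
    if not X.any():
        raise ValueError("all features are zero")
    clf = SVC(
        kernel="linear",
        C=float(cost_base) ** float(cost_exponent),
        tol=tol,
        max_iter=max_iter,
        shrinking=False,
    )
    clf.fit(X, y.astype(int))
    if clf.fit_status_ != 0:
        raise RuntimeError("SVM solver did not converge within max_iter")
    w = np.zeros(stack.grid.shape)
    w[tuple(idx.T)] = clf.coef_.ravel()
    return WeightMap(
        grid=stack.grid,
        weights=w,
        bias=float(clf.intercept_[0]),
        cost_exponent=float(cost_exponent),
        feature_mask=feature_mask,
        cost_base=float(cost_base),
    )


def svm_score(weight_map: WeightMap, lesion: np.ndarray) -> float:
    """Decision score for one lesion: sum of weights over its damaged
    voxels, plus the bias.  Voxels outside the feature mask contribute 0."""
    lesion = np.asarray(lesion, dtype=bool)
    if lesion.shape != weight_map.grid.shape:
        raise ValueError("lesion is on a different grid")
    return float(weight_map.weights[lesion].sum() + weight_map.bias)


def svm_scores(weight_map: WeightMap, stack: LesionStack) -> np.ndarray:
    """Vectorized :func:`svm_score` over a stack."""
    flat_w = weight_map.weights.reshape(-1)
    return stack.masks.reshape(stack.n, -1) @ flat_w + weight_map.bias
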