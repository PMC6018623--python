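"""Mass-univariate voxel-wise lesion-deficit mapping and its spatial bias.

The classical VLSM procedure: at every voxel hit more than ``min_hits``
times, cross-tabulate damaged/intact against deficit/no-deficit and test
the association with Fisher's exact test (two-sided, by summing
hypergeometric probabilities of all tables with the observed margins that
are no more probable than the observed one).  Significant voxels under a
Bonferroni-corrected threshold form a cluster whose unweighted centre of
mass is the method's localisation.

The mislocalisation field repeats this with a noiseless single-voxel
ground truth planted at *every* eligible voxel in turn: lesions are
labelled by whether they cover the target voxel, the cluster centroid is
computed, and the error vector runs from the target's true mm location to
that centroid.  Under spatially random lesions the error is identically
zero; under structured lesions the parasitic voxels collaterally damaged
with the target drag the centroid away, and the field of error vectors
traces the lesion architecture.

The exact test is implemented here as a vectorized hypergeometric
enumeration with memoised per-margin tables, because the field requires on
the order of V² tests (every target voxel against every tested voxel).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy.special import gammaln
from scipy.stats import chi2 as _chi2

from .grid import VoxelGrid, LesionStack
from .deficits import DeficitLabels

__all__ = [
    "PValueField",
    "SignificanceCluster",
    "MislocalisationField",
    "fisher_exact",
    "vlsm_map",
    "significant_cluster",
    "mislocalisation_field",
]


# ---------------------------------------------------------------------------
# Fisher's exact test, vectorized


def _log_comb(n, k):
    return gammaln(n + 1.0) - gammaln(k + 1.0) - gammaln(n - k + 1.0)


@lru_cache(maxsize=500_000)
def _pval_table(N: int, K: int, n: int) -> tuple[int, tuple[float, ...]]:
    """Two-sided exact p-values for all feasible tables with margins
    (N, K, n): returns (kmin, p[a - kmin]) for a in [kmin, kmax].

    p(a) sums hypergeometric probabilities of every table no more probable
    than the observed one (with a small relative tolerance against
    floating-point ties), the same convention as the classical two-sided
    Fisher test.
    """
    if K > n:  # pmf is symmetric in the margins; normalise the cache key
        kmin, tab = _pval_table(N, n, K)
        return kmin, tab
    kmin = max(0, K + n - N)
    kmax = min(K, n)
    k = np.arange(kmin, kmax + 1)
    logpmf = _log_comb(K, k) + _log_comb(N - K, n - k) - _log_comb(N, n)
    pmf = np.exp(logpmf)
    order = np.argsort(pmf, kind="stable")
    cum = np.cumsum(pmf[order])
    idx = np.searchsorted(pmf[order], pmf * (1.0 + 1e-7), side="right")
    p = np.minimum(cum[np.clip(idx - 1, 0, len(cum) - 1)], 1.0)
    p[idx == 0] = 0.0  # unreachable in practice
    return kmin, tuple(p)


def fisher_exact(a: int, b: int, c: int, d: int, variant: str = "exact") -> float:
    """Two-sided p for the 2x2 table [[a, b], [c, d]].

    Rows: damaged / intact at the voxel; columns: deficit / no deficit.
    Degenerate margins return p = 1.  ``variant='asymptotic'`` uses the
    chi-squared approximation with Yates continuity correction.
    """
    for x in (a, b, c, d):
        if x < 0 or x != int(x):
            raise ValueError("cell counts must be nonnegative integers")
    a, b, c, d = int(a), int(b), int(c), int(d)
    N = a + b + c + d
    if N < 1:
        raise ValueError("the table must contain at least one observation")
    n, K = a + b, a + c
    if variant == "asymptotic":
        return _yates_chi2_p(
            np.array([a]), np.array([n]), np.array([K]), N
        )[0]
    kmin, tab = _pval_table(N, K, n)
    return float(tab[a - kmin])


def _yates_chi2_p(a, n, K, N):
    """Vectorized chi-squared p with continuity correction for tables
    parameterised by (a, row margin n, column margin K, total N)."""
    a = np.asarray(a, dtype=float)
    n = np.asarray(n, dtype=float)
    K = np.asarray(K, dtype=float)
    b, c = n - a, K - a
    d = N - n - K + a
    denom = n * (N - n) * K * (N - K)
    with np.errstate(divide="ignore", invalid="ignore"):
        stat = N * np.maximum(np.abs(a * d - b * c) - N / 2.0, 0.0) ** 2 / denom
    p = np.where(denom > 0, _chi2.sf(stat, 1), 1.0)
    return np.minimum(p, 1.0)


def _pvalues_grouped(a: np.ndarray, n: np.ndarray, K: int, N: int) -> np.ndarray:
    """Exact two-sided p for many tables sharing one column margin K."""
    p = np.empty(len(a))
    for nv in np.unique(n):
        sel = n == nv
        kmin, tab = _pval_table(N, int(K), int(nv))
        p[sel] = np.asarray(tab)[a[sel] - kmin]
    return p


def _pairwise_pvalues(H: np.ndarray, h: np.ndarray, N: int, variant: str) -> np.ndarray:
    """Exact two-sided p for every (target, voxel) pair.

    ``H[t, v]`` is the number of lesions hitting both voxels, ``h`` the
    per-voxel hit counts; the table at (t, v) has a=H[t,v], margins
    (h[t], h[v], N).  Tables are memoised per unique margin pair and the
    lookup is fully vectorized.
    """
    if variant == "asymptotic":
        return _yates_chi2_p(H, h[None, :], h[:, None], N)
    uh, ranks = np.unique(h, return_inverse=True)
    nu = len(uh)
    flat: list[np.ndarray] = []
    offsets = np.empty(nu * nu, dtype=np.int64)
    pos = 0
    for i, K in enumerate(uh):
        for j, n in enumerate(uh):
            kmin, tab = _pval_table(N, int(K), int(n))
            offsets[i * nu + j] = pos - kmin
            flat.append(np.asarray(tab))
            pos += len(tab)
    flat_tab = np.concatenate(flat)
    pid = ranks[:, None] * nu + ranks[None, :]
    return flat_tab[offsets[pid] + H]


# ---------------------------------------------------------------------------
# P-value fields and clusters


@dataclass
class PValueField:
    """Per-voxel p-values over the grid; NaN where untested."""

    grid: VoxelGrid
    p: np.ndarray
    tested_mask: np.ndarray
    test_name: str = "fisher_exact"
    sidedness: str = "two"
    variant: str = "exact"

    def __post_init__(self) -> None:
        tested = self.p[self.tested_mask]
        if np.isnan(tested).any() or (tested < 0).any() or (tested > 1).any():
            raise ValueError("tested p-values must lie in [0, 1]")
        if not np.isnan(self.p[~self.tested_mask]).all():
            raise ValueError("untested voxels must be NaN")

    @property
    def n_tested(self) -> int:
        return int(self.tested_mask.sum())

    def tested_pvalues(self) -> np.ndarray:
        return self.p[self.tested_mask]

    def save(self, path: str) -> None:
        """Write the p-value volume as NIfTI (NaN where untested)."""
        import nibabel as nib

        nib.save(
            nib.Nifti1Image(self.p.astype(np.float32), self.grid.affine), path
        )


@dataclass
class SignificanceCluster:
    """Supra-threshold voxels and their unweighted centre of mass (mm)."""

    voxels: np.ndarray  # (k, 3) indices
    threshold: float
    centroid_mm: np.ndarray | None

    @property
    def n_voxels(self) -> int:
        return len(self.voxels)

    @property
    def is_empty(self) -> bool:
        return self.n_voxels == 0


def vlsm_map(
    stack: LesionStack,
    labels: DeficitLabels | np.ndarray,
    min_hits: int = 3,
    variant: str = "exact",
    smooth_fwhm_mm: float | None = None,
    volume_covariate: bool = False,
) -> PValueField:
    """Voxel-wise Fisher-exact lesion-deficit map.

    Tests every voxel hit strictly more than ``min_hits`` times; the 2x2
    table at voxel v is damage-at-v x deficit.

    ``smooth_fwhm_mm`` and ``volume_covariate`` are deliberately labelled
    *distortion* options for didactic experiments — neither belongs in the
    default procedure.  Smoothing Gaussian-filters each lesion mask and
    re-binarises at 0.5 before testing.  The volume covariate replaces the
    exact test with a per-voxel logistic likelihood-ratio test of the
    damage indicator with standardized log lesion volume entered as a
    nuisance regressor; because lesion volume itself varies systematically
    with anatomy, this "correction" distorts the map rather than cleaning
    it (which is the point of offering it).
    """
    y = labels.labels if isinstance(labels, DeficitLabels) else np.asarray(labels, bool)
    if len(y) != stack.n:
        raise ValueError("labels and stack have different lengths")
    masks = stack.masks
    if smooth_fwhm_mm:
        from scipy.ndimage import gaussian_filter

        sigma = smooth_fwhm_mm / (2.3548 * stack.grid.voxel_size)
        masks = np.stack(
            [gaussian_filter(m.astype(float), sigma) > 0.5 for m in masks]
        )
    hits = masks.sum(axis=0)
    tested = (hits > min_hits) & stack.grid.brain_mask
    p_vol = np.full(stack.grid.shape, np.nan)
    if y.all() or not y.any():
        warnings.warn("labels have no contrast; all tested p-values are 1", stacklevel=2)
    if tested.any():
        idx = np.argwhere(tested)
        i, j, k = idx.T
        M = masks[:, i, j, k]
        if volume_covariate:
            p = _logistic_lrt_pvalues(M, y, stack.volumes_mm3)
        elif variant == "asymptotic":
            a = M[y].sum(axis=0).astype(np.int64)
            n = M.sum(axis=0).astype(np.int64)
            K = int(y.sum())
            p = _yates_chi2_p(a, n, np.full_like(n, K), stack.n)
        else:
            a = M[y].sum(axis=0).astype(np.int64)
            n = M.sum(axis=0).astype(np.int64)
            K = int(y.sum())
            p = _pvalues_grouped(a, n, K, stack.n)
        p_vol[tested] = p
    return PValueField(
        grid=stack.grid,
        p=p_vol,
        tested_mask=tested,
        test_name="logistic_lrt_volume" if volume_covariate else "fisher_exact",
        variant=variant,
    )


def _logistic_lrt_pvalues(M: np.ndarray, y: np.ndarray, volumes: np.ndarray) -> np.ndarray:
    """Likelihood-ratio p for the damage term in deficit ~ damage + log
    volume, fit per voxel by unpenalized logistic regression."""
    from sklearn.linear_model import LogisticRegression

    logv = np.log(np.maximum(volumes, 1e-12))
    z = (logv - logv.mean()) / (logv.std() or 1.0)
    yi = y.astype(int)

    def loglik(X):
        clf = LogisticRegression(C=np.inf, max_iter=2000, tol=1e-8)
        clf.fit(X, yi)
        eta = X @ clf.coef_.ravel() + clf.intercept_[0]
        return -(np.logaddexp(0.0, eta) - yi * eta).sum()

    ll_null = loglik(z[:, None])
    p = np.empty(M.shape[1])
    for v in range(M.shape[1]):
        X = np.column_stack([M[:, v].astype(float), z])
        lr = max(2.0 * (loglik(X) - ll_null), 0.0)
        p[v] = _chi2.sf(lr, 1)
    return p


def significant_cluster(
    field: PValueField, alpha: float = 0.01, correction: str = "bonferroni"
) -> SignificanceCluster:
    """Threshold a p-value field and return the supra-threshold cluster.

    Bonferroni divides alpha by the number of *tested* voxels (untested
    voxels raise no hypotheses).  The centroid is the unweighted mean of
    the member voxels' world coordinates; an empty cluster is flagged with
    an undefined centroid.
    """
    if field.n_tested == 0:
        raise ValueError("field has no tested voxels")
    if correction == "bonferroni":
        cutoff = alpha / field.n_tested
    elif correction == "none":
        cutoff = alpha
    else:
        raise ValueError(f"unknown correction {correction!r}")
    sig = np.zeros_like(field.tested_mask)
    sig[field.tested_mask] = field.p[field.tested_mask] < cutoff
    voxels = np.argwhere(sig)
    centroid = (
        field.grid.voxel_to_world(voxels).mean(axis=0) if len(voxels) else None
    )
    return SignificanceCluster(voxels=voxels, threshold=cutoff, centroid_mm=centroid)


# ---------------------------------------------------------------------------
# The mislocalisation field


@dataclass
class MislocalisationField:
    """Per-target-voxel localisation error of the mass-univariate method.

    For every eligible voxel t (hit more than ``min_hits`` times), a
    noiseless single-voxel deficit is planted at t and the vector from t's
    world position to the significant-cluster centroid is recorded.
    """

    grid: VoxelGrid
    eligible_mask: np.ndarray
    empty_cluster_mask: np.ndarray
    vector_mm: np.ndarray  # (nx, ny, nz, 3), NaN where undefined
    magnitude_mm: np.ndarray  # (nx, ny, nz), NaN where undefined
    cluster_sizes: np.ndarray  # int volume, 0 where ineligible
    alpha: float
    correction: str
    min_hits: int

    @property
    def n_eligible(self) -> int:
        return int(self.eligible_mask.sum())

    def defined_mask(self) -> np.ndarray:
        return self.eligible_mask & ~self.empty_cluster_mask

    def mean_magnitude_mm(self) -> float:
        """Mean error magnitude over eligible voxels with a non-empty cluster."""
        m = self.magnitude_mm[self.defined_mask()]
        return float(m.mean()) if len(m) else float("nan")

    def to_dataframe(self) -> pd.DataFrame:
        rows = np.argwhere(self.eligible_mask)
        world = self.grid.voxel_to_world(rows)
        vec = self.vector_mm[tuple(rows.T)]
        mag = self.magnitude_mm[tuple(rows.T)]
        size = self.cluster_sizes[tuple(rows.T)]
        empty = self.empty_cluster_mask[tuple(rows.T)]
        return pd.DataFrame(
            {
                "i": rows[:, 0],
                "j": rows[:, 1],
                "k": rows[:, 2],
                "x_mm": world[:, 0],
                "y_mm": world[:, 1],
                "z_mm": world[:, 2],
                "dx_mm": vec[:, 0],
                "dy_mm": vec[:, 1],
                "dz_mm": vec[:, 2],
                "magnitude_mm": mag,
                "cluster_size": size,
                "empty_cluster": empty.astype(int),
            }
        )


def mislocalisation_field(
    stack: LesionStack,
    alpha: float = 0.01,
    correction: str = "bonferroni",
    min_hits: int = 3,
    variant: str = "exact",
) -> MislocalisationField:
    """Compute the localisation-error vector field of the VLSM procedure.

    For each eligible target voxel t, lesions are labelled "affected" iff
    they cover t (the noiseless single-voxel ground truth), the voxel-wise
    Fisher-exact map is computed over all eligible voxels, thresholded at
    the Bonferroni-corrected ``alpha``, and the error vector is the cluster
    centroid minus t's world position.

    All targets share the same tested-voxel set (eligibility depends only
    on hit counts), so the computation reduces to the pairwise lesion
    co-occurrence matrix, from which every 2x2 table's cell counts follow.
    """
    hits = stack.hit_counts()
    eligible = (hits > min_hits) & stack.grid.brain_mask
    idx = np.argwhere(eligible)
    V = len(idx)
    shape = stack.grid.shape
    vec = np.full((*shape, 3), np.nan)
    mag = np.full(shape, np.nan)
    sizes = np.zeros(shape, dtype=np.int64)
    empty = np.zeros(shape, dtype=bool)
    if V == 0:
        return MislocalisationField(
            grid=stack.grid,
            eligible_mask=eligible,
            empty_cluster_mask=empty,
            vector_mm=vec,
            magnitude_mm=mag,
            cluster_sizes=sizes,
            alpha=alpha,
            correction=correction,
            min_hits=min_hits,
        )
    from scipy import sparse

    M = sparse.csr_matrix(stack.design_matrix(idx).astype(np.int64))
    H = np.asarray((M.T @ M).todense())  # pairwise co-occurrence counts
    h = np.diag(H).copy()
    P = _pairwise_pvalues(H, h, stack.n, variant)
    cutoff = alpha / V if correction == "bonferroni" else alpha
    S = P < cutoff  # S[t, v]: voxel v significant under target t's labels
    n_sig = S.sum(axis=1)
    W = stack.grid.voxel_to_world(idx)
    with np.errstate(invalid="ignore"):
        centroids = (S.astype(np.float64) @ W) / n_sig[:, None]
    vecs = centroids - W
    mags = np.linalg.norm(vecs, axis=1)
    t_i, t_j, t_k = idx.T
    empty_t = n_sig == 0
    empty[t_i, t_j, t_k] = empty_t
    sizes[t_i, t_j, t_k] = n_sig
    ok = ~empty_t
    vec[t_i[ok], t_j[ok], t_k[ok]] = vecs[ok]
    mag[t_i[ok], t_j[ok], t_k[ok]] = mags[ok]
    return MislocalisationField(
        grid=stack.grid,
        eligible_mask=eligible,
        empty_cluster_mask=empty,
        vector_mm=vec,
        magnitude_mm=mag,
        cluster_sizes=sizes,
        alpha=alpha,
        correction=correction,
        min_hits=min_hits,
    )
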