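"""Fisher's exact test, VLSM maps, clusters, and the mislocalisation field."""

from math import comb

import numpy as np
import pytest
import scipy.stats

import lesionlab as ll
from lesionlab.vlsm import _pairwise_pvalues


def enumeration_oracle(a, b, c, d):
    """Two-sided Fisher p by exact integer hypergeometric enumeration."""
    N, n, K = a + b + c + d, a + b, a + c
    kmin, kmax = max(0, K + n - N), min(K, n)
    num = {k: comb(K, k) * comb(N - K, n - k) for k in range(kmin, kmax + 1)}
    return sum(v for v in num.values() if v <= num[a]) / comb(N, n)


class TestFisherExact:
    def test_printed_examples(self):
        assert ll.fisher_exact(5, 0, 0, 5) == pytest.approx(2 / 252, abs=1e-12)
        assert ll.fisher_exact(2, 2, 2, 2) == pytest.approx(1.0, abs=1e-12)
        assert ll.fisher_exact(0, 0, 3, 3) == pytest.approx(1.0, abs=1e-12)

    @pytest.mark.parametrize("seed", range(3))
    def test_matches_enumeration_and_scipy(self, seed):
        rng = np.random.default_rng(seed)
        for _ in range(200):
            a, b, c, d = rng.integers(0, 12, size=4)
            if a + b + c + d == 0:
                continue
            p = ll.fisher_exact(a, b, c, d)
            assert p == pytest.approx(enumeration_oracle(a, b, c, d), abs=1e-12)
            p_scipy = scipy.stats.fisher_exact([[a, b], [c, d]])[1]
            assert p == pytest.approx(p_scipy, abs=1e-9)

    def test_asymptotic_matches_chi2_contingency(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            a, b, c, d = rng.integers(1, 20, size=4)
            p = ll.fisher_exact(a, b, c, d, variant="asymptotic")
            expected = scipy.stats.chi2_contingency(
                [[a, b], [c, d]], correction=True
            ).pvalue
            assert p == pytest.approx(expected, abs=1e-9)

    def test_invalid_counts(self):
        with pytest.raises(ValueError):
            ll.fisher_exact(-1, 0, 0, 1)
        with pytest.raises(ValueError):
            ll.fisher_exact(0, 0, 0, 0)

    def test_pairwise_engine_matches_scalar(self):
        """The vectorized pairwise table lookup agrees with the scalar
        test on every pair of a random co-occurrence matrix."""
        rng = np.random.default_rng(1)
        N = 40
        M = rng.random((N, 6)) < rng.uniform(0.2, 0.7, size=6)
        H = (M.astype(int).T @ M.astype(int))
        h = np.diag(H)
        P = _pairwise_pvalues(H, h, N, variant="exact")
        for t in range(6):
            for v in range(6):
                a = H[t, v]
                b = h[v] - a
                c = h[t] - a
                d = N - a - b - c
                assert P[t, v] == pytest.approx(
                    ll.fisher_exact(a, b, c, d), abs=1e-12
                )


def build_stack(grid, voxel_lists):
    masks = np.zeros((len(voxel_lists), *grid.shape), bool)
    for i, voxels in enumerate(voxel_lists):
        for v in voxels:
            masks[i][v] = True
    return ll.LesionStack(grid=grid, masks=masks)


class TestVlsmMap:
    def test_perfectly_associated_voxel_has_smallest_p(self):
        grid = ll.make_grid((6, 6, 6), 1.0)
        target = (2, 2, 2)
        other = (4, 4, 4)
        lesions = [[target, other] for _ in range(10)] + [[other] for _ in range(10)]
        stack = build_stack(grid, lesions)
        y = np.array([True] * 10 + [False] * 10)
        field = ll.vlsm_map(stack, y)
        p = field.p
        assert field.tested_mask[target] and field.tested_mask[other]
        assert p[target] == np.nanmin(p)
        assert p[target] < 1e-4 < p[other]

    def test_min_hits_strictly_greater(self):
        grid = ll.make_grid((6, 6, 6), 1.0)
        hit3 = (1, 1, 1)
        hit4 = (3, 3, 3)
        filler = (5, 5, 5)
        lesions = (
            [[hit3, filler]] * 3 + [[hit4, filler]] * 4 + [[filler]] * 5
        )
        stack = build_stack(grid, lesions)
        y = np.zeros(12, bool)
        y[:6] = True
        field = ll.vlsm_map(stack, y, min_hits=3)
        assert not field.tested_mask[hit3]  # hit exactly 3 times: excluded
        assert field.tested_mask[hit4]  # hit 4 times: tested
        assert np.isnan(field.p[hit3])

    def test_no_contrast_warns_p_one(self):
        grid = ll.make_grid((5, 5, 5), 1.0)
        stack = build_stack(grid, [[(2, 2, 2)]] * 6)
        with pytest.warns(UserWarning, match="no contrast"):
            field = ll.vlsm_map(stack, np.ones(6, bool))
        assert np.allclose(field.tested_pvalues(), 1.0)

    def test_distortion_options_change_pvalues(self, tree_world):
        """The labelled distortion options (smoothing, volume covariate)
        produce valid but different p-value fields from the default."""
        _, _, _, stack = tree_world
        y = stack.masks[:, 12, 12, 12].astype(bool)
        sub = stack.subset(np.arange(60))
        ysub = y[:60]
        if ysub.all() or not ysub.any():
            ysub = sub.masks[:, 11, 12, 12].astype(bool)
        base = ll.vlsm_map(sub, ysub)
        volcov = ll.vlsm_map(sub, ysub, volume_covariate=True)
        assert volcov.test_name == "logistic_lrt_volume"
        assert np.array_equal(volcov.tested_mask, base.tested_mask)
        pv = volcov.tested_pvalues()
        assert ((pv >= 0) & (pv <= 1)).all()
        assert not np.allclose(pv, base.tested_pvalues())
        smoothed = ll.vlsm_map(sub, ysub, smooth_fwhm_mm=4.0)
        assert smoothed.n_tested != 0

    def test_null_pvalues_never_anticonservative(self, tree_world, rng):
        grid, _, _, stack = tree_world
        pooled = []
        for _ in range(20):
            y = np.zeros(stack.n, bool)
            y[rng.choice(stack.n, stack.n // 2, replace=False)] = True
            pooled.append(ll.vlsm_map(stack, y).tested_pvalues())
        pooled = np.sort(np.concatenate(pooled))
        alphas = np.linspace(0.005, 1.0, 200)
        ecdf = np.searchsorted(pooled, alphas, side="right") / len(pooled)
        assert (ecdf - alphas).max() <= 0.01


class TestSignificantCluster:
    def test_single_voxel_cluster(self):
        grid = ll.make_grid((5, 5, 5), 2.0)
        p = np.full(grid.shape, np.nan)
        tested = np.zeros(grid.shape, bool)
        tested[2, 2, 2] = True
        p[2, 2, 2] = 0.005
        field = ll.PValueField(grid=grid, p=p, tested_mask=tested)
        cl = ll.significant_cluster(field, alpha=0.01, correction="bonferroni")
        assert cl.n_voxels == 1
        assert np.allclose(cl.centroid_mm, grid.voxel_to_world((2, 2, 2)))

    def test_symmetric_pair_centroid_midpoint(self):
        grid = ll.make_grid((5, 5, 5), 2.0)
        p = np.full(grid.shape, np.nan)
        tested = np.zeros(grid.shape, bool)
        for v in [(1, 2, 2), (3, 2, 2)]:
            tested[v] = True
            p[v] = 1e-6
        field = ll.PValueField(grid=grid, p=p, tested_mask=tested)
        cl = ll.significant_cluster(field, alpha=0.01)
        assert cl.n_voxels == 2
        assert np.allclose(cl.centroid_mm, grid.voxel_to_world((2, 2, 2)))

    def test_bonferroni_cutoff_arithmetic(self):
        grid = ll.make_grid((10, 10, 10), 1.0)
        p = np.full(grid.shape, np.nan)
        tested = np.ones(grid.shape, bool)
        p[:] = 0.5
        field = ll.PValueField(grid=grid, p=p, tested_mask=tested)
        cl = ll.significant_cluster(field, alpha=0.01)
        assert cl.threshold == pytest.approx(0.01 / 1000)
        assert cl.is_empty and cl.centroid_mm is None


class TestMislocalisationField:
    def test_uniform_lesions_zero_error(self, uniform_cohort):
        field = ll.mislocalisation_field(uniform_cohort)
        assert field.n_eligible > 50
        assert not field.empty_cluster_mask[field.eligible_mask].any()
        mags = field.magnitude_mm[field.defined_mask()]
        assert (mags == 0.0).all()

    def test_codamaged_pair_midpoint(self):
        """Two voxels damaged together in every lesion are indissociable:
        each maps to the pair's midpoint."""
        grid = ll.make_grid((7, 7, 7), 2.0)
        pair_a = [(1, 3, 3), (3, 3, 3)]
        pair_b = [(5, 1, 1), (5, 3, 1)]
        single = [(1, 6, 6)]
        lesions = [pair_a] * 6 + [pair_b] * 6 + [single] * 6
        stack = build_stack(grid, lesions)
        field = ll.mislocalisation_field(stack)
        mid_a = grid.voxel_to_world((2, 3, 3))
        for t in pair_a:
            world_t = grid.voxel_to_world(t)
            vec = field.vector_mm[t]
            assert np.allclose(world_t + vec, mid_a)
        assert field.magnitude_mm[pair_a[0]] == pytest.approx(2.0)

    def test_structured_exceeds_uniform(self, tree_world):
        grid, cfg, tree, stack = tree_world
        tree_field = ll.mislocalisation_field(stack)
        assert tree_field.mean_magnitude_mm() > 0.5
        ucfg = ll.LesionGeneratorConfig(
            mode="uniform_single_voxel", n_lesions=8000, seed=1
        )
        ustack = ll.generate_lesions(grid, ucfg)
        ufield = ll.mislocalisation_field(ustack)
        assert ufield.mean_magnitude_mm() == 0.0
        assert tree_field.mean_magnitude_mm() > ufield.mean_magnitude_mm()

    def test_error_vectors_align_within_territory(self, tree_world):
        grid, _, tree, stack = tree_world
        field = ll.mislocalisation_field(stack)
        idx = np.argwhere(field.defined_mask())
        vec = field.vector_mm[tuple(idx.T)]
        keep = np.linalg.norm(vec, axis=1) > 0
        vecn = vec[keep] / np.linalg.norm(vec[keep], axis=1, keepdims=True)
        terr = tree.territory_of_voxel[tuple(idx[keep].T)]
        within = []
        for t in np.unique(terr):
            v = vecn[terr == t]
            if len(v) < 2:
                continue
            gram = v @ v.T
            iu = np.triu_indices(len(v), 1)
            within.append(gram[iu].mean())
        assert np.mean(within) > 0.05

    def test_empty_field_on_undersampled_stack(self):
        grid = ll.make_grid((5, 5, 5), 1.0)
        stack = build_stack(grid, [[(2, 2, 2)]] * 2)
        field = ll.mislocalisation_field(stack)
        assert field.n_eligible == 0
        assert np.isnan(field.mean_magnitude_mm())

    def test_dataframe_export(self, uniform_cohort):
        field = ll.mislocalisation_field(uniform_cohort)
        df = field.to_dataframe()
        assert len(df) == field.n_eligible
        assert {"magnitude_mm", "cluster_size", "empty_cluster"} <= set(df.columns)
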