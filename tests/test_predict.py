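"""Splits, Fisher's-method scoring, ROC machinery, and the full
prediction experiment."""

import numpy as np
import pytest
from scipy.stats import chi2

import lesionlab as ll
from lesionlab.predict import summarize_rocs, fishers_method_scores
from lesionlab.synth import regions_on_tree


class TestMakeSplits:
    def test_581_to_407_174(self):
        plan = ll.make_splits(581, 0.70, 3, seed=0)
        assert plan.n_train == 407 and plan.n_test == 174
        for tr, te in zip(plan.train_sets, plan.test_sets):
            assert len(tr) == 407 and len(te) == 174
            assert len(np.intersect1d(tr, te)) == 0
            assert len(np.union1d(tr, te)) == 581

    def test_even_split(self):
        plan = ll.make_splits(10, 0.5, 1, seed=1)
        assert plan.n_train == 5 and plan.n_test == 5

    def test_determinism(self):
        p1 = ll.make_splits(50, 0.7, 5, seed=3)
        p2 = ll.make_splits(50, 0.7, 5, seed=3)
        for a, b in zip(p1.train_sets, p2.train_sets):
            assert np.array_equal(a, b)

    def test_class_presence_enforced(self):
        labels = np.zeros(30, bool)
        labels[:2] = True  # rare class: naive splits often miss it
        plan = ll.make_splits(30, 0.5, 20, seed=5, labels=labels)
        for tr, te in zip(plan.train_sets, plan.test_sets):
            assert 0 < labels[tr].sum() and 0 < labels[te].sum()

    def test_invalid_fraction(self):
        with pytest.raises(ValueError):
            ll.make_splits(10, 1.0, 1, seed=0)
        with pytest.raises(ValueError):
            ll.make_splits(1, 0.5, 1, seed=0)


def field_with_pvalues(grid, pvals):
    p = np.full(grid.shape, np.nan)
    tested = np.zeros(grid.shape, bool)
    for v, val in pvals.items():
        tested[v] = True
        p[v] = val
    return ll.PValueField(grid=grid, p=p, tested_mask=tested)


@pytest.fixture(scope="module")
def grid():
    return ll.make_grid((6, 6, 6), 1.0)


class TestFishersMethod:
    def test_single_p_identity(self, grid):
        """Fisher's method on one p-value returns that p-value."""
        field = field_with_pvalues(grid, {(1, 1, 1): 0.5})
        lesion = np.zeros(grid.shape, bool)
        lesion[1, 1, 1] = True
        score = ll.fishers_method_score(field, lesion, p_threshold=0.6)
        assert score == pytest.approx(-np.log10(0.5), abs=1e-6)

    def test_no_subthreshold_voxels_scores_zero(self, grid):
        field = field_with_pvalues(grid, {(1, 1, 1): 0.5})
        lesion = np.zeros(grid.shape, bool)
        lesion[1, 1, 1] = True
        assert ll.fishers_method_score(field, lesion, p_threshold=1e-3) == 0.0

    def test_two_p_chi2_oracle(self, grid):
        """{0.01, 0.04}: X = -2(ln .01 + ln .04) ~ chi2(4)."""
        field = field_with_pvalues(grid, {(1, 1, 1): 0.01, (2, 2, 2): 0.04})
        lesion = np.zeros(grid.shape, bool)
        lesion[1, 1, 1] = lesion[2, 2, 2] = True
        X = -2 * (np.log(0.01) + np.log(0.04))
        expected = -np.log10(chi2.sf(X, 4))
        score = ll.fishers_method_score(field, lesion, p_threshold=0.05)
        assert X == pytest.approx(15.648, abs=1e-3)
        assert score == pytest.approx(expected, abs=1e-9)
        assert score == pytest.approx(2.451, abs=2e-3)

    def test_extreme_evidence_finite_monotone(self, grid):
        """Scores stay finite and ordered when the combined p underflows."""
        strong = field_with_pvalues(
            grid, {(i, j, 1): 1e-280 for i in range(4) for j in range(4)}
        )
        lesion_small = np.zeros(grid.shape, bool)
        lesion_small[0, 0, 1] = True
        lesion_big = np.zeros(grid.shape, bool)
        lesion_big[:4, :4, 1] = True
        s_small = ll.fishers_method_score(strong, lesion_small)
        s_big = ll.fishers_method_score(strong, lesion_big)
        assert np.isfinite(s_small) and np.isfinite(s_big)
        assert s_big > s_small > 100

    def test_vectorized_matches_scalar(self, grid, rng):
        pvals = {
            (int(i), int(j), int(k)): float(p)
            for (i, j, k), p in zip(
                rng.integers(0, 6, size=(8, 3)), rng.random(8)
            )
        }
        field = field_with_pvalues(grid, pvals)
        masks = rng.random((5, *grid.shape)) < 0.3
        stack = ll.LesionStack(grid=grid, masks=masks)
        vec = fishers_method_scores(field, stack, p_threshold=0.5)
        for i in range(5):
            assert vec[i] == pytest.approx(
                ll.fishers_method_score(field, masks[i], 0.5), abs=1e-9
            )


def concordance_oracle(scores, labels):
    """AUC as brute-force pairwise concordance with ties counted 1/2."""
    pos = scores[labels]
    neg = scores[~labels]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


class TestRocCurve:
    def test_perfect_separation(self):
        c = ll.roc_curve(np.array([3.0, 2.0, 1.0, 0.0]), np.array([1, 1, 0, 0], bool))
        assert c.auc == 1.0

    def test_all_ties(self):
        c = ll.roc_curve(np.zeros(6), np.array([1, 1, 1, 0, 0, 0], bool))
        assert c.auc == pytest.approx(0.5)

    def test_three_quarters_example(self):
        scores = np.array([0.9, 0.4, 0.6, 0.1])
        labels = np.array([1, 1, 0, 0], bool)
        assert ll.roc_curve(scores, labels).auc == pytest.approx(0.75)

    @pytest.mark.parametrize("seed", range(5))
    def test_auc_equals_concordance(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 51))
        scores = np.round(rng.normal(size=n), 1)  # rounding induces ties
        labels = rng.random(n) < 0.5
        if labels.all() or not labels.any():
            labels[0] = ~labels[0]
        auc = ll.roc_curve(scores, labels).auc
        assert auc == pytest.approx(concordance_oracle(scores, labels), abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            ll.roc_curve(np.arange(4.0), np.ones(4, bool))


class TestRocSummary:
    def make_curves(self, n_iter, rng):
        curves = []
        for _ in range(n_iter):
            scores = rng.normal(size=40) + np.where(np.arange(40) < 20, 1.0, 0.0)
            labels = np.arange(40) < 20
            curves.append(ll.roc_curve(scores, labels))
        return curves

    def test_endpoints_and_bracketing(self, rng):
        s = summarize_rocs(self.make_curves(30, rng))
        assert s.mean_tpr[0] == 0.0 and s.mean_tpr[-1] == 1.0
        assert (s.ci_low <= s.mean_tpr).all() and (s.mean_tpr <= s.ci_high).all()
        assert 0.0 <= s.auc_ci[0] <= s.mean_auc <= s.auc_ci[1] <= 1.0

    def test_ci_width_shrinks_with_iterations(self):
        rng20 = np.random.default_rng(0)
        rng200 = np.random.default_rng(0)
        s20 = summarize_rocs(self.make_curves(20, rng20))
        s200 = summarize_rocs(self.make_curves(200, rng200))
        w20 = s20.auc_mean_ci[1] - s20.auc_mean_ci[0]
        w200 = s200.auc_mean_ci[1] - s200.auc_mean_ci[0]
        assert w200 < w20


class TestRunExperiment:
    def test_noiseless_single_voxel_uniform_auc_one(self, small_grid):
        """With uniform single-voxel lesions and a deterministic
        single-voxel ground truth, both methods separate perfectly."""
        cfg = ll.LesionGeneratorConfig(
            mode="uniform_single_voxel", n_lesions=4000, seed=2
        )
        stack = ll.generate_lesions(small_grid, cfg)
        hits = stack.hit_counts()
        target = tuple(np.argwhere(hits == hits.max())[0])
        model = ll.DeficitModel(
            kind="single_voxel", target_voxel=target,
            p_deficit_given_criterion=1.0, p_deficit_baseline=0.0,
        )
        labels = ll.assign_deficits(stack, model, seed=0)
        plan = ll.make_splits(stack.n, 0.7, 5, seed=1, labels=labels.labels)
        res = ll.run_experiment(stack, labels, plan)
        assert res["fisher"].mean_auc == pytest.approx(1.0)
        assert res["svm"].mean_auc == pytest.approx(1.0)

    def test_shuffled_labels_null_auc(self, tree_world, rng):
        grid, _, tree, stack = tree_world
        y = rng.random(stack.n) < 0.3
        labels = ll.DeficitLabels(
            labels=y, criterion_met=y, model=ll.DeficitModel(
                kind="single_voxel", target_voxel=(12, 12, 12)
            ), seed=0,
        )
        plan = ll.make_splits(stack.n, 0.7, 25, seed=4, labels=y)
        res = ll.run_experiment(stack, labels, plan)
        for m in ("fisher", "svm"):
            lo, hi = res[m].auc_ci
            assert lo <= 0.5 <= hi
            assert abs(res[m].mean_auc - 0.5) < 0.1

    def test_train_test_hygiene(self, tree_world):
        """Fitted maps depend only on the training half: corrupting the
        test lesions changes no training-derived object."""
        grid, _, _, stack = tree_world
        y = stack.masks[:, 12, 12, 12].astype(bool)
        if y.all() or not y.any():
            y = stack.masks[:, 11, 12, 12].astype(bool)
        plan = ll.make_splits(stack.n, 0.7, 1, seed=0, labels=y)
        tr, te = plan.train_sets[0], plan.test_sets[0]
        field1 = ll.vlsm_map(stack.subset(tr), y[tr])
        wmap1 = ll.fit_linear_svm(stack.subset(tr), y[tr])
        corrupted = stack.masks.copy()
        corrupted[te] = False
        corrupted[te, 12, 12, 12] = True
        stack2 = ll.LesionStack(grid=grid, masks=corrupted)
        field2 = ll.vlsm_map(stack2.subset(tr), y[tr])
        wmap2 = ll.fit_linear_svm(stack2.subset(tr), y[tr])
        assert np.array_equal(
            field1.p[field1.tested_mask], field2.p[field2.tested_mask]
        )
        assert np.array_equal(wmap1.weights, wmap2.weights)

    def test_multivariate_wins_across_worlds(self):
        """Across independent structured-lesion worlds with two-region OR
        ground truth, the multivariate model's mean AUC is at least the
        mass-univariate one in nearly every world."""
        shape = (24, 24, 24)
        g = ll.make_grid(shape, 2.0, brain_mask=ll.spherical_mask(shape, 9))
        wins = 0
        n_worlds = 4
        for seed in range(n_worlds):
            cfg = ll.LesionGeneratorConfig(
                mode="tree_structured", n_lesions=300, seed=50 + seed
            )
            tree = ll.grow_vascular_tree(g, cfg)
            stack = ll.generate_lesions(g, cfg, tree=tree)
            rA, rB = regions_on_tree(g, tree, radius_voxels=3.0, depth=4)
            model = ll.DeficitModel(regions=[rA, rB], operator="OR")
            labels = ll.assign_deficits(stack, model, seed=60 + seed)
            if not 0.02 < labels.labels.mean() < 0.98:
                wins += 1  # degenerate world: skip without penalising
                continue
            plan = ll.make_splits(stack.n, 0.7, 8, seed=70 + seed, labels=labels.labels)
            res = ll.run_experiment(stack, labels, plan)
            wins += res["svm"].mean_auc >= res["fisher"].mean_auc - 1e-9
        assert wins >= n_worlds - 1
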