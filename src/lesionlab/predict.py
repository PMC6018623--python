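"""Out-of-sample deficit prediction: mass-univariate vs multivariate.

The experiment: draw repeated random 70/30 train/test splits of a cohort;
on each training set fit (i) the voxel-wise Fisher-exact p-value field and
(ii) a linear SVM weight map; score every held-out lesion with each method;
sweep thresholds into a ROC curve per method and iteration; and average
the curves vertically on a fixed false-positive-rate grid with pointwise
95% percentile bands.

Mass-univariate scoring uses Fisher's method: the lesion selects the
tested voxels it covers whose training p-value falls below an uncorrected
threshold (0.001 by default, chosen lenient so that voxels of low
significance still contribute), combines them as X = -2 Σ ln p ~ χ²(2k),
and reports -log10 of the combined upper-tail p.  A lesion covering no
sub-threshold voxel scores 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import chi2 as _chi2
from sklearn import metrics as _skm

from .grid import LesionStack
from .deficits import DeficitModel, DeficitLabels, assign_deficits
from .vlsm import PValueField, vlsm_map
from .svm import fit_linear_svm, svm_scores

__all__ = [
    "SplitPlan",
    "RocCurve",
    "RocSummary",
    "make_splits",
    "fishers_method_score",
    "fishers_method_scores",
    "roc_curve",
    "run_experiment",
    "plot_roc_summaries",
]

LN10 = np.log(10.0)


def _chi2_logsf(x: np.ndarray, df: np.ndarray) -> np.ndarray:
    """log of the chi-squared upper tail, stable for extreme evidence.

    scipy's ``chi2.logsf`` returns -inf once the tail underflows; beyond
    that point the log-tail is evaluated with the standard continued
    fraction for the upper incomplete gamma function Q(s, z), s = df/2,
    z = x/2 (valid and rapidly convergent for z > s + 1).
    """
    x = np.asarray(x, dtype=float)
    df = np.asarray(df, dtype=float)
    out = _chi2.logsf(x, df)
    bad = ~np.isfinite(out) & np.isfinite(x)
    if bad.any():
        from scipy.special import gammaln as _gammaln

        s = df[bad] / 2.0 if df.shape else np.full(bad.sum(), df / 2.0)
        z = x[bad] / 2.0
        # modified Lentz continued fraction for Q(s, z)
        tiny = 1e-300
        b = z + 1.0 - s
        c = np.full_like(z, 1.0 / tiny)
        d = 1.0 / np.where(np.abs(b) < tiny, tiny, b)
        h = d.copy()
        for i in range(1, 300):
            an = -i * (i - s)
            b = b + 2.0
            d = an * d + b
            d = np.where(np.abs(d) < tiny, tiny, d)
            c = b + an / c
            c = np.where(np.abs(c) < tiny, tiny, c)
            d = 1.0 / d
            delta = d * c
            h = h * delta
            if np.max(np.abs(delta - 1.0)) < 1e-14:
                break
        out[bad] = -z + s * np.log(z) - _gammaln(s) + np.log(h)
    return out


@dataclass
class SplitPlan:
    """Deterministic train/test partitions for repeated random splits."""

    n_total: int
    train_fraction: float
    n_iterations: int
    seed: int
    train_sets: list[np.ndarray] = field(default_factory=list)
    test_sets: list[np.ndarray] = field(default_factory=list)

    @property
    def n_train(self) -> int:
        return int(round(self.train_fraction * self.n_total))

    @property
    def n_test(self) -> int:
        return self.n_total - self.n_train


def make_splits(
    n_total: int,
    train_fraction: float = 0.70,
    n_iterations: int = 200,
    seed: int = 0,
    labels: np.ndarray | None = None,
    max_retries: int = 100,
) -> SplitPlan:
    """Uniform random train/test partitions without replacement.

    ``|train| = round(train_fraction * n_total)`` — a 70% split of 581
    lesions gives 407 training and 174 test cases.  If ``labels`` is given,
    splits leaving either class absent from train or test are resampled
    (bounded retries).
    """
    if not 0.0 < train_fraction < 1.0:
        raise ValueError("train_fraction must be in (0, 1)")
    if n_total < 2:
        raise ValueError("need at least two cases to split")
    plan = SplitPlan(n_total, train_fraction, n_iterations, seed)
    n_train = plan.n_train
    rng = np.random.default_rng(seed)
    for _ in range(n_iterations):
        for attempt in range(max_retries):
            perm = rng.permutation(n_total)
            tr, te = perm[:n_train], perm[n_train:]
            if labels is None or (
                0 < labels[tr].sum() < len(tr) and 0 < labels[te].sum() < len(te)
            ):
                break
        else:
            raise RuntimeError(
                "could not draw a split with both classes on each side"
            )
        plan.train_sets.append(np.sort(tr))
        plan.test_sets.append(np.sort(te))
    return plan


# ---------------------------------------------------------------------------
# Scoring


def fishers_method_scores(
    p_field: PValueField, stack: LesionStack, p_threshold: float = 1e-3
) -> np.ndarray:
    """Fisher's-method score for every lesion in a stack.

    For each lesion: k = number of tested voxels it covers with
    p < p_threshold; X = -2 Σ ln p; combined p = upper tail of χ²(2k);
    score = -log10(combined p) (computed on the log scale, so extreme
    evidence does not overflow).  k = 0 scores 0.
    """
    sel = p_field.tested_mask & (p_field.p < p_threshold)
    idx = np.argwhere(sel)
    if len(idx) == 0:
        return np.zeros(stack.n)
    logp = np.log(np.maximum(p_field.p[tuple(idx.T)], 1e-300))
    M = stack.design_matrix(idx)
    X = -2.0 * (M @ logp)
    k = M.sum(axis=1)
    scores = np.zeros(stack.n)
    nz = k > 0
    scores[nz] = -_chi2_logsf(X[nz], 2.0 * k[nz]) / LN10
    return scores


def fishers_method_score(
    p_field: PValueField, lesion: np.ndarray, p_threshold: float = 1e-3
) -> float:
    """Scalar :func:`fishers_method_scores` for a single lesion volume."""
    grid = p_field.grid
    stack = LesionStack(grid=grid, masks=np.asarray(lesion, bool)[None])
    return float(fishers_method_scores(p_field, stack, p_threshold)[0])


# ---------------------------------------------------------------------------
# ROC machinery


@dataclass
class RocCurve:
    """A single ROC curve: threshold sweep over unique scores."""

    thresholds: np.ndarray
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float

    def __post_init__(self) -> None:
        if (np.diff(self.fpr) < -1e-12).any() or (np.diff(self.tpr) < -1e-12).any():
            raise ValueError("ROC curve must be monotone nondecreasing")


def roc_curve(scores: np.ndarray, labels: np.ndarray) -> RocCurve:
    """ROC over all unique score thresholds (higher score => predict
    deficit); AUC by trapezoid, which equals the Mann-Whitney concordance
    probability with ties counted one half."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    if labels.all() or not labels.any():
        raise ValueError("both classes must be present")
    fpr, tpr, thr = _skm.roc_curve(labels.astype(int), scores)
    return RocCurve(thresholds=thr, fpr=fpr, tpr=tpr, auc=float(_skm.auc(fpr, tpr)))


@dataclass
class RocSummary:
    """Vertically averaged ROC over iterations with pointwise 95% bands."""

    fpr_grid: np.ndarray
    mean_tpr: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    mean_auc: float
    auc_ci: tuple[float, float]
    n_iterations: int
    aucs: np.ndarray

    @property
    def auc_mean_ci(self) -> tuple[float, float]:
        """95% CI of the *mean* AUC (normal approximation over iterations).

        This is the interval conventionally drawn alongside a mean ROC
        curve; ``auc_ci`` is the wider 2.5/97.5 percentile spread of the
        per-iteration AUCs.
        """
        se = float(self.aucs.std(ddof=1)) / np.sqrt(len(self.aucs))
        return (self.mean_auc - 1.959964 * se, self.mean_auc + 1.959964 * se)

    def __post_init__(self) -> None:
        if not (
            (self.ci_low <= self.mean_tpr + 1e-12).all()
            and (self.mean_tpr <= self.ci_high + 1e-12).all()
        ):
            raise ValueError("CI bands must bracket the mean curve")


def summarize_rocs(curves: list[RocCurve], n_grid: int = 101) -> RocSummary:
    """Vertical averaging: interpolate each curve's TPR onto a fixed FPR
    grid, then take pointwise means and 2.5/97.5 percentiles."""
    fpr_grid = np.linspace(0.0, 1.0, n_grid)
    tprs = np.stack([np.interp(fpr_grid, c.fpr, c.tpr) for c in curves])
    tprs[:, 0] = 0.0
    tprs[:, -1] = 1.0
    aucs = np.array([c.auc for c in curves])
    lo, hi = np.percentile(aucs, [2.5, 97.5])
    mean_tpr = tprs.mean(axis=0)
    # pointwise percentile bands, widened if needed so they always bracket
    # the mean (percentiles of a heavily skewed pointwise distribution can
    # otherwise exclude it)
    return RocSummary(
        fpr_grid=fpr_grid,
        mean_tpr=mean_tpr,
        ci_low=np.minimum(np.percentile(tprs, 2.5, axis=0), mean_tpr),
        ci_high=np.maximum(np.percentile(tprs, 97.5, axis=0), mean_tpr),
        mean_auc=float(aucs.mean()),
        auc_ci=(float(lo), float(hi)),
        n_iterations=len(curves),
        aucs=aucs,
    )


# ---------------------------------------------------------------------------
# The full experiment


@dataclass
class MethodConfig:
    """Per-method knobs of the prediction experiment."""

    fisher_p_threshold: float = 1e-3
    fisher_min_hits: int = 3
    fisher_variant: str = "exact"
    svm_cost_exponent: float = -14.0
    svm_cost_base: float = 2.0


def run_experiment(
    stack: LesionStack,
    model: DeficitModel | DeficitLabels,
    plan: SplitPlan,
    methods: MethodConfig | None = None,
    label_seed: int = 0,
    max_failure_fraction: float = 0.10,
    collect_scores: bool = False,
) -> dict:
    """Run the iterated split-fit-score-ROC comparison.

    Deficit labels are drawn once for the whole cohort (iterations vary
    only in the split).  Returns ``{"fisher": RocSummary, "svm":
    RocSummary, "labels": DeficitLabels, "n_failed": int}``; iterations
    whose training or test half lacks a class are dropped and counted, and
    more than ``max_failure_fraction`` failures aborts.
    """
    methods = methods or MethodConfig()
    if isinstance(model, DeficitLabels):
        labels = model
    else:
        labels = assign_deficits(stack, model, seed=label_seed)
    y = labels.labels
    curves: dict[str, list[RocCurve]] = {"fisher": [], "svm": []}
    rows = []
    n_failed = 0
    for it, (tr, te) in enumerate(zip(plan.train_sets, plan.test_sets)):
        y_tr, y_te = y[tr], y[te]
        if (
            not 0 < y_tr.sum() < len(tr)
            or not 0 < y_te.sum() < len(te)
        ):
            n_failed += 1
            continue
        train = stack.subset(tr)
        test = stack.subset(te)
        p_field = vlsm_map(
            train, y_tr, min_hits=methods.fisher_min_hits,
            variant=methods.fisher_variant,
        )
        f_scores = fishers_method_scores(p_field, test, methods.fisher_p_threshold)
        wmap = fit_linear_svm(
            train, y_tr,
            cost_exponent=methods.svm_cost_exponent,
            cost_base=methods.svm_cost_base,
        )
        s_scores = svm_scores(wmap, test)
        curves["fisher"].append(roc_curve(f_scores, y_te))
        curves["svm"].append(roc_curve(s_scores, y_te))
        if collect_scores:
            for method, sc in (("fisher", f_scores), ("svm", s_scores)):
                for j, li in enumerate(te):
                    rows.append(
                        (it, stack.lesion_ids[li], method, sc[j], int(y_te[j]))
                    )
    if n_failed > max_failure_fraction * len(plan.train_sets):
        raise RuntimeError(
            f"{n_failed}/{len(plan.train_sets)} iterations degenerate"
        )
    out = {
        "fisher": summarize_rocs(curves["fisher"]),
        "svm": summarize_rocs(curves["svm"]),
        "labels": labels,
        "n_failed": n_failed,
    }
    if collect_scores:
        import pandas as pd

        out["scores"] = pd.DataFrame(
            rows, columns=["iteration", "lesion_id", "method", "score", "label"]
        )
    return out


def plot_roc_summaries(summaries: dict[str, "RocSummary"], path: str) -> None:
    """Publication-style mean-ROC figure: solid mean curves, dotted 95%
    bands, one colour per method."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 5))
    colours = {"fisher": "black", "svm": "red"}
    for name, s in summaries.items():
        c = colours.get(name)
        ax.plot(s.fpr_grid, s.mean_tpr, color=c,
                label=f"{name} (AUC {s.mean_auc:.3f})")
        ax.plot(s.fpr_grid, s.ci_low, linestyle=":", color=c, linewidth=1)
        ax.plot(s.fpr_grid, s.ci_high, linestyle=":", color=c, linewidth=1)
    ax.plot([0, 1], [0, 1], color="grey", linewidth=0.5)
    ax.set_xlabel("False positive rate")
    ax.set_ylabel("True positive rate")
    ax.legend(loc="lower right")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
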