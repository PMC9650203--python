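"""Cohort assembly and statistics.

Joins per-subject module counts, streamline asymmetries, gait metrics and
clinical scores, and runs the study's statistics: tie-corrected Spearman
correlations (pairwise-complete, t-approximation p-values), two-sided
Mann-Whitney U, one-way ANOVA with Bonferroni pairwise post-hocs, a coarse
classification tree (CART, Gini impurity, at most four splits) on the CST and
CRP asymmetry ratios predicting the two-module dichotomy with stratified
five-fold cross-validation, an FMA-LE-threshold comparator, and exact
confusion arithmetic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import UndefinedCorrelationError, UndefinedMetricError

TWO = "two_modules"
MULTI = "more_than_two"
CLASSES = (MULTI, TWO)  # deterministic label order (lexicographic)

FMA_SYNERGY_CUTOFF = 15.0  # on the 22-point synergy subsection, strict <


@dataclass
class CorrelationResult:
    x_name: str
    y_name: str
    rho: float
    p_value: float
    n_used: int

    @property
    def df(self) -> int:
        return self.n_used - 2


@dataclass
class ConfusionSummary:
    """Exact counts per (true, predicted) class with derived percentages.

    Display percentages follow the convention of truncating toward zero
    (7/13 -> 53%), matching how such tables are conventionally printed.
    """

    counts: dict  # (true, pred) -> int

    @property
    def n(self) -> int:
        return sum(self.counts.values())

    def class_n(self, cls: str) -> int:
        return sum(v for (t, _), v in self.counts.items() if t == cls)

    def class_correct(self, cls: str) -> int:
        return self.counts.get((cls, cls), 0)

    def per_class_percent(self, cls: str) -> float:
        n = self.class_n(cls)
        if n == 0:
            raise UndefinedMetricError(f"no subjects with true class {cls}")
        return 100.0 * self.class_correct(cls) / n

    @property
    def overall_percent(self) -> float:
        if self.n == 0:
            raise UndefinedMetricError("empty confusion")
        correct = sum(v for (t, p), v in self.counts.items() if t == p)
        return 100.0 * correct / self.n

    @property
    def false_positive_two_percent(self) -> float:
        """Share of true more-than-two-module subjects misread as two-module."""
        n = self.class_n(MULTI)
        if n == 0:
            raise UndefinedMetricError("no more-than-two-module subjects")
        return 100.0 * self.counts.get((MULTI, TWO), 0) / n

    @staticmethod
    def display(pct: float) -> int:
        return int(pct)  # truncate toward zero


def spearman(
    x, y, x_name: str = "x", y_name: str = "y"
) -> CorrelationResult:
    """Tie-corrected (average-rank) Spearman correlation on pairwise-complete
    observations; p from the t-approximation on n - 2 degrees of freedom."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if x.size < 4:
        raise ValueError(f"need at least 4 complete pairs, got {x.size}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedCorrelationError("constant input vector")
    rho, p = stats.spearmanr(x, y)
    return CorrelationResult(x_name, y_name, float(rho), float(p), int(x.size))


def mann_whitney(a, b) -> tuple[float, float]:
    """Two-sided Mann-Whitney U (U counted for the first sample, ties as
    half); exact p for small tie-free samples, else the tie-corrected normal
    approximation."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be nonempty")
    has_ties = np.unique(np.concatenate([a, b])).size < a.size + b.size
    method = "exact" if (a.size * b.size <= 10_000 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def anova_posthoc(
    groups: dict[str, np.ndarray],
) -> tuple[float, float, dict[tuple[str, str], float]]:
    """One-way ANOVA F and p plus Bonferroni-adjusted pairwise t-test
    p-values capped at 1.0."""
    names = list(groups)
    samples = [np.asarray(groups[g], dtype=float) for g in names]
    if len(samples) < 2 or any(s.size < 2 for s in samples):
        raise ValueError("need at least 2 groups with at least 2 observations each")
    if all(np.ptp(np.concatenate(samples)) == 0 for _ in (0,)):
        raise UndefinedMetricError("zero variance across all groups")
    f, p = stats.f_oneway(*samples)
    n_pairs = len(names) * (len(names) - 1) // 2
    pairwise = {}
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            _, p_ij = stats.ttest_ind(samples[i], samples[j])
            pairwise[(names[i], names[j])] = min(1.0, float(p_ij) * n_pairs)
    return float(f), float(p), pairwise


# --- coarse classification tree -------------------------------------------


@dataclass
class TreeNode:
    prediction: str
    counts: dict
    feature: int | None = None
    threshold: float | None = None
    left: "TreeNode | None" = None
    right: "TreeNode | None" = None

    @property
    def is_leaf(self) -> bool:
        return self.feature is None


@dataclass
class TreeModel:
    root: TreeNode
    n_splits: int
    feature_names: tuple[str, ...] = ("asymm_cst", "asymm_crp")

    def to_rules(self) -> list[str]:
        out: list[str] = []

        def walk(node: TreeNode, path: str) -> None:
            if node.is_leaf:
                out.append(f"{path or 'always'} -> {node.prediction}")
                return
            name = self.feature_names[node.feature]
            walk(node.left, f"{path} & {name} < {node.threshold:g}".lstrip(" &"))
            walk(node.right, f"{path} & {name} >= {node.threshold:g}".lstrip(" &"))

        walk(self.root, "")
        return out


def _gini(y: np.ndarray) -> float:
    if y.size == 0:
        return 0.0
    _, c = np.unique(y, return_counts=True)
    p = c / y.size
    return float(1.0 - np.sum(p * p))


def _majority(y: np.ndarray) -> str:
    vals, c = np.unique(y, return_counts=True)
    # np.unique sorts labels, so ties resolve to the lexicographically
    # smaller class, independent of record order.
    return str(vals[np.argmax(c)])


def _counts(y: np.ndarray) -> dict:
    vals, c = np.unique(y, return_counts=True)
    return {str(v): int(n) for v, n in zip(vals, c)}


def _best_split(X: np.ndarray, y: np.ndarray):
    """Best (impurity decrease, feature, threshold) over midpoint candidate
    thresholds; ties broken toward lower feature index then lower threshold
    by strict-improvement iteration order."""
    n = y.size
    parent = _gini(y) * n
    best = None
    for f in range(X.shape[1]):
        v = X[:, f]
        uniq = np.unique(v)
        for thr in (uniq[:-1] + uniq[1:]) / 2.0:
            left = v < thr
            score = parent - _gini(y[left]) * left.sum() - _gini(y[~left]) * (
                n - left.sum()
            )
            if score > 1e-12 and (best is None or score > best[0] + 1e-12):
                best = (float(score), f, float(thr))
    return best


def fit_coarse_tree(
    X: np.ndarray,
    y,
    max_splits: int = 4,
    feature_names: tuple[str, ...] = ("asymm_cst", "asymm_crp"),
) -> TreeModel:
    """Greedy CART with Gini impurity, best-first growth, at most
    ``max_splits`` internal nodes, minimum leaf size 1; deterministic and
    invariant to record order."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if X.ndim != 2 or X.shape[0] != y.size:
        raise ValueError("X must be (n, n_features) matching y")
    if not np.all(np.isfinite(X)):
        raise ValueError("tree features must be complete (listwise deletion)")

    root = TreeNode(_majority(y), _counts(y))
    # leaves: creation-ordered list of (node, X, y, cached best split)
    leaves = [(root, X, y, _best_split(X, y))]
    n_splits = 0
    while n_splits < max_splits:
        best_i = None
        for i, (_, _, _, split) in enumerate(leaves):
            if split is None:
                continue
            if best_i is None or split[0] > leaves[best_i][3][0] + 1e-12:
                best_i = i
        if best_i is None:
            break
        node, Xn, yn, (_, f, thr) = leaves.pop(best_i)
        mask = Xn[:, f] < thr
        node.feature, node.threshold = f, thr
        node.left = TreeNode(_majority(yn[mask]), _counts(yn[mask]))
        node.right = TreeNode(_majority(yn[~mask]), _counts(yn[~mask]))
        leaves.append((node.left, Xn[mask], yn[mask], _best_split(Xn[mask], yn[mask])))
        leaves.append(
            (node.right, Xn[~mask], yn[~mask], _best_split(Xn[~mask], yn[~mask]))
        )
        n_splits += 1
    return TreeModel(root, n_splits, tuple(feature_names))


def predict_tree(model: TreeModel, features) -> str:
    """Deterministic path evaluation; left branch is strict less-than."""
    x = np.asarray(features, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("missing feature value")
    node = model.root
    while not node.is_leaf:
        node = node.left if x[node.feature] < node.threshold else node.right
    return node.prediction


def predict_tree_many(model: TreeModel, X) -> np.ndarray:
    return np.array([predict_tree(model, row) for row in np.asarray(X, float)])


def printed_rule_tree(
    crp_cutoff: float = 0.27, cst_cutoff: float = -0.02
) -> TreeModel:
    """Fixture tree encoding the published decision rule: predict two modules
    when CRP asymmetry < 0.27, or otherwise when CST asymmetry < -0.02."""
    root = TreeNode(TWO, {}, feature=1, threshold=crp_cutoff)
    root.left = TreeNode(TWO, {})
    root.right = TreeNode(MULTI, {}, feature=0, threshold=cst_cutoff)
    root.right.left = TreeNode(TWO, {})
    root.right.right = TreeNode(MULTI, {})
    return TreeModel(root, 2)


def confusion_report(true_labels, predicted_labels) -> ConfusionSummary:
    t = list(true_labels)
    p = list(predicted_labels)
    if len(t) != len(p):
        raise ValueError("label lists must have equal length")
    counts: dict = {}
    for ti, pi in zip(t, p):
        counts[(ti, pi)] = counts.get((ti, pi), 0) + 1
    return ConfusionSummary(counts)


@dataclass
class CVResult:
    accuracy_percent: float
    pooled_confusion: ConfusionSummary
    resubstitution_confusion: ConfusionSummary
    model: TreeModel
    fold_confusions: list = field(default_factory=list)


def cross_validate(
    X: np.ndarray, y, k_folds: int = 5, seed: int = 0, max_splits: int = 4
) -> CVResult:
    """Stratified seeded k-fold cross-validation of the coarse tree plus the
    resubstitution confusion of the full-data tree (both are reported because
    published classification counts do not state which was used)."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    n = y.size
    if n < k_folds:
        raise ValueError("need at least k_folds records")
    rng = np.random.default_rng(seed)
    fold_of = np.empty(n, dtype=int)
    for cls in np.unique(y):
        idx = np.flatnonzero(y == cls)
        rng.shuffle(idx)
        fold_of[idx] = np.arange(idx.size) % k_folds

    oof_true: list = []
    oof_pred: list = []
    fold_confusions = []
    import warnings

    for f in range(k_folds):
        test = fold_of == f
        if np.unique(y[~test]).size < 2:
            warnings.warn(f"fold {f} skipped: a class is absent from training")
            continue
        model_f = fit_coarse_tree(X[~test], y[~test], max_splits)
        pred = predict_tree_many(model_f, X[test])
        oof_true += list(y[test])
        oof_pred += list(pred)
        fold_confusions.append(confusion_report(y[test], pred))

    pooled = confusion_report(oof_true, oof_pred)
    full_model = fit_coarse_tree(X, y, max_splits)
    resub = confusion_report(y, predict_tree_many(full_model, X))
    return CVResult(
        pooled.overall_percent, pooled, resub, full_model, fold_confusions
    )


def fma_threshold_classifier(fma_le_synergy: float) -> str:
    """Two-module prediction from the 22-point FMA-LE synergy subsection:
    scores below 15 predict the mass flexion-extension (two-module) pattern."""
    if not 0.0 <= fma_le_synergy <= 22.0:
        raise ValueError(f"FMA-LE synergy score must be in [0, 22]")
    return TWO if fma_le_synergy < FMA_SYNERGY_CUTOFF else MULTI


# --- subject table ---------------------------------------------------------


def subject_table(subjects, harmonize: bool = True) -> pd.DataFrame:
    """Join module truth/labels, harmonized streamline asymmetries, clinical
    scores and gait-symmetry targets into the per-subject analysis table."""
    from .connectivity import asymmetry_ratios, harmonize_batches
    from .gaitmetrics import symmetry_deviation

    records = [s.streamlines for s in subjects]
    if harmonize and len({r.scanner_batch for r in records}) > 1:
        records = harmonize_batches(records)
    rows = []
    for s, rec in zip(subjects, records):
        ratios = asymmetry_ratios(rec)
        k = s.config.true_n_modules if s.config is not None else np.nan
        pp = s.config.pp_true if s.config is not None else np.nan
        psr = s.config.psr_true if s.config is not None else np.nan
        rows.append(
            {
                "subject_id": s.subject_id,
                "group": s.group,
                "subgroup": s.subgroup,
                "k_true": k,
                "pattern_class": (TWO if k <= 2 else MULTI)
                if np.isfinite(k)
                else None,
                "asymm_cst": ratios.asymm_cst,
                "asymm_crp": ratios.asymm_crp,
                "fma_le": s.clinical.fma_le,
                "fma_le_synergy": s.clinical.fma_le_synergy,
                "dgi": s.clinical.dgi,
                "bbs": s.clinical.bbs,
                "smwt_m": s.clinical.smwt_m,
                "ss_speed_m_s": s.clinical.ss_speed_m_s,
                "pp": pp,
                "psr": psr,
                "pp_deviation": symmetry_deviation(pp) if np.isfinite(pp) else np.nan,
                "psr_deviation": symmetry_deviation(psr)
                if np.isfinite(psr)
                else np.nan,
            }
        )
    return pd.DataFrame(rows)
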