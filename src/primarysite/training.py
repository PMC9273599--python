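"""Per-class binary training: feature selection, resampling search, forest.

Each cancer-type classifier is a binary random forest trained case-vs-rest.
Before training, univariate selection keeps only features associated with
the case class (Wilcoxon rank-sum + Cliff's delta for numeric features,
Fisher exact + Cramer's V for boolean ones; p < 0.01, effect >= 0.1, at most
100 features). Class imbalance is handled by jointly oversampling the case
group and undersampling the control group toward their geometric mean; the
over/under target pair is chosen by a grid search scored with the area under
the precision-recall curve in stratified cross-validation.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier

from primarysite.features.matrix import FeatureMatrix
from primarysite.stats import auprc, cliffs_delta, cramers_v_2x2, fisher_p, rank_sum_p

P_THRESHOLD = 0.01
EFFECT_THRESHOLD = 0.1
FEATURE_CAP = 100
N_TREES = 500
GRID_SIZE = 5
GRID_CV_FOLDS = 10


@dataclass
class SelectionResult:
    """Univariate test table and the capped selected-feature list."""

    table: pd.DataFrame  # feature -> p_value, effect_size, sidedness, selected
    selected: list[str]


@dataclass
class ResamplingChoice:
    """Grid of candidate resampling targets and the AUPRC-optimal pair."""

    oversample_targets: np.ndarray
    undersample_targets: np.ndarray
    mean_auprc: pd.DataFrame  # oversample target x undersample target
    chosen: tuple[int, int]  # (oversample target, undersample target)


@dataclass
class TrainedBinaryModel:
    """One class's forest plus everything needed to reproduce and explain it."""

    class_name: str
    features: list[str]
    forest: RandomForestClassifier
    resampling: ResamplingChoice | None
    selection: SelectionResult | None
    seed: int

    def predict_proba(self, X: pd.DataFrame) -> np.ndarray:
        """Raw positive-class probability (mean leaf positive fraction)."""
        missing = [f for f in self.features if f not in X.columns]
        if missing:
            raise KeyError(f"feature vector lacks model features: {missing[:5]}")
        arr = X[self.features].to_numpy(dtype=float)
        proba = self.forest.predict_proba(arr)
        pos = list(self.forest.classes_).index(1)
        return proba[:, pos]


def univariate_select(
    X: FeatureMatrix,
    y: np.ndarray,
    cap: int = FEATURE_CAP,
    p_threshold: float = P_THRESHOLD,
    effect_threshold: float = EFFECT_THRESHOLD,
) -> SelectionResult:
    """Univariate case-vs-control feature selection for one class.

    Numeric features are tested with the Wilcoxon rank-sum test and scored
    with Cliff's delta; boolean features with the Fisher exact test and
    Cramer's V. Sidedness follows the per-feature metadata (one-sided
    "greater in case" for burden/presence families, two-sided for ploidy
    families, where the absolute effect is thresholded). If more than ``cap``
    features pass, the best ``cap`` by (effect desc, p asc, name) are kept.
    """
    y = np.asarray(y).astype(bool)
    if y.all() or not y.any():
        raise ValueError("both case and control groups must be nonempty")
    rows = []
    for feat in X.features:
        values = X.data[feat].to_numpy(dtype=float)
        case, ctrl = values[y], values[~y]
        meta = X.metadata.loc[feat]
        sidedness = meta["sidedness"]
        if meta["is_boolean"]:
            a, b = int(case.sum()), int(ctrl.sum())
            c, d = len(case) - a, len(ctrl) - b
            if (a + b == 0) or (c + d == 0):
                p, eff = 1.0, 0.0  # constant feature
            else:
                p = fisher_p(a, c, b, d, alternative=sidedness)
                eff = cramers_v_2x2([[a, b], [c, d]])
        else:
            if np.all(values == values[0]):
                p, eff = 1.0, 0.0
            else:
                p = rank_sum_p(case, ctrl, alternative=sidedness)
                eff = cliffs_delta(case, ctrl)
        magnitude = abs(eff) if sidedness == "two-sided" else eff
        passed = p < p_threshold and magnitude >= effect_threshold
        rows.append((feat, p, eff, magnitude, sidedness, passed))
    table = pd.DataFrame(
        rows,
        columns=["feature", "p_value", "effect_size", "effect_magnitude",
                 "sidedness", "passed"],
    ).set_index("feature")
    passing = table[table["passed"]]
    ranked = passing.sort_values(
        by=["effect_magnitude", "p_value", "feature"],
        ascending=[False, True, True],
        kind="mergesort",
    )
    selected = list(ranked.index[:cap])
    if not selected:
        raise ValueError("no informative features for class")
    table["selected"] = table.index.isin(selected)
    return SelectionResult(table=table, selected=selected)


def build_resampling_grid(
    n_case: int, n_control: int, k: int = GRID_SIZE
) -> tuple[np.ndarray, np.ndarray]:
    """Candidate resampling targets between each group size and their geometric mean.

    Oversample targets run log-spaced from ``n_case`` up to the geometric
    mean g = sqrt(n_case * n_control); undersample targets from ``n_control``
    down to g (both inclusive, rounded to the nearest integer). When the case
    group is not smaller than the control group the grid degenerates to
    identity resampling.
    """
    if n_case <= 0 or n_control <= 0:
        raise ValueError("group sizes must be positive")
    if n_case >= n_control:
        return (np.full(1, n_case), np.full(1, n_control))
    g = np.sqrt(n_case * n_control)
    if k == 1:  # endpoints coincide at the geometric mean
        target = np.array([int(np.rint(g))])
        return target, target.copy()
    over = np.rint(np.logspace(np.log10(n_case), np.log10(g), k)).astype(int)
    under = np.rint(np.logspace(np.log10(n_control), np.log10(g), k)).astype(int)
    return over, under


def resample_indices(
    y: np.ndarray,
    over_target: int,
    under_target: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Indices realizing one over/under pair: case with, control without replacement."""
    y = np.asarray(y).astype(bool)
    case_idx = np.flatnonzero(y)
    ctrl_idx = np.flatnonzero(~y)
    if over_target <= len(case_idx):
        case_sel = case_idx
    else:
        extra = rng.choice(case_idx, size=over_target - len(case_idx), replace=True)
        case_sel = np.concatenate([case_idx, extra])
    under_target = min(under_target, len(ctrl_idx))
    ctrl_sel = rng.choice(ctrl_idx, size=under_target, replace=False)
    return np.sort(np.concatenate([case_sel, ctrl_sel]))


def deterministic_folds(
    sample_ids: list[str], y: np.ndarray, n_folds: int, seed: int
) -> np.ndarray:
    """Stratified fold assignment, reproducible across runs and platforms.

    Within each stratum, samples are ordered by the MD5 hash of
    "seed:sample_id" and dealt round-robin to folds, so per-fold class
    proportions are within one sample of the global proportions.
    """
    y = np.asarray(y)
    folds = np.empty(len(sample_ids), dtype=int)
    for stratum in np.unique(y):
        idx = np.flatnonzero(y == stratum)
        keys = [
            hashlib.md5(f"{seed}:{sample_ids[i]}".encode()).hexdigest() for i in idx
        ]
        order = idx[np.argsort(keys)]
        for j, i in enumerate(order):
            folds[i] = j % n_folds
    return folds


def _fit_forest(
    X: np.ndarray, y: np.ndarray, n_trees: int, seed: int
) -> RandomForestClassifier:
    if len(np.unique(y)) < 2:
        raise ValueError("single-class input; cannot train a binary forest")
    forest = RandomForestClassifier(
        n_estimators=n_trees,
        criterion="gini",
        max_features="sqrt",
        min_samples_leaf=1,
        bootstrap=True,
        random_state=seed,
        n_jobs=1,
    )
    forest.fit(X, y.astype(int))
    return forest


def choose_resampling(
    X_selected: pd.DataFrame,
    y: np.ndarray,
    grid: tuple[np.ndarray, np.ndarray] | None = None,
    folds: int = GRID_CV_FOLDS,
    seed: int = 0,
    n_trees: int = 100,
) -> ResamplingChoice:
    """Grid-search the resampling pair by mean AUPRC in stratified CV.

    Resampling is applied to training folds only; validation folds are left
    untouched. Ties in mean AUPRC resolve to the least-distorting pair
    (smallest total displacement from the original group sizes).
    """
    y = np.asarray(y).astype(bool)
    n_case, n_control = int(y.sum()), int((~y).sum())
    if grid is None:
        grid = build_resampling_grid(n_case, n_control)
    over_targets, under_targets = grid
    sample_ids = [str(s) for s in X_selected.index]
    folds = min(folds, n_case)  # every fold needs at least one positive
    if folds < 2:
        raise ValueError("case group too small to stratify the grid-search CV")
    fold_of = deterministic_folds(sample_ids, y, folds, seed)
    arr = X_selected.to_numpy(dtype=float)
    scores = np.zeros((len(over_targets), len(under_targets)))
    for i, over in enumerate(over_targets):
        for j, under in enumerate(under_targets):
            fold_scores = []
            for f in range(folds):
                train = fold_of != f
                val = ~train
                rng = np.random.default_rng(
                    _pair_seed(seed, i, j, f)
                )
                idx = resample_indices(y[train], int(over), int(under), rng)
                train_idx = np.flatnonzero(train)[idx]
                forest = _fit_forest(
                    arr[train_idx], y[train_idx], n_trees, _pair_seed(seed, i, j, f)
                )
                pos = list(forest.classes_).index(1)
                val_scores = forest.predict_proba(arr[val])[:, pos]
                fold_scores.append(auprc(val_scores, y[val]))
            scores[i, j] = float(np.mean(fold_scores))
    mean_auprc = pd.DataFrame(scores, index=over_targets, columns=under_targets)
    best = scores.max()
    candidates = [
        (int(over_targets[i]), int(under_targets[j]))
        for i in range(len(over_targets))
        for j in range(len(under_targets))
        if scores[i, j] == best
    ]
    chosen = min(
        candidates, key=lambda p: (abs(p[0] - n_case) + abs(n_control - p[1]), p)
    )
    return ResamplingChoice(
        oversample_targets=over_targets,
        undersample_targets=under_targets,
        mean_auprc=mean_auprc,
        chosen=chosen,
    )


def _pair_seed(seed: int, i: int, j: int, f: int) -> int:
    return (seed * 1_000_003 + i * 10_007 + j * 101 + f) % (2**31 - 1)


def train_binary_rf(
    X_selected: pd.DataFrame,
    y: np.ndarray,
    seed: int = 0,
    n_trees: int = N_TREES,
    class_name: str = "",
    resampling: ResamplingChoice | None = None,
    selection: SelectionResult | None = None,
) -> TrainedBinaryModel:
    """Train the binary forest for one class on (already resampled) data.

    The forest grows ``n_trees`` fully-developed trees (Gini impurity,
    bootstrap, sqrt(p) candidate features per split, minimum leaf size 1);
    each node stores the fraction of positive training samples reaching it,
    which doubles as the probability model and the basis for per-feature
    contribution explanations.
    """
    y = np.asarray(y).astype(int)
    forest = _fit_forest(X_selected.to_numpy(dtype=float), y, n_trees, seed)
    return TrainedBinaryModel(
        class_name=class_name,
        features=list(X_selected.columns),
        forest=forest,
        resampling=resampling,
        selection=selection,
        seed=seed,
    )


def train_class_model(
    X: FeatureMatrix,
    y: np.ndarray,
    class_name: str,
    seed: int,
    cap: int = FEATURE_CAP,
    grid_size: int = GRID_SIZE,
    grid_folds: int = GRID_CV_FOLDS,
    grid_trees: int = 100,
    n_trees: int = N_TREES,
) -> TrainedBinaryModel:
    """Full per-class procedure: selection -> resampling search -> forest."""
    y = np.asarray(y).astype(bool)
    selection = univariate_select(X, y, cap=cap)
    X_sel = X.data[selection.selected]
    n_case, n_control = int(y.sum()), int((~y).sum())
    grid = build_resampling_grid(n_case, n_control, k=grid_size)
    choice = choose_resampling(
        X_sel, y, grid=grid, folds=grid_folds, seed=seed, n_trees=grid_trees
    )
    rng = np.random.default_rng(_pair_seed(seed, 97, 89, 83))
    idx = resample_indices(y, choice.chosen[0], choice.chosen[1], rng)
    return train_binary_rf(
        X_sel.iloc[idx],
        y[idx],
        seed=seed,
        n_trees=n_trees,
        class_name=class_name,
        resampling=choice,
        selection=selection,
    )
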