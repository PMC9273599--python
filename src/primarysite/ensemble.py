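"""The trained one-vs-rest ensemble: training orchestration and serialization.

``train_ensemble`` runs the full procedure on a feature matrix with class
labels: regional-mutational-density profile extraction (replacing raw
``rmd_bin.*`` columns with ``rmd.*`` profile contributions), per-class
selection / resampling search / forest training, stratified cross-validation
to obtain out-of-fold probabilities, isotonic calibration, and the gender
filter for sex-specific cancer types.
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import joblib
import numpy as np
import pandas as pd

from primarysite.calibration import CalibratorSet, fit_calibrators
from primarysite.features.matrix import FeatureMatrix, default_metadata
from primarysite.profiles import (
    RMDProfileSet,
    deduplicate_profiles,
    extract_profiles_per_class,
    fit_profile_matrix,
)
from primarysite.training import (
    TrainedBinaryModel,
    deterministic_folds,
    train_class_model,
)

logger = logging.getLogger(__name__)

MIN_CLASS_SIZE = 15

#: Default gender filter: probabilities of these classes are zeroed for the
#: opposite sex (matched case-insensitively against class-name prefixes).
MALE_ZERO_PREFIXES = ("breast", "ovar", "cervix")
FEMALE_ZERO_PREFIXES = ("prostate",)


@dataclass
class GenderFilterRules:
    """Class-name prefixes whose probability is zeroed per gender."""

    male_zero: tuple[str, ...] = MALE_ZERO_PREFIXES
    female_zero: tuple[str, ...] = FEMALE_ZERO_PREFIXES

    def zeroed_classes(self, classes: Sequence[str], gender: str) -> list[str]:
        if gender == "male":
            prefixes = self.male_zero
        elif gender == "female":
            prefixes = self.female_zero
        else:
            return []
        return [
            c for c in classes if any(c.lower().startswith(p) for p in prefixes)
        ]


def apply_gender_filter(
    probs: pd.DataFrame, gender: pd.Series | Mapping[str, str],
    rules: GenderFilterRules | None = None,
) -> pd.DataFrame:
    """Zero sex-incompatible class probabilities per sample.

    Unknown gender leaves the row unchanged. Applied to raw probabilities
    before calibration and re-applied afterwards, so a filtered zero can
    never be resurrected by the calibrator.
    """
    rules = rules or GenderFilterRules()
    gender = pd.Series(gender).reindex(probs.index).fillna("unknown")
    out = probs.copy()
    for g in ("male", "female"):
        cols = rules.zeroed_classes(list(probs.columns), g)
        if cols:
            out.loc[(gender == g).to_numpy(), cols] = 0.0
    return out


@dataclass
class TrainingConfig:
    """Knobs of the training procedure with the reference defaults.

    The defaults mirror the full-scale procedure (500-tree forests, 10-fold
    grid-search CV, 15-fold calibration CV, 50-run NMF rank search over
    ranks 1-10); reduced values give a faithful desk-scale run.
    """

    min_class_size: int = MIN_CLASS_SIZE
    feature_cap: int = 100
    n_trees: int = 500
    grid_size: int = 5
    grid_folds: int = 10
    grid_trees: int = 100
    calib_folds: int = 15
    rmd_max_rank: int = 10
    rmd_rank_runs: int = 50
    rmd_subset_size: int = 100
    extract_rmd_profiles: bool = True

    def config_hash(self) -> str:
        return hashlib.md5(
            json.dumps(asdict(self), sort_keys=True).encode()
        ).hexdigest()[:12]


def desk_scale_config(**overrides) -> TrainingConfig:
    """A configuration sized for a single CPU on a synthetic cohort."""
    params = dict(
        n_trees=100, grid_size=3, grid_folds=3, grid_trees=25, calib_folds=5,
        rmd_max_rank=5, rmd_rank_runs=8, rmd_subset_size=60,
    )
    params.update(overrides)
    return TrainingConfig(**params)


@dataclass
class Ensemble:
    """Per-class binary models, calibrators, gender rules and cohort summaries."""

    classes: list[str]
    models: dict[str, TrainedBinaryModel]
    calibrators: CalibratorSet
    gender_rules: GenderFilterRules
    profile_set: RMDProfileSet | None
    feature_names: list[str]
    cohort_summaries: pd.DataFrame  # feature x (mean per class + mean_rest_<class>)
    config: TrainingConfig
    seed: int
    cv_probs_raw: pd.DataFrame | None = field(default=None, repr=False)

    def raw_probabilities(self, X: pd.DataFrame) -> pd.DataFrame:
        cols = {c: self.models[c].predict_proba(X) for c in self.classes}
        return pd.DataFrame(cols, index=X.index)

    # -- serialization ----------------------------------------------------

    def save(self, directory) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        joblib.dump(
            {c: self.models[c] for c in self.classes}, directory / "forests.joblib"
        )
        knots = pd.concat(
            {
                c: cal.knots
                for c, cal in self.calibrators.calibrators.items()
            },
            names=["class", "knot"],
        )
        knots.to_csv(directory / "calibrator_knots.tsv", sep="\t")
        self.cohort_summaries.to_csv(
            directory / "cohort_summaries.tsv", sep="\t", index_label="feature"
        )
        if self.profile_set is not None:
            self.profile_set.profiles.to_csv(
                directory / "rmd_profiles.tsv", sep="\t", index_label="profile"
            )
            self.profile_set.provenance.to_csv(
                directory / "rmd_profile_provenance.tsv", sep="\t", index=False
            )
        selections = pd.concat(
            {
                c: self.models[c].selection.table
                for c in self.classes
                if self.models[c].selection is not None
            },
            names=["class", "feature"],
        )
        selections.to_csv(directory / "selection_tables.tsv", sep="\t")
        provenance = {
            "classes": self.classes,
            "feature_names": self.feature_names,
            "gender_rules": asdict(self.gender_rules),
            "config": asdict(self.config),
            "config_hash": self.config.config_hash(),
            "seed": self.seed,
        }
        (directory / "provenance.json").write_text(
            json.dumps(provenance, indent=2, sort_keys=True)
        )

    @classmethod
    def load(cls, directory) -> "Ensemble":
        from primarysite.calibration import Calibrator

        directory = Path(directory)
        provenance = json.loads((directory / "provenance.json").read_text())
        models = joblib.load(directory / "forests.joblib")
        knots = pd.read_csv(
            directory / "calibrator_knots.tsv", sep="\t", index_col=[0, 1]
        )
        calibrators = CalibratorSet(
            {
                cls_name: Calibrator.from_knots(knots.loc[cls_name])
                for cls_name in provenance["classes"]
            }
        )
        summaries = pd.read_csv(
            directory / "cohort_summaries.tsv", sep="\t", index_col="feature"
        )
        profile_set = None
        profile_path = directory / "rmd_profiles.tsv"
        if profile_path.exists():
            profiles = pd.read_csv(profile_path, sep="\t", index_col="profile")
            prov = pd.read_csv(directory / "rmd_profile_provenance.tsv", sep="\t")
            profile_set = RMDProfileSet(profiles=profiles, provenance=prov)
        rules = GenderFilterRules(
            male_zero=tuple(provenance["gender_rules"]["male_zero"]),
            female_zero=tuple(provenance["gender_rules"]["female_zero"]),
        )
        return cls(
            classes=provenance["classes"],
            models=models,
            calibrators=calibrators,
            gender_rules=rules,
            profile_set=profile_set,
            feature_names=provenance["feature_names"],
            cohort_summaries=summaries,
            config=TrainingConfig(**provenance["config"]),
            seed=provenance["seed"],
        )


# ---------------------------------------------------------------------------
# Training orchestration


def _prepare_rmd_features(
    X: FeatureMatrix,
    labels: pd.Series,
    config: TrainingConfig,
    seed: int,
    profile_set: RMDProfileSet | None = None,
) -> tuple[FeatureMatrix, RMDProfileSet | None]:
    """Replace raw rmd_bin.* columns with rmd.* profile contributions."""
    bin_cols = [f for f in X.features if f.startswith("rmd_bin.")]
    if not bin_cols or not config.extract_rmd_profiles:
        return X, profile_set
    rmd = X.data[bin_cols]
    if profile_set is None:
        class_profiles = extract_profiles_per_class(
            rmd,
            labels,
            seed=seed,
            n_runs=config.rmd_rank_runs,
            max_rank=config.rmd_max_rank,
            subset_size=config.rmd_subset_size,
        )
        sizes = labels.value_counts().to_dict()
        profile_set = deduplicate_profiles(class_profiles, class_sizes=sizes)
    contributions = fit_profile_matrix(rmd, profile_set)
    rest = X.data.drop(columns=bin_cols)
    data = pd.concat([contributions, rest], axis=1)
    from primarysite.features.matrix import sort_feature_columns

    data = data[sort_feature_columns(data.columns)]
    return FeatureMatrix(data), profile_set


def cross_validated_probabilities(
    X: FeatureMatrix,
    class_labels: pd.Series,
    folds: int = 15,
    seed: int = 0,
    config: TrainingConfig | None = None,
) -> pd.DataFrame:
    """Out-of-fold raw probabilities from rerunning the per-class procedure.

    Folds are stratified by class with a deterministic hash-based
    assignment; in each round the entire per-class training procedure
    (selection -> resampling search -> forest) is rerun on the in-fold data
    and the held-out fold is scored, so every sample receives exactly one
    out-of-fold probability per class.
    """
    config = config or TrainingConfig()
    labels = pd.Series(class_labels).reindex(X.data.index)
    if labels.isna().any():
        raise ValueError("class labels missing for some samples")
    counts = labels.value_counts()
    too_small = counts[counts < folds]
    if not too_small.empty:
        raise ValueError(
            f"classes smaller than the fold count: {dict(too_small)}"
        )
    sample_ids = [str(s) for s in X.data.index]
    y_codes = labels.to_numpy()
    fold_of = deterministic_folds(sample_ids, y_codes, folds, seed)
    classes = sorted(counts.index)
    probs = pd.DataFrame(
        np.full((len(sample_ids), len(classes)), np.nan),
        index=X.data.index,
        columns=classes,
    )
    for f in range(folds):
        train_mask = fold_of != f
        X_train = FeatureMatrix(
            X.data.loc[train_mask].copy(), X.metadata.copy()
        )
        for k, cls in enumerate(classes):
            y_train = (labels[train_mask] == cls).to_numpy()
            model = train_class_model(
                X_train,
                y_train,
                class_name=cls,
                seed=_fold_seed(seed, f, k),
                cap=config.feature_cap,
                grid_size=config.grid_size,
                grid_folds=config.grid_folds,
                grid_trees=config.grid_trees,
                n_trees=config.n_trees,
            )
            probs.loc[~train_mask, cls] = model.predict_proba(
                X.data.loc[~train_mask]
            )
    assert not probs.isna().any().any()
    return probs


def _fold_seed(seed: int, fold: int, k: int) -> int:
    return (seed * 1_000_003 + fold * 7919 + k * 131 + 17) % (2**31 - 1)


def cohort_feature_summaries(
    X: FeatureMatrix, labels: pd.Series
) -> pd.DataFrame:
    """Per-feature mean within each class and over all other samples."""
    labels = pd.Series(labels).reindex(X.data.index)
    cols = {}
    for cls in sorted(labels.unique()):
        in_cls = (labels == cls).to_numpy()
        cols[f"mean.{cls}"] = X.data.loc[in_cls].mean()
        cols[f"mean_rest.{cls}"] = X.data.loc[~in_cls].mean()
    return pd.DataFrame(cols)


def train_ensemble(
    X: FeatureMatrix,
    class_labels: pd.Series,
    config: TrainingConfig | None = None,
    seed: int = 0,
    gender_rules: GenderFilterRules | None = None,
    genders: pd.Series | None = None,
) -> Ensemble:
    """Train the full calibrated one-vs-rest ensemble.

    Classes with fewer than ``config.min_class_size`` samples are dropped
    with a warning. The final per-class models are trained on all remaining
    training data; the calibrators come from the stratified
    ``config.calib_folds``-fold cross-validation probabilities. When
    ``genders`` is given, the gender filter is applied to the CV
    probabilities before calibration (mirroring prediction time).
    """
    config = config or TrainingConfig()
    gender_rules = gender_rules or GenderFilterRules()
    labels = pd.Series(class_labels).reindex(X.data.index)
    counts = labels.value_counts()
    small = counts[counts < config.min_class_size]
    if not small.empty:
        for cls, n in small.items():
            warnings.warn(
                f"class {cls!r} has {n} samples (< {config.min_class_size}); excluded"
            )
        keep = labels.isin(counts[counts >= config.min_class_size].index)
        X = FeatureMatrix(X.data.loc[keep.to_numpy()].copy(), X.metadata.copy())
        labels = labels[keep]
        if genders is not None:
            genders = genders.reindex(X.data.index)
    classes = sorted(labels.unique())
    if len(classes) < 2:
        raise ValueError("need at least 2 classes with enough samples")

    X, profile_set = _prepare_rmd_features(X, labels, config, seed)

    cv_probs = cross_validated_probabilities(
        X, labels, folds=config.calib_folds, seed=seed, config=config
    )
    if genders is not None:
        cv_probs = apply_gender_filter(cv_probs, genders, gender_rules)
    calibrators = fit_calibrators(cv_probs, labels)

    models = {}
    for k, cls in enumerate(classes):
        y = (labels == cls).to_numpy()
        models[cls] = train_class_model(
            X,
            y,
            class_name=cls,
            seed=_fold_seed(seed, 10_000, k),
            cap=config.feature_cap,
            grid_size=config.grid_size,
            grid_folds=config.grid_folds,
            grid_trees=config.grid_trees,
            n_trees=config.n_trees,
        )
    summaries = cohort_feature_summaries(X, labels)
    return Ensemble(
        classes=classes,
        models=models,
        calibrators=calibrators,
        gender_rules=gender_rules,
        profile_set=profile_set,
        feature_names=list(X.data.columns),
        cohort_summaries=summaries,
        config=config,
        seed=seed,
        cv_probs_raw=cv_probs,
    )
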