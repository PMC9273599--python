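"""Prediction and local-increment feature contributions.

The prediction pipeline is: raw per-class forest probability -> gender
filter -> isotonic calibration -> gender filter -> ranking. Explanations use
local increments: along each tree's root-to-leaf path, the change in the
node's positive-class fraction at a split is credited to the split feature;
averaged over trees these per-feature contributions plus the mean root
fraction (the baseline) reconstruct the raw forest probability exactly.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from primarysite.ensemble import Ensemble, apply_gender_filter
from primarysite.features.matrix import FeatureMatrix
from primarysite.training import TrainedBinaryModel

logger = logging.getLogger(__name__)


@dataclass
class PredictionResult:
    """Per-class probabilities at each pipeline stage, with rankings."""

    sample_id: str
    raw: pd.Series
    calibrated: pd.Series
    filtered: pd.Series
    ranking: list[str]  # classes by descending filtered probability

    @property
    def top1(self) -> str:
        return self.ranking[0]

    @property
    def top2(self) -> list[str]:
        return self.ranking[:2]

    @property
    def top3(self) -> list[str]:
        return self.ranking[:3]


def _rank(filtered: pd.Series) -> list[str]:
    # descending probability; ties broken lexicographically by class name
    return sorted(filtered.index, key=lambda c: (-filtered[c], c))


def predict_proba_table(
    ensemble: Ensemble,
    features: pd.DataFrame,
    genders: pd.Series | None = None,
) -> dict[str, pd.DataFrame]:
    """Raw, calibrated and filtered probability tables for many samples.

    Features missing from the ensemble's namespace are filled with 0 (with a
    warning); extra features are ignored.
    """
    features = _map_rmd_bins(ensemble, features)
    missing = [f for f in ensemble.feature_names if f not in features.columns]
    if missing:
        warnings.warn(
            f"{len(missing)} model features missing from input; filled with 0 "
            f"(e.g. {missing[:3]})"
        )
        features = features.copy()
        for f in missing:
            features[f] = 0.0
    features = features[ensemble.feature_names]
    raw = ensemble.raw_probabilities(features)
    if genders is None:
        genders = pd.Series("unknown", index=features.index)
    filtered_raw = apply_gender_filter(raw, genders, ensemble.gender_rules)
    calibrated = ensemble.calibrators.transform(filtered_raw)
    filtered = apply_gender_filter(calibrated, genders, ensemble.gender_rules)
    return {"raw": raw, "calibrated": calibrated, "filtered": filtered}


def _map_rmd_bins(ensemble: Ensemble, features: pd.DataFrame) -> pd.DataFrame:
    """Fit raw rmd_bin.* columns to the ensemble's profile set when needed."""
    if ensemble.profile_set is None:
        return features
    have_profiles = any(f in features.columns for f in ensemble.profile_set.names)
    bin_cols = [c for c in features.columns if c.startswith("rmd_bin.")]
    if have_profiles or not bin_cols:
        return features
    expected = list(ensemble.profile_set.profiles.columns)
    if set(bin_cols) != set(expected):
        raise ValueError(
            "rmd_bin.* columns do not match the bins the profiles were trained on"
        )
    from primarysite.profiles import fit_profile_matrix

    contributions = fit_profile_matrix(features[expected], ensemble.profile_set)
    return pd.concat([features.drop(columns=bin_cols), contributions], axis=1)


def predict(
    ensemble: Ensemble,
    features: pd.DataFrame | FeatureMatrix,
    genders: pd.Series | None = None,
) -> list[PredictionResult]:
    """Predict tissue of origin for each sample row."""
    if isinstance(features, FeatureMatrix):
        features = features.data
    tables = predict_proba_table(ensemble, features, genders)
    results = []
    for sid in features.index:
        filtered = tables["filtered"].loc[sid]
        results.append(
            PredictionResult(
                sample_id=str(sid),
                raw=tables["raw"].loc[sid],
                calibrated=tables["calibrated"].loc[sid],
                filtered=filtered,
                ranking=_rank(filtered),
            )
        )
    return results


def predictions_frame(results: list[PredictionResult]) -> pd.DataFrame:
    """Tabular prediction output: calibrated+filtered probabilities and top-3."""
    rows = {}
    for r in results:
        row = r.filtered.to_dict()
        row["top1"], row["top2"], row["top3"] = (r.ranking + [None] * 3)[:3]
        rows[r.sample_id] = row
    frame = pd.DataFrame.from_dict(rows, orient="index")
    frame.index.name = "sample_id"
    return frame


@dataclass
class FeatureContributionSet:
    """Signed per-feature contributions decomposing one forest probability."""

    class_name: str
    baseline: float
    contributions: pd.Series
    raw_probability: float

    @property
    def residual(self) -> float:
        return self.raw_probability - (self.baseline + self.contributions.sum())


def compute_feature_contributions(
    model: TrainedBinaryModel, feature_vector: pd.Series
) -> FeatureContributionSet:
    """Local-increment decomposition of one sample's raw forest probability.

    For each tree the sample's root-to-leaf path is followed; at every split
    the child-minus-parent positive-class fraction is credited to the split
    feature. Contributions are means over trees; baseline is the mean root
    fraction. baseline + sum(contributions) equals the raw probability.
    """
    missing = [f for f in model.features if f not in feature_vector.index]
    if missing:
        raise KeyError(f"feature vector lacks model features: {missing[:5]}")
    x = feature_vector[model.features].to_numpy(dtype=float).reshape(1, -1)
    n_features = len(model.features)
    pos = list(model.forest.classes_).index(1)
    totals = np.zeros(n_features)
    baseline = 0.0
    leaf_sum = 0.0
    for est in model.forest.estimators_:
        tree = est.tree_
        frac = tree.value[:, 0, pos] / np.maximum(tree.value[:, 0, :].sum(axis=1), 1e-300)
        node = 0
        baseline += frac[0]
        while tree.children_left[node] != -1:
            feat = tree.feature[node]
            if x[0, feat] <= tree.threshold[node]:
                child = tree.children_left[node]
            else:
                child = tree.children_right[node]
            totals[feat] += frac[child] - frac[node]
            node = child
        leaf_sum += frac[node]
    n_trees = len(model.forest.estimators_)
    contributions = pd.Series(totals / n_trees, index=model.features)
    return FeatureContributionSet(
        class_name=model.class_name,
        baseline=baseline / n_trees,
        contributions=contributions,
        raw_probability=leaf_sum / n_trees,
    )
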