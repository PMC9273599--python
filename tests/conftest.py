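"""Shared fixtures: toy genomes, synthetic cohorts and trained ensembles.

Everything is generated programmatically at test time; the heavier trained
ensembles are session-scoped so the end-to-end, calibration and report tests
share one training run.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from primarysite.ensemble import desk_scale_config, train_ensemble
from primarysite.features.matrix import FeatureMatrix
from primarysite.simulate import (
    example_cohort_config,
    generate_feature_cohort,
    make_toy_genome,
)


@pytest.fixture(scope="session")
def toy_genome():
    return make_toy_genome(seed=101)


@pytest.fixture(scope="session")
def small_cohort():
    """Four classes x 40 samples, feature level."""
    config = example_cohort_config(n_classes=4, samples_per_class=40)
    X, truth = generate_feature_cohort(config, seed=11)
    return config, X, truth


@pytest.fixture(scope="session")
def small_ensemble(small_cohort):
    """A quick trained ensemble for prediction/report/serialization tests."""
    _, X, truth = small_cohort
    config = desk_scale_config(calib_folds=3, n_trees=50, grid_trees=20)
    ensemble = train_ensemble(
        X, truth["class"], config=config, seed=5, genders=truth["gender"]
    )
    return ensemble, X, truth


@pytest.fixture(scope="session")
def learnability_cohort():
    """Eight classes x 150 samples with a deterministic 90/10 split."""
    config = example_cohort_config(n_classes=8, samples_per_class=150)
    X, truth = generate_feature_cohort(config, seed=23)
    rng = np.random.default_rng(23)
    holdout_ids = []
    for cls in truth["class"].unique():
        ids = truth.index[truth["class"] == cls].to_numpy()
        holdout_ids += list(rng.choice(ids, size=len(ids) // 10, replace=False))
    is_holdout = truth.index.isin(holdout_ids)
    X_train = FeatureMatrix(X.data.loc[~is_holdout].copy(), X.metadata.copy())
    X_test = FeatureMatrix(X.data.loc[is_holdout].copy(), X.metadata.copy())
    return config, X_train, X_test, truth


@pytest.fixture(scope="session")
def trained_split(learnability_cohort):
    """Ensemble trained on the 90% split of the eight-class cohort."""
    _, X_train, X_test, truth = learnability_cohort
    config = desk_scale_config()
    ensemble = train_ensemble(
        X_train,
        truth.loc[X_train.samples, "class"],
        config=config,
        seed=37,
        genders=truth.loc[X_train.samples, "gender"],
    )
    return ensemble, X_train, X_test, truth
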