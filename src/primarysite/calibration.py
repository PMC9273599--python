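"""Isotonic probability calibration for the one-vs-rest forests.

Random forests are typically overconfident near 0 and underconfident near 1,
with a bias that differs between forests, so their raw probabilities are not
comparable across classes. Per class, an isotonic (monotone non-decreasing)
regression is fitted on out-of-fold cross-validation probabilities against
the binary class indicator; after calibration a probability of 0.8 means an
~80% chance of the prediction being correct. Between fitted knots the map
interpolates linearly and outside the observed range it clamps to the
boundary values.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.isotonic import IsotonicRegression


@dataclass
class Calibrator:
    """A fitted monotone map from raw to calibrated probability."""

    model: IsotonicRegression

    def transform(self, raw: np.ndarray) -> np.ndarray:
        return self.model.predict(np.asarray(raw, dtype=float))

    @property
    def knots(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"raw": self.model.X_thresholds_, "calibrated": self.model.y_thresholds_}
        )

    @classmethod
    def from_knots(cls, knots: pd.DataFrame) -> "Calibrator":
        model = IsotonicRegression(y_min=0.0, y_max=1.0, out_of_bounds="clip")
        model.fit(knots["raw"].to_numpy(), knots["calibrated"].to_numpy())
        return cls(model)


@dataclass
class CalibratorSet:
    """One isotonic calibrator per class."""

    calibrators: dict[str, Calibrator]

    def transform(self, raw_probs: pd.DataFrame) -> pd.DataFrame:
        missing = set(raw_probs.columns) - set(self.calibrators)
        if missing:
            raise KeyError(f"no calibrator for classes: {sorted(missing)}")
        out = {}
        for cls in raw_probs.columns:
            out[cls] = self.calibrators[cls].transform(raw_probs[cls].to_numpy())
        return pd.DataFrame(out, index=raw_probs.index)


def fit_calibrator(raw: np.ndarray, labels: np.ndarray) -> Calibrator:
    """Fit one isotonic map (pool-adjacent-violators) of labels on raw scores."""
    raw = np.asarray(raw, dtype=float)
    labels = np.asarray(labels, dtype=float)
    model = IsotonicRegression(y_min=0.0, y_max=1.0, out_of_bounds="clip")
    model.fit(raw, labels)
    return Calibrator(model)


def fit_calibrators(cv_probs: pd.DataFrame, class_labels: pd.Series) -> CalibratorSet:
    """Fit per-class calibrators from out-of-fold probabilities.

    ``cv_probs`` holds one raw out-of-fold probability per (sample, class);
    the regression target for class c is the indicator (true label == c).
    """
    labels = pd.Series(class_labels).reindex(cv_probs.index)
    if labels.isna().any():
        raise ValueError("class labels missing for some samples")
    calibrators = {}
    for cls in cv_probs.columns:
        if cls not in set(labels):
            raise ValueError(f"class {cls!r} absent from labels")
        indicator = (labels == cls).to_numpy(dtype=float)
        calibrators[cls] = fit_calibrator(cv_probs[cls].to_numpy(), indicator)
    return CalibratorSet(calibrators)


def reliability_gap(
    probs: np.ndarray, outcomes: np.ndarray, n_bins: int = 10
) -> float:
    """Summed |empirical accuracy - mean probability| over equal-width bins.

    A calibration summary: 0 means each probability bin's mean prediction
    matches its empirical positive rate. Empty bins contribute 0.
    """
    probs = np.asarray(probs, dtype=float)
    outcomes = np.asarray(outcomes, dtype=float)
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    which = np.clip(np.digitize(probs, edges[1:-1]), 0, n_bins - 1)
    gap = 0.0
    for b in range(n_bins):
        in_bin = which == b
        if in_bin.any():
            gap += abs(outcomes[in_bin].mean() - probs[in_bin].mean())
    return float(gap)
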