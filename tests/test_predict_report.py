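"""Prediction pipeline, local-increment explanations and the patient report."""

import numpy as np
import pandas as pd
import pytest
from sklearn.ensemble import RandomForestClassifier

from primarysite.ensemble import GenderFilterRules, apply_gender_filter
from primarysite.predict import (
    PredictionResult,
    compute_feature_contributions,
    predict,
    predictions_frame,
)
from primarysite.report import (
    build_patient_report,
    render_report,
    report_for_sample,
    select_panel_classes,
)
from primarysite.training import TrainedBinaryModel, train_binary_rf


def _model_from_forest(forest, features, name="A"):
    return TrainedBinaryModel(
        class_name=name, features=features, forest=forest,
        resampling=None, selection=None, seed=0,
    )


class TestContributions:
    def test_single_split_tree_contribution(self):
        """Root at fraction 0.5, left leaf at 0.9: contribution is +0.4."""
        X = np.array([[0.0]] * 10 + [[1.0]] * 10)
        y = np.array([1] * 9 + [0] + [1] + [0] * 9)  # left: 9/10 pos, right: 1/10
        forest = RandomForestClassifier(
            n_estimators=1, max_depth=1, bootstrap=False, random_state=0
        ).fit(X, y)
        model = _model_from_forest(forest, ["sigs.f"])
        result = compute_feature_contributions(model, pd.Series({"sigs.f": 0.0}))
        assert result.baseline == pytest.approx(0.5)
        assert result.contributions["sigs.f"] == pytest.approx(0.4)
        assert result.raw_probability == pytest.approx(0.9)

    def test_rootonly_trees_have_zero_contributions(self):
        X = np.array([[0.0], [1.0], [0.5], [0.2]])
        y = np.array([1, 0, 1, 0])
        forest = RandomForestClassifier(
            n_estimators=5, max_depth=1, min_samples_split=10,
            bootstrap=False, random_state=0,
        ).fit(X, y)
        model = _model_from_forest(forest, ["sigs.f"])
        result = compute_feature_contributions(model, pd.Series({"sigs.f": 0.3}))
        assert (result.contributions == 0).all()
        assert result.baseline == pytest.approx(result.raw_probability)

    def test_additivity_reconstructs_forest_probability(self):
        rng = np.random.default_rng(1)
        features = [f"sigs.f{i}" for i in range(6)]
        X = pd.DataFrame(rng.normal(size=(80, 6)), columns=features)
        y = (X["sigs.f0"] + 0.5 * X["sigs.f1"] > 0).astype(int).to_numpy()
        model = train_binary_rf(X, y, seed=2, n_trees=40)
        for i in range(20):
            vec = pd.Series(rng.normal(size=6), index=features)
            result = compute_feature_contributions(model, vec)
            raw = model.predict_proba(vec.to_frame().T)[0]
            assert abs(result.baseline + result.contributions.sum() - raw) < 1e-9

    def test_unused_feature_has_exactly_zero_contribution(self):
        rng = np.random.default_rng(3)
        features = ["sigs.signal", "sigs.constant"]
        X = pd.DataFrame(
            {"sigs.signal": rng.normal(size=60), "sigs.constant": np.zeros(60)},
            columns=features,
        )
        y = (X["sigs.signal"] > 0).astype(int).to_numpy()
        model = train_binary_rf(X, y, seed=4, n_trees=30)
        vec = pd.Series({"sigs.signal": 1.0, "sigs.constant": 0.0})
        result = compute_feature_contributions(model, vec)
        assert result.contributions["sigs.constant"] == 0.0

    def test_missing_model_feature_rejected(self):
        X = pd.DataFrame({"sigs.a": [0.0, 1.0, 0.0, 1.0]})
        model = train_binary_rf(X, np.array([0, 1, 0, 1]), seed=5, n_trees=5)
        with pytest.raises(KeyError):
            compute_feature_contributions(model, pd.Series({"sigs.b": 1.0}))


class TestGenderFilter:
    def test_male_sample_zeroed_for_female_specific_classes(self):
        probs = pd.DataFrame(
            {"BreastLike": [0.9], "OvarianLike": [0.5], "CervixLike": [0.3],
             "ProstateLike": [0.2], "LungLike": [0.4]},
            index=["s1"],
        )
        out = apply_gender_filter(probs, pd.Series({"s1": "male"}))
        assert out.loc["s1", "BreastLike"] == 0.0
        assert out.loc["s1", "OvarianLike"] == 0.0
        assert out.loc["s1", "CervixLike"] == 0.0
        assert out.loc["s1", "ProstateLike"] == 0.2
        assert out.loc["s1", "LungLike"] == 0.4

    def test_female_sample_zeroed_for_prostate(self):
        probs = pd.DataFrame({"ProstateLike": [0.4], "BreastLike": [0.9]}, index=["s1"])
        out = apply_gender_filter(probs, pd.Series({"s1": "female"}))
        assert out.loc["s1", "ProstateLike"] == 0.0
        assert out.loc["s1", "BreastLike"] == 0.9

    def test_unknown_gender_unchanged(self):
        probs = pd.DataFrame({"BreastLike": [0.9]}, index=["s1"])
        out = apply_gender_filter(probs, pd.Series({"s1": "unknown"}))
        assert out.loc["s1", "BreastLike"] == 0.9


class TestPredictionPipeline:
    def test_ranking_is_descending_filtered_probability(self, small_ensemble):
        ensemble, X, truth = small_ensemble
        results = predict(ensemble, X.data.iloc[:5], truth["gender"].iloc[:5])
        for r in results:
            probs = [r.filtered[c] for c in r.ranking]
            assert probs == sorted(probs, reverse=True)

    def test_male_samples_have_zero_female_class_probability(self, small_ensemble):
        ensemble, X, truth = small_ensemble
        males = truth.index[truth["gender"] == "male"][:5]
        results = predict(ensemble, X.data.loc[males], truth.loc[males, "gender"])
        female_classes = [
            c for c in ensemble.classes
            if c.lower().startswith(("breast", "ovar", "cervix"))
        ]
        assert female_classes
        for r in results:
            for c in female_classes:
                assert r.filtered[c] == 0.0

    def test_archetype_samples_rank_their_class_first(self, small_ensemble):
        ensemble, X, truth = small_ensemble
        results = predict(ensemble, X.data, truth["gender"])
        frame = predictions_frame(results)
        accuracy = (frame["top1"] == truth["class"]).mean()
        assert accuracy > 0.9  # training-set sanity, archetypes well separated


def _fake_prediction(probs: dict) -> PredictionResult:
    s = pd.Series(probs, dtype=float)
    ranking = sorted(s.index, key=lambda c: (-s[c], c))
    return PredictionResult("sX", s, s, s, ranking)


class TestReport:
    def test_confident_top_class_yields_single_panel(self):
        pred = _fake_prediction({"A": 0.96, "B": 0.05, "C": 0.01})
        assert select_panel_classes(pred) == ["A"]

    def test_close_runner_up_yields_two_panels(self):
        pred = _fake_prediction({"A": 0.78, "B": 0.75, "C": 0.05})
        assert select_panel_classes(pred) == ["A", "B"]

    def test_many_high_classes_capped_at_three_panels(self):
        pred = _fake_prediction({"A": 0.8, "B": 0.79, "C": 0.78, "D": 0.77})
        assert select_panel_classes(pred) == ["A", "B", "C"]

    def test_report_features_sorted_by_absolute_contribution(self, small_ensemble):
        ensemble, X, truth = small_ensemble
        sid = X.samples[0]
        result = predict(ensemble, X.data.loc[[sid]], truth.loc[[sid], "gender"])[0]
        report = report_for_sample(ensemble, result, X.data.loc[sid])
        assert 1 <= len(report.panels) <= 3
        for panel in report.panels:
            magnitudes = panel.features["contribution"].abs().tolist()
            assert magnitudes == sorted(magnitudes, reverse=True)

    def test_text_rendering_is_deterministic(self, small_ensemble):
        ensemble, X, truth = small_ensemble
        sid = X.samples[0]
        result = predict(ensemble, X.data.loc[[sid]], truth.loc[[sid], "gender"])[0]
        report = report_for_sample(ensemble, result, X.data.loc[sid])
        a = render_report(report, format="text")
        b = render_report(report, format="text")
        assert a == b
        assert sid in a

    def test_hide_values_option_removes_value_panel(self, small_ensemble):
        ensemble, X, truth = small_ensemble
        sid = X.samples[0]
        result = predict(ensemble, X.data.loc[[sid]], truth.loc[[sid], "gender"])[0]
        report = report_for_sample(ensemble, result, X.data.loc[sid])
        with_values = render_report(report, format="text", show_values=True)
        without = render_report(report, format="text", show_values=False)
        assert "rest mean" in with_values
        assert "rest mean" not in without

    def test_all_zero_probabilities_render_banner(self):
        from primarysite.report import PatientReport

        report = PatientReport("sX", pd.Series({"A": 0.0, "B": 0.0}))
        text = render_report(report, format="text")
        assert "NO CONFIDENT CLASS" in text

    def test_figure_rendering_writes_file(self, tmp_path):
        from primarysite.report import ClassPanel, PatientReport

        panel = ClassPanel(
            class_name="A",
            probability=0.9,
            features=pd.DataFrame(
                {
                    "feature": ["sigs.SBS1", "gene.TP53.amp"],
                    "contribution": [0.3, -0.1],
                    "patient_value": [0.5, 1.0],
                    "mean_class": [0.4, 0.6],
                    "mean_rest": [0.1, 0.05],
                }
            ),
        )
        report = PatientReport("sX", pd.Series({"A": 0.9, "B": 0.1}), [panel])
        out = tmp_path / "report.png"
        render_report(report, format="figure", path=out)
        assert out.exists() and out.stat().st_size > 0

    def test_unknown_format_rejected(self):
        from primarysite.report import PatientReport

        report = PatientReport("sX", pd.Series({"A": 1.0}))
        with pytest.raises(ValueError, match="unknown report format"):
            render_report(report, format="pdf")
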