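"""Patient-level prediction report.

The report mirrors a clinical summary: a probability panel over all cancer
types, and for the top predicted type(s) a panel of the features that
contributed most to the probability, alongside the patient's feature value,
the mean among training patients of the target type, and the mean among all
other training samples. When the ranking is uncertain (runner-up
probabilities close to the top), up to three class panels are shown.
"""

from __future__ import annotations

import html as _html
from dataclasses import dataclass, field

import pandas as pd

from primarysite.ensemble import Ensemble
from primarysite.features.matrix import is_boolean_feature
from primarysite.predict import (
    FeatureContributionSet,
    PredictionResult,
    compute_feature_contributions,
)

#: Extra class panels are included when their calibrated probability is at
#: least max(PANEL_MIN_PROB, PANEL_RELATIVE * top probability); at most 3.
PANEL_MIN_PROB = 0.2
PANEL_RELATIVE = 0.5
MAX_PANELS = 3


@dataclass
class ClassPanel:
    """Top contributing features of one candidate class for one patient."""

    class_name: str
    probability: float
    features: pd.DataFrame  # feature, contribution, patient_value, mean_class, mean_rest


@dataclass
class PatientReport:
    sample_id: str
    probabilities: pd.Series  # filtered, all classes, descending
    panels: list[ClassPanel] = field(default_factory=list)


def select_panel_classes(prediction: PredictionResult) -> list[str]:
    """Classes whose panels are shown, per the uncertainty rule."""
    ranking = prediction.ranking
    top_prob = float(prediction.filtered[ranking[0]])
    panels = [ranking[0]]
    threshold = max(PANEL_MIN_PROB, PANEL_RELATIVE * top_prob)
    for cls in ranking[1:MAX_PANELS]:
        if prediction.filtered[cls] >= threshold:
            panels.append(cls)
    return panels


def build_patient_report(
    prediction: PredictionResult,
    contributions: dict[str, FeatureContributionSet],
    cohort_summaries: pd.DataFrame,
    top_n_features: int = 10,
) -> PatientReport:
    """Assemble the report object from a prediction and its explanations.

    ``contributions`` must cover at least the classes chosen by the panel
    rule; ``cohort_summaries`` holds the per-class and rest-of-cohort
    feature means stored in the ensemble at training time.
    """
    order = prediction.ranking
    probabilities = prediction.filtered[order]
    panels = []
    for cls in select_panel_classes(prediction):
        contrib_set = contributions[cls]
        ranked = contrib_set.contributions.reindex(
            contrib_set.contributions.abs().sort_values(ascending=False).index
        )
        ranked = ranked[ranked != 0].head(top_n_features)
        rows = []
        for feat, contribution in ranked.items():
            mean_cls = cohort_summaries.get(f"mean.{cls}", pd.Series()).get(feat)
            mean_rest = cohort_summaries.get(f"mean_rest.{cls}", pd.Series()).get(feat)
            rows.append(
                {
                    "feature": feat,
                    "contribution": float(contribution),
                    "patient_value": None,  # filled by report_for_sample
                    "mean_class": None if mean_cls is None else float(mean_cls),
                    "mean_rest": None if mean_rest is None else float(mean_rest),
                }
            )
        panels.append(
            ClassPanel(
                class_name=cls,
                probability=float(prediction.filtered[cls]),
                features=pd.DataFrame(
                    rows,
                    columns=["feature", "contribution", "patient_value",
                             "mean_class", "mean_rest"],
                ),
            )
        )
    return PatientReport(
        sample_id=prediction.sample_id, probabilities=probabilities, panels=panels
    )


def report_for_sample(
    ensemble: Ensemble,
    prediction: PredictionResult,
    feature_vector: pd.Series,
    top_n_features: int = 10,
) -> PatientReport:
    """Convenience wrapper: compute contributions for the panel classes."""
    from primarysite.predict import _map_rmd_bins

    mapped = _map_rmd_bins(ensemble, feature_vector.to_frame().T)
    feature_vector = mapped.iloc[0]
    contributions = {}
    for cls in select_panel_classes(prediction):
        contributions[cls] = compute_feature_contributions(
            ensemble.models[cls], feature_vector
        )
    report = build_patient_report(
        prediction, contributions, ensemble.cohort_summaries, top_n_features
    )
    for panel in report.panels:
        panel.features["patient_value"] = [
            float(feature_vector.get(f, 0.0)) for f in panel.features["feature"]
        ]
    return report


# ---------------------------------------------------------------------------
# Rendering


def _format_value(feature: str, value, is_mean: bool = False) -> str:
    if value is None:
        return "."
    if is_boolean_feature(feature):
        if is_mean:  # cohort means of booleans are prevalences
            return f"{value:.0%}"
        return "present" if value >= 0.5 else "absent"
    return f"{value:.4g}"


def render_report(
    report: PatientReport,
    format: str = "text",
    path=None,
    show_contributions: bool = True,
    show_values: bool = True,
):
    """Render a report deterministically as text, HTML or a matplotlib figure.

    ``path`` writes the output to a file (required for ``figure``); for text
    and HTML the rendered string is also returned. The contribution and
    feature-value panels can each be hidden.
    """
    if format == "text":
        out = _render_text(report, show_contributions, show_values)
    elif format == "html":
        out = _render_html(report, show_contributions, show_values)
    elif format == "figure":
        if path is None:
            raise ValueError("figure format requires a path")
        _render_figure(report, path, show_contributions, show_values)
        return None
    else:
        raise ValueError(f"unknown report format {format!r}")
    if path is not None:
        with open(path, "w") as fh:
            fh.write(out)
    return out


def _render_text(report: PatientReport, show_contributions: bool, show_values: bool) -> str:
    lines = [f"Tissue-of-origin report for sample {report.sample_id}", "=" * 60, ""]
    lines.append("Cancer type probabilities (calibrated, gender-filtered):")
    for cls, p in report.probabilities.items():
        bar = "#" * int(round(20 * p))
        lines.append(f"  {cls:<28s} {p:6.3f} {bar}")
    lines.append("")
    if float(report.probabilities.max()) == 0.0:
        lines.append("NO CONFIDENT CLASS: all probabilities are 0 after filtering.")
        return "\n".join(lines) + "\n"
    for panel in report.panels:
        lines.append(
            f"Top features for {panel.class_name} (probability {panel.probability:.3f}):"
        )
        for row in panel.features.itertuples(index=False):
            parts = [f"  {row.feature:<34s}"]
            if show_contributions:
                parts.append(f"contribution {row.contribution:+.4f}")
            if show_values:
                parts.append(
                    "patient "
                    + _format_value(row.feature, row.patient_value)
                    + f" | {panel.class_name} mean "
                    + _format_value(row.feature, row.mean_class, is_mean=True)
                    + " | rest mean "
                    + _format_value(row.feature, row.mean_rest, is_mean=True)
                )
            lines.append("  ".join(parts))
        lines.append("")
    return "\n".join(lines) + "\n"


def _render_html(report: PatientReport, show_contributions: bool, show_values: bool) -> str:
    esc = _html.escape
    parts = [
        "<html><head><meta charset='utf-8'>",
        f"<title>Report {esc(report.sample_id)}</title></head><body>",
        f"<h1>Tissue-of-origin report: {esc(report.sample_id)}</h1>",
        "<h2>Cancer type probabilities</h2><table border='1'>",
        "<tr><th>Cancer type</th><th>Probability</th></tr>",
    ]
    for cls, p in report.probabilities.items():
        parts.append(f"<tr><td>{esc(str(cls))}</td><td>{p:.3f}</td></tr>")
    parts.append("</table>")
    if float(report.probabilities.max()) == 0.0:
        parts.append("<p><b>No confident class</b>: all probabilities are 0 after filtering.</p>")
    for panel in report.panels:
        parts.append(
            f"<h2>{esc(panel.class_name)} (probability {panel.probability:.3f})</h2>"
        )
        headers = ["Feature"]
        if show_contributions:
            headers.append("Contribution")
        if show_values:
            headers += ["Patient value", "Class mean", "Rest mean"]
        parts.append(
            "<table border='1'><tr>"
            + "".join(f"<th>{h}</th>" for h in headers)
            + "</tr>"
        )
        for row in panel.features.itertuples(index=False):
            cells = [esc(row.feature)]
            if show_contributions:
                cells.append(f"{row.contribution:+.4f}")
            if show_values:
                cells += [
                    _format_value(row.feature, row.patient_value),
                    _format_value(row.feature, row.mean_class, is_mean=True),
                    _format_value(row.feature, row.mean_rest, is_mean=True),
                ]
            parts.append(
                "<tr>" + "".join(f"<td>{c}</td>" for c in cells) + "</tr>"
            )
        parts.append("</table>")
    parts.append("</body></html>")
    return "".join(parts)


def _render_figure(report: PatientReport, path, show_contributions: bool, show_values: bool) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    n_panels = max(1, len(report.panels))
    n_cols = 1 + int(show_contributions) + int(show_values)
    fig, axes = plt.subplots(
        n_panels, n_cols, figsize=(4.5 * n_cols, 2.2 + 2.2 * n_panels), squeeze=False
    )
    probs = report.probabilities[::-1]
    axes[0][0].barh(range(len(probs)), probs.values, color="#555555")
    axes[0][0].set_yticks(range(len(probs)), [str(c) for c in probs.index], fontsize=7)
    axes[0][0].set_xlim(0, 1)
    axes[0][0].set_title(f"{report.sample_id}: probabilities", fontsize=9)
    for r in range(1, n_panels):
        axes[r][0].axis("off")
    for r, panel in enumerate(report.panels):
        col = 1
        feats = panel.features["feature"].tolist()[::-1]
        if show_contributions:
            ax = axes[r][col]
            ax.barh(
                range(len(feats)),
                panel.features["contribution"].tolist()[::-1],
                color="#aa3333",
            )
            ax.set_yticks(range(len(feats)), feats, fontsize=6)
            ax.set_title(f"{panel.class_name} contributions", fontsize=8)
            col += 1
        if show_values:
            ax = axes[r][col]
            y = range(len(feats))
            rev = panel.features.iloc[::-1]
            ax.scatter(rev["patient_value"], y, color="red", label="patient", s=14)
            ax.scatter(rev["mean_class"], y, color="pink", label="class mean", s=14)
            ax.scatter(rev["mean_rest"], y, color="steelblue", label="rest mean", s=14)
            ax.set_yticks(y, feats, fontsize=6)
            ax.set_title("feature values", fontsize=8)
            if r == 0:
                ax.legend(fontsize=6)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
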