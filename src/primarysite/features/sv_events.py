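"""Boolean and count features from SV clusters, drivers, fusions and viruses.

Structural-variant clusters are summarized into burden features (total load,
length-stratified deletion/duplication counts, size-stratified complex-event
counts, LINE insertions, double minutes, and the breakend count of the
largest complex cluster as a chromothripsis proxy). Driver, fusion and
viral-insertion events become presence/absence features, subject to a
preliminary association screen against the class labels.
"""

from __future__ import annotations

import logging
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import fisher_exact

from primarysite.features.records import DRIVER_TYPES, EventRecord, SVClusterRecord
from primarysite.stats import cramers_v_2x2

logger = logging.getLogger(__name__)

#: DEL/DUP length bins (bp, half-open); lengths under 1 kb count in the first bin.
SV_LENGTH_BIN_EDGES = (1e3, 1e4, 1e5, 1e6, 1e7, np.inf)
SV_LENGTH_BIN_LABELS = ("1e3_1e4", "1e4_1e5", "1e5_1e6", "1e6_1e7", "1e7_Inf")

#: COMPLEX cluster size bins (number of SVs in the cluster, half-open [lo, hi)).
SV_COMPLEX_SIZE_EDGES = (0, 25, 50, 100, 200, 400, 800, np.inf)
SV_COMPLEX_SIZE_LABELS = (
    "0_25", "25_50", "50_100", "100_200", "200_400", "400_800", "800_Inf",
)

#: The nine virus categories strains are merged into.
VIRUS_CATEGORIES = ("AAV", "EBV", "HBV", "HCV", "HIV", "HPV", "HSV", "HTLV", "MCPyV")

#: Keyword -> category map for free-text virus strain names (lowercased match).
DEFAULT_VIRUS_KEYWORDS: Mapping[str, str] = {
    "adeno-associated": "AAV",
    "epstein": "EBV",
    "hepatitis b": "HBV",
    "hepatitis c": "HCV",
    "immunodeficiency": "HIV",
    "papillomavirus": "HPV",
    "herpes simplex": "HSV",
    "t-lymphotropic": "HTLV",
    "merkel": "MCPyV",
}

MONOALLELIC_LIKELIHOOD_MIN = 0.9


def sv_feature_names() -> list[str]:
    names = ["sv.load"]
    names += [f"sv.DEL.{b}" for b in SV_LENGTH_BIN_LABELS]
    names += [f"sv.DUP.{b}" for b in SV_LENGTH_BIN_LABELS]
    names += [f"sv.COMPLEX.{b}" for b in SV_COMPLEX_SIZE_LABELS]
    names += ["sv.COMPLEX.largest_cluster", "sv.LINE", "sv.double_minutes"]
    return names


def _length_bin(length: int) -> str:
    edges = SV_LENGTH_BIN_EDGES
    for i, label in enumerate(SV_LENGTH_BIN_LABELS):
        if length < edges[i + 1]:
            return label
    raise AssertionError("unreachable")


def _complex_bin(n_sv: int) -> str:
    edges = SV_COMPLEX_SIZE_EDGES
    for i, label in enumerate(SV_COMPLEX_SIZE_LABELS):
        if edges[i] <= n_sv < edges[i + 1]:
            return label
    raise AssertionError("unreachable")


def encode_sv_features(clusters: Sequence[SVClusterRecord]) -> pd.Series:
    """Numeric ``sv.*`` burden features from SV clusters."""
    feats = pd.Series(0.0, index=sv_feature_names())
    largest = 0
    for cl in clusters:
        feats["sv.load"] += 1
        rtype = cl.resolved_type
        if rtype in ("DEL", "DUP"):
            feats[f"sv.{rtype}.{_length_bin(cl.length_bp)}"] += 1
        elif rtype == "COMPLEX":
            feats[f"sv.COMPLEX.{_complex_bin(cl.n_sv)}"] += 1
            largest = max(largest, cl.n_breakends)
        elif rtype == "LINE":
            feats["sv.LINE"] += 1
        elif rtype == "DOUBLE_MINUTE":
            feats["sv.double_minutes"] += 1
        elif rtype != "OTHER":
            logger.warning("unknown SV resolved_type %r counted only in sv.load", rtype)
    feats["sv.COMPLEX.largest_cluster"] = largest
    return feats


def driver_feature_names(gene_catalog: Sequence[str]) -> list[str]:
    return [f"gene.{g}.{t}" for g in gene_catalog for t in DRIVER_TYPES]


def encode_driver_features(
    events: Iterable[EventRecord], gene_catalog: Sequence[str]
) -> pd.Series:
    """Boolean ``gene.*`` features: one per (catalog gene, driver type).

    Monoallelic hits require a driver likelihood of at least 0.9; the other
    event types (amplification, deep deletion, biallelic loss) count by
    presence. Genes outside the catalog are ignored with a warning.
    """
    catalog = set(gene_catalog)
    feats = pd.Series(0, index=driver_feature_names(gene_catalog), dtype=int)
    for ev in events:
        if ev.kind != "driver":
            continue
        if ev.name not in catalog:
            logger.warning("driver gene %s not in catalog; ignored", ev.name)
            continue
        if (
            ev.driver_type == "monoallelic"
            and (ev.driver_likelihood or 0.0) < MONOALLELIC_LIKELIHOOD_MIN
        ):
            continue
        feats[f"gene.{ev.name}.{ev.driver_type}"] = 1
    return feats


def fusion_feature_names(
    known_pairs: Sequence[str], promiscuous: Sequence[str]
) -> list[str]:
    names = [f"fusion.{p}" for p in known_pairs]
    names.append("fusion.IGH")
    for g in promiscuous:
        names += [f"fusion.{g}_*", f"fusion.*_{g}"]
    return sorted(set(names))


def encode_fusion_and_viral_features(
    events: Iterable[EventRecord],
    known_pairs: Sequence[str] = (),
    promiscuous: Sequence[str] = (),
    virus_keywords: Mapping[str, str] | None = None,
) -> pd.Series:
    """Boolean ``fusion.*`` and ``viral_ins.*`` features.

    Fusions named "A_B" set the known-pair feature when cataloged; any fusion
    involving the immunoglobulin heavy-chain locus sets ``fusion.IGH``; a
    promiscuous 5' partner G sets ``fusion.G_*`` and a promiscuous 3' partner
    sets ``fusion.*_G`` (both when both partners are promiscuous). Virus
    strains are mapped into nine categories by keyword.
    """
    if virus_keywords is None:
        virus_keywords = DEFAULT_VIRUS_KEYWORDS
    names = fusion_feature_names(known_pairs, promiscuous) + [
        f"viral_ins.{v}" for v in VIRUS_CATEGORIES
    ]
    feats = pd.Series(0, index=names, dtype=int)
    known = set(known_pairs)
    prom = set(promiscuous)
    for ev in events:
        if ev.kind == "fusion":
            name = ev.name
            if name == "IGH" or name.startswith("IGH_") or name.endswith("_IGH"):
                feats["fusion.IGH"] = 1
                continue
            if name in known:
                feats[f"fusion.{name}"] = 1
                continue
            if "_" in name:
                g5, g3 = name.split("_", 1)
                hit = False
                if g5 in prom:
                    feats[f"fusion.{g5}_*"] = 1
                    hit = True
                if g3 in prom:
                    feats[f"fusion.*_{g3}"] = 1
                    hit = True
                if not hit:
                    logger.warning("fusion %s not in catalog; ignored", name)
        elif ev.kind == "viral":
            category = _map_virus(ev.name, virus_keywords)
            if category is None:
                logger.warning("unmapped virus strain %r; feature untouched", ev.name)
            else:
                feats[f"viral_ins.{category}"] = 1
    return feats


def _map_virus(strain: str, keywords: Mapping[str, str]) -> str | None:
    if strain in VIRUS_CATEGORIES:
        return strain
    low = strain.lower()
    for key, category in keywords.items():
        if key in low:
            return category
    return None


def preliminary_screen_boolean_features(
    bool_matrix: pd.DataFrame,
    class_labels: pd.Series,
    p_threshold: float = 0.01,
    v_threshold: float = 0.1,
    gene_level: bool = True,
) -> tuple[list[str], pd.DataFrame]:
    """Screen boolean features for any-class enrichment before training.

    For every feature and class a one-sided Fisher exact test (presence
    enriched in the class) and Cramer's V on the 2x2 table are computed; a
    feature is retained iff some class reaches p < 0.01 and V >= 0.1.
    ``gene.*`` features are retained at gene level: if any of a gene's
    driver-type features passes, all four are kept.

    Returns the retained feature names and the per-(feature, class) test
    table (columns: feature, class, p_value, cramers_v).
    """
    labels = pd.Series(class_labels).reindex(bool_matrix.index)
    if labels.isna().any():
        raise ValueError("class labels missing for some samples")
    classes = sorted(labels.unique())
    if len(classes) < 2:
        raise ValueError("need at least 2 classes for screening")
    rows = []
    passing: set[str] = set()
    for feat in bool_matrix.columns:
        x = bool_matrix[feat].to_numpy().astype(bool)
        if x.all() or not x.any():
            continue  # constant feature: automatically dropped
        for cls in classes:
            in_cls = (labels == cls).to_numpy()
            a = int(np.sum(x & in_cls))
            b = int(np.sum(x & ~in_cls))
            c = int(np.sum(~x & in_cls))
            d = int(np.sum(~x & ~in_cls))
            _, p = fisher_exact([[a, b], [c, d]], alternative="greater")
            v = cramers_v_2x2(np.array([[a, b], [c, d]]))
            rows.append((feat, cls, p, v))
            if p < p_threshold and v >= v_threshold:
                passing.add(feat)
    if gene_level:
        genes = {
            f.split(".")[1] for f in passing if f.startswith("gene.") and f.count(".") >= 2
        }
        for feat in bool_matrix.columns:
            if feat.startswith("gene.") and feat.count(".") >= 2:
                if feat.split(".")[1] in genes:
                    passing.add(feat)
    retained = [f for f in bool_matrix.columns if f in passing]
    stats = pd.DataFrame(rows, columns=["feature", "class", "p_value", "cramers_v"])
    return retained, stats
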