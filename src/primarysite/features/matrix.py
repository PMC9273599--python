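"""The sample x feature matrix and its metadata.

Feature names follow the grammar ``{feature_type}.{feature_name}`` with
feature types ``rmd, sigs, mut_load, gene, chrom_arm, genome, gender, sv,
fusion, viral_ins`` (plus the internal ``rmd_bin`` type holding raw regional
mutational density bins before profile extraction). Per-feature metadata
records whether a feature is boolean and the sidedness of its univariate
test.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from primarysite.features.records import SampleMeta

FEATURE_TYPES = (
    "rmd", "sigs", "mut_load", "gene", "chrom_arm", "genome", "gender",
    "sv", "fusion", "viral_ins", "rmd_bin",
)

BOOLEAN_TYPES = frozenset({"gene", "fusion", "viral_ins", "gender"})
#: genome.wgd is boolean despite living in a numeric family.
BOOLEAN_FEATURES = frozenset({"genome.wgd"})

#: Default univariate-test sidedness by family: burden/presence features are
#: tested for enrichment in the case class; ploidy-type features two-sided.
DEFAULT_SIDEDNESS: Mapping[str, str] = {
    "rmd": "greater", "sigs": "greater", "mut_load": "greater",
    "gene": "greater", "fusion": "greater", "viral_ins": "greater",
    "sv": "greater", "gender": "greater",
    "chrom_arm": "two-sided", "genome": "two-sided", "rmd_bin": "greater",
}

MIN_SMALL_VARIANTS = 50
MIN_PURITY = 0.2


def feature_type(name: str) -> str:
    ftype = name.split(".", 1)[0]
    if ftype not in FEATURE_TYPES:
        raise ValueError(f"feature {name!r} has unknown feature type {ftype!r}")
    return ftype


def is_boolean_feature(name: str) -> bool:
    return name in BOOLEAN_FEATURES or feature_type(name) in BOOLEAN_TYPES


def feature_sidedness(name: str) -> str:
    return DEFAULT_SIDEDNESS[feature_type(name)]


@dataclass
class FeatureMatrix:
    """Samples x named features with per-feature metadata.

    ``data`` holds one row per sample (index = sample ids) and one column per
    feature, with no missing values. ``metadata`` is indexed by feature name
    with columns ``feature_type``, ``is_boolean`` and ``sidedness``.
    """

    data: pd.DataFrame
    metadata: pd.DataFrame = field(default=None)

    def __post_init__(self) -> None:
        if self.data.isna().any().any():
            raise ValueError("feature matrix contains missing values")
        if self.data.index.duplicated().any():
            raise ValueError("duplicate sample ids")
        if self.metadata is None:
            self.metadata = default_metadata(self.data.columns)
        mask = (
            self.metadata["is_boolean"]
            .reindex(self.data.columns)
            .fillna(False)
            .astype(bool)
            .to_numpy()
        )
        for name in self.data.columns[mask]:
            vals = self.data[name]
            if not vals.isin([0, 1]).all():
                raise ValueError(f"boolean feature {name} has values outside {{0,1}}")

    @property
    def samples(self) -> list[str]:
        return list(self.data.index)

    @property
    def features(self) -> list[str]:
        return list(self.data.columns)

    def subset_features(self, names: Iterable[str]) -> "FeatureMatrix":
        names = list(names)
        return FeatureMatrix(self.data[names].copy(), self.metadata.loc[names].copy())

    def drop_feature_types(self, types: Iterable[str]) -> "FeatureMatrix":
        drop = set(types)
        keep = [f for f in self.features if feature_type(f) not in drop]
        return self.subset_features(keep)

    def to_tsv(self, data_path, metadata_path=None) -> None:
        self.data.to_csv(data_path, sep="\t", index_label="sample_id")
        if metadata_path is not None:
            self.metadata.to_csv(metadata_path, sep="\t", index_label="feature")

    @classmethod
    def from_tsv(cls, data_path, metadata_path=None) -> "FeatureMatrix":
        data = pd.read_csv(data_path, sep="\t", index_col="sample_id")
        meta = (
            pd.read_csv(metadata_path, sep="\t", index_col="feature")
            if metadata_path is not None
            else None
        )
        return cls(data, meta)


def default_metadata(feature_names: Iterable[str]) -> pd.DataFrame:
    names = list(feature_names)
    return pd.DataFrame(
        {
            "feature_type": [feature_type(f) for f in names],
            "is_boolean": [is_boolean_feature(f) for f in names],
            "sidedness": [feature_sidedness(f) for f in names],
        },
        index=pd.Index(names, name="feature"),
    )


def sort_feature_columns(names: Iterable[str]) -> list[str]:
    """Deterministic column order: by feature type (grammar order), then name."""
    order = {t: i for i, t in enumerate(FEATURE_TYPES)}
    return sorted(names, key=lambda f: (order[feature_type(f)], f))


def check_inclusion(meta: SampleMeta, n_small_variants: int) -> None:
    """Raise if a sample fails the cohort inclusion filters.

    Samples need at least 50 SNVs+indels and tumor purity >= 0.2; below
    either threshold somatic calls are too sparse or unreliable.
    """
    if n_small_variants < MIN_SMALL_VARIANTS:
        raise ValueError(
            f"sample {meta.sample_id} has {n_small_variants} SNVs/indels "
            f"(< {MIN_SMALL_VARIANTS}); excluded by inclusion filter"
        )
    if meta.purity < MIN_PURITY:
        raise ValueError(
            f"sample {meta.sample_id} purity {meta.purity} < {MIN_PURITY}; "
            "excluded by inclusion filter"
        )


def assemble_feature_matrix(
    per_sample: Mapping[str, pd.Series],
    metadata: pd.DataFrame | None = None,
) -> FeatureMatrix:
    """Assemble per-sample feature vectors into one matrix.

    The feature set is the union across samples; features absent from a
    sample are filled with 0 (absence for booleans, zero burden for counts).
    Columns are ordered deterministically by feature type then name, so the
    same inputs always serialize to the same file.
    """
    ids = list(per_sample)
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate sample ids")
    frame = pd.DataFrame.from_dict(
        {sid: vec.astype(float) for sid, vec in per_sample.items()}, orient="index"
    )
    frame = frame.fillna(0.0)
    frame = frame[sort_feature_columns(frame.columns)]
    frame.index.name = "sample_id"
    if metadata is not None:
        metadata = metadata.loc[frame.columns]
    return FeatureMatrix(frame, metadata)
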