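"""End-to-end per-sample feature extraction.

Bundles the individual encoders into one pass over a sample's raw inputs
(mutations, copy-number segments, SV clusters, events, metadata) and produces
the named feature vector consumed by training and prediction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import pandas as pd

from primarysite.features.contexts import count_mutation_contexts
from primarysite.features.copynumber import (
    compute_arm_copy_number,
    compute_genome_properties,
)
from primarysite.features.matrix import (
    FeatureMatrix,
    assemble_feature_matrix,
    check_inclusion,
)
from primarysite.features.records import SampleInputs
from primarysite.features.rmd import compute_rmd_bins, rmd_bin_feature_names
from primarysite.features.signatures import fit_signature_exposures
from primarysite.features.sv_events import (
    encode_driver_features,
    encode_fusion_and_viral_features,
    encode_sv_features,
)


@dataclass
class FeatureCatalog:
    """Reference tables shared by every sample: bins, arms, catalogs.

    The bin and arm tables and the signature catalogs must be identical
    between training and prediction.
    """

    bin_table: pd.DataFrame
    arm_table: pd.DataFrame
    signature_catalogs: Mapping[str, pd.DataFrame]  # scheme -> contexts x sigs
    gene_catalog: Sequence[str] = ()
    known_fusion_pairs: Sequence[str] = ()
    promiscuous_genes: Sequence[str] = ()
    virus_keywords: Mapping[str, str] | None = None
    merge_map: Mapping[str, tuple[str, ...]] | None = None


def extract_sample_features(
    inputs: SampleInputs,
    genome,
    catalog: FeatureCatalog,
    enforce_inclusion: bool = True,
) -> pd.Series:
    """Feature vector of one sample (named per the {type}.{name} grammar).

    Raw regional-mutational-density bins appear as ``rmd_bin.*`` columns;
    profile extraction (the ``rmd.*`` features) happens at training time.
    """
    parts: list[pd.Series] = []
    n_small = sum(1 for m in inputs.mutations if m.is_snv or m.is_indel)
    if enforce_inclusion:
        check_inclusion(inputs.meta, n_small)

    loads = {}
    for scheme, prefix in (("SBS96", "snv"), ("DBS78", "dbs"), ("ID83", "indel")):
        counts = count_mutation_contexts(inputs.mutations, genome, scheme)
        loads[prefix] = int(counts.sum())
        sig_catalog = catalog.signature_catalogs.get(scheme)
        if sig_catalog is not None:
            _, normalized = fit_signature_exposures(
                counts, sig_catalog, catalog.merge_map
            )
            normalized.index = [f"sigs.{n}" for n in normalized.index]
            parts.append(normalized)
    parts.append(
        pd.Series(
            {f"mut_load.{k}": float(v) for k, v in loads.items()}
        )
    )

    rmd = compute_rmd_bins(inputs.mutations, catalog.bin_table)
    parts.append(pd.Series(rmd, index=rmd_bin_feature_names(catalog.bin_table)))

    if inputs.cn_segments:
        arm = compute_arm_copy_number(inputs.cn_segments, catalog.arm_table)
        parts.append(
            pd.Series(
                {f"chrom_arm.{a}": v for a, v in arm.fold_change.items()}
            )
        )
        props = compute_genome_properties(inputs.cn_segments, inputs.meta)
        parts.append(
            pd.Series(
                {
                    "genome.ploidy": props["genome_ploidy"],
                    "genome.diploid_proportion": props["diploid_proportion"],
                    "genome.wgd": float(props["wgd_flag"]),
                }
            )
        )
        gender = props["gender"]
    else:
        gender = inputs.meta.gender
    parts.append(pd.Series({"gender.male": 1.0 if gender == "male" else 0.0}))

    parts.append(encode_sv_features(inputs.sv_clusters))
    if catalog.gene_catalog:
        parts.append(encode_driver_features(inputs.events, catalog.gene_catalog))
    parts.append(
        encode_fusion_and_viral_features(
            inputs.events,
            catalog.known_fusion_pairs,
            catalog.promiscuous_genes,
            catalog.virus_keywords,
        )
    )
    vec = pd.concat(parts)
    if vec.index.duplicated().any():
        dupes = vec.index[vec.index.duplicated()].tolist()
        raise ValueError(f"duplicate feature names: {dupes}")
    return vec


def extract_cohort_features(
    cohort: Mapping[str, SampleInputs],
    genome,
    catalog: FeatureCatalog,
    enforce_inclusion: bool = True,
) -> FeatureMatrix:
    """Extract and assemble the feature matrix for a whole cohort."""
    vectors = {
        sid: extract_sample_features(inp, genome, catalog, enforce_inclusion)
        for sid, inp in cohort.items()
    }
    return assemble_feature_matrix(vectors)
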