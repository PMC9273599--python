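"""Chromosome-arm ploidy and genome-level copy-number properties.

Arm copy numbers are assigned from somatic copy-number segments by coverage
voting: segments are split at arm boundaries, rounded to integer CN, and the
integer covering the largest fraction of the arm becomes the preliminary arm
CN. The modal preliminary CN across arms is the genome CN, against which each
arm's final CN is expressed as a fold change. Acrocentric chromosomes
(chr13/14/15/21/22) carry only a q arm.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from primarysite.features.records import CNSegment, SampleMeta

#: Fold change reported when the genome CN is 0 but an arm CN is not.
FOLD_CHANGE_CAP = 10.0

#: Chromosomes considered to have only a q arm.
ACROCENTRIC = frozenset({"13", "14", "15", "21", "22"})

AUTOSOMES = tuple(str(i) for i in range(1, 23))
ALLOWED_CHROMS = AUTOSOMES + ("X",)


def normalize_chrom(chrom: str) -> str:
    """Strip an optional 'chr' prefix."""
    return chrom[3:] if chrom.lower().startswith("chr") else chrom


def round_half_away(x: float) -> int:
    """Round to nearest integer, halves away from zero (CN is non-negative)."""
    return int(math.floor(x + 0.5))


def build_arm_table(
    chrom_sizes: dict[str, int], centromeres: dict[str, int]
) -> pd.DataFrame:
    """Construct an arm interval table from chromosome sizes and centromeres.

    Returns a DataFrame with columns chrom, start, end (0-based half-open)
    and arm name like "1p"/"1q". Acrocentric chromosomes get a single q arm
    spanning the whole chromosome.
    """
    rows = []
    for chrom, size in chrom_sizes.items():
        c = normalize_chrom(chrom)
        if c not in ALLOWED_CHROMS:
            continue
        if c in ACROCENTRIC:
            rows.append((chrom, 0, size, f"{c}q"))
            continue
        cen = centromeres[chrom]
        rows.append((chrom, 0, cen, f"{c}p"))
        rows.append((chrom, cen, size, f"{c}q"))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "arm"])


@dataclass
class ArmCopyNumberResult:
    """Per-arm copy-number calls relative to the genome copy number."""

    preliminary_cn: pd.Series  # arm -> int
    final_cn: pd.Series  # arm -> int
    genome_cn: int
    fold_change: pd.Series  # arm -> float
    coverage: dict  # arm -> {int CN: coverage fraction}


def _arm_coverage(
    segments: Iterable[CNSegment], arm_table: pd.DataFrame
) -> dict[str, dict[int, float]]:
    """Coverage fraction of each integer CN per arm (of covered length)."""
    coverage: dict[str, dict[int, float]] = {arm: {} for arm in arm_table["arm"]}
    arms_by_chrom: dict[str, list[tuple[int, int, str]]] = {}
    for row in arm_table.itertuples(index=False):
        arms_by_chrom.setdefault(normalize_chrom(row.chrom), []).append(
            (int(row.start), int(row.end), row.arm)
        )
    for seg in segments:
        chrom = normalize_chrom(seg.chrom)
        if chrom not in arms_by_chrom:
            continue
        s0, e0 = seg.start - 1, seg.end  # to half-open
        cn = round_half_away(seg.copy_number)
        for a_start, a_end, arm in arms_by_chrom[chrom]:
            overlap = min(e0, a_end) - max(s0, a_start)
            if overlap > 0:
                bucket = coverage[arm]
                bucket[cn] = bucket.get(cn, 0.0) + overlap
    for arm, bucket in coverage.items():
        total = sum(bucket.values())
        if total > 0:
            for cn in bucket:
                bucket[cn] /= total
    return coverage


def _max_coverage_cn(bucket: dict[int, float]) -> int:
    """Integer CN with highest coverage; ties resolve to the smaller CN."""
    return min(
        (cn for cn in bucket if bucket[cn] == max(bucket.values()))
    )


def compute_arm_copy_number(
    segments: Sequence[CNSegment], arm_table: pd.DataFrame
) -> ArmCopyNumberResult:
    """Assign per-arm integer copy numbers and fold changes vs the genome CN.

    The preliminary arm CN is the integer CN covering the largest fraction of
    the arm. The genome CN is the modal preliminary CN across arms (ties to
    the smaller CN). The final arm CN keeps the preliminary call when it
    covers >= 50% of the arm; otherwise the genome CN is assigned if it is
    among the arm's observed integer CNs, else the preliminary call stands.
    Arms with no covering segment take the genome CN (fold change 1).
    """
    coverage = _arm_coverage(segments, arm_table)
    arms = list(arm_table["arm"])
    preliminary = {}
    for arm in arms:
        bucket = coverage[arm]
        preliminary[arm] = _max_coverage_cn(bucket) if bucket else None
    observed = [cn for cn in preliminary.values() if cn is not None]
    if not observed:
        raise ValueError("no copy-number segments overlap any chromosome arm")
    values, counts = np.unique(observed, return_counts=True)
    genome_cn = int(min(values[counts == counts.max()]))

    final = {}
    for arm in arms:
        bucket = coverage[arm]
        if not bucket:
            final[arm] = genome_cn
            continue
        prelim = preliminary[arm]
        if bucket[prelim] >= 0.5:
            final[arm] = prelim
        elif genome_cn in bucket:
            final[arm] = genome_cn
        else:
            final[arm] = prelim

    fold = {}
    for arm in arms:
        if genome_cn == 0:
            fold[arm] = 0.0 if final[arm] == 0 else FOLD_CHANGE_CAP
        else:
            fold[arm] = final[arm] / genome_cn
    prelim_out = pd.Series(
        {a: (genome_cn if p is None else p) for a, p in preliminary.items()}
    )
    return ArmCopyNumberResult(
        preliminary_cn=prelim_out,
        final_cn=pd.Series(final),
        genome_cn=genome_cn,
        fold_change=pd.Series(fold),
        coverage=coverage,
    )


def compute_genome_properties(
    segments: Sequence[CNSegment], meta: SampleMeta | None = None
) -> dict:
    """Genome ploidy, diploid proportion, WGD flag and gender of a sample.

    Ploidy is the segment-length-weighted mean CN over autosomes; the diploid
    proportion is the autosomal length fraction with rounded CN equal to 2;
    whole-genome duplication is flagged when ploidy exceeds 2.5. Gender comes
    from metadata when stated, otherwise it is inferred from chrX dosage
    (female iff length-weighted mean chrX CN >= 1.5).
    """
    if not segments:
        raise ValueError("no segments provided")
    auto_len = auto_cn_len = diploid_len = 0.0
    x_len = x_cn_len = 0.0
    for seg in segments:
        chrom = normalize_chrom(seg.chrom)
        if chrom in AUTOSOMES:
            auto_len += seg.length
            auto_cn_len += seg.length * seg.copy_number
            if round_half_away(seg.copy_number) == 2:
                diploid_len += seg.length
        elif chrom == "X":
            x_len += seg.length
            x_cn_len += seg.length * seg.copy_number
    if auto_len == 0:
        raise ValueError("no autosomal segments; cannot compute genome properties")
    ploidy = auto_cn_len / auto_len
    gender = meta.gender if meta is not None else "unknown"
    if gender == "unknown" and x_len > 0:
        gender = "female" if x_cn_len / x_len >= 1.5 else "male"
    return {
        "genome_ploidy": ploidy,
        "diploid_proportion": diploid_len / auto_len,
        "wgd_flag": ploidy > 2.5,
        "gender": gender,
    }
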