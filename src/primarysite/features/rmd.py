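"""Regional mutational density: SBS counts over fixed genomic bins.

The regional mutational density (RMD) of a tumor is the genome-wide
distribution of its somatic single-base substitutions over a fixed table of
megabase-scale bins, normalized by total SBS load. It reflects tissue-specific
chromatin organisation and replication timing and is therefore informative for
the tumor's tissue of origin. The bin table is an input (BED) and must be
identical between training and prediction.
"""

from __future__ import annotations

from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from primarysite.features.records import MutationRecord

BED_COLUMNS = ("chrom", "start", "end")


def read_bed(path) -> pd.DataFrame:
    """Read a 3+ column BED file (0-based half-open) into a DataFrame."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    df = df.iloc[:, : max(3, df.shape[1])]
    names = list(BED_COLUMNS) + [f"col{i}" for i in range(3, df.shape[1])]
    df.columns = names[: df.shape[1]]
    if df.shape[1] == 4:
        df = df.rename(columns={"col3": "name"})
    return df


def write_bed(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", header=False, index=False)


def build_bin_table(
    chrom_sizes: Mapping[str, int], bin_size: int = 1_000_000
) -> pd.DataFrame:
    """Tile chromosomes into fixed-width bins (BED coordinates).

    The trailing partial bin of each chromosome is kept. Chromosome order
    follows the mapping's iteration order, which must be held constant
    between training and prediction.
    """
    rows = []
    for chrom, size in chrom_sizes.items():
        for start in range(0, size, bin_size):
            rows.append((chrom, start, min(start + bin_size, size)))
    table = pd.DataFrame(rows, columns=list(BED_COLUMNS))
    validate_bin_table(table)
    return table


def validate_bin_table(bin_table: pd.DataFrame) -> None:
    if not set(BED_COLUMNS) <= set(bin_table.columns):
        raise ValueError(f"bin table needs columns {BED_COLUMNS}")
    if (bin_table["start"] >= bin_table["end"]).any():
        raise ValueError("bin table has empty or inverted intervals")
    for chrom, grp in bin_table.groupby("chrom", sort=False):
        starts = grp["start"].to_numpy()
        ends = grp["end"].to_numpy()
        order = np.argsort(starts)
        if (ends[order][:-1] > starts[order][1:]).any():
            raise ValueError(f"bin table has overlapping intervals on {chrom}")


def compute_rmd_bins(
    mutations: Iterable[MutationRecord], bin_table: pd.DataFrame
) -> np.ndarray:
    """Normalized RMD vector of a sample over a fixed bin table.

    Only single-base substitutions are counted. SBSs falling outside every
    bin are excluded from both numerator and denominator. A sample with no
    binned SBS yields an all-zero vector (a defined degenerate value, not an
    error).

    Returns
    -------
    numpy.ndarray
        Length ``len(bin_table)``; sums to 1 whenever at least one SBS falls
        in a bin.
    """
    validate_bin_table(bin_table)
    table = bin_table.reset_index(drop=True)
    counts = np.zeros(len(table), dtype=float)
    by_chrom: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
    for chrom, grp in table.groupby("chrom", sort=False):
        order = np.argsort(grp["start"].to_numpy())
        by_chrom[chrom] = (
            grp["start"].to_numpy()[order],
            grp["end"].to_numpy()[order],
            grp.index.to_numpy()[order],  # positional rows in the full table
        )
    for mut in mutations:
        if not mut.is_snv:
            continue
        entry = by_chrom.get(mut.chrom)
        if entry is None:
            continue
        starts, ends, rows = entry
        pos0 = mut.pos - 1
        j = np.searchsorted(starts, pos0, side="right") - 1
        if j >= 0 and pos0 < ends[j]:
            counts[rows[j]] += 1
    total = counts.sum()
    if total > 0:
        counts /= total
    return counts


def rmd_bin_feature_names(bin_table: pd.DataFrame) -> list[str]:
    """Internal ``rmd_bin.*`` feature names (one per bin, in table order)."""
    return [
        f"rmd_bin.{row.chrom}_{int(row.start)}"
        for row in bin_table.itertuples(index=False)
    ]
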