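"""Readers and writers for the tabular input formats.

Mutations come from a VCF or a 4-column TSV (chrom, pos, ref, alt);
copy-number segments, SV clusters, events and sample metadata are TSVs with
fixed headers. All readers return the record dataclasses used by the
extraction pipeline.
"""

from __future__ import annotations

import csv
from pathlib import Path
from typing import Iterator

import pandas as pd

from primarysite.features.records import (
    CNSegment,
    EventRecord,
    MutationRecord,
    SampleMeta,
    SVClusterRecord,
)


def read_mutations(path) -> list[MutationRecord]:
    """Read somatic mutations from a VCF (.vcf) or a TSV (chrom,pos,ref,alt)."""
    path = Path(path)
    if path.suffix == ".vcf" or path.name.endswith(".vcf.gz"):
        return list(_iter_vcf(path))
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    required = {"chrom", "pos", "ref", "alt"}
    if not required <= set(df.columns):
        raise ValueError(f"mutation TSV needs columns {sorted(required)}")
    return [
        MutationRecord(str(r.chrom), int(r.pos), str(r.ref), str(r.alt))
        for r in df.itertuples(index=False)
    ]


def _iter_vcf(path: Path) -> Iterator[MutationRecord]:
    import gzip

    opener = gzip.open if path.name.endswith(".gz") else open
    with opener(path, "rt") as fh:
        for line in fh:
            if line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            chrom, pos, _, ref, alts = fields[0], fields[1], fields[2], fields[3], fields[4]
            for alt in alts.split(","):
                if alt in (".", "*") or set(alt) - set("ACGT"):
                    continue
                yield MutationRecord(chrom, int(pos), ref, alt)


def write_mutations_tsv(mutations, path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t")
        writer.writerow(["chrom", "pos", "ref", "alt"])
        for m in mutations:
            writer.writerow([m.chrom, m.pos, m.ref, m.alt])


def read_cn_segments(path) -> list[CNSegment]:
    """Read copy-number segments (TSV: chrom, start, end, copy_number; 1-based)."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    return [
        CNSegment(str(r.chrom), int(r.start), int(r.end), float(r.copy_number))
        for r in df.itertuples(index=False)
    ]


def write_cn_segments_tsv(segments, path) -> None:
    pd.DataFrame(
        [(s.chrom, s.start, s.end, s.copy_number) for s in segments],
        columns=["chrom", "start", "end", "copy_number"],
    ).to_csv(path, sep="\t", index=False)


def read_sv_clusters(path) -> list[SVClusterRecord]:
    """Read SV clusters (TSV: cluster_id, resolved_type, length_bp, n_sv, n_breakends)."""
    df = pd.read_csv(path, sep="\t")
    out = []
    for r in df.itertuples(index=False):
        length = None if pd.isna(r.length_bp) else int(r.length_bp)
        out.append(
            SVClusterRecord(
                str(r.cluster_id), str(r.resolved_type),
                n_sv=int(r.n_sv), n_breakends=int(r.n_breakends), length_bp=length,
            )
        )
    return out


def write_sv_clusters_tsv(clusters, path) -> None:
    pd.DataFrame(
        [
            (c.cluster_id, c.resolved_type, "" if c.length_bp is None else c.length_bp,
             c.n_sv, c.n_breakends)
            for c in clusters
        ],
        columns=["cluster_id", "resolved_type", "length_bp", "n_sv", "n_breakends"],
    ).to_csv(path, sep="\t", index=False)


def read_events(path) -> list[EventRecord]:
    """Read driver/fusion/viral events (TSV: kind, name, driver_type, driver_likelihood)."""
    df = pd.read_csv(path, sep="\t")
    out = []
    for r in df.itertuples(index=False):
        dtype = None if pd.isna(getattr(r, "driver_type", None)) else str(r.driver_type)
        dl = getattr(r, "driver_likelihood", None)
        dl = None if dl is None or pd.isna(dl) else float(dl)
        out.append(EventRecord(str(r.kind), str(r.name), dtype, dl))
    return out


def write_events_tsv(events, path) -> None:
    pd.DataFrame(
        [
            (e.kind, e.name, e.driver_type or "",
             "" if e.driver_likelihood is None else e.driver_likelihood)
            for e in events
        ],
        columns=["kind", "name", "driver_type", "driver_likelihood"],
    ).to_csv(path, sep="\t", index=False)


def read_sample_meta(path) -> dict[str, SampleMeta]:
    """Read sample metadata (TSV: sample_id, gender, purity)."""
    df = pd.read_csv(path, sep="\t")
    metas = {}
    for r in df.itertuples(index=False):
        if r.sample_id in metas:
            raise ValueError(f"duplicate sample id {r.sample_id}")
        metas[str(r.sample_id)] = SampleMeta(
            str(r.sample_id), str(r.gender), float(r.purity)
        )
    return metas


def write_sample_meta_tsv(metas, path) -> None:
    pd.DataFrame(
        [(m.sample_id, m.gender, m.purity) for m in metas],
        columns=["sample_id", "gender", "purity"],
    ).to_csv(path, sep="\t", index=False)


def write_fasta(sequences: dict[str, str], path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def open_genome(path):
    """Open a reference FASTA with pyfaidx (builds the .fai index if absent)."""
    from pyfaidx import Fasta

    return Fasta(str(path), sequence_always_upper=True)
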