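"""COSMIC-style mutation context classification: SBS96, DBS78 and ID83.

Single-base substitutions are canonicalized to the pyrimidine strand and
classified by their trinucleotide context (96 categories). Double-base
substitutions use the 78 canonical doublet categories. Indels follow the
COSMIC/PCAWG 83-category scheme based on indel length, repeat context of the
inserted/deleted sequence, and flanking microhomology for non-repetitive
deletions.
"""

from __future__ import annotations

import logging
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from primarysite.features.records import MutationRecord

logger = logging.getLogger(__name__)

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string."""
    return seq.translate(_COMPLEMENT)[::-1]


# ---------------------------------------------------------------------------
# Category enumerations


def _enumerate_sbs96() -> list[str]:
    cats = []
    for ref, alts in (("C", "AGT"), ("T", "ACG")):
        for alt in alts:
            for five in "ACGT":
                for three in "ACGT":
                    cats.append(f"{five}[{ref}>{alt}]{three}")
    return cats


# Order: substitution class major, then 5' flank, then 3' flank — the
# conventional COSMIC layout.
SBS96_CONTEXTS: tuple[str, ...] = tuple(
    f"{five}[{ref}>{alt}]{three}"
    for ref, alts in (("C", "AGT"), ("T", "ACG"))
    for alt in alts
    for five in "ACGT"
    for three in "ACGT"
)

_DBS_REF_DOUBLETS = ("AC", "AT", "CC", "CG", "CT", "GC", "TA", "TC", "TG", "TT")
_DBS_PALINDROMIC = frozenset(d for d in _DBS_REF_DOUBLETS if revcomp(d) == d)


def _enumerate_dbs78() -> tuple[str, ...]:
    cats = []
    for ref in _DBS_REF_DOUBLETS:
        seen = set()
        for a0 in "ACGT":
            for a1 in "ACGT":
                alt = a0 + a1
                if alt[0] == ref[0] or alt[1] == ref[1]:
                    continue
                if ref in _DBS_PALINDROMIC:
                    alt = min(alt, revcomp(alt))
                if alt not in seen:
                    seen.add(alt)
                    cats.append(f"{ref}>{alt}")
    return tuple(cats)


DBS78_CONTEXTS: tuple[str, ...] = _enumerate_dbs78()
assert len(DBS78_CONTEXTS) == 78


def _enumerate_id83() -> tuple[str, ...]:
    cats = []
    # 1 bp deletions: pyrimidine base x homopolymer length 1..6+ (labels 1..6)
    for base in "CT":
        cats.extend(f"1:Del:{base}:{n}" for n in range(1, 7))
    # 1 bp insertions: pyrimidine base x existing homopolymer length 0..5+
    for base in "CT":
        cats.extend(f"1:Ins:{base}:{n}" for n in range(0, 6))
    # >=2 bp deletions at repeats: length 2..5+ x tandem copy count 1..6+
    for length in range(2, 6):
        cats.extend(f"{length}:Del:R:{n}" for n in range(1, 7))
    # >=2 bp insertions at repeats: length 2..5+ x existing copy count 0..5+
    for length in range(2, 6):
        cats.extend(f"{length}:Ins:R:{n}" for n in range(0, 6))
    # microhomology deletions: length 2..5+ x MH length (capped at length-1, 5)
    for length in range(2, 6):
        top = min(length - 1, 5) if length < 5 else 5
        cats.extend(f"{length}:Del:M:{m}" for m in range(1, top + 1))
    return tuple(cats)


ID83_CONTEXTS: tuple[str, ...] = _enumerate_id83()
assert len(ID83_CONTEXTS) == 83

SCHEMES: Mapping[str, tuple[str, ...]] = {
    "SBS96": SBS96_CONTEXTS,
    "DBS78": DBS78_CONTEXTS,
    "ID83": ID83_CONTEXTS,
}


# ---------------------------------------------------------------------------
# Genome access


def fetch_sequence(genome, chrom: str, start0: int, end0: int) -> str:
    """Fetch genome[chrom][start0:end0] (0-based half-open), uppercased.

    Accepts a ``pyfaidx.Fasta``, a plain mapping of chrom -> sequence string,
    or anything with a similar ``__getitem__`` returning a sliceable object.
    Positions outside the contig raise ``KeyError``/``IndexError``.
    """
    if chrom not in genome:
        raise KeyError(f"chromosome {chrom!r} not in genome")
    record = genome[chrom]
    if start0 < 0:
        raise IndexError(f"negative coordinate on {chrom}")
    seq = str(record[start0:end0])
    if len(seq) != end0 - start0:
        raise IndexError(f"{chrom}:{start0}-{end0} extends past contig end")
    return seq.upper()


def _contig_length(genome, chrom: str) -> int:
    return len(genome[chrom])


# ---------------------------------------------------------------------------
# Per-record classification


def classify_sbs(mut: MutationRecord, genome) -> str | None:
    """SBS96 category of a single-base substitution; None if flanks contain N."""
    if not mut.is_snv:
        raise ValueError(f"not an SNV: {mut}")
    tri = fetch_sequence(genome, mut.chrom, mut.pos - 2, mut.pos + 1)
    if "N" in tri:
        return None
    if tri[1] != mut.ref:
        raise ValueError(
            f"reference mismatch at {mut.chrom}:{mut.pos}: genome has {tri[1]}, record has {mut.ref}"
        )
    ref, alt = mut.ref, mut.alt
    if ref in "AG":  # canonicalize to pyrimidine strand
        tri = revcomp(tri)
        ref = revcomp(ref)
        alt = revcomp(alt)
    return f"{tri[0]}[{ref}>{alt}]{tri[2]}"


def classify_dbs(mut: MutationRecord, genome) -> str | None:
    """DBS78 category of a doublet substitution; None if unclassifiable."""
    if not (mut.is_mnv and len(mut.ref) == 2):
        raise ValueError(f"not a doublet substitution: {mut}")
    ref_genome = fetch_sequence(genome, mut.chrom, mut.pos - 1, mut.pos + 1)
    if "N" in ref_genome:
        return None
    if ref_genome != mut.ref:
        raise ValueError(
            f"reference mismatch at {mut.chrom}:{mut.pos}: genome has {ref_genome}, record has {mut.ref}"
        )
    ref, alt = mut.ref, mut.alt
    if ref not in _DBS_REF_DOUBLETS:
        ref, alt = revcomp(ref), revcomp(alt)
    if ref in _DBS_PALINDROMIC:
        alt = min(alt, revcomp(alt))
    if alt[0] == ref[0] or alt[1] == ref[1]:
        # partially overlapping doublet (one base unchanged) — not a true DBS
        return None
    return f"{ref}>{alt}"


def _normalize_indel(mut: MutationRecord) -> tuple[int, str, bool]:
    """Strip the shared VCF anchor prefix; return (start0, sequence, is_deletion).

    ``start0`` is the 0-based position of the first inserted/deleted base in
    the reference (for insertions, the base before which the sequence goes in).
    """
    ref, alt, pos = mut.ref, mut.alt, mut.pos
    k = 0
    while k < min(len(ref), len(alt)) and ref[k] == alt[k]:
        k += 1
    if len(ref) > len(alt):
        if k != len(alt):
            raise ValueError(f"complex indel not supported: {mut}")
        return pos - 1 + k, ref[k:], True
    if len(alt) > len(ref):
        if k != len(ref):
            raise ValueError(f"complex indel not supported: {mut}")
        return pos - 1 + k, alt[k:], False
    raise ValueError(f"not an indel: {mut}")


def _count_tandem_copies(context: str, unit: str) -> int:
    """Number of consecutive copies of ``unit`` at the start of ``context``."""
    n = 0
    i = 0
    while context[i : i + len(unit)] == unit:
        n += 1
        i += len(unit)
    return n


def classify_indel(mut: MutationRecord, genome) -> str | None:
    """ID83 category of an insertion or deletion; None if context contains N."""
    start0, seq, is_del = _normalize_indel(mut)
    length = len(seq)
    cap_len = min(length, 5)
    contig_len = _contig_length(genome, mut.chrom)
    flank = 6 * length  # enough context for the 6+ repeat classes
    if is_del:
        down_start = start0 + length
    else:
        down_start = start0
    down = str(genome[mut.chrom][down_start : min(down_start + flank, contig_len)]).upper()
    up = str(genome[mut.chrom][max(0, start0 - flank) : start0]).upper()
    if "N" in seq:
        return None
    if is_del:
        genome_seq = fetch_sequence(genome, mut.chrom, start0, start0 + length)
        if genome_seq != seq:
            raise ValueError(
                f"reference mismatch for deletion at {mut.chrom}:{mut.pos}"
            )
    if "N" in up or "N" in down:
        return None

    # tandem copies of the indel sequence downstream of the event
    extra = _count_tandem_copies(down, seq)
    if length == 1:
        base = seq if seq in "CT" else revcomp(seq)
        if is_del:
            hp_len = min(1 + extra, 6)  # homopolymer length incl. deleted base
            return f"1:Del:{base}:{hp_len}"
        return f"1:Ins:{base}:{min(extra, 5)}"
    if is_del:
        if extra >= 1:
            return f"{cap_len}:Del:R:{min(1 + extra, 6)}"
        # microhomology: longest prefix of the deleted sequence matching
        # downstream, or longest suffix matching upstream
        mh_down = 0
        while mh_down < length - 1 and mh_down < len(down) and seq[mh_down] == down[mh_down]:
            mh_down += 1
        mh_up = 0
        while mh_up < length - 1 and mh_up < len(up) and seq[length - 1 - mh_up] == up[len(up) - 1 - mh_up]:
            mh_up += 1
        mh = max(mh_down, mh_up)
        if mh >= 1:
            return f"{cap_len}:Del:M:{min(mh, cap_len - 1 if length < 5 else 5)}"
        return f"{cap_len}:Del:R:1"
    return f"{cap_len}:Ins:R:{min(extra, 5)}"


# ---------------------------------------------------------------------------
# Counting


def count_mutation_contexts(
    mutations: Iterable[MutationRecord],
    genome,
    scheme: str,
) -> pd.Series:
    """Count mutations into the categories of one context scheme.

    Parameters
    ----------
    mutations
        Somatic mutation records; records of other mutation classes than the
        scheme's (e.g. indels under SBS96) are ignored.
    genome
        Reference-sequence accessor (``pyfaidx.Fasta`` or mapping of
        chromosome name to sequence string).
    scheme
        One of ``"SBS96"``, ``"DBS78"``, ``"ID83"``.

    Returns
    -------
    pandas.Series
        Integer counts indexed by the scheme's categories in canonical order.
        The number of records skipped for ambiguous (N) context is recorded in
        ``result.attrs["skipped"]``.

    Raises
    ------
    KeyError, IndexError
        If a mutation locus falls outside the genome.
    ValueError
        If the record's reference allele disagrees with the genome.
    """
    if scheme not in SCHEMES:
        raise ValueError(f"unknown scheme {scheme!r}; choose from {sorted(SCHEMES)}")
    categories = SCHEMES[scheme]
    counts = pd.Series(np.zeros(len(categories), dtype=int), index=list(categories))
    skipped = 0
    for mut in mutations:
        if scheme == "SBS96":
            if not mut.is_snv:
                continue
            cat = classify_sbs(mut, genome)
        elif scheme == "DBS78":
            if not (mut.is_mnv and len(mut.ref) == 2):
                continue
            cat = classify_dbs(mut, genome)
        else:
            if not mut.is_indel:
                continue
            cat = classify_indel(mut, genome)
        if cat is None:
            skipped += 1
            logger.debug("skipping unclassifiable record %s", mut)
        else:
            counts[cat] += 1
    counts.attrs["skipped"] = skipped
    counts.attrs["scheme"] = scheme
    return counts
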