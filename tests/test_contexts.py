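"""Mutation-context classification: category tables and strand canonicalization."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from primarysite.features.contexts import (
    DBS78_CONTEXTS,
    ID83_CONTEXTS,
    SBS96_CONTEXTS,
    classify_dbs,
    classify_indel,
    classify_sbs,
    count_mutation_contexts,
    revcomp,
)
from primarysite.features.records import MutationRecord


@pytest.mark.parametrize(
    "table,n",
    [(SBS96_CONTEXTS, 96), (DBS78_CONTEXTS, 78), (ID83_CONTEXTS, 83)],
)
def test_context_tables_enumerate_expected_categories(table, n):
    assert len(table) == n
    assert len(set(table)) == n


class TestSBS:
    def test_pyrimidine_reference_kept_as_is(self):
        genome = {"1": "AACAA"}
        cat = classify_sbs(MutationRecord("1", 3, "C", "T"), genome)
        assert cat == "A[C>T]A"

    def test_purine_reference_reverse_complemented(self):
        # G>A flanked by T_ and _T is the reverse complement of A[C>T]A
        genome = {"1": "TTGTT"}
        cat = classify_sbs(MutationRecord("1", 3, "G", "A"), genome)
        assert cat == "A[C>T]A"

    def test_reference_mismatch_raises(self):
        genome = {"1": "AACAA"}
        with pytest.raises(ValueError, match="reference mismatch"):
            classify_sbs(MutationRecord("1", 3, "T", "G"), genome)

    def test_locus_outside_genome_raises(self):
        with pytest.raises((KeyError, IndexError)):
            classify_sbs(MutationRecord("2", 3, "C", "T"), {"1": "AACAA"})
        with pytest.raises(IndexError):
            classify_sbs(MutationRecord("1", 50, "C", "T"), {"1": "AACAA"})

    def test_ambiguous_flank_skipped_in_counting(self):
        genome = {"1": "NNCAA"}
        counts = count_mutation_contexts(
            [MutationRecord("1", 3, "C", "T")], genome, "SBS96"
        )
        assert counts.sum() == 0
        assert counts.attrs["skipped"] == 1

    @settings(max_examples=50, deadline=None)
    @given(st.data())
    def test_reverse_complement_strand_lands_in_same_category(self, data):
        """A substitution and its reverse-complement representation agree."""
        rng_bases = st.sampled_from("ACGT")
        five = data.draw(rng_bases)
        three = data.draw(rng_bases)
        ref = data.draw(rng_bases)
        alt = data.draw(st.sampled_from([b for b in "ACGT" if b != ref]))
        fwd_genome = {"1": "A" + five + ref + three + "A"}
        rev_genome = {"1": revcomp(fwd_genome["1"])}
        cat_fwd = classify_sbs(MutationRecord("1", 3, ref, alt), fwd_genome)
        cat_rev = classify_sbs(
            MutationRecord("1", 3, revcomp(ref), revcomp(alt)), rev_genome
        )
        assert cat_fwd == cat_rev


class TestDBS:
    def test_canonical_reference_doublet(self):
        genome = {"1": "AAACT"}  # doublet AC at 3-4
        rec = MutationRecord("1", 3, "AC", "TG")
        assert classify_dbs(rec, genome) == "AC>TG"

    def test_non_canonical_doublet_reverse_complemented(self):
        # GT>CA is the reverse complement of AC>TG
        genome = {"1": "AAGTA"}
        cat = classify_dbs(MutationRecord("1", 3, "GT", "CA"), genome)
        assert cat == "AC>TG"
        assert cat in DBS78_CONTEXTS

    def test_counts_sum_to_classifiable_doublets(self):
        genome = {"1": "AACAAGTA"}
        muts = [
            MutationRecord("1", 3, "CA", "TG"),
            MutationRecord("1", 6, "GT", "CA"),
            MutationRecord("1", 2, "A", "T"),  # SNV, ignored under DBS78
        ]
        counts = count_mutation_contexts(muts, genome, "DBS78")
        assert counts.sum() == 2


class TestID83:
    def test_single_base_deletion_in_homopolymer(self):
        # delete one C from a CCCC homopolymer -> length-4 category
        genome = {"1": "TACCCCGA"}
        rec = MutationRecord("1", 2, "AC", "A")
        assert classify_indel(rec, genome) == "1:Del:C:4"

    def test_single_base_deletion_of_purine_canonicalized(self):
        genome = {"1": "TAGGTA"}  # delete a G (-> C on pyrimidine strand), GG run
        rec = MutationRecord("1", 2, "AG", "A")
        assert classify_indel(rec, genome) == "1:Del:C:2"

    def test_single_base_insertion(self):
        genome = {"1": "TATTTGA"}  # insert T next to a TTT run
        rec = MutationRecord("1", 2, "A", "AT")
        assert classify_indel(rec, genome) == "1:Ins:T:3"

    def test_repeat_deletion(self):
        # delete one CAG from CAGCAGCAG (3 copies)
        genome = {"1": "TCAGCAGCAGTT"}
        rec = MutationRecord("1", 1, "TCAG", "T")
        assert classify_indel(rec, genome) == "3:Del:R:3"

    def test_microhomology_deletion(self):
        # deleted TAGC followed by TA: 2 bp of microhomology, no full repeat
        genome = {"1": "GGTAGCTACCGG"}
        rec = MutationRecord("1", 2, "GTAGC", "G")
        assert classify_indel(rec, genome) == "4:Del:M:2"

    def test_long_deletion_capped_at_five(self):
        genome = {"1": "GGATCGATCCCGGAA"}
        rec = MutationRecord("1", 2, "GATCGATC", "G")  # 7 bp deletion
        cat = classify_indel(rec, genome)
        assert cat.startswith("5:Del:")

    def test_insertion_without_repeat_context(self):
        genome = {"1": "GGGGACCCC"}
        rec = MutationRecord("1", 5, "A", "ATG")
        assert classify_indel(rec, genome) == "2:Ins:R:0"


class TestCounting:
    def test_empty_input_gives_zero_vector(self):
        counts = count_mutation_contexts([], {"1": "ACGT"}, "SBS96")
        assert len(counts) == 96
        assert counts.sum() == 0

    def test_sum_equals_classifiable_mutations(self, toy_genome):
        rng = np.random.default_rng(5)
        chrom = "1"
        seq = toy_genome[chrom]
        muts = []
        for pos0 in rng.choice(np.arange(2, len(seq) - 2), size=200, replace=False):
            ref = seq[pos0]
            alt = rng.choice([b for b in "ACGT" if b != ref])
            muts.append(MutationRecord(chrom, int(pos0) + 1, ref, str(alt)))
        counts = count_mutation_contexts(muts, toy_genome, "SBS96")
        assert counts.sum() == 200
        assert (counts >= 0).all()

    def test_unknown_scheme_rejected(self):
        with pytest.raises(ValueError, match="unknown scheme"):
            count_mutation_contexts([], {"1": "ACGT"}, "SBS1536")
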