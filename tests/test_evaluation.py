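"""Error rates, common-error overlap, and the six-way error taxonomy."""

import numpy as np
import pytest

from tcncall.evaluation import (
    Alignment,
    SiteError,
    align,
    classify_errors,
    common_error_proportion,
    error_rates,
    read_sam_alignments,
    site_errors,
)
from tcncall.simulate import random_genome


def mutate(seq: str, rng: np.random.Generator, p_sub=0.03, p_del=0.03, p_ins=0.03) -> str:
    out = []
    bases = "ACGT"
    for b in seq:
        r = rng.random()
        if r < p_del:
            continue
        if r < p_del + p_sub:
            out.append(str(rng.choice([c for c in bases if c != b])))
        else:
            out.append(b)
        if rng.random() < p_ins:
            out.append(str(rng.choice(list(bases))))
    return "".join(out) or "A"


class TestErrorRates:
    def test_identical_sequences(self):
        prof = error_rates(align("ACGTACGT", "ACGTACGT"))
        assert prof.identity_rate == 1.0
        assert prof.total_error_rate == 0.0

    def test_single_deletion(self):
        prof = error_rates(align("ACT", "ACGT"))
        assert prof.identity_rate == pytest.approx(0.75)
        assert prof.deletion_rate == pytest.approx(0.25)
        assert prof.insertion_rate == 0.0
        assert prof.mismatch_rate == 0.0

    def test_single_insertion(self):
        prof = error_rates(align("AAGAA", "AAAA"))
        assert prof.identity_rate == pytest.approx(1.0)
        assert prof.insertion_rate == pytest.approx(0.25)

    def test_identity_mismatch_deletion_partition(self):
        """identity + mismatch + deletion == 1 on full-span alignments of 100
        randomly mutated pairs, and taxonomy counts partition total errors."""
        rng = np.random.default_rng(7)
        for trial in range(100):
            ref = random_genome(int(rng.integers(50, 300)), seed=1000 + trial)
            read = mutate(ref, rng)
            aln = align(read, ref)
            prof = error_rates(aln)
            assert prof.identity_rate + prof.mismatch_rate + prof.deletion_rate == pytest.approx(1.0, abs=1e-9)
            tax = classify_errors(aln)
            total_errors = round(prof.total_error_rate * prof.reference_span)
            assert tax.total == total_errors

    def test_empty_alignment_rejected(self):
        with pytest.raises(ValueError):
            error_rates(Alignment("", "", ""))


class TestSiteErrors:
    def test_positions_projected_to_reference(self):
        #       read: A C - G A
        #        ref: A C T G -
        aln = Alignment("ACGA", "ACTG", "==D=I")
        errs = site_errors(aln, "c1")
        assert {(e.error_type, e.reference_position) for e in errs} == {
            ("deletion", 2),
            ("insertion", 4),
        }

    def test_ref_start_offset(self):
        aln = Alignment("AG", "AC", "=X", ref_start=100)
        assert site_errors(aln)[0].reference_position == 101


class TestCommonErrors:
    def make(self, caller, typed_positions):
        return [
            SiteError(p, t, caller) for t, ps in typed_positions.items() for p in ps
        ]

    def test_identical_error_sets_full_overlap(self):
        errs = {"insertion": [1, 5], "deletion": [2], "mismatch": [9]}
        by_caller = {c: self.make(c, errs) for c in "abcd"}
        prop = common_error_proportion(by_caller, "a")
        assert prop["insertion"] == 1.0
        assert prop["deletion"] == 1.0
        assert prop["mismatch"] == 1.0
        assert prop["overall"] == 1.0

    def test_partial_insertion_overlap(self):
        by_caller = {
            "A": self.make("A", {"insertion": [3, 7]}),
            "B": self.make("B", {"insertion": [3, 11]}),
        }
        assert common_error_proportion(by_caller, "A")["insertion"] == 0.5

    def test_disjoint_sets_zero(self):
        by_caller = {
            "A": self.make("A", {"deletion": [1, 2]}),
            "B": self.make("B", {"deletion": [3, 4]}),
        }
        assert common_error_proportion(by_caller, "A")["deletion"] == 0.0

    def test_zero_error_type_undefined(self):
        by_caller = {
            "A": self.make("A", {"deletion": [1]}),
            "B": self.make("B", {"deletion": [1], "insertion": [2]}),
        }
        prop = common_error_proportion(by_caller, "A")
        assert prop["insertion"] is None
        assert prop["deletion"] == 1.0

    def test_invariant_to_caller_ordering(self):
        a = self.make("A", {"insertion": [3, 7], "mismatch": [1]})
        b = self.make("B", {"insertion": [3], "mismatch": [1, 4]})
        fwd = common_error_proportion({"A": a, "B": b}, "A")
        rev = common_error_proportion({"B": b, "A": a}, "A")
        assert fwd == rev

    def test_requires_two_callers(self):
        with pytest.raises(ValueError):
            common_error_proportion({"A": []}, "A")


class TestTaxonomy:
    def test_homopolymer_deletion(self):
        # delete one A from a run of four
        ref = "GGCAAAACGG"
        read = "GGCAAACGG"
        tax = classify_errors(align(read, ref))
        assert tax.counts["homopolymer_deletion"] == 1
        assert tax.total == 1

    def test_homopolymer_insertion(self):
        ref = "GGCAAACGG"
        read = "GGCAAAACGG"
        tax = classify_errors(align(read, ref))
        assert tax.counts["homopolymer_insertion"] == 1

    def test_dcm_substitution(self):
        ref = "TATACCAGGTATA"
        read = "TATACCGGGTATA"  # A->G inside CCAGG
        tax = classify_errors(align(read, ref))
        assert tax.counts["dcm_error"] == 1
        assert tax.total == 1

    def test_plain_substitution(self):
        ref = "TATATGTATA"
        read = "TATACGTATA"
        tax = classify_errors(align(read, ref))
        assert tax.counts["substitution"] == 1
        assert tax.total == 1

    def test_homopolymer_takes_precedence_over_dcm(self):
        # CCTGG contains run CC only (len 2): build overlap with a >=3 run:
        # ref has AAACCTGG; deleting an A is homopolymer, not dcm
        ref = "GGAAACCTGGTT"
        read = "GGAACCTGGTT"
        tax = classify_errors(align(read, ref))
        assert tax.counts["homopolymer_deletion"] == 1
        assert tax.counts["dcm_error"] == 0

    def test_rates_use_reference_length(self):
        ref = "A" * 50
        read = "A" * 49
        tax = classify_errors(align(read, ref))
        assert tax.rates["homopolymer_deletion"] == pytest.approx(1 / 50)


class TestSamImport:
    def test_sam_round_trip_matches_internal_aligner(self, tmp_path):
        """A SAM record with CIGAR+MD reproduces the internal alignment ops."""
        ref = "ACGTACGTAA"
        read = "ACGTTCGTAA"  # one mismatch at position 4
        sam = tmp_path / "one.sam"
        sam.write_text(
            "@HD\tVN:1.6\tSO:unknown\n"
            "@SQ\tSN:chr1\tLN:10\n"
            f"r1\t0\tchr1\t1\t60\t10M\t*\t0\t0\t{read}\t*\tMD:Z:4A5\n"
        )
        loaded = read_sam_alignments(sam)
        assert len(loaded) == 1
        name, aln = loaded[0]
        assert name == "r1"
        assert aln.ops == align(read, ref).ops
        assert aln.ops.count("X") == 1
        prof = error_rates(aln)
        assert prof.mismatch_rate == pytest.approx(0.1)

    def test_sam_with_indels(self, tmp_path):
        # read: ACG-ACGT + TT insertion  vs ref ACGTACGT
        sam = tmp_path / "two.sam"
        sam.write_text(
            "@HD\tVN:1.6\n@SQ\tSN:c\tLN:8\n"
            "r2\t0\tc\t1\t60\t3M1D3M2I2M\t*\t0\t0\tACGACGTTGT\t*\tMD:Z:3^T5\n"
        )
        _, aln = read_sam_alignments(sam)[0]
        assert aln.ops.count("D") == 1
        assert aln.ops.count("I") == 2
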