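import itertools

import numpy as np
import pytest
from oracle_sw import local_alignment_score

from tailprofiler.refprep import HairpinReference
from tailprofiler.tail_align import (
    CandidateAlignment,
    TailCall,
    align_local,
    align_to_references,
    call_nta,
    call_read,
    rescue_au_suffix,
    select_best_alignment,
)


def _cand(**kw):
    defaults = dict(
        hairpin_id="h",
        query_span=(0, 20),
        target_span=(0, 20),
        blocks=(((0, 20), (0, 20)),),
        matched=20,
        mismatched=0,
        q_gap_count=0,
        t_gap_count=0,
        q_gap_bases=0,
        t_gap_bases=0,
        score=20.0,
    )
    defaults.update(kw)
    return CandidateAlignment(**defaults)


class TestAlignLocal:
    def test_exact_substring_alignment(self, plain_ref):
        insert = plain_ref.sequence[5:25] + plain_ref.sequence[25:30]  # 25-nt slice
        best = select_best_alignment(align_local(insert, plain_ref))
        assert best.matched == 25
        assert best.mismatched == 0
        assert best.q_gap_count == best.t_gap_count == 0
        assert best.target_span == (5, 30)

    def test_t_suffix_left_unaligned(self):
        ref = HairpinReference("h", "ACGGTTCAGACCGGAATGTC" + "GCATTGCACG", 0, 30, extension_nt=0)
        insert = ref.sequence[:20] + "TTT"
        best = select_best_alignment(align_local(insert, ref))
        assert best.query_span == (0, 20)
        assert best.matched == 20

    def test_low_identity_optimum_filtered_out(self):
        ref = HairpinReference("h", "ACGTACGTACGTACGTACGT", 0, 20, extension_nt=0)
        insert = list(ref.sequence)
        for pos in (2, 5, 8, 10, 13, 16, 18):  # 7 interior substitutions
            insert[pos] = {"A": "C", "C": "A", "G": "T", "T": "G"}[insert[pos]]
        assert align_local("".join(insert), ref, min_identity=0.70) == []

    def test_non_nucleotide_insert_rejected(self, plain_ref):
        with pytest.raises(ValueError):
            align_local("ACGTXACGTACGTACG", plain_ref)


class TestSelectBestAlignment:
    def test_matched_bases_dominate_mismatch_count(self):
        a = _cand(matched=20, mismatched=1)
        b = _cand(matched=21, mismatched=3)
        assert select_best_alignment([a, b]) is b

    def test_mismatch_count_precedes_gap_criteria(self):
        a = _cand(matched=20, mismatched=1)
        b = _cand(matched=20, mismatched=0, q_gap_count=1, q_gap_bases=1)
        assert select_best_alignment([a, b]) is b

    def test_single_candidate_returned(self):
        a = _cand()
        assert select_best_alignment([a]) is a

    def test_empty_returns_none(self):
        assert select_best_alignment([]) is None

    def test_gap_criteria_order_query_before_target(self):
        a = _cand(t_gap_count=1, t_gap_bases=2)
        b = _cand(q_gap_count=1, q_gap_bases=2)
        assert select_best_alignment([a, b]) is a

    def test_residual_tie_lexicographic_then_three_prime(self):
        a = _cand(hairpin_id="hsa-mir-b")
        b = _cand(hairpin_id="hsa-mir-a")
        assert select_best_alignment([a, b]) is b
        c = _cand(target_span=(0, 20))
        d = _cand(target_span=(5, 25))
        assert select_best_alignment([c, d]) is d

    def test_total_order_invariant_under_permutation(self):
        cands = [
            _cand(matched=18, mismatched=0),
            _cand(matched=19, mismatched=2),
            _cand(matched=19, mismatched=1, q_gap_count=1),
            _cand(matched=19, mismatched=1, t_gap_count=1),
            _cand(hairpin_id="aaa", matched=19, mismatched=1),
        ]
        picks = {
            id(select_best_alignment(list(p))) for p in itertools.permutations(cands)
        }
        assert len(picks) == 1


class TestCallNta:
    def test_fully_aligned_insert_has_empty_nta(self, plain_ref):
        insert = plain_ref.sequence[0:22]
        best = select_best_alignment(align_local(insert, plain_ref))
        assert call_nta(best, insert).nta == ""

    def test_two_base_t_suffix_reported_as_uu(self):
        ref = HairpinReference("h", "ACGGTTCAGACCGGAATGTCGCATTGCACG", 0, 30, extension_nt=0)
        insert = ref.sequence[:20] + "TT"
        best = select_best_alignment(align_local(insert, ref))
        assert call_nta(best, insert).nta == "UU"

    def test_mixed_tat_suffix_reported_as_uau(self):
        ref = HairpinReference("h", "ACGGTTCAGACCGGAATGTCGCAGGGCACG", 0, 30, extension_nt=0)
        insert = ref.sequence[:20] + "TAT"
        best = select_best_alignment(align_local(insert, ref))
        assert call_nta(best, insert).nta == "UAU"

    def test_length_conservation(self, toy_refs, rng):
        # |5'-unaligned| + |aligned query span| + |nta| == |insert|
        ref = toy_refs[0]
        for _ in range(30):
            start = int(rng.integers(ref.core_start, ref.core_start + 10))
            end = int(rng.integers(start + 25, ref.core_end))
            insert = "G" * int(rng.integers(0, 3)) + ref.sequence[start:end] + "T" * int(
                rng.integers(0, 5)
            )
            best = select_best_alignment(align_to_references(insert, toy_refs))
            call = call_nta(best, insert)
            q0, q1 = best.query_span
            assert q0 + (q1 - q0) + len(call.nta) == len(insert)


class TestRescue:
    REF = HairpinReference("h1", "CCGGAATGT", 0, 9, extension_nt=0)
    INSERT = "CCGGAATTTTT"

    def _nine_column_call(self):
        # the co-optimal alignment spanning all 9 reference bases
        # (one T.G mismatch at column 7), nta = "UU"
        aln = CandidateAlignment(
            hairpin_id="h1",
            query_span=(0, 9),
            target_span=(0, 9),
            blocks=(((0, 9), (0, 9)),),
            matched=8,
            mismatched=1,
            q_gap_count=0,
            t_gap_count=0,
            q_gap_bases=0,
            t_gap_bases=0,
            score=7.0,
        )
        return call_nta(aln, self.INSERT, read_id="r1")

    def test_worked_example_reclassifies_from_first_mismatch(self):
        call = self._nine_column_call()
        assert call.nta == "UU"
        rescued = rescue_au_suffix(call, self.INSERT, self.REF)
        assert rescued.rescued
        assert rescued.templated_read_end == 6  # templated region "CCGGAAT"
        assert rescued.templated_end == 6
        assert rescued.nta == "UUUU"

    def test_rescue_is_idempotent(self):
        call = self._nine_column_call()
        once = rescue_au_suffix(call, self.INSERT, self.REF)
        twice = rescue_au_suffix(once, self.INSERT, self.REF)
        assert once == twice

    def test_engine_reaches_same_end_state(self):
        # the production aligner picks the 7-column co-optimal, so the tail
        # is never absorbed; the final call must match the rescued one
        call = call_read(self.INSERT, [self.REF], min_identity=0.0, read_id="r1")
        assert call.templated_read_end == 6
        assert call.nta == "UUUU"

    def test_no_au_suffix_leaves_call_unchanged(self, plain_ref):
        insert = plain_ref.sequence[0:22]  # ends in "GC"
        call = call_read(insert, [plain_ref], min_identity=0.0)
        assert not call.rescued and call.nta == ""

    def test_matching_pure_t_suffix_stays_templated(self):
        # a terminal U run that matches the genomic sequence is counted as
        # templated (tail rates deliberately conservative)
        ref = HairpinReference("h", "GCCGGCAGGCATTT", 0, 14, extension_nt=0)
        insert = ref.sequence
        call = call_read(insert, [ref], min_identity=0.0)
        assert call.nta == "" and not call.rescued
        assert call.templated_read_end == 13

    def test_rescue_triggers_on_absorbed_tail(self):
        # reference continues ...TGTT: a TTTT tail aligns net-positively
        # (match, mismatch, match, match) and is cut back at the first
        # A/U-region mismatch; the leading tail T matches the template and
        # deliberately stays templated (conservative rule)
        ref = HairpinReference("h", "ACGGCCCAGACCGGCCGTGTT", 0, 21, extension_nt=0)
        insert = ref.sequence[:17] + "TTTT"
        call = call_read(insert, [ref], min_identity=0.0)
        assert call.rescued
        assert call.templated_read_end == 17
        assert call.templated_end == 17
        assert call.nta == "UUU"

    def test_rescue_never_extends_templated_region(self, library_run):
        for call in library_run["calls"][:500]:
            if call.alignment is None:
                continue
            assert call.templated_read_end <= call.alignment.query_span[1] - 1


def test_optimum_score_matches_brute_force_oracle(rng):
    """Production aligner vs independent Gotoh DP on random small instances."""
    bases = np.array(list("ACGT"))
    for _ in range(300):
        ref_len = int(rng.integers(20, 81))
        ins_len = int(rng.integers(15, 31))
        ref_seq = "".join(rng.choice(bases, ref_len))
        insert = "".join(rng.choice(bases, ins_len))
        ref = HairpinReference("h", ref_seq, 0, ref_len, extension_nt=0)
        cands = align_local(insert, ref, min_identity=0.0)
        got = max((c.score for c in cands), default=0.0)
        assert got == local_alignment_score(ref_seq, insert)
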