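"""Tail-caller unit and property tests against the brute-force oracle."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from srnatail.calling import (
    TailCaller,
    assign_reference,
    call_sample,
    call_tail,
    classify_tail,
    trim_adapter,
)
from srnatail.refio import ReadRecord, ReferenceRecord

from oracle import classify_regex, oracle_call, random_insert

ADAPTER = "UGGAAUUCUCGGGUGCCAAGG"


class TestTrimAdapter:
    def test_full_adapter_removed(self, mir_guga):
        insert = mir_guga.mature_seq
        out, status = trim_adapter(insert + ADAPTER, ADAPTER)
        assert (out, status) == (insert, "called")

    def test_no_adapter_returns_full_read(self, mir_guga):
        read = mir_guga.mature_seq
        out, status = trim_adapter(read, ADAPTER)
        assert (out, status) == (read, "no_adapter")

    def test_partial_adapter_at_read_end(self, mir_guga):
        read = mir_guga.mature_seq + ADAPTER[:6]
        out, status = trim_adapter(read, ADAPTER)
        assert (out, status) == (mir_guga.mature_seq, "called")
        out, status = trim_adapter(mir_guga.mature_seq + ADAPTER[:4], ADAPTER)
        assert status == "no_adapter"

    def test_one_substitution_anywhere_in_seed_still_trims(self, mir_guga):
        # enumerate every 1-substitution variant of the first 6 adapter bases
        insert = mir_guga.mature_seq
        for pos in range(6):
            for base in "ACGU":
                if base == ADAPTER[pos]:
                    continue
                mutated = ADAPTER[:pos] + base + ADAPTER[pos + 1 :]
                out, status = trim_adapter(insert + mutated, ADAPTER)
                assert (out, status) == (insert, "called"), (pos, base)

    def test_adapter_never_found_before_position_15(self):
        # read where an adapter-like stretch sits inside the first 15 bases
        read = ADAPTER[:8] + "ACGUACGUACGUACG" + ADAPTER
        out, status = trim_adapter(read, ADAPTER)
        assert status == "called"
        assert out == ADAPTER[:8] + "ACGUACGUACGUACG"


class TestCallTail:
    def test_identity_insert(self, mir_guga):
        call = call_tail(mir_guga.mature_seq, mir_guga)
        assert (call.status, call.end_offset, call.tail_seq, call.tail_class) == (
            "called", 0, "", "none")

    def test_templated_genomic_a_is_not_a_tail(self, mir_guga):
        # ...CCUGUGA: the extra A is genomically encoded downstream
        call = call_tail(mir_guga.mature_seq + "A", mir_guga)
        assert (call.end_offset, call.tail_seq, call.tail_class) == (1, "", "none")

    def test_first_a_templated_rest_is_tail(self, mir_guga):
        call = call_tail(mir_guga.mature_seq + "AAA", mir_guga)
        assert (call.end_offset, call.tail_seq, call.tail_class) == (1, "AA", "oligoA")

    def test_u_then_a_tail_at_canonical_end(self, mir_guga):
        # downstream starts with A, so UUA cannot extend the templated match
        call = call_tail(mir_guga.mature_seq + "UUA", mir_guga)
        assert (call.end_offset, call.tail_seq, call.tail_class) == (0, "UUA", "U_then_A")

    @pytest.mark.parametrize("trim", [1, 2, 3])
    def test_trimmed_species_called_with_negative_offset(self, mir_guga, trim):
        call = call_tail(mir_guga.mature_seq[:-trim], mir_guga)
        assert (call.status, call.end_offset, call.tail_class) == ("called", -trim, "none")

    def test_over_trimmed_is_unmatched(self, mir_guga):
        call = call_tail(mir_guga.mature_seq[:-4], mir_guga)
        assert call.status == "unmatched"

    def test_short_insert_unmatched(self, mir_guga):
        assert call_tail("ACGUACGUACGUAC", mir_guga).status == "unmatched"

    def test_one_body_mismatch_tolerated(self, mir_guga):
        seq = mir_guga.mature_seq
        mutated = "A" + seq[1:] if seq[0] != "A" else "C" + seq[1:]
        call = call_tail(mutated + "AA", mir_guga)
        assert call.status == "called"
        assert call.n_mismatch == 1
        # downstream A absorbs the first tail A
        assert (call.end_offset, call.tail_seq) == (1, "A")

    def test_mismatch_in_final_four_rejected(self, mir_guga):
        # substitute the canonical-end base itself: the boundary must be
        # exact, so the match is truncated and the leftover base makes the
        # read uncallable rather than yielding a spurious tail
        seq = mir_guga.mature_seq
        mutated = seq[:-1] + ("A" if seq[-1] != "A" else "C")
        call = call_tail(mutated, mir_guga)
        assert call.status == "unmatched"

    def test_no_mismatch_allowed_in_downstream_extension(self, mir_guga):
        # tail starting with a non-A base stops the match at the canonical end
        call = call_tail(mir_guga.mature_seq + "GA", mir_guga)
        assert (call.end_offset, call.tail_seq, call.tail_class) == (0, "GA", "other")

    def test_snrna_oligou_extends_templated_u_tract(self, u6_like):
        # U tail on a genomic U tract is templated-absorbed (maximal convention)
        call = call_tail(u6_like.mature_seq + "UUU", u6_like)
        assert (call.end_offset, call.tail_seq, call.tail_class) == (3, "", "none")


class TestClassification:
    @given(st.text(alphabet="ACGU", max_size=12))
    @settings(max_examples=300, deadline=None, derandomize=True)
    def test_totality_and_regex_agreement(self, tail):
        """Every tail string maps to exactly one class, matching the regex oracle."""
        assert classify_tail(tail) == classify_regex(tail)

    @pytest.mark.parametrize("tail,expected", [
        ("", "none"), ("A", "monoA"), ("AA", "oligoA"), ("U", "monoU"),
        ("UUU", "oligoU"), ("UA", "U_then_A"), ("UUAAA", "U_then_A"),
        ("AU", "other"), ("UAU", "other"), ("C", "other"), ("ACGU", "other"),
    ])
    def test_known_classes(self, tail, expected):
        assert classify_tail(tail) == expected


@pytest.mark.parametrize("max_mismatch", [0, 1, 2])
def test_oracle_equivalence_randomized(refset, rng, max_mismatch):
    """Greedy caller agrees with exhaustive split enumeration on random inserts."""
    refs = list(refset.values())
    for _ in range(2000):
        ref = refs[int(rng.integers(len(refs)))]
        insert = random_insert(rng, ref)
        got = call_tail(insert, ref, max_mismatch=max_mismatch)
        expected = oracle_call(insert, ref, max_mismatch=max_mismatch)
        assert (got.status, got.end_offset, got.tail_seq, got.tail_class,
                got.n_mismatch) == expected, insert


def test_maximality_no_tail_starts_with_next_templated_base(refset, rng):
    """At max_mismatch=0 the first tail base always differs from the next templated base."""
    refs = list(refset.values())
    for _ in range(2000):
        ref = refs[int(rng.integers(len(refs)))]
        insert = random_insert(rng, ref)
        call = call_tail(insert, ref, max_mismatch=0)
        if call.status != "called" or not call.tail_seq:
            continue
        pos = len(ref.mature_seq) + call.end_offset
        if pos < len(ref.template):
            assert call.tail_seq[0] != ref.template[pos]


class TestCallSample:
    def test_two_distinct_references_all_called(self, clean_pair):
        reads = []
        for ref in clean_pair.values():
            for i in range(10):
                reads.append(ReadRecord(f"{ref.ref_id}-{i}", ref.mature_seq + "A" + ADAPTER))
        calls, counts = call_sample(reads, clean_pair, adapter_seq=ADAPTER)
        assert counts == {"called": 20}
        assert (calls["tail_class"] == "monoA").all()

    def test_unmatched_read(self, clean_pair):
        reads = [ReadRecord("junk", "CACACACACACACACACACACA" + ADAPTER)]
        calls, counts = call_sample(reads, clean_pair, adapter_seq=ADAPTER)
        assert counts == {"unmatched": 1}

    def test_collision_fixture_is_ambiguous(self):
        shared = "ACGUACGUACGUACGU"
        refs = {
            "a": ReferenceRecord("a", "miRNA", shared + "CCAAG", "GGGGCCCC"),
            "b": ReferenceRecord("b", "miRNA", shared + "CCAAC", "GGGGCCCC"),
        }
        # read matches both references over its first 16+ bases equally
        read = ReadRecord("r", shared + "CC" + ADAPTER)
        calls, counts = call_sample([read], refs, adapter_seq=ADAPTER)
        assert counts == {"ambiguous_ref": 1}
        assert calls.loc[0, "status"] == "ambiguous_ref"

    def test_no_adapter_flagged_but_called_fields_populated(self, mir_guga):
        reads = [ReadRecord("r", mir_guga.mature_seq + "AA")]
        calls, counts = call_sample(reads, {mir_guga.ref_id: mir_guga}, adapter_seq=ADAPTER)
        assert counts == {"no_adapter": 1}
        # downstream A absorbs the first A
        assert calls.loc[0, "end_offset"] == 1
        assert calls.loc[0, "tail_seq"] == "A"

    def test_empty_reference_set_errors(self):
        with pytest.raises(ValueError):
            call_sample([], {})


def test_tail_caller_estimator_round(clean_pair):
    """sklearn-style transformer produces the same table as call_sample."""
    reads = [ReadRecord(f"r{i}", list(clean_pair.values())[0].mature_seq + "AA" + ADAPTER)
             for i in range(5)]
    est = TailCaller(references=clean_pair, adapter_seq=ADAPTER)
    params = est.get_params()
    assert params["max_mismatch"] == 1
    out = est.fit(reads).transform(reads)
    expected, _ = call_sample(reads, clean_pair, adapter_seq=ADAPTER)
    assert out.equals(expected)
    assert est.status_counts_ == {"called": 5}


def test_assign_reference_prefers_longest_anchor(refset, mir_guga):
    ref_id, status = assign_reference(mir_guga.mature_seq + "AAAA", refset)
    assert (ref_id, status) == (mir_guga.ref_id, "called")
    assert assign_reference("CACACACACACACACA", refset) == (None, "unmatched")
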