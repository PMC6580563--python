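"""Adapter alignment: examples, oracle equivalence, and invariants."""

import random

import pytest
from hypothesis import given, settings, strategies as st

from fqprep.adapter_align import (
    AdapterKind,
    AdapterSpec,
    AlignParams,
    exact_search,
    find_best_match,
    remove_adapter,
    semiglobal_align,
)

from conftest import make_record, random_alignment_case, run_case
from oracles import align_oracle, enumerate_alignments_recursive, _pair_outcomes

TRUSEQ = "AGATCGGAAGAGC"


class TestExactSearch:
    def test_internal_occurrence_leftmost(self):
        m = exact_search("TTAGATCGGAAGAGCTT", TRUSEQ)
        assert (m.read_start, m.read_stop) == (2, 15)
        assert m.errors == 0 and m.matches == len(TRUSEQ)

    def test_absent(self):
        assert exact_search("ACGTACGT", "GGGG") is None

    def test_identity(self):
        m = exact_search("AAAA", "AAAA")
        assert (m.read_start, m.read_stop) == (0, 4)

    def test_n_never_matches(self):
        # a verbatim 'N' hit would disagree with the aligner's N-mismatch rule
        assert exact_search("AANAA", "ANA") is None
        assert exact_search("AANAA", "NAA") is None


class TestSemiglobalExamples:
    def test_one_substitution_within_rate(self):
        # adapter with a single substitution planted mid-read
        read = "CCCCAGATCGGTAGAGC"
        m = semiglobal_align(read, AdapterSpec(TRUSEQ), AlignParams(0.1, 3, True))
        assert m is not None
        assert m.errors == 1 and m.aligned_length == 13
        assert m.error_rate == pytest.approx(1 / 13)
        assert m.read_start == 4

    def test_overlap_below_minimum_absent(self):
        read = "GTCAGTCAGTCAGTCAAG"  # ends with 2-base adapter prefix
        m = semiglobal_align(read, AdapterSpec(TRUSEQ), AlignParams(0.1, 3, True))
        assert m is None

    def test_three_mismatches_above_rate_absent(self):
        corrupted = "AGGTCGGATGAGT"  # TRUSEQ with 3 substitutions
        read = "CC" + corrupted + "CC"
        assert align_oracle(read, TRUSEQ, "3p", False, 0.1, 3, True) is None
        assert semiglobal_align(read, AdapterSpec(TRUSEQ), AlignParams(0.1, 3, True)) is None

    def test_three_prime_partial_overlap_at_end(self):
        read = "TTTTTTTTTTTT" + TRUSEQ[:6]
        m = semiglobal_align(read, AdapterSpec(TRUSEQ), AlignParams(0.1, 3, True))
        assert m is not None
        assert (m.read_stop, m.adapter_start, m.adapter_stop) == (len(read), 0, 6)

    def test_five_prime_partial_overlap_at_start(self):
        read = TRUSEQ[-6:] + "TTTTTTTTTTTT"
        spec = AdapterSpec(TRUSEQ, kind=AdapterKind.FIVE_PRIME)
        m = semiglobal_align(read, spec, AlignParams(0.1, 3, True))
        assert m is not None
        assert (m.read_start, m.adapter_start, m.adapter_stop) == (0, 7, 13)

    def test_anchored_requires_read_end(self):
        spec = AdapterSpec("ACGT", kind=AdapterKind.THREE_PRIME, anchored=True)
        assert semiglobal_align("TTACGTTT", spec, AlignParams(0.0, 1, True)) is None
        m = semiglobal_align("TTTTACGT", spec, AlignParams(0.0, 1, True))
        assert m is not None and m.read_stop == 8 and m.aligned_length == 4


class TestOracleEquivalence:
    def test_randomized_cases_match_oracle(self, rng):
        for _ in range(400):
            case = random_alignment_case(rng)
            got, want = run_case(*case)
            assert got == want, f"case {case}: impl {got} != oracle {want}"

    def test_oracle_agrees_with_recursive_enumeration(self, rng):
        """The set-DP oracle equals naive edit-script recursion on tiny pairs."""
        for _ in range(60):
            n = rng.randint(1, 8)
            m = rng.randint(1, 4)
            read = "".join(rng.choice("ACGT") for _ in range(n))
            adapter = "".join(rng.choice("ACGT") for _ in range(m))
            budget = rng.randint(0, 2)
            s = rng.randint(0, n)
            got = _pair_outcomes(read, adapter, 0, m, s, budget)
            want = enumerate_alignments_recursive(read, adapter, 0, m, s, budget)
            flat = {
                (t, c): mat for t, cell in got.items() for c, mat in cell.items()
            }
            best_rec = {}
            for (t, c, mat) in want:
                if best_rec.get((t, c), -1) < mat:
                    best_rec[(t, c)] = mat
            assert flat == best_rec


class TestInvariants:
    def test_exact_hit_implies_zero_error_alignment(self, rng):
        for _ in range(100):
            read = "".join(rng.choice("ACGT") for _ in range(rng.randint(5, 30)))
            pos = rng.randint(0, len(read) - 4)
            adapter = read[pos : pos + 4]
            hit = exact_search(read, adapter)
            assert hit is not None and hit.errors == 0
            m = semiglobal_align(read, AdapterSpec(adapter), AlignParams(0.2, 3, True))
            assert m is not None and m.errors == 0
            assert (m.read_start, m.read_stop) == (hit.read_start, hit.read_stop)

    def test_monotone_in_error_rate_and_overlap(self, rng):
        reads = []
        for _ in range(150):
            reads.append(random_alignment_case(rng)[0])
        spec = AdapterSpec(TRUSEQ)

        def hits(e, O):
            p = AlignParams(e, O, True)
            return [semiglobal_align(r, spec, p) is not None for r in reads]

        for O in (1, 3):
            found = [hits(e, O) for e in (0.0, 0.1, 0.2)]
            for lo, hi in zip(found, found[1:]):
                assert all(h or not l for l, h in zip(lo, hi))
        for e in (0.0, 0.2):
            found = [hits(e, O) for O in (1, 3, 5)]
            for big, small in zip(found, found[1:]):
                assert all(b or not s for s, b in zip(small, big))

    def test_no_indels_never_fewer_errors_than_indels(self, rng):
        for _ in range(150):
            read, adapter, kind, anchored, e, O, _ = random_alignment_case(rng)
            spec = AdapterSpec(adapter, AdapterKind.THREE_PRIME)
            with_i = semiglobal_align(read, spec, AlignParams(e, O, True))
            without = semiglobal_align(read, spec, AlignParams(e, O, False))
            if without is not None:
                assert with_i is not None
                assert with_i.matches >= without.matches

    def test_removal_conserves_length(self):
        read = "TT" + TRUSEQ + "GG"
        rec = make_record(read)
        spec = AdapterSpec(TRUSEQ)
        m = semiglobal_align(read, spec, AlignParams(0.1, 3, True))
        out = remove_adapter(rec, spec, m)
        removed = len(rec) - len(out)
        assert removed == len(rec) - m.read_start
        assert out.seq == "TT" and len(out.qual) == len(out.seq)

    def test_five_prime_removal_keeps_tail(self):
        rec = make_record(TRUSEQ + "GGCCGGC")
        spec = AdapterSpec(TRUSEQ, kind=AdapterKind.FIVE_PRIME)
        m = semiglobal_align(rec.seq, spec, AlignParams(0.1, 3, True))
        out = remove_adapter(rec, spec, m)
        assert out.seq == "GGCCGGC"

    def test_remove_out_of_bounds_raises(self):
        from fqprep.adapter_align import AdapterMatch

        rec = make_record("ACGT")
        bad = AdapterMatch(2, 9, 0, 7, 0, 7)
        with pytest.raises(ValueError):
            remove_adapter(rec, AdapterSpec("ACGTACG"), bad)


class TestFindBestMatch:
    def test_prefers_more_matches(self):
        read = "TT" + TRUSEQ + "GG"
        good = AdapterSpec(TRUSEQ, label="good")
        other = AdapterSpec("AGATCGGAAG", label="short")  # 10-base prefix
        found = find_best_match(read, [other, good], AlignParams(0.1, 3, True))
        assert found is not None and found[0].label == "good"

    def test_tie_goes_to_earlier_adapter(self):
        read = "CCCCAAAATTTT"
        a1 = AdapterSpec("AAAA", label="first")
        a2 = AdapterSpec("TTTT", label="second")
        found = find_best_match(read, [a1, a2], AlignParams(0.0, 3, True))
        assert found[0].label == "first"

    def test_none_when_nothing_matches(self):
        found = find_best_match("ACGTACGTACGT", [AdapterSpec("GGGGGGG")],
                                AlignParams(0.0, 3, True))
        assert found is None

    def test_empty_adapter_list_rejected(self):
        with pytest.raises(ValueError):
            find_best_match("ACGT", [], AlignParams())


@settings(max_examples=60, deadline=None, derandomize=True)
@given(
    read=st.text(alphabet="ACGTN", min_size=1, max_size=20),
    adapter=st.text(alphabet="ACGT", min_size=1, max_size=6),
    e=st.sampled_from([0.0, 0.1, 0.2]),
    O=st.sampled_from([1, 3]),
    indels=st.booleans(),
)
def test_property_alignment_matches_oracle(read, adapter, e, O, indels):
    got, want = run_case(read, adapter, "3p", False, e, O, indels)
    assert got == want
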