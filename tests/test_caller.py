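import numpy as np
import pytest

from isomirkit import (
    CallerParams,
    CollapsedRead,
    HairpinRef,
    MatureAnnotation,
    call_sample,
    decompose,
    label_call,
    rank_isoforms,
    reconstruct,
)
from isomirkit.caller import CallerError, write_mirgff3

from _oracle import brute_force_decompose
from conftest import TOY_MATURE

M = TOY_MATURE  # 22-nt mature ending ...UGA; next hairpin base is G


class TestDecomposeToyCases:
    def test_canonical_identity(self, toy_hairpin, toy_annot):
        call = decompose(M, toy_hairpin, toy_annot)
        assert (call.shift5, call.trim3, call.ext3, call.tail) == (0, 0, 0, "")
        assert call.label == "canonical"

    def test_plus_a_is_non_templated(self, toy_hairpin, toy_annot):
        call = decompose(M + "A", toy_hairpin, toy_annot)
        assert (call.ext3, call.tail) == (0, "A")
        assert call.label == "Plus A"

    def test_templated_extension_g(self, toy_hairpin, toy_annot):
        call = decompose(M + "G", toy_hairpin, toy_annot)
        assert (call.ext3, call.tail) == (1, "")
        assert call.label == "Ext+1"

    def test_trim_one_is_trim_a(self, toy_hairpin, toy_annot):
        call = decompose(M[:-1], toy_hairpin, toy_annot)
        assert call.trim3 == 1
        assert call.label == "Trim A"

    def test_trim_three_is_trim_agu(self, toy_hairpin, toy_annot):
        call = decompose(M[:-3], toy_hairpin, toy_annot)
        assert call.trim3 == 3
        assert call.label == "Trim AGU"

    def test_trim_two_is_trim_ag(self, toy_hairpin, toy_annot):
        assert decompose(M[:-2], toy_hairpin, toy_annot).label == "Trim AG"

    def test_five_prime_shift(self, toy_hairpin, toy_annot):
        assert decompose(M[1:], toy_hairpin, toy_annot).label == "5p+1"
        extended = toy_hairpin.sequence[toy_annot.start - 1 : toy_annot.end]
        assert decompose(extended, toy_hairpin, toy_annot).label == "5p-1"

    def test_substitution_outside_core(self, toy_hairpin, toy_annot):
        pos = len(M) - 2
        alt = "A" if M[pos] != "A" else "C"
        seq = M[:pos] + alt + M[pos + 1 :]
        call = decompose(seq, toy_hairpin, toy_annot)
        assert call.substitutions == ((pos, M[pos], alt),)
        assert call.label == f"canonical;sub{pos}{M[pos]}>{alt}"

    def test_core_mismatch_is_no_call(self, toy_hairpin, toy_annot):
        # position 5 is inside the default mismatch-free anchor region
        alt = "A" if M[5] != "A" else "C"
        seq = M[:5] + alt + M[6:]
        assert decompose(seq, toy_hairpin, toy_annot) is None

    def test_unrelated_sequence_is_no_call(self, toy_hairpin, toy_annot):
        assert decompose("ACGU" * 5, toy_hairpin, toy_annot) is None

    def test_length_window_enforced(self, toy_hairpin, toy_annot):
        with pytest.raises(CallerError):
            decompose("ACGUACGUACGUAC", toy_hairpin, toy_annot)  # 14 nt

    def test_greedy_maximality(self, toy_hairpin, toy_annot):
        # overhang GC: both bases templated (context GCUAG) -> pure extension
        call = decompose(M + "GC", toy_hairpin, toy_annot)
        assert (call.ext3, call.tail) == (2, "")
        # overhang GA: templated G then non-templated A
        call = decompose(M + "GA", toy_hairpin, toy_annot)
        assert (call.ext3, call.tail) == (1, "A")
        assert call.label == "Ext+1 Plus A"

    def test_produced_tail_never_starts_templated(self, toy_hairpin, toy_annot):
        ctx = toy_hairpin.sequence[toy_annot.end :]
        for tail_base in "ACGU":
            call = decompose(M + tail_base, toy_hairpin, toy_annot)
            if call.tail and call.ext3 < CallerParams().max_3p_ext:
                assert call.tail[0] != ctx[call.ext3]


class TestTrimTailFlag:
    def test_disabled_by_default(self, toy_hairpin, toy_annot):
        call = decompose(M[:-2] + "C", toy_hairpin, toy_annot)
        # explained as a trim plus a substitution, not trim-then-tail
        assert call.tail == "" and call.trim3 == 1

    def test_enabled_enumerates_mixed_forms(self, toy_hairpin, toy_annot):
        params = CallerParams(allow_trim_tail=True, max_mismatch=0)
        call = decompose(M[:-2] + "C", toy_hairpin, toy_annot, params)
        assert call is not None
        assert call.trim3 == 2 and call.tail == "C"
        assert call.label == "Trim AG Plus C"


class TestRoundTrip:
    @pytest.mark.parametrize(
        "variant",
        [M, M + "A", M + "G", M + "GC", M + "GA", M[:-1], M[:-2], M[:-3], M[1:], M[2:]],
        ids=["canonical", "plusA", "ext1", "ext2", "ext1plusA", "trim1", "trim2",
             "trim3", "5p+1", "5p+2"],
    )
    def test_reconstruct_inverts_decompose(self, toy_ref, toy_hairpin, toy_annot, variant):
        call = decompose(variant, toy_hairpin, toy_annot)
        assert call is not None
        assert reconstruct(call, toy_ref) == variant

    def test_reconstruct_with_substitution(self, toy_ref, toy_hairpin, toy_annot):
        pos = len(M) - 2
        alt = "A" if M[pos] != "A" else "C"
        seq = M[:pos] + alt + M[pos + 1 :]
        call = decompose(seq, toy_hairpin, toy_annot)
        assert reconstruct(call, toy_ref) == seq

    def test_inconsistent_call_rejected(self, toy_ref, toy_hairpin, toy_annot):
        call = decompose(M, toy_hairpin, toy_annot)
        bad = type(call)(
            sequence=M, mature_id=call.mature_id, shift5=0, trim3=1, ext3=1,
            tail="", substitutions=(), label="x",
        )
        with pytest.raises(CallerError):
            reconstruct(bad, toy_ref)


class TestOracleEquivalence:
    def test_matches_brute_force_on_toy_variants(self, toy_hairpin, toy_annot):
        params = CallerParams()
        variants = [M, M + "A", M + "G", M + "GA", M + "AAA", M[:-1], M[:-3],
                    M[1:], M[2:], M[1:] + "A"]
        for seq in variants:
            got = decompose(seq, toy_hairpin, toy_annot, params)
            exp = brute_force_decompose(
                seq, toy_hairpin.sequence, toy_annot.start, toy_annot.end, params,
                toy_annot.mature_id,
            )
            assert got is not None and exp is not None
            assert (got.shift5, got.trim3, got.ext3, got.tail, got.substitutions) == (
                exp["shift5"], exp["trim3"], exp["ext3"], exp["tail"],
                exp["substitutions"],
            )

    def test_matches_brute_force_on_random_pairs(self):
        from _oracle import random_read_pair

        params = CallerParams()
        rng = np.random.default_rng(20240)
        for _ in range(300):
            hp_seq, start, end, read = random_read_pair(rng, params)
            hairpin = HairpinRef("h", hp_seq)
            annot = MatureAnnotation("m", "h", start, end)
            got = decompose(read, hairpin, annot, params)
            exp = brute_force_decompose(read, hp_seq, start, end, params, "m")
            if exp is None:
                assert got is None
            else:
                assert got is not None
                assert (got.edits, abs(got.shift5), len(got.tail)) == (
                    exp["edits"], abs(exp["shift5"]), len(exp["tail"]),
                )
                assert (got.shift5, got.trim3, got.ext3, got.tail) == (
                    exp["shift5"], exp["trim3"], exp["ext3"], exp["tail"],
                )


class TestLabeling:
    def test_label_call_matches_stored_label(self, toy_ref, toy_hairpin, toy_annot):
        for seq in [M, M + "A", M[:-2], M[1:]]:
            call = decompose(seq, toy_hairpin, toy_annot)
            assert label_call(call, toy_ref) == call.label

    def test_compound_label_order(self, toy_hairpin, toy_annot):
        call = decompose(M[1:-1], toy_hairpin, toy_annot)
        assert call.label == "5p+1 Trim A"


class TestCallSample:
    def test_counts_and_rpm(self, toy_ref):
        collapsed = [CollapsedRead(M, 900), CollapsedRead(M + "A", 100)]
        prof = call_sample(collapsed, toy_ref, sample_id="s")
        key_c = ("toy-miR-5p", "canonical")
        key_a = ("toy-miR-5p", "Plus A")
        assert prof.entries == {key_c: 900, key_a: 100}
        assert prof.rpm[key_c] == pytest.approx(9e5)
        assert prof.rpm[key_a] == pytest.approx(1e5)
        assert sum(prof.rpm.values()) == pytest.approx(1e6)

    def test_unassigned_accumulates(self, toy_ref):
        collapsed = [CollapsedRead("ACGU" * 5, 7)]
        prof = call_sample(collapsed, toy_ref)
        assert prof.total_assigned == 0
        assert prof.total_unassigned == 7
        assert prof.rpm == {}

    def test_conservation(self, toy_ref):
        collapsed = [
            CollapsedRead(M, 10),
            CollapsedRead(M[:-1], 5),
            CollapsedRead("ACGU" * 5, 3),
        ]
        prof = call_sample(collapsed, toy_ref)
        assert prof.total_assigned + prof.total_unassigned == 18

    def test_order_invariance(self, toy_ref):
        collapsed = [CollapsedRead(M, 10), CollapsedRead(M[:-1], 5)]
        a = call_sample(collapsed, toy_ref)
        b = call_sample(list(reversed(collapsed)), toy_ref)
        assert a.entries == b.entries

    def test_empty_reference_is_error(self):
        from isomirkit import ReferenceSet

        with pytest.raises(CallerError, match="empty"):
            call_sample([], ReferenceSet())

    def test_profile_tsv_round_trip(self, toy_ref, tmp_path):
        from isomirkit import IsomiRProfile

        prof = call_sample([CollapsedRead(M, 3), CollapsedRead(M + "A", 2)], toy_ref, sample_id="s9")
        p = tmp_path / "prof.tsv"
        prof.write_tsv(p)
        again = IsomiRProfile.read_tsv(p)
        assert again.entries == prof.entries
        assert again.sample_id == "s9"


class TestRankIsoforms:
    def test_non_canonical_can_rank_first(self, toy_ref):
        prof = call_sample([CollapsedRead(M, 5), CollapsedRead(M[:-1], 10)], toy_ref)
        assert rank_isoforms(prof, "toy-miR-5p", 1) == [("Trim A", 10)]

    def test_n_larger_than_entries(self, toy_ref):
        prof = call_sample([CollapsedRead(M, 5)], toy_ref)
        assert rank_isoforms(prof, "toy-miR-5p", 10) == [("canonical", 5)]

    def test_ties_break_lexicographically(self, toy_ref):
        prof = call_sample([CollapsedRead(M + "A", 5), CollapsedRead(M[:-1], 5)], toy_ref)
        assert rank_isoforms(prof, "toy-miR-5p", 2) == [("Plus A", 5), ("Trim A", 5)]

    def test_unknown_mature_raises(self, toy_ref):
        prof = call_sample([CollapsedRead(M, 1)], toy_ref)
        with pytest.raises(CallerError):
            rank_isoforms(prof, "nope", 1)


def test_mirgff3_output_variant_attributes(toy_ref, tmp_path):
    collapsed = [CollapsedRead(M, 3), CollapsedRead(M[:-1], 2), CollapsedRead(M + "A", 1)]
    prof = call_sample(collapsed, toy_ref)
    out = tmp_path / "iso.gff3"
    write_mirgff3(prof, toy_ref, out)
    text = out.read_text()
    assert "Variant=iso_3p:-1" in text
    assert "Variant=iso_add3p:1" in text
    assert "Variant=NA" in text  # canonical
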