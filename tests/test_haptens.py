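"""GRAVY, run lengths, filtering, ranking, synthesis strings."""

import pytest
from hypothesis import given, strategies as st

from grainpep.errors import AlphabetError
from grainpep.haptens import (HaptenCandidate, KYTE_DOOLITTLE,
                              count_occurrences, filter_candidates, gravy,
                              max_residue_run, prepare_synthesis,
                              rank_candidates)

RESIDUES = "ACDEFGHIKLMNPQRSTVWY"


class TestGravy:
    @pytest.mark.parametrize("seq,expected", [
        ("IIIII", 4.5),                    # homopolymer equals residue value
        ("CDEF", (2.5 - 3.5 - 3.5 + 2.8) / 4),   # hand sum = -0.425
        ("RRRR", -4.5),
    ])
    def test_hand_computed_values(self, seq, expected):
        assert gravy(seq) == pytest.approx(expected, abs=1e-12)

    def test_ambiguity_errors_by_default(self):
        with pytest.raises(AlphabetError):
            gravy("QX")

    def test_ambiguity_skip_policy(self):
        assert gravy("QX", on_ambiguity="skip") == pytest.approx(-3.5)

    def test_empty_sequence_errors(self):
        with pytest.raises(AlphabetError):
            gravy("")

    @given(st.text(RESIDUES, min_size=1, max_size=30),
           st.text(RESIDUES, min_size=1, max_size=30))
    def test_concatenation_weighted_mean_identity(self, a, b):
        combined = gravy(a + b)
        weighted = (len(a) * gravy(a) + len(b) * gravy(b)) / (len(a) + len(b))
        assert combined == pytest.approx(weighted, abs=1e-12)

    @given(st.text(RESIDUES, min_size=1, max_size=50))
    def test_bounded_and_reversal_invariant(self, seq):
        g = gravy(seq)
        assert min(KYTE_DOOLITTLE.values()) <= g <= max(KYTE_DOOLITTLE.values())
        assert g == pytest.approx(gravy(seq[::-1]), abs=1e-12)


@pytest.mark.parametrize("seq,expected", [
    ("QQQPFP", 3), ("ABAB", 1), ("AAAAA", 5), ("Q", 1), ("PQQQQP", 4),
])
def test_max_residue_run(seq, expected):
    assert max_residue_run(seq) == expected


def _cand(seq, gravy_val=None, gpt="gliadin", occurrence=1, start=0,
          status="candidate", reason=""):
    return HaptenCandidate(
        grain="wheat", gpt_name=gpt, start=start, end=start + len(seq),
        sequence=seq, gravy=gravy(seq) if gravy_val is None else gravy_val,
        max_run=max_residue_run(seq), occurrence=occurrence,
        status=status, reject_reason=reason)


class TestFilter:
    def test_survivor_passes_all_bounds(self):
        out = filter_candidates([_cand("CDEFCDEF")])  # gravy -0.425, run 1
        assert out[0].status == "candidate"

    def test_hydrophobic_rejection(self):
        out = filter_candidates([_cand("IVLFIVLF")])
        assert out[0].reject_reason == "hydrophobic"

    def test_gravy_zero_is_hydrophobic_under_strict_threshold(self):
        out = filter_candidates([_cand("QQ", gravy_val=0.0)])
        assert out[0].reject_reason == "hydrophobic"

    def test_repeat_run_fires_before_length(self):
        # run of 4 AND length 22: repeat_run wins by fixed rule order
        seq = "QQQQPFP" + "DE" * 8  # hydrophilic, run 4, length 23
        out = filter_candidates([_cand(seq)])
        assert out[0].reject_reason == "repeat_run"

    def test_too_long_rejection(self):
        seq = "DEKR" * 6  # 24 residues, hydrophilic, run 1
        out = filter_candidates([_cand(seq)])
        assert out[0].reject_reason == "too_long"

    def test_audit_conservation_and_vocabulary(self):
        cands = [_cand("CDEFCDEF"), _cand("IVLFIVLF"),
                 _cand("QQQQPFPDE"), _cand("DEKR" * 6),
                 _cand("NNDEQK", status="rejected", reason="exclusion_shared")]
        out = filter_candidates(cands)
        assert len(out) == len(cands)
        kept = [c for c in out if c.status == "candidate"]
        rejected = [c for c in out if c.status == "rejected"]
        assert len(kept) + len(rejected) == len(cands)
        assert {c.reject_reason for c in rejected} <= {
            "exclusion_shared", "hydrophobic", "repeat_run", "too_long"}

    def test_prior_rejection_passes_through_unchanged(self):
        c = _cand("IVLFIVLF", status="rejected", reason="exclusion_shared")
        out = filter_candidates([c])
        assert out[0].reject_reason == "exclusion_shared"


class TestOccurrence:
    def test_overlapping_count(self):
        assert count_occurrences("QQP", ["AQQPQQPA"]) == 2

    def test_overlap_within_single_match_region(self):
        assert count_occurrences("QQ", ["QQQQ"]) == 3

    def test_full_consensus_once(self):
        assert count_occurrences("AQQPA", ["AQQPA"]) == 1

    def test_absent_segment_zero(self):
        assert count_occurrences("WWW", ["AQQPA", "QNDKE"]) == 0

    def test_counts_across_whole_grain_set(self):
        assert count_occurrences("QQP", ["AQQPA", "QQPQQP"]) == 3

    @given(st.text("QP", min_size=1, max_size=4),
           st.text("QP", min_size=1, max_size=40))
    def test_matches_naive_sliding_window(self, needle, hay):
        naive = sum(hay[i:i + len(needle)] == needle
                    for i in range(len(hay) - len(needle) + 1))
        assert count_occurrences(needle, [hay]) == naive


ABUNDANCE = {"gliadin": 0.3, "hordein": 0.2}


class TestRanking:
    def test_occurrence_dominates(self):
        a = _cand("DDEEKKRRA", occurrence=3)
        b = _cand("DDEEKKRRN", occurrence=1)
        ranked = rank_candidates([b, a], ABUNDANCE)
        assert [c.occurrence for c in ranked] == [3, 1]
        assert [c.rank_score for c in ranked] == [1, 2]

    def test_length_priority_flag(self):
        # lengths 8 vs 12 with preferred_min_len=9: only the 12-mer is
        # prioritised, so it ranks first despite identical occurrence
        short = _cand("DDEEKKRR", occurrence=1)
        long = _cand("DDEEKKRRDDEE", occurrence=1)
        ranked = rank_candidates([short, long], ABUNDANCE, preferred_min_len=9)
        assert ranked[0].length == 12

    def test_abundance_breaks_ties(self):
        a = _cand("DDEEKKRRA", gpt="gliadin")
        b = _cand("DDEEKKRRN", gpt="hordein")
        ranked = rank_candidates([b, a], ABUNDANCE)
        assert ranked[0].gpt_name == "gliadin"

    def test_alphabetical_final_tiebreak(self):
        a = _cand("AADDEEKKR")
        q = _cand("QQDDEEKKR")
        ranked = rank_candidates([q, a], ABUNDANCE)
        assert ranked[0].sequence.startswith("AA")

    def test_total_order_permutation_invariant(self):
        import itertools
        cands = [_cand("DDEEKKRRA", occurrence=2),
                 _cand("DDEEKKRR"), _cand("AADDEEKKR"),
                 _cand("QQDDEEKKR", gpt="hordein")]
        reference = rank_candidates(cands, ABUNDANCE)
        for perm in itertools.permutations(cands):
            assert rank_candidates(list(perm), ABUNDANCE) == reference

    def test_missing_abundance_names_gpt(self):
        with pytest.raises(KeyError, match="secalin"):
            rank_candidates([_cand("DDEEKKRRA", gpt="secalin")], ABUNDANCE)

    def test_rejected_input_refused(self):
        bad = _cand("DDEEKKRRA", status="rejected", reason="hydrophobic")
        with pytest.raises(ValueError):
            rank_candidates([bad], ABUNDANCE)


class TestSynthesis:
    def test_cysteine_prepended_when_absent(self):
        assert prepare_synthesis("QPFPQQ") == "Ac-CQPFPQQ-NH2"

    def test_no_prepend_when_cys_present(self):
        assert prepare_synthesis("CQQPFP") == "Ac-CQQPFP-NH2"

    def test_internal_cys_counts(self):
        assert prepare_synthesis("QQCPFP") == "Ac-QQCPFP-NH2"

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            prepare_synthesis("")
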