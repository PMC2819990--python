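import math

import numpy as np
import pytest

from slimsig import (
    Alphabet,
    MotifParseError,
    ProteinSequence,
    SequenceDataset,
    UnsupportedMotifError,
    count_support,
    motif_probability,
    parse_motif,
    prob_one_or_more,
    scan_occurrences,
)
from slimsig.motif_model import placement_count

AA = Alphabet()
LW = Alphabet(("L", "W"))


class TestParseMotif:
    def test_table4_style_pattern(self):
        m = parse_motif("P..P.[KR]", AA)
        assert m.l == 3
        assert m.is_ambiguous()
        assert m.span == 6
        assert m.pattern() == "P..P.[KR]"

    def test_fixed_dimer(self):
        m = parse_motif("WW", LW)
        assert (m.l, m.span, m.n_anchor, m.c_anchor) == (2, 2, False, False)
        assert not m.is_ambiguous()

    def test_terminal_anchors(self):
        m = parse_motif("^M", AA)
        assert m.n_anchor and not m.c_anchor and m.l == 1
        m2 = parse_motif("LL$", AA)
        assert m2.c_anchor and m2.pattern() == "LL$"

    def test_variable_spacer(self):
        m = parse_motif("RR.L.{0,1}F", AA)
        assert m.l == 4
        assert m.is_ambiguous()
        assert m.span_range == (5, 6)
        assert m.pattern() == "RR.L.{0,1}F"

    @pytest.mark.parametrize(
        "pattern",
        ["", "[]A", "[ZB]", "A^B", "AB$C", "A.{2,1}B", "A{1,2}B", "[AB", "..."],
    )
    def test_malformed_patterns_rejected(self, pattern):
        with pytest.raises(MotifParseError):
            parse_motif(pattern, AA)

    def test_parse_error_reports_offset(self):
        with pytest.raises(MotifParseError) as err:
            parse_motif("AA[]B", AA)
        assert err.value.position == 2

    def test_single_residue_bracket_collapses_to_fixed(self):
        m = parse_motif("[K]R", AA)
        assert not m.is_ambiguous()
        assert m.pattern() == "KR"


class TestMotifProbability:
    def test_dimer_probabilities(self, worked_freqs):
        assert motif_probability(parse_motif("WW", LW), worked_freqs) == pytest.approx(0.01)
        assert motif_probability(parse_motif("LL", LW), worked_freqs) == pytest.approx(0.81)
        assert motif_probability(parse_motif("WL", LW), worked_freqs) == pytest.approx(0.09)

    def test_wildcard_is_neutral(self, worked_freqs):
        assert motif_probability(parse_motif("W.W", LW), worked_freqs) == pytest.approx(0.01)

    def test_exhaustive_ambiguity_sums_to_one(self, worked_freqs):
        assert motif_probability(parse_motif("[LW]", LW), worked_freqs) == pytest.approx(1.0)

    def test_variable_spacer_refused(self, worked_freqs):
        with pytest.raises(UnsupportedMotifError):
            motif_probability(parse_motif("W.{0,1}W", LW), worked_freqs)

    def test_missing_residue_gives_zero(self):
        assert motif_probability(parse_motif("WW", LW), {"L": 1.0}) == 0.0


class TestProbOneOrMore:
    def test_ww_on_length5_protein(self, worked_dataset, worked_freqs):
        p = prob_one_or_more(parse_motif("WW", LW), worked_dataset.proteins[0], worked_freqs)
        assert round(p, 4) == 0.0394

    def test_wl_on_length5_protein(self, worked_dataset, worked_freqs):
        for pat in ("WL", "LW"):
            p = prob_one_or_more(parse_motif(pat, LW), worked_dataset.proteins[0], worked_freqs)
            assert round(p, 4) == 0.3143

    def test_impossible_motif_is_zero(self):
        prot = ProteinSequence("p", "LLLL")
        assert prob_one_or_more(parse_motif("WW", LW), prot, {"L": 1.0, "W": 0.0}) == 0.0

    def test_single_placement_equals_p_motif(self, worked_freqs):
        prot = ProteinSequence("p", "LW")
        m = parse_motif("WL", LW)
        assert prob_one_or_more(m, prot, worked_freqs) == pytest.approx(0.09)

    def test_protein_shorter_than_motif(self, worked_freqs):
        prot = ProteinSequence("p", "L")
        assert prob_one_or_more(parse_motif("WW", LW), prot, worked_freqs) == 0.0

    @pytest.mark.parametrize(
        "pattern,length,expected_n",
        [
            ("WW", 5, 4),
            ("^WW", 5, 1),
            ("WW$", 5, 1),
            ("^WW$", 2, 1),
            ("^WW$", 5, 0),
            ("^WW", 1, 0),
        ],
    )
    def test_placement_count_with_anchors(self, pattern, length, expected_n):
        assert placement_count(parse_motif(pattern, LW), length) == expected_n

    def test_monotone_in_length_and_probability(self, worked_freqs):
        m = parse_motif("WW", LW)
        probs = [
            prob_one_or_more(m, ProteinSequence("p", "L" * n), worked_freqs)
            for n in range(2, 30)
        ]
        assert all(b >= a for a, b in zip(probs, probs[1:]))
        assert all(0.0 <= p <= 1.0 for p in probs)


class TestScanning:
    def test_scan_examples(self):
        prot = ProteinSequence("p", "LWWLL")
        assert scan_occurrences(parse_motif("WW", LW), prot, LW) == [1]
        assert scan_occurrences(parse_motif("LL", LW), ProteinSequence("p", "LLLLL"), LW) == [0, 1, 2, 3]
        assert scan_occurrences(parse_motif("^L", LW), prot, LW) == [0]
        assert scan_occurrences(parse_motif("^W", LW), prot, LW) == []

    def test_c_anchor_matches_last_offset_only(self):
        prot = ProteinSequence("p", "LLWLL")
        assert scan_occurrences(parse_motif("LL$", LW), prot, LW) == [3]

    def test_variable_spacer_matches_each_admissible_span(self):
        prot = ProteinSequence("p", "WLWWW")
        m = parse_motif("W.{0,1}W", LW)
        # starts 0 (W-L-W, gap 1), 2 (WW gap 0), 3 (WW gap 0); offset 2 also W.W
        assert scan_occurrences(m, prot, LW) == [0, 2, 3]

    def test_masked_residue_matches_nothing_even_for_wildcard(self):
        prot = ProteinSequence("p", "WXW")
        m = parse_motif("W.W", LW)
        assert scan_occurrences(m, prot, LW) == []

    def test_support_counting(self, worked_dataset):
        assert count_support(parse_motif("LL", LW), worked_dataset) == 4
        assert count_support(parse_motif("WW", LW), worked_dataset) == 1
        empty = SequenceDataset([], LW)
        assert count_support(parse_motif("WW", LW), empty) == 0

    def test_scan_and_support_agree(self, worked_dataset):
        for pat in ("LL", "LW", "WL", "WW", "WWW"):
            m = parse_motif(pat, LW)
            k = count_support(m, worked_dataset)
            hits = sum(
                1 for p in worked_dataset if scan_occurrences(m, p, LW)
            )
            assert k == hits


def test_occurrence_model_agrees_with_simulation():
    """Empirical >=1-match frequency matches the independence model within 3 SE.

    Uses a motif without self-overlap (LWW) at a low per-window match
    probability, where the placement-independence assumption of the
    occurrence model is accurate well below Monte-Carlo resolution (at
    higher match densities the model visibly understates the no-match
    probability; that regime is a documented approximation, not a bug).
    """
    rng = np.random.default_rng(42)
    freqs = {"L": 0.9, "W": 0.1}
    m = parse_motif("LWW", LW)
    L, draws = 12, 20000
    expected = prob_one_or_more(m, ProteinSequence("t", "L" * L), freqs)
    seqs = rng.choice(["L", "W"], size=(draws, L), p=[0.9, 0.1])
    hits = sum(1 for row in seqs if "LWW" in "".join(row))
    observed = hits / draws
    se = math.sqrt(expected * (1 - expected) / draws)
    assert abs(observed - expected) < 3 * se
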