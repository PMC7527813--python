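"""Motif matching, maturation routing and degron assignment."""

import re

import pytest
from hypothesis import given
from hypothesis import strategies as st

from dppscan import (
    DEFAULT_DEGRON_TABLE,
    DegronClass,
    MotifRuleSet,
    classify_nterm,
    degron_class,
    match_motif,
    met_excision,
)
from dppscan.rules import CANONICAL_AA

LEGEND = MotifRuleSet.legend()
TEXT = MotifRuleSet.text()

canonical = st.text(alphabet=CANONICAL_AA, min_size=1, max_size=12)


class TestMatchMotif:
    @pytest.mark.parametrize(
        "sequence, legend_hit, text_hit",
        [
            ("MAPSVPAA", "P4", "P4"),  # AK2-style, Met excision then AP release
            ("MPGLVDSN", "P3", "P3"),  # COX17-style direct MP release
            ("MPGIVELP", "P3", "P3"),  # NDUFA8-style
            ("MEPS", "P4", "none"),  # Glu at position 2: variants disagree
            ("MDPS", "none", "none"),  # Asp excluded in both
            ("MAPP", "none", "none"),  # Pro after cleavage site blocks release
            ("MPPS", "P4", "P4"),  # Pro at 2 and 3: only the excision route fits
            ("MKKT", "none", "none"),
            ("AAPS", "none", "none"),  # no initiator Met
            ("MXPS", "none", "none"),  # ambiguity letter at constrained position
            ("MAPX", "none", "none"),
            ("MPXA", "none", "none"),
            ("MP", "none", "none"),  # too short for either motif
            ("MAPSX", "P4", "P4"),  # ambiguity outside the motif is fine
        ],
    )
    def test_worked_examples(self, sequence, legend_hit, text_hit):
        assert match_motif(sequence, LEGEND) == legend_hit
        assert match_motif(sequence, TEXT) == text_hit

    def test_empty_sequence_errors(self):
        with pytest.raises(ValueError):
            match_motif("", LEGEND)

    def test_lowercase_input_matches(self):
        assert match_motif("mapsvp", LEGEND) == "P4"

    @given(canonical)
    def test_patterns_disjoint(self, seq):
        """No sequence can satisfy both the direct and the excision pattern."""
        for rules in (LEGEND, TEXT):
            hit = match_motif(seq, rules)
            assert hit in ("none", "P3", "P4")
            if hit == "P3":
                assert seq[2] != "P"
            if hit == "P4":
                assert seq[2] == "P"

    @given(canonical)
    def test_text_variant_nested_in_legend(self, seq):
        """The stricter D/E exclusion can only lose matches, never gain them."""
        if match_motif(seq, TEXT) != "none":
            assert match_motif(seq, TEXT) == match_motif(seq, LEGEND)


def brute_force_match(seq: str, variant: str) -> str:
    """Independent regex-based oracle for the recognition motifs."""
    y_class = "".join(a for a in CANONICAL_AA if a not in ("D" if variant == "legend" else "DE"))
    x_class = "".join(a for a in CANONICAL_AA if a != "P")
    if re.match(f"^M[{y_class}]P[{x_class}]", seq):
        return "P4"
    if re.match(f"^MP[{x_class}]", seq):
        return "P3"
    return "none"


@given(st.text(alphabet=CANONICAL_AA + "XBZUJO", min_size=1, max_size=8))
def test_oracle_agreement_sampled(seq):
    for variant, rules in (("legend", LEGEND), ("text", TEXT)):
        assert match_motif(seq, rules) == brute_force_match(seq, variant)


class TestClassify:
    def test_ak2_ladder(self):
        """Met excision then AP release exposes Ser: the observed ladder."""
        outcome = classify_nterm("MAPSVPAA", LEGEND)
        assert outcome.pattern == "P4"
        assert outcome.route == "map_then_dpp"
        assert outcome.released == ("M", "AP")
        assert outcome.neo_residue == "S"
        assert outcome.neo_prefix == "SV"
        assert outcome.degron.branch == "AcN"

    def test_direct_route_neo_prefixes(self):
        for seq, prefix in [("MPGLVDSN", "GL"), ("MPGIVELP", "GI")]:
            outcome = classify_nterm(seq, LEGEND)
            assert outcome.pattern == "P3"
            assert outcome.route == "dpp_direct"
            assert outcome.released == ("MP",)
            assert outcome.neo_prefix == prefix
            assert outcome.degron.branch == "stabilizing"

    def test_non_substrate_fields_null(self):
        outcome = classify_nterm("MDPSVPAA", LEGEND)
        assert outcome.pattern == "none"
        assert outcome.route == "none"
        assert outcome.released == ()
        assert outcome.neo_residue is None
        assert outcome.neo_prefix is None
        assert outcome.degron is None

    def test_short_p3_match_truncated_prefix(self):
        outcome = classify_nterm("MPG", LEGEND)
        assert outcome.pattern == "P3"
        assert outcome.neo_prefix == "G"

    @given(canonical)
    def test_consistency_with_match(self, seq):
        outcome = classify_nterm(seq, LEGEND)
        assert outcome.pattern == match_motif(seq, LEGEND)
        if outcome.pattern == "P4":
            assert outcome.released == ("M", seq[1:3])
            assert outcome.neo_residue == seq[3]
        elif outcome.pattern == "P3":
            assert outcome.released == (seq[0:2],)
            assert outcome.neo_residue == seq[2]

    def test_determinism(self):
        assert classify_nterm("MAPSVPAA") == classify_nterm("MAPSVPAA")


class TestMetExcision:
    @pytest.mark.parametrize(
        "seq, expected",
        [
            ("MAPS", ("APS", True)),
            ("MDPS", ("MDPS", False)),
            ("AAPS", ("AAPS", False)),
            ("MPGL", ("PGL", True)),  # Pro is in the canonical small set
        ],
    )
    def test_rule(self, seq, expected):
        assert met_excision(seq) == expected

    def test_custom_small_set(self):
        assert met_excision("MAPS", small_residue_set={"S"}) == ("MAPS", False)

    def test_too_short_errors(self):
        with pytest.raises(ValueError):
            met_excision("M")


class TestDegron:
    @pytest.mark.parametrize(
        "residue, branch",
        [
            ("S", "AcN"),
            ("T", "AcN"),
            ("R", "ArgN_primary"),
            ("D", "ArgN_secondary"),
            ("N", "ArgN_tertiary"),
            ("Q", "ArgN_tertiary"),
            ("G", "stabilizing"),
            ("V", "stabilizing"),
        ],
    )
    def test_default_table(self, residue, branch):
        assert degron_class(residue).branch == branch

    def test_deamidation_note(self):
        assert "deamidation" in degron_class("N").note

    def test_table_covers_all_canonical(self):
        assert set(DEFAULT_DEGRON_TABLE) == set(CANONICAL_AA)
        assert set(DEFAULT_DEGRON_TABLE.values()) <= set(DegronClass.BRANCHES)

    def test_override_table(self):
        table = {aa: "stabilizing" for aa in CANONICAL_AA}
        table["G"] = "AcN"
        assert degron_class("G", table).branch == "AcN"
        assert classify_nterm("MPGL", degron_table=table).degron.branch == "AcN"

    def test_ambiguity_letter_errors(self):
        with pytest.raises(ValueError):
            degron_class("X")
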