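"""QUDT-phase rewriting, finalization conventions, order sensitivity."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from unitlink.pseudo import to_pseudounit
from unitlink.rewrite import finalize_candidate, map_pseudounit, rewrite_to_candidate
from unitlink.rules import RuleSet


def test_worked_example_passes_through_printed_intermediates(qudt_rules):
    candidate = rewrite_to_candidate("grampermetersquaredperday", qudt_rules)
    states = [after for _, _, after in candidate.trace]
    assert "gramper-M2-perday" in states
    assert "gramper-M2-per-DAY-" in states
    assert "-GM-per-M2-per-DAY-" in states
    assert candidate.marked == "-GM--PER--M2--PER--DAY-"
    assert candidate.finalized == "GM-PER-M2-DAY"


def test_rewrite_is_noop_on_unknown_text(qudt_rules):
    candidate = rewrite_to_candidate("xyzzy", qudt_rules)
    assert candidate.marked == "xyzzy"
    assert candidate.trace == ()


def test_rewrite_rejects_dashes_and_wrong_phase(qudt_rules, pseudo_rules):
    with pytest.raises(ValueError, match="dash"):
        rewrite_to_candidate("already-dashed", qudt_rules)
    with pytest.raises(ValueError, match="phase"):
        rewrite_to_candidate("meter", pseudo_rules)


@pytest.mark.parametrize(
    "marked, expected",
    [
        ("-GM--PER--M2--PER--DAY-", "GM-PER-M2-DAY"),
        ("GM-PER-M2-DAY", "GM-PER-M2-DAY"),
        ("---M---", "M"),
        ("-PER--M2-", "PER-M2"),  # a leading PER is the (kept) first PER
        ("-PER--M2--PER--DAY-", "PER-M2-DAY"),
        ("", ""),
    ],
)
def test_finalize_examples(marked, expected):
    assert finalize_candidate(marked) == expected


_TOKENS = st.sampled_from(["GM", "PER", "M2", "DAY", "CentiM", "DEG_C", "", "-"])


@settings(max_examples=500, deadline=None, derandomize=True)
@given(st.lists(_TOKENS, max_size=10).map("-".join))
def test_finalize_idempotent_and_convention_compliant(text):
    once = finalize_candidate(text)
    assert finalize_candidate(once) == once
    assert not once.startswith("-") and not once.endswith("-")
    assert "--" not in once
    assert once.split("-").count("PER") <= 1


def test_underscore_qualifiers_are_never_split(qudt_rules, vocab):
    result = map_pseudounit("degreescelsius", qudt_rules, vocab)
    assert result.matched_unit.code == "DEG_C"
    assert finalize_candidate("-DEG_C-") == "DEG_C"


@pytest.mark.parametrize(
    "pseudounit, code",
    [
        ("grampermetersquared", "GM-PER-M2"),
        ("grampercentimetersquared", "GM-PER-CentiM2"),
        ("degreescelcius", "DEG_C"),  # misspelling rule
        ("micromoleperliter", "MicroMOL-PER-L"),
        ("permetersquared", "PER-M2"),
    ],
)
def test_map_pseudounit_matches(pseudounit, code, qudt_rules, vocab):
    result = map_pseudounit(pseudounit, qudt_rules, vocab)
    assert result.match_path == "rewritten"
    assert result.matched_unit.code == code


def test_map_pseudounit_unmatched_keeps_candidate(qudt_rules, vocab):
    result = map_pseudounit("marthastewart", qudt_rules, vocab)
    assert result.match_path == "unmatched"
    assert result.matched_unit is None
    assert result.candidate.finalized == "marthastewart"


def test_embedded_unit_words_do_not_match_spuriously(qudt_rules, vocab):
    # "percent" is a substring of gram-per-CENTImeter-squared; the longer
    # centimetre fragment must win
    result = map_pseudounit("grampercentimetersquared", qudt_rules, vocab)
    assert result.matched_unit.code == "GM-PER-CentiM2"
    assert "PERCENT" not in result.candidate.finalized


def test_rule_order_is_load_bearing(qudt_rules, vocab):
    """Re-sorting the rules alphabetically must change at least one outcome.

    Guards against an accidental rule sort destroying the
    longest-fragment-first discipline.
    """
    by_pattern = sorted(qudt_rules.rules, key=lambda r: r.pattern)
    permuted = RuleSet(
        phase="qudt",
        rules=tuple(
            type(r)(order=i + 1, pattern=r.pattern, replacement=r.replacement, phase="qudt")
            for i, r in enumerate(by_pattern)
        ),
    )
    good = rewrite_to_candidate("grampercentimetersquared", qudt_rules).finalized
    bad = rewrite_to_candidate("grampercentimetersquared", permuted).finalized
    assert good == "GM-PER-CentiM2"
    assert bad != good


def test_label_roundtrip_on_covered_subset(label_manifest, vocab, pseudo_rules, qudt_rules):
    """Every manifest unit's own label maps back to its code."""
    assert len(label_manifest) >= 40
    for code in label_manifest:
        label = vocab[code].label
        pseudo = to_pseudounit(label, pseudo_rules)
        result = map_pseudounit(pseudo, qudt_rules, vocab)
        assert result.matched, f"{code}: label {label!r} did not match ({result.candidate.finalized})"
        assert result.matched_unit.code == code


def test_qudt_inconsistent_legacy_code_is_loaded_as_published(vocab, pseudo_rules, qudt_rules):
    # the rules produce the pattern-consistent MicroGM-PER-CentiM2, which is
    # deliberately NOT what QUDT published for this mass-per-area unit
    pseudo = to_pseudounit("microgram per square centimeter", pseudo_rules)
    result = map_pseudounit(pseudo, qudt_rules, vocab)
    assert not result.matched
    assert result.candidate.finalized == "MicroGM-PER-CentiM2"
    assert "MicroG-PER-CentiM2" in vocab
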