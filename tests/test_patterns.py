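"""Unit and property tests for the consensus-pattern mini-language."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mapkin.patterns import (
    MotifElement,
    PatternSyntaxError,
    SequenceAlphabetError,
    brute_force_match,
    instantiate,
    match_all,
    parse_pattern,
    validate_sequence,
)

# ----------------------------------------------------------------- parsing


def test_parse_literal_choice_literal():
    p = parse_pattern("D-[L/I/V]-K")
    kinds = [e.kind for e in p.elements]
    assert kinds == ["literal", "choice", "literal"]
    assert p.elements[0].residues == ("D",)
    assert p.elements[1].residues == ("L", "I", "V")  # listed order kept
    assert (p.min_span, p.max_span) == (3, 3)
    assert p.is_fixed_span


def test_parse_bare_slash_choice_and_ranged_wildcard():
    p = parse_pattern("S/T-X_3-5_-S/T")
    assert [e.kind for e in p.elements] == ["choice", "wildcard", "choice"]
    assert p.elements[1].min_repeat == 3
    assert p.elements[1].max_repeat == 5
    assert (p.min_span, p.max_span) == (5, 7)
    assert not p.is_fixed_span


def test_parse_parenthesized_choice_and_fixed_wildcard():
    p = parse_pattern("(L/H)-D-X_2_-D-E-P")
    assert p.elements[0].kind == "choice"
    assert p.elements[0].residues == ("L", "H")
    assert p.elements[2] == MotifElement("wildcard", (), 2, 2)
    assert (p.min_span, p.max_span) == (7, 7)


def test_parse_plain_wildcard():
    p = parse_pattern("T-X-Y")
    assert p.elements[1] == MotifElement("wildcard", ())


def test_choice_duplicates_collapse_to_literal():
    # [A/A] carries a single distinct residue: treated as the literal A
    p = parse_pattern("K-[A/A]")
    assert p.elements[1].kind == "literal"
    assert p.elements[1].residues == ("A",)


@pytest.mark.parametrize(
    "bad",
    [
        "",
        "  ",
        "D--K",          # empty token
        "X_0_",          # zero repeat
        "X_5-3_",        # inverted bounds
        "X_a_",          # non-numeric bound
        "D-[L/I",        # unbalanced bracket
        "D-L]-K",        # unbalanced bracket
        "X_3",           # unbalanced underscore
        "D-[B/I]-K",     # B is not an amino acid
        "D-J-K",         # J is not an amino acid
        "DL-K",          # multi-letter literal
        "[L]extra",      # trailing garbage
    ],
)
def test_parse_rejects_malformed(bad):
    with pytest.raises(PatternSyntaxError):
        parse_pattern(bad)


def test_serialize_round_trip_default_library(lib):
    for d in lib:
        for pat in (d.pattern, d.alias_pattern):
            if pat is None:
                continue
            again = parse_pattern(pat.serialize(), pat.pattern_id)
            assert again.elements == pat.elements, d.def_id


# ----------------------------------------------------------------- matching


def test_match_fixed_span_example():
    p = parse_pattern("D-[L/I/V]-K", "DVK")
    hits = match_all(p, "ADVKD")
    assert [(m.start, m.end, m.mismatches) for m in hits] == [(1, 4, 0)]
    assert hits[0].matched_text == "DVK"
    assert hits[0].pattern_id == "DVK"
    assert hits[0].length == 3


def test_match_variable_span_reports_all_windows():
    p = parse_pattern("X_1-2_")
    hits = match_all(p, "AC")
    assert [(m.start, m.end) for m in hits] == [(0, 1), (0, 2), (1, 2)]


def test_match_st_gap_example():
    p = parse_pattern("S/T-X_3-5_-S/T")
    hits = match_all(p, "SAAAT")
    assert [(m.start, m.end, m.mismatches) for m in hits] == [(0, 5, 0)]


def test_sequence_x_matches_only_wildcards():
    # wildcard element admits the unknown residue X...
    assert [(m.start, m.end) for m in match_all(parse_pattern("A-X"), "AX")] == [(0, 2)]
    # ...but literal and choice elements never do
    assert match_all(parse_pattern("A-C"), "AX", 0) == []
    assert match_all(parse_pattern("A-[C/D]"), "AX", 0) == []
    # under tolerance the X costs a mismatch like any other wrong residue
    hits = match_all(parse_pattern("A-C"), "AX", 1)
    assert [(m.start, m.end, m.mismatches) for m in hits] == [(0, 2, 1)]


def test_tolerance_yields_minimum_mismatch_count():
    p = parse_pattern("D-E-K")
    assert match_all(p, "DAK", 0) == []
    hits = match_all(p, "DAK", 2)
    assert [(m.start, m.end, m.mismatches) for m in hits] == [(0, 3, 1)]


def test_validate_sequence():
    validate_sequence("ACDX")
    with pytest.raises(SequenceAlphabetError):
        validate_sequence("ACdE")
    with pytest.raises(SequenceAlphabetError):
        validate_sequence("ACB")


# ------------------------------------------------ randomized oracle checks


def _random_pattern(rng: np.random.Generator, alphabet: str):
    """Small random pattern over *alphabet* (<=4 elements)."""
    parts = []
    for _ in range(int(rng.integers(1, 5))):
        kind = rng.integers(0, 3)
        if kind == 0:
            parts.append(alphabet[rng.integers(len(alphabet))])
        elif kind == 1:
            k = int(rng.integers(2, min(4, len(alphabet)) + 1))
            picks = rng.choice(list(alphabet), size=k, replace=False)
            parts.append("[" + "/".join(picks) + "]")
        else:
            lo = int(rng.integers(1, 3))
            hi = lo + int(rng.integers(0, 3))
            parts.append(f"X_{lo}-{hi}_" if hi > lo else (f"X_{lo}_" if lo > 1 else "X"))
    return parse_pattern("-".join(parts))


def _random_seq(rng: np.random.Generator, alphabet: str) -> str:
    n = int(rng.integers(0, 13))
    return "".join(rng.choice(list(alphabet), size=n)) if n else ""


def test_match_all_equals_brute_force_random_sweep():
    rng = np.random.default_rng(20240917)
    alphabet = "ACDE"
    for _ in range(300):
        pat = _random_pattern(rng, alphabet)
        seq = _random_seq(rng, alphabet)
        tol = int(rng.integers(0, 2))
        assert match_all(pat, seq, tol) == brute_force_match(pat, seq, tol), (
            pat.serialize(),
            seq,
            tol,
        )


def test_tolerance_monotonicity_random_sweep():
    rng = np.random.default_rng(42)
    for _ in range(100):
        pat = _random_pattern(rng, "ACDE")
        seq = _random_seq(rng, "ACDE")
        lo = {(m.start, m.end) for m in match_all(pat, seq, 0)}
        hi = {(m.start, m.end) for m in match_all(pat, seq, 2)}
        assert lo <= hi


@settings(max_examples=60, derandomize=True, deadline=None)
@given(
    seq=st.text(alphabet="ACDEG", max_size=15),
    tol=st.integers(min_value=0, max_value=2),
)
def test_match_span_soundness(lib, seq, tol):
    for d in lib[:6]:
        pat = d.scan_pattern
        for m in match_all(pat, seq, tol):
            assert pat.min_span <= m.length <= pat.max_span
            assert seq[m.start : m.end] == m.matched_text
            assert m.mismatches <= tol


# --------------------------------------------------------------- instantiate


def test_instantiate_first_listed_choice_and_min_wildcards():
    assert instantiate(parse_pattern("D-[L/I/V]-K")) == "DLK"
    assert instantiate(parse_pattern("T-X-Y")) == "TAY"
    assert instantiate(parse_pattern("S-X_3-5_-T")) == "SAAAT"


def test_instantiate_self_matches_at_tolerance_zero(lib):
    for d in lib:
        pat = d.scan_pattern
        text = instantiate(pat)
        hits = match_all(pat, text, 0)
        assert any(
            m.start == 0 and m.end == len(text) and m.mismatches == 0 for m in hits
        ), d.def_id


def test_instantiate_avoid_flips_wildcard():
    target = parse_pattern("A-X-A", "target")
    other = parse_pattern("A-A-A", "other")
    assert instantiate(target) == "AAA"
    text = instantiate(target, avoid=[other])
    assert text == "AGA"
    assert match_all(other, text, 0) == []
    assert match_all(target, text, 0)  # still realizes its own pattern
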