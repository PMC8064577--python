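"""Tests for domain scanning, chain construction, activation typing,
family gating and group assignment."""

from __future__ import annotations

import numpy as np
import pytest

from mapkin.library import get
from mapkin.patterns import MotifMatch, instantiate
from mapkin.scan import (
    KinaseCall,
    MAPK_CHAIN_ORDER,
    MEK_CHAIN_ORDER,
    ActivationCall,
    best_chain,
    brute_force_chain,
    classify,
    identify_family,
    scan_domains,
    summarize_cohort,
)
from mapkin.simulate import SynthSpec, generate_protein

ROMANS_MEK = ("I", "II", "III", "IV", "V", "VI", "VII", "VIII")


def _inst(lib, def_id):
    return instantiate(get(lib, def_id).scan_pattern)


@pytest.fixture(scope="module")
def canonical_mapk_seq(lib):
    """Textbook MAPK: all canonical instantiations in order, TEY signature
    between VII and VIII, CD before XI, glycine linkers."""
    # realize the signature with the canonical TEY triplet at its
    # activation frame (pattern elements 1-3)
    sig_text = list(instantiate(get(lib, "MAPK.signature").pattern))
    sig_text[1:4] = "TEY"
    sig_text = "".join(sig_text)
    parts = []
    for num in ("I", "II", "III", "IV", "V", "VIa", "VIb", "VII"):
        parts.append(_inst(lib, f"MAPK.{num}"))
    parts.append(sig_text)
    for num in ("VIII", "IX", "X"):
        parts.append(_inst(lib, f"MAPK.{num}"))
    parts.append(_inst(lib, "MAPK.CD"))
    parts.append(_inst(lib, "MAPK.XI"))
    return "GGGGG".join(parts)


def test_chain_recovers_full_canonical_mapk(lib, canonical_mapk_seq):
    arch = scan_domains("toy", canonical_mapk_seq, lib, "MAPK")
    chain = arch.chain_ids()
    expected = [d for d in MAPK_CHAIN_ORDER]
    assert chain == expected
    # chain is ordered and non-overlapping
    for a, b in zip(arch.chain, arch.chain[1:]):
        assert a.end <= b.start
    assert arch.has_cd


def test_activation_canonical_tey(lib, canonical_mapk_seq):
    arch = scan_domains("toy", canonical_mapk_seq, lib, "MAPK")
    act = arch.activation
    assert act.cls == "canonical-TEY"
    assert act.triplet == "TEY"
    # the triplet sits between the chain anchors VII and VIII
    anchors = {m.pattern_id: m for m in arch.chain}
    assert anchors["MAPK.VII"].end <= act.position < anchors["MAPK.VIII"].start


def test_empty_sequence_architecture(lib):
    arch = scan_domains("glycine", "G" * 200, lib, "MAPK")
    assert arch.chain == []
    assert arch.all_matches == []
    assert arch.activation.cls == "absent"
    call, _ = identify_family("glycine", "G" * 200, lib)
    assert call.family == "none"


def test_mek_gate_on_minimal_evidence(lib):
    # eight canonical domains + membership signatures are enough for MEK
    seq = "DLK" + "GGGGG" + "GGGGG".join(
        _inst(lib, f"MEK.{r}") for r in ROMANS_MEK
    ) + "GGGGG" + "SAAAT"
    call, arch = identify_family("mini-mek", seq, lib)
    assert call.family == "MEK"
    assert arch.has_match("MEK.DVK")
    assert arch.has_match("MEK.STgap")
    numbered = [d for d in call.missing_domains]
    # the three non-Roman canonicals may be missing, the Romans are not
    assert all(d.split(".")[1] not in ROMANS_MEK for d in numbered)


def test_mekk_like_gate_on_raf_signature(lib):
    seq = "GGGG" + _inst(lib, "RAF.sig") + "GGGG"
    assert _inst(lib, "RAF.sig") == "GTAAWMAPE"
    call, _ = identify_family("raf", seq, lib)
    assert call.family == "MEKK-like"
    assert call.group == "unassigned"


def test_family_precedence_mapk_before_mek(lib, canonical_mapk_seq):
    # a full MAPK also contains S/T gaps etc.; the MAPK gate must win
    call, _ = identify_family("toy", canonical_mapk_seq, lib)
    assert call.family == "MAPK"
    assert call.missing_domains == []


# ---------------------------------------------------------- chain optimum


def _random_matches(rng, order):
    out = []
    for _ in range(int(rng.integers(0, 13))):
        pid = order[rng.integers(len(order))]
        start = int(rng.integers(0, 40))
        length = int(rng.integers(3, 9))
        out.append(MotifMatch(start, start + length, pid, "A" * length,
                              int(rng.integers(0, 2))))
    return sorted(out)


def test_best_chain_matches_brute_force_random():
    rng = np.random.default_rng(5)
    for _ in range(150):
        order = MEK_CHAIN_ORDER if rng.random() < 0.5 else MAPK_CHAIN_ORDER
        matches = _random_matches(rng, order)
        fast = best_chain(matches, order)
        slow = brute_force_chain(matches, order)
        score = lambda ch: sum(m.length - 2 * m.mismatches for m in ch)
        assert score(fast) == score(slow), matches
        assert [m.start for m in fast] == [m.start for m in slow], matches


def test_best_chain_enforces_strict_order():
    order = ("A.1", "A.2")
    m1 = MotifMatch(0, 5, "A.2", "AAAAA", 0)
    m2 = MotifMatch(10, 15, "A.1", "AAAAA", 0)
    # out of order: only one can be kept, the longer-scoring one (tie -> leftmost)
    chain = best_chain([m1, m2], order)
    assert len(chain) == 1
    assert chain[0].start == 0


# ------------------------------------------------------- group assignment


@pytest.mark.parametrize("family", ["MAPK", "MEK"])
@pytest.mark.parametrize("group", list("ABCDE"))
def test_group_assignment_recovers_generated_group(lib, family, group):
    seq, truth = generate_protein(family, group, SynthSpec(seed=23), 0, lib)
    call, _ = classify("t", seq, lib)
    assert call.family == family
    assert call.group == group
    # the vote must win by a full point
    ranked = sorted(call.group_scores.values(), reverse=True)
    assert ranked[0] - ranked[1] >= 1


def test_group_e_mapk_uses_noncanonical_activation(lib):
    seq, truth = generate_protein("MAPK", "E", SynthSpec(seed=29), 0, lib)
    call, arch = classify("e", seq, lib)
    assert call.activation.triplet == "THE"
    assert call.activation.cls == "non-canonical"
    assert not arch.has_cd


def test_group_d_mapk_tdy_and_long_extension(lib):
    seq, _ = generate_protein("MAPK", "D", SynthSpec(seed=31), 0, lib)
    call, arch = classify("d", seq, lib)
    assert call.activation.cls == "canonical-TDY"
    assert arch.c_terminal_extension_length > 60


def test_mek_group_b_ntf2_extension_after_chain(lib):
    seq, _ = generate_protein("MEK", "B", SynthSpec(seed=37), 0, lib)
    call, arch = classify("b", seq, lib)
    assert call.group == "B"
    assert "MEK.NTF2ext" in call.evidence
    ext = arch.matches_of("MEK.NTF2ext")
    assert ext and all(m.start >= arch.chain[-1].end for m in ext)


def test_mek_group_d_is_canonical_only(lib):
    seq, truth = generate_protein("MEK", "D", SynthSpec(seed=41), 0, lib)
    call, _ = classify("d", seq, lib)
    assert call.group == "D"
    novel_ids = {f"MEK.n{i}" for i in range(9, 15)}
    assert not novel_ids & set(call.evidence)


# --------------------------------------------------------------- summaries


def _call(seq_id, family, group="unassigned", triplet=None, missing=()):
    cls = {"TEY": "canonical-TEY", "TDY": "canonical-TDY"}.get(triplet,
            "absent" if triplet is None else "non-canonical")
    return KinaseCall(
        seq_id,
        family,
        group=group,
        missing_domains=list(missing),
        activation=ActivationCall(triplet, 0 if triplet else None, cls),
    )


def test_summarize_cohort_tables():
    calls = [
        _call("s1", "MAPK", "A", "TEY"),
        _call("s2", "MAPK", "D", "TDY", missing=("MAPK.I",)),
        _call("s3", "MEK", "B"),
        _call("s4", "none"),
    ]
    smap = {"s1": ("Genus", "one"), "s2": ("Genus", "one"), "s3": ("Genus", "two")}
    tables = summarize_cohort(calls, smap)
    gc = tables["group_counts"]
    assert gc.loc["Genus one", ("MAPK", "A")] == 1
    assert gc.loc["Genus one", ("MAPK", "D")] == 1
    assert gc.loc["Genus two", ("MEK", "B")] == 1
    act = tables["activation"]
    assert act.loc["TEY", "count"] == 1
    assert act.loc["TDY", "count"] == 1
    assert tables["missing_domains"].loc[("MAPK", "MAPK.I"), "count"] == 1
    totals = tables["totals"]
    assert int(totals.loc["none", "count"]) == 1
    assert int(totals.loc["MAPK", "count"]) == 2


def test_summarize_cohort_rejects_empty():
    with pytest.raises(ValueError):
        summarize_cohort([])
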