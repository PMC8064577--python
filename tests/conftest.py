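"""Shared fixtures: the default library, synthetic cohorts and toy
reference sets used across the test modules.

Heavy cohorts are session-scoped so each is generated exactly once.
"""

from __future__ import annotations

import numpy as np
import pytest

from mapkin.library import load_default_library
from mapkin.simulate import SynthSpec, generate_cohort, generate_protein


@pytest.fixture(scope="session")
def lib():
    return load_default_library()


@pytest.fixture(scope="session")
def clean_cohort():
    """Mutation-free cohort: 2 records per (family, group), no decoys."""
    return generate_cohort(SynthSpec(seed=1))


@pytest.fixture(scope="session")
def big_gene_cohort():
    """200-record cohort used for gene-model statistics."""
    spec = SynthSpec(
        n_per_group={("MAPK", g): 20 for g in "ABCDE"}
        | {("MEK", g): 20 for g in "ABCDE"},
        utr_intron_fraction=0.5,
        seed=7,
    )
    return spec, generate_cohort(spec)


def _mutate_avoiding_implants(seq: str, implants, n_sub: int, seed: int) -> str:
    """Substitute *n_sub* residues at positions outside every implant."""
    rng = np.random.default_rng(seed)
    protected = np.zeros(len(seq), dtype=bool)
    for im in implants:
        protected[im.start : im.end] = True
    free = np.flatnonzero(~protected)
    picks = rng.choice(free, size=n_sub, replace=False)
    aa = "ACDEFGHIKLMNPQRSTVWY"
    chars = list(seq)
    for p in picks:
        chars[p] = aa[(aa.index(chars[p]) + 1) % len(aa)]
    return "".join(chars)


@pytest.fixture(scope="session")
def toy_reference():
    """Three labeled reference kinases (distinct MAPK groups).

    Returns (refs, truths): refs maps AtMPK3/AtMPK5/AtMPK6 to sequences,
    truths maps the same names to the generator truth records (implant
    coordinates are used to place mutations outside motifs).
    """
    refs, truths = {}, {}
    for name, group, seed in (
        ("AtMPK3", "B", 11),
        ("AtMPK5", "A", 12),
        ("AtMPK6", "D", 13),
    ):
        seq, truth = generate_protein("MAPK", group, SynthSpec(seed=seed), 0)
        refs[name] = seq
        truths[name] = truth
    return refs, truths


@pytest.fixture(scope="session")
def pt_queries(toy_reference):
    """Three Pinus taeda-style queries derived from AtMPK5.

    ptq1/ptq2/ptq3 carry 2/5/8 substitutions (outside motif implants), so
    all three share AtMPK5 as top ortholog with strictly ordered scores.
    """
    refs, truths = toy_reference
    base = refs["AtMPK5"]
    implants = truths["AtMPK5"].implants
    queries = {
        f"ptq{i}": _mutate_avoiding_implants(base, implants, n, seed=100 + i)
        for i, n in ((1, 2), (2, 5), (3, 8))
    }
    species_map = {sid: ("Pinus", "taeda") for sid in queries}
    return queries, species_map
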