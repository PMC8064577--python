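"""Ortholog-based kinase nomenclature.

Names follow the convention used for plant MAPK/MEK families: a species
letter code (first letters of genus and species, extended on collision,
e.g. At for *Arabidopsis thaliana* and Amtr for *Amborella trichopoda*),
the family acronym (MPK or MEK), the number of the most similar reference
(Arabidopsis) protein, and a lowercase suffix a, b, c... when several
sequences in one species share the same reference ortholog.

"Most likely ortholog" is operationalized as the best normalized global
alignment score against the reference set (BLOSUM62, affine gaps
open 10 / extend 1), a proxy for tree-adjacent assignment.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

from Bio import Align
from Bio.Align import substitution_matrices

from .scan import KinaseCall


@dataclass(frozen=True)
class NameRecord:
    seq_id: str
    species_code: str
    acronym: str            # MPK | MEK
    ortholog_number: int
    suffix: str             # '' or a single lowercase letter
    full_name: str
    top_reference: str
    normalized_score: float
    tied_references: tuple[str, ...] = ()


def species_code(genus: str, species: str, taken_codes: set[str] | None = None) -> str:
    """Two-letter genus+species code, extended until unique.

    Default is the genus initial (uppercase) plus species initial
    (lowercase); on collision the first two letters of each are used
    (e.g. Amtr), then further species letters are appended.
    """
    if not genus or not species:
        raise ValueError("genus and species must be non-empty")
    taken = taken_codes or set()
    code = genus[0].upper() + species[0].lower()
    if code not in taken:
        return code
    if len(genus) < 2 or len(species) < 2:
        raise ValueError(
            f"cannot disambiguate single-letter name {genus!r}/{species!r}"
        )
    code = genus[:2].capitalize() + species[:2].lower()
    k = 2
    while code in taken:
        k += 1
        if k > len(species):
            raise ValueError(
                f"cannot build a unique code for {genus} {species}"
            )
        code = genus[:2].capitalize() + species[:k].lower()
    return code


def _aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -10.0
    aligner.extend_gap_score = -1.0
    return aligner


def ortholog_similarity(
    query: str, reference_set: dict[str, str]
) -> list[tuple[str, float]]:
    """References ranked by normalized global-alignment score.

    Scores are raw BLOSUM62 affine-gap global scores normalized by the
    geometric mean of the two self-scores, so the measure is symmetric
    and identical sequences score exactly 1.0.  Ties order by ref_id.
    """
    if not reference_set:
        raise ValueError("reference set is empty")
    aligner = _aligner()
    self_q = aligner.score(query, query)
    out = []
    for ref_id in sorted(reference_set):
        ref = reference_set[ref_id]
        raw = aligner.score(query, ref)
        norm = raw / (self_q * aligner.score(ref, ref)) ** 0.5
        out.append((ref_id, norm))
    out.sort(key=lambda t: (-t[1], t[0]))
    return out


_REF_NUM = re.compile(r"(\d+)\s*$")


def _reference_number(ref_id: str) -> int:
    m = _REF_NUM.search(ref_id)
    if not m:
        raise ValueError(f"reference id {ref_id!r} carries no ortholog number")
    return int(m.group(1))


def assign_names(
    calls: list[KinaseCall],
    sequences: dict[str, str],
    reference_set: dict[str, str],
    species_map: dict[str, tuple[str, str]],
) -> tuple[list[NameRecord], list[str]]:
    """Full cohort naming.

    Per sequence: ortholog number = number parsed from the top reference
    hit; sequences sharing (species, acronym, number) receive suffixes
    a, b, c... ordered by descending similarity, ties by seq_id.
    Sequences whose family call is neither MAPK nor MEK are skipped with
    a warning.  Equal-best references are reported as ties, not resolved.
    """
    warnings: list[str] = []
    codes: dict[tuple[str, str], str] = {}
    taken: set[str] = set()
    for sid in sorted(species_map):
        key = species_map[sid]
        if key not in codes:
            codes[key] = species_code(key[0], key[1], taken)
            taken.add(codes[key])

    staged = []
    for call in calls:
        if call.family not in ("MAPK", "MEK"):
            warnings.append(f"{call.seq_id}: family {call.family}; not named")
            continue
        if call.seq_id not in species_map:
            warnings.append(f"{call.seq_id}: no species mapping; not named")
            continue
        acronym = "MPK" if call.family == "MAPK" else "MEK"
        ranked = ortholog_similarity(sequences[call.seq_id], reference_set)
        top_ref, top_score = ranked[0]
        ties = tuple(
            r for r, s in ranked[1:] if abs(s - top_score) < 1e-12
        )
        staged.append(
            {
                "seq_id": call.seq_id,
                "code": codes[species_map[call.seq_id]],
                "acronym": acronym,
                "number": _reference_number(top_ref),
                "top_ref": top_ref,
                "score": top_score,
                "ties": ties,
            }
        )

    groups: dict[tuple[str, str, int], list[dict]] = {}
    for s in staged:
        groups.setdefault((s["code"], s["acronym"], s["number"]), []).append(s)

    records: list[NameRecord] = []
    for key in sorted(groups):
        members = sorted(groups[key], key=lambda s: (-s["score"], s["seq_id"]))
        for rank, s in enumerate(members):
            suffix = "" if len(members) == 1 else chr(ord("a") + rank)
            full = f"{s['code']}{s['acronym']}{s['number']}{suffix}"
            records.append(
                NameRecord(
                    seq_id=s["seq_id"],
                    species_code=s["code"],
                    acronym=s["acronym"],
                    ortholog_number=s["number"],
                    suffix=suffix,
                    full_name=full,
                    top_reference=s["top_ref"],
                    normalized_score=s["score"],
                    tied_references=s["ties"],
                )
            )
    records.sort(key=lambda r: r.seq_id)
    return records, warnings
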