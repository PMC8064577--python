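"""Intron statistics from GFF3 gene models.

Intron counts per mRNA (exon count minus one) and untranslated-region
intron flags, the two quantities behind gene-structure censuses of kinase
families.  Introns are always derived from exon intervals, never read
from ``intron`` features, so annotations with and without explicit introns
are treated identically.  Coordinates are GFF3 1-based inclusive.
"""

from __future__ import annotations

import tempfile
from dataclasses import dataclass, field
from pathlib import Path

import gffutils

Interval = tuple[int, int]


@dataclass
class GeneModel:
    gene_id: str
    mrna_id: str
    seqid: str
    strand: str
    exons: list[Interval]                  # sorted by genomic start
    cds: list[Interval] = field(default_factory=list)
    five_utr: list[Interval] = field(default_factory=list)
    three_utr: list[Interval] = field(default_factory=list)

    def introns(self) -> list[Interval]:
        """Inter-exon gaps, 1-based inclusive genomic intervals."""
        return [
            (a_end + 1, b_start - 1)
            for (_, a_end), (b_start, _) in zip(self.exons, self.exons[1:])
        ]


@dataclass
class ReadResult:
    models: list[GeneModel]
    errors: list[str]


def read_gene_models(gff3: str | Path) -> ReadResult:
    """One :class:`GeneModel` per mRNA; invalid records are reported, not fatal.

    A record is rejected when its exons overlap or when an mRNA has no
    exons; orphan mRNAs (missing gene Parent) are reported but kept.
    """
    db = gffutils.create_db(
        str(gff3),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
    )
    models: list[GeneModel] = []
    errors: list[str] = []
    for mrna in db.features_of_type("mRNA"):
        mrna_id = mrna.id
        parents = mrna.attributes.get("Parent", [])
        gene_id = parents[0] if parents else ""
        if not gene_id:
            errors.append(f"{mrna_id}: missing Parent gene link")
        exons = sorted(
            (f.start, f.end) for f in db.children(mrna, featuretype="exon")
        )
        if not exons:
            errors.append(f"{mrna_id}: no exon features; record skipped")
            continue
        overlap = any(b0 <= a1 for (_, a1), (b0, _) in zip(exons, exons[1:]))
        if overlap:
            errors.append(f"{mrna_id}: overlapping exons; record skipped")
            continue
        model = GeneModel(
            gene_id=gene_id,
            mrna_id=mrna_id,
            seqid=mrna.seqid,
            strand=mrna.strand,
            exons=exons,
            cds=sorted((f.start, f.end) for f in db.children(mrna, featuretype="CDS")),
            five_utr=sorted(
                (f.start, f.end)
                for f in db.children(mrna, featuretype="five_prime_UTR")
            ),
            three_utr=sorted(
                (f.start, f.end)
                for f in db.children(mrna, featuretype="three_prime_UTR")
            ),
        )
        models.append(model)
    return ReadResult(models, errors)


def intron_count(model: GeneModel) -> int:
    """Number of introns = number of exons - 1."""
    return len(model.exons) - 1


def _hull(intervals: list[Interval]) -> Interval | None:
    if not intervals:
        return None
    return min(s for s, _ in intervals), max(e for _, e in intervals)


def utr_intron_flags(model: GeneModel) -> tuple[bool | None, bool | None]:
    """(five_prime, three_prime) UTR-intron flags; None when UTRs unannotated.

    A flag is true iff some inter-exon gap lies entirely within the hull
    of the corresponding annotated UTR intervals (annotated UTR features
    cover exonic stretches only, so an intron separating two UTR exons
    falls inside the hull but an intron spanning the UTR/CDS junction does
    not).  The 5'/3' assignment is the annotation's own, hence
    strand-aware by construction.
    """
    gaps = model.introns()

    def flag(intervals: list[Interval]) -> bool | None:
        hull = _hull(intervals)
        if hull is None:
            return None
        return any(hull[0] <= s and e <= hull[1] for s, e in gaps)

    return flag(model.five_utr), flag(model.three_utr)


def structure_table(models: list[GeneModel]):
    """Per-mRNA TSV-ready table of exon/intron counts and UTR-intron flags."""
    import pandas as pd

    rows = []
    for m in models:
        u5, u3 = utr_intron_flags(m)
        rows.append(
            {
                "mrna_id": m.mrna_id,
                "exon_count": len(m.exons),
                "intron_count": intron_count(m),
                "utr5_intron": "NA" if u5 is None else str(u5).lower(),
                "utr3_intron": "NA" if u3 is None else str(u3).lower(),
            }
        )
    return pd.DataFrame(rows)


def read_gene_models_str(gff3_text: str) -> ReadResult:
    """Convenience wrapper: parse GFF3 given as text (tests, generator)."""
    with tempfile.NamedTemporaryFile("w", suffix=".gff3", delete=False) as fh:
        fh.write(gff3_text)
        path = fh.name
    try:
        return read_gene_models(path)
    finally:
        Path(path).unlink(missing_ok=True)
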