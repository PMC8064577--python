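"""Curated consensus-motif library for plant MAPK/MEK/MEKK kinases.

The library bundles the published consensus sequences that define the
family: the Hanks-style catalytic subdomains of plant MAPKs (I–XI plus the
common docking domain), the six group-diagnostic novel MAPK domains
(12–17), the full-length MAPK signature with its embedded T-X-Y activation
frame, the MEK catalytic subdomains (I–VIII) plus ATP-binding,
MAPK-binding and activation domains, the group-specific MAPK-binding
variants, the six novel MEK domains (9–14), the NTF2-like C-terminal
extension of group B MEKs, the two MEK membership signatures
(D-[L/I/V]-K and S/T-X_3-5_-S/T) and the MAPKKK/ZIK/RAF subfamily
signatures.  Every entry carries a provenance string naming its source
table or section.

The default library is immutable at runtime; user extensions load as a
separate TSV overlay via :func:`read_library_tsv`.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace
from pathlib import Path

from .patterns import MotifPattern, PatternSyntaxError, instantiate, match_all, parse_pattern

FAMILIES = ("MAPK", "MEK", "MEKK")
ROLES = ("canonical", "novel", "activation", "docking", "binding", "signature", "extension")
GROUPS = ("A", "B", "C", "D", "E")


@dataclass(frozen=True)
class MotifDef:
    """A library entry binding a pattern to family/role/group metadata.

    ``alias_pattern`` holds a documented spelling variant that scans should
    prefer (used for the common docking domain, which is printed both as
    L-H-D-X_2_-D-E-P and as the more permissive (L/H)-D-X_2_-D-E-P).
    """

    def_id: str
    family: str
    role: str
    group_assoc: frozenset[str]
    pattern: MotifPattern
    provenance: str
    alias_pattern: MotifPattern | None = None

    @property
    def scan_pattern(self) -> MotifPattern:
        """Pattern actually used when scanning (permissive alias if any)."""
        return self.alias_pattern if self.alias_pattern is not None else self.pattern


def _d(def_id, family, role, groups, spec, provenance, alias=None) -> MotifDef:
    return MotifDef(
        def_id=def_id,
        family=family,
        role=role,
        group_assoc=frozenset(groups),
        pattern=parse_pattern(spec, def_id),
        provenance=provenance,
        alias_pattern=parse_pattern(alias, def_id) if alias else None,
    )


_T2 = "MAPK conserved-domain consensus table"
_T3 = "MAPK novel-domain consensus table"
_T5 = "MEK conserved-domain consensus table"
_T6 = "MEK group-specific MAPK-binding domain table"
_T7 = "MEK novel-domain consensus table"
_ID = "family membership signatures (identification criteria)"
_KKK = "MEKK subfamily kinase-domain signatures"


def _build_default() -> tuple[MotifDef, ...]:
    e = []
    # ---- MAPK canonical subdomains (13 entries incl. CD) ----
    mapk_canon = {
        "I": "[V/P]-[I/V]-G-[K/R]-G-[S/A]-Y-G-[V/I]-V-C-S-A",
        "II": "E-X-V-A-I-K-K-I-X-[N/D]-[A/V/I]-F-[E/D]-[N/H]-X_2_-D-A",
        "III": "R-[T/I]-L-R-E-[I/L]-K-L-L-R-[H/L]-[L/M]-[R/D]",
        "IV": "P-X-[R/K]-X_2_-F-X-D-[V/I]-Y",
        "V": "V-[F/Y]-E-L-M-[E/D]-[T/S]-D-L-H-Q-[V/I]-I-[K/R]",
        "VIa": "[F/Y]-F-L-Y-Q-[L/I/M]-L-R-[G/A]-L-K-Y",
        "VIb": "H-[S/T]-A-N-[V/I]-[L/F/Y]-H-R-D-K-L-P-[K/S]-N-[L/I]-L-[A/L]-N",
        "VII": "C-[D/K]-L-K-I-[C/A]-D-F-G-L-A-R-[V/T]",
        "VIII": "[V/A]-T-R-W-Y-R-A-P-E-L-[L/C]-[L/G]-[S/N]",
        "IX": "A-I-D-[I/V/M]-W-S-[V/I]-G-C-I-F-[A/M]-E-[L/I/M]-[L/M]",
        "X": "P-[L/I]-F-P-G-X_3_-[V/L]-X-Q-L-X-L-[I/M]-T-[D/E]",
        "XI": "F-D-P-X_2_-R-[I/P]-[T/S]-[A/V]-X-[E/D]-A-L-X-[H/D]-P-Y-[F/L]",
    }
    for num, spec in mapk_canon.items():
        e.append(_d(f"MAPK.{num}", "MAPK", "canonical", (), spec, _T2))
    e.append(
        _d(
            "MAPK.CD",
            "MAPK",
            "canonical",
            (),
            "L-H-D-X_2_-D-E-P",
            _T2 + "; permissive in-text spelling (L/H)-D-X_2_-D-E-P used for scans",
            alias="(L/H)-D-X_2_-D-E-P",
        )
    )
    # ---- MAPK novel group-diagnostic domains (6) ----
    mapk_novel = {
        "n12": ("G-N-X-F-E-V-[T/S]-X-K-Y", ("A", "B")),
        "n13": ("Y-X-[M/L]-W-[Q/R]-[T/S]-X-F-E-I-D-T-K-Y", ("C",)),
        "n14": ("H-[P/K]-D-I-V-E-[I/V/K]-[K/L]-[I/H/N]-[I/K]-[M/L]-L-P", ("D",)),
        "n15": ("M-L-X-F-[D/N]-P-X_2_-R-I-[T/S]", ("B", "E")),
        "n16": ("E-[L/V]-[I/L]-G-[T/S]-P-X-[E/D]-X-D-L-X-F-[L/I/V]", ("B",)),
        "n17": ("A-[R/K]-[R/K]-Y-[L/I/V]-X_2_-[L/M]-[R/P]-X_3_-[P/R/K]-X-[P/S]", ("A", "B", "D")),
    }
    for num, (spec, groups) in mapk_novel.items():
        e.append(_d(f"MAPK.{num}", "MAPK", "novel", groups, spec, _T3))
    # ---- MAPK full-length membership signature (T-X-Y frame at elements 1-3) ----
    e.append(
        _d(
            "MAPK.signature",
            "MAPK",
            "signature",
            (),
            "[L/I/V/M]-[T/S]-X-X-[L/I/V/M]-X-T-[K/R]-[W/Y]-Y-R-X-P-X-[L/I/V/M]-[L/I/V/M]",
            _ID,
        )
    )
    # ---- MEK canonical domains (11) ----
    mek_canon = {
        "I": "G-X-[S/A/N]-[G/S]-G-X-V-X-[K/L]-[V/A]-X-H-[K/R]",
        "II": "P-X-[V/L]-V-X-[C/F]-[H/Y]-X_2_-[F/Y]",
        "III": "[L/M]-E-[Y/F]-M-D-X-G-S-L-[A/E]",
        "IV": "[A/S]-X_6_-L-X-G-L-X-Y-L-H",
        "V": "V-G-T-X_2_-Y-M-S-P-E-R-[I/F]",
        "VI": "[G/S/A]-D-[I/V]-W-S-[L/F]-G-[L/V]-X_2_-L-E",
        "VII": "[F/A]-S-X-E-[F/L]-[R/C]-X-F-[I/V]-X_2_-C",
        "VIII": "[S/T]-[A/V]-X_2_-L-L-X-H-P-F-[I/V/L]",
        "ATP": "H-K-X_3-8_-A-L-K-X_4_-[N/D]-X-[D/E/Q]",
        "MAPKbind": "[V/I]-H-R-D-[I/L]-K-P-[S/A]-N-L-L",
        "ACT": "V-S-X_5_-[S/T]-[M/L]-[D/G/A]",
    }
    for num, spec in mek_canon.items():
        e.append(_d(f"MEK.{num}", "MEK", "canonical", (), spec, _T5))
    e.append(
        _d(
            "MEK.NTF2bind",
            "MEK",
            "binding",
            ("B",),
            "E-[K/R]-[L/I]-[V/I]-H-V-V-E-[K/N]-L-[Q/H]-C",
            _T5,
        )
    )
    # ---- MEK group-specific MAPK-binding variants (5) ----
    mek_bind = {
        "A": "H-X_2_-[R/K]-[H/R]-[I/V]-I-H-R-D-[I/L]-K-P-S-N-L-L",
        "B": "H-X-V-R-H-L-V-H-R-D-I-K-P-A-N-[L/M]-L",
        "C": "H-X_2_-R-X-I-V-H-R-D-X-K-P-[S/A]-N-L-L",
        "D": "H-X_3_-K-I-V-H-R-D-I-K-P-X-N-L-L",
        "E": "H-K-X_2_-[H/N]-K-I-V-H-R-D-I-K-P-S-N-L-L",
    }
    for grp, spec in mek_bind.items():
        e.append(_d(f"MEK.bind{grp}", "MEK", "binding", (grp,), spec, _T6))
    # ---- MEK novel group-diagnostic domains (6) ----
    mek_novel = {
        "n9": ("[A/Q]-S-G-T-F-X-D-G-D-[L/I]-X-[L/V]-N-X_2_-G", ("A",)),
        "n10": ("N-L-L-S-R-S-X_3_-Y-N-[I/F]-N-E-X-G-[L/F]", ("B",)),
        "n11": ("L-P-[L/M]-P-X-R-X_2_-D-X_2-4_-S-L-A-V-P-L", ("C",)),
        "n12": ("M-L-[T/A]-[V/I]-H-Y-Y-[L/M]-L-F-[D/N]-G-X-D", ("B",)),
        "n13": ("G-[V/I]-X-I-R-S-G-S-F-[I/V]-V-G-X_2_-F", ("B",)),
        "n14": ("[D/E]-P-P-X-P-P-X_3_-[S/T]-P-X-F-X_2_-F-I", ("E",)),
    }
    for num, (spec, groups) in mek_novel.items():
        e.append(_d(f"MEK.{num}", "MEK", "novel", groups, spec, _T7))
    # ---- group-B MEK NTF2-like C-terminal extension ----
    e.append(
        _d(
            "MEK.NTF2ext",
            "MEK",
            "extension",
            (),
            "E-[K/R]-L-V-H-V-V-E-[K/N]-L-[H/Q]-C-X-A-X_1-4_-G-[I/V]-X-I-R-V",
            "group-B MEK C-terminal extension (in-text consensus)",
        )
    )
    # ---- MEK membership signatures ----
    e.append(_d("MEK.DVK", "MEK", "signature", (), "D-[L/I/V]-K", _ID))
    e.append(_d("MEK.STgap", "MEK", "signature", (), "S/T-X_3-5_-S/T", _ID))
    # ---- MEKK subfamily signatures ----
    e.append(_d("MEKK.sig", "MEKK", "signature", (), "G-[T/S]-P-X-[F/Y/W]-M-A-P-E-V", _KKK))
    e.append(_d("ZIK.sig", "MEKK", "signature", (), "G-T-P-E-F-M-A-P-E-[L/V/M]-[Y/F/L]", _KKK))
    e.append(_d("RAF.sig", "MEKK", "signature", (), "G-T-X-X-[W/Y]-M-A-P-E", _KKK))
    return tuple(e)


_DEFAULT: tuple[MotifDef, ...] | None = None


def load_default_library() -> list[MotifDef]:
    """The bundled 49-entry library, in table order."""
    global _DEFAULT
    if _DEFAULT is None:
        _DEFAULT = _build_default()
    return list(_DEFAULT)


@dataclass
class ValidationReport:
    errors: list[str] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.errors


def validate_library(lib: list[MotifDef]) -> ValidationReport:
    """Report-only consistency checks.

    Errors: duplicate def_ids, unparseable patterns (when round-tripping
    the text form), span bounds outside [3, 30], group associations on
    roles other than novel/binding.  Warnings: cross-talk — a canonical
    instantiation of one entry that zero-mismatch-matches a different
    entry of the same family.
    """
    rep = ValidationReport()
    seen: set[str] = set()
    for d in lib:
        if d.def_id in seen:
            rep.errors.append(f"duplicate def_id {d.def_id}")
        seen.add(d.def_id)
        try:
            parse_pattern(d.pattern.serialize(), d.def_id)
        except PatternSyntaxError as exc:
            rep.errors.append(f"{d.def_id}: unparseable pattern ({exc})")
            continue
        if not (3 <= d.pattern.min_span and d.pattern.max_span <= 30):
            rep.errors.append(
                f"{d.def_id}: span bounds ({d.pattern.min_span}, {d.pattern.max_span}) "
                "outside [3, 30]"
            )
        if d.group_assoc and d.role not in ("novel", "binding"):
            rep.errors.append(f"{d.def_id}: group_assoc set on role {d.role}")
        if d.family not in FAMILIES:
            rep.errors.append(f"{d.def_id}: unknown family {d.family}")
        if d.role not in ROLES:
            rep.errors.append(f"{d.def_id}: unknown role {d.role}")
    # cross-talk: within one family, does one entry's instantiation hit another?
    by_family: dict[str, list[MotifDef]] = {}
    for d in lib:
        by_family.setdefault(d.family, []).append(d)
    for fam_defs in by_family.values():
        for d in fam_defs:
            inst = instantiate(d.scan_pattern)
            for other in fam_defs:
                if other.def_id == d.def_id:
                    continue
                if match_all(other.scan_pattern, inst, 0):
                    rep.warnings.append(
                        f"cross-talk: instantiation of {d.def_id} matches {other.def_id}"
                    )
    return rep


def query(
    lib: list[MotifDef],
    family: str | None = None,
    role: str | None = None,
    group: str | None = None,
) -> list[MotifDef]:
    """Filter the library, preserving library order."""
    if family is not None and family not in FAMILIES:
        raise ValueError(f"unknown family {family!r}")
    if role is not None and role not in ROLES:
        raise ValueError(f"unknown role {role!r}")
    if group is not None and group not in GROUPS:
        raise ValueError(f"unknown group {group!r}")
    out = []
    for d in lib:
        if family is not None and d.family != family:
            continue
        if role is not None and d.role != role:
            continue
        if group is not None and group not in d.group_assoc:
            continue
        out.append(d)
    return out


def get(lib: list[MotifDef], def_id: str) -> MotifDef:
    for d in lib:
        if d.def_id == def_id:
            return d
    raise KeyError(def_id)


# ---------------------------------------------------------------- TSV I/O

_TSV_HEADER = "def_id\tfamily\trole\tgroups\tpattern\tprovenance"


def write_library_tsv(lib: list[MotifDef], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(_TSV_HEADER + "\n")
        for d in lib:
            fh.write(
                "\t".join(
                    [
                        d.def_id,
                        d.family,
                        d.role,
                        ",".join(sorted(d.group_assoc)),
                        d.pattern.serialize(),
                        d.provenance,
                    ]
                )
                + "\n"
            )


def read_library_tsv(path: str | Path) -> list[MotifDef]:
    """Load a library (or user overlay) from the tab-separated format."""
    lib: list[MotifDef] = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n")
        if header != _TSV_HEADER:
            raise ValueError(f"bad library header in {path}: {header!r}")
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 6:
                raise ValueError(f"{path}:{lineno}: expected 6 columns")
            def_id, family, role, groups, spec, prov = fields
            lib.append(
                _d(
                    def_id,
                    family,
                    role,
                    tuple(g for g in groups.split(",") if g),
                    spec,
                    prov,
                )
            )
    return lib
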