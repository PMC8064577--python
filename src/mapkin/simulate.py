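"""Labeled synthetic proteomes and gene models.

The generator emits kinase proteins assembled from the canonical domain
instantiations of the bundled motif library, laid out in the family's
canonical domain order with group-specific activation motifs and novel
domains at their described loci, joined by random linkers.  Realism knobs
emulate the failure modes the analysis must tolerate: per-residue
substitution noise, N/C-terminal truncation (fragmented genome
assemblies), and decoy non-kinase proteins including "near-miss" decoys
that carry a T-X-Y triplet but lack the core catalytic subdomains.
Gene models with 0-16 introns (the empirically observed range), including
untranslated-region introns, are emitted as GFF3.

Everything is deterministic under the spec seed.  Mutation positions are
drawn rate-independently (a per-position uniform compared against the
rate), so cohorts generated at increasing mutation rates from one seed
have nested mutation sets — motif evidence can then only degrade as the
rate grows.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .library import MotifDef, get, load_default_library
from .patterns import SEQ_ALPHABET, instantiate, match_all
from .scan import ScanParams, identify_family

AA = "ACDEFGHIKLMNPQRSTVWY"

#: intron-count census observed across plant MAPK gene models (0-16)
DEFAULT_INTRON_COUNTS = {
    0: 6, 1: 18, 2: 8, 3: 5, 4: 5, 5: 46, 6: 8, 7: 10,
    8: 8, 9: 33, 10: 20, 11: 2, 12: 2, 14: 2, 15: 7, 16: 1,
}

#: synthetic species pool used for the bundled cohort species map
SPECIES_POOL = (
    ("Synthetica", "alpha"),
    ("Synthetica", "beta"),
    ("Simulata", "gamma"),
    ("Simulata", "delta"),
    ("Fictus", "epsilon"),
)

MAPK_GROUP_PLANS = {
    # group: (activation triplet, novel domains, CD present, long C tail)
    "A": ("TEY", ("MAPK.n12", "MAPK.n17"), True, False),
    "B": ("TEY", ("MAPK.n12", "MAPK.n15", "MAPK.n16", "MAPK.n17"), True, False),
    "C": ("TEY", ("MAPK.n13",), True, False),
    "D": ("TDY", ("MAPK.n14", "MAPK.n17"), False, True),
    "E": ("THE", ("MAPK.n15",), False, False),
}

MEK_GROUP_PLANS = {
    # group: (N-terminal novels, C-terminal novels, NTF2 extension)
    "A": (("MEK.n9",), (), False),
    "B": (("MEK.n10",), ("MEK.n12", "MEK.n13"), True),
    "C": ((), ("MEK.n11",), False),
    "D": ((), (), False),
    "E": ((), ("MEK.n14",), False),
}


@dataclass
class SynthSpec:
    """Study conditions of a synthetic cohort."""

    n_per_group: dict[tuple[str, str], int] = field(
        default_factory=lambda: {
            (fam, g): 2 for fam in ("MAPK", "MEK") for g in "ABCDE"
        }
    )
    mutation_rate: float = 0.0
    protected_fraction: float = 0.25   # fraction of motif positions spared by mutation
    truncation_prob: float = 0.0
    truncation_fraction: float = 0.3
    n_decoys: int = 0                  # half plain, half near-miss (T-X-Y, no core domains)
    linker_length_range: tuple[int, int] = (8, 20)
    intron_count_distribution: dict[int, float] = field(
        default_factory=lambda: dict(DEFAULT_INTRON_COUNTS)
    )
    utr_intron_fraction: float = 0.1
    seed: int = 0

    def validate(self) -> None:
        for p in (self.mutation_rate, self.protected_fraction,
                  self.truncation_prob, self.truncation_fraction,
                  self.utr_intron_fraction):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"probability {p} outside [0, 1]")
        if any(n < 0 for n in self.n_per_group.values()) or self.n_decoys < 0:
            raise ValueError("counts must be >= 0")
        if self.seed is None:
            raise ValueError("seed is mandatory")


@dataclass
class Implant:
    def_id: str
    start: int
    end: int
    lost: bool = False


@dataclass
class SynthTruth:
    seq_id: str
    family: str            # MAPK | MEK | decoy
    group: str             # A-E or "" for decoys
    activation_triplet: str
    implants: list[Implant]
    mutation_rate: float
    n_mutations: int = 0
    truncated: bool = False
    seed: int = 0


def _rng(seed: int, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=tuple(key)))


def _linker(rng: np.random.Generator, lo: int, hi: int) -> str:
    n = int(rng.integers(lo, hi + 1))
    return "".join(rng.choice(list(AA), size=n))


_INST_CACHE: dict[str, str] = {}


def _inst(def_id: str, lib: list[MotifDef]) -> str:
    if def_id not in _INST_CACHE:
        _INST_CACHE[def_id] = instantiate(get(lib, def_id).scan_pattern)
    return _INST_CACHE[def_id]


def _bind_variant_inst(group: str, lib: list[MotifDef]) -> str:
    """Group-specific docking-site instantiation.

    The group-C variant writes its catalytic-core [I/L] position as a
    wildcard; real sequences carry I there (the HRD-I-K core), and the
    membership signature D-[L/I/V]-K depends on it, so the generator pins
    that position to I.
    """
    inst = _inst(f"MEK.bind{group}", lib)
    if group == "C":
        inst = inst[:10] + "I" + inst[11:]
    return inst


def _signature_with_triplet(lib: list[MotifDef], triplet: str) -> str:
    """Canonical signature instantiation with the T-X-Y frame overridden."""
    base = list(_inst("MAPK.signature", lib))
    base[1:4] = list(triplet)
    return "".join(base)


def _assemble(
    segments: list[tuple[str | None, str]],
) -> tuple[str, list[Implant]]:
    seq_parts: list[str] = []
    implants: list[Implant] = []
    pos = 0
    for def_id, text in segments:
        if def_id is not None:
            implants.append(Implant(def_id, pos, pos + len(text)))
        seq_parts.append(text)
        pos += len(text)
    return "".join(seq_parts), implants


def _sanitize(
    seq: str, implants: list[Implant], lib: list[MotifDef]
) -> str:
    """Remove accidental motif hits created by random linkers.

    Any zero-mismatch hit of a library pattern whose window is not fully
    contained in an implanted span must involve linker residues; the
    leftmost non-'G' linker residue in the window is set to 'G' and the
    scan repeats.  Glycine runs satisfy no bundled pattern, so the loop
    terminates.
    """
    spans = [(im.start, im.end) for im in implants]

    def in_implant(i: int) -> bool:
        return any(s <= i < e for s, e in spans)

    chars = list(seq)
    for _ in range(200):
        text = "".join(chars)
        offending = None
        for d in lib:
            for m in match_all(d.scan_pattern, text, 0):
                if not any(s <= m.start and m.end <= e for s, e in spans):
                    offending = m
                    break
            if offending:
                break
        if offending is None:
            return "".join(chars)
        fixed = False
        for i in range(offending.start, offending.end):
            if not in_implant(i) and chars[i] != "G":
                chars[i] = "G"
                fixed = True
                break
        if not fixed:  # pragma: no cover - all linker chars already G
            break
    return "".join(chars)


def generate_protein(
    family: str,
    group: str,
    spec: SynthSpec,
    index: int = 0,
    lib: list[MotifDef] | None = None,
) -> tuple[str, SynthTruth]:
    """One labeled synthetic kinase protein.

    The clean sequence is assembled from canonical instantiations in the
    family's domain order, sanitized against accidental motif creation,
    then mutated (substitutions only) and optionally truncated.
    """
    lib = lib if lib is not None else load_default_library()
    if family == "MAPK":
        plans = MAPK_GROUP_PLANS
    elif family == "MEK":
        plans = MEK_GROUP_PLANS
    else:
        raise ValueError(f"no generator for family {family!r}")
    if group not in plans:
        raise ValueError(f"unknown group {group!r} for family {family}")
    rng = _rng(spec.seed, index, 0)
    lo, hi = spec.linker_length_range
    L = lambda: (None, _linker(rng, lo, hi))

    segments: list[tuple[str | None, str]] = []
    if family == "MAPK":
        triplet, novels, has_cd, long_tail = plans[group]
        n_nterm = [n for n in novels if n in ("MAPK.n12", "MAPK.n13")]
        n_mid = [n for n in novels if n == "MAPK.n14"]
        n_cterm = [n for n in novels if n in ("MAPK.n15", "MAPK.n16", "MAPK.n17")]
        for n in n_nterm:
            segments.append((n, _inst(n, lib)))
            # the N-terminal novel domains sit ~15 residues before domain I
            segments.append((None, _linker(rng, 13, 16)))
        for dom in ("MAPK.I", "MAPK.II"):
            segments += [(dom, _inst(dom, lib)), L()]
        for n in n_mid:  # between II and III
            segments += [(n, _inst(n, lib)), L()]
        for dom in ("MAPK.III", "MAPK.IV", "MAPK.V", "MAPK.VIa", "MAPK.VIb", "MAPK.VII"):
            segments += [(dom, _inst(dom, lib)), L()]
        segments += [("MAPK.signature", _signature_with_triplet(lib, triplet)), L()]
        for dom in ("MAPK.VIII", "MAPK.IX", "MAPK.X"):
            segments += [(dom, _inst(dom, lib)), L()]
        for n in n_cterm:  # between X and XI, before the docking domain
            segments += [(n, _inst(n, lib)), L()]
        if has_cd:
            segments += [("MAPK.CD", _inst("MAPK.CD", lib))]
            segments += [(None, _linker(rng, 28, 32))]
        segments += [("MAPK.XI", _inst("MAPK.XI", lib))]
        if long_tail:
            segments += [(None, _linker(rng, 80, 100))]
        else:
            segments += [(None, _linker(rng, 3, 12))]
    else:
        n_nterm, n_cterm, ntf2 = plans[group]
        triplet = ""
        for n in n_nterm:
            segments += [(n, _inst(n, lib)), L()]
        for dom in ("MEK.I", "MEK.ATP", "MEK.II", "MEK.III"):
            segments += [(dom, _inst(dom, lib)), L()]
        segments += [(f"MEK.bind{group}", _bind_variant_inst(group, lib)), L()]
        for dom in ("MEK.IV", "MEK.ACT", "MEK.V", "MEK.VI", "MEK.VII", "MEK.VIII"):
            segments += [(dom, _inst(dom, lib)), L()]
        for n in n_cterm:
            segments += [(n, _inst(n, lib)), L()]
        if ntf2:
            segments += [("MEK.NTF2ext", _inst("MEK.NTF2ext", lib)), L()]

    seq, implants = _assemble(segments)
    seq = _sanitize(seq, implants, lib)

    # --- substitution noise (positions drawn rate-independently) ---
    rng_mut = _rng(spec.seed, index, 1)
    n_total = len(seq)
    u = rng_mut.random(n_total)
    targets = rng_mut.integers(0, 19, size=n_total)
    protect_u = rng_mut.random(n_total)
    motif_pos = np.zeros(n_total, dtype=bool)
    for im in implants:
        motif_pos[im.start : im.end] = True
    protected = motif_pos & (protect_u < spec.protected_fraction)
    chars = list(seq)
    n_mut = 0
    for i in range(n_total):
        if u[i] < spec.mutation_rate and not protected[i]:
            alt = AA.replace(chars[i], "")
            chars[i] = alt[targets[i] % len(alt)]
            n_mut += 1
    seq = "".join(chars)

    # --- truncation (fragmented-assembly emulation) ---
    rng_trunc = _rng(spec.seed, index, 2)
    truncated = False
    if rng_trunc.random() < spec.truncation_prob:
        truncated = True
        cut = int(spec.truncation_fraction * len(seq))
        if rng_trunc.random() < 0.5:  # N-terminal clip
            seq = seq[cut:]
            for im in implants:
                if im.start < cut:
                    im.lost = True
                im.start = max(im.start - cut, 0)
                im.end = max(im.end - cut, 0)
        else:  # C-terminal clip
            keep = len(seq) - cut
            seq = seq[:keep]
            for im in implants:
                if im.end > keep:
                    im.lost = True
                    im.end = min(im.end, keep)
                    im.start = min(im.start, keep)

    truth = SynthTruth(
        seq_id=f"syn{index:04d}",
        family=family,
        group=group,
        activation_triplet=triplet,
        implants=implants,
        mutation_rate=spec.mutation_rate,
        n_mutations=n_mut,
        truncated=truncated,
        seed=spec.seed,
    )
    return seq, truth


def _decoy(
    spec: SynthSpec, index: int, near_miss: bool, lib: list[MotifDef]
) -> tuple[str, SynthTruth]:
    """A non-kinase decoy; regenerated until the family gate stays silent."""
    params = ScanParams()
    for attempt in range(25):
        rng = _rng(spec.seed, 100_000 + index, attempt)
        n = int(rng.integers(150, 451))
        seq = "".join(rng.choice(list(AA), size=n))
        if near_miss:
            p = int(rng.integers(10, n - 13))
            seq = seq[:p] + "TEY" + seq[p + 3 :]
        call, _ = identify_family(f"dec{index:04d}", seq, lib, params)
        if call.family == "none":
            truth = SynthTruth(
                seq_id=f"dec{index:04d}",
                family="decoy",
                group="",
                activation_triplet="TEY" if near_miss else "",
                implants=[],
                mutation_rate=0.0,
                seed=spec.seed,
            )
            return seq, truth
    raise RuntimeError("could not generate a silent decoy")  # pragma: no cover


@dataclass
class Cohort:
    records: list[tuple[str, str]]          # (seq_id, sequence)
    truths: list[SynthTruth]
    species_map: dict[str, tuple[str, str]]  # seq_id -> (genus, species)

    def truth_of(self, seq_id: str) -> SynthTruth:
        for t in self.truths:
            if t.seq_id == seq_id:
                return t
        raise KeyError(seq_id)


def generate_cohort(spec: SynthSpec, lib: list[MotifDef] | None = None) -> Cohort:
    """Deterministic labeled cohort: kinases per (family, group) plus decoys."""
    spec.validate()
    lib = lib if lib is not None else load_default_library()
    total = sum(spec.n_per_group.values()) + spec.n_decoys
    if total == 0:
        raise ValueError("cohort would be empty")
    records: list[tuple[str, str]] = []
    truths: list[SynthTruth] = []
    idx = 0
    for (family, group), count in sorted(spec.n_per_group.items()):
        for _ in range(count):
            seq, truth = generate_protein(family, group, spec, idx, lib)
            records.append((truth.seq_id, seq))
            truths.append(truth)
            idx += 1
    n_near = spec.n_decoys // 2
    for j in range(spec.n_decoys):
        seq, truth = _decoy(spec, j, near_miss=(j < n_near), lib=lib)
        records.append((truth.seq_id, seq))
        truths.append(truth)
    species_map = {
        sid: SPECIES_POOL[i % len(SPECIES_POOL)]
        for i, (sid, _) in enumerate(records)
    }
    return Cohort(records, truths, species_map)


# ------------------------------------------------------------ gene models


@dataclass
class GeneTruth:
    mrna_id: str
    n_introns: int
    utr5_intron: bool
    utr3_intron: bool


def generate_gene_models(
    cohort: Cohort, spec: SynthSpec
) -> tuple[str, list[GeneTruth]]:
    """GFF3 gene models for every cohort record, plus the sampled truth.

    Exon counts are sampled from the intron-count distribution (+1); a
    ``utr_intron_fraction`` of multi-exon models place their first intron
    entirely inside the 5' UTR.  Models alternate strand.
    """
    rng = _rng(spec.seed, 999)
    counts = np.array(sorted(spec.intron_count_distribution))
    weights = np.array(
        [spec.intron_count_distribution[int(c)] for c in counts], dtype=float
    )
    weights /= weights.sum()

    lines = ["##gff-version 3"]
    truths: list[GeneTruth] = []
    for i, (seq_id, seq) in enumerate(cohort.records):
        n_introns = int(rng.choice(counts, p=weights))
        utr5 = bool(rng.random() < spec.utr_intron_fraction) and n_introns >= 1
        strand = "+" if rng.random() < 0.5 else "-"
        cds_len = 3 * len(seq) + 3
        utr5_len, utr3_len = 150, 120
        t_len = utr5_len + cds_len + utr3_len
        # transcript-space breakpoints after which an intron is inserted
        n_cds_introns = n_introns - (1 if utr5 else 0)
        bps: list[int] = []
        if utr5:
            bps.append(int(rng.integers(20, utr5_len - 20)))
        lo_b, hi_b = utr5_len + 3, utr5_len + cds_len - 3
        cds_bps = sorted(
            int(b) for b in rng.choice(
                np.arange(lo_b, hi_b), size=n_cds_introns, replace=False
            )
        ) if n_cds_introns > 0 else []
        bps.extend(cds_bps)
        intron_lens = [int(rng.integers(80, 201)) for _ in bps]

        g0 = 1001  # genomic start of the transcript
        exons: list[tuple[int, int]] = []
        # map transcript coordinate -> genomic, inserting introns at breakpoints
        prev_t = 0
        g = g0
        for bp, ilen in zip(bps, intron_lens):
            exons.append((g, g + (bp - prev_t) - 1))
            g += (bp - prev_t) + ilen
            prev_t = bp
        exons.append((g, g + (t_len - prev_t) - 1))

        def t2g_intervals(t_start: int, t_end: int) -> list[tuple[int, int]]:
            """Project a transcript interval [t_start, t_end] (1-based) onto exons."""
            out = []
            t_cursor = 1
            for es, ee in exons:
                span = ee - es + 1
                seg_lo, seg_hi = t_cursor, t_cursor + span - 1
                a, b = max(t_start, seg_lo), min(t_end, seg_hi)
                if a <= b:
                    out.append((es + (a - seg_lo), es + (b - seg_lo)))
                t_cursor += span
            return out

        utr5_iv = t2g_intervals(1, utr5_len)
        cds_iv = t2g_intervals(utr5_len + 1, utr5_len + cds_len)
        utr3_iv = t2g_intervals(utr5_len + cds_len + 1, t_len)

        gene_end = exons[-1][1]
        if strand == "-":
            # reflect within the scaffold so '-' models exercise the mirror path
            total_span = gene_end + 1000

            def refl(iv: tuple[int, int]) -> tuple[int, int]:
                s, e = iv
                return total_span - e, total_span - s

            exons = sorted(refl(iv) for iv in exons)
            utr5_iv = sorted(refl(iv) for iv in utr5_iv)
            cds_iv = sorted(refl(iv) for iv in cds_iv)
            utr3_iv = sorted(refl(iv) for iv in utr3_iv)
        seqid = f"scaffold_{i + 1}"
        gene_id = f"gene_{seq_id}"
        mrna_id = f"mRNA_{seq_id}"
        gs, ge = exons[0][0], exons[-1][1]
        lines.append(
            f"{seqid}\tmapkin\tgene\t{gs}\t{ge}\t.\t{strand}\t.\tID={gene_id}"
        )
        lines.append(
            f"{seqid}\tmapkin\tmRNA\t{gs}\t{ge}\t.\t{strand}\t.\t"
            f"ID={mrna_id};Parent={gene_id}"
        )
        for k, (s, e) in enumerate(exons, 1):
            lines.append(
                f"{seqid}\tmapkin\texon\t{s}\t{e}\t.\t{strand}\t.\t"
                f"ID={mrna_id}.exon{k};Parent={mrna_id}"
            )
        for k, (s, e) in enumerate(cds_iv, 1):
            lines.append(
                f"{seqid}\tmapkin\tCDS\t{s}\t{e}\t.\t{strand}\t0\t"
                f"ID={mrna_id}.cds{k};Parent={mrna_id}"
            )
        for k, (s, e) in enumerate(utr5_iv, 1):
            lines.append(
                f"{seqid}\tmapkin\tfive_prime_UTR\t{s}\t{e}\t.\t{strand}\t.\t"
                f"ID={mrna_id}.utr5.{k};Parent={mrna_id}"
            )
        for k, (s, e) in enumerate(utr3_iv, 1):
            lines.append(
                f"{seqid}\tmapkin\tthree_prime_UTR\t{s}\t{e}\t.\t{strand}\t.\t"
                f"ID={mrna_id}.utr3.{k};Parent={mrna_id}"
            )
        truths.append(GeneTruth(mrna_id, n_introns, utr5, False))
    return "\n".join(lines) + "\n", truths


def write_fasta(cohort: Cohort, path) -> None:
    with open(path, "w") as fh:
        for seq_id, seq in cohort.records:
            fh.write(f">{seq_id}\n")
            for i in range(0, len(seq), 60):
                fh.write(seq[i : i + 60] + "\n")


def write_truth_tsv(cohort: Cohort, path) -> None:
    with open(path, "w") as fh:
        fh.write(
            "seq_id\tfamily\tgroup\tactivation_triplet\tmutation_rate\t"
            "n_mutations\ttruncated\timplants\n"
        )
        for t in cohort.truths:
            implants = ";".join(
                f"{im.def_id}:{im.start + 1}-{im.end}{'(lost)' if im.lost else ''}"
                for im in t.implants
            )
            fh.write(
                f"{t.seq_id}\t{t.family}\t{t.group}\t{t.activation_triplet}\t"
                f"{t.mutation_rate}\t{t.n_mutations}\t{int(t.truncated)}\t{implants}\n"
            )


def write_species_map(cohort: Cohort, path) -> None:
    with open(path, "w") as fh:
        fh.write("seq_id\tgenus\tspecies\n")
        for sid, (genus, species) in cohort.species_map.items():
            fh.write(f"{sid}\t{genus}\t{species}\n")
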