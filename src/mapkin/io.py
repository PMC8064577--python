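"""FASTA/TSV input-output helpers shared by the CLI and scripts."""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import pandas as pd
from Bio import SeqIO

from . import __version__


class InputError(ValueError):
    """Malformed input file; message names the first offending record."""


def read_fasta(path: str | Path) -> dict[str, str]:
    """Sequences keyed by the first whitespace-delimited token of the header.

    Duplicate ids and empty sequences are rejected.
    """
    seqs: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        sid = rec.id
        if sid in seqs:
            raise InputError(f"duplicate FASTA id {sid!r} in {path}")
        seq = str(rec.seq).upper()
        if not seq:
            raise InputError(f"empty sequence for {sid!r} in {path}")
        seqs[sid] = seq
    if not seqs:
        raise InputError(f"no FASTA records in {path}")
    return seqs


def read_species_map(path: str | Path) -> dict[str, tuple[str, str]]:
    """TSV with columns seq_id, genus, species (header required)."""
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    required = {"seq_id", "genus", "species"}
    if not required.issubset(df.columns):
        raise InputError(f"species map {path} must have columns {sorted(required)}")
    return {r.seq_id: (r.genus, r.species) for r in df.itertuples()}


def params_digest(params: object) -> str:
    blob = json.dumps(
        getattr(params, "__dict__", params), sort_keys=True, default=str
    ).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def write_report(df: pd.DataFrame, path: str | Path, seed: int | None, params: object) -> None:
    """TSV report with a reproducibility header.

    All coordinates in reports are 1-based inclusive.
    """
    with open(path, "w") as fh:
        fh.write(f"# mapkin {__version__}\n")
        fh.write(f"# seed={seed} params_digest={params_digest(params)}\n")
        fh.write("# coordinates: 1-based inclusive\n")
        df.to_csv(fh, sep="\t", index=False)


def read_report(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")
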