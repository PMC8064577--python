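"""Molecular weight, theoretical isoelectric point and length summaries.

MW is the sum of average residue masses plus one water; pI is the pH at
which the Henderson–Hasselbalch net charge crosses zero, solved by
bisection on [0, 14].  The pKa set follows the Bjellqvist values used by
the common web calculators, with residue-specific N-terminal pKas and a
flat C-terminal carboxyl pKa of 3.55 (net charge is then strictly
decreasing in pH, so bisection always converges and adding an acidic
residue can never raise the pI).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .patterns import AMINO_ACIDS

#: average (isotope-abundance weighted) residue masses, daltons
AVERAGE_RESIDUE_MASS = {
    "A": 71.0788, "R": 156.1875, "N": 114.1038, "D": 115.0886,
    "C": 103.1388, "E": 129.1155, "Q": 128.1307, "G": 57.0519,
    "H": 137.1411, "I": 113.1594, "L": 113.1594, "K": 128.1741,
    "M": 131.1926, "F": 147.1766, "P": 97.1167, "S": 87.0782,
    "T": 101.1051, "W": 186.2132, "Y": 163.1760, "V": 99.1326,
}
WATER_MASS = 18.0153

#: Bjellqvist pKa set (pI calculation)
PKA_POSITIVE = {"K": 10.0, "R": 12.0, "H": 5.98}
PKA_NEGATIVE = {"D": 4.05, "E": 4.45, "C": 9.0, "Y": 10.0}
PKA_NTERM_DEFAULT = 7.5
PKA_NTERM_BY_RESIDUE = {
    "A": 7.59, "M": 7.0, "S": 6.93, "P": 8.36, "T": 6.82, "V": 7.44, "E": 7.7,
}
PKA_CTERM = 3.55
PKA_SET_NAME = "Bjellqvist (flat C-terminal carboxyl)"


class ResidueError(ValueError):
    """Sequence contains residues outside the 20-letter alphabet."""


@dataclass(frozen=True)
class PhyschemRecord:
    seq_id: str
    length: int
    mw: float
    pi: float


def _check(seq: str) -> None:
    if not seq:
        raise ResidueError("empty sequence")
    bad = set(seq) - AMINO_ACIDS
    if bad:
        raise ResidueError(
            f"nonstandard residues not allowed here: {''.join(sorted(bad))!r}"
        )


def molecular_weight(seq: str) -> float:
    """Average molecular mass in daltons (residue masses + one water)."""
    _check(seq)
    return sum(AVERAGE_RESIDUE_MASS[a] for a in seq) + WATER_MASS


def net_charge(seq: str, ph: float) -> float:
    """Henderson–Hasselbalch net charge of *seq* at *ph*."""
    _check(seq)
    pos_pkas = [PKA_NTERM_BY_RESIDUE.get(seq[0], PKA_NTERM_DEFAULT)]
    neg_pkas = [PKA_CTERM]
    for a in seq:
        if a in PKA_POSITIVE:
            pos_pkas.append(PKA_POSITIVE[a])
        elif a in PKA_NEGATIVE:
            neg_pkas.append(PKA_NEGATIVE[a])
    charge = sum(1.0 / (1.0 + 10 ** (ph - pk)) for pk in pos_pkas)
    charge -= sum(1.0 / (1.0 + 10 ** (pk - ph)) for pk in neg_pkas)
    return charge


def isoelectric_point(seq: str, tol: float = 1e-4) -> float:
    """pH at which :func:`net_charge` crosses zero (bisection on [0, 14])."""
    _check(seq)
    lo, hi = 0.0, 14.0
    while hi - lo > tol:
        mid = (lo + hi) / 2.0
        if net_charge(seq, mid) > 0:
            lo = mid
        else:
            hi = mid
    return (lo + hi) / 2.0


def profile(records: list[tuple[str, str]]) -> pd.DataFrame:
    """Per-sequence table: seq_id, length, mw_da, pi."""
    rows = [
        {
            "seq_id": sid,
            "length": len(seq),
            "mw_da": round(molecular_weight(seq), 2),
            "pi": round(isoelectric_point(seq), 2),
        }
        for sid, seq in records
    ]
    return pd.DataFrame(rows)


def group_summary(
    records: list[PhyschemRecord], group_labels: dict[str, str]
) -> tuple[pd.DataFrame, list[str]]:
    """Quartile summary per group for length, MW and pI.

    Per group and metric: n, mean, median, Q1, Q3 (linear-interpolation
    quantiles) and the values outside median +/- 1.5 IQR whiskers
    (classical boxplot outliers).  Groups with no members are omitted
    with a warning.
    """
    warnings: list[str] = []
    by_group: dict[str, list[PhyschemRecord]] = {}
    for r in records:
        g = group_labels.get(r.seq_id)
        if g is None:
            warnings.append(f"{r.seq_id}: no group label; skipped")
            continue
        by_group.setdefault(g, []).append(r)
    rows = []
    for g in sorted(by_group):
        members = by_group[g]
        if not members:
            warnings.append(f"group {g}: empty; omitted")
            continue
        for metric, getter in (
            ("length", lambda r: float(r.length)),
            ("mw", lambda r: r.mw),
            ("pi", lambda r: r.pi),
        ):
            vals = np.array([getter(r) for r in members])
            q1, med, q3 = np.percentile(vals, [25, 50, 75], method="linear")
            iqr = q3 - q1
            lo_w, hi_w = q1 - 1.5 * iqr, q3 + 1.5 * iqr
            outliers = [float(v) for v in vals if v < lo_w or v > hi_w]
            rows.append(
                {
                    "group": g,
                    "metric": metric,
                    "n": len(vals),
                    "mean": float(vals.mean()),
                    "median": float(med),
                    "q1": float(q1),
                    "q3": float(q3),
                    "outliers": ";".join(f"{v:g}" for v in outliers),
                }
            )
    return pd.DataFrame(rows), warnings
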