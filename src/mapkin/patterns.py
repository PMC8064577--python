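"""Degenerate consensus-motif patterns and matching.

Kinase-domain consensus sequences in the plant MAPK/MEK literature are
written in a hyphenated mini-language::

    D-[L/I/V]-K            literal / choice tokens
    S/T-X_3-5_-S/T         unbracketed choice, bounded wildcard run
    L-H-D-X_2_-D-E-P       fixed-length wildcard run

This module parses that notation into :class:`MotifPattern` objects and
finds all occurrences of a pattern in a protein sequence, optionally
tolerating a bounded number of substitutions at literal/choice positions.
A deliberately naive :func:`brute_force_match` with the same contract is
provided as an independent oracle for testing.

Coordinates are 0-based half-open internally; user-facing reports convert
to 1-based inclusive.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

AMINO_ACIDS = frozenset("ACDEFGHIKLMNPQRSTVWY")
#: residues legal in an input protein sequence ('X' = unknown residue;
#: it matches wildcard elements only, never a literal or a choice)
SEQ_ALPHABET = AMINO_ACIDS | {"X"}

LITERAL = "literal"
CHOICE = "choice"
WILDCARD = "wildcard"


class PatternSyntaxError(ValueError):
    """Raised when a consensus string cannot be parsed."""


class SequenceAlphabetError(ValueError):
    """Raised when a protein sequence contains illegal characters."""


@dataclass(frozen=True)
class MotifElement:
    """One token of a consensus pattern.

    kind
        ``literal`` (one fixed residue), ``choice`` (one of several
        residues) or ``wildcard`` (any residue, possibly repeated).
    residues
        Allowed residues in listed order (the first listed residue is the
        canonical choice for :func:`instantiate`); empty for a wildcard.
    min_repeat / max_repeat
        Repeat bounds; always 1/1 for literal and choice.
    """

    kind: str
    residues: tuple[str, ...]
    min_repeat: int = 1
    max_repeat: int = 1

    def __post_init__(self) -> None:
        if self.kind == LITERAL and len(self.residues) != 1:
            raise PatternSyntaxError("literal element needs exactly one residue")
        if self.kind == CHOICE and len(set(self.residues)) < 2:
            raise PatternSyntaxError("choice element needs >=2 distinct residues")
        if self.kind == WILDCARD and self.residues:
            raise PatternSyntaxError("wildcard element carries no residues")
        if self.min_repeat < 1 or self.max_repeat < self.min_repeat:
            raise PatternSyntaxError(
                f"bad repeat bounds {self.min_repeat}-{self.max_repeat}"
            )
        if self.kind in (LITERAL, CHOICE) and (self.min_repeat, self.max_repeat) != (1, 1):
            raise PatternSyntaxError("repeats are only allowed on wildcards")

    def admits(self, residue: str) -> bool:
        """True if *residue* satisfies this element without a mismatch."""
        if self.kind == WILDCARD:
            return True
        return residue in self.residues


@dataclass(frozen=True)
class MotifPattern:
    """A parsed consensus pattern with precomputed span bounds."""

    pattern_id: str
    elements: tuple[MotifElement, ...]
    min_span: int = field(init=False)
    max_span: int = field(init=False)

    def __post_init__(self) -> None:
        if not self.elements:
            raise PatternSyntaxError(f"{self.pattern_id}: empty pattern")
        object.__setattr__(self, "min_span", sum(e.min_repeat for e in self.elements))
        object.__setattr__(self, "max_span", sum(e.max_repeat for e in self.elements))

    @property
    def is_fixed_span(self) -> bool:
        return self.min_span == self.max_span

    def serialize(self) -> str:
        """Normalized hyphenated text form (choices bracketed, sorted input order kept)."""
        parts = []
        for el in self.elements:
            if el.kind == LITERAL:
                parts.append(next(iter(el.residues)))
            elif el.kind == CHOICE:
                parts.append("[" + "/".join(el.residues) + "]")
            else:
                lo, hi = el.min_repeat, el.max_repeat
                if (lo, hi) == (1, 1):
                    parts.append("X")
                elif lo == hi:
                    parts.append(f"X_{lo}_")
                else:
                    parts.append(f"X_{lo}-{hi}_")
        return "-".join(parts)


@dataclass(frozen=True, order=True)
class MotifMatch:
    """One occurrence of a pattern: 0-based half-open window on the sequence."""

    start: int
    end: int
    pattern_id: str
    matched_text: str
    mismatches: int

    @property
    def length(self) -> int:
        return self.end - self.start


def _tokenize(spec: str) -> list[str]:
    """Split on '-' except inside brackets, parentheses or underscore runs."""
    tokens: list[str] = []
    buf: list[str] = []
    depth = 0
    in_underscore = False
    for ch in spec:
        if ch in "[(":
            depth += 1
            buf.append(ch)
        elif ch in "])":
            depth -= 1
            if depth < 0:
                raise PatternSyntaxError(f"unbalanced bracket in {spec!r}")
            buf.append(ch)
        elif ch == "_":
            in_underscore = not in_underscore
            buf.append(ch)
        elif ch == "-" and depth == 0 and not in_underscore:
            tokens.append("".join(buf))
            buf = []
        else:
            buf.append(ch)
    if depth != 0 or in_underscore:
        raise PatternSyntaxError(f"unbalanced bracket or underscore in {spec!r}")
    tokens.append("".join(buf))
    return tokens


def _parse_choice_body(body: str, token: str) -> MotifElement:
    residues = body.split("/")
    for r in residues:
        if len(r) != 1 or r not in AMINO_ACIDS:
            raise PatternSyntaxError(f"unknown residue {r!r} in token {token!r}")
    seen: list[str] = []
    for r in residues:
        if r not in seen:
            seen.append(r)
    res = tuple(seen)
    if len(res) == 1:
        return MotifElement(LITERAL, res)
    return MotifElement(CHOICE, res)


def _parse_token(token: str) -> MotifElement:
    token = token.strip()
    if not token:
        raise PatternSyntaxError("empty token")
    # bracketed or parenthesized choice: [L/I/V] or (L/H)
    if (token.startswith("[") and token.endswith("]")) or (
        token.startswith("(") and token.endswith(")")
    ):
        return _parse_choice_body(token[1:-1], token)
    # unbracketed choice as printed in running text: S/T
    if "/" in token:
        return _parse_choice_body(token, token)
    # wildcards: X, X_n_, X_m-n_
    if token[0] == "X":
        if token == "X":
            return MotifElement(WILDCARD, ())
        if token[1] == "_" and token.endswith("_"):
            body = token[2:-1]
            try:
                if "-" in body:
                    lo_s, hi_s = body.split("-")
                    lo, hi = int(lo_s), int(hi_s)
                else:
                    lo = hi = int(body)
            except ValueError as exc:
                raise PatternSyntaxError(f"malformed wildcard token {token!r}") from exc
            if lo < 1 or hi < lo:
                raise PatternSyntaxError(f"bad wildcard bounds in token {token!r}")
            return MotifElement(WILDCARD, (), lo, hi)
        raise PatternSyntaxError(f"malformed wildcard token {token!r}")
    # single-letter literal
    if len(token) == 1 and token in AMINO_ACIDS:
        return MotifElement(LITERAL, (token,))
    raise PatternSyntaxError(f"unrecognized token {token!r}")


def parse_pattern(spec: str, pattern_id: str = "") -> MotifPattern:
    """Parse a hyphenated consensus string into a :class:`MotifPattern`.

    Raises :class:`PatternSyntaxError` naming the offending token on any
    malformed input (unknown residue letter, bad brackets/underscores,
    empty spec).
    """
    if not spec or not spec.strip():
        raise PatternSyntaxError("empty pattern specification")
    return MotifPattern(pattern_id or spec, tuple(_parse_token(t) for t in _tokenize(spec)))


def validate_sequence(seq: str) -> None:
    """Reject lowercase or non-alphabet characters."""
    bad = set(seq) - SEQ_ALPHABET
    if bad:
        raise SequenceAlphabetError(
            f"illegal sequence characters: {''.join(sorted(bad))!r}"
        )


def _element_cost(el: MotifElement, residue: str) -> int | None:
    """Substitution cost of placing *residue* at a single-position element.

    Returns None for wildcard elements (handled separately); 0 if allowed,
    1 if a substitution is needed.  An 'X' in the sequence never satisfies
    a literal/choice, so it always costs 1 there.
    """
    return 0 if el.admits(residue) else 1


def match_all(
    pattern: MotifPattern, seq: str, max_mismatches: int = 0
) -> list[MotifMatch]:
    """All distinct (start, end) windows of *seq* matching *pattern*.

    A window matches when the elements can be laid over it, in order, with
    at most ``max_mismatches`` substitutions at literal/choice positions;
    wildcard repeats are never charged.  For each window the minimum
    achievable mismatch count is reported.  Output sorted by (start, end).
    """
    validate_sequence(seq)
    n = len(seq)
    elements = pattern.elements
    k = len(elements)
    # suffix min/max spans for pruning
    suf_min = [0] * (k + 1)
    suf_max = [0] * (k + 1)
    for i in range(k - 1, -1, -1):
        suf_min[i] = suf_min[i + 1] + elements[i].min_repeat
        suf_max[i] = suf_max[i + 1] + elements[i].max_repeat

    results: list[MotifMatch] = []
    first = elements[0]
    for start in range(0, n - pattern.min_span + 1):
        # cheap prefilter on the first element
        if first.kind != WILDCARD and not first.admits(seq[start]) and max_mismatches == 0:
            continue
        # best[pos] = min mismatches to consume elements[0..i) ending at pos
        # iterative DP over elements
        frontier: dict[int, int] = {start: 0}
        ends: dict[int, int] = {}
        for i, el in enumerate(elements):
            nxt: dict[int, int] = {}
            for pos, cost in frontier.items():
                if el.kind == WILDCARD:
                    for rep in range(el.min_repeat, el.max_repeat + 1):
                        p2 = pos + rep
                        if p2 > n:
                            break
                        if p2 + suf_min[i + 1] > n:
                            break
                        if p2 not in nxt or cost < nxt[p2]:
                            nxt[p2] = cost
                else:
                    if pos >= n:
                        continue
                    c2 = cost + (0 if el.admits(seq[pos]) else 1)
                    if c2 <= max_mismatches:
                        p2 = pos + 1
                        if p2 + suf_min[i + 1] <= n and (p2 not in nxt or c2 < nxt[p2]):
                            nxt[p2] = c2
            frontier = nxt
            if not frontier:
                break
        for end, cost in frontier.items():
            if cost <= max_mismatches:
                ends[end] = cost
        for end in sorted(ends):
            results.append(
                MotifMatch(start, end, pattern.pattern_id, seq[start:end], ends[end])
            )
    results.sort(key=lambda m: (m.start, m.end))
    return results


def brute_force_match(
    pattern: MotifPattern, seq: str, max_mismatches: int = 0
) -> list[MotifMatch]:
    """Exhaustive oracle with the same contract as :func:`match_all`.

    Enumerates every window and every wildcard-repeat decomposition
    explicitly.  Exponential in the number of variable wildcards; intended
    for small test inputs only.
    """
    validate_sequence(seq)
    n = len(seq)
    elements = pattern.elements
    repeat_ranges = [range(e.min_repeat, e.max_repeat + 1) for e in elements]
    found: dict[tuple[int, int], int] = {}
    for start in range(n + 1):
        for reps in itertools.product(*repeat_ranges):
            end = start + sum(reps)
            if end > n:
                continue
            pos = start
            cost = 0
            ok = True
            for el, rep in zip(elements, reps):
                if el.kind == WILDCARD:
                    pos += rep
                    continue
                if not el.admits(seq[pos]):
                    cost += 1
                    if cost > max_mismatches:
                        ok = False
                        break
                pos += 1
            if ok:
                key = (start, end)
                if key not in found or cost < found[key]:
                    found[key] = cost
    return sorted(
        MotifMatch(s, e, pattern.pattern_id, seq[s:e], c)
        for (s, e), c in found.items()
    )


def instantiate(
    pattern: MotifPattern,
    avoid: list[MotifPattern] | None = None,
) -> str:
    """Canonical concrete sequence realizing *pattern*.

    Policy: first listed residue at each choice, 'A' at each wildcard
    position, minimum repeat at variable wildcards.  If *avoid* patterns are given and an 'A' placed at
    a wildcard position lets a different pattern match with zero
    mismatches, that 'A' is flipped to 'G' (collision-avoidance fallback).
    """
    chars: list[str] = []
    wildcard_positions: list[int] = []
    for el in pattern.elements:
        if el.kind == WILDCARD:
            for _ in range(el.min_repeat):
                wildcard_positions.append(len(chars))
                chars.append("A")
        else:
            chars.append(el.residues[0])
    if avoid:
        for _ in range(len(wildcard_positions) + 1):
            text = "".join(chars)
            collisions = []
            for other in avoid:
                if other.pattern_id == pattern.pattern_id:
                    continue
                collisions.extend(match_all(other, text, 0))
            flipped = False
            for m in collisions:
                for wp in wildcard_positions:
                    if m.start <= wp < m.end and chars[wp] == "A":
                        chars[wp] = "G"
                        flipped = True
                        break
                if flipped:
                    break
            if not flipped:
                break
    return "".join(chars)
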