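"""PROSITE pattern parsing and motif scanning.

The supported dialect is the dash-separated pattern syntax: an exact residue
(``C``), the wildcard ``x``, an allowed set ``[DE]``, a forbidden set
``{FWY}``, each optionally followed by a repetition count ``(n)`` or a bounded
repetition ``(n,m)``.  Terminal anchors (``<``, ``>``) are rejected with a
clear message rather than silently mis-parsed.

Matching backtracks over variable repetition bounds.  Every start position
admitting a match is reported once, with the shortest satisfying span;
matching against sequences is case-insensitive.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

from .seqio import ALPHABET, SglutError, WindowSample

#: Patterns discussed in the motif analysis of known modified windows
#: (phosphagen kinase, GAPDH, NF-kB/Rel, and thiol protease active sites).
REFERENCE_PATTERNS = {
    "PS00112": "C-P-x(0,1)-[ST]-N-[ILV]-G-T",
    "PS00071": "[ASV]-S-C-[NT]-T-{S}-x-[LIM]",
    "PS01204": "F-R-Y-x-C-E-G",
    "PS00139": "Q-{V}-x-{DE}-[GE]-{F}-C-[YW]-{DN}-x-[STAGC]-[STAGCV]",
}


class PrositeParseError(SglutError):
    pass


@dataclass(frozen=True)
class PatternElement:
    """One pattern position: what residues it admits and how often it repeats."""

    kind: str  # residue | any | allowed | forbidden
    residues: frozenset[str]  # admitted residues (already complemented for {..})
    min_rep: int = 1
    max_rep: int = 1

    def admits(self, aa: str) -> bool:
        return aa in self.residues


@dataclass(frozen=True)
class PrositePattern:
    id: str
    elements: tuple[PatternElement, ...]

    def min_span(self) -> int:
        return sum(e.min_rep for e in self.elements)


@dataclass(frozen=True)
class MotifMatch:
    pattern_id: str
    sequence_id: str
    start: int  # 1-based
    matched_span: str


_BOUNDS_RE = re.compile(r"\((\d+)(?:,(\d+))?\)$")


def _parse_element(token: str, position: int) -> PatternElement:
    min_rep, max_rep = 1, 1
    m = _BOUNDS_RE.search(token)
    if m:
        min_rep = int(m.group(1))
        max_rep = int(m.group(2)) if m.group(2) is not None else min_rep
        if min_rep > max_rep:
            raise PrositeParseError(
                f"element {position}: repetition bounds ({min_rep},{max_rep}) inverted"
            )
        token = token[: m.start()]
    elif "(" in token or ")" in token:
        raise PrositeParseError(
            f"element {position}: malformed repetition bounds in {token!r}"
        )

    if token in ("<", ">") or "<" in token or ">" in token:
        raise PrositeParseError(
            f"element {position}: terminal anchors (<, >) are not supported"
        )
    if token == "x":
        return PatternElement("any", frozenset(ALPHABET), min_rep, max_rep)
    if len(token) == 1 and token in ALPHABET:
        return PatternElement("residue", frozenset(token), min_rep, max_rep)
    if token.startswith("[") and token.endswith("]"):
        inner = token[1:-1]
        if not inner or not set(inner) <= set(ALPHABET):
            raise PrositeParseError(f"element {position}: bad allowed set {token!r}")
        return PatternElement("allowed", frozenset(inner), min_rep, max_rep)
    if token.startswith("{") and token.endswith("}"):
        inner = token[1:-1]
        if not inner or not set(inner) <= set(ALPHABET):
            raise PrositeParseError(f"element {position}: bad forbidden set {token!r}")
        return PatternElement(
            "forbidden", frozenset(ALPHABET) - frozenset(inner), min_rep, max_rep
        )
    raise PrositeParseError(f"element {position}: cannot parse {token!r}")


def parse_prosite(text: str, pattern_id: str = "") -> PrositePattern:
    """Parse a dash-separated PROSITE pattern string."""
    cleaned = text.strip().rstrip(".")
    if not cleaned:
        raise PrositeParseError("empty pattern")
    elements = tuple(
        _parse_element(tok.strip(), i + 1)
        for i, tok in enumerate(cleaned.split("-"))
    )
    return PrositePattern(pattern_id or cleaned, elements)


def unparse(pattern: PrositePattern) -> str:
    parts = []
    for e in pattern.elements:
        if e.kind == "any":
            core = "x"
        elif e.kind == "residue":
            core = next(iter(e.residues))
        elif e.kind == "allowed":
            core = "[" + "".join(sorted(e.residues)) + "]"
        else:
            core = "{" + "".join(sorted(frozenset(ALPHABET) - e.residues)) + "}"
        if (e.min_rep, e.max_rep) == (1, 1):
            parts.append(core)
        elif e.min_rep == e.max_rep:
            parts.append(f"{core}({e.min_rep})")
        else:
            parts.append(f"{core}({e.min_rep},{e.max_rep})")
    return "-".join(parts)


def _match_from(
    elements: tuple[PatternElement, ...], seq: str, pos: int, elem_i: int
) -> int | None:
    """Shortest end offset of a match of elements[elem_i:] starting at pos.

    Backtracks over repetition counts, trying smaller counts first so the
    first success is the shortest span; returns None when no count works.
    """
    if elem_i == len(elements):
        return pos
    e = elements[elem_i]
    # consume the mandatory repetitions
    for k in range(e.min_rep):
        if pos + k >= len(seq) or not e.admits(seq[pos + k]):
            return None
    best: int | None = None
    for reps in range(e.min_rep, e.max_rep + 1):
        if reps > e.min_rep:
            idx = pos + reps - 1
            if idx >= len(seq) or not e.admits(seq[idx]):
                break
        end = _match_from(elements, seq, pos + reps, elem_i + 1)
        if end is not None and (best is None or end < best):
            best = end
    return best


def scan(pattern: PrositePattern, sequence: str, sequence_id: str = "") -> list[MotifMatch]:
    """All start positions of ``sequence`` admitting a match of ``pattern``.

    Overlapping matches at distinct starts are all reported; each start
    reports its shortest satisfying span.
    """
    seq = sequence.upper()
    matches: list[MotifMatch] = []
    for start in range(len(seq) - pattern.min_span() + 1):
        end = _match_from(pattern.elements, seq, start, 0)
        if end is not None:
            matches.append(
                MotifMatch(pattern.id, sequence_id, start + 1, seq[start:end])
            )
    return matches


def motif_report(
    patterns: list[PrositePattern], windows: list[WindowSample]
) -> list[dict]:
    """Count, per pattern, the positive and negative windows it matches.

    A window counts once per pattern regardless of how many matches it
    contains.
    """
    rows = []
    for pat in patterns:
        n_pos = n_neg = 0
        for win in windows:
            if scan(pat, win.peptide, win.protein_id):
                if win.label == "positive":
                    n_pos += 1
                else:
                    n_neg += 1
        rows.append(
            {
                "pattern_id": pat.id,
                "n_matching_positive_windows": n_pos,
                "n_matching_negative_windows": n_neg,
            }
        )
    return rows
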