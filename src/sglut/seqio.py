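"""Sequence and site-annotation I/O, window extraction, negative sampling.

The unit of prediction is a cysteine-centered peptide window of odd length
``w`` (default 15: seven flanking residues on each side).  Windows that would
run past either protein terminus are *discarded*, never padded, because every
downstream encoder assumes a full-length window.

Coordinates are 1-based in all files and reports, following the biology
convention for residue numbering.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from Bio import SeqIO

logger = logging.getLogger("sglut")

#: The 20 standard amino acids in fixed alphabetical one-letter order.
#: This ordering indexes every encoder's feature space.
ALPHABET = "ACDEFGHIKLMNPQRSTVWY"

STANDARD_AA = frozenset(ALPHABET)

POSITIVE = "positive"
NEGATIVE = "negative"


class SglutError(Exception):
    """Base class for data-validation and parse errors."""


class FastaParseError(SglutError):
    pass


class DegenerateComputationError(SglutError):
    """A computation that cannot proceed on this data (e.g. a single-class
    fold or dataset), as opposed to malformed input."""


class SiteValidationError(SglutError):
    pass


@dataclass(frozen=True)
class ProteinRecord:
    """A protein sequence with a unique identifier."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise SglutError(f"protein {self.id!r}: empty sequence")

    def nonstandard_residues(self) -> set[str]:
        return set(self.sequence) - STANDARD_AA


@dataclass(frozen=True)
class SiteAnnotation:
    """A labeled cysteine site: 1-based position within a named protein."""

    protein_id: str
    position: int
    label: str

    def __post_init__(self) -> None:
        if self.label not in (POSITIVE, NEGATIVE):
            raise SglutError(f"label must be positive/negative, got {self.label!r}")


@dataclass(frozen=True)
class WindowSample:
    """A fixed-width peptide centered on a cysteine, with a binary label."""

    protein_id: str
    center: int  # 1-based position of the cysteine in the source protein
    peptide: str
    label: str

    def __post_init__(self) -> None:
        w = len(self.peptide)
        if w % 2 == 0 or w < 3:
            raise SglutError(f"window length must be odd and >= 3, got {w}")
        mid = w // 2
        if self.peptide[mid] != "C":
            raise SglutError(
                f"window center must be 'C', got {self.peptide[mid]!r} in {self.peptide}"
            )

    @property
    def w(self) -> int:
        return len(self.peptide)

    def is_standard(self) -> bool:
        return set(self.peptide) <= STANDARD_AA


# ---------------------------------------------------------------------------
# FASTA and site-table I/O


def read_fasta(path) -> list[ProteinRecord]:
    """Read a FASTA file into :class:`ProteinRecord` objects.

    Sequences are upper-cased.  Residues outside the 20-letter alphabet are
    retained but reported through the ``sglut`` logger; duplicate record ids
    raise.  A file whose first non-blank line is not a header raises
    :class:`FastaParseError` naming the offending line.
    """
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.strip():
                if not line.startswith(">"):
                    raise FastaParseError(
                        f"{path}: line {lineno} is not a FASTA header: {line.strip()!r}"
                    )
                break

    records: list[ProteinRecord] = []
    seen: set[str] = set()
    for entry in SeqIO.parse(str(path), "fasta"):
        if entry.id in seen:
            raise FastaParseError(f"{path}: duplicate record id {entry.id!r}")
        seen.add(entry.id)
        rec = ProteinRecord(entry.id, str(entry.seq).upper())
        odd = rec.nonstandard_residues()
        if odd:
            logger.warning(
                "protein %s contains non-standard residues: %s",
                rec.id,
                ",".join(sorted(odd)),
            )
        records.append(rec)
    return records


def write_fasta(path, records: list[ProteinRecord], width: int = 60) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.sequence), width):
                fh.write(rec.sequence[i : i + width] + "\n")


def read_site_table(
    path, proteins: list[ProteinRecord], strict: bool = False
) -> list[SiteAnnotation]:
    """Read a TSV of columns ``protein_id  position  label``.

    Each row is validated against the proteins: the id must be known, the
    position in bounds, and the residue there a cysteine.  Invalid rows are
    rejected and logged with the protein, position and actual residue; with
    ``strict=True`` the first invalid row raises instead.
    """
    by_id = {p.id: p for p in proteins}
    annotations: list[SiteAnnotation] = []
    n_rejected = 0
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        expected = ["protein_id", "position", "label"]
        if [h.strip() for h in header[:3]] != expected:
            raise SiteValidationError(
                f"{path}: expected header {expected}, got {header[:3]}"
            )
        for lineno, line in enumerate(fh, start=2):
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                reason = f"line {lineno}: fewer than 3 columns"
            else:
                pid, pos_s, label = parts[0], parts[1], parts[2].strip().lower()
                reason = _validate_site(by_id, pid, pos_s, label)
            if reason is None:
                annotations.append(SiteAnnotation(pid, int(pos_s), label))
            else:
                n_rejected += 1
                msg = f"{path}: {reason}"
                if strict:
                    raise SiteValidationError(msg)
                logger.warning("rejected site row: %s", msg)
    if n_rejected:
        logger.warning("%s: %d site rows rejected", path, n_rejected)
    return annotations


def _validate_site(by_id, pid: str, pos_s: str, label: str) -> str | None:
    """Return a rejection reason, or None if the row is valid."""
    if label not in (POSITIVE, NEGATIVE):
        return f"protein {pid}: unknown label {label!r}"
    if pid not in by_id:
        return f"unknown protein id {pid!r}"
    try:
        pos = int(pos_s)
    except ValueError:
        return f"protein {pid}: non-integer position {pos_s!r}"
    seq = by_id[pid].sequence
    if not 1 <= pos <= len(seq):
        return f"protein {pid}: position {pos} outside sequence of length {len(seq)}"
    if seq[pos - 1] != "C":
        return f"protein {pid}: residue at position {pos} is {seq[pos - 1]!r}, not 'C'"
    return None


def write_site_table(path, annotations: list[SiteAnnotation]) -> None:
    with open(path, "w") as fh:
        fh.write("protein_id\tposition\tlabel\n")
        for a in annotations:
            fh.write(f"{a.protein_id}\t{a.position}\t{a.label}\n")


# ---------------------------------------------------------------------------
# Window extraction


def extract_window(
    record: ProteinRecord, position: int, w: int, label: str = POSITIVE
) -> WindowSample | None:
    """Extract the length-``w`` window centered on the cysteine at ``position``.

    Returns ``None`` (a discard signal, not an error) when the window would
    extend past either terminus: terminal sites are dropped rather than padded.
    A non-cysteine center, or an even or tiny ``w``, raises.
    """
    if w % 2 == 0 or w < 3:
        raise SglutError(f"window size must be odd and >= 3, got {w}")
    seq = record.sequence
    if not 1 <= position <= len(seq):
        raise SglutError(
            f"protein {record.id}: position {position} outside sequence bounds"
        )
    if seq[position - 1] != "C":
        raise SglutError(
            f"protein {record.id}: residue at {position} is {seq[position - 1]!r}, not 'C'"
        )
    half = (w - 1) // 2
    start = position - half  # 1-based
    end = position + half
    if start < 1 or end > len(seq):
        return None
    return WindowSample(record.id, position, seq[start - 1 : end], label)


def extract_labeled_windows(
    proteins: list[ProteinRecord],
    annotations: list[SiteAnnotation],
    w: int,
) -> tuple[list[WindowSample], int]:
    """Extract windows for every annotation; return (windows, n_discarded).

    Terminal sites are discarded with a logged notice.  Windows containing
    non-standard residues are kept here; composition/profile encoders filter
    them (see :func:`sglut.encoders.filter_standard`).
    """
    by_id = {p.id: p for p in proteins}
    windows: list[WindowSample] = []
    n_discarded = 0
    for ann in annotations:
        win = extract_window(by_id[ann.protein_id], ann.position, w, ann.label)
        if win is None:
            n_discarded += 1
            logger.info(
                "discarded terminal window: %s position %d (w=%d)",
                ann.protein_id,
                ann.position,
                w,
            )
        else:
            windows.append(win)
    return windows, n_discarded


# ---------------------------------------------------------------------------
# Negative sampling


def sample_negatives(
    record: ProteinRecord,
    positives: list[int],
    w: int,
    ratio: int = 3,
    seed: int = 0,
) -> list[SiteAnnotation]:
    """Sample unmodified cysteines of ``record`` as negatives.

    Candidates are all cysteines not listed in ``positives`` whose window of
    size ``w`` survives :func:`extract_window`.  At most ``ratio`` negatives
    per positive are drawn (the per-protein cap that keeps the class balance
    manageable), uniformly without replacement; fewer when candidates run out.
    Deterministic for a fixed ``seed``.
    """
    if ratio < 1:
        raise SglutError(f"negative ratio must be >= 1, got {ratio}")
    pos_set = set(positives)
    candidates = [
        i + 1
        for i, aa in enumerate(record.sequence)
        if aa == "C"
        and (i + 1) not in pos_set
        and extract_window(record, i + 1, w, NEGATIVE) is not None
    ]
    n_draw = min(ratio * len(pos_set), len(candidates))
    rng = np.random.default_rng(seed)
    chosen = sorted(rng.choice(len(candidates), size=n_draw, replace=False))
    return [SiteAnnotation(record.id, candidates[i], NEGATIVE) for i in chosen]
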