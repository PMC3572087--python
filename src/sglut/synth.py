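"""Synthetic proteins with planted cysteine-flank signal.

The generator emulates the *structure* of a curated modification-site
dataset: a few dozen proteins, each containing several cysteines, a minority
of which are labeled positive, with negatives drawn from the remaining
cysteines at a per-protein cap of three per positive.  The learnable signal
is position-specific residue enrichment in the flanks of positive sites —
with probability ``enrichment`` the stated residue is placed at the stated
offset from the central cysteine.  This is the simplest generative structure
that triplet and profile encoders can provably recover; it is a testing
stand-in, not a biological model.

Defaults mirror the study conditions: 39 proteins, 75 positive sites, a
negative cap of 3 per positive, and a strong three-offset signal at
enrichment 0.9.  Everything is deterministic for a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .seqio import (
    ALPHABET,
    NEGATIVE,
    POSITIVE,
    ProteinRecord,
    SiteAnnotation,
    SglutError,
    WindowSample,
    sample_negatives,
)

#: Default planted signal: (offset from center, residue, enrichment).
STRONG_SIGNAL = ((-3, "L", 0.9), (1, "P", 0.9), (2, "S", 0.9))

#: Margin from each terminus for planted sites; keeps windows up to 21 intact.
_SITE_MARGIN = 10


@dataclass
class SynthConfig:
    n_proteins: int = 39
    length_mean: float = 350.0
    length_sd: float = 80.0
    n_positive_sites: int = 75
    negative_ratio: int = 3
    w: int = 15
    signal: tuple[tuple[int, str, float], ...] = STRONG_SIGNAL
    background: np.ndarray = field(
        default_factory=lambda: np.full(20, 1 / 20)
    )
    seed: int = 0

    def __post_init__(self) -> None:
        self.background = np.asarray(self.background, dtype=float)
        if self.background.shape != (20,) or not np.isclose(self.background.sum(), 1):
            raise SglutError("background must be a 20-vector summing to 1")
        for off, aa, p in self.signal:
            if off == 0:
                raise SglutError("signal offset 0 is the center cysteine itself")
            if not -7 <= off <= 7:
                raise SglutError(f"signal offset {off} outside -7..7")
            if aa not in ALPHABET:
                raise SglutError(f"signal residue {aa!r} not a standard amino acid")
            if not 0 <= p <= 1:
                raise SglutError(f"enrichment {p} outside [0,1]")


def null_config(seed: int = 0, **kwargs) -> SynthConfig:
    """A configuration with no planted signal (labels carry no information)."""
    return SynthConfig(signal=(), seed=seed, **kwargs)


def generate_dataset(
    config: SynthConfig,
) -> tuple[list[ProteinRecord], list[SiteAnnotation]]:
    """Generate proteins and labeled cysteine sites under ``config``.

    Sequences are drawn residue-wise from the background distribution;
    positive cysteines are planted at interior positions with their flanks
    enriched per the signal; negatives are the remaining cysteines, sampled
    at most ``negative_ratio`` per positive in each protein.
    """
    rng = np.random.default_rng(config.seed)
    aa = np.array(list(ALPHABET))

    per_protein = _allocate_positives(config, rng)
    proteins: list[ProteinRecord] = []
    annotations: list[SiteAnnotation] = []
    for i, n_pos in enumerate(per_protein):
        length = max(
            int(round(rng.normal(config.length_mean, config.length_sd))),
            4 * _SITE_MARGIN,
        )
        seq = rng.choice(aa, size=length, p=config.background)
        centers = _plant_positives(seq, n_pos, config, rng)
        record = ProteinRecord(f"synth{i + 1:03d}", "".join(seq))
        proteins.append(record)
        for c in centers:
            annotations.append(SiteAnnotation(record.id, c, POSITIVE))
        annotations.extend(
            sample_negatives(
                record,
                centers,
                w=config.w,
                ratio=config.negative_ratio,
                seed=int(rng.integers(2**31)),
            )
        )
    return proteins, annotations


def _allocate_positives(config: SynthConfig, rng: np.random.Generator) -> np.ndarray:
    if config.n_proteins < 1 or config.n_positive_sites < 1:
        raise SglutError("need at least one protein and one positive site")
    base, rem = divmod(config.n_positive_sites, config.n_proteins)
    per = np.full(config.n_proteins, base)
    per[rng.choice(config.n_proteins, size=rem, replace=False)] += 1
    # capacity check: centers are spaced >= w apart inside the margins
    capacity = (config.length_mean - 2 * _SITE_MARGIN) // config.w
    if per.max() > max(capacity, 1):
        raise SglutError(
            f"config infeasible: up to {per.max()} positives per protein "
            f"but typical capacity is {capacity}"
        )
    return per


def _plant_positives(
    seq: np.ndarray, n_pos: int, config: SynthConfig, rng: np.random.Generator
) -> list[int]:
    """Plant ``n_pos`` positive cysteines in ``seq`` (0-based array, mutated).

    Centers keep a margin from both termini and at least ``w`` separation
    from each other, so a later planting never overwrites an earlier site's
    center or signal flanks.  Returns 1-based center positions.
    """
    length = len(seq)
    lo, hi = _SITE_MARGIN, length - _SITE_MARGIN - 1
    centers: list[int] = []
    attempts = 0
    while len(centers) < n_pos:
        attempts += 1
        if attempts > 1000 * n_pos:
            raise SglutError("config infeasible: cannot place positive sites")
        c = int(rng.integers(lo, hi + 1))
        if all(abs(c - other) >= config.w for other in centers):
            centers.append(c)
    for c in centers:
        seq[c] = "C"
        for off, residue, p in config.signal:
            if rng.random() < p:
                seq[c + off] = residue
    return sorted(c + 1 for c in centers)


def worked_example_windows() -> list[WindowSample]:
    """Five real positive 15-mer windows from well-studied glutathionylated
    proteins (creatine kinase, GAPDH, NF-kB p50 and p65, papain).

    Each has the modified cysteine at window position 8; the papain window
    NQGSCGSCWAFSAVV is centered on its *second* cysteine.  Useful as a small
    genuine fixture for the encoders and the motif scanner.
    """
    peptides = [
        ("creatine_kinase", "HLGYVLTCPSNLGTG"),
        ("gapdh", "KIVSNASCTTNCLAP"),
        ("nfkb_p50", "GMRFRYKCEGRSAGS"),
        ("nfkb_p65", "GFRFRYVCEGPSHGG"),
        ("papain", "NQGSCGSCWAFSAVV"),
    ]
    return [WindowSample(pid, 8, pep, POSITIVE) for pid, pep in peptides]
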