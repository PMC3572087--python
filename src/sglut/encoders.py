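"""Feature encodings for cysteine-centered peptide windows.

Eight schemes turn a window of odd length ``w`` into a fixed-length numeric
vector:

==================== ============ ====================================================
scheme               dimension    description
==================== ============ ====================================================
single_aa            20           amino-acid composition (frequencies)
reduced_comp         10           3-class + 7-class reduced-alphabet composition
pair_aa              400          contiguous dipeptide composition (frequencies)
triplet_aa           8000         contiguous tripeptide counts
reduced_triplet_aa   4200         tripeptide counts with a 3-mer and its reversal merged
binary_profile       20*w         one-hot residue identity per position
biprofile_bayes      2*w          per-position residue frequency in positive / negative
                                  training windows (Bi-profile Bayes)
physchem             10           window sums of ten physicochemical property scales
==================== ============ ====================================================

Feature indexing uses the fixed alphabetical residue order ``ACDEFGHIKLMNPQRSTVWY``
everywhere.  Composition encoders are normalized to frequencies; the two
triplet encoders keep raw counts, so each vector sums to the number of
triplets in the window (w - 2).
"""

from __future__ import annotations

import functools
import importlib.resources
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .seqio import ALPHABET, STANDARD_AA, POSITIVE, NEGATIVE, SglutError, WindowSample

AA_INDEX = {aa: i for i, aa in enumerate(ALPHABET)}

# Reduced alphabets: physicochemical groupings of the 20 residues.
THREE_CLASSES = {
    "polar": "RKEDQN",
    "neutral": "GASTPHY",
    "hydrophobic": "CVLIMFW",
}
SEVEN_CLASSES = {
    "aliphatic": "AILVGP",
    "acid": "DE",
    "base": "HKR",
    "aromatic": "FWY",
    "amide": "NQ",
    "small_hydroxyl": "ST",
    "sulfur": "CM",
}

SCHEMES = (
    "single_aa",
    "reduced_comp",
    "pair_aa",
    "triplet_aa",
    "reduced_triplet_aa",
    "binary_profile",
    "biprofile_bayes",
    "physchem",
)


def scheme_dimension(name: str, w: int) -> int:
    """Dimensionality of a scheme at window size ``w``."""
    fixed = {
        "single_aa": 20,
        "reduced_comp": 10,
        "pair_aa": 400,
        "triplet_aa": 8000,
        "reduced_triplet_aa": len(reduced_triplet_classes()),
        "physchem": 10,
    }
    if name in fixed:
        return fixed[name]
    if name == "binary_profile":
        return 20 * w
    if name == "biprofile_bayes":
        return 2 * w
    raise SglutError(f"unknown encoding scheme {name!r}")


@dataclass(frozen=True)
class EncodingScheme:
    name: str
    dimensionality: int


@dataclass
class FeatureMatrix:
    """Samples x features table with scheme metadata and per-sample labels."""

    scheme: EncodingScheme
    feature_names: list[str]
    values: np.ndarray  # (n_samples, dimensionality)
    labels: list[str]
    protein_ids: list[str] = field(default_factory=list)
    positions: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[1] != self.scheme.dimensionality:
            raise SglutError(
                f"{self.scheme.name}: value matrix has {self.values.shape[1:]} columns, "
                f"expected {self.scheme.dimensionality}"
            )
        if len(set(self.feature_names)) != len(self.feature_names):
            raise SglutError("feature names must be unique")

    @property
    def y(self) -> np.ndarray:
        """Binary label vector: 1 for positive, 0 for negative."""
        return np.array([1 if l == POSITIVE else 0 for l in self.labels])

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=self.feature_names)
        df.insert(0, "label", self.labels)
        if self.positions:
            df.insert(0, "position", self.positions)
        if self.protein_ids:
            df.insert(0, "protein_id", self.protein_ids)
        return df

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def _check_standard(peptide: str) -> None:
    odd = set(peptide) - STANDARD_AA
    if odd:
        raise SglutError(
            f"peptide contains non-standard residues {sorted(odd)}; "
            "filter windows before encoding"
        )


def filter_standard(windows: list[WindowSample]) -> list[WindowSample]:
    """Drop windows containing residues outside the 20-letter alphabet."""
    return [win for win in windows if win.is_standard()]


# ---------------------------------------------------------------------------
# Composition encoders


def encode_single(peptide: str) -> np.ndarray:
    """Amino-acid composition: per-residue occurrence frequency (sums to 1)."""
    _check_standard(peptide)
    v = np.zeros(20)
    for aa in peptide:
        v[AA_INDEX[aa]] += 1
    return v / len(peptide)


def encode_reduced_comp(peptide: str) -> np.ndarray:
    """Reduced-alphabet composition: 3-class block then 7-class block.

    Each block is a frequency vector over its classes and sums to 1.
    """
    _check_standard(peptide)
    v = np.zeros(10)
    for aa in peptide:
        for j, members in enumerate(THREE_CLASSES.values()):
            if aa in members:
                v[j] += 1
        for j, members in enumerate(SEVEN_CLASSES.values()):
            if aa in members:
                v[3 + j] += 1
    return v / len(peptide)


def encode_pair(peptide: str) -> np.ndarray:
    """Contiguous dipeptide composition, normalized by w-1 (sums to 1)."""
    _check_standard(peptide)
    v = np.zeros(400)
    for i in range(len(peptide) - 1):
        v[AA_INDEX[peptide[i]] * 20 + AA_INDEX[peptide[i + 1]]] += 1
    return v / (len(peptide) - 1)


def encode_triplet(peptide: str) -> np.ndarray:
    """Contiguous tripeptide counts (raw; the vector sums to w-2)."""
    _check_standard(peptide)
    v = np.zeros(8000)
    for i in range(len(peptide) - 2):
        idx = (
            AA_INDEX[peptide[i]] * 400
            + AA_INDEX[peptide[i + 1]] * 20
            + AA_INDEX[peptide[i + 2]]
        )
        v[idx] += 1
    return v


def canonical_triplet(t: str) -> str:
    """Canonical form of a 3-mer under reversal: min(t, reversed t)."""
    r = t[::-1]
    return t if t <= r else r


@functools.lru_cache(maxsize=1)
def reduced_triplet_classes() -> tuple[str, ...]:
    """All reversal-merged triplet classes, enumerated from the 20^3 triplets.

    A 3-mer and its reversal name the same class ('ABD' == 'DBA'); palindromic
    triplets (first residue == last) are their own class.  The class count is
    derived by enumeration, not assumed.
    """
    classes = {
        canonical_triplet(a + b + c)
        for a in ALPHABET
        for b in ALPHABET
        for c in ALPHABET
    }
    return tuple(sorted(classes))


@functools.lru_cache(maxsize=1)
def _reduced_triplet_index() -> dict[str, int]:
    return {t: i for i, t in enumerate(reduced_triplet_classes())}


def encode_reduced_triplet(peptide: str) -> np.ndarray:
    """Reversal-merged tripeptide counts (raw; sums to w-2).

    Invariant under reversing the peptide, since every triplet maps to the
    same class as its reversal.
    """
    _check_standard(peptide)
    index = _reduced_triplet_index()
    v = np.zeros(len(index))
    for i in range(len(peptide) - 2):
        v[index[canonical_triplet(peptide[i : i + 3])]] += 1
    return v


# ---------------------------------------------------------------------------
# Profile encoders


def encode_binary(peptide: str) -> np.ndarray:
    """One-hot residue identity per position: w blocks of 20 (sums to w)."""
    _check_standard(peptide)
    w = len(peptide)
    v = np.zeros(20 * w)
    for i, aa in enumerate(peptide):
        v[20 * i + AA_INDEX[aa]] = 1.0
    return v


@dataclass
class BiProfileMatrix:
    """Per-position residue frequencies from positive and negative windows.

    ``pos_freq`` and ``neg_freq`` are (w, 20) arrays; with ``pseudocount`` c,
    entry [i, a] = (count of residue a at position i + c) / (n_class + 20 c),
    so every position's 20 frequencies sum to 1.
    """

    w: int
    pos_freq: np.ndarray
    neg_freq: np.ndarray
    pseudocount: float = 0.0


def fit_biprofile(train: list[WindowSample], pseudocount: float = 0.0) -> BiProfileMatrix:
    """Estimate the Bi-profile Bayes posterior matrix from training windows."""
    if pseudocount < 0:
        raise SglutError("pseudocount must be non-negative")
    pos = [t for t in train if t.label == POSITIVE]
    neg = [t for t in train if t.label == NEGATIVE]
    if not pos or not neg:
        raise SglutError("bi-profile fitting needs >= 1 window of each class")
    w = pos[0].w
    if any(t.w != w for t in train):
        raise SglutError("all training windows must share one length")

    def tally(windows: list[WindowSample]) -> np.ndarray:
        counts = np.full((w, 20), pseudocount, dtype=float)
        for win in windows:
            for i, aa in enumerate(win.peptide):
                counts[i, AA_INDEX[aa]] += 1
        return counts / (len(windows) + 20 * pseudocount)

    return BiProfileMatrix(w, tally(pos), tally(neg), pseudocount)


def encode_biprofile(peptide: str, profile: BiProfileMatrix) -> np.ndarray:
    """Bi-profile Bayes vector: positive-class then negative-class frequencies
    of the observed residue at each of the w positions (2w entries)."""
    _check_standard(peptide)
    if len(peptide) != profile.w:
        raise SglutError(
            f"peptide length {len(peptide)} != profile window {profile.w}"
        )
    idx = np.array([AA_INDEX[aa] for aa in peptide])
    rows = np.arange(profile.w)
    return np.concatenate([profile.pos_freq[rows, idx], profile.neg_freq[rows, idx]])


# ---------------------------------------------------------------------------
# Physicochemical encoder

PROPERTY_NAMES = (
    "n_atoms",
    "charge",
    "h_bonds",
    "hydrophobicity",
    "hydrophilicity",
    "propensity",
    "isoelectric_point",
    "mass",
    "contacts_14A",
    "eiip",
)


@functools.lru_cache(maxsize=1)
def load_property_table() -> pd.DataFrame:
    """Load the packaged 20 x 10 physicochemical property table.

    Rows are amino acids, columns the ten scales: atom count, net charge,
    side-chain hydrogen-bond capacity, hydrophobicity (Kyte-Doolittle),
    hydrophilicity (Hopp-Woods), helix propensity, isoelectric point, residue
    mass, expected contacts within a 14 angstrom sphere, and electron-ion
    interaction potential.  The TSV file, assembled from the standard
    published scales, is the editable source of truth.
    """
    ref = importlib.resources.files("sglut.data") / "physchem_properties.tsv"
    with importlib.resources.as_file(ref) as path:
        df = pd.read_csv(path, sep="\t", index_col="aa")
    if list(df.columns) != list(PROPERTY_NAMES) or sorted(df.index) != sorted(ALPHABET):
        raise SglutError("packaged property table is malformed")
    if df.isna().any().any():
        raise SglutError("packaged property table has missing values")
    return df


def encode_physchem(peptide: str, table: pd.DataFrame | None = None) -> np.ndarray:
    """Sum each of the ten property scales over the window residues."""
    _check_standard(peptide)
    if table is None:
        table = load_property_table()
    missing = set(peptide) - set(table.index)
    if missing:
        raise SglutError(f"property table lacks rows for {sorted(missing)}")
    return table.loc[list(peptide)].to_numpy(dtype=float).sum(axis=0)


# ---------------------------------------------------------------------------
# Batch encoding


def feature_names(scheme: str, w: int) -> list[str]:
    if scheme == "single_aa":
        return list(ALPHABET)
    if scheme == "reduced_comp":
        return [f"c3_{k}" for k in THREE_CLASSES] + [f"c7_{k}" for k in SEVEN_CLASSES]
    if scheme == "pair_aa":
        return [a + b for a in ALPHABET for b in ALPHABET]
    if scheme == "triplet_aa":
        return [a + b + c for a in ALPHABET for b in ALPHABET for c in ALPHABET]
    if scheme == "reduced_triplet_aa":
        return list(reduced_triplet_classes())
    if scheme == "binary_profile":
        return [f"p{i + 1}_{aa}" for i in range(w) for aa in ALPHABET]
    if scheme == "biprofile_bayes":
        return [f"pos_p{i + 1}" for i in range(w)] + [f"neg_p{i + 1}" for i in range(w)]
    if scheme == "physchem":
        return list(PROPERTY_NAMES)
    raise SglutError(f"unknown encoding scheme {scheme!r}")


def encode_windows(
    windows: list[WindowSample],
    scheme: str,
    profile: BiProfileMatrix | None = None,
    table: pd.DataFrame | None = None,
) -> FeatureMatrix:
    """Encode a list of same-length windows under one scheme.

    ``biprofile_bayes`` requires a fitted :class:`BiProfileMatrix` (fit on
    training windows only — never on the windows being scored, unless they
    are the training set itself).
    """
    if not windows:
        raise SglutError("no windows to encode")
    w = windows[0].w
    if any(win.w != w for win in windows):
        raise SglutError("windows must share one length")
    if scheme == "biprofile_bayes" and profile is None:
        raise SglutError("biprofile_bayes encoding requires a fitted profile")

    encoders = {
        "single_aa": encode_single,
        "reduced_comp": encode_reduced_comp,
        "pair_aa": encode_pair,
        "triplet_aa": encode_triplet,
        "reduced_triplet_aa": encode_reduced_triplet,
        "binary_profile": encode_binary,
        "biprofile_bayes": lambda p: encode_biprofile(p, profile),
        "physchem": lambda p: encode_physchem(p, table),
    }
    if scheme not in encoders:
        raise SglutError(f"unknown encoding scheme {scheme!r}")
    fn = encoders[scheme]
    values = np.vstack([fn(win.peptide) for win in windows])
    return FeatureMatrix(
        scheme=EncodingScheme(scheme, scheme_dimension(scheme, w)),
        feature_names=feature_names(scheme, w),
        values=values,
        labels=[win.label for win in windows],
        protein_ids=[win.protein_id for win in windows],
        positions=[win.center for win in windows],
    )
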