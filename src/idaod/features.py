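"""Mixed g-gap dipeptide composition features.

A g-gap dipeptide is an ordered residue pair (R_p, R_{p+g+1}) separated by
exactly g intervening residues; g = 0 gives ordinary adjacent dipeptides.
For a sequence of length L there are L - g - 1 such pairs, and the g-gap
profile is the 400-vector of their frequencies

    f_i^g = n_i^g / (L - g - 1),  i = 1..400,

over the 20x20 ordered pairs of standard amino acids. The model input is
the mixed vector P: the 0-gap profile concatenated with the 1-gap profile,
800 dimensions in total.

Dipeptide indexing is frozen as row-major alphabetical:
index(a, b) = 20 * rank(a) + rank(b) with A < C < D < ... < Y, so AA -> 0,
AC -> 1, CA -> 20, YY -> 399.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .alphabet import AA_RANK, AMINO_ACIDS, N_AMINO_ACIDS
from .errors import ShortSequenceError, ValidationError
from .sequence_io import ProteinRecord

__all__ = [
    "N_DIPEPTIDES",
    "MIXED_DIM",
    "DIPEPTIDES",
    "GGapProfile",
    "MixedFeatureVector",
    "dipeptide_index",
    "count_ggap_dipeptides",
    "ggap_frequencies",
    "mixed_feature_vector",
    "featurize_dataset",
    "feature_names",
    "fit_feature_scale",
    "apply_feature_scale",
]

N_DIPEPTIDES = N_AMINO_ACIDS * N_AMINO_ACIDS  # 400
MIXED_DIM = 2 * N_DIPEPTIDES  # 800

#: All 400 ordered dipeptides in index order ("AA", "AC", ..., "YY").
DIPEPTIDES: list[str] = [a + b for a in AMINO_ACIDS for b in AMINO_ACIDS]

# Sparse 128-wide lookup from ASCII code to residue rank; -1 marks letters
# outside the alphabet.
_CODE_TO_RANK = np.full(128, -1, dtype=np.int64)
for _aa, _r in AA_RANK.items():
    _CODE_TO_RANK[ord(_aa)] = _r


def dipeptide_index(first: str, second: str) -> int:
    """Index of the ordered dipeptide (first, second) in [0, 399]."""
    try:
        return N_AMINO_ACIDS * AA_RANK[first] + AA_RANK[second]
    except KeyError as exc:
        raise ValidationError(f"invalid amino-acid letter {exc.args[0]!r}") from None


@dataclass(frozen=True)
class GGapProfile:
    """Counts and frequencies of the 400 g-gap dipeptides of one sequence."""

    g: int
    counts: np.ndarray  # (400,) int64
    frequencies: np.ndarray  # (400,) float64
    source_id: str = ""


@dataclass(frozen=True)
class MixedFeatureVector:
    """The 800-dim input vector P: 0-gap frequencies then 1-gap frequencies."""

    values: np.ndarray  # (800,) float64
    source_id: str = ""


def _ranks(record: ProteinRecord) -> np.ndarray:
    codes = np.frombuffer(record.residues.encode("ascii"), dtype=np.uint8)
    return _CODE_TO_RANK[codes]


def _require_length(record: ProteinRecord, g: int) -> None:
    if g < 0:
        raise ValidationError(f"gap must be non-negative, got {g}")
    if record.length <= g + 1:
        raise ShortSequenceError(
            f"record {record.id!r} has length {record.length}; "
            f"g={g} requires at least {g + 2} residues"
        )


def count_ggap_dipeptides(record: ProteinRecord, g: int) -> np.ndarray:
    """Count all g-gap dipeptides of ``record``.

    Returns the 400-vector n^g with sum L - g - 1.
    """
    _require_length(record, g)
    r = _ranks(record)
    idx = N_AMINO_ACIDS * r[: record.length - g - 1] + r[g + 1:]
    return np.bincount(idx, minlength=N_DIPEPTIDES).astype(np.int64)


def ggap_frequencies(record: ProteinRecord, g: int) -> GGapProfile:
    """The normalized g-gap profile f^g = n^g / (L - g - 1)."""
    counts = count_ggap_dipeptides(record, g)
    denom = record.length - g - 1
    return GGapProfile(
        g=g,
        counts=counts,
        frequencies=counts / float(denom),
        source_id=record.id,
    )


def mixed_feature_vector(record: ProteinRecord) -> MixedFeatureVector:
    """Concatenate the 0-gap and 1-gap profiles into the 800-dim vector P."""
    if record.length < 3:
        raise ShortSequenceError(
            f"record {record.id!r} has length {record.length}; "
            "mixed 0-gap + 1-gap features require at least 3 residues"
        )
    f0 = ggap_frequencies(record, 0).frequencies
    f1 = ggap_frequencies(record, 1).frequencies
    return MixedFeatureVector(
        values=np.concatenate([f0, f1]), source_id=record.id
    )


def featurize_dataset(
    records: list[ProteinRecord],
    gaps: tuple[int, ...] = (0, 1),
) -> tuple[np.ndarray, list[str]]:
    """Stack per-gap frequency profiles into an (n, 400*len(gaps)) matrix.

    The default ``gaps=(0, 1)`` yields the mixed 800-dim model input; row
    order preserves input order. Raises an aggregate
    :class:`ShortSequenceError` naming every record too short for the
    largest requested gap.
    """
    if not gaps:
        raise ValidationError("at least one gap value is required")
    min_len = max(gaps) + 2
    short = [r.id for r in records if r.length < min_len]
    if short:
        raise ShortSequenceError(
            f"{len(short)} record(s) shorter than the {min_len} residues "
            f"required for gaps {gaps}: {short}"
        )
    matrix = np.empty((len(records), N_DIPEPTIDES * len(gaps)), dtype=np.float64)
    ids = []
    for k, rec in enumerate(records):
        matrix[k] = np.concatenate(
            [ggap_frequencies(rec, g).frequencies for g in gaps]
        )
        ids.append(rec.id)
    return matrix, ids


def feature_names(gaps: tuple[int, ...] = (0, 1)) -> list[str]:
    """Stable column headers, e.g. ``g0_AA ... g1_YY``."""
    return [f"g{g}_{dp}" for g in gaps for dp in DIPEPTIDES]


def fit_feature_scale(X: np.ndarray) -> np.ndarray:
    """Per-column scale (the column max) mapping training features to [0, 1].

    Raw dipeptide frequencies average 1/400, which starves a
    Glorot-initialized network of gradient; dividing each column by its
    training max restores O(1) inputs while keeping them in [0, 1] for the
    sigmoid reconstruction layer. Columns that are all-zero in training get
    scale 1 (identity).
    """
    scale = np.asarray(X, dtype=np.float64).max(axis=0)
    scale[scale == 0] = 1.0
    return scale


def apply_feature_scale(X: np.ndarray, scale: np.ndarray) -> np.ndarray:
    """Divide columns by the training scale (values may exceed 1 on new data)."""
    return np.asarray(X, dtype=np.float64) / scale
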