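"""Reading, validating and writing protein FASTA under the 20-letter rule.

Sequences containing any letter outside the 20 standard amino acids
(ambiguity codes B/X/Z, rare residues U/O, wildcard J, stops ``*``, gaps)
are rejected: the dipeptide feature space is a fixed 20x20 grid and
ambiguous letters have no well-defined cell in it. Lowercase letters are
treated as softmasking and uppercased before validation.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .alphabet import AA_SET
from .errors import EmptyInputError, FastaParseError, SequenceValidationError

logger = logging.getLogger(__name__)

__all__ = [
    "ProteinRecord",
    "read_fasta",
    "write_fasta",
    "read_labels",
    "write_labels",
]


@dataclass(frozen=True)
class ProteinRecord:
    """A validated protein sequence R_1 R_2 ... R_L.

    Attributes
    ----------
    id : str
        FASTA header token up to the first whitespace; non-empty.
    description : str
        Remainder of the header line (may be empty).
    residues : str
        Uppercase sequence over the 20 standard amino-acid letters.
    """

    id: str
    residues: str
    description: str = field(default="")

    def __post_init__(self) -> None:
        if not self.id:
            raise SequenceValidationError("record id must be non-empty")
        if len(self.residues) < 1:
            raise SequenceValidationError(f"record {self.id!r}: empty sequence")
        bad = set(self.residues) - AA_SET
        if bad:
            raise SequenceValidationError(
                f"record {self.id!r}: non-standard letters {sorted(bad)}"
            )

    @property
    def length(self) -> int:
        """Number of residues L."""
        return len(self.residues)


def _check_leading_garbage(path: Path) -> None:
    # Biopython silently skips text before the first '>'; the contract here is
    # stricter: sequence data before any header is a parse error.
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped:
                continue
            if stripped.startswith(">"):
                return
            raise FastaParseError(
                "sequence data found before any '>' header", line_number=lineno
            )


def read_fasta(
    path: str | Path, strict: bool = False
) -> tuple[list[ProteinRecord], list[str]]:
    """Read a protein FASTA file, validating against the 20-letter alphabet.

    Parameters
    ----------
    path : path-like
        FASTA file, possibly multi-record, arbitrary line wrapping.
    strict : bool
        If True, any record with a non-standard letter aborts the run;
        if False (default) such records are dropped and reported.

    Returns
    -------
    (records, rejected_ids)
        Accepted :class:`ProteinRecord` objects in file order, and the ids
        of records rejected for non-standard letters.

    Raises
    ------
    FileNotFoundError
        Missing input file.
    FastaParseError
        Sequence data before any header.
    SequenceValidationError
        In strict mode, on the first invalid record.
    EmptyInputError
        File contains no records, or none survive validation.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"FASTA file not found: {path}")
    _check_leading_garbage(path)

    records: list[ProteinRecord] = []
    rejected: list[str] = []
    seen: Counter[str] = Counter()
    for raw in SeqIO.parse(str(path), "fasta"):
        residues = str(raw.seq).upper()
        rec_id = raw.id
        seen[rec_id] += 1
        bad = set(residues) - AA_SET
        if bad or not residues:
            if strict:
                raise SequenceValidationError(
                    f"record {rec_id!r}: non-standard letters {sorted(bad)} "
                    "(strict mode)"
                )
            rejected.append(rec_id)
            continue
        description = raw.description[len(raw.id):].strip()
        records.append(ProteinRecord(id=rec_id, residues=residues,
                                     description=description))

    for rec_id, n in seen.items():
        if n > 1:
            logger.warning("duplicate record id %r occurs %d times", rec_id, n)

    if not seen:
        raise EmptyInputError(f"no FASTA records found in {path}")
    if not records:
        raise EmptyInputError(
            f"no records survived validation in {path} "
            f"({len(rejected)} rejected)"
        )
    return records, rejected


def write_fasta(records: list[ProteinRecord], path: str | Path) -> None:
    """Write records as FASTA with 60-column wrapping.

    The output round-trips through :func:`read_fasta` to identical ids and
    residues.
    """
    seq_records = [
        SeqRecord(Seq(r.residues), id=r.id, description=r.description)
        for r in records
    ]
    with open(path, "w") as fh:
        SeqIO.write(seq_records, fh, "fasta")


def read_labels(path: str | Path) -> dict[str, int]:
    """Read a two-column tab-separated label file: ``id<TAB>{0,1}``.

    1 marks the positive (antioxidant) class.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"label file not found: {path}")
    labels: dict[str, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2 or parts[1] not in {"0", "1"}:
                raise FastaParseError(
                    f"malformed label line {line!r}; expected 'id<TAB>0|1'",
                    line_number=lineno,
                )
            labels[parts[0]] = int(parts[1])
    if not labels:
        raise EmptyInputError(f"no labels found in {path}")
    return labels


def write_labels(labels: dict[str, int], path: str | Path) -> None:
    with open(path, "w") as fh:
        for rec_id, lab in labels.items():
            fh.write(f"{rec_id}\t{int(lab)}\n")
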