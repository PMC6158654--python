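"""The 20-letter standard amino-acid alphabet shared by all modules.

Anything outside this alphabet (B, X, Z, U, O, J, ``*``, gap characters, ...)
is ambiguous for a fixed 20x20 dipeptide feature space and is rejected at
input validation time.
"""

AMINO_ACIDS: str = "ACDEFGHIKLMNPQRSTVWY"
"""One-letter codes in alphabetical order; this ordering is frozen because it
defines the dipeptide feature indexing (see :mod:`idaod.features`)."""

AA_SET = frozenset(AMINO_ACIDS)

AA_RANK = {aa: i for i, aa in enumerate(AMINO_ACIDS)}

N_AMINO_ACIDS = len(AMINO_ACIDS)
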