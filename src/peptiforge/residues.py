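"""Amino-acid alphabet and sequence validation.

The package works exclusively over the 20 standard one-letter residue
codes; ambiguity codes (B, J, Z, X) and the rare residues O/U are
rejected everywhere, so every downstream module can assume a clean
alphabet.
"""

from __future__ import annotations

#: The 20 standard residues, alphabetical by one-letter code.
AMINO_ACIDS: str = "ACDEFGHIKLMNPQRSTVWY"

AMINO_ACID_SET = frozenset(AMINO_ACIDS)

#: Residues treated as hydrophobic by the synthetic-data generators.
HYDROPHOBIC_RESIDUES = frozenset("AVLIPFMWG")

#: Basic residues (used e.g. by the bromelain cleavage rule).
BASIC_RESIDUES = frozenset("HKR")


class InvalidResidueError(ValueError):
    """A sequence contains a character outside the 20-letter alphabet."""


def validate_sequence(sequence: str, name: str = "sequence") -> str:
    """Validate an amino-acid string and return it unchanged.

    Raises
    ------
    InvalidResidueError
        If the sequence is empty or contains any character that is not
        one of the 20 standard uppercase one-letter codes.  The message
        names the first offending character.
    """
    if not isinstance(sequence, str):
        raise InvalidResidueError(f"{name} must be a string, got {type(sequence).__name__}")
    if not sequence:
        raise InvalidResidueError(f"{name} is empty")
    for ch in sequence:
        if ch not in AMINO_ACID_SET:
            raise InvalidResidueError(
                f"{name} contains invalid residue {ch!r}; allowed: {AMINO_ACIDS}"
            )
    return sequence


def validate_residue_set(residues, name: str = "residue set") -> frozenset:
    """Coerce an iterable of residue letters to a validated frozenset."""
    s = frozenset(residues)
    bad = s - AMINO_ACID_SET
    if bad:
        raise InvalidResidueError(f"{name} contains invalid residues {sorted(bad)!r}")
    return s
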