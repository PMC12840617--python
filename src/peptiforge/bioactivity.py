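"""Bioactive-fragment frequency statistic.

The potential of a precursor protein to release bioactive peptides is
summarised by the occurrence frequency A = a / N, where ``a`` is the
number of occurrences of known bioactive fragments (motifs) as
substrings of the protein and ``N`` is the protein length in residues.
A higher A marks a richer precursor.  A says nothing about the potency
of the released peptides — it is a density of known-active subsequences.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from fractions import Fraction

import pandas as pd

from .residues import AMINO_ACID_SET, InvalidResidueError, validate_sequence

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class MotifDatabase:
    """A deduplicated set of known bioactive peptide motifs.

    Motifs are amino-acid strings of length >= 2; ``ic50_uM`` optionally
    records a potency per motif.
    """

    motifs: frozenset
    activity_label: str = "DPP-IV inhibitor"
    ic50_uM: dict | None = None

    def __post_init__(self):
        object.__setattr__(self, "motifs", frozenset(self.motifs))
        for m in self.motifs:
            validate_sequence(m, "motif")
            if len(m) < 2:
                raise ValueError(f"motif {m!r} shorter than 2 residues")

    def __contains__(self, sequence: str) -> bool:
        return sequence in self.motifs

    def __len__(self) -> int:
        return len(self.motifs)

    def __iter__(self):
        return iter(self.motifs)


def count_occurrences(text: str, pattern: str) -> int:
    """Overlapping occurrence count of ``pattern`` in ``text``."""
    count = start = 0
    while True:
        idx = text.find(pattern, start)
        if idx < 0:
            return count
        count += 1
        start = idx + 1


def a_value(protein, motifs: MotifDatabase, count: str = "occurrences") -> float:
    """Frequency of bioactive fragment occurrence, A = a / N.

    Parameters
    ----------
    protein
        A ``ProteinRecord`` (or anything with a ``sequence`` attribute).
    motifs
        Database of known bioactive fragments.
    count
        ``"occurrences"`` (default): ``a`` sums every, possibly
        overlapping, occurrence of every motif.  ``"distinct_motifs"``:
        each motif present at least once contributes 1.
    """
    seq = protein.sequence if hasattr(protein, "sequence") else validate_sequence(protein)
    if count == "occurrences":
        a = sum(count_occurrences(seq, m) for m in motifs)
    elif count == "distinct_motifs":
        a = sum(1 for m in motifs if m in seq)
    else:
        raise ValueError(f"count must be 'occurrences' or 'distinct_motifs', got {count!r}")
    return a / len(seq)


def load_motif_db(path, activity_label: str = "DPP-IV inhibitor", errors: str = "raise") -> MotifDatabase:
    """Load a motif database from a delimited table.

    Expected columns: ``sequence``, ``activity`` and optionally
    ``ic50_uM``.  Duplicate motifs are logged and collapsed.  Malformed
    rows (invalid residues, too short) raise a ``ValueError`` naming the
    offending line numbers, or are skipped with a logged error when
    ``errors="skip"``.
    """
    sep = "\t" if str(path).endswith((".tsv", ".tab")) else ","
    df = pd.read_csv(path, sep=sep)
    missing = {"sequence", "activity"} - set(df.columns)
    if missing:
        raise ValueError(f"motif table {path} missing columns: {sorted(missing)}")

    motifs: dict[str, float | None] = {}
    bad_lines: list[str] = []
    for idx, row in df.iterrows():
        line_no = idx + 2  # header is line 1
        seq = str(row["sequence"]).strip().upper()
        if len(seq) < 2 or not set(seq) <= AMINO_ACID_SET:
            bad_lines.append(f"line {line_no}: invalid motif {seq!r}")
            continue
        if seq in motifs:
            log.warning("duplicate motif %r at line %d collapsed", seq, line_no)
            continue
        ic50 = float(row["ic50_uM"]) if "ic50_uM" in df.columns and pd.notna(row.get("ic50_uM")) else None
        motifs[seq] = ic50
    if bad_lines:
        msg = f"motif table {path}: {len(bad_lines)} malformed row(s): " + "; ".join(bad_lines)
        if errors == "raise":
            raise ValueError(msg)
        log.error(msg)
    ic50_map = {m: v for m, v in motifs.items() if v is not None}
    return MotifDatabase(frozenset(motifs), activity_label, ic50_map or None)
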