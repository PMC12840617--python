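"""Multi-criteria peptidomics screening.

Candidate peptides from a peptidomics experiment are filtered on four
criteria, applied in this order:

1. relative abundance strictly greater than a threshold (default 1e7);
2. chain length strictly less than a threshold (default 10 residues);
3. external bioactivity score strictly greater than a threshold
   (default 0.9);
4. the substrate-motif rule: Pro or Ala at the second position from the
   N-terminus, the preference of DPP-IV's dipeptidase activity.

Strict inequalities are deliberate; a row at exactly the abundance
threshold is rejected.  Rejected rows are attributed to the first
criterion they fail, so survivor count plus per-criterion rejections
always equals the input size.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .residues import validate_residue_set, validate_sequence


@dataclass(frozen=True)
class ScreeningCriteria:
    """Filter thresholds; see module docstring for semantics."""

    min_abundance: float = 1e7
    max_length: int = 10
    min_score: float = 0.9
    position2_residues: frozenset = frozenset("PA")

    def __post_init__(self):
        if self.min_abundance <= 0 or self.max_length <= 0 or self.min_score <= 0:
            raise ValueError("screening thresholds must be positive")
        object.__setattr__(
            self,
            "position2_residues",
            validate_residue_set(self.position2_residues, "position2_residues"),
        )
        if not self.position2_residues:
            raise ValueError("position2_residues must be non-empty")


@dataclass(frozen=True)
class CandidateRow:
    """One peptidomics candidate: sequence, abundance and external score."""

    sequence: str
    abundance: float
    score: float
    probability: float | None = None
    source: str = ""

    def __post_init__(self):
        validate_sequence(self.sequence, "candidate")
        if self.abundance < 0:
            raise ValueError("abundance must be >= 0")
        if not 0 <= self.score <= 1:
            raise ValueError("score must be in [0, 1]")


def position2_rule(sequence: str, allowed=frozenset("PA")) -> bool:
    """True iff the residue at position 2 from the N-terminus is allowed.

    Dipeptides participate through their C-terminal residue (position 2);
    single residues always fail.
    """
    seq = validate_sequence(sequence, "sequence")
    allowed = validate_residue_set(allowed, "allowed")
    if len(seq) < 2:
        return False
    return seq[1] in allowed


_CRITERIA_ORDER = ("abundance", "length", "score", "position2")


def _to_frame(rows) -> tuple[pd.DataFrame, bool]:
    if isinstance(rows, pd.DataFrame):
        return rows, True
    df = pd.DataFrame(
        {
            "sequence": [r.sequence for r in rows],
            "abundance": [r.abundance for r in rows],
            "score": [r.score for r in rows],
        }
    )
    return df, False


def apply_filters(rows, criteria: ScreeningCriteria = ScreeningCriteria()):
    """Filter candidates; return (survivors, per-criterion rejection counts).

    ``rows`` is a DataFrame with columns ``sequence``, ``abundance``,
    ``score`` (extra columns pass through) or a list of
    :class:`CandidateRow`; survivors come back in the same form, input
    order preserved.
    """
    df, was_frame = _to_frame(rows)
    missing = {"sequence", "abundance", "score"} - set(df.columns)
    if missing:
        raise ValueError(f"candidate table missing columns: {sorted(missing)}")

    seqs = df["sequence"].astype(str)
    passes = {
        "abundance": df["abundance"].to_numpy() > criteria.min_abundance,
        "length": seqs.str.len().to_numpy() < criteria.max_length,
        "score": df["score"].to_numpy() > criteria.min_score,
        "position2": seqs.map(lambda s: position2_rule(s, criteria.position2_residues)).to_numpy(),
    }

    rejections = dict.fromkeys(_CRITERIA_ORDER, 0)
    keep = []
    for i in range(len(df)):
        for crit in _CRITERIA_ORDER:
            if not passes[crit][i]:
                rejections[crit] += 1
                break
        else:
            keep.append(i)

    if was_frame:
        survivors = df.iloc[keep].copy()
    else:
        survivors = [rows[i] for i in keep]
    return survivors, rejections


def rank_candidates(rows: pd.DataFrame, keys, descending: bool = True) -> pd.DataFrame:
    """Stable lexicographic sort of a candidate table; ties keep input order."""
    keys = list(keys)
    missing = set(keys) - set(rows.columns)
    if missing:
        raise KeyError(f"sort keys not in table: {sorted(missing)}")
    return rows.sort_values(keys, ascending=not descending, kind="mergesort")
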