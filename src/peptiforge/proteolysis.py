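"""Rule-based in silico enzymatic hydrolysis.

This module implements theoretical proteolysis of proteins and peptides:
single-enzyme digestion with optional missed cleavages, two-stage
gastric -> intestinal digestion, and counting of released bioactive
fragments (the statistic behind protease ranking).

A cleavage rule is a site specificity: the bond after residue ``i``
(1-based) is cut iff residue ``i`` is in the rule's ``c_terminal_of`` set
OR residue ``i+1`` is in its ``n_terminal_of`` set, unless residue
``i+1`` is in ``blocked_p1prime`` (a P1' veto, used e.g. for the classic
"no chymotryptic cut before Pro" exception and for expressing
between-hydrophobic-and-basic specificity such as bromelain's).

Coordinates are 1-based inclusive throughout, the convention of the
peptide literature.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Sequence

import yaml

from .residues import InvalidResidueError, validate_residue_set, validate_sequence


@dataclass(frozen=True)
class ProteinRecord:
    """A precursor protein: id, validated sequence and free-text source."""

    id: str
    sequence: str
    source: str = ""

    def __post_init__(self):
        validate_sequence(self.sequence, f"protein {self.id!r}")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class Peptide:
    """A digestion fragment with provenance coordinates in its parent.

    ``start`` and ``end`` are 1-based inclusive positions in the parent
    sequence; ``length == end - start + 1 == len(sequence)``.
    """

    sequence: str
    parent_id: str = ""
    start: int = 1
    end: int = 0

    def __post_init__(self):
        validate_sequence(self.sequence, "peptide")
        if self.end == 0:
            object.__setattr__(self, "end", self.start + len(self.sequence) - 1)
        if self.end - self.start + 1 != len(self.sequence):
            raise ValueError(
                f"coordinates [{self.start}, {self.end}] inconsistent with "
                f"sequence length {len(self.sequence)}"
            )
        if self.start < 1:
            raise ValueError("start must be >= 1 (1-based coordinates)")

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class CleavageRule:
    """A protease's site specificity (see module docstring for semantics)."""

    enzyme_name: str
    c_terminal_of: frozenset = frozenset()
    n_terminal_of: frozenset = frozenset()
    blocked_p1prime: frozenset = frozenset()

    def __post_init__(self):
        object.__setattr__(self, "c_terminal_of", validate_residue_set(self.c_terminal_of, "c_terminal_of"))
        object.__setattr__(self, "n_terminal_of", validate_residue_set(self.n_terminal_of, "n_terminal_of"))
        object.__setattr__(self, "blocked_p1prime", validate_residue_set(self.blocked_p1prime, "blocked_p1prime"))
        if not self.c_terminal_of and not self.n_terminal_of:
            raise ValueError(f"rule {self.enzyme_name!r}: at least one residue set must be non-empty")


@dataclass(frozen=True)
class DigestConfig:
    """Digestion options: missed-cleavage tolerance and minimum fragment length.

    ``missed_cleavages = 0`` is theoretical (exhaustive) digestion, matching
    database-style "enzyme action" predictions.
    """

    missed_cleavages: int = 0
    min_length: int = 1

    def __post_init__(self):
        if self.missed_cleavages < 0:
            raise ValueError("missed_cleavages must be >= 0")
        if self.min_length < 1:
            raise ValueError("min_length must be >= 1")


def find_cleavage_sites(sequence: str, rule: CleavageRule) -> list[int]:
    """Return cut positions for ``rule`` in ``sequence``.

    A returned position ``i`` means the bond between residues ``i`` and
    ``i+1`` (1-based) is cut.  Positions are strictly increasing and lie
    in ``[1, len(sequence) - 1]``.
    """
    seq = validate_sequence(sequence)
    sites = []
    for i in range(1, len(seq)):
        p1, p1prime = seq[i - 1], seq[i]
        if p1prime in rule.blocked_p1prime:
            continue
        if p1 in rule.c_terminal_of or p1prime in rule.n_terminal_of:
            sites.append(i)
    return sites


def _union_sites(sequence: str, rules: Iterable[CleavageRule]) -> list[int]:
    """Cut sites for several enzymes acting simultaneously (site union)."""
    sites: set[int] = set()
    for rule in rules:
        sites.update(find_cleavage_sites(sequence, rule))
    return sorted(sites)


def digest(protein: ProteinRecord, rule: CleavageRule, config: DigestConfig = DigestConfig()) -> list[Peptide]:
    """Digest a protein with one enzyme.

    With ``missed_cleavages = 0`` the fragments partition the parent
    (their in-order concatenation reconstructs it).  With
    ``missed_cleavages = k`` every run of at most ``k + 1`` consecutive
    zero-missed fragments is also returned.  Fragments shorter than
    ``config.min_length`` are dropped after enumeration.
    """
    seq = protein.sequence
    sites = find_cleavage_sites(seq, rule)
    bounds = [0, *sites, len(seq)]
    peptides: list[Peptide] = []
    n_frag = len(bounds) - 1
    for i in range(n_frag):
        for j in range(i + 1, min(i + 2 + config.missed_cleavages, len(bounds))):
            start, end = bounds[i] + 1, bounds[j]
            if end - start + 1 < config.min_length:
                continue
            peptides.append(Peptide(seq[start - 1 : end], protein.id, start, end))
    peptides.sort(key=lambda p: (p.start, p.end))
    return peptides


def _stage_products(sequence: str, rules: Sequence[CleavageRule], config: DigestConfig) -> set[str]:
    """Unique fragment sequences from one digestion stage.

    ``missed_cleavages = 0``: complete digestion (terminal fragments only).
    ``missed_cleavages > 0``: incomplete digestion — the full partial-
    digestion closure is retained, i.e. every fragment bounded by cut
    sites or termini, including the undigested input.  This models the
    observed product spectrum of in vitro gastrointestinal phases, where
    cleavage at each susceptible bond is probabilistic and partial
    products coexist with terminal ones.
    """
    sites = _union_sites(sequence, rules)
    bounds = [0, *sites, len(sequence)]
    out: set[str] = set()
    if config.missed_cleavages == 0:
        pairs = zip(bounds[:-1], bounds[1:])
    else:
        pairs = ((bounds[i], bounds[j]) for i in range(len(bounds) - 1) for j in range(i + 1, len(bounds)))
    for a, b in pairs:
        if b - a >= config.min_length:
            out.add(sequence[a:b])
    return out


def sequential_digest(
    peptide,
    stage1_rules: Sequence[CleavageRule],
    stage2_rules: Sequence[CleavageRule],
    config: DigestConfig = DigestConfig(missed_cleavages=1),
) -> set[str]:
    """Two-stage (gastric then intestinal) digestion of a peptide.

    Stage-1 rules (e.g. pepsin) are applied first; every stage-1 product
    is then digested by the stage-2 rules (e.g. trypsin + chymotrypsin
    acting together).  The result is the set of unique fragment
    sequences: terminal fragments plus, when ``missed_cleavages > 0``,
    all surviving intermediates of both stages (see ``_stage_products``).

    ``peptide`` may be a :class:`Peptide`, :class:`ProteinRecord` or a
    plain sequence string.
    """
    seq = peptide.sequence if hasattr(peptide, "sequence") else validate_sequence(peptide)
    stage1 = _stage_products(seq, stage1_rules, config)
    out: set[str] = set()
    for frag in stage1:
        out |= _stage_products(frag, stage2_rules, config)
    if config.missed_cleavages > 0:
        out |= stage1
    return out


def count_released_bioactive(protein: ProteinRecord, rule: CleavageRule, motifs) -> int:
    """Number of theoretical (zero-missed-cleavage) digestion fragments whose
    sequences occur in a motif database of known bioactive peptides.

    Each released fragment occurrence counts, so a motif released twice
    contributes 2.  This is the statistic used to rank proteases by
    predicted bioactive-peptide release.
    """
    fragments = digest(protein, rule, DigestConfig(missed_cleavages=0))
    return sum(1 for frag in fragments if frag.sequence in motifs)


# ---------------------------------------------------------------------------
# Enzyme registry


def load_enzyme_registry(path=None) -> dict[str, CleavageRule]:
    """Load cleavage rules from a YAML registry (the packaged one by default).

    The registry is an editable structured file so additional enzymes can
    be added without code changes.
    """
    if path is None:
        text = resources.files("peptiforge.data").joinpath("enzymes.yaml").read_text()
    else:
        with open(path) as fh:
            text = fh.read()
    raw = yaml.safe_load(text)
    registry = {}
    for name, entry in raw.items():
        registry[name] = CleavageRule(
            enzyme_name=name,
            c_terminal_of=frozenset(entry.get("c_terminal_of") or ()),
            n_terminal_of=frozenset(entry.get("n_terminal_of") or ()),
            blocked_p1prime=frozenset(entry.get("blocked_p1prime") or ()),
        )
    return registry


_DEFAULT_REGISTRY: dict[str, CleavageRule] | None = None


def get_rule(name: str) -> CleavageRule:
    """Look up an enzyme in the packaged registry."""
    global _DEFAULT_REGISTRY
    if _DEFAULT_REGISTRY is None:
        _DEFAULT_REGISTRY = load_enzyme_registry()
    try:
        return _DEFAULT_REGISTRY[name]
    except KeyError:
        known = ", ".join(sorted(_DEFAULT_REGISTRY))
        raise KeyError(f"unknown enzyme {name!r}; registry has: {known}") from None
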