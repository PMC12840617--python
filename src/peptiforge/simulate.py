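"""Synthetic-data generators for every pipeline input.

These generators emulate the study conditions end to end so that each
stage is testable without downloads: binary-labeled peptide sets with
the reported sequence-activity structure (Pro/Ala enrichment at the
second N-terminal position and hydrophobic termini in actives),
lognormal peptidomics abundance tables, Michaelis-Menten velocity data
under each inhibition mode with multiplicative noise, and digestible
protein fixtures with planted motifs.

Every generator is a pure function of (parameters, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .kinetics import KineticsDataset, velocity
from .ml import ACTIVITY_THRESHOLD_UM, LabeledPeptide
from .proteolysis import ProteinRecord
from .residues import AMINO_ACIDS, HYDROPHOBIC_RESIDUES
from .screening import CandidateRow

_AA = np.array(list(AMINO_ACIDS))
_HYDRO = np.array(sorted(HYDROPHOBIC_RESIDUES))
_NON_P2 = np.array([a for a in AMINO_ACIDS if a not in "PA"])

#: Default substrate grid of the inhibition assay (0.025-0.4 concentration units).
DEFAULT_S_GRID = (0.025, 0.05, 0.1, 0.2, 0.3, 0.4)
#: Default inhibitor levels (uM) of the assay design.
DEFAULT_I_GRID = (0.0, 400.0, 800.0)


@dataclass(frozen=True)
class ActivityModel:
    """Sequence-activity structure of the labeled peptide generator.

    Actives carry Pro/Ala at position 2 with probability
    ``p_pro2_active`` and hydrophobic N- and C-termini with probability
    ``p_hydrophobic_terminal_active``; inactives use the corresponding
    ``_inactive`` rates.  IC50s are lognormal per class, resampled so the
    active mass lies below and the inactive mass at or above the 2000 uM
    activity threshold.  Default class sizes elsewhere follow the
    588-active / 210-inactive composition of the curated training set.
    """

    p_pro2_active: float = 0.7
    p_pro2_inactive: float = 0.2
    p_hydrophobic_terminal_active: float = 0.85
    p_hydrophobic_terminal_inactive: float = 0.30
    min_length: int = 2
    max_length: int = 8
    active_ic50_log_mu: float = float(np.log(200.0))  # median 200 uM
    active_ic50_log_sigma: float = 1.0
    inactive_ic50_log_mu: float = float(np.log(5000.0))  # median 5000 uM
    inactive_ic50_log_sigma: float = 0.5

    def __post_init__(self):
        for p in (
            self.p_pro2_active,
            self.p_pro2_inactive,
            self.p_hydrophobic_terminal_active,
            self.p_hydrophobic_terminal_inactive,
        ):
            if not 0 <= p <= 1:
                raise ValueError("probabilities must be in [0, 1]")
        if not 2 <= self.min_length <= self.max_length:
            raise ValueError("need 2 <= min_length <= max_length")
        if self.active_ic50_log_mu >= np.log(ACTIVITY_THRESHOLD_UM) and self.active_ic50_log_sigma == 0:
            raise ValueError("active IC50 mode above the activity threshold with zero variance")
        if self.inactive_ic50_log_mu < np.log(ACTIVITY_THRESHOLD_UM) and self.inactive_ic50_log_sigma == 0:
            raise ValueError("inactive IC50 mode below the activity threshold with zero variance")


@dataclass(frozen=True)
class NoiseModel:
    """Noise settings: multiplicative CV for velocities, lognormal abundances."""

    velocity_cv: float = 0.02
    abundance_log_mu: float = float(np.log(2e6))
    abundance_log_sigma: float = 2.5

    def __post_init__(self):
        if self.velocity_cv < 0:
            raise ValueError("velocity CV must be >= 0")
        if self.abundance_log_sigma <= 0:
            raise ValueError("abundance sigma must be > 0")


def _sample_sequence(rng: np.random.Generator, length: int, p_pro2: float, p_hydro_term: float) -> str:
    residues = list(rng.choice(_AA, size=length))
    if rng.random() < p_hydro_term:
        residues[0] = str(rng.choice(_HYDRO))
        residues[-1] = str(rng.choice(_HYDRO))
    # position-2 forcing last: for dipeptides position 2 is the C-terminus
    # and the substrate-motif signal takes precedence.
    if rng.random() < p_pro2:
        residues[1] = "P" if rng.random() < 0.5 else "A"
    else:
        residues[1] = str(rng.choice(_NON_P2))
    return "".join(residues)


def _sample_ic50(rng: np.random.Generator, mu: float, sigma: float, active: bool) -> float:
    # Rejection-sample so labels and IC50s respect the 2000 uM rule.
    for _ in range(10000):
        value = float(rng.lognormal(mu, sigma))
        if active and value < ACTIVITY_THRESHOLD_UM:
            return value
        if not active and value >= ACTIVITY_THRESHOLD_UM:
            return value
    raise RuntimeError("could not sample an IC50 consistent with the class label")


def gen_labeled_peptides(
    n_active: int, n_inactive: int, model: ActivityModel = ActivityModel(), seed: int = 0
) -> list[LabeledPeptide]:
    """Generate a labeled peptide dataset with the stated class structure."""
    if n_active < 0 or n_inactive < 0:
        raise ValueError("class sizes must be >= 0")
    rng = np.random.default_rng(seed)
    out: list[LabeledPeptide] = []
    for label, n, p2, pht, mu, sg in (
        (1, n_active, model.p_pro2_active, model.p_hydrophobic_terminal_active,
         model.active_ic50_log_mu, model.active_ic50_log_sigma),
        (0, n_inactive, model.p_pro2_inactive, model.p_hydrophobic_terminal_inactive,
         model.inactive_ic50_log_mu, model.inactive_ic50_log_sigma),
    ):
        for _ in range(n):
            length = int(rng.integers(model.min_length, model.max_length + 1))
            seq = _sample_sequence(rng, length, p2, pht)
            ic50 = _sample_ic50(rng, mu, sg, active=bool(label))
            out.append(LabeledPeptide(seq, label, ic50))
    return out


def gen_kinetics(
    model_type: str,
    Km: float,
    Vmax: float,
    Ki: float | None = None,
    S_grid=DEFAULT_S_GRID,
    I_grid=DEFAULT_I_GRID,
    noise: NoiseModel = NoiseModel(velocity_cv=0.0),
    replicates: int = 1,
    seed: int = 0,
    alpha: float | None = None,
) -> KineticsDataset:
    """Simulate initial velocities on an (S, I) design with lognormal noise.

    Zero-noise mode reproduces the model velocities exactly; the noisy
    velocity is v_model * exp(N(0, cv)), a median-unbiased multiplicative
    error.
    """
    if Km <= 0 or Vmax <= 0 or (Ki is not None and Ki <= 0):
        raise ValueError("kinetic parameters must be positive")
    rng = np.random.default_rng(seed)
    S, I = [], []
    for i_level in I_grid:
        for s in S_grid:
            S.extend([s] * replicates)
            I.extend([i_level] * replicates)
    S = np.asarray(S, dtype=float)
    I = np.asarray(I, dtype=float)
    v = velocity(model_type, S, I, Km, Vmax, Ki, alpha)
    if noise.velocity_cv > 0:
        v = v * rng.lognormal(0.0, noise.velocity_cv, size=v.shape)
    return KineticsDataset(S, I, v)


def gen_peptidomics_table(
    n: int,
    noise: NoiseModel = NoiseModel(),
    score_beta=(1.0, 1.0),
    min_length: int = 2,
    max_length: int = 15,
    seed: int = 0,
    as_dataframe: bool = False,
):
    """Generate a peptidomics candidate table of ``n`` rows.

    Sequences are uniform over the alphabet (so the position-2 pass rate
    is analytically 2/20), abundances are lognormal and external scores
    Beta-distributed; the expected survivor fraction under the screening
    criteria is the product of the per-criterion tail probabilities.
    The defaults put about 1.5 % of rows past the abundance, length and
    score criteria combined, the candidate yield of a real peptidomics
    screen of this kind.
    """
    if n <= 0:
        raise ValueError("n must be > 0")
    rng = np.random.default_rng(seed)
    lengths = rng.integers(min_length, max_length + 1, size=n)
    seqs = ["".join(rng.choice(_AA, size=int(L))) for L in lengths]
    abundances = rng.lognormal(noise.abundance_log_mu, noise.abundance_log_sigma, size=n)
    scores = rng.beta(score_beta[0], score_beta[1], size=n)
    if as_dataframe:
        return pd.DataFrame({"sequence": seqs, "abundance": abundances, "score": scores})
    return [CandidateRow(s, float(a), float(sc)) for s, a, sc in zip(seqs, abundances, scores)]


def gen_protein_fixtures(
    n: int,
    length: int,
    composition_bias: dict[str, float] | None = None,
    planted_motifs: list[str] | None = None,
    seed: int = 0,
) -> tuple[list[ProteinRecord], dict[str, list[tuple[str, int]]]]:
    """Generate random proteins, optionally planting motifs at known sites.

    ``composition_bias`` maps residues to relative weights (unlisted
    residues keep weight 1).  Planted motifs are placed at
    non-overlapping positions recorded in the returned map of protein id
    to (motif, 1-based start) pairs.
    """
    planted_motifs = planted_motifs or []
    need = sum(len(m) for m in planted_motifs)
    if need > length:
        raise ValueError(f"cannot plant {need} motif residues into length {length}")
    rng = np.random.default_rng(seed)
    weights = np.array([composition_bias.get(a, 1.0) if composition_bias else 1.0 for a in AMINO_ACIDS])
    probs = weights / weights.sum()

    records, plantings = [], {}
    for i in range(n):
        seq = list(rng.choice(_AA, size=length, p=probs))
        placed: list[tuple[str, int]] = []
        occupied: set[int] = set()
        for motif in planted_motifs:
            free_starts = [
                s
                for s in range(length - len(motif) + 1)
                if not (set(range(s, s + len(motif))) & occupied)
            ]
            if not free_starts:
                raise ValueError(f"no room to plant motif {motif!r}")
            start = int(rng.choice(free_starts))
            seq[start : start + len(motif)] = list(motif)
            occupied.update(range(start, start + len(motif)))
            placed.append((motif, start + 1))
        pid = f"synthetic_{i}"
        records.append(ProteinRecord(pid, "".join(seq), source="synthetic fixture"))
        plantings[pid] = placed
    return records, plantings
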