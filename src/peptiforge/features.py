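"""Pseudo amino acid composition (PseAAC) featurization.

Each peptide is mapped to a 27-dimensional vector:

* components 1-20 — amino-acid composition terms, ordered alphabetically
  by one-letter code (A, C, D, ..., W, Y);
* component 21 — the first-order hydrophobicity sequence-correlation
  factor (Chou's type-1 PseAAC with lambda = 1, squared-difference
  correlation over the normalized hydrophobicity scale), weighted by
  ``w``;
* components 22-27 — unweighted sequence means of six raw
  physicochemical properties: hydrophobicity, hydrophilicity, residue
  mass (Da), pK1 (alpha-carboxyl), pK2 (alpha-amino) and pI.

Components 1-21 follow the Chou normalization
``f_u / (sum f + w*theta1)`` and ``w*theta1 / (sum f + w*theta1)``, so
they sum to 1.  Components 22-27 use raw (un-normalized) scale values so
that the average-mass feature stays interpretable in Daltons; only the
correlation factor uses the normalized (zero-mean, unit-variance over
the 20 residues) hydrophobicity table.

Default scales: Kyte-Doolittle hydrophobicity, Hopp-Woods
hydrophilicity, average residue masses, standard free-amino-acid
pK1/pK2/pI values.  All are overridable through a scales CSV.
"""

from __future__ import annotations

from importlib import resources

import numpy as np
import pandas as pd

from .residues import AMINO_ACIDS, validate_sequence

PROPERTY_NAMES = ("hydrophobicity", "hydrophilicity", "mass", "pk1", "pk2", "pi")

#: Names of the 27 feature-vector components, in order.
FEATURE_NAMES: tuple[str, ...] = (
    tuple(f"comp_{aa}" for aa in AMINO_ACIDS)
    + ("corr1_hydrophobicity",)
    + tuple(f"avg_{p}" for p in PROPERTY_NAMES)
)

N_FEATURES = 27


class PropertyScales:
    """Per-residue numeric tables for the six physicochemical properties."""

    def __init__(self, table: pd.DataFrame):
        table = table.copy()
        if "residue" in table.columns:
            table = table.set_index("residue")
        missing_props = set(PROPERTY_NAMES) - set(table.columns)
        if missing_props:
            raise ValueError(f"scales table missing properties: {sorted(missing_props)}")
        missing_res = set(AMINO_ACIDS) - set(table.index)
        if missing_res:
            raise ValueError(f"scales table missing residues: {sorted(missing_res)}")
        self.table = table.loc[list(AMINO_ACIDS), list(PROPERTY_NAMES)].astype(float)

    @classmethod
    def from_csv(cls, path) -> "PropertyScales":
        return cls(pd.read_csv(path))

    @classmethod
    def default(cls) -> "PropertyScales":
        with resources.files("peptiforge.data").joinpath("scales.csv").open() as fh:
            return cls(pd.read_csv(fh))

    def raw(self, prop: str) -> np.ndarray:
        """Raw values for one property, ordered like ``AMINO_ACIDS``."""
        return self.table[prop].to_numpy()

    def normalized(self, prop: str) -> np.ndarray:
        """Zero-mean, unit-variance (population) version of one property."""
        v = self.raw(prop)
        return (v - v.mean()) / v.std()


_DEFAULT_SCALES: PropertyScales | None = None


def default_scales() -> PropertyScales:
    global _DEFAULT_SCALES
    if _DEFAULT_SCALES is None:
        _DEFAULT_SCALES = PropertyScales.default()
    return _DEFAULT_SCALES


_AA_INDEX = {aa: i for i, aa in enumerate(AMINO_ACIDS)}


def featurize(peptide: str, w: float = 0.05, scales: PropertyScales | None = None) -> np.ndarray:
    """Compute the 27-component PseAAC vector for one peptide.

    ``w`` is the sequence-order weight of the correlation factor
    (default 0.05, the standard PseAAC convention).  For a single-residue
    peptide the correlation factor is defined as 0.
    """
    seq = validate_sequence(peptide, "peptide")
    if w < 0:
        raise ValueError("w must be non-negative")
    scales = scales or default_scales()
    idx = np.fromiter((_AA_INDEX[ch] for ch in seq), dtype=int, count=len(seq))

    counts = np.bincount(idx, minlength=20).astype(float)
    freqs = counts / len(seq)

    h_norm = scales.normalized("hydrophobicity")[idx]
    theta1 = 0.0 if len(seq) == 1 else float(np.mean(np.diff(h_norm) ** 2))

    denom = 1.0 + w * theta1
    vec = np.empty(N_FEATURES)
    vec[:20] = freqs / denom
    vec[20] = w * theta1 / denom
    for k, prop in enumerate(PROPERTY_NAMES):
        vec[21 + k] = float(scales.raw(prop)[idx].mean())
    return vec


def featurize_many(peptides, w: float = 0.05, scales: PropertyScales | None = None) -> pd.DataFrame:
    """Featurize an iterable of peptide sequences into a named DataFrame."""
    scales = scales or default_scales()
    rows = [featurize(p, w=w, scales=scales) for p in peptides]
    return pd.DataFrame(rows, columns=list(FEATURE_NAMES), index=list(peptides))


class Standardizer:
    """Column-wise standardization with training-time parameters preserved.

    Fitted on a training matrix; applying to new data reuses the training
    means and standard deviations (population, ddof=0).  Columns that are
    constant on the training data are flagged in ``constant_mask`` and
    passed through unscaled.
    """

    def __init__(self):
        self.mean_: np.ndarray | None = None
        self.std_: np.ndarray | None = None
        self.constant_mask: np.ndarray | None = None

    def fit(self, X) -> "Standardizer":
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[0] < 2:
            raise ValueError("standardizer requires a 2-D matrix with at least 2 rows")
        self.mean_ = X.mean(axis=0)
        self.std_ = X.std(axis=0)
        self.constant_mask = self.std_ < 1e-12
        return self

    def transform(self, X) -> np.ndarray:
        if self.mean_ is None:
            raise RuntimeError("standardizer is not fitted")
        X = np.asarray(X, dtype=float)
        out = X.copy()
        keep = ~self.constant_mask
        out[:, keep] = (X[:, keep] - self.mean_[keep]) / self.std_[keep]
        return out

    def fit_transform(self, X) -> np.ndarray:
        return self.fit(X).transform(X)

    def to_dict(self) -> dict:
        return {
            "mean": self.mean_.tolist(),
            "std": self.std_.tolist(),
            "constant_mask": self.constant_mask.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Standardizer":
        s = cls()
        s.mean_ = np.asarray(d["mean"], dtype=float)
        s.std_ = np.asarray(d["std"], dtype=float)
        s.constant_mask = np.asarray(d["constant_mask"], dtype=bool)
        return s


def fit_standardizer(matrix) -> Standardizer:
    """Functional wrapper: fit a :class:`Standardizer` on a feature matrix."""
    return Standardizer().fit(np.asarray(matrix, dtype=float))


def apply_standardizer(standardizer: Standardizer, matrix) -> np.ndarray:
    """Apply training-time standardization parameters to a matrix."""
    return standardizer.transform(np.asarray(matrix, dtype=float))
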