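"""Physicochemical encoding of amino-acid sequences.

Each residue is described by eight scalar properties: hydrophobicity
(H1), hydrophilicity (H2), side-chain volume (V), polarity (P1),
polarizability (P2), solvent-accessible surface area (SASA), net charge
index of the side chain (NCI), and a composite P value combining the
isoelectric point PI with the ionization constant pKa,

    P_n = PI_n + u * pKa_n,   u = sum_n PI_n / sum_n pKa_n,

summed over the 20 standard amino acids.  Properties are z-scored over
the 20 amino acids (population standard deviation: the table is the
whole population, not a sample) and a sequence of length L becomes an
L x 8 matrix of standardized signals, one column per property.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from ppiwave.exceptions import (
    DegenerateInputError,
    InvalidInputError,
    InvalidResidueError,
)

AMINO_ACIDS: tuple[str, ...] = (
    "A", "C", "D", "E", "F", "G", "H", "I", "K", "L",
    "M", "N", "P", "Q", "R", "S", "T", "V", "W", "Y",
)

PROPERTY_NAMES: tuple[str, ...] = ("H1", "H2", "V", "P1", "P2", "SASA", "NCI", "P")

# 20 x 8 reference table, rows in AMINO_ACIDS order, columns in
# PROPERTY_NAMES order.  The P column is the published composite value;
# compute_p_property() exists for users supplying their own PI/pKa sets.
_RAW_TABLE = np.array([
    #   H1     H2      V      P1     P2     SASA    NCI        P
    [ 0.62, -0.5,   27.5,   8.1, 0.046, 1.181,  0.007187, 12.772 ],   # A
    [ 0.29, -1.0,   44.6,   5.5, 0.128, 1.461, -0.03661,  10.4312],   # C
    [-0.90,  3.0,   40.0,  13.0, 0.105, 1.587, -0.02382,   8.4134],   # D
    [-0.74,  3.0,   62.0,  12.3, 0.151, 1.862,  0.006802,  9.1455],   # E
    [ 1.19, -2.5,  115.5,   5.2, 0.290, 2.228,  0.037552, 11.6877],   # F
    [ 0.48,  0.0,    0.0,   9.0, 0.000, 0.881,  0.179052, 12.742 ],   # G
    [-0.40, -0.5,   79.0,  10.4, 0.230, 2.025, -0.01069,  12.669 ],   # H
    [ 1.38, -1.8,   93.5,   5.2, 0.186, 1.810,  0.021631, 12.5099],   # I
    [-1.50,  3.0,  100.0,  11.3, 0.219, 2.258,  0.017708, 15.9477],   # K
    [ 1.06, -1.8,   93.5,   4.9, 0.186, 1.931,  0.051672, 12.4699],   # L
    [ 0.64, -1.3,   94.1,   5.7, 0.221, 2.034,  0.002683, 11.6655],   # M
    [-0.78,  2.0,   58.7,  11.6, 0.134, 1.655,  0.005392, 11.3355],   # N
    [ 0.12,  0.0,   41.9,   8.0, 0.131, 1.468,  0.239531, 11.9434],   # P
    [-0.85,  0.2,   80.7,  10.5, 0.180, 1.932,  0.049211, 11.8677],   # Q
    [-2.53,  3.0,  105.0,  10.5, 0.291, 2.560,  0.043587, 15.839 ],   # R
    [-0.18,  0.3,   29.3,   9.2, 0.062, 1.298,  0.004627, 11.8877],   # S
    [-0.05, -0.4,   51.3,   8.6, 0.108, 1.525,  0.003352, 12.0855],   # T
    [ 1.08, -1.5,   71.5,   5.9, 0.140, 1.645,  0.057004, 12.1677],   # V
    [ 0.81, -3.4,  145.5,   5.4, 0.409, 2.663,  0.037977, 12.662 ],   # W
    [ 0.26, -2.3,  117.3,   6.2, 0.298, 2.368,  0.023599, 11.8677],   # Y
])
_RAW_TABLE.flags.writeable = False


def compute_p_property(pi_values, pka_values) -> np.ndarray:
    """Combine isoelectric points and ionization constants into P values.

    P_n = PI_n + u * pKa_n with u = (sum PI_n) / (sum pKa_n), both sums
    over the 20 amino acids in table order.

    Parameters
    ----------
    pi_values, pka_values : array-like of 20 floats
        Aligned to :data:`AMINO_ACIDS` order.
    """
    pi = np.asarray(pi_values, dtype=float)
    pka = np.asarray(pka_values, dtype=float)
    if pi.shape != (20,) or pka.shape != (20,):
        raise InvalidInputError(
            f"expected 20 PI and 20 pKa values, got {pi.shape} and {pka.shape}"
        )
    pka_sum = pka.sum()
    if pka_sum == 0:
        raise DegenerateInputError("sum of pKa values is zero; u is undefined")
    u = pi.sum() / pka_sum
    return pi + u * pka


def standardize_table(raw: np.ndarray) -> np.ndarray:
    """Z-score each property column over the 20 amino acids.

    Uses the population standard deviation (ddof=0): the 20 amino acids
    are the entire population the table describes.
    """
    raw = np.asarray(raw, dtype=float)
    if raw.ndim != 2:
        raise InvalidInputError("property table must be 2-D")
    mean = raw.mean(axis=0)
    sd = raw.std(axis=0)
    constant = sd <= 1e-12 * (np.abs(mean) + 1)
    if constant.any():
        cols = [i for i in np.flatnonzero(constant)]
        raise DegenerateInputError(f"constant property column(s) {cols}: sd is zero")
    return (raw - mean) / sd


@dataclass(frozen=True)
class AminoAcidPropertyTable:
    """The 20-amino-acid x 8-property reference table.

    Attributes
    ----------
    codes : one-letter amino-acid codes, fixed order.
    property_names : the 8 property names, fixed order.
    raw : 20 x 8 matrix of raw property values.
    standardized : 20 x 8 matrix, each column z-scored over the 20 rows.
    """

    codes: tuple[str, ...] = AMINO_ACIDS
    property_names: tuple[str, ...] = PROPERTY_NAMES
    raw: np.ndarray = field(default_factory=lambda: _RAW_TABLE.copy())
    standardized: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        raw = np.asarray(self.raw, dtype=float)
        if raw.shape != (len(self.codes), len(self.property_names)):
            raise InvalidInputError(
                f"table shape {raw.shape} does not match "
                f"{len(self.codes)} codes x {len(self.property_names)} properties"
            )
        if len(set(self.codes)) != len(self.codes):
            raise InvalidInputError("duplicate amino-acid codes")
        object.__setattr__(self, "raw", raw)
        if self.standardized is None:
            object.__setattr__(self, "standardized", standardize_table(raw))
        self._row_index  # build lookup eagerly so bad codes fail here

    @property
    def _row_index(self) -> dict[str, int]:
        return {c: i for i, c in enumerate(self.codes)}

    def row(self, code: str, standardized: bool = True) -> np.ndarray:
        table = self.standardized if standardized else self.raw
        return table[self._row_index[code]]

    def to_tsv(self, path) -> None:
        """Write the raw table as delimited text (header = property names)."""
        import pandas as pd

        df = pd.DataFrame(self.raw, index=list(self.codes),
                          columns=list(self.property_names))
        df.to_csv(path, sep="\t", index_label="code")

    @classmethod
    def from_tsv(cls, path) -> "AminoAcidPropertyTable":
        """Read a property table written by :meth:`to_tsv`; any 8-column
        numeric table with matching header works, letting users swap
        property sets."""
        import pandas as pd

        df = pd.read_csv(Path(path), sep="\t", index_col="code")
        return cls(
            codes=tuple(df.index.astype(str)),
            property_names=tuple(df.columns.astype(str)),
            raw=df.to_numpy(dtype=float),
            standardized=None,
        )


_DEFAULT_TABLE: AminoAcidPropertyTable | None = None


def default_property_table() -> AminoAcidPropertyTable:
    """The built-in reference table (cached singleton)."""
    global _DEFAULT_TABLE
    if _DEFAULT_TABLE is None:
        _DEFAULT_TABLE = AminoAcidPropertyTable()
    return _DEFAULT_TABLE


@dataclass(frozen=True)
class DigitalSequence:
    """A protein sequence digitized into 8 standardized property signals.

    ``signals`` is an L x 8 matrix: row i is the standardized property
    row of residue i, column j the full-length signal of property j.
    """

    protein_id: str
    signals: np.ndarray

    @property
    def length(self) -> int:
        return self.signals.shape[0]


def encode_sequence(
    sequence: str,
    table: AminoAcidPropertyTable | None = None,
    *,
    protein_id: str = "",
    policy: str = "strict",
) -> DigitalSequence:
    """Digitize an amino-acid sequence into 8 numeric signals.

    Parsing is case-insensitive.  Non-standard residues (B, J, O, U, X,
    Z, and anything else outside the 20-letter alphabet, including stop
    codons '*'):

    - ``policy="strict"`` (default): raise :class:`InvalidResidueError`
      naming the position and character.
    - ``policy="lenient"``: drop the residue with a warning.  Silent
      imputation is never done -- it would corrupt the wavelet features.
    """
    if table is None:
        table = default_property_table()
    if policy not in ("strict", "lenient"):
        raise InvalidInputError(f"unknown residue policy {policy!r}")
    if not sequence:
        raise InvalidInputError("empty sequence")
    index = table._row_index
    rows: list[int] = []
    dropped: list[tuple[int, str]] = []
    for pos, ch in enumerate(sequence.upper(), start=1):
        i = index.get(ch)
        if i is None:
            if policy == "strict":
                raise InvalidResidueError(ch, pos, protein_id or None)
            dropped.append((pos, ch))
        else:
            rows.append(i)
    if dropped:
        warnings.warn(
            f"dropped {len(dropped)} non-standard residue(s) from "
            f"{protein_id or 'sequence'}: "
            + ", ".join(f"{c!r}@{p}" for p, c in dropped[:5])
            + ("..." if len(dropped) > 5 else ""),
            stacklevel=2,
        )
    if not rows:
        raise InvalidInputError(
            f"sequence {protein_id or ''} has no standard residues after filtering"
        )
    return DigitalSequence(protein_id=protein_id,
                           signals=table.standardized[rows, :].copy())
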