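"""Codon–tRNA decoding matrix and per-codon concentration aggregation.

Each sense codon classifies every elongator-tRNA species as cognate,
near-cognate (one mismatched codon–anticodon position) or non-cognate.  The
classification matrix is supplied as data; for each codon, the free
ternary-complex concentrations of the member species of each class are
summed to form the codon's decoding context.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from os import PathLike
from typing import Mapping

import pandas as pd

from .elongation import CodonContext

__all__ = [
    "SENSE_CODONS",
    "STOP_CODONS",
    "DecodingMatrix",
    "ConcentrationProfile",
    "read_decoding_matrix",
    "write_decoding_matrix",
    "build_codon_contexts",
    "normalize_codon",
]

logger = logging.getLogger(__name__)

STOP_CODONS: frozenset[str] = frozenset({"UAA", "UAG", "UGA"})

#: The 61 sense codons of the standard bacterial code, RNA alphabet,
#: lexicographic order.
SENSE_CODONS: tuple[str, ...] = tuple(
    a + b + c
    for a in "ACGU"
    for b in "ACGU"
    for c in "ACGU"
    if a + b + c not in STOP_CODONS
)

_CLASS_SYMBOLS = {"C": "cognate", "N": "near_cognate", "X": "non_cognate"}


def normalize_codon(codon: str, where: str = "") -> str:
    """Validate a codon, upper-casing and converting DNA (T) to RNA (U)."""
    c = str(codon).strip().upper()
    if "T" in c:
        logger.warning("codon %r%s contains T; converting DNA to RNA alphabet", codon, where)
        c = c.replace("T", "U")
    if len(c) != 3 or any(base not in "ACGU" for base in c):
        raise ValueError(f"invalid codon {codon!r}{where}: expected a 3-letter ACGU triplet")
    if c in STOP_CODONS:
        raise ValueError(f"stop codon {c!r}{where} is not decodable by elongator tRNA")
    return c


@dataclass(frozen=True)
class DecodingMatrix:
    """Classification of every (codon, tRNA) pair as cognate/near-/non-cognate.

    Backed by a :class:`pandas.DataFrame` with codon rows, tRNA-id columns
    and cells in ``{"C", "N", "X"}``; row and column order are preserved.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        t = self.table
        if t.index.duplicated().any():
            dupes = t.index[t.index.duplicated()].tolist()
            raise ValueError(f"duplicate codon rows: {dupes}")
        if t.columns.duplicated().any():
            raise ValueError("duplicate tRNA columns")
        for pos, codon in enumerate(t.index, start=1):
            normalized = normalize_codon(codon, where=f" (row {pos})")
            if normalized != codon:
                raise ValueError(f"codon row {pos} ({codon!r}) is not normalized RNA; use {normalized!r}")
        for codon, row in t.iterrows():
            for trna, cell in row.items():
                if cell not in _CLASS_SYMBOLS:
                    raise ValueError(
                        f"bad classification symbol {cell!r} at codon {codon!r} / tRNA {trna!r}; expected C, N or X"
                    )
            if not (row == "C").any():
                raise ValueError(f"codon {codon!r} has no cognate tRNA")
        for trna in t.columns:
            if not (t[trna] == "C").any():
                raise ValueError(f"tRNA {trna!r} has no cognate codon")

    @property
    def codons(self) -> tuple[str, ...]:
        return tuple(self.table.index)

    @property
    def trnas(self) -> tuple[str, ...]:
        return tuple(self.table.columns)

    @property
    def complete(self) -> bool:
        """True when all 61 sense codons are present."""
        return set(self.table.index) == set(SENSE_CODONS)

    def classification(self, codon: str, trna: str) -> str:
        """Long-form class name for one (codon, tRNA) pair."""
        return _CLASS_SYMBOLS[self.table.at[codon, trna]]

    def species_of(self, codon: str, symbol: str) -> tuple[str, ...]:
        """tRNA ids classified with the given symbol ("C", "N" or "X") for a codon."""
        row = self.table.loc[codon]
        return tuple(row.index[row == symbol])

    def near_cognate_codons(self, trna: str) -> tuple[str, ...]:
        """Codons for which the given species is classified near-cognate."""
        col = self.table[trna]
        return tuple(col.index[col == "N"])


@dataclass(frozen=True)
class ConcentrationProfile:
    """Free ternary-complex concentration (µM) per tRNA species for one growth condition."""

    concentrations: dict[str, float]
    growth_label: str = ""

    def __post_init__(self) -> None:
        for trna, value in self.concentrations.items():
            if not math.isfinite(value) or value < 0:
                raise ValueError(f"concentration of {trna!r} must be finite and >= 0, got {value!r}")

    @property
    def total(self) -> float:
        return sum(self.concentrations.values())

    def __getitem__(self, trna: str) -> float:
        return self.concentrations[trna]


def read_decoding_matrix(path: str | PathLike) -> DecodingMatrix:
    """Read a decoding matrix TSV: header row of tRNA ids, first column codons, cells C/N/X."""
    table = pd.read_csv(path, sep="\t", index_col=0, dtype=str, comment="#")
    table.index = table.index.astype(str)
    try:
        return DecodingMatrix(table=table)
    except ValueError as exc:
        raise ValueError(f"{path}: {exc}") from exc


def write_decoding_matrix(matrix: DecodingMatrix, path: str | PathLike) -> None:
    matrix.table.to_csv(path, sep="\t", index_label="codon")


def build_codon_contexts(
    matrix: DecodingMatrix,
    conc: ConcentrationProfile,
    usage: Mapping[str, float],
) -> dict[str, CodonContext]:
    """Aggregate per-species concentrations into per-codon decoding contexts.

    For each codon, ``c_cog``/``c_nea``/``c_non`` are the summed
    concentrations of its cognate, near-cognate and non-cognate species, so
    their total equals the profile total for every codon.  ``usage`` must
    provide a probability for every codon of the matrix.
    """
    missing_species = set(matrix.trnas) - set(conc.concentrations)
    if missing_species:
        raise KeyError(f"concentration profile lacks tRNA species: {sorted(missing_species)}")
    missing_codons = set(matrix.codons) - set(usage)
    if missing_codons:
        raise KeyError(f"codon usage lacks codons: {sorted(missing_codons)}")
    contexts: dict[str, CodonContext] = {}
    for codon in matrix.codons:
        sums = {"C": 0.0, "N": 0.0, "X": 0.0}
        row = matrix.table.loc[codon]
        for trna, cell in row.items():
            sums[cell] += conc[trna]
        contexts[codon] = CodonContext(
            codon=codon,
            c_cog=sums["C"],
            c_nea=sums["N"],
            c_non=sums["X"],
            usage=float(usage[codon]),
        )
    return contexts
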