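"""Physicochemical residue property tables and their standardization.

The pseudo-amino-acid composition correlates residues through three
properties: hydrophobicity (Tanford's transfer free-energy scale),
hydrophilicity (Hopp & Woods) and side-chain mass.  Before use each scale
is centred and divided by its population standard deviation over the 20
residues, so the three properties contribute on a common scale.

The Kyte-Doolittle hydropathy scale used by the positional analysis lives
here as well.  Tables may be overridden from a two-column tab-delimited
file (``residue  value``).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

from .seqio import AMINO_ACIDS

# Tanford transfer free energies (hydrophobicity), kcal/mol.
TANFORD_HYDROPHOBICITY: dict[str, float] = {
    "A": 0.62, "C": 0.29, "D": -0.90, "E": -0.74, "F": 1.19,
    "G": 0.48, "H": -0.40, "I": 1.38, "K": -1.50, "L": 1.06,
    "M": 0.64, "N": -0.78, "P": 0.12, "Q": -0.85, "R": -2.53,
    "S": -0.18, "T": -0.05, "V": 1.08, "W": 0.81, "Y": 0.26,
}

# Hopp & Woods hydrophilicity values.
HOPP_WOODS_HYDROPHILICITY: dict[str, float] = {
    "A": -0.5, "C": -1.0, "D": 3.0, "E": 3.0, "F": -2.5,
    "G": 0.0, "H": -0.5, "I": -1.8, "K": 3.0, "L": -1.8,
    "M": -1.3, "N": 0.2, "P": 0.0, "Q": 0.2, "R": 3.0,
    "S": 0.3, "T": -0.4, "V": -1.5, "W": -3.4, "Y": -2.3,
}

# Side-chain masses (Da), glycine side chain = 1 (a hydrogen).
SIDE_CHAIN_MASS: dict[str, float] = {
    "A": 15.0, "C": 47.0, "D": 59.0, "E": 73.0, "F": 91.0,
    "G": 1.0, "H": 82.0, "I": 57.0, "K": 73.0, "L": 57.0,
    "M": 75.0, "N": 58.0, "P": 42.0, "Q": 72.0, "R": 101.0,
    "S": 31.0, "T": 45.0, "V": 43.0, "W": 130.0, "Y": 107.0,
}

# Kyte & Doolittle hydropathy index.
KYTE_DOOLITTLE: dict[str, float] = {
    "A": 1.8, "C": 2.5, "D": -3.5, "E": -3.5, "F": 2.8,
    "G": -0.4, "H": -3.2, "I": 4.5, "K": -3.9, "L": 3.8,
    "M": 1.9, "N": -3.5, "P": -1.6, "Q": -3.5, "R": -4.5,
    "S": -0.8, "T": -0.7, "V": 4.2, "W": -0.9, "Y": -1.3,
}


def _validate_table(table: Mapping[str, float], name: str) -> dict[str, float]:
    missing = [aa for aa in AMINO_ACIDS if aa not in table]
    if missing:
        raise ValueError(f"property table {name!r} missing residues: {missing}")
    extra = set(table) - set(AMINO_ACIDS)
    if extra:
        raise ValueError(f"property table {name!r} has unknown residues: {sorted(extra)}")
    return {aa: float(table[aa]) for aa in AMINO_ACIDS}


def standardize_table(raw: Mapping[str, float], name: str = "property") -> dict[str, float]:
    """Centre ``raw`` and scale to unit population standard deviation.

    A constant table has zero spread and cannot be standardized; that is an
    error rather than a silent zero division.
    """
    table = _validate_table(raw, name)
    values = [table[aa] for aa in AMINO_ACIDS]
    mean = sum(values) / 20.0
    var = sum((v - mean) ** 2 for v in values) / 20.0
    if var == 0.0:
        raise ValueError(f"property table {name!r} is constant: zero denominator")
    sd = math.sqrt(var)
    return {aa: (table[aa] - mean) / sd for aa in AMINO_ACIDS}


@dataclass(frozen=True)
class PropertyTables:
    """Raw and standardized hydrophobicity / hydrophilicity / mass tables."""

    h1_raw: dict[str, float]
    h2_raw: dict[str, float]
    mass_raw: dict[str, float]
    h1: dict[str, float]
    h2: dict[str, float]
    m_norm: dict[str, float]

    @classmethod
    def from_raw(
        cls,
        h1: Mapping[str, float] | None = None,
        h2: Mapping[str, float] | None = None,
        mass: Mapping[str, float] | None = None,
    ) -> "PropertyTables":
        h1 = _validate_table(h1 or TANFORD_HYDROPHOBICITY, "hydrophobicity")
        h2 = _validate_table(h2 or HOPP_WOODS_HYDROPHILICITY, "hydrophilicity")
        mass = _validate_table(mass or SIDE_CHAIN_MASS, "side-chain mass")
        return cls(
            h1_raw=h1,
            h2_raw=h2,
            mass_raw=mass,
            h1=standardize_table(h1, "hydrophobicity"),
            h2=standardize_table(h2, "hydrophilicity"),
            m_norm=standardize_table(mass, "side-chain mass"),
        )


def default_tables() -> PropertyTables:
    """Standardized Tanford / Hopp-Woods / side-chain-mass tables."""
    return PropertyTables.from_raw()


def read_property_table(path: str | Path) -> dict[str, float]:
    """Read a residue-value override table (``residue<TAB>value`` lines)."""
    table: dict[str, float] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.split()
        if len(parts) != 2:
            raise ValueError(f"{path}:{lineno}: expected 'residue value'")
        table[parts[0].upper()] = float(parts[1])
    return _validate_table(table, str(path))
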