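"""Composition encodings of protein sequences and alignments.

Three schemes are implemented:

* **AAC** — amino-acid composition: the 20 normalized residue frequencies
  ``c_i = F_i / L``.
* **PAAC** — pair (dipeptide) amino-acid composition: the 400 normalized
  frequencies of ordered adjacent residue pairs, ``d_ij = F_ij / (L - 1)``.
* **PseAAC** — Chou's pseudo-amino-acid composition: the 20 frequencies
  plus ``lambda`` sequence-order correlation factors built from
  standardized hydrophobicity, hydrophilicity and side-chain mass,
  weighted by ``omega`` and jointly normalized to sum to one.

Each encoder also has an alignment-pooled form: residue (or pair) counts
are gathered over every row of a multiple sequence alignment, with gaps
and masked cells ignored, so the vector summarizes the whole family
rather than the single query sequence.

Vector entry order is canonical and fixed: residues alphabetically
(ACDEFGHIKLMNPQRSTVWY) and residue pairs row-major in that order, so
feature tables are comparable across runs.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .properties import PropertyTables, default_tables
from .seqio import AMINO_ACIDS, GAP, Alignment, ColumnMask, SequenceRecord

log = logging.getLogger(__name__)

_AA_INDEX = {aa: i for i, aa in enumerate(AMINO_ACIDS)}

#: Feature names for the AAC scheme.
AAC_NAMES: tuple[str, ...] = tuple(AMINO_ACIDS)

#: Feature names for the PAAC scheme, row-major over ordered pairs.
PAAC_NAMES: tuple[str, ...] = tuple(a + b for a in AMINO_ACIDS for b in AMINO_ACIDS)

SCHEMES = ("AAC", "PAAC", "PseAAC")


@dataclass(frozen=True)
class CompositionVector:
    """One encoded sequence or alignment."""

    scheme: str
    values: np.ndarray
    lam: int | None = None
    omega: float | None = None

    def __post_init__(self) -> None:
        if self.scheme not in SCHEMES:
            raise ValueError(f"unknown scheme {self.scheme!r}")
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        n = len(self.values)
        if self.scheme == "AAC" and n != 20:
            raise ValueError(f"AAC vector must have 20 entries, got {n}")
        if self.scheme == "PAAC" and n != 400:
            raise ValueError(f"PAAC vector must have 400 entries, got {n}")
        if self.scheme == "PseAAC":
            if self.lam is None:
                raise ValueError("PseAAC vector requires lambda")
            if n != 20 + self.lam:
                raise ValueError(
                    f"PseAAC vector must have 20+{self.lam} entries, got {n}"
                )

    @property
    def feature_names(self) -> tuple[str, ...]:
        if self.scheme == "AAC":
            return AAC_NAMES
        if self.scheme == "PAAC":
            return PAAC_NAMES
        return AAC_NAMES + tuple(f"theta_{k}" for k in range(1, (self.lam or 0) + 1))

    def __len__(self) -> int:
        return len(self.values)


def _countable(seq: str) -> str:
    """Residues of ``seq`` restricted to the 20-letter alphabet.

    Gaps and any non-standard codes are removed, compacting the string so
    that residues separated only by ignored cells become adjacent.
    """
    return "".join(ch for ch in seq.upper() if ch in _AA_INDEX)


def aac(seq: str | SequenceRecord) -> CompositionVector:
    """Amino-acid composition: 20 normalized residue frequencies."""
    s = _countable(seq.residues if isinstance(seq, SequenceRecord) else seq)
    if not s:
        raise ValueError("no countable residues for AAC")
    counts = np.zeros(20)
    for ch in s:
        counts[_AA_INDEX[ch]] += 1
    return CompositionVector("AAC", counts / len(s))


def paac(seq: str | SequenceRecord) -> CompositionVector:
    """Pair amino-acid composition: 400 normalized adjacent-pair frequencies."""
    s = _countable(seq.residues if isinstance(seq, SequenceRecord) else seq)
    if len(s) < 2:
        raise ValueError(
            f"need at least 2 countable residues for PAAC, got {len(s)}"
        )
    counts = np.zeros((20, 20))
    for a, b in zip(s, s[1:]):
        counts[_AA_INDEX[a], _AA_INDEX[b]] += 1
    return CompositionVector("PAAC", counts.ravel() / (len(s) - 1))


def theta_factors(
    seq: str, lam: int, tables: PropertyTables | None = None
) -> np.ndarray:
    """Sequence-order correlation factors ``theta_1 .. theta_lambda``.

    ``theta_k`` averages the correlation function over all residue pairs at
    sequence separation ``k``; the correlation of two residues is the mean
    of squared differences of their three standardized properties, hence
    always non-negative.  Requires ``lam < L``.
    """
    tables = tables or default_tables()
    s = _countable(seq)
    L = len(s)
    if lam < 1:
        raise ValueError(f"lambda must be >= 1, got {lam}")
    if lam >= L:
        raise ValueError(f"lambda ({lam}) must be < countable length ({L})")
    h1 = np.array([tables.h1[ch] for ch in s])
    h2 = np.array([tables.h2[ch] for ch in s])
    m = np.array([tables.m_norm[ch] for ch in s])
    thetas = np.empty(lam)
    for k in range(1, lam + 1):
        d = (
            (h1[k:] - h1[:-k]) ** 2
            + (h2[k:] - h2[:-k]) ** 2
            + (m[k:] - m[:-k]) ** 2
        ) / 3.0
        thetas[k - 1] = d.mean()
    return thetas


def pseaac(
    seq: str | SequenceRecord,
    lam: int = 10,
    omega: float = 0.05,
    tables: PropertyTables | None = None,
) -> CompositionVector:
    """Pseudo-amino-acid composition of length ``20 + lambda``.

    With ``lam=0`` the order factors vanish and the vector equals the
    plain AAC.  The weight ``omega`` is conventionally chosen in
    [0.05, 0.7]; values outside trigger a warning but are accepted.
    """
    if not 0.05 <= omega <= 0.7:
        warnings.warn(
            f"omega={omega} is outside the conventional [0.05, 0.7] range",
            stacklevel=2,
        )
    s = _countable(seq.residues if isinstance(seq, SequenceRecord) else seq)
    if not s:
        raise ValueError("no countable residues for PseAAC")
    freqs = aac(s).values
    if lam == 0:
        return CompositionVector("PseAAC", freqs, lam=0, omega=omega)
    thetas = theta_factors(s, lam, tables)
    denom = freqs.sum() + omega * thetas.sum()
    values = np.concatenate([freqs, omega * thetas]) / denom
    return CompositionVector("PseAAC", values, lam=lam, omega=omega)


def encode_sequence(
    seq: str | SequenceRecord,
    scheme: str,
    lam: int = 10,
    omega: float = 0.05,
    tables: PropertyTables | None = None,
) -> CompositionVector:
    """Dispatch to :func:`aac`, :func:`paac` or :func:`pseaac`."""
    if scheme == "AAC":
        return aac(seq)
    if scheme == "PAAC":
        return paac(seq)
    if scheme == "PseAAC":
        return pseaac(seq, lam=lam, omega=omega, tables=tables)
    raise ValueError(f"unknown scheme {scheme!r}")


def _masked_rows(aln: Alignment, mask: ColumnMask | None) -> list[str]:
    """Alignment rows with masked columns replaced by gaps."""
    if mask is None:
        mask = aln.mask
    if mask is None:
        return list(aln.seqs)
    if len(mask) != aln.n_cols:
        raise ValueError(
            f"mask has {len(mask)} columns for alignment with {aln.n_cols}"
        )
    keep = mask.keep
    return [
        "".join(ch if keep[c] else GAP for c, ch in enumerate(row))
        for row in aln.seqs
    ]


def encode_alignment(
    aln: Alignment,
    scheme: str,
    lam: int = 10,
    omega: float = 0.05,
    tables: PropertyTables | None = None,
    mask: ColumnMask | None = None,
) -> CompositionVector:
    """Pool composition counts over every row of an alignment.

    Gaps and masked cells never contribute.  For AAC the denominator is
    the total number of counted residues over all rows; for PAAC each row
    is compacted to its countable residues before pairing, and the pooled
    pair counts are divided by the total number of pairs.  For PseAAC the
    frequencies come from pooled counts while the order factors are
    computed per row (rows shorter than ``lambda + 1`` are skipped with a
    warning) and averaged with equal weight.

    A one-row alignment therefore encodes exactly like the bare sequence
    for AAC and PAAC, and pooling is invariant to row order.
    """
    rows = [_countable(r) for r in _masked_rows(aln, mask)]
    if scheme == "AAC":
        counts = np.zeros(20)
        for row in rows:
            for ch in row:
                counts[_AA_INDEX[ch]] += 1
        total = counts.sum()
        if total == 0:
            raise ValueError("nothing countable in alignment for AAC")
        return CompositionVector("AAC", counts / total)

    if scheme == "PAAC":
        counts = np.zeros((20, 20))
        n_pairs = 0
        for row in rows:
            for a, b in zip(row, row[1:]):
                counts[_AA_INDEX[a], _AA_INDEX[b]] += 1
                n_pairs += 1
        if n_pairs == 0:
            raise ValueError("nothing countable in alignment for PAAC")
        return CompositionVector("PAAC", counts.ravel() / n_pairs)

    if scheme == "PseAAC":
        counts = np.zeros(20)
        for row in rows:
            for ch in row:
                counts[_AA_INDEX[ch]] += 1
        total = counts.sum()
        if total == 0:
            raise ValueError("nothing countable in alignment for PseAAC")
        freqs = counts / total
        if lam == 0:
            return CompositionVector("PseAAC", freqs, lam=0, omega=omega)
        tables = tables or default_tables()
        row_thetas = []
        skipped = 0
        for rid, row in zip(aln.ids, rows):
            if len(row) <= lam:
                skipped += 1
                log.warning(
                    "row %r has %d countable residues, <= lambda=%d; "
                    "skipped for order factors",
                    rid,
                    len(row),
                    lam,
                )
                continue
            row_thetas.append(theta_factors(row, lam, tables))
        if not row_thetas:
            raise ValueError(
                f"no alignment row has more than lambda={lam} countable residues"
            )
        thetas = np.mean(row_thetas, axis=0)
        denom = freqs.sum() + omega * thetas.sum()
        values = np.concatenate([freqs, omega * thetas]) / denom
        return CompositionVector("PseAAC", values, lam=lam, omega=omega)

    raise ValueError(f"unknown scheme {scheme!r}")


def feature_table(
    vectors: dict[str, CompositionVector] | Sequence[tuple[str, CompositionVector]],
) -> pd.DataFrame:
    """Tab-delimited-ready feature table: one row per sequence id."""
    items = list(vectors.items()) if isinstance(vectors, dict) else list(vectors)
    if not items:
        raise ValueError("no vectors to tabulate")
    names = items[0][1].feature_names
    scheme = items[0][1].scheme
    for sid, vec in items:
        if vec.scheme != scheme or len(vec) != len(names):
            raise ValueError(f"vector for {sid!r} does not match scheme {scheme}")
    frame = pd.DataFrame(
        [vec.values for _, vec in items],
        index=pd.Index([sid for sid, _ in items], name="seq_id"),
        columns=list(names),
    )
    return frame


def write_feature_table(
    vectors: dict[str, CompositionVector],
    path: str | Path,
    header_lines: Iterable[str] = (),
) -> None:
    path = Path(path)
    with path.open("w") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        feature_table(vectors).to_csv(fh, sep="\t")
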