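"""Deterministic synthetic data for exercising the whole pipeline offline.

Two generators are provided.  :func:`make_dataset` draws class-labelled
protein sequences whose classes differ by construction in dipeptide
composition: each class enriches a small disjoint set of ordered residue
pairs, so pair-composition vectors are separable with a margin controlled
by the enrichment factor.  :func:`make_alignment` derives an alignment
from a seed sequence by per-cell point substitution and gap placement,
with designated conserved ("TMS-like") blocks mutated at a reduced rate
so their columns earn systematically higher conservation scores.

All randomness flows through numpy's PCG64 generator under a mandatory
integer seed, so identical specs produce byte-identical outputs across
platforms.  Emitted files use exactly the formats :mod:`.seqio` consumes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .msa_pipeline import fallback_reliability
from .seqio import AMINO_ACIDS, GAP, Alignment, SequenceRecord


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of the synthetic class-labelled sequence set.

    ``enrichment`` multiplies the expected frequency of each class's
    signature dipeptides relative to the uniform baseline of 1/400; a
    factor of 1 makes classes indistinguishable in expectation.
    """

    seed: int
    n_classes: int = 3
    seqs_per_class: int = 30
    length_range: tuple[int, int] = (120, 200)
    enrichment: float = 20.0
    pairs_per_class: int = 3
    rows_per_alignment: int = 8
    substitution_rate: float = 0.08
    gap_rate: float = 0.03

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        for name in ("substitution_rate", "gap_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.enrichment < 0:
            raise ValueError("enrichment must be non-negative")
        if self.n_classes < 2:
            raise ValueError("need at least 2 classes")
        if self.n_classes * self.pairs_per_class > 200:
            raise ValueError("too many signature pairs to keep them disjoint")


def class_names(n: int) -> list[str]:
    return [f"class_{i}" for i in range(n)]


def signature_pairs(spec: FixtureSpec) -> dict[str, list[str]]:
    """Disjoint ordered dipeptide signatures per class (seed-deterministic)."""
    rng = np.random.default_rng(np.random.PCG64(spec.seed))
    all_pairs = [a + b for a in AMINO_ACIDS for b in AMINO_ACIDS]
    chosen = rng.choice(
        len(all_pairs), size=spec.n_classes * spec.pairs_per_class, replace=False
    )
    out: dict[str, list[str]] = {}
    for i, cls in enumerate(class_names(spec.n_classes)):
        idx = chosen[i * spec.pairs_per_class : (i + 1) * spec.pairs_per_class]
        out[cls] = [all_pairs[j] for j in idx]
    return out


def _draw_sequence(
    rng: np.random.Generator,
    length: int,
    pairs: list[str],
    enrichment: float,
) -> str:
    """One sequence as a token stream of uniform residues and signature pairs.

    At each step a signature dipeptide is emitted with probability chosen
    so each signature pair's expected per-position frequency is about
    ``enrichment / 400``; otherwise a uniform residue is emitted.
    """
    # Each emitted pair contributes ~2 positions; solve for token probability.
    p_pair_token = min(0.45, enrichment * len(pairs) / 400.0)
    chunks: list[str] = []
    n = 0
    while n < length:
        if pairs and rng.random() < p_pair_token:
            tok = pairs[rng.integers(len(pairs))]
        else:
            tok = AMINO_ACIDS[rng.integers(20)]
        chunks.append(tok)
        n += len(tok)
    return "".join(chunks)[:length]


def make_dataset(
    spec: FixtureSpec,
) -> tuple[list[SequenceRecord], dict[str, str]]:
    """Class-labelled sequences with class-biased dipeptide composition.

    Returns the records in generation order and a seq_id -> class map.
    Identical specs produce identical output.
    """
    rng = np.random.default_rng(np.random.PCG64(spec.seed))
    signatures = signature_pairs(spec)
    records: list[SequenceRecord] = []
    labels: dict[str, str] = {}
    lo, hi = spec.length_range
    for cls in class_names(spec.n_classes):
        for j in range(spec.seqs_per_class):
            length = int(rng.integers(lo, hi + 1))
            seq = _draw_sequence(rng, length, signatures[cls], spec.enrichment)
            sid = f"{cls}_seq{j:03d}"
            records.append(SequenceRecord(id=sid, residues=seq))
            labels[sid] = cls
    return records, labels


def make_alignment(
    seed_seq: str | SequenceRecord,
    rows: int = 8,
    substitution_rate: float = 0.08,
    gap_rate: float = 0.03,
    seed: int = 0,
    conserved_blocks: tuple[tuple[int, int], ...] = (),
    conserved_factor: float = 0.2,
    row_prefix: str = "row",
) -> Alignment:
    """Alignment of mutated copies of ``seed_seq`` with a reliability track.

    Every row (including the first) is an independent per-cell mutation of
    the seed: with ``gap_rate`` the cell becomes a gap, else with
    ``substitution_rate`` it is replaced by a different uniform residue.
    Inside ``conserved_blocks`` (1-based inclusive intervals, e.g. TMS-like
    stretches) both rates are multiplied by ``conserved_factor``, so those
    columns stay conserved and earn higher fallback reliability scores.
    The track is attached via :func:`.msa_pipeline.fallback_reliability`.
    """
    residues = (
        seed_seq.residues if isinstance(seed_seq, SequenceRecord) else seed_seq
    )
    ref_id = seed_seq.id if isinstance(seed_seq, SequenceRecord) else "seed"
    rng = np.random.default_rng(np.random.PCG64(seed))
    n = len(residues)
    in_block = np.zeros(n, dtype=bool)
    for start, end in conserved_blocks:
        if not 1 <= start <= end <= n:
            raise ValueError(f"conserved block ({start}, {end}) outside [1, {n}]")
        in_block[start - 1 : end] = True
    ids: list[str] = []
    seqs: list[str] = []
    for r in range(rows):
        cells: list[str] = []
        for i, ch in enumerate(residues):
            factor = conserved_factor if in_block[i] else 1.0
            u = rng.random()
            if u < gap_rate * factor:
                cells.append(GAP)
            elif u < (gap_rate + substitution_rate) * factor:
                alternatives = AMINO_ACIDS.replace(ch, "")
                cells.append(alternatives[rng.integers(len(alternatives))])
            else:
                cells.append(ch)
        ids.append(ref_id if r == 0 else f"{row_prefix}{r:02d}")
        seqs.append("".join(cells))
    aln = Alignment(ids=ids, seqs=seqs)
    return fallback_reliability(aln)
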