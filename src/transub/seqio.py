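"""Readers and writers for the file formats the pipeline touches.

Formats handled here: FASTA protein sequences, aligned FASTA / ClustalW
multiple sequence alignments, T-Coffee ``score_ascii``-style per-residue
reliability reports, tab-delimited transmembrane-segment (TMS) interval
annotations, and tab-delimited class-label tables.

All sequence coordinates at this interface are 1-based inclusive, matching
the UniProt/TOPCONS convention.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO

log = logging.getLogger(__name__)

#: Canonical alphabetical order of the 20 natural amino acids.
AMINO_ACIDS: str = "ACDEFGHIKLMNPQRSTVWY"

_AA_SET = frozenset(AMINO_ACIDS)

#: Ambiguity / non-standard codes that are not counted in compositions.
NONSTANDARD: frozenset[str] = frozenset("BJOUXZ")

GAP = "-"

#: The seven transported-substrate categories.
SUBSTRATE_CLASSES: tuple[str, ...] = (
    "amino_acid",
    "anion",
    "cation",
    "electron",
    "protein_mrna",
    "sugar",
    "other",
)


@dataclass(frozen=True)
class SequenceRecord:
    """One protein sequence: identifier plus residue string."""

    id: str
    residues: str

    def __post_init__(self) -> None:
        if not self.residues:
            raise ValueError(f"sequence {self.id!r}: empty residue string")
        bad = set(self.residues) - _AA_SET
        if bad:
            raise ValueError(
                f"sequence {self.id!r}: residues outside the 20-letter "
                f"alphabet: {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.residues)


@dataclass
class ColumnMask:
    """Per-column keep/drop decision derived from a reliability track."""

    keep: list[bool]
    threshold: int

    def __post_init__(self) -> None:
        if not 0 <= self.threshold <= 10:
            raise ValueError(f"threshold must be in [0, 10], got {self.threshold}")

    @property
    def n_kept(self) -> int:
        return sum(self.keep)

    def __len__(self) -> int:
        return len(self.keep)


@dataclass
class Alignment:
    """Rectangular gapped alignment with an optional column reliability track.

    ``rows`` maps identifiers to gapped strings of identical length.
    ``reliability``, when present, holds one integer in [0, 9] per column.
    ``mask`` records which columns a reliability filter kept, so that
    filtered alignments stay index-compatible with the unfiltered one.
    """

    ids: list[str]
    seqs: list[str]
    reliability: list[int] | None = None
    reliability_source: str | None = None
    mask: ColumnMask | None = None

    def __post_init__(self) -> None:
        if not self.ids:
            raise ValueError("alignment has no rows")
        if len(self.ids) != len(self.seqs):
            raise ValueError("ids and seqs differ in length")
        n = len(self.seqs[0])
        for rid, s in zip(self.ids, self.seqs):
            if len(s) != n:
                raise ValueError(
                    f"ragged alignment: row {rid!r} has length {len(s)}, "
                    f"expected {n} (row {self.ids[0]!r})"
                )
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("duplicate row identifiers in alignment")
        if self.reliability is not None:
            self._check_reliability(self.reliability)

    def _check_reliability(self, track: Sequence[int]) -> None:
        if len(track) != self.n_cols:
            raise ValueError(
                f"reliability track has {len(track)} entries for "
                f"{self.n_cols} columns"
            )
        for c, v in enumerate(track):
            if not 0 <= int(v) <= 9:
                raise ValueError(f"reliability at column {c + 1} out of [0, 9]: {v}")

    @property
    def n_rows(self) -> int:
        return len(self.ids)

    @property
    def n_cols(self) -> int:
        return len(self.seqs[0])

    def row(self, rid: str) -> str:
        try:
            return self.seqs[self.ids.index(rid)]
        except ValueError:
            raise KeyError(f"no alignment row with id {rid!r}") from None

    def column(self, c: int) -> str:
        """Column ``c`` (0-based) as a string over rows."""
        return "".join(s[c] for s in self.seqs)


@dataclass(frozen=True)
class TmsAnnotation:
    """Transmembrane segments of one protein on its ungapped sequence.

    ``intervals`` are 1-based inclusive ``(start, end)`` pairs, sorted and
    non-overlapping.  ``kind`` distinguishes alpha-helical from beta-barrel
    segments.
    """

    seq_id: str
    intervals: tuple[tuple[int, int], ...]
    kind: str = "alpha"

    def __post_init__(self) -> None:
        if self.kind not in ("alpha", "beta"):
            raise ValueError(f"TMS kind must be 'alpha' or 'beta', got {self.kind!r}")
        prev_end = 0
        for start, end in self.intervals:
            if start < 1 or start > end:
                raise ValueError(
                    f"{self.seq_id}: invalid interval ({start}, {end})"
                )
            if start <= prev_end:
                raise ValueError(
                    f"{self.seq_id}: overlapping or unsorted intervals at "
                    f"({start}, {end})"
                )
            prev_end = end


def normalize_residues(raw: str, seq_id: str, policy: str = "drop") -> str:
    """Uppercase ``raw`` and apply the non-standard residue policy.

    ``policy='drop'`` removes B/J/O/U/X/Z (and ``*``/gap characters) with a
    logged warning; ``policy='strict'`` raises on the first such character,
    reporting its 1-based position.
    """
    if policy not in ("drop", "strict"):
        raise ValueError(f"unknown residue policy {policy!r}")
    seq = raw.upper().replace("*", "").replace(GAP, "").replace(".", "")
    kept: list[str] = []
    dropped: list[tuple[int, str]] = []
    for pos, ch in enumerate(seq, start=1):
        if ch in _AA_SET:
            kept.append(ch)
        elif ch in NONSTANDARD:
            if policy == "strict":
                raise ValueError(
                    f"sequence {seq_id!r}: non-standard residue {ch!r} at "
                    f"position {pos}"
                )
            dropped.append((pos, ch))
        else:
            raise ValueError(
                f"sequence {seq_id!r}: invalid character {ch!r} at position {pos}"
            )
    if dropped:
        log.warning(
            "sequence %r: dropped %d non-standard residue(s): %s",
            seq_id,
            len(dropped),
            ", ".join(f"{ch}@{pos}" for pos, ch in dropped[:5]),
        )
    return "".join(kept)


def read_fasta(path: str | Path, policy: str = "drop") -> list[SequenceRecord]:
    """Read protein sequences from a FASTA file.

    Residues are uppercased; non-standard codes follow ``policy`` (see
    :func:`normalize_residues`).  Record order is preserved.  Duplicate
    identifiers and empty files are errors.
    """
    path = Path(path)
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"{path}: duplicate sequence identifier {rec.id!r}")
        seen.add(rec.id)
        residues = normalize_residues(str(rec.seq), rec.id, policy=policy)
        records.append(SequenceRecord(id=rec.id, residues=residues))
    if not records:
        raise ValueError(f"{path}: no FASTA records found")
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path, width: int = 60) -> None:
    """Write records as FASTA with fixed line width."""
    path = Path(path)
    with path.open("w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.residues), width):
                fh.write(rec.residues[i : i + width] + "\n")


def read_alignment(path: str | Path) -> Alignment:
    """Read an aligned FASTA or ClustalW-style alignment.

    Rows must all have the same length; a ragged file is an error naming
    the offending row.  No reliability track is attached.
    """
    path = Path(path)
    text = path.read_text()
    if not text.strip():
        raise ValueError(f"{path}: empty alignment file")
    if text.lstrip().startswith(">"):
        ids, seqs = _parse_fasta_rows(text, path)
    else:
        ids, seqs = _parse_clustal_rows(text, path)
    for rid, s in zip(ids, seqs):
        if len(s) != len(seqs[0]):
            raise ValueError(
                f"{path}: ragged alignment: row {ids[0]!r} has length "
                f"{len(seqs[0])} but row {rid!r} has length {len(s)}"
            )
    return Alignment(ids=ids, seqs=seqs)


def _parse_fasta_rows(text: str, path: Path) -> tuple[list[str], list[str]]:
    ids: list[str] = []
    seqs: list[str] = []
    cur: list[str] = []
    for line in text.splitlines():
        if line.startswith(">"):
            if ids:
                seqs.append("".join(cur))
            ids.append(line[1:].split()[0])
            cur = []
        elif line.strip():
            cur.append(line.strip().upper())
    if ids:
        seqs.append("".join(cur))
    if not ids:
        raise ValueError(f"{path}: no alignment rows found")
    return ids, seqs


def _parse_clustal_rows(text: str, path: Path) -> tuple[list[str], list[str]]:
    chunks: dict[str, list[str]] = {}
    order: list[str] = []
    for line in text.splitlines():
        if line.startswith(("CLUSTAL", "MUSCLE")) or not line.strip():
            continue
        if line.startswith((" ", "\t")):  # conservation line
            continue
        parts = line.split()
        if len(parts) < 2:
            continue
        rid, block = parts[0], parts[1]
        if rid not in chunks:
            chunks[rid] = []
            order.append(rid)
        chunks[rid].append(block.upper())
    if not order:
        raise ValueError(f"{path}: no alignment rows found")
    return order, ["".join(chunks[r]) for r in order]


def write_alignment(aln: Alignment, path: str | Path, width: int = 60) -> None:
    """Write an alignment as aligned FASTA."""
    path = Path(path)
    with path.open("w") as fh:
        for rid, s in zip(aln.ids, aln.seqs):
            fh.write(f">{rid}\n")
            for i in range(0, len(s), width):
                fh.write(s[i : i + width] + "\n")


_SCORE_ROW = re.compile(r"^(\S+)\s*:?\s+([0-9\-]+)\s*$")


def read_reliability(path: str | Path, aln: Alignment) -> Alignment:
    """Attach per-column reliability scores from a ``score_ascii`` report.

    The report is block-formatted: each row is ``id [:] digits`` where the
    digits (0-9, with '-' over gaps) accumulate across blocks to alignment
    length.  The ``cons`` row supplies the per-column track; when no
    consensus row is present the track is derived as the rounded mean of
    per-residue digits in each column.  Score rows must match the alignment
    ids and its column count; rows are matched by id, never by order.
    """
    path = Path(path)
    rows: dict[str, str] = {}
    for line in path.read_text().splitlines():
        if not line.strip() or line.startswith(("T-COFFEE", "SCORE", "BAD", "AVG", "*")):
            continue
        m = _SCORE_ROW.match(line)
        if not m:
            continue
        rid, digits = m.group(1), m.group(2)
        rows[rid] = rows.get(rid, "") + digits

    cons = rows.pop("cons", None)
    expected = set(aln.ids)
    got = set(rows)
    if got != expected:
        missing = sorted(expected - got)
        extra = sorted(got - expected)
        raise ValueError(
            f"{path}: score rows do not match alignment ids "
            f"(missing: {missing or 'none'}, unexpected: {extra or 'none'})"
        )
    for rid, digits in rows.items():
        if len(digits) != aln.n_cols:
            raise ValueError(
                f"{path}: score row {rid!r} has {len(digits)} entries for "
                f"{aln.n_cols} columns"
            )

    if cons is not None:
        if len(cons) != aln.n_cols:
            raise ValueError(
                f"{path}: consensus row has {len(cons)} entries for "
                f"{aln.n_cols} columns"
            )
        track = [0 if ch == GAP else int(ch) for ch in cons]
    else:
        track = []
        for c in range(aln.n_cols):
            vals = [int(rows[rid][c]) for rid in aln.ids if rows[rid][c] != GAP]
            track.append(int(_round_half_up(sum(vals) / len(vals))) if vals else 0)
    return Alignment(
        ids=list(aln.ids),
        seqs=list(aln.seqs),
        reliability=track,
        reliability_source="tcs",
    )


def _round_half_up(x: float) -> int:
    import math

    return int(math.floor(x + 0.5))


def write_reliability(aln: Alignment, path: str | Path, width: int = 60) -> None:
    """Write a minimal ``score_ascii``-style report for ``aln``.

    Per-residue digits are not tracked internally, so each row repeats the
    column track (with '-' over that row's gaps) and a ``cons`` row carries
    the column scores.
    """
    if aln.reliability is None:
        raise ValueError("alignment has no reliability track to write")
    path = Path(path)
    track = "".join(str(v) for v in aln.reliability)
    with path.open("w") as fh:
        fh.write("T-COFFEE, score_ascii-style column reliability\n\n")
        for start in range(0, aln.n_cols, width):
            stop = min(start + width, aln.n_cols)
            for rid, s in zip(aln.ids, aln.seqs):
                digits = "".join(
                    GAP if s[c] == GAP else track[c] for c in range(start, stop)
                )
                fh.write(f"{rid} : {digits}\n")
            fh.write(f"cons : {track[start:stop]}\n\n")


def read_tms_intervals(path: str | Path) -> list[TmsAnnotation]:
    """Read tab-delimited TMS intervals: ``seq_id  start  end  kind``.

    Lines are grouped per sequence; intervals are sorted and validated
    (1-based inclusive, non-overlapping, start <= end).  A sequence must
    carry a single segment kind.
    """
    path = Path(path)
    per_seq: dict[str, list[tuple[int, int]]] = {}
    kinds: dict[str, str] = {}
    order: list[str] = []
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.split()
        if len(parts) != 4:
            raise ValueError(f"{path}:{lineno}: expected 'seq_id start end kind'")
        sid, start_s, end_s, kind = parts
        start, end = int(start_s), int(end_s)
        if start > end:
            raise ValueError(
                f"{path}:{lineno}: interval start {start} > end {end} for {sid!r}"
            )
        if sid not in per_seq:
            per_seq[sid] = []
            kinds[sid] = kind
            order.append(sid)
        elif kinds[sid] != kind:
            raise ValueError(f"{path}:{lineno}: mixed TMS kinds for {sid!r}")
        per_seq[sid].append((start, end))
    annotations = []
    for sid in order:
        intervals = tuple(sorted(per_seq[sid]))
        annotations.append(TmsAnnotation(seq_id=sid, intervals=intervals, kind=kinds[sid]))
    return annotations


def write_tms_intervals(annotations: Iterable[TmsAnnotation], path: str | Path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        for ann in annotations:
            for start, end in ann.intervals:
                fh.write(f"{ann.seq_id}\t{start}\t{end}\t{ann.kind}\n")


def read_labels(path: str | Path, allowed: Iterable[str] | None = None) -> dict[str, str]:
    """Read a tab-delimited ``seq_id  class`` table into an ordered dict."""
    path = Path(path)
    allowed_set = set(allowed) if allowed is not None else None
    labels: dict[str, str] = {}
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.split()
        if len(parts) != 2:
            raise ValueError(f"{path}:{lineno}: expected 'seq_id class'")
        sid, cls = parts
        if sid in labels:
            raise ValueError(f"{path}:{lineno}: duplicate label for {sid!r}")
        if allowed_set is not None and cls not in allowed_set:
            raise ValueError(
                f"{path}:{lineno}: unknown class {cls!r}; expected one of "
                f"{sorted(allowed_set)}"
            )
        labels[sid] = cls
    if not labels:
        raise ValueError(f"{path}: no labels found")
    return labels


def write_labels(labels: dict[str, str], path: str | Path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        for sid, cls in labels.items():
            fh.write(f"{sid}\t{cls}\n")
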