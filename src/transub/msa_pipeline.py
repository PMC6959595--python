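"""Positional filtering of alignments and external-tool contracts.

The evolutionary step of the pipeline (homolog retrieval, TM-Coffee
alignment, TCS evaluation) runs through external binaries and is consumed
via files; this module documents the exact commands and offers an opt-in
runner.  The positional step — discarding alignment columns whose
reliability index falls below a threshold — is implemented here, together
with a conservation-based fallback reliability score so the whole
pipeline can run offline.
"""

from __future__ import annotations

import math
import shutil
import subprocess
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

from .seqio import (
    GAP,
    Alignment,
    ColumnMask,
    read_alignment,
    read_reliability,
    write_fasta,
)

__all__ = [
    "ColumnMask",
    "filter_alignment",
    "fallback_reliability",
    "write_mask_sidecar",
    "external_msa_contract",
    "run_external_stage",
    "ToolResult",
]

DEFAULT_THRESHOLD = 4


def column_mask(reliability: Sequence[int], threshold: int = DEFAULT_THRESHOLD) -> ColumnMask:
    """Keep exactly the columns whose reliability index is >= threshold."""
    return ColumnMask(keep=[int(v) >= threshold for v in reliability], threshold=threshold)


def filter_alignment(aln: Alignment, threshold: int = DEFAULT_THRESHOLD) -> Alignment:
    """Gap out the columns whose reliability index falls below ``threshold``.

    The returned alignment has identical shape: every cell of a removed
    column becomes a gap, kept columns are untouched, and the column mask
    is retained so positions remain mappable to the unfiltered alignment.
    The reliability track is carried over unchanged, which makes the
    operation idempotent at a fixed threshold.
    """
    if aln.reliability is None:
        raise ValueError("filter_alignment requires a reliability track")
    mask = column_mask(aln.reliability, threshold)
    keep = mask.keep
    seqs = [
        "".join(ch if keep[c] else GAP for c, ch in enumerate(row))
        for row in aln.seqs
    ]
    return Alignment(
        ids=list(aln.ids),
        seqs=seqs,
        reliability=list(aln.reliability),
        reliability_source=aln.reliability_source,
        mask=mask,
    )


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def fallback_reliability(aln: Alignment) -> Alignment:
    """Attach a conservation-based column reliability track.

    Score of a column = round-half-up of ``9 *`` (fraction of rows carrying
    the column's modal non-gap residue); an all-gap column scores 0.  This
    is a simple conservation index for offline runs and is labelled
    ``"fallback"`` in the alignment's provenance so it is never mistaken
    for a consistency-based (TCS) score.
    """
    n_rows = aln.n_rows
    track: list[int] = []
    for c in range(aln.n_cols):
        col = aln.column(c)
        residues = [ch for ch in col if ch != GAP]
        if not residues:
            track.append(0)
            continue
        modal = max(set(residues), key=residues.count)
        track.append(_round_half_up(9.0 * residues.count(modal) / n_rows))
    return Alignment(
        ids=list(aln.ids),
        seqs=list(aln.seqs),
        reliability=track,
        reliability_source="fallback",
        mask=aln.mask,
    )


def write_mask_sidecar(aln: Alignment, path: str | Path) -> None:
    """Write a ``column  score  kept`` tab-delimited sidecar (1-based columns)."""
    if aln.reliability is None:
        raise ValueError("alignment has no reliability track")
    mask = aln.mask or column_mask(aln.reliability, DEFAULT_THRESHOLD)
    with Path(path).open("w") as fh:
        fh.write("column\tscore\tkept\n")
        for c, (score, kept) in enumerate(zip(aln.reliability, mask.keep), start=1):
            fh.write(f"{c}\t{score}\t{int(kept)}\n")


@dataclass(frozen=True)
class Stage:
    """One external pipeline stage: a command and its expected output."""

    name: str
    command: list[str]
    output: str
    description: str


@dataclass
class ToolResult:
    """Outcome of an opt-in external stage run."""

    stage: str
    status: str  # "ok" | "tool unavailable" | "failed"
    detail: str = ""
    output_path: Path | None = None


def external_msa_contract(
    query_fasta: str | Path,
    workdir: str | Path = ".",
    max_homologs: int = 120,
    protein_db: str = "swissprot",
) -> list[Stage]:
    """Describe the three external stages of the evolutionary/positional step.

    Nothing is executed.  The stages are (1) homolog retrieval by sequence
    search against a protein database, capped at ``max_homologs`` hits,
    (2) transmembrane-aware alignment with TM-Coffee in PSI-Coffee mode,
    and (3) TCS evaluation producing per-column reliability indices.
    Output filenames are the conventional ones parsed by :mod:`.seqio`.
    """
    query = str(query_fasta)
    wd = Path(workdir)
    hits = str(wd / "homologs.fasta")
    aln = str(wd / "myMSA.aln")
    return [
        Stage(
            name="homolog-search",
            command=[
                "blastp",
                "-query", query,
                "-db", protein_db,
                "-max_target_seqs", str(max_homologs),
                "-outfmt", "6 sseqid",
                "-out", str(wd / "homolog_ids.txt"),
            ],
            output=hits,
            description=(
                f"retrieve at most {max_homologs} homologous sequences from "
                f"{protein_db}; fetch their sequences into homologs.fasta "
                "(query included; exact test-set hits must be removed from "
                "the search database beforehand)"
            ),
        ),
        Stage(
            name="tm-coffee-align",
            command=[
                "t_coffee", hits,
                "-mode", "psicoffee",
                "-protein_db", "uniref50", "-TM",
                "-template_file", "PSITM",
                "-outfile", aln,
            ],
            output=aln,
            description="transmembrane-aware multiple sequence alignment",
        ),
        Stage(
            name="tcs-evaluate",
            command=[
                "t_coffee",
                "-infile", aln,
                "-evaluate",
                "-output", "score_ascii",
            ],
            output=str(wd / "myMSA.score_ascii"),
            description="per-column reliability indices (0-9) for filtering",
        ),
    ]


def run_external_stage(stage: Stage, timeout: float | None = None) -> ToolResult:
    """Opt-in execution of one contract stage.

    A missing binary is reported as ``"tool unavailable"``; a non-zero exit
    as ``"failed"`` with captured stderr.  Outputs are parsed separately by
    the caller through :mod:`.seqio`.
    """
    exe = stage.command[0]
    if shutil.which(exe) is None:
        return ToolResult(stage=stage.name, status="tool unavailable", detail=exe)
    try:
        proc = subprocess.run(
            stage.command,
            capture_output=True,
            text=True,
            timeout=timeout,
            check=False,
        )
    except subprocess.TimeoutExpired:
        return ToolResult(stage=stage.name, status="failed", detail="timeout")
    if proc.returncode != 0:
        return ToolResult(
            stage=stage.name,
            status="failed",
            detail=proc.stderr.strip()[-500:],
        )
    return ToolResult(
        stage=stage.name,
        status="ok",
        output_path=Path(stage.output),
    )


def run_evolutionary_step(
    query_fasta: str | Path,
    workdir: str | Path,
    max_homologs: int = 120,
    protein_db: str = "swissprot",
) -> tuple[list[ToolResult], Alignment | None]:
    """Run all contract stages and parse the scored alignment if they succeed."""
    stages = external_msa_contract(query_fasta, workdir, max_homologs, protein_db)
    results: list[ToolResult] = []
    for stage in stages:
        res = run_external_stage(stage)
        results.append(res)
        if res.status != "ok":
            return results, None
    aln = read_alignment(stages[1].output)
    aln = read_reliability(stages[2].output, aln)
    return results, aln
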