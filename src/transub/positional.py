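"""Where do the informative alignment columns fall on the protein?

This module maps reliability-filtered alignment columns back to ungapped
positions of a reference sequence, partitions those positions by their
relation to annotated transmembrane segments (TMS) — interior third of a
TMS, remaining TMS exterior, non-TMS within a margin of a TMS ("close"),
and the rest ("far") — and compares informative-position rates between
segment kinds with a paired two-tailed t-test.  It also computes the
per-column Kyte-Doolittle hydropathy profile of an alignment for
visualizing informative regions against membrane-spanning ones.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from .properties import KYTE_DOOLITTLE
from .seqio import GAP, Alignment, ColumnMask, TmsAnnotation

SEGMENT_KINDS = ("tms_interior", "tms_exterior", "nontms_close", "nontms_far")

#: Aggregate segment groupings reported alongside the four base kinds.
AGGREGATES = {
    "tms": ("tms_interior", "tms_exterior"),
    "nontms": ("nontms_close", "nontms_far"),
}


@dataclass(frozen=True)
class SegmentPartition:
    """Per-position segment labels for one protein (1-based positions)."""

    seq_id: str
    labels: tuple[str, ...]

    def __post_init__(self) -> None:
        bad = set(self.labels) - set(SEGMENT_KINDS)
        if bad:
            raise ValueError(f"unknown segment labels: {sorted(bad)}")

    @property
    def seq_len(self) -> int:
        return len(self.labels)

    def positions(self, kind: str) -> list[int]:
        """1-based positions carrying ``kind`` (or an aggregate name)."""
        kinds = AGGREGATES.get(kind, (kind,))
        return [p for p, lbl in enumerate(self.labels, start=1) if lbl in kinds]


def map_informative_to_sequence(
    aln: Alignment, mask: ColumnMask, ref_id: str
) -> set[int]:
    """Ungapped reference positions whose alignment column is kept.

    Position ``p`` (1-based) of the ungapped reference sequence is
    informative exactly when the column holding it survives the
    reliability filter.
    """
    row = aln.row(ref_id)  # raises KeyError if absent
    if len(mask) != aln.n_cols:
        raise ValueError(
            f"mask has {len(mask)} columns for alignment with {aln.n_cols}"
        )
    informative: set[int] = set()
    pos = 0
    for c, ch in enumerate(row):
        if ch == GAP:
            continue
        pos += 1
        if mask.keep[c]:
            informative.add(pos)
    return informative


def partition_positions(
    seq_len: int, tms: TmsAnnotation, margin: int = 10
) -> SegmentPartition:
    """Label every position of a sequence by its relation to the TMSs.

    For a TMS of length ``m`` the interior is the central
    ``q = max(1, round(m / 3))`` positions starting at
    ``start + floor((m - q) / 2)``; the remaining TMS positions are
    exterior.  Non-TMS positions within ``margin`` of the nearest TMS
    residue are close, the rest far.  With no TMS everything is far.
    """
    for start, end in tms.intervals:
        if end > seq_len:
            raise ValueError(
                f"{tms.seq_id}: interval ({start}, {end}) exceeds length {seq_len}"
            )
    labels = ["nontms_far"] * seq_len
    in_tms = [False] * seq_len
    for start, end in tms.intervals:
        m = end - start + 1
        q = max(1, round(m / 3))
        int_start = start + (m - q) // 2
        for p in range(start, end + 1):
            in_tms[p - 1] = True
            if int_start <= p <= int_start + q - 1:
                labels[p - 1] = "tms_interior"
            else:
                labels[p - 1] = "tms_exterior"
    if tms.intervals and margin > 0:
        tms_positions = [p for p in range(1, seq_len + 1) if in_tms[p - 1]]
        for p in range(1, seq_len + 1):
            if in_tms[p - 1]:
                continue
            dist = min(abs(p - t) for t in tms_positions)
            if dist <= margin:
                labels[p - 1] = "nontms_close"
    return SegmentPartition(seq_id=tms.seq_id, labels=tuple(labels))


@dataclass(frozen=True)
class RateRecord:
    """Informative-position counts and percentage rates per segment kind.

    ``rates`` maps each base and aggregate segment kind to
    ``(n_positions, n_informative, rate_percent)``; the rate is NaN when
    the segment is empty.
    """

    seq_id: str
    rates: dict[str, tuple[int, int, float]]

    def rate(self, kind: str) -> float:
        return self.rates[kind][2]


def informative_rates(
    partition: SegmentPartition, informative: set[int]
) -> RateRecord:
    """Percentage of informative positions in each segment kind."""
    out_of_range = {p for p in informative if not 1 <= p <= partition.seq_len}
    if out_of_range:
        raise ValueError(
            f"{partition.seq_id}: informative positions outside sequence: "
            f"{sorted(out_of_range)[:5]}"
        )
    rates: dict[str, tuple[int, int, float]] = {}
    for kind in list(SEGMENT_KINDS) + list(AGGREGATES):
        positions = partition.positions(kind)
        count = len(positions)
        hit = sum(1 for p in positions if p in informative)
        rate = 100.0 * hit / count if count else math.nan
        rates[kind] = (count, hit, rate)
    return RateRecord(seq_id=partition.seq_id, rates=rates)


@dataclass(frozen=True)
class PairedTestResult:
    t: float
    p: float
    n: int
    mean_x: float
    sd_x: float
    mean_y: float
    sd_y: float

    def __str__(self) -> str:
        return (
            f"x = {self.mean_x:.2f}+/-{self.sd_x:.2f}, "
            f"y = {self.mean_y:.2f}+/-{self.sd_y:.2f}, "
            f"t({self.n - 1}) = {self.t:.3f}, two-tailed p = {self.p:.4g}"
        )


def paired_t_test(
    x: Sequence[float], y: Sequence[float]
) -> PairedTestResult:
    """Two-tailed paired Student t-test on rate samples.

    Pairs containing an undefined (NaN) rate are dropped, so proteins
    lacking one segment kind never contribute a fabricated zero.  All-zero
    differences give t = 0, p = 1; a nonzero constant shift with zero
    difference variance is degenerate and raises.
    """
    if len(x) != len(y):
        raise ValueError("paired samples must have equal length")
    xs, ys = [], []
    for xi, yi in zip(x, y):
        if math.isnan(xi) or math.isnan(yi):
            continue
        xs.append(float(xi))
        ys.append(float(yi))
    n = len(xs)
    if n < 2:
        raise ValueError(f"need at least 2 complete pairs, got {n}")
    xa, ya = np.array(xs), np.array(ys)
    d = xa - ya
    mean_d = d.mean()
    sd_d = d.std(ddof=1)
    if sd_d == 0.0:
        if mean_d == 0.0:
            t, p = 0.0, 1.0
        else:
            raise ValueError(
                "degenerate paired test: constant nonzero difference "
                "(zero variance)"
            )
    else:
        t = mean_d / (sd_d / math.sqrt(n))
        p = 2.0 * stats.t.sf(abs(t), df=n - 1)
    return PairedTestResult(
        t=float(t),
        p=float(p),
        n=n,
        mean_x=float(xa.mean()),
        sd_x=float(xa.std(ddof=1)),
        mean_y=float(ya.mean()),
        sd_y=float(ya.std(ddof=1)),
    )


def compare_segments(
    records: Iterable[RateRecord], kind_x: str, kind_y: str
) -> PairedTestResult:
    """Paired test of per-protein rates between two segment kinds."""
    recs = list(records)
    return paired_t_test(
        [r.rate(kind_x) for r in recs],
        [r.rate(kind_y) for r in recs],
    )


@dataclass(frozen=True)
class HydropathyProfile:
    """Per-column mean hydropathy with reliability and kept flags."""

    mean_hydropathy: tuple[float, ...]  # NaN for all-gap columns
    reliability: tuple[int, ...] | None
    kept: tuple[bool, ...] | None

    def __len__(self) -> int:
        return len(self.mean_hydropathy)


def column_hydropathy(
    aln: Alignment, mask: ColumnMask | None = None
) -> HydropathyProfile:
    """Mean Kyte-Doolittle hydropathy of each alignment column.

    The mean runs over non-gap residues with a scale entry; an all-gap
    column is NaN.  Positive column means point at hydrophobic, likely
    membrane-embedded stretches.  The profile carries the alignment's
    reliability track and the filter's kept flags when available, so
    informative columns can be highlighted against the hydropathy trace.
    """
    mask = mask or aln.mask
    means: list[float] = []
    for c in range(aln.n_cols):
        vals = [
            KYTE_DOOLITTLE[ch]
            for ch in aln.column(c)
            if ch != GAP and ch in KYTE_DOOLITTLE
        ]
        means.append(sum(vals) / len(vals) if vals else math.nan)
    return HydropathyProfile(
        mean_hydropathy=tuple(means),
        reliability=tuple(aln.reliability) if aln.reliability is not None else None,
        kept=tuple(mask.keep) if mask is not None else None,
    )


def write_hydropathy_profile(profile: HydropathyProfile, path: str | Path) -> None:
    """Tab-delimited export: column, mean hydropathy, reliability, kept."""
    with Path(path).open("w") as fh:
        fh.write("column\tmean_hydropathy\treliability\tkept\n")
        for c in range(len(profile)):
            h = profile.mean_hydropathy[c]
            rel = profile.reliability[c] if profile.reliability is not None else ""
            kept = (
                int(profile.kept[c]) if profile.kept is not None else ""
            )
            fh.write(f"{c + 1}\t{'' if math.isnan(h) else f'{h:.4f}'}\t{rel}\t{kept}\n")


def write_rate_table(records: Iterable[RateRecord], path: str | Path) -> None:
    """Per-protein segment rate table (counts and percentage rates)."""
    kinds = list(SEGMENT_KINDS) + list(AGGREGATES)
    with Path(path).open("w") as fh:
        header = ["seq_id"]
        for kind in kinds:
            header += [f"{kind}_n", f"{kind}_informative", f"{kind}_rate"]
        fh.write("\t".join(header) + "\n")
        for rec in records:
            row = [rec.seq_id]
            for kind in kinds:
                count, hit, rate = rec.rates[kind]
                row += [str(count), str(hit), "" if math.isnan(rate) else f"{rate:.2f}"]
            fh.write("\t".join(row) + "\n")


def plot_hydropathy(profile: HydropathyProfile, path: str | Path, title: str = "") -> None:
    """Render the hydropathy profile with informative columns highlighted.

    Requires matplotlib (optional dependency).
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    x = np.arange(1, len(profile) + 1)
    y = np.array(profile.mean_hydropathy)
    fig, ax = plt.subplots(figsize=(10, 3))
    if profile.kept is not None:
        kept = np.array(profile.kept)
        for start, stop in _runs(kept):
            ax.axvspan(start + 0.5, stop + 1.5, color="red", alpha=0.2, lw=0)
    ax.plot(x, y, lw=0.8, color="black")
    ax.axhline(0.0, color="gray", lw=0.5)
    ax.set_xlabel("alignment column")
    ax.set_ylabel("mean hydropathy")
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def _runs(flags: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of True as (start, stop) 0-based inclusive indices."""
    runs = []
    start = None
    for i, f in enumerate(flags):
        if f and start is None:
            start = i
        elif not f and start is not None:
            runs.append((start, i - 1))
            start = None
    if start is not None:
        runs.append((start, len(flags) - 1))
    return runs
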