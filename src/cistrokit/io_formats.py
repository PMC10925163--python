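"""Readers and writers for the genomic text formats the pipeline touches.

Every coordinate in the package is 0-based half-open (BED convention).
A 1-based closed interval ``(a, b)`` converts to ``(a - 1, b)``.
narrowPeak summits are stored as an offset from ``start`` and resolved to an
absolute position on demand.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import numpy as np
import pandas as pd
from Bio import SeqIO

__all__ = [
    "GenomicInterval",
    "PeakSet",
    "SignalTrack",
    "SequenceStore",
    "read_bed",
    "write_bed",
    "read_fasta",
    "write_fasta",
    "read_bedgraph",
    "write_bedgraph",
    "read_guide_counts",
    "write_guide_counts",
]

_VALID_STRANDS = {"+", "-", "."}
# anything outside the unambiguous alphabet is normalised to N so the
# scanner is total over its input
_NON_ACGT = re.compile(r"[^ACGTN]")


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A 0-based half-open genomic interval.

    ``summit_offset`` is the narrowPeak column-10 convention: bp offset of the
    point-source summit from ``start``, or ``None`` when absent.
    """

    chrom: str
    start: int
    end: int
    name: str = "."
    score: float = 0.0
    strand: str = "."
    summit_offset: int | None = None

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if self.end <= self.start:
            raise ValueError(
                f"end must exceed start: got [{self.start}, {self.end}) on {self.chrom}"
            )
        if self.strand not in _VALID_STRANDS:
            raise ValueError(f"strand must be one of +, -, . (got {self.strand!r})")
        if self.summit_offset is not None and not (
            0 <= self.summit_offset < self.end - self.start
        ):
            raise ValueError(
                f"summit_offset {self.summit_offset} outside [0, {self.end - self.start})"
            )

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def summit(self) -> int:
        """Absolute summit position; interval midpoint when no summit is recorded."""
        if self.summit_offset is not None:
            return self.start + self.summit_offset
        return (self.start + self.end) // 2

    @property
    def center(self) -> int:
        return (self.start + self.end) // 2


@dataclass
class PeakSet:
    """A named, ordered collection of genomic intervals.

    Input order is preserved; duplicates are permitted on input and removed by
    merge operations.
    """

    label: str = ""
    intervals: list[GenomicInterval] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.intervals)

    def __iter__(self) -> Iterator[GenomicInterval]:
        return iter(self.intervals)

    def __getitem__(self, i: int) -> GenomicInterval:
        return self.intervals[i]

    def sorted(self) -> "PeakSet":
        return PeakSet(
            self.label,
            sorted(self.intervals, key=lambda iv: (iv.chrom, iv.start, iv.end)),
        )

    def total_bp(self) -> int:
        return sum(len(iv) for iv in self.intervals)

    def with_label(self, label: str) -> "PeakSet":
        return PeakSet(label, list(self.intervals))


class SignalTrack:
    """Step-function genome signal with bedGraph semantics.

    Per chromosome the track holds sorted, non-overlapping ``(start, end, value)``
    steps; positions not covered by a step have value 0.
    """

    def __init__(self, steps: Mapping[str, Iterable[tuple[int, int, float]]] | None = None):
        self._chroms: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
        if steps:
            for chrom, rows in steps.items():
                self.set_chrom(chrom, rows)

    def set_chrom(self, chrom: str, rows: Iterable[tuple[int, int, float]]) -> None:
        arr = sorted(rows)
        starts = np.array([r[0] for r in arr], dtype=np.int64)
        ends = np.array([r[1] for r in arr], dtype=np.int64)
        values = np.array([r[2] for r in arr], dtype=float)
        if np.any(ends <= starts):
            raise ValueError(f"{chrom}: step with end <= start")
        if np.any(starts[1:] < ends[:-1]):
            raise ValueError(f"{chrom}: overlapping steps")
        if not np.all(np.isfinite(values)):
            raise ValueError(f"{chrom}: non-finite signal value")
        self._chroms[chrom] = (starts, ends, values)

    @property
    def chroms(self) -> list[str]:
        return list(self._chroms)

    def steps(self, chrom: str) -> list[tuple[int, int, float]]:
        if chrom not in self._chroms:
            return []
        s, e, v = self._chroms[chrom]
        return [(int(a), int(b), float(c)) for a, b, c in zip(s, e, v)]

    def values(self, chrom: str, start: int, end: int) -> np.ndarray:
        """Per-bp signal over [start, end); zero where the track is absent."""
        if end <= start:
            raise ValueError("end must exceed start")
        out = np.zeros(end - start, dtype=float)
        if chrom not in self._chroms:
            return out
        starts, ends, values = self._chroms[chrom]
        lo = int(np.searchsorted(ends, start, side="right"))
        hi = int(np.searchsorted(starts, end, side="left"))
        for i in range(lo, hi):
            a = max(int(starts[i]), start) - start
            b = min(int(ends[i]), end) - start
            if b > a:
                out[a:b] = values[i]
        return out

    def sum(self, chrom: str, start: int, end: int) -> float:
        """Total signal (value x bp) over [start, end)."""
        if chrom not in self._chroms:
            return 0.0
        starts, ends, values = self._chroms[chrom]
        lo = int(np.searchsorted(ends, start, side="right"))
        hi = int(np.searchsorted(starts, end, side="left"))
        total = 0.0
        for i in range(lo, hi):
            ov = min(int(ends[i]), end) - max(int(starts[i]), start)
            if ov > 0:
                total += ov * float(values[i])
        return total


class SequenceStore:
    """In-memory genome: chromosome name -> uppercase DNA over {A,C,G,T,N}."""

    def __init__(self, sequences: Mapping[str, str] | None = None):
        self._seqs: dict[str, str] = {}
        if sequences:
            for name, seq in sequences.items():
                self.add(name, seq)

    def add(self, name: str, seq: str) -> None:
        if name in self._seqs:
            raise ValueError(f"duplicate sequence name: {name}")
        self._seqs[name] = _NON_ACGT.sub("N", seq.upper())

    def replace(self, name: str, seq: str) -> None:
        self._seqs[name] = _NON_ACGT.sub("N", seq.upper())

    def __contains__(self, name: str) -> bool:
        return name in self._seqs

    @property
    def chroms(self) -> list[str]:
        return list(self._seqs)

    def length(self, name: str) -> int:
        return len(self._seqs[name])

    def fetch(self, chrom: str, start: int, end: int) -> str:
        if chrom not in self._seqs:
            raise KeyError(f"chromosome not in store: {chrom}")
        seq = self._seqs[chrom]
        if start < 0 or end > len(seq) or end <= start:
            raise ValueError(
                f"interval [{start}, {end}) out of bounds for {chrom} (len {len(seq)})"
            )
        return seq[start:end]

    def sequence(self, chrom: str) -> str:
        return self._seqs[chrom]


# ---------------------------------------------------------------------------
# BED / narrowPeak


def read_bed(path: str | Path) -> PeakSet:
    """Read BED3-BED6 or ENCODE narrowPeak (10 columns, auto-detected).

    Coordinates are taken verbatim (already 0-based half-open); file order is
    preserved. The narrowPeak 10th column, when >= 0, is kept as the summit
    offset.
    """
    path = Path(path)
    intervals: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith(("track", "browser", "#")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: expected >=3 tab-separated fields")
            try:
                chrom = fields[0]
                start, end = int(fields[1]), int(fields[2])
                name = fields[3] if len(fields) > 3 else "."
                score = float(fields[4]) if len(fields) > 4 and fields[4] != "." else 0.0
                strand = fields[5] if len(fields) > 5 else "."
                summit = None
                if len(fields) == 10:
                    s = int(fields[9])
                    summit = s if s >= 0 else None
                intervals.append(
                    GenomicInterval(chrom, start, end, name, score, strand, summit)
                )
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from exc
    return PeakSet(label=path.stem, intervals=intervals)


def write_bed(peaks: PeakSet, path: str | Path) -> None:
    """Write BED6; intervals with a summit are written as 10-column narrowPeak."""
    with open(path, "w") as fh:
        for iv in peaks:
            cols = [iv.chrom, str(iv.start), str(iv.end), iv.name,
                    _fmt_score(iv.score), iv.strand]
            if iv.summit_offset is not None:
                cols += [_fmt_score(iv.score), "-1", "-1", str(iv.summit_offset)]
            fh.write("\t".join(cols) + "\n")


def _fmt_score(x: float) -> str:
    return str(int(x)) if float(x).is_integer() else repr(float(x))


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: str | Path) -> SequenceStore:
    store = SequenceStore()
    for rec in SeqIO.parse(str(path), "fasta"):
        store.add(rec.id, str(rec.seq))
    return store


def write_fasta(store: SequenceStore, path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for chrom in store.chroms:
            fh.write(f">{chrom}\n")
            seq = store.sequence(chrom)
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# bedGraph


def read_bedgraph(path: str | Path) -> SignalTrack:
    """Read bedGraph; rows may arrive out of order and are sorted on load."""
    per_chrom: dict[str, list[tuple[int, int, float]]] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith(("track", "#")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise ValueError(f"{path}:{lineno}: expected 4 fields")
            try:
                chrom, start, end, value = fields[0], int(fields[1]), int(fields[2]), float(fields[3])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from exc
            per_chrom.setdefault(chrom, []).append((start, end, value))
    return SignalTrack(per_chrom)


def write_bedgraph(track: SignalTrack, path: str | Path) -> None:
    with open(path, "w") as fh:
        for chrom in track.chroms:
            for start, end, value in track.steps(chrom):
                fh.write(f"{chrom}\t{start}\t{end}\t{value:g}\n")


# ---------------------------------------------------------------------------
# guide-count table


REQUIRED_GUIDE_COLUMNS = ("guide", "gene", "count_low", "count_high")


def read_guide_counts(path: str | Path) -> pd.DataFrame:
    """Read a sgRNA count table (TSV with header).

    Required columns: guide, gene, count_low, count_high; count_input is kept
    when present. Counts must be non-negative integers and guide ids unique.
    """
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in REQUIRED_GUIDE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    count_cols = [c for c in df.columns if c.startswith("count_")]
    for col in count_cols:
        if not pd.api.types.is_numeric_dtype(df[col]):
            raise ValueError(f"{path}: non-numeric values in {col}")
        if (df[col] < 0).any():
            raise ValueError(f"{path}: negative count in {col}")
    if df["guide"].duplicated().any():
        dup = df.loc[df["guide"].duplicated(), "guide"].iloc[0]
        raise ValueError(f"{path}: duplicate guide id {dup!r}")
    return df


def write_guide_counts(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)
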