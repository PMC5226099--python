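"""Interval I/O (BED / ENCODE broadPeak) and fixed-width window grids.

All coordinates are 0-based half-open, the convention shared by every
BED-family format this toolkit reads or writes.  Strand is carried through
readers but never consulted: histone-mark peaks and enhancer calls are
unstranded.

The :class:`WindowGrid` is the toolkit's spatial backbone — a regular 200-bp
tiling of the genome whose bins are the atomic units of featurization,
labeling and prediction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence


class BedParseError(ValueError):
    """Raised on a malformed BED/broadPeak line; the message names the line."""


_HEADER_PREFIXES = ("track", "browser", "#")


@dataclass(frozen=True)
class GenomicInterval:
    """A genomic span: 0-based inclusive ``start``, exclusive ``end``."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if self.start < 0:
            raise ValueError(f"start must be >= 0, got {self.start}")
        if self.end <= self.start:
            raise ValueError(f"end ({self.end}) must exceed start ({self.start})")
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"strand must be one of +,-,. got {self.strand!r}")

    @property
    def width(self) -> int:
        return self.end - self.start

    @property
    def id(self) -> str:
        return f"{self.chrom}:{self.start}-{self.end}"

    def overlap(self, other: "GenomicInterval") -> int:
        """Overlap length in bp (0 if disjoint or on different chromosomes)."""
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))


@dataclass(frozen=True)
class PeakRecord:
    """One ENCODE broadPeak line (BED6+3).

    ``signal_value`` (column 7) is the enrichment statistic used as the
    feature input; ``p_value``/``q_value`` use the format's -1 sentinel for
    "not available".
    """

    interval: GenomicInterval
    name: str = "."
    score: int = 0
    signal_value: float = 1.0
    p_value: float = -1.0
    q_value: float = -1.0

    def __post_init__(self) -> None:
        if self.signal_value < 0:
            raise ValueError(f"signal_value must be >= 0, got {self.signal_value}")


@dataclass
class WindowGrid:
    """Non-overlapping fixed-width tiling of a genome.

    Each chromosome is tiled from 0 in ``width``-bp bins; a chromosome whose
    length is not a multiple of ``width`` keeps a truncated final bin so no
    position is dropped.  ``windows`` is sorted by (input chromosome order,
    start).
    """

    chrom_sizes: dict[str, int]
    width: int = 200
    windows: list[GenomicInterval] = field(default_factory=list)
    _offsets: dict[str, int] = field(default_factory=dict, repr=False)

    @property
    def n_windows(self) -> int:
        return len(self.windows)

    def window_ids(self) -> list[str]:
        return [w.id for w in self.windows]

    def chrom_offset(self, chrom: str) -> int:
        """Index of the first window of ``chrom``."""
        return self._offsets[chrom]

    def overlapping_range(self, chrom: str, start: int, end: int) -> tuple[int, int]:
        """Half-open range of window indices overlapping [start, end) by >= 1 bp.

        Returns (0, 0) if ``chrom`` is not in the grid or the clipped span is
        empty.
        """
        size = self.chrom_sizes.get(chrom)
        if size is None:
            return (0, 0)
        start = max(0, start)
        end = min(end, size)
        if end <= start:
            return (0, 0)
        off = self._offsets[chrom]
        return (off + start // self.width, off + (end - 1) // self.width + 1)


def make_windows(chrom_sizes: Mapping[str, int], width: int = 200) -> WindowGrid:
    """Tile every chromosome into ``width``-bp windows.

    Total window count is sum(ceil(length / width)) over chromosomes; the
    last window of a chromosome is truncated when the length is not a
    multiple of ``width``.
    """
    if width <= 0:
        raise ValueError(f"window width must be positive, got {width}")
    windows: list[GenomicInterval] = []
    offsets: dict[str, int] = {}
    for chrom, size in chrom_sizes.items():
        if size <= 0:
            raise ValueError(f"chromosome {chrom!r} has non-positive length {size}")
        offsets[chrom] = len(windows)
        for i in range(math.ceil(size / width)):
            windows.append(GenomicInterval(chrom, i * width, min((i + 1) * width, size)))
    return WindowGrid(dict(chrom_sizes), width, windows, offsets)


def read_chrom_sizes(path: str | Path) -> dict[str, int]:
    """Read a two-column ``chrom.sizes`` table (name TAB length)."""
    sizes: dict[str, int] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) < 2:
                raise BedParseError(f"{path} line {lineno}: expected 'name length'")
            try:
                sizes[parts[0]] = int(parts[1])
            except ValueError as exc:
                raise BedParseError(f"{path} line {lineno}: non-integer length {parts[1]!r}") from exc
    return sizes


def _parse_coords(parts: Sequence[str], path: str | Path, lineno: int) -> GenomicInterval:
    if len(parts) < 3:
        raise BedParseError(f"{path} line {lineno}: fewer than 3 columns")
    try:
        start, end = int(parts[1]), int(parts[2])
    except ValueError as exc:
        raise BedParseError(
            f"{path} line {lineno}: non-integer coordinates {parts[1]!r}, {parts[2]!r}"
        ) from exc
    strand = parts[5] if len(parts) > 5 and parts[5] in ("+", "-") else "."
    try:
        return GenomicInterval(parts[0], start, end, strand)
    except ValueError as exc:
        raise BedParseError(f"{path} line {lineno}: {exc}") from exc


def _data_lines(path: str | Path) -> Iterable[tuple[int, list[str]]]:
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith(_HEADER_PREFIXES):
                continue
            yield lineno, line.split("\t") if "\t" in line else line.split()


def read_broadpeak(path: str | Path) -> list[PeakRecord]:
    """Read an ENCODE broadPeak (BED6+3) file; order preserved.

    Files with fewer columns (down to BED3) are accepted with the missing
    optional columns defaulted (signal_value 1.0), so plain BED label files
    can flow through the same reader.
    """
    records: list[PeakRecord] = []
    for lineno, parts in _data_lines(path):
        interval = _parse_coords(parts, path, lineno)
        name = parts[3] if len(parts) > 3 else "."
        try:
            score = int(float(parts[4])) if len(parts) > 4 else 0
            signal = float(parts[6]) if len(parts) > 6 else 1.0
            p_value = float(parts[7]) if len(parts) > 7 else -1.0
            q_value = float(parts[8]) if len(parts) > 8 else -1.0
            records.append(PeakRecord(interval, name, score, signal, p_value, q_value))
        except ValueError as exc:
            raise BedParseError(f"{path} line {lineno}: {exc}") from exc
    return records


def read_bed(path: str | Path) -> list[GenomicInterval]:
    """Read a >=3-column BED file; track/browser/# lines skipped."""
    return [_parse_coords(parts, path, lineno) for lineno, parts in _data_lines(path)]


def sort_intervals(intervals: Iterable[GenomicInterval]) -> list[GenomicInterval]:
    """Sort lexicographically by chromosome, then numerically by start, end."""
    return sorted(intervals, key=lambda iv: (iv.chrom, iv.start, iv.end))


def write_broadpeak(records: Iterable[PeakRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in records:
            iv = r.interval
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{r.name}\t{r.score}\t{iv.strand}"
                f"\t{r.signal_value:g}\t{r.p_value:g}\t{r.q_value:g}\n"
            )


def write_bed(intervals: Iterable[GenomicInterval], path: str | Path) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")


def write_predictions_bed(
    windows: Sequence[GenomicInterval],
    scores: Sequence[float],
    labels: Sequence[int],
    path: str | Path,
) -> None:
    """Write per-window predictions as BED6.

    The name column carries the predicted label (0/1); the BED score column
    carries the classifier confidence scaled to 0-1000 (clipped).
    """
    if not (len(windows) == len(scores) == len(labels)):
        raise ValueError(
            f"length mismatch: {len(windows)} windows, {len(scores)} scores, {len(labels)} labels"
        )
    with open(path, "w") as fh:
        for w, s, lab in zip(windows, scores, labels):
            bed_score = int(round(max(0.0, min(1.0, float(s))) * 1000))
            fh.write(f"{w.chrom}\t{w.start}\t{w.end}\t{int(lab)}\t{bed_score}\t.\n")
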