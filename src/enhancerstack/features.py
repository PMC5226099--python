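"""Per-window feature construction: peak signal mapping, min-max scaling,
window labeling, and k-mer frequency features.

Feature semantics
-----------------
The histone-mark feature of a window is the maximum ``signal_value`` of the
peaks of that mark overlapping the window by at least 1 bp (0 when none);
peak enrichment is a statistic, and the maximum is stable under peak
fragmentation.  ``sum`` and ``count`` aggregation modes are available for
comparison.  Each feature column is then affinely rescaled so that its
minimum maps to 0 and its maximum to 1:

    x_i <- (x_i - x_min) / (x_max - x_min)

A window is labeled as enhancer when a single label interval (e.g. an EP300
peak or a CAGE-defined enhancer) covers at least half of the window's width.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from enhancerstack.genomic_io import GenomicInterval, PeakRecord, WindowGrid

logger = logging.getLogger(__name__)

_BASES = "ACGT"
_BASE_CODE = {ord("A"): 0, ord("C"): 1, ord("G"): 2, ord("T"): 3}


@dataclass
class FeatureMatrix:
    """n_windows x n_features real matrix with aligned window and feature names."""

    window_ids: list[str]
    mark_names: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.window_ids), len(self.mark_names)):
            raise ValueError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.window_ids)} windows x {len(self.mark_names)} features"
            )

    @property
    def n_windows(self) -> int:
        return len(self.window_ids)

    def subset(self, idx: Sequence[int] | np.ndarray) -> "FeatureMatrix":
        idx = np.asarray(idx)
        return FeatureMatrix(
            [self.window_ids[i] for i in idx], list(self.mark_names), self.values[idx]
        )

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("window\t" + "\t".join(self.mark_names) + "\n")
            for wid, row in zip(self.window_ids, self.values):
                fh.write(wid + "\t" + "\t".join(f"{v:g}" for v in row) + "\n")


@dataclass
class LabeledDataset:
    """A feature matrix plus its binary enhancer labels for one tissue."""

    features: FeatureMatrix
    labels: np.ndarray
    source_name: str = ""

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if self.labels.shape != (self.features.n_windows,):
            raise ValueError(
                f"{len(self.labels)} labels for {self.features.n_windows} windows"
            )
        if not np.isin(self.labels, (0, 1)).all():
            raise ValueError("labels must be binary 0/1")

    @property
    def n_positive(self) -> int:
        return int(self.labels.sum())

    def subset(self, idx: Sequence[int] | np.ndarray) -> "LabeledDataset":
        idx = np.asarray(idx)
        return LabeledDataset(self.features.subset(idx), self.labels[idx], self.source_name)


def map_signal(
    peaks_by_mark: Mapping[str, Sequence[PeakRecord]],
    grid: WindowGrid,
    aggregate: str = "max",
) -> FeatureMatrix:
    """Project per-mark peak sets onto the window grid (raw, unnormalized).

    Entry (w, m) aggregates ``signal_value`` over the mark-m peaks that
    overlap window w by >= 1 bp; windows with no overlapping peak get 0.
    Peaks on chromosomes absent from the grid are ignored with a warning.
    """
    if aggregate not in ("max", "sum", "count"):
        raise ValueError(f"unknown aggregation {aggregate!r}")
    mark_names = list(peaks_by_mark)
    values = np.zeros((grid.n_windows, len(mark_names)))
    for j, mark in enumerate(mark_names):
        skipped: set[str] = set()
        col = values[:, j]
        for peak in peaks_by_mark[mark]:
            iv = peak.interval
            if iv.chrom not in grid.chrom_sizes:
                skipped.add(iv.chrom)
                continue
            lo, hi = grid.overlapping_range(iv.chrom, iv.start, iv.end)
            if aggregate == "max":
                np.maximum(col[lo:hi], peak.signal_value, out=col[lo:hi])
            elif aggregate == "sum":
                col[lo:hi] += peak.signal_value
            else:
                col[lo:hi] += 1.0
        if skipped:
            logger.warning(
                "mark %s: ignored peaks on chromosomes absent from grid: %s",
                mark,
                ", ".join(sorted(skipped)),
            )
    return FeatureMatrix(grid.window_ids(), mark_names, values)


@dataclass
class MinMaxNormalizer:
    """Per-column min-max scaler with clipping on transform.

    Constant columns (x_max == x_min) map to all zeros — an uninformative
    feature stays uninformative rather than dividing by zero.
    """

    mins: np.ndarray = field(default_factory=lambda: np.empty(0))
    maxs: np.ndarray = field(default_factory=lambda: np.empty(0))

    def fit(self, values: np.ndarray) -> "MinMaxNormalizer":
        values = np.asarray(values, dtype=float)
        self.mins = values.min(axis=0)
        self.maxs = values.max(axis=0)
        n_const = int((self.maxs == self.mins).sum())
        if n_const:
            logger.warning("%d constant feature column(s) will normalize to 0", n_const)
        return self

    def transform(self, values: np.ndarray, clip: bool = True) -> np.ndarray:
        span = self.maxs - self.mins
        safe = np.where(span > 0, span, 1.0)
        out = (np.asarray(values, dtype=float) - self.mins) / safe
        out[:, span == 0] = 0.0
        return np.clip(out, 0.0, 1.0) if clip else out


def minmax_normalize(matrix: FeatureMatrix) -> FeatureMatrix:
    """Rescale each column of ``matrix`` to [0, 1] on its own min/max."""
    if matrix.n_windows == 0:
        raise ValueError("cannot normalize an empty feature matrix")
    scaled = MinMaxNormalizer().fit(matrix.values).transform(matrix.values, clip=False)
    return FeatureMatrix(list(matrix.window_ids), list(matrix.mark_names), scaled)


def label_windows(
    grid: WindowGrid,
    label_intervals: Iterable[GenomicInterval],
    min_overlap_fraction: float = 0.5,
) -> np.ndarray:
    """Binary label per window: 1 iff some single label interval overlaps the
    window by >= ``min_overlap_fraction`` of the window's own width."""
    labels = np.zeros(grid.n_windows, dtype=int)
    for iv in label_intervals:
        if iv.chrom not in grid.chrom_sizes:
            continue
        lo, hi = grid.overlapping_range(iv.chrom, iv.start, iv.end)
        for k in range(lo, hi):
            w = grid.windows[k]
            if w.overlap(iv) >= min_overlap_fraction * w.width:
                labels[k] = 1
    return labels


def kmer_names(k_set: Sequence[int] = (1, 2, 3, 4)) -> list[str]:
    """Feature names: all 4^k k-mers per k, lexicographic, k ascending."""
    return ["".join(p) for k in sorted(k_set) for p in itertools.product(_BASES, repeat=k)]


def kmer_frequencies(sequence: str, k_set: Sequence[int] = (1, 2, 3, 4)) -> np.ndarray:
    """Concatenated k-mer frequency vector of a DNA sequence.

    For each k, counts of the 4^k k-mers (lexicographic order) divided by
    the number of k-length windows not containing N; N-containing windows
    are skipped and excluded from the denominator.  A sequence shorter than
    k yields an all-zero block for that k.
    """
    arr = np.frombuffer(sequence.upper().encode("ascii"), dtype=np.uint8)
    codes = np.full(arr.shape, -1, dtype=np.int64)
    for byte, code in _BASE_CODE.items():
        codes[arr == byte] = code
    blocks: list[np.ndarray] = []
    for k in sorted(k_set):
        n_win = len(codes) - k + 1
        if n_win <= 0:
            blocks.append(np.zeros(4**k))
            continue
        idx = np.zeros(n_win, dtype=np.int64)
        valid = np.ones(n_win, dtype=bool)
        for j in range(k):
            seg = codes[j : j + n_win]
            idx = idx * 4 + np.where(seg >= 0, seg, 0)
            valid &= seg >= 0
        counts = np.bincount(idx[valid], minlength=4**k).astype(float)
        blocks.append(counts / valid.sum() if valid.any() else counts)
    return np.concatenate(blocks)


def kmer_feature_matrix(
    grid: WindowGrid, fasta_path: str | Path, k_set: Sequence[int] = (1, 2, 3, 4)
) -> FeatureMatrix:
    """Per-window k-mer frequency features from an indexed FASTA."""
    from pyfaidx import Fasta

    fasta = Fasta(str(fasta_path))
    names = kmer_names(k_set)
    values = np.zeros((grid.n_windows, len(names)))
    for i, w in enumerate(grid.windows):
        values[i] = kmer_frequencies(str(fasta[w.chrom][w.start : w.end]), k_set)
    return FeatureMatrix(grid.window_ids(), names, values)
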