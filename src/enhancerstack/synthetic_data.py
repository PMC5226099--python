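"""Synthetic multi-tissue epigenomes for testing and demonstration.

Emulates the statistical structure the classifier assumes: a genome tiled
into 200-bp windows of which ~2% are enhancers; enhancer-associated marks
(H3K4me1/H3K27ac analogues) emit peaks with elevated, right-skewed
(lognormal) signal over enhancer windows plus scattered background peaks;
uninformative marks emit background only.  Enhancers are partly shared
across tissues and partly tissue-specific, and per-tissue multiplicative
jitter on mark effects models tissue-to-tissue variation.  Output is
standard broadPeak / BED / chrom.sizes / FASTA text that round-trips
through :mod:`enhancerstack.genomic_io`.

A mark is *informative* for a tissue exactly when its resolved effect for
that tissue is > 0; with all effects at 0 every mark is background-only and
the features carry no label signal (the null regime used for calibration).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from enhancerstack.genomic_io import (
    GenomicInterval,
    PeakRecord,
    WindowGrid,
    make_windows,
    write_bed,
    write_broadpeak,
)


@dataclass
class MarkSpec:
    """One histone-mark analogue.

    effect: added mean peak signal at enhancer windows over the background
        mean — a scalar (same in every tissue) or one value per tissue;
        0 means the mark is uninformative (background only).
    noise_sd: sdlog of the lognormal signal distribution.
    background_rate: fraction of windows receiving a background peak.
    """

    name: str
    effect: float | Sequence[float] = 0.0
    noise_sd: float = 0.25
    background_rate: float = 0.10

    def effect_for(self, tissue_index: int) -> float:
        if np.isscalar(self.effect):
            eff = float(self.effect)  # type: ignore[arg-type]
        else:
            eff = float(self.effect[tissue_index])  # type: ignore[index]
        if eff < 0:
            raise ValueError(f"mark {self.name}: effect must be >= 0, got {eff}")
        return eff


@dataclass
class SynthSpec:
    """Study-level parameters of the synthetic epigenome."""

    chrom_sizes: dict[str, int]
    marks: list[MarkSpec]
    enhancer_fraction: float = 0.02
    shared_enhancer_fraction: float = 0.5
    n_tissues: int = 4
    peak_width_range: tuple[int, int] = (200, 1000)
    base_signal: float = 1.0
    window_width: int = 200
    effect_jitter_sd: float = 0.15
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.enhancer_fraction < 1:
            raise ValueError(f"enhancer_fraction must be in (0,1), got {self.enhancer_fraction}")
        if not 0 <= self.shared_enhancer_fraction <= 1:
            raise ValueError("shared_enhancer_fraction must be in [0,1]")
        if self.n_tissues < 1:
            raise ValueError("n_tissues must be >= 1")

    def grid(self) -> WindowGrid:
        return make_windows(self.chrom_sizes, self.window_width)


@dataclass
class TissueFiles:
    """Paths emitted for one tissue, plus its in-memory truth labels."""

    name: str
    peak_paths: dict[str, Path]
    label_path: Path
    truth_path: Path
    labels: np.ndarray = field(repr=False, default_factory=lambda: np.empty(0, dtype=int))


@dataclass
class StudyFiles:
    chrom_sizes_path: Path
    tissues: list[TissueFiles]
    truth_path: Path
    fasta_path: Path | None = None


def _rng(spec: SynthSpec, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([spec.seed, *key]))


def enhancer_pools(spec: SynthSpec) -> tuple[np.ndarray, list[np.ndarray]]:
    """Window indices of the shared enhancer pool and each tissue's own pool.

    Each tissue's enhancers are the shared pool plus a tissue-specific draw
    from the remaining windows, sized to hit ``enhancer_fraction`` exactly.
    """
    grid = spec.grid()
    n_windows = grid.n_windows
    n_pos = round(spec.enhancer_fraction * n_windows)
    n_shared = round(spec.shared_enhancer_fraction * n_pos)
    n_specific = n_pos - n_shared
    if n_pos < 1:
        raise ValueError("enhancer_fraction too small: no positive windows")
    if n_shared + n_specific > n_windows:
        raise ValueError(
            f"enhancer_fraction {spec.enhancer_fraction} too high: shared + "
            f"tissue-specific pools ({n_shared}+{n_specific}) exceed {n_windows} windows"
        )
    rng = _rng(spec, 0)
    shared = np.sort(rng.choice(n_windows, size=n_shared, replace=False))
    rest = np.setdiff1d(np.arange(n_windows), shared)
    specific = [
        np.sort(_rng(spec, 1, t).choice(rest, size=n_specific, replace=False))
        for t in range(spec.n_tissues)
    ]
    return shared, specific


def tissue_labels(spec: SynthSpec, tissue_index: int) -> np.ndarray:
    shared, specific = enhancer_pools(spec)
    grid = spec.grid()
    labels = np.zeros(grid.n_windows, dtype=int)
    labels[shared] = 1
    labels[specific[tissue_index]] = 1
    return labels


def _lognormal_mean(rng: np.random.Generator, mean: float, sdlog: float, size: int) -> np.ndarray:
    # parametrize by the distribution's arithmetic mean
    mu = np.log(mean) - sdlog**2 / 2
    return rng.lognormal(mu, sdlog, size)


def _mark_peaks(
    spec: SynthSpec, grid: WindowGrid, labels: np.ndarray, mark: MarkSpec, tissue_index: int, mark_index: int
) -> list[PeakRecord]:
    rng = _rng(spec, 2, tissue_index, mark_index)
    effect = mark.effect_for(tissue_index)
    if spec.effect_jitter_sd > 0 and effect > 0:
        effect *= rng.lognormal(0.0, spec.effect_jitter_sd)
    peaks: list[tuple[GenomicInterval, float]] = []
    lo, hi = spec.peak_width_range

    def add_peak(window: GenomicInterval, signal: float) -> None:
        width = int(rng.integers(lo, hi + 1))
        size = grid.chrom_sizes[window.chrom]
        center = (window.start + window.end) // 2
        start = max(0, min(center - width // 2, size - 1))
        end = min(start + width, size)
        peaks.append((GenomicInterval(window.chrom, start, end), signal))

    if effect > 0:
        pos = np.flatnonzero(labels == 1)
        signals = _lognormal_mean(rng, spec.base_signal + effect, mark.noise_sd, len(pos))
        for w_idx, sig in zip(pos, signals):
            add_peak(grid.windows[w_idx], float(sig))
    n_bg = round(mark.background_rate * grid.n_windows)
    bg_windows = rng.choice(grid.n_windows, size=n_bg, replace=False)
    bg_signals = _lognormal_mean(rng, spec.base_signal, mark.noise_sd, n_bg)
    for w_idx, sig in zip(bg_windows, bg_signals):
        add_peak(grid.windows[w_idx], float(sig))

    peaks.sort(key=lambda p: (p[0].chrom, p[0].start, p[0].end))
    return [
        PeakRecord(
            interval=iv,
            name=f"{mark.name}_peak{i}",
            score=min(1000, int(sig * 100)),
            signal_value=round(sig, 5),
        )
        for i, (iv, sig) in enumerate(peaks)
    ]


def generate_tissue(spec: SynthSpec, tissue_index: int, out_dir: str | Path) -> TissueFiles:
    """Emit one tissue's per-mark broadPeak files, enhancer label BED and
    truth table.  Byte-identical across runs for a fixed seed."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    grid = spec.grid()
    labels = tissue_labels(spec, tissue_index)
    name = f"tissue{tissue_index}"

    peak_paths: dict[str, Path] = {}
    for m_idx, mark in enumerate(spec.marks):
        path = out_dir / f"{name}_{mark.name}.broadPeak"
        write_broadpeak(_mark_peaks(spec, grid, labels, mark, tissue_index, m_idx), path)
        peak_paths[mark.name] = path

    label_path = out_dir / f"{name}_enhancers.bed"
    write_bed([grid.windows[i] for i in np.flatnonzero(labels == 1)], label_path)

    truth_path = out_dir / f"{name}_truth.tsv"
    with open(truth_path, "w") as fh:
        fh.write("window\tlabel\n")
        for w, lab in zip(grid.windows, labels):
            fh.write(f"{w.id}\t{lab}\n")

    return TissueFiles(name, peak_paths, label_path, truth_path, labels)


def generate_sequences(
    spec: SynthSpec,
    enhancer_labels: np.ndarray,
    out_path: str | Path,
    motif: str = "GTCA",
    copies_per_window: int = 10,
) -> Path:
    """Random genome FASTA with a tetramer motif enriched in enhancer windows.

    Background sequence is i.i.d. uniform ACGT; each enhancer window gets
    ``copies_per_window`` motif plants at random offsets, so k-mer features
    are informative for the label.
    """
    out_path = Path(out_path)
    grid = spec.grid()
    rng = _rng(spec, 3)
    bases = np.frombuffer(b"ACGT", dtype=np.uint8)
    with open(out_path, "w") as fh:
        for chrom, size in spec.chrom_sizes.items():
            seq = bases[rng.integers(0, 4, size)].copy()
            off = grid.chrom_offset(chrom)
            n_chrom = sum(1 for w in grid.windows if w.chrom == chrom)
            for k in range(off, off + n_chrom):
                if enhancer_labels[k]:
                    w = grid.windows[k]
                    if w.width <= len(motif):
                        continue
                    starts = rng.integers(w.start, w.end - len(motif), copies_per_window)
                    for s in starts:
                        seq[s : s + len(motif)] = np.frombuffer(motif.encode(), dtype=np.uint8)
            fh.write(f">{chrom}\n")
            text = seq.tobytes().decode("ascii")
            for i in range(0, size, 60):
                fh.write(text[i : i + 60] + "\n")
    return out_path


def simulate_study(
    spec: SynthSpec, out_dir: str | Path, with_sequence: bool = False
) -> StudyFiles:
    """Emit a full multi-tissue study: chrom.sizes, per-tissue peak/label
    files, a combined truth table, and optionally a genome FASTA."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    chrom_sizes_path = out_dir / "chrom.sizes"
    with open(chrom_sizes_path, "w") as fh:
        for chrom, size in spec.chrom_sizes.items():
            fh.write(f"{chrom}\t{size}\n")

    tissues = [generate_tissue(spec, t, out_dir) for t in range(spec.n_tissues)]

    grid = spec.grid()
    truth_path = out_dir / "truth.tsv"
    with open(truth_path, "w") as fh:
        fh.write("window\ttissue\tlabel\n")
        for tf in tissues:
            for w, lab in zip(grid.windows, tf.labels):
                fh.write(f"{w.id}\t{tf.name}\t{lab}\n")

    fasta_path = None
    if with_sequence:
        union = np.zeros(grid.n_windows, dtype=int)
        for tf in tissues:
            union |= tf.labels
        fasta_path = generate_sequences(spec, union, out_dir / "genome.fa")

    return StudyFiles(chrom_sizes_path, tissues, truth_path, fasta_path)
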