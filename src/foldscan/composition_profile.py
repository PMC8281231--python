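"""Windowed genome-composition tracks and locus statistics.

Provides the C/G% bedGraph in 100 bp windows, coordinate BEDs for every
CpG dinucleotide and GCC/GGC trinucleotide, exact 1,000 bp homogenized
window tilings with per-window quantification (no normalization), 100x100
2D histograms of per-window values, locus GC%, and the
longest-contiguous-unit-run computation used to show that a CGG locus is
interrupted (e.g. a longest run of only 17 CGG units despite >900 bp of
CG-rich repeats).

Scans are forward-strand only: CpG is strand-symmetric, and the GCC/GGC
pattern pair jointly covers both strands of the GCC codon pattern.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from .genome_io import GenomeInfo, Interval

__all__ = [
    "GenomeWindow",
    "Histogram2D",
    "gc_percent_track",
    "dinucleotide_positions",
    "trinucleotide_positions",
    "homogenize_windows",
    "quantify_windows",
    "histogram2d",
    "locus_gc",
    "longest_unit_run",
]


@dataclass(frozen=True)
class GenomeWindow:
    """Fixed-width genomic bin with composition counts; the final window of
    a chromosome may be shorter than the nominal size."""

    chrom: str
    start: int
    end: int
    gc_percent: float
    cpg_count: int
    gcc_ggc_count: int


@dataclass(frozen=True)
class Histogram2D:
    """100x100-style 2D histogram of window tallies; values above the axis
    maxima are clipped into the last bin, so counts conserve window count."""

    x_edges: np.ndarray
    y_edges: np.ndarray
    counts: np.ndarray

    @property
    def total(self) -> int:
        return int(self.counts.sum())


def _gc_count(seq: str) -> int:
    return seq.count("C") + seq.count("G")


def gc_percent_track(
    genome: Mapping[str, str],
    window: int = 100,
    exclude_n: bool = False,
) -> list[tuple[str, int, int, float]]:
    """Consecutive non-overlapping windows per chromosome with
    100 * (#C + #G) / window-length. The final partial window uses its actual
    length. With ``exclude_n`` the denominator is the non-N base count
    (all-N windows report 0)."""
    if window < 1:
        raise ValueError("window must be >= 1")
    out: list[tuple[str, int, int, float]] = []
    for chrom, seq in genome.items():
        for start in range(0, len(seq), window):
            end = min(start + window, len(seq))
            sub = seq[start:end]
            denom = (end - start) - (sub.count("N") if exclude_n else 0)
            value = 100.0 * _gc_count(sub) / denom if denom else 0.0
            out.append((chrom, start, end, value))
    return out


def _scan(seq: str, pattern: str) -> list[int]:
    """All (possibly overlapping) occurrence starts of ``pattern``."""
    starts: list[int] = []
    i = seq.find(pattern)
    while i != -1:
        starts.append(i)
        i = seq.find(pattern, i + 1)
    return starts


def dinucleotide_positions(genome: Mapping[str, str], pattern: str = "CG") -> list[Interval]:
    """One length-2 interval per occurrence of ``pattern`` on the forward
    strand; overlapping occurrences allowed."""
    if len(pattern) != 2:
        raise ValueError("pattern must have length 2")
    if "N" in pattern.upper():
        raise ValueError("pattern must not contain N")
    p = pattern.upper()
    return [
        Interval(chrom, s, s + 2)
        for chrom, seq in genome.items()
        for s in _scan(seq, p)
    ]


def trinucleotide_positions(
    genome: Mapping[str, str], patterns: Sequence[str] = ("GCC", "GGC")
) -> list[Interval]:
    """Union of occurrence intervals of all length-3 patterns, forward
    strand, sorted genome order; overlaps between patterns allowed."""
    if not patterns:
        raise ValueError("empty pattern set")
    if any(len(p) != 3 for p in patterns):
        raise ValueError("all patterns must have length 3")
    out: list[Interval] = []
    for chrom, seq in genome.items():
        starts = sorted({s for p in patterns for s in _scan(seq, p.upper())})
        out.extend(Interval(chrom, s, s + 3) for s in starts)
    return out


def homogenize_windows(genome_info: GenomeInfo, size: int = 1000) -> list[Interval]:
    """Exact fixed-width tiling of every chromosome (final window
    truncated): ceil(length/size) windows per chromosome, no gaps, no
    overlaps."""
    if size < 1:
        raise ValueError("size must be >= 1")
    out: list[Interval] = []
    for chrom, length in zip(genome_info.chrom_names, genome_info.chrom_lengths):
        for start in range(0, length, size):
            out.append(Interval(chrom, start, min(start + size, length)))
    return out


def quantify_windows(
    windows: Sequence[Interval],
    cpg_positions: Sequence[Interval],
    gcc_ggc_positions: Sequence[Interval],
    genome: Mapping[str, str],
    exclude_n: bool = False,
) -> list[GenomeWindow]:
    """Per-window CpG and GCC/GGC counts plus C/G% from sequence, with no
    normalization. A position is counted in the window containing its START
    coordinate, so a motif straddling a window boundary counts once, in the
    left window."""
    # Bin starts per chromosome with searchsorted against window starts;
    # windows of one chromosome must tile contiguously (homogenize_windows).
    by_chrom: dict[str, list[Interval]] = {}
    for w in windows:
        by_chrom.setdefault(w.chrom, []).append(w)
    counts_cpg: dict[tuple[str, int], int] = {}
    counts_tri: dict[tuple[str, int], int] = {}
    for positions, counts in ((cpg_positions, counts_cpg), (gcc_ggc_positions, counts_tri)):
        for chrom, wins in by_chrom.items():
            starts = np.array([w.start for w in wins])
            ends = np.array([w.end for w in wins])
            pos = np.array([p.start for p in positions if p.chrom == chrom], dtype=int)
            if pos.size == 0:
                continue
            idx = np.searchsorted(starts, pos, side="right") - 1
            ok = (idx >= 0) & (pos < ends[np.clip(idx, 0, len(ends) - 1)])
            for i in idx[ok]:
                key = (chrom, int(i))
                counts[key] = counts.get(key, 0) + 1

    out: list[GenomeWindow] = []
    for chrom, wins in by_chrom.items():
        seq = genome[chrom]
        for i, w in enumerate(wins):
            sub = seq[w.start : w.end]
            denom = len(sub) - (sub.count("N") if exclude_n else 0)
            gc = 100.0 * _gc_count(sub) / denom if denom else 0.0
            out.append(
                GenomeWindow(
                    chrom=chrom,
                    start=w.start,
                    end=w.end,
                    gc_percent=gc,
                    cpg_count=counts_cpg.get((chrom, i), 0),
                    gcc_ggc_count=counts_tri.get((chrom, i), 0),
                )
            )
    return out


def histogram2d(
    windows: Sequence[GenomeWindow],
    x: str = "gcc_ggc_count",
    y: str = "gc_percent",
    bins: int = 100,
    x_max: float | None = None,
    y_max: float | None = None,
) -> Histogram2D:
    """2D histogram of two per-window quantities on uniform [0, max] bins.

    Values above the axis maximum are clipped into the last bin (the plots
    this reproduces use adjusted fixed scales), so the histogram total
    always equals the window count.
    """
    if bins < 1:
        raise ValueError("bins must be >= 1")
    xv = np.array([getattr(w, x) for w in windows], dtype=float)
    yv = np.array([getattr(w, y) for w in windows], dtype=float)
    xm = float(x_max) if x_max is not None else (float(xv.max()) if len(xv) else 1.0)
    ym = float(y_max) if y_max is not None else (float(yv.max()) if len(yv) else 1.0)
    if xm <= 0 or ym <= 0:
        raise ValueError("axis ranges must be positive")
    x_edges = np.linspace(0.0, xm, bins + 1)
    y_edges = np.linspace(0.0, ym, bins + 1)
    counts, _, _ = np.histogram2d(
        np.clip(xv, 0.0, xm), np.clip(yv, 0.0, ym), bins=[x_edges, y_edges]
    )
    return Histogram2D(x_edges=x_edges, y_edges=y_edges, counts=counts.astype(int))


def locus_gc(genome: Mapping[str, str], region: Interval) -> float:
    """Percent C+G of a region (e.g. the 92.6% reported for the FOLD1
    locus on hg38)."""
    if region.chrom not in genome:
        raise ValueError(f"unknown chromosome {region.chrom!r}")
    seq = genome[region.chrom]
    if region.end > len(seq):
        raise ValueError(
            f"region {region.chrom}:{region.start}-{region.end} outside chromosome"
        )
    sub = seq[region.start : region.end]
    return 100.0 * _gc_count(sub) / len(sub)


def longest_unit_run(sequence: str, unit: str = "CGG") -> int:
    """Maximum k such that ``unit`` repeated k times in phase is a substring.

    Measures how interrupted a repeat tract is: a CGG locus whose longest
    contiguous run is short (e.g. 17 units) is broken up by non-unit bases
    even if the tract as a whole is long.
    """
    if not unit:
        raise ValueError("unit must be non-empty")
    seq = sequence.upper()
    u = unit.upper()
    p = len(u)
    best = 0
    i = 0
    n = len(seq)
    while i < n:
        if seq.startswith(u, i):
            k = 1
            j = i + p
            while seq.startswith(u, j):
                k += 1
                j += p
            best = max(best, k)
            i += 1  # re-check shifted phases overlapping this run
        else:
            i += 1
    return best
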