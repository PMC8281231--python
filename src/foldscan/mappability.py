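"""Pseudoread generation and exact-match k-mer uniqueness mappability.

A pseudoread is an error-free fixed-length copy of the reference sequence.
Tiling a region with such reads and asking whether each read's sequence
occurs anywhere else in the genome (on either strand) separates two causes
of missing short-read coverage: if a locus is repetitive or generally
unmappable, its pseudoreads recur elsewhere; if its pseudoreads are unique
yet real reads are still absent, the dropout must come from the chemistry
(e.g. extreme GC content suppressing PCR amplification), not from
mappability. "Mappability" here is exact-match L-mer uniqueness with
strand folding, not alignment scoring; the FASTQ export lets users rerun
the question through a real aligner externally.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

from .genome_io import Interval, write_fastq

__all__ = [
    "Pseudoread",
    "MappabilityReport",
    "generate_pseudoreads",
    "classify_uniqueness",
    "region_mappability",
    "reverse_complement",
]

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class Pseudoread:
    """An error-free read copied from the reference at ``origin``."""

    origin: Interval
    sequence: str

    @property
    def id(self) -> str:
        return f"{self.origin.chrom}:{self.origin.start}-{self.origin.end}"


@dataclass(frozen=True)
class MappabilityReport:
    """Uniqueness classification of a region's pseudoread tiling.

    Reads containing N are not classifiable by exact match and are excluded
    from the unique/multi denominator; ``unique_fraction`` is
    n_unique / (n_unique + n_multi) (0.0 when nothing is classifiable).
    """

    region: Interval
    read_length: int
    step: int
    n_reads: int
    n_unique: int
    n_multi: int
    n_containing_n: int

    @property
    def unique_fraction(self) -> float:
        classified = self.n_unique + self.n_multi
        return self.n_unique / classified if classified else 0.0


def generate_pseudoreads(
    genome: Mapping[str, str],
    region: Interval,
    length: int = 100,
    step: int = 1,
) -> list[Pseudoread]:
    """Tile ``region`` with reads at starts region.start, +step, ...; the
    last start is the largest one with start + length <= region.end, giving
    floor((region_len - length) / step) + 1 reads."""
    if length < 1:
        raise ValueError("read length must be >= 1")
    if step < 1:
        raise ValueError("step must be >= 1")
    if region.chrom not in genome:
        raise ValueError(f"unknown chromosome {region.chrom!r}")
    seq = genome[region.chrom]
    if region.end > len(seq):
        raise ValueError("region extends beyond chromosome end")
    if len(region) < length:
        raise ValueError(
            f"region length {len(region)} shorter than read length {length}"
        )
    reads = []
    for start in range(region.start, region.end - length + 1, step):
        reads.append(
            Pseudoread(
                origin=Interval(region.chrom, start, start + length),
                sequence=seq[start : start + length],
            )
        )
    return reads


def _canonical(seq: str) -> str:
    rc = reverse_complement(seq)
    return seq if seq <= rc else rc


def classify_uniqueness(
    reads: Sequence[Pseudoread], genome: Mapping[str, str]
) -> MappabilityReport:
    """Count genomic occurrences of each read's sequence, strand-folded.

    A read is ``unique`` if its sequence (or reverse complement) occurs at
    exactly one genomic site and ``multi`` at two or more; a palindromic
    read's forward/reverse hit at one site collapses to one occurrence.
    The genome is scanned once, indexing only the L-mers the reads ask
    about, rather than re-searching per read.
    """
    if not reads:
        raise ValueError("no reads to classify")
    lengths = {len(r.sequence) for r in reads}
    if len(lengths) != 1:
        raise ValueError(f"mixed read lengths {sorted(lengths)}")
    L = lengths.pop()

    wanted: dict[str, int] = {}
    lookup: dict[str, str] = {}  # forward or reverse-complement L-mer -> canonical
    for r in reads:
        if "N" not in r.sequence:
            canon = _canonical(r.sequence)
            wanted.setdefault(canon, 0)
            lookup[r.sequence] = canon
            lookup[reverse_complement(r.sequence)] = canon

    # One pass over the genome: each genomic site contributes one count when
    # its forward L-mer matches a queried read in either orientation, so a
    # palindromic read's forward/reverse hit at one site is counted once.
    for seq in genome.values():
        n = len(seq)
        for i in range(n - L + 1):
            canon = lookup.get(seq[i : i + L])
            if canon is not None:
                wanted[canon] += 1

    n_unique = n_multi = n_with_n = 0
    region_chrom = reads[0].origin.chrom
    lo = min(r.origin.start for r in reads)
    hi = max(r.origin.end for r in reads)
    for r in reads:
        if "N" in r.sequence:
            n_with_n += 1
        elif wanted[_canonical(r.sequence)] >= 2:
            n_multi += 1
        else:
            n_unique += 1
    return MappabilityReport(
        region=Interval(region_chrom, lo, hi),
        read_length=L,
        step=reads[1].origin.start - reads[0].origin.start if len(reads) > 1 else 1,
        n_reads=len(reads),
        n_unique=n_unique,
        n_multi=n_multi,
        n_containing_n=n_with_n,
    )


def region_mappability(
    genome: Mapping[str, str],
    region: Interval,
    length: int = 100,
    step: int = 1,
    fastq_path: str | Path | None = None,
) -> MappabilityReport:
    """Tile ``region``, classify every pseudoread's uniqueness in the whole
    genome, optionally writing the reads as FASTQ for external mappers."""
    reads = generate_pseudoreads(genome, region, length=length, step=step)
    if fastq_path is not None:
        write_fastq(((r.id, r.sequence) for r in reads), fastq_path)
    return classify_uniqueness(reads, genome)
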