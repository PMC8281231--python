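"""Readers and writers for the formats the pipeline touches.

All coordinates everywhere in this package are 0-based half-open
(UCSC/BED convention), matching the source annotation tables.

Supported formats: multi-record FASTA, BED3+name, bedGraph, FASTQ, and
three UCSC repeat-table dialects (``rmsk``, ``simpleRepeat``,
``microsat``) as minimal tab-separated column projections.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .repeat_catalog import RepeatRecord

__all__ = [
    "GenomeInfo",
    "Interval",
    "FormatError",
    "read_fasta",
    "write_fasta",
    "parse_repeat_table",
    "read_bed",
    "write_bed",
    "write_bedgraph",
    "write_fastq",
    "REPEAT_TABLE_DIALECTS",
]


class FormatError(ValueError):
    """A file did not match the expected dialect/format."""


@dataclass(frozen=True)
class GenomeInfo:
    """Chromosome names and lengths; ``total_length`` is the |genome| that
    normalizes the representation formulas."""

    chrom_names: tuple[str, ...]
    chrom_lengths: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.chrom_names) != len(self.chrom_lengths):
            raise ValueError("chrom_names and chrom_lengths differ in length")
        if len(set(self.chrom_names)) != len(self.chrom_names):
            raise ValueError("chromosome names must be unique")
        if any(l <= 0 for l in self.chrom_lengths):
            raise ValueError("all chromosome lengths must be > 0")

    @property
    def total_length(self) -> int:
        return sum(self.chrom_lengths)

    @property
    def lengths(self) -> dict[str, int]:
        return dict(zip(self.chrom_names, self.chrom_lengths))

    @classmethod
    def from_sequences(cls, genome: Mapping[str, str]) -> "GenomeInfo":
        return cls(tuple(genome), tuple(len(s) for s in genome.values()))


@dataclass(frozen=True, order=True)
class Interval:
    """Half-open genomic interval [start, end) on ``chrom``."""

    chrom: str
    start: int
    end: int
    name: str | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )

    def __len__(self) -> int:
        return self.end - self.start

    def validate_against(self, info: GenomeInfo) -> None:
        lengths = info.lengths
        if self.chrom not in lengths:
            raise ValueError(f"unknown chromosome {self.chrom!r}")
        if self.end > lengths[self.chrom]:
            raise ValueError(
                f"interval {self.chrom}:{self.start}-{self.end} exceeds "
                f"chromosome length {lengths[self.chrom]}"
            )


# ---------------------------------------------------------------------------
# FASTA

_VALID_FASTA = re.compile(r"^[ACGTNacgtn]*$")


def read_fasta(path: str | Path) -> tuple[dict[str, str], GenomeInfo]:
    """Read a multi-record FASTA into ``{chrom: UPPERCASE sequence}``.

    Lowercase (soft-masked) bases are folded to uppercase; record order is
    preserved. Raises :class:`FormatError` on empty records or sequences
    outside the {A, C, G, T, N} alphabet.
    """
    path = Path(path)
    genome: dict[str, str] = {}
    try:
        records = list(SeqIO.parse(str(path), "fasta"))
    except ValueError as exc:
        raise FormatError(f"{path}: {exc}") from exc
    for record in records:
        seq = str(record.seq)
        if not seq:
            raise FormatError(f"{path}: empty record {record.id!r}")
        if record.id in genome:
            raise FormatError(f"{path}: duplicate record {record.id!r}")
        if not _VALID_FASTA.match(seq):
            bad = sorted(set(seq) - set("ACGTNacgtn"))
            raise FormatError(
                f"{path}: record {record.id!r} contains invalid characters {bad}"
            )
        genome[record.id] = seq.upper()
    if not genome:
        raise FormatError(f"{path}: no FASTA records found")
    return genome, GenomeInfo.from_sequences(genome)


def write_fasta(genome: Mapping[str, str], path: str | Path, width: int = 60) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in genome.items()
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(records)


# ---------------------------------------------------------------------------
# UCSC repeat-table dialects
#
# Minimal column projections (extra trailing columns are ignored):
#   simpleRepeat: chrom chromStart chromEnd period copyNum perMatch consensus
#   rmsk:         genoName genoStart genoEnd repName repClass repFamily
#   microsat:     chrom chromStart chromEnd name      name = "(UNIT)n xCOPIES"

REPEAT_TABLE_DIALECTS = ("rmsk", "simpleRepeat", "microsat")

_MICROSAT_NAME = re.compile(r"^\((?P<unit>[ACGTNacgtn]+)\)n\s*[x×]\s*(?P<copies>[\d.]+)$")
_RMSK_NAME = re.compile(r"^\((?P<unit>[ACGTNacgtn]+)\)n$")

#: rmsk repClass values retained as simple repeats (Satellite optional).
RMSK_SIMPLE_CLASSES = frozenset({"Simple_repeat"})
RMSK_SATELLITE_CLASSES = frozenset({"Satellite"})


def _split_row(line: str, min_cols: int, dialect: str, lineno: int, path: Path) -> list[str]:
    cols = line.rstrip("\n").split("\t")
    if len(cols) < min_cols:
        raise FormatError(
            f"{path}:{lineno}: expected >= {min_cols} tab-separated columns "
            f"for dialect {dialect!r}, got {len(cols)}"
        )
    return cols


def _int_field(value: str, what: str, lineno: int, path: Path) -> int:
    try:
        return int(value)
    except ValueError as exc:
        raise FormatError(f"{path}:{lineno}: non-numeric {what} {value!r}") from exc


def _float_field(value: str, what: str, lineno: int, path: Path) -> float:
    try:
        return float(value)
    except ValueError as exc:
        raise FormatError(f"{path}:{lineno}: non-numeric {what} {value!r}") from exc


def parse_repeat_table(
    path: str | Path,
    dialect: str,
    *,
    include_satellites: bool = False,
) -> list[RepeatRecord]:
    """Parse one UCSC repeat-annotation table into :class:`RepeatRecord` rows.

    ``dialect`` is one of ``rmsk`` (RepeatMasker), ``simpleRepeat`` (Tandem
    Repeat Finder) or ``microsat``. Coordinates are kept 0-based half-open as
    stored by UCSC. For ``rmsk``, only rows whose ``repClass`` marks them as
    simple repeats are kept (plus Satellite rows when ``include_satellites``);
    interspersed-repeat classes (LINE/SINE/LTR/...) belong to the
    transposable-element side of the analysis, not the repeat catalogue.
    """
    path = Path(path)
    if dialect not in REPEAT_TABLE_DIALECTS:
        raise ValueError(f"unknown dialect {dialect!r}; expected one of {REPEAT_TABLE_DIALECTS}")

    records: list[RepeatRecord] = []
    keep_classes = RMSK_SIMPLE_CLASSES | (RMSK_SATELLITE_CLASSES if include_satellites else frozenset())

    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            if dialect == "simpleRepeat":
                cols = _split_row(line, 7, dialect, lineno, path)
                chrom = cols[0]
                start = _int_field(cols[1], "chromStart", lineno, path)
                end = _int_field(cols[2], "chromEnd", lineno, path)
                period = _int_field(cols[3], "period", lineno, path)
                copies = _float_field(cols[4], "copyNum", lineno, path)
                similarity = _float_field(cols[5], "perMatch", lineno, path)
                unit = cols[6].upper()
                # TRF's reported period can disagree with the consensus; the
                # record schema derives period from the consensus length.
                period = len(unit) if unit else period
                records.append(
                    RepeatRecord(
                        chrom=chrom, start=start, end=end, unit=unit,
                        period=period, copies=copies, similarity=similarity,
                        source_db="simpleRepeat",
                    )
                )
            elif dialect == "rmsk":
                cols = _split_row(line, 6, dialect, lineno, path)
                chrom = cols[0]
                start = _int_field(cols[1], "genoStart", lineno, path)
                end = _int_field(cols[2], "genoEnd", lineno, path)
                rep_name, rep_class = cols[3], cols[4]
                if rep_class not in keep_classes:
                    continue
                m = _RMSK_NAME.match(rep_name)
                unit = m.group("unit").upper() if m else rep_name.upper()
                period = len(unit)
                copies = (end - start) / period if period else 0.0
                records.append(
                    RepeatRecord(
                        chrom=chrom, start=start, end=end, unit=unit,
                        period=period, copies=copies, similarity=100.0,
                        source_db="rmsk",
                    )
                )
            else:  # microsat
                cols = _split_row(line, 4, dialect, lineno, path)
                chrom = cols[0]
                start = _int_field(cols[1], "chromStart", lineno, path)
                end = _int_field(cols[2], "chromEnd", lineno, path)
                m = _MICROSAT_NAME.match(cols[3].strip())
                if not m:
                    raise FormatError(
                        f"{path}:{lineno}: microsat name {cols[3]!r} does not "
                        "match '(UNIT)n xCOPIES'"
                    )
                unit = m.group("unit").upper()
                records.append(
                    RepeatRecord(
                        chrom=chrom, start=start, end=end, unit=unit,
                        period=len(unit), copies=float(m.group("copies")),
                        similarity=100.0, source_db="microsat",
                    )
                )
    return records


# ---------------------------------------------------------------------------
# BED / bedGraph / FASTQ


def read_bed(path: str | Path) -> list[Interval]:
    """Read BED3+name; extra columns ignored, track/browser lines skipped."""
    path = Path(path)
    intervals: list[Interval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped or stripped.startswith(("#", "track", "browser")):
                continue
            cols = stripped.split("\t")
            if len(cols) < 3:
                raise FormatError(f"{path}:{lineno}: BED line has < 3 columns")
            start = _int_field(cols[1], "start", lineno, path)
            end = _int_field(cols[2], "end", lineno, path)
            if start >= end:
                raise FormatError(f"{path}:{lineno}: start {start} >= end {end}")
            intervals.append(
                Interval(cols[0], start, end, cols[3] if len(cols) > 3 else None)
            )
    return intervals


def write_bed(intervals: Iterable[Interval], path: str | Path) -> None:
    """Canonical BED: tab-separated, newline-terminated, name column only
    when present."""
    with open(path, "w") as fh:
        for iv in intervals:
            if iv.name is not None:
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.name}\n")
            else:
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")


def write_bedgraph(
    windows: Iterable[tuple[str, int, int, float]],
    path: str | Path,
    decimals: int = 2,
) -> None:
    """bedGraph with fixed decimal formatting so output is byte-stable."""
    with open(path, "w") as fh:
        for chrom, start, end, value in windows:
            if start >= end:
                raise ValueError(f"bedGraph window {chrom}:{start}-{end} has start >= end")
            fh.write(f"{chrom}\t{start}\t{end}\t{value:.{decimals}f}\n")


def write_fastq(reads: Iterable[tuple[str, str]], path: str | Path, quality_char: str = "I") -> None:
    """FASTQ with a constant maximal quality string: the pseudoreads are
    error-free reference copies, so only id and sequence carry information."""
    if len(quality_char) != 1:
        raise ValueError("quality_char must be a single character")
    with open(path, "w") as fh:
        for read_id, seq in reads:
            fh.write(f"@{read_id}\n{seq}\n+\n{quality_char * len(seq)}\n")
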