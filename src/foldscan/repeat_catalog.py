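"""Simple-repeat catalogue: composition classification, filtering,
concatenation, TNR identification, locus clustering and summaries.

The catalogue pipeline mirrors how AT-/CG-rich simple repeats are extracted
from UCSC annotation tracks: repeat-unit lengths 1-14 bp, a 60 %
composition threshold on the consensus unit (the mean human GC content is
~41 %, so a unit above 60 % C/G is distinctly GC-enriched), trinucleotide
repeats (TNRs) taken from the RepeatMasker track, and records from the
Tandem Repeat Finder / microsatellite tracks concatenated when adjacent
records continue the same unit. Clustering nearby CG-rich TNRs into loci is
the computation that singles out the largest such cluster in a genome — on
hg38 this is the ~333-member locus at 2p11.2 known as FOLD1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import pandas as pd

__all__ = [
    "RepeatRecord",
    "RepeatCluster",
    "CatalogSummary",
    "ClassSummary",
    "unit_composition",
    "classify",
    "filter_catalog",
    "normalize_unit",
    "concatenate",
    "identify_tnrs",
    "cluster_tnrs",
    "summarize",
    "build_catalog",
    "catalog_to_frame",
    "frame_to_catalog",
    "write_catalog",
    "read_catalog",
    "DEFAULT_THRESHOLD",
    "DEFAULT_MIN_PERIOD",
    "DEFAULT_MAX_PERIOD",
    "DEFAULT_CLUSTER_GAP",
]

DEFAULT_THRESHOLD = 0.60
DEFAULT_MIN_PERIOD = 1
DEFAULT_MAX_PERIOD = 14
#: Suggested clustering gap: chosen so that a BAC-scale locus (~150-200 kb)
#: chains into a single cluster.
DEFAULT_CLUSTER_GAP = 10_000

COMP_CLASSES = ("CG_rich", "AT_rich", "other")
SOURCE_DBS = ("rmsk", "simpleRepeat", "microsat")


@dataclass
class RepeatRecord:
    """One annotated simple repeat.

    Fields follow the catalogue schema: position, consensus unit, unit
    length (period), copy number, total span, percent similarity of the
    repeat chain to the consensus, source database, and the composition
    fractions/class derived from the consensus unit.
    """

    chrom: str
    start: int
    end: int
    unit: str
    period: int
    copies: float
    similarity: float
    source_db: str
    cg_fraction: float = 0.0
    at_fraction: float = 0.0
    comp_class: str = "other"

    def __post_init__(self) -> None:
        if self.start < 0 or self.end <= self.start:
            raise ValueError(
                f"invalid repeat coordinates {self.chrom}:{self.start}-{self.end}"
            )
        if self.source_db not in SOURCE_DBS:
            raise ValueError(f"unknown source_db {self.source_db!r}")

    @property
    def span(self) -> int:
        return self.end - self.start


@dataclass
class RepeatCluster:
    """A run of nearby TNRs treated as one locus."""

    chrom: str
    start: int
    end: int
    member_records: list[RepeatRecord]
    max_gap_used: int

    @property
    def member_count(self) -> int:
        return len(self.member_records)

    @property
    def tnr_count(self) -> int:
        return sum(1 for r in self.member_records if r.period == 3)

    @property
    def span(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class ClassSummary:
    record_count: int
    unit_length_classes: int
    copy_min: float | None
    copy_max: float | None


@dataclass(frozen=True)
class CatalogSummary:
    """Per-composition-class record counts, unit-length diversity and copy
    number ranges; TNR (period-3) ranges reported separately."""

    by_class: dict[str, ClassSummary]
    tnr_by_class: dict[str, ClassSummary]


# ---------------------------------------------------------------------------
# Composition and classification


def unit_composition(unit: str) -> tuple[float, float]:
    """(cg_fraction, at_fraction) of a consensus unit.

    N bases count in the denominator but in neither numerator, which is
    conservative for classification.
    """
    if not unit:
        raise ValueError("empty repeat unit")
    u = unit.upper()
    bad = set(u) - set("ACGTN")
    if bad:
        raise ValueError(f"unit {unit!r} contains invalid characters {sorted(bad)}")
    n = len(u)
    cg = (u.count("C") + u.count("G")) / n
    at = (u.count("A") + u.count("T")) / n
    return cg, at


def classify(record: RepeatRecord, threshold: float = DEFAULT_THRESHOLD) -> RepeatRecord:
    """Assign the composition class from the consensus unit.

    CG_rich iff cg_fraction >= threshold, else AT_rich iff
    at_fraction >= threshold, else other. Returns a new record with
    ``cg_fraction``, ``at_fraction`` and ``comp_class`` filled in.
    """
    if not (0.0 < threshold <= 1.0):
        raise ValueError(f"threshold {threshold} outside (0, 1]")
    cg, at = unit_composition(record.unit)
    if cg >= threshold:
        comp = "CG_rich"
    elif at >= threshold:
        comp = "AT_rich"
    else:
        comp = "other"
    return replace(record, cg_fraction=cg, at_fraction=at, comp_class=comp)


def filter_catalog(
    records: Iterable[RepeatRecord],
    min_period: int = DEFAULT_MIN_PERIOD,
    max_period: int = DEFAULT_MAX_PERIOD,
    classes: Sequence[str] = ("CG_rich", "AT_rich"),
) -> list[RepeatRecord]:
    """Order-preserving subset: keep records whose unit length lies in
    [min_period, max_period] and whose composition class is wanted."""
    keep = set(classes)
    return [
        r
        for r in records
        if min_period <= r.period <= max_period and r.comp_class in keep
    ]


# ---------------------------------------------------------------------------
# Concatenation of continued records (TRF / microsat tracks)


def normalize_unit(unit: str) -> str:
    """Lexicographically minimal rotation — TRF reports arbitrary phase, so
    CGGCGG... may be annotated as CGG, GGC or GCG. Strand is NOT folded
    (CGG and CCG stay distinct classes)."""
    u = unit.upper()
    return min(u[i:] + u[:i] for i in range(len(u)))


def concatenate(
    records: Sequence[RepeatRecord],
    same_unit_only: bool = True,
    max_gap: int = 0,
) -> list[RepeatRecord]:
    """Merge runs of records that continue the same repeat chain.

    Records must be on one chromosome and sorted by start. Consecutive
    records whose normalized units match (when ``same_unit_only``) and whose
    gap is <= ``max_gap`` merge into one record with copies = span / period
    and span-weighted mean similarity. Only simpleRepeat/microsat records
    participate; rmsk records pass through untouched (the TNR side of the
    pipeline uses them as annotated).
    """
    if max_gap < 0:
        raise ValueError("max_gap must be >= 0")
    recs = list(records)
    chroms = {r.chrom for r in recs}
    if len(chroms) > 1:
        raise ValueError(f"concatenate expects one chromosome, got {sorted(chroms)}")
    if any(a.start > b.start for a, b in zip(recs, recs[1:])):
        raise ValueError("records must be sorted by start")

    out: list[RepeatRecord] = []
    run: list[RepeatRecord] = []

    def flush() -> None:
        if not run:
            return
        if len(run) == 1:
            out.append(run[0])
        else:
            start = run[0].start
            end = max(r.end for r in run)
            span = end - start
            period = run[0].period
            total_member_span = sum(r.span for r in run)
            sim = sum(r.similarity * r.span for r in run) / total_member_span
            out.append(
                replace(
                    run[0],
                    start=start,
                    end=end,
                    copies=span / period if period else 0.0,
                    similarity=sim,
                )
            )
        run.clear()

    for rec in recs:
        if rec.source_db == "rmsk":
            flush()
            out.append(rec)
            continue
        if run:
            prev = run[-1]
            joinable = (
                prev.source_db != "rmsk"
                and rec.start - prev.end <= max_gap
                and rec.start >= prev.end
                and (not same_unit_only or normalize_unit(rec.unit) == normalize_unit(prev.unit))
            )
            if not joinable:
                flush()
        run.append(rec)
    flush()
    return out


# ---------------------------------------------------------------------------
# TNRs and clustering


def identify_tnrs(
    records: Iterable[RepeatRecord],
    tnr_source_rmsk_only: bool = True,
) -> list[RepeatRecord]:
    """Period-3 subset; restricted to RepeatMasker records by default, the
    track the TNR analysis is anchored on."""
    return [
        r
        for r in records
        if r.period == 3 and (not tnr_source_rmsk_only or r.source_db == "rmsk")
    ]


def cluster_tnrs(records: Sequence[RepeatRecord], max_gap: int) -> list[RepeatCluster]:
    """Single-linkage chaining of genome-sorted TNRs into loci.

    Consecutive records on the same chromosome whose gap is <= ``max_gap``
    join one cluster. Clusters are returned sorted by member count
    descending, ties broken by genomic position, so the top entry is the
    FOLD1-style answer: the largest TNR cluster in the genome.
    """
    if max_gap < 0:
        raise ValueError("max_gap must be >= 0")
    recs = sorted(records, key=lambda r: (r.chrom, r.start, r.end))
    clusters: list[RepeatCluster] = []
    current: list[RepeatRecord] = []

    def flush() -> None:
        if not current:
            return
        clusters.append(
            RepeatCluster(
                chrom=current[0].chrom,
                start=min(r.start for r in current),
                end=max(r.end for r in current),
                member_records=list(current),
                max_gap_used=max_gap,
            )
        )
        current.clear()

    prev: RepeatRecord | None = None
    for rec in recs:
        if prev is not None and (rec.chrom != prev.chrom or rec.start - prev.end > max_gap):
            flush()
        current.append(rec)
        prev = rec
    flush()
    clusters.sort(key=lambda c: (-c.member_count, c.chrom, c.start))
    return clusters


# ---------------------------------------------------------------------------
# Summaries


def _summarize_subset(records: Sequence[RepeatRecord]) -> ClassSummary:
    if not records:
        return ClassSummary(0, 0, None, None)
    copies = [r.copies for r in records]
    return ClassSummary(
        record_count=len(records),
        unit_length_classes=len({r.period for r in records}),
        copy_min=min(copies),
        copy_max=max(copies),
    )


def summarize(records: Sequence[RepeatRecord]) -> CatalogSummary:
    """Catalogue summary: per-class totals, unit-length diversity and
    copy-number ranges, with period-3 (TNR) ranges reported separately."""
    by_class = {
        cls: _summarize_subset([r for r in records if r.comp_class == cls])
        for cls in COMP_CLASSES
    }
    tnr_by_class = {
        cls: _summarize_subset(
            [r for r in records if r.comp_class == cls and r.period == 3]
        )
        for cls in COMP_CLASSES
    }
    return CatalogSummary(by_class=by_class, tnr_by_class=tnr_by_class)


# ---------------------------------------------------------------------------
# Catalogue assembly and TSV round trip


def build_catalog(
    records: Iterable[RepeatRecord],
    threshold: float = DEFAULT_THRESHOLD,
    min_period: int = DEFAULT_MIN_PERIOD,
    max_period: int = DEFAULT_MAX_PERIOD,
    concat_gap: int = 0,
    deduplicate: bool = True,
) -> list[RepeatRecord]:
    """Classify, filter and concatenate records from all source tables into
    the AT/CG-rich catalogue.

    The same genomic repeat can be annotated in more than one source track;
    with ``deduplicate`` (default) records sharing (chrom, start, end,
    normalized unit) are kept once, preferring the RepeatMasker copy so TNR
    identification still sees it. simpleRepeat/microsat records are then
    concatenated per chromosome.
    """
    classified = [classify(r, threshold) for r in records]
    kept = filter_catalog(classified, min_period, max_period)

    if deduplicate:
        priority = {"rmsk": 0, "simpleRepeat": 1, "microsat": 2}
        best: dict[tuple, RepeatRecord] = {}
        for r in kept:
            key = (r.chrom, r.start, r.end, normalize_unit(r.unit))
            if key not in best or priority[r.source_db] < priority[best[key].source_db]:
                best[key] = r
        kept = list(best.values())

    kept.sort(key=lambda r: (r.chrom, r.start, r.end))
    out: list[RepeatRecord] = []
    for chrom in sorted({r.chrom for r in kept}):
        out.extend(concatenate([r for r in kept if r.chrom == chrom], max_gap=concat_gap))
    return out


_CATALOG_COLUMNS = [
    "chrom", "start", "end", "unit", "period", "copies", "span",
    "similarity", "source_db", "cg_fraction", "at_fraction", "comp_class",
]


def catalog_to_frame(records: Sequence[RepeatRecord]) -> pd.DataFrame:
    rows = [
        {
            "chrom": r.chrom, "start": r.start, "end": r.end, "unit": r.unit,
            "period": r.period, "copies": r.copies, "span": r.span,
            "similarity": r.similarity, "source_db": r.source_db,
            "cg_fraction": r.cg_fraction, "at_fraction": r.at_fraction,
            "comp_class": r.comp_class,
        }
        for r in records
    ]
    return pd.DataFrame(rows, columns=_CATALOG_COLUMNS)


def frame_to_catalog(frame: pd.DataFrame) -> list[RepeatRecord]:
    return [
        RepeatRecord(
            chrom=row.chrom, start=int(row.start), end=int(row.end),
            unit=row.unit, period=int(row.period), copies=float(row.copies),
            similarity=float(row.similarity), source_db=row.source_db,
            cg_fraction=float(row.cg_fraction), at_fraction=float(row.at_fraction),
            comp_class=row.comp_class,
        )
        for row in frame.itertuples(index=False)
    ]


def write_catalog(records: Sequence[RepeatRecord], path) -> None:
    catalog_to_frame(records).to_csv(path, sep="\t", index=False)


def read_catalog(path) -> list[RepeatRecord]:
    return frame_to_catalog(pd.read_csv(path, sep="\t"))
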