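"""Synthetic genomes with embedded tandem repeats and known ground truth.

Every downstream stage of the pipeline (cataloguing, clustering,
enrichment, composition profiling, mappability) is testable against
genomes built here: a multi-chromosome FASTA with tandem repeats embedded
verbatim at known positions, matched annotation rows in all three UCSC
repeat-table dialects, and feature BED files placed either uniformly at
random or with configured enrichment near repeat loci.

:func:`build_benchmark_spec` assembles the default study conditions — a
miniature of the human repeat landscape with the genome facts planted as
inputs: ~30x as many AT-rich as CG-rich simple repeats, CG-rich TNR copy
numbers spanning 1-332 (a FRAXA-like uninterrupted CGG tract at the top)
and AT-rich 1-161, and a 333-member CG-rich TNR cluster on a chr2
analogue whose locus GC content is 92.6 % by construction and whose
longest contiguous CGG run is 17 units.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Mapping, Sequence

import numpy as np

from .genome_io import GenomeInfo, Interval, write_bed, write_fasta
from .repeat_catalog import (
    DEFAULT_CLUSTER_GAP,
    DEFAULT_THRESHOLD,
    RepeatRecord,
    unit_composition,
)

__all__ = [
    "InterruptionRule",
    "RepeatSpec",
    "FeatureSpec",
    "SyntheticSpec",
    "GroundTruth",
    "SyntheticBundle",
    "embed_interruptions",
    "generate",
    "write_bundle",
    "build_benchmark_spec",
]


@dataclass(frozen=True)
class InterruptionRule:
    """Interrupt a tandem repeat after every ``period`` units with
    ``base``, so the longest uninterrupted unit run equals ``period``."""

    period: int
    base: str = "A"

    def __post_init__(self) -> None:
        if self.period < 1:
            raise ValueError("interruption period must be >= 1")
        if len(self.base) < 1 or set(self.base.upper()) - set("ACGT"):
            raise ValueError("interrupting base(s) must be non-empty ACGT")


@dataclass(frozen=True)
class RepeatSpec:
    chrom: str
    position: int
    unit: str
    copies: int
    interruption: InterruptionRule | None = None

    def realized_sequence(self) -> str:
        if self.interruption is None:
            return self.unit * self.copies
        return embed_interruptions(self.unit, self.copies, self.interruption)

    @property
    def end(self) -> int:
        return self.position + len(self.realized_sequence())


@dataclass(frozen=True)
class SequenceInsert:
    """Verbatim sequence placed in the genome WITHOUT a matching annotation
    row — used for spacers and other fixed context around planted repeats."""

    chrom: str
    position: int
    sequence: str

    @property
    def end(self) -> int:
        return self.position + len(self.sequence)


@dataclass(frozen=True)
class FeatureSpec:
    """``placement`` is ``"uniform"`` or ``"near_repeats"``; the latter
    samples feature starts uniformly within +/- ``distance`` of a randomly
    chosen embedded-repeat midpoint (clipped to the chromosome), creating
    tunable true enrichment."""

    name: str
    count: int
    length: int
    placement: Literal["uniform", "near_repeats"] = "uniform"
    distance: int = 1000


@dataclass
class SyntheticSpec:
    chrom_lengths: dict[str, int]
    background_gc: float = 0.41
    repeat_specs: list[RepeatSpec] = field(default_factory=list)
    insert_specs: list[SequenceInsert] = field(default_factory=list)
    feature_specs: list[FeatureSpec] = field(default_factory=list)
    seed: int = 0
    cluster_gap: int = DEFAULT_CLUSTER_GAP
    threshold: float = DEFAULT_THRESHOLD

    def validate(self) -> None:
        if not self.chrom_lengths:
            raise ValueError("spec needs at least one chromosome")
        if not (0.0 <= self.background_gc <= 1.0):
            raise ValueError("background_gc must lie in [0, 1]")
        by_chrom: dict[str, list[tuple[int, int, str]]] = {}
        for rs in self.repeat_specs:
            if rs.chrom not in self.chrom_lengths:
                raise ValueError(f"repeat on unknown chromosome {rs.chrom!r}")
            if rs.end > self.chrom_lengths[rs.chrom]:
                raise ValueError(
                    f"repeat {rs.unit}x{rs.copies} at {rs.chrom}:{rs.position} "
                    "extends beyond the chromosome"
                )
            by_chrom.setdefault(rs.chrom, []).append(
                (rs.position, rs.end, f"{rs.unit}x{rs.copies}")
            )
        for ins in self.insert_specs:
            if ins.chrom not in self.chrom_lengths:
                raise ValueError(f"insert on unknown chromosome {ins.chrom!r}")
            if ins.end > self.chrom_lengths[ins.chrom]:
                raise ValueError(f"insert at {ins.chrom}:{ins.position} out of bounds")
            by_chrom.setdefault(ins.chrom, []).append(
                (ins.position, ins.end, "insert")
            )
        for chrom, spans in by_chrom.items():
            spans.sort()
            for a, b in zip(spans, spans[1:]):
                if b[0] < a[1]:
                    raise ValueError(
                        f"overlapping embedded sequences on {chrom}: "
                        f"[{a[0]},{a[1]}) ({a[2]}) and [{b[0]},{b[1]}) ({b[2]})"
                    )


@dataclass
class GroundTruth:
    """What the generator knows the genome contains."""

    repeat_records: list[RepeatRecord]
    feature_sets: dict[str, list[Interval]]
    cluster_loci: list[tuple[str, int, int, int]]  # (chrom, start, end, members)


@dataclass
class SyntheticBundle:
    genome: dict[str, str]
    info: GenomeInfo
    truth: GroundTruth
    tables: dict[str, list[str]]  # dialect -> table lines


def embed_interruptions(unit: str, copies: int, rule: InterruptionRule | None) -> str:
    """Tandem repeat sequence with an interrupting base inserted after every
    ``rule.period`` full units, so the longest in-phase run of the unit in
    the output equals ``rule.period`` (when copies exceed it)."""
    if not unit:
        raise ValueError("unit must be non-empty")
    if copies < 1:
        raise ValueError("copies must be >= 1")
    if rule is None:
        return unit * copies
    if rule.period > copies:
        raise ValueError(
            f"interruption period {rule.period} exceeds copy number {copies}"
        )
    parts: list[str] = []
    done = 0
    while done < copies:
        block = min(rule.period, copies - done)
        if parts:
            parts.append(rule.base)
        parts.append(unit * block)
        done += block
    return "".join(parts)


# ---------------------------------------------------------------------------
# Generation

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def _random_sequence(rng: np.random.Generator, length: int, gc: float) -> np.ndarray:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return _BASES[rng.choice(4, size=length, p=p)]


def _truth_record(rs: RepeatSpec) -> RepeatRecord:
    seq = rs.realized_sequence()
    span = len(seq)
    matched = rs.copies * len(rs.unit)
    return RepeatRecord(
        chrom=rs.chrom,
        start=rs.position,
        end=rs.position + span,
        unit=rs.unit.upper(),
        period=len(rs.unit),
        copies=float(rs.copies),
        similarity=round(100.0 * matched / span, 1),
        source_db="simpleRepeat",
    )


def _chain_loci(
    records: Sequence[RepeatRecord], gap: int
) -> list[tuple[str, int, int, int]]:
    """Ground-truth chaining, kept deliberately separate from the catalogue
    module's clustering so recovery tests compare two implementations."""
    recs = sorted(records, key=lambda r: (r.chrom, r.start))
    loci: list[tuple[str, int, int, int]] = []
    i = 0
    while i < len(recs):
        j = i
        while (
            j + 1 < len(recs)
            and recs[j + 1].chrom == recs[i].chrom
            and recs[j + 1].start - recs[j].end <= gap
        ):
            j += 1
        loci.append(
            (recs[i].chrom, recs[i].start, max(r.end for r in recs[i : j + 1]), j - i + 1)
        )
        i = j + 1
    loci.sort(key=lambda l: (-l[3], l[0], l[1]))
    return loci


def _table_lines(records: Sequence[RepeatRecord]) -> dict[str, list[str]]:
    """Annotation rows in the three UCSC dialects.

    Every repeat gets a Tandem Repeat Finder (simpleRepeat) row; period-3
    repeats also get a RepeatMasker row (the track TNR identification is
    anchored on); dinucleotide repeats with >= 15 copies also get a
    microsat row — mirroring which tracks carry which annotations.
    """
    simple, rmsk, microsat = [], [], []
    for r in records:
        simple.append(
            f"{r.chrom}\t{r.start}\t{r.end}\t{r.period}\t{r.copies:g}"
            f"\t{r.similarity:g}\t{r.unit}"
        )
        if r.period == 3:
            rmsk.append(
                f"{r.chrom}\t{r.start}\t{r.end}\t({r.unit})n\tSimple_repeat\tSimple_repeat"
            )
        if r.period == 2 and r.copies >= 15:
            microsat.append(f"{r.chrom}\t{r.start}\t{r.end}\t({r.unit})n x{r.copies:g}")
    return {"simpleRepeat": simple, "rmsk": rmsk, "microsat": microsat}


def generate(spec: SyntheticSpec) -> SyntheticBundle:
    """Materialize a spec: background bases i.i.d. with
    P(C)+P(G) = background_gc, every repeat embedded verbatim at its
    position, feature sets placed after all sequence is fixed. One seeded
    stream drives everything in documented order (chromosome backgrounds in
    spec order, then feature sets in listed order), so output is
    byte-identical across runs."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)

    genome: dict[str, str] = {}
    for chrom, length in spec.chrom_lengths.items():
        arr = _random_sequence(rng, length, spec.background_gc)
        for rs in spec.repeat_specs:
            if rs.chrom == chrom:
                seq = rs.realized_sequence().upper()
                arr[rs.position : rs.position + len(seq)] = np.frombuffer(
                    seq.encode(), dtype=np.uint8
                )
        for ins in spec.insert_specs:
            if ins.chrom == chrom:
                seq = ins.sequence.upper()
                arr[ins.position : ins.position + len(seq)] = np.frombuffer(
                    seq.encode(), dtype=np.uint8
                )
        genome[chrom] = arr.tobytes().decode()

    info = GenomeInfo.from_sequences(genome)
    records = [_truth_record(rs) for rs in spec.repeat_specs]
    records.sort(key=lambda r: (r.chrom, r.start))

    # CG-rich TNRs define the cluster ground truth (the FOLD1-style answer).
    cg_tnrs = [
        r
        for r in records
        if r.period == 3 and unit_composition(r.unit)[0] >= spec.threshold
    ]
    loci = _chain_loci(cg_tnrs, spec.cluster_gap)

    chrom_names = list(spec.chrom_lengths)
    chrom_len = spec.chrom_lengths
    weights = np.array([chrom_len[c] for c in chrom_names], dtype=float)
    weights /= weights.sum()

    feature_sets: dict[str, list[Interval]] = {}
    for fs in spec.feature_specs:
        ivs: list[Interval] = []
        for k in range(fs.count):
            if fs.placement == "uniform":
                chrom = chrom_names[rng.choice(len(chrom_names), p=weights)]
                start = int(rng.integers(0, max(1, chrom_len[chrom] - fs.length)))
            else:  # near_repeats
                if not spec.repeat_specs:
                    raise ValueError("near_repeats placement requires repeat_specs")
                rs = spec.repeat_specs[rng.integers(0, len(spec.repeat_specs))]
                chrom = rs.chrom
                mid = (rs.position + rs.end) // 2
                lo = max(0, mid - fs.distance)
                hi = min(chrom_len[chrom] - fs.length, mid + fs.distance)
                hi = max(hi, lo + 1)
                start = int(rng.integers(lo, hi))
            ivs.append(Interval(chrom, start, start + fs.length, f"{fs.name}_{k}"))
        feature_sets[fs.name] = ivs

    return SyntheticBundle(
        genome=genome,
        info=info,
        truth=GroundTruth(records, feature_sets, loci),
        tables=_table_lines(records),
    )


def write_bundle(bundle: SyntheticBundle, outdir: str | Path) -> dict[str, Path]:
    """Write genome.fa, truth.json, the three dialect tables and
    features/*.bed; returns the path manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    paths["genome"] = outdir / "genome.fa"
    write_fasta(bundle.genome, paths["genome"])

    for dialect, lines in bundle.tables.items():
        p = outdir / f"{dialect}.txt"
        p.write_text("".join(line + "\n" for line in lines))
        paths[dialect] = p

    feat_dir = outdir / "features"
    feat_dir.mkdir(exist_ok=True)
    for name, ivs in bundle.truth.feature_sets.items():
        p = feat_dir / f"{name}.bed"
        write_bed(ivs, p)
        paths[f"features/{name}"] = p

    truth = {
        "repeat_records": [
            {
                "chrom": r.chrom, "start": r.start, "end": r.end, "unit": r.unit,
                "period": r.period, "copies": r.copies, "similarity": r.similarity,
            }
            for r in bundle.truth.repeat_records
        ],
        "cluster_loci": [
            {"chrom": c, "start": s, "end": e, "member_count": n}
            for c, s, e, n in bundle.truth.cluster_loci
        ],
        "feature_sets": {
            name: [[iv.chrom, iv.start, iv.end] for iv in ivs]
            for name, ivs in bundle.truth.feature_sets.items()
        },
    }
    paths["truth"] = outdir / "truth.json"
    paths["truth"].write_text(json.dumps(truth, indent=1, sort_keys=True))
    return paths


# ---------------------------------------------------------------------------
# Default study conditions ("benchmark" bundle)

#: AT-rich unit pool spanning periods 1-14 (all units 100 % A/T).
_AT_UNITS = [
    "T", "AT", "AAT", "AATT", "TATTT", "AATATT", "TTTAATA", "AATATTTA",
    "ATTTATTTA", "AATATTTTAT", "TTATAATTTAT", "AATTTATATTTA",
    "TTTATAATATTTA", "TTATTTTAAATAAT",
]
#: CG-rich unit pool for the sparse non-cluster repeats (>= 60 % C/G).
_CG_UNITS = [
    "C", "CG", "CGG", "CCGG", "GCGCC", "CGGCGC", "GCCGCCG", "CGGCGGCC",
    "GCGGCGGCC", "CCGCGGCGGC", "GCGGCCGCGGC", "CGGCGGCGGCCG",
    "GCCGCCGCCGCGG", "CGGCGGCCGCGGCC",
]

#: Spacer between cluster member records: 6 bp, 2 A/T + 4 G/C, so the
#: locus [first record start, last record end) works out to 92.6 % G+C.
_SPACER_LETTERS = "ATGGCC"


def _cluster_spacer(rng: np.random.Generator) -> str:
    """Random arrangement of the fixed spacer composition; distinct spacer
    contexts keep 100-mers across the locus from recurring exactly."""
    letters = list(_SPACER_LETTERS)
    rng.shuffle(letters)
    return "".join(letters)


def build_benchmark_spec(seed: int = 0) -> SyntheticSpec:
    """The default study conditions: a ~4.4 Mb three-chromosome miniature of
    the human simple-repeat landscape.

    Planted ground truth (all recoverable by the pipeline):

    * 12,600 AT-rich repeats on chr1 (periods 1-14); the period-3 subset has
      copy numbers spanning exactly 1-161.
    * 420 CG-rich repeats (30x fewer than AT-rich): a 333-member CGG cluster
      on chr2 (the FOLD1 analogue), a 332-copy uninterrupted CGG tract on
      chrX (the FRAXA analogue), a single-copy CGG record, and sparse
      singletons spaced beyond the clustering gap.
    * The chr2 cluster: 332 records of (CGG)x7 and one central record of
      (CGG)x17, separated by 6 bp spacers of fixed composition (2 A/T,
      4 G/C). Locus GC is (332*21 + 51 + 332*4) / (332*21 + 51 + 332*6)
      = 8351/9015 = 92.6 %, and the longest contiguous CGG run is the
      central record's 17 units.
    * One feature set placed near repeats (true enrichment) and one placed
      uniformly (null).
    """
    rng = np.random.default_rng(seed)
    chrom_lengths = {"chr1": 2_400_000, "chr2": 1_250_000, "chrX": 700_000}
    repeats: list[RepeatSpec] = []
    inserts: list[SequenceInsert] = []

    # chr1: the AT-rich bulk. Walk along the chromosome with random gaps.
    n_at = 12_600
    at_copies = [int(c) for c in rng.integers(2, 30, size=n_at)]
    at_units = [_AT_UNITS[int(i)] for i in rng.integers(0, len(_AT_UNITS), size=n_at)]
    # plant the exact copy-number extremes in the period-3 subset
    p3_idx = [i for i, u in enumerate(at_units) if len(u) == 3]
    at_copies[p3_idx[0]] = 161
    at_copies[p3_idx[1]] = 1
    pos = 10_000
    for unit, copies in zip(at_units, at_copies):
        if len(unit) >= 6:
            copies = min(copies, 12)  # keep long-unit records compact
        repeats.append(RepeatSpec("chr1", pos, unit, copies))
        pos += len(unit) * copies + int(rng.integers(40, 110))
    if pos >= chrom_lengths["chr1"]:
        raise AssertionError("chr1 walk overflowed; enlarge the chromosome")

    # chr2: the FOLD1 analogue — 333 CG-rich TNR records chained by 6 bp
    # un-annotated spacers into one cluster.
    pos = 200_000
    for k in range(333):
        copies = 17 if k == 166 else 7
        repeats.append(RepeatSpec("chr2", pos, "CGG", copies))
        pos += 3 * copies
        if k < 332:
            spacer = _cluster_spacer(rng)
            # spacers flanking the 17-copy record must not extend its run
            while (k == 165 and spacer.endswith("CGG")) or (
                k == 166 and spacer.startswith("CGG")
            ):
                spacer = _cluster_spacer(rng)
            inserts.append(SequenceInsert("chr2", pos, spacer))
            pos += 6

    # sparse CG-rich singletons on chr2, each farther apart than the
    # clustering gap so they stay singletons
    pos = 300_000
    for k in range(60):
        unit = _CG_UNITS[k % len(_CG_UNITS)]
        copies = int(rng.integers(2, 40)) if len(unit) <= 3 else int(rng.integers(2, 8))
        repeats.append(RepeatSpec("chr2", pos, unit, copies))
        pos += 15_000

    # chrX: FRAXA analogue (332 uninterrupted CGG copies), the single-copy
    # CGG record, and more sparse singletons
    repeats.append(RepeatSpec("chrX", 100_000, "CGG", 332))
    repeats.append(RepeatSpec("chrX", 120_000, "CGG", 1))
    pos = 150_000
    for k in range(25):
        unit = _CG_UNITS[(k * 3) % len(_CG_UNITS)]
        copies = int(rng.integers(2, 40)) if len(unit) <= 3 else int(rng.integers(2, 8))
        repeats.append(RepeatSpec("chrX", pos, unit, copies))
        pos += 14_000

    features = [
        FeatureSpec("near_repeat_features", count=400, length=300,
                    placement="near_repeats", distance=500),
        FeatureSpec("uniform_features", count=400, length=300,
                    placement="uniform"),
    ]
    return SyntheticSpec(
        chrom_lengths=chrom_lengths,
        background_gc=0.41,
        repeat_specs=repeats,
        insert_specs=inserts,
        feature_specs=features,
        seed=seed,
    )
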