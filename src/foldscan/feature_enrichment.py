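"""Expected/observed representation of repeats in genomic feature sets.

For a repeat group of size n and one feature database of size m, on a
genome of length |genome|:

    expected = (sum_i |repeat_i| * sum_j |feature_j|) / |genome|^2
    observed = (sum_j sum_i |repeat_i ∩ feature_j|) / |genome|

The overlap criterion is 1 bp: any pair sharing at least one base
contributes its intersection length. Both spans are raw sums of record
lengths exactly as the formulas are written (no union-merging), and the
enrichment statistic is log2(observed / expected). Under uniform random
placement of features the ratio tends to 1, so log fold change 0 is the
null baseline.
"""

from __future__ import annotations

import math
from collections import defaultdict
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from intervaltree import IntervalTree

from .genome_io import GenomeInfo, Interval

__all__ = [
    "EnrichmentResult",
    "span_sum",
    "merged_span",
    "overlap_sum",
    "count_overlapping_pairs",
    "enrich",
    "permutation_pvalue",
]


@dataclass(frozen=True)
class EnrichmentResult:
    """Representation statistic for one (repeat subset x feature set) pair.

    ``log_fold_change`` is ``None`` when either representation is zero
    (the ratio is undefined and is reported as missing, not as +/-inf).
    """

    feature_db: str
    repeat_subset: str
    repeat_span: int
    feature_span: int
    genome_length: int
    overlap_sum: int
    expected: float
    observed: float
    log_fold_change: float | None


def span_sum(intervals: Iterable[Interval]) -> int:
    """Raw sum of interval lengths — NOT the merged union; the formulas sum
    record lengths as given, so stacked records double count."""
    return sum(len(iv) for iv in intervals)


def merged_span(intervals: Iterable[Interval]) -> int:
    """Union length after merging per chromosome (the sensitivity-analysis
    alternative to the literal raw sum)."""
    by_chrom: dict[str, list[Interval]] = defaultdict(list)
    for iv in intervals:
        by_chrom[iv.chrom].append(iv)
    total = 0
    for ivs in by_chrom.values():
        ivs.sort(key=lambda i: (i.start, i.end))
        cur_start, cur_end = None, None
        for iv in ivs:
            if cur_end is None or iv.start > cur_end:
                if cur_end is not None:
                    total += cur_end - cur_start
                cur_start, cur_end = iv.start, iv.end
            else:
                cur_end = max(cur_end, iv.end)
        if cur_end is not None:
            total += cur_end - cur_start
    return total


def _trees_by_chrom(intervals: Iterable[Interval]) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = defaultdict(IntervalTree)
    for iv in intervals:
        trees[iv.chrom].addi(iv.start, iv.end)
    return dict(trees)


def overlap_sum(repeats: Sequence[Interval], features: Sequence[Interval]) -> int:
    """Sum over all (repeat, feature) cross pairs of their intersection
    length; pairs sharing >= 1 bp contribute. Interval-tree accelerated."""
    trees = _trees_by_chrom(features)
    total = 0
    for rep in repeats:
        tree = trees.get(rep.chrom)
        if tree is None:
            continue
        for hit in tree.overlap(rep.start, rep.end):
            total += min(rep.end, hit.end) - max(rep.start, hit.begin)
    return total


def count_overlapping_pairs(repeats: Sequence[Interval], features: Sequence[Interval]) -> int:
    """Number of (repeat, feature) pairs sharing >= 1 bp."""
    trees = _trees_by_chrom(features)
    return sum(
        len(trees[rep.chrom].overlap(rep.start, rep.end))
        for rep in repeats
        if rep.chrom in trees
    )


def enrich(
    repeats: Sequence[Interval],
    feature_sets: Mapping[str, Sequence[Interval]],
    genome: GenomeInfo,
    repeat_subset: str = "repeats",
    log_base: float = 2.0,
    merged_spans: bool = False,
) -> list[EnrichmentResult]:
    """One :class:`EnrichmentResult` per feature database.

    Feature chromosomes absent from ``genome`` are skipped with a warning
    (they cannot overlap anything in the bound assembly). ``merged_spans``
    switches both span terms to union lengths for sensitivity analysis; the
    default is the literal raw-sum reading of the formulas.
    """
    if genome.total_length <= 0:
        raise ValueError("genome length must be > 0")
    if log_base <= 0 or log_base == 1:
        raise ValueError("log_base must be positive and != 1")
    known = set(genome.chrom_names)
    span = merged_span if merged_spans else span_sum

    reps = [r for r in repeats if r.chrom in known]
    if len(reps) < len(repeats):
        import warnings

        warnings.warn(
            f"{len(repeats) - len(reps)} repeat intervals on chromosomes "
            "absent from the genome were skipped"
        )
    rep_span = span(reps)
    g = genome.total_length

    results: list[EnrichmentResult] = []
    for name, feats in feature_sets.items():
        fs = [f for f in feats if f.chrom in known]
        if len(fs) < len(feats):
            import warnings

            warnings.warn(
                f"feature set {name!r}: {len(feats) - len(fs)} intervals on "
                "unknown chromosomes skipped"
            )
        feat_span = span(fs)
        ov = overlap_sum(reps, fs)
        expected = rep_span * feat_span / (g * g)
        observed = ov / g
        if expected > 0 and observed > 0:
            lfc = math.log(observed / expected, log_base)
        else:
            lfc = None
        results.append(
            EnrichmentResult(
                feature_db=name,
                repeat_subset=repeat_subset,
                repeat_span=rep_span,
                feature_span=feat_span,
                genome_length=g,
                overlap_sum=ov,
                expected=expected,
                observed=observed,
                log_fold_change=lfc,
            )
        )
    return results


def permutation_pvalue(
    repeats: Sequence[Interval],
    features: Sequence[Interval],
    genome: GenomeInfo,
    n_permutations: int = 1000,
    seed: int = 0,
) -> float:
    """Optional shift-permutation p-value for one feature set.

    Each permutation applies an independent circular shift to the repeat set
    on every chromosome and recomputes the overlap sum; the p-value is the
    fraction of permutations with overlap >= observed (add-one corrected).
    Descriptive enrichment reporting does not use this; it is provided for
    users who want a significance attached.
    """
    rng = np.random.default_rng(seed)
    lengths = genome.lengths
    observed = overlap_sum(repeats, features)
    hits = 0
    for _ in range(n_permutations):
        shifts = {c: int(rng.integers(0, l)) for c, l in lengths.items()}
        shifted: list[Interval] = []
        for r in repeats:
            L = lengths[r.chrom]
            s = (r.start + shifts[r.chrom]) % L
            e = s + len(r)
            if e <= L:
                shifted.append(Interval(r.chrom, s, e))
            else:  # wrap across the origin: split
                shifted.append(Interval(r.chrom, s, L))
                shifted.append(Interval(r.chrom, 0, e - L))
        if overlap_sum(shifted, features) >= observed:
            hits += 1
    return (hits + 1) / (n_permutations + 1)
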