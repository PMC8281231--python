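"""Classification, filtering, concatenation, clustering and summaries."""

import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from foldscan.repeat_catalog import (
    RepeatRecord,
    build_catalog,
    classify,
    cluster_tnrs,
    concatenate,
    filter_catalog,
    identify_tnrs,
    normalize_unit,
    read_catalog,
    summarize,
    unit_composition,
    write_catalog,
)


def rec(chrom="c1", start=0, end=None, unit="CGG", copies=10.0,
        source="simpleRepeat", **kw):
    if end is None:
        end = start + int(len(unit) * copies)
    r = RepeatRecord(chrom=chrom, start=start, end=end, unit=unit,
                     period=len(unit), copies=copies, similarity=100.0,
                     source_db=source, **kw)
    return classify(r)


class TestComposition:
    @pytest.mark.parametrize(
        "unit,cg,at",
        [
            ("CGG", 1.0, 0.0),
            ("CGA", 2 / 3, 1 / 3),
            ("AT", 0.0, 1.0),
            ("ACGT", 0.5, 0.5),
            ("CGN", 2 / 3, 0.0),  # N in denominator, neither numerator
            ("NNNN", 0.0, 0.0),
        ],
    )
    def test_fractions(self, unit, cg, at):
        got_cg, got_at = unit_composition(unit)
        assert math.isclose(got_cg, cg) and math.isclose(got_at, at)

    @given(st.text(alphabet="ACGTN", min_size=1, max_size=30))
    @settings(max_examples=200, derandomize=True)
    def test_matches_character_count_oracle(self, unit):
        cg, at = unit_composition(unit)
        assert cg == (unit.count("C") + unit.count("G")) / len(unit)
        assert at == (unit.count("A") + unit.count("T")) / len(unit)
        assert cg + at <= 1.0 + 1e-12

    def test_empty_unit_rejected(self):
        with pytest.raises(ValueError):
            unit_composition("")


class TestClassify:
    @pytest.mark.parametrize(
        "unit,expected",
        [("CGG", "CG_rich"), ("ACGT", "other"), ("AAT", "AT_rich"),
         ("CGC", "CG_rich"), ("ATAT", "AT_rich")],
    )
    def test_threshold_rule(self, unit, expected):
        assert rec(unit=unit).comp_class == expected

    def test_invalid_threshold(self):
        r = rec()
        with pytest.raises(ValueError):
            classify(r, threshold=0.0)
        with pytest.raises(ValueError):
            classify(r, threshold=1.5)

    @given(
        st.text(alphabet="ACGT", min_size=1, max_size=12),
        st.floats(min_value=0.05, max_value=0.95),
        st.floats(min_value=0.0, max_value=0.5),
    )
    @settings(max_examples=150, derandomize=True)
    def test_threshold_monotone(self, unit, threshold, bump):
        """Raising the threshold never promotes a record toward CG_rich."""
        lo = classify(rec(unit=unit), threshold)
        hi = classify(rec(unit=unit), min(1.0, threshold + bump))
        rank = {"other": 0, "AT_rich": 1, "CG_rich": 2}
        if hi.comp_class == "CG_rich":
            assert lo.comp_class == "CG_rich"
        if lo.comp_class == "other":
            assert hi.comp_class == "other" or rank[hi.comp_class] <= rank[lo.comp_class]


class TestFilter:
    def test_period_bounds(self):
        long_unit = "ACG" * 5  # period 15
        records = [rec(unit=long_unit, copies=2), rec(unit="CGG")]
        kept = filter_catalog(records)
        assert [r.unit for r in kept] == ["CGG"]

    def test_empty_input(self):
        assert filter_catalog([]) == []

    def test_class_filter_counts(self):
        records = [rec(unit="CGG", start=i * 100) for i in range(3)] + [
            rec(unit="ACGT", start=1000 + i * 100) for i in range(2)
        ]
        assert len(filter_catalog(records)) == 3


class TestConcatenate:
    def test_adjacent_same_unit_merge(self):
        a = rec(start=100, end=130, copies=10)
        b = rec(start=130, end=160, copies=10)
        (m,) = concatenate([a, b])
        assert (m.start, m.end, m.copies) == (100, 160, 20.0)
        assert m.span == 60

    def test_gap_rule(self):
        a = rec(start=100, end=130)
        b = rec(start=135, end=165)
        assert len(concatenate([a, b], max_gap=0)) == 2
        assert len(concatenate([a, b], max_gap=5)) == 1

    def test_rotation_equivalent_units_merge(self):
        # minimal-rotation oracle: CGG and GGC rotate to the same unit
        assert normalize_unit("GGC") == normalize_unit("CGG") == "CGG"
        assert normalize_unit("CCG") == "CCG" != normalize_unit("CGG")
        a = rec(start=0, end=30, unit="CGG")
        b = rec(start=30, end=60, unit="GGC")
        assert len(concatenate([a, b])) == 1
        c = rec(start=30, end=60, unit="CCG")  # reverse complement, distinct
        assert len(concatenate([a, c])) == 2

    def test_rmsk_records_pass_through(self):
        a = rec(start=0, end=30, source="rmsk")
        b = rec(start=30, end=60, source="rmsk")
        assert len(concatenate([a, b])) == 2

    def test_unsorted_input_rejected(self):
        with pytest.raises(ValueError):
            concatenate([rec(start=100, end=130), rec(start=0, end=30)])

    def test_idempotent_and_coverage_preserving(self):
        records = [rec(start=s, end=s + 30) for s in (0, 30, 60, 200, 400)]
        once = concatenate(records, max_gap=10)
        twice = concatenate(once, max_gap=10)
        assert [(r.start, r.end) for r in once] == [(r.start, r.end) for r in twice]
        assert sum(r.span for r in once) >= sum(r.span for r in records) - 0

    def test_similarity_span_weighted(self):
        a = classify(RepeatRecord("c1", 0, 30, "CGG", 3, 10, 90.0, "simpleRepeat"))
        b = classify(RepeatRecord("c1", 30, 90, "CGG", 3, 20, 99.0, "simpleRepeat"))
        (m,) = concatenate([a, b])
        assert math.isclose(m.similarity, (90.0 * 30 + 99.0 * 60) / 90)


class TestTnrsAndClusters:
    def test_tnr_source_restriction(self):
        records = [
            rec(unit="CGG", source="rmsk"),
            rec(unit="CGG", start=100, source="simpleRepeat"),
            rec(unit="CA", start=200, source="rmsk"),
        ]
        assert len(identify_tnrs(records)) == 1
        assert len(identify_tnrs(records, tnr_source_rmsk_only=False)) == 2

    def test_gap_arithmetic(self):
        records = [
            rec(start=0, end=50, source="rmsk"),
            rec(start=60, end=100, source="rmsk"),
            rec(start=5000, end=5050, source="rmsk"),
        ]
        clusters = cluster_tnrs(records, max_gap=1000)
        assert sorted(c.member_count for c in clusters) == [1, 2]
        assert clusters[0].member_count == 2  # ranked by size

    def test_singleton_cluster_is_its_interval(self):
        (c,) = cluster_tnrs([rec(start=40, end=70, source="rmsk")], max_gap=0)
        assert (c.start, c.end, c.member_count) == (40, 70, 1)

    def test_zero_gap_gives_singletons_and_inf_one_per_chrom(self):
        records = [rec(start=s, end=s + 30, source="rmsk") for s in (0, 100, 200)]
        records += [rec(chrom="c2", start=s, end=s + 30, source="rmsk") for s in (0, 100)]
        assert all(c.member_count == 1 for c in cluster_tnrs(records, max_gap=0))
        big = cluster_tnrs(records, max_gap=10**9)
        assert sorted(c.member_count for c in big) == [2, 3]

    def test_negative_gap_rejected(self):
        with pytest.raises(ValueError):
            cluster_tnrs([], max_gap=-1)

    def test_tie_break_by_position(self):
        records = [rec(start=s, end=s + 30, source="rmsk") for s in (0, 10_000)]
        clusters = cluster_tnrs(records, max_gap=100)
        assert clusters[0].start == 0 and clusters[1].start == 10_000


class TestSummaryAndRoundTrip:
    def test_copy_ranges(self):
        records = [
            rec(unit="CGG", copies=c, start=i * 10_000, source="rmsk")
            for i, c in enumerate((1, 5, 332))
        ]
        s = summarize(records)
        cls = s.tnr_by_class["CG_rich"]
        assert (cls.copy_min, cls.copy_max) == (1, 332)
        assert s.by_class["AT_rich"].record_count == 0
        assert s.by_class["AT_rich"].copy_min is None

    def test_catalog_tsv_round_trip(self, tmp_path):
        records = [rec(unit="CGG"), rec(unit="AAT", start=500)]
        p = tmp_path / "cat.tsv"
        write_catalog(records, p)
        back = read_catalog(p)
        assert [(r.chrom, r.start, r.end, r.unit, r.comp_class) for r in back] == [
            (r.chrom, r.start, r.end, r.unit, r.comp_class) for r in records
        ]

    def test_build_catalog_deduplicates_across_sources(self):
        raw = [
            RepeatRecord("c1", 0, 30, "CGG", 3, 10, 100.0, "simpleRepeat"),
            RepeatRecord("c1", 0, 30, "CGG", 3, 10, 100.0, "rmsk"),
        ]
        cat = build_catalog(raw)
        assert len(cat) == 1
        assert cat[0].source_db == "rmsk"  # TNR identification still sees it
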