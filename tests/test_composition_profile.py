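"""Composition tracks: window tilings, motif scans, histograms, locus GC
and longest-run computation, each against an independent oracle."""

import re

import numpy as np
import pytest

from foldscan.composition_profile import (
    dinucleotide_positions,
    gc_percent_track,
    histogram2d,
    homogenize_windows,
    locus_gc,
    longest_unit_run,
    quantify_windows,
    trinucleotide_positions,
)
from foldscan.genome_io import GenomeInfo, Interval


def regex_starts(seq, pattern):
    return [m.start() for m in re.finditer(f"(?={pattern})", seq)]


def random_genome(seed, length=10_000):
    rng = np.random.default_rng(seed)
    return {"c1": "".join(rng.choice(list("ACGT"), size=length))}


class TestGcTrack:
    def test_simple_windows(self):
        track = gc_percent_track({"c1": "GGGGGAAAAA"}, window=5)
        assert [t[3] for t in track] == [100.0, 0.0]

    def test_all_n_window_is_zero(self):
        track = gc_percent_track({"c1": "NNNNN"}, window=5)
        assert track == [("c1", 0, 5, 0.0)]

    def test_partial_tail_window(self):
        track = gc_percent_track({"c1": "A" * 250}, window=100)
        assert [(t[1], t[2]) for t in track] == [(0, 100), (100, 200), (200, 250)]

    def test_exclude_n_switches_denominator(self):
        seq = {"c1": "GGNNN"}
        assert gc_percent_track(seq, 5)[0][3] == 40.0
        assert gc_percent_track(seq, 5, exclude_n=True)[0][3] == 100.0

    def test_values_bounded_and_mean_matches_locus_gc(self):
        genome = random_genome(1)
        track = gc_percent_track(genome, window=100)
        assert all(0.0 <= t[3] <= 100.0 for t in track)
        weighted = sum(t[3] * (t[2] - t[1]) for t in track) / len(genome["c1"])
        whole = locus_gc(genome, Interval("c1", 0, len(genome["c1"])))
        assert abs(weighted - whole) < 1e-9

    def test_window_below_one_rejected(self):
        with pytest.raises(ValueError):
            gc_percent_track({"c1": "ACGT"}, window=0)


class TestScans:
    def test_cpg_scan(self):
        ivs = dinucleotide_positions({"c1": "ACGCGT"})
        assert [iv.start for iv in ivs] == [1, 3]

    def test_no_occurrences(self):
        assert dinucleotide_positions({"c1": "CCCC"}) == []

    def test_trinucleotide_union_and_overlap(self):
        ivs = trinucleotide_positions({"c1": "AGCCGGCT"})
        assert [iv.start for iv in ivs] == [1, 4]
        # GGCC: GGC at 0 and GCC at 1, overlap permitted
        ivs = trinucleotide_positions({"c1": "GGCC"})
        assert [iv.start for iv in ivs] == [0, 1]
        ivs = trinucleotide_positions({"c1": "GCCGCC"}, patterns=("GCC",))
        assert [iv.start for iv in ivs] == [0, 3]

    def test_scan_matches_regex_oracle(self):
        genome = random_genome(2)
        got = [iv.start for iv in dinucleotide_positions(genome)]
        assert got == regex_starts(genome["c1"], "CG")
        got3 = {iv.start for iv in trinucleotide_positions(genome)}
        want3 = set(regex_starts(genome["c1"], "GCC")) | set(
            regex_starts(genome["c1"], "GGC")
        )
        assert got3 == want3

    def test_pattern_validation(self):
        with pytest.raises(ValueError):
            dinucleotide_positions({"c1": "ACGT"}, pattern="CN")
        with pytest.raises(ValueError):
            dinucleotide_positions({"c1": "ACGT"}, pattern="CGG")
        with pytest.raises(ValueError):
            trinucleotide_positions({"c1": "ACGT"}, patterns=())


class TestWindows:
    def test_homogenize_tiling(self):
        info = GenomeInfo(("c1",), (2500,))
        wins = homogenize_windows(info, 1000)
        assert [(w.start, w.end) for w in wins] == [(0, 1000), (1000, 2000), (2000, 2500)]

    def test_single_exact_window(self):
        info = GenomeInfo(("c1",), (1000,))
        assert len(homogenize_windows(info, 1000)) == 1

    def test_tiling_conserves_length_no_gaps(self):
        info = GenomeInfo(("c1", "c2"), (12_345, 999))
        wins = homogenize_windows(info, 1000)
        for chrom, length in zip(info.chrom_names, info.chrom_lengths):
            cw = [w for w in wins if w.chrom == chrom]
            assert sum(len(w) for w in cw) == length
            assert cw[0].start == 0 and cw[-1].end == length
            assert all(a.end == b.start for a, b in zip(cw, cw[1:]))

    def test_start_coordinate_assignment(self):
        genome = {"c1": "A" * 2000}
        wins = homogenize_windows(GenomeInfo(("c1",), (2000,)), 1000)
        cpg = [Interval("c1", 10, 12), Interval("c1", 999, 1001)]
        out = quantify_windows(wins, cpg, [], genome)
        # the motif starting at 999 crosses the boundary but counts left only
        assert out[0].cpg_count == 2 and out[1].cpg_count == 0

    def test_quantify_matches_recount_oracle(self):
        genome = random_genome(3, length=7_777)
        info = GenomeInfo(("c1",), (7_777,))
        wins = homogenize_windows(info, 1000)
        cpg = dinucleotide_positions(genome)
        tri = trinucleotide_positions(genome)
        out = quantify_windows(wins, cpg, tri, genome)
        for w in out:
            assert w.cpg_count == sum(1 for p in cpg if w.start <= p.start < w.end)
            assert w.gcc_ggc_count == sum(1 for p in tri if w.start <= p.start < w.end)
            seq = genome["c1"][w.start : w.end]
            assert abs(w.gc_percent - 100 * (seq.count("C") + seq.count("G")) / len(seq)) < 1e-9


class TestHistogram:
    def _windows(self, seed=4):
        genome = random_genome(seed, length=20_000)
        info = GenomeInfo(("c1",), (20_000,))
        return quantify_windows(
            homogenize_windows(info, 1000),
            dinucleotide_positions(genome),
            trinucleotide_positions(genome),
            genome,
        )

    def test_counts_conserve_window_count(self):
        wins = self._windows()
        h = histogram2d(wins, bins=100, x_max=50, y_max=100)
        assert h.total == len(wins)
        assert h.counts.shape == (100, 100)
        assert len(h.x_edges) == 101 and len(h.y_edges) == 101

    def test_out_of_range_clipped_into_last_bin(self):
        wins = self._windows()
        h = histogram2d(wins, bins=10, x_max=1, y_max=1)
        assert h.total == len(wins)
        assert h.counts[-1, -1] == len(wins)  # everything clips high

    def test_marginals_match_1d_oracle(self):
        wins = self._windows()
        h = histogram2d(wins, bins=20, x_max=60, y_max=100)
        x = np.clip([w.gcc_ggc_count for w in wins], 0, 60)
        marginal, _ = np.histogram(x, bins=np.linspace(0, 60, 21))
        assert np.array_equal(h.counts.sum(axis=1), marginal)

    def test_identical_windows_single_cell(self):
        wins = self._windows()
        one = [wins[0]] * 7
        h = histogram2d(one, bins=100, x_max=50, y_max=100)
        assert h.counts.max() == 7 and h.total == 7


class TestLocusStats:
    def test_locus_gc_of_cgg_tract(self):
        genome = {"c1": "CGG" * 10}
        assert abs(locus_gc(genome, Interval("c1", 0, 30)) - 100.0) < 1e-9
        genome = {"c1": "CGA" * 10}
        assert abs(locus_gc(genome, Interval("c1", 0, 30)) - 200 / 3) < 1e-9

    def test_locus_gc_all_a(self):
        assert locus_gc({"c1": "AAAA"}, Interval("c1", 0, 4)) == 0.0

    def test_locus_gc_bounds_error(self):
        with pytest.raises(ValueError):
            locus_gc({"c1": "ACGT"}, Interval("c1", 2, 8))

    @pytest.mark.parametrize(
        "seq,unit,expect",
        [
            ("CGGCGGACGG", "CGG", 2),
            ("TTTT", "CGG", 0),
            ("CGG" * 17 + "A" + "CGG" * 16, "CGG", 17),
            ("ACGGCGGCGGA", "CGG", 3),
        ],
    )
    def test_longest_unit_run_examples(self, seq, unit, expect):
        assert longest_unit_run(seq, unit) == expect

    def test_longest_run_matches_regex_oracle(self):
        genome = random_genome(6, length=30_000)["c1"]
        oracle = max(
            (len(m.group(0)) // 3 for m in re.finditer("(?:CGG)+", genome)),
            default=0,
        )
        assert longest_unit_run(genome, "CGG") == oracle
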