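"""Interval containers, BED/bedGraph IO, and overlap primitives against
brute-force oracles."""

import numpy as np
import pandas as pd
import pytest

import lockei as lk
from lockei.intervals import (BedParseError, GenomeLayout, IntervalSet,
                              base_overlap_fraction,
                              interval_overlap_fraction, merge_intervals,
                              read_bed, read_probe_track, write_bed)

LAYOUT = GenomeLayout(("chr1", "chr2"), (1_000_000, 500_000))


def random_intervals(rng, n, chrom_len=1_000_000, max_len=5_000,
                     chroms=("chr1",)):
    rows = []
    for _ in range(n):
        chrom = chroms[rng.integers(len(chroms))]
        start = int(rng.integers(0, chrom_len - max_len))
        length = int(rng.integers(1, max_len))
        rows.append((chrom, start, start + length))
    return IntervalSet(pd.DataFrame(rows, columns=["chrom", "start", "end"]))


# --- brute-force oracles ----------------------------------------------------

def overlap_fraction_bruteforce(query, features):
    hits = 0
    for q in query:
        if any(q.chrom == f.chrom and q.start < f.end and f.start < q.end
               for f in features):
            hits += 1
    return hits / len(query)


def base_fraction_bruteforce(query, features, chrom_len=1_000_000):
    covered = total = 0
    for chrom in query.chroms():
        mask = np.zeros(chrom_len, dtype=bool)
        for f in features:
            if f.chrom == chrom:
                mask[f.start:f.end] = True
        for q in query:
            if q.chrom == chrom:
                covered += int(mask[q.start:q.end].sum())
                total += q.length
    return covered / total


# --- IO ---------------------------------------------------------------------

class TestProbeTrackIO:
    def test_sorted_regardless_of_input_order(self, tmp_path):
        p = tmp_path / "t.bedgraph"
        p.write_text("chr1\t400\t450\t1.5\nchr1\t0\t50\t-0.5\nchr1\t200\t250\t0.25\n")
        track = read_probe_track(p, LAYOUT)
        np.testing.assert_array_equal(track.probes["chr1"]["start"],
                                      [0, 200, 400])
        np.testing.assert_allclose(track.probes["chr1"]["value"],
                                   [-0.5, 0.25, 1.5])

    def test_empty_file_is_valid(self, tmp_path):
        p = tmp_path / "empty.bedgraph"
        p.write_text("")
        assert read_probe_track(p, LAYOUT).n_probes == 0

    def test_start_ge_end_names_the_line(self, tmp_path):
        p = tmp_path / "bad.bedgraph"
        p.write_text("chr1\t0\t50\t1.0\nchr1\t300\t300\t2.0\n")
        with pytest.raises(BedParseError, match="line 2"):
            read_probe_track(p, LAYOUT)

    def test_unknown_chromosome_rejected(self, tmp_path):
        p = tmp_path / "bad.bedgraph"
        p.write_text("chrMT\t0\t50\t1.0\n")
        with pytest.raises(BedParseError, match="chrMT"):
            read_probe_track(p, LAYOUT)


class TestBedIO:
    def test_bed3_line(self, tmp_path):
        p = tmp_path / "a.bed"
        p.write_text("chr1\t100\t200\n")
        iv = read_bed(p)
        assert list(iv)[0] == lk.Interval("chr1", 100, 200)

    def test_round_trip_preserves_coordinates(self, tmp_path, rng):
        original = random_intervals(rng, 5)
        path = tmp_path / "rt.bed"
        write_bed(original, path)
        back = read_bed(path)
        pd.testing.assert_frame_equal(
            original.df[["chrom", "start", "end"]],
            back.df[["chrom", "start", "end"]])

    def test_malformed_line_reports_position(self, tmp_path):
        p = tmp_path / "bad.bed"
        p.write_text("chr1\t100\t200\nchr1\tx\t300\n")
        with pytest.raises(BedParseError, match="line 2"):
            read_bed(p)


# --- overlap statistics -----------------------------------------------------

class TestOverlapFractions:
    def test_single_containment(self):
        q = IntervalSet.from_intervals([lk.Interval("chr1", 100, 200)])
        f = IntervalSet.from_intervals([lk.Interval("chr1", 150, 300)])
        assert interval_overlap_fraction(q, f) == 1.0

    def test_half_hit(self):
        q = IntervalSet.from_intervals([lk.Interval("chr1", 100, 200),
                                        lk.Interval("chr1", 500, 600)])
        f = IntervalSet.from_intervals([lk.Interval("chr1", 150, 300)])
        assert interval_overlap_fraction(q, f) == 0.5

    def test_base_fraction_simple(self):
        q = IntervalSet.from_intervals([lk.Interval("chr1", 0, 100)])
        f = IntervalSet.from_intervals([lk.Interval("chr1", 50, 100)])
        assert base_overlap_fraction(q, f) == 0.5

    def test_base_fraction_full_tiling(self):
        q = IntervalSet.from_intervals([lk.Interval("chr1", 1000, 9000)])
        tiles = [lk.Interval("chr1", s, s + 1000) for s in range(0, 10000, 1000)]
        assert base_overlap_fraction(q, IntervalSet.from_intervals(tiles)) == 1.0

    def test_empty_query_is_error(self):
        f = IntervalSet.from_intervals([lk.Interval("chr1", 0, 10)])
        with pytest.raises(ValueError):
            interval_overlap_fraction(IntervalSet(), f)
        with pytest.raises(ValueError):
            base_overlap_fraction(IntervalSet(), f)

    @pytest.mark.parametrize("seed", range(30))
    def test_interval_fraction_matches_bruteforce(self, seed):
        rng = np.random.default_rng(seed)
        q = random_intervals(rng, 200)
        f = random_intervals(rng, 200)
        assert interval_overlap_fraction(q, f) == pytest.approx(
            overlap_fraction_bruteforce(q, f), abs=1e-12)

    @pytest.mark.parametrize("seed", range(30))
    def test_base_fraction_matches_per_base_mask(self, seed):
        rng = np.random.default_rng(seed)
        q = random_intervals(rng, 50, chrom_len=100_000, max_len=2_000)
        f = random_intervals(rng, 50, chrom_len=100_000, max_len=2_000)
        assert base_overlap_fraction(q, f) == pytest.approx(
            base_fraction_bruteforce(q, f, 100_000), abs=1e-12)

    def test_order_and_split_invariance(self, rng):
        q = random_intervals(rng, 40, chrom_len=100_000, max_len=2_000)
        f = random_intervals(rng, 40, chrom_len=100_000, max_len=2_000)
        base = base_overlap_fraction(q, f)
        inter = interval_overlap_fraction(q, f)
        # shuffle rows: IntervalSet re-sorts, results identical
        shuffled = IntervalSet(f.df.sample(frac=1, random_state=0))
        assert base_overlap_fraction(q, shuffled) == base
        assert interval_overlap_fraction(q, shuffled) == inter
        # split every feature interval into two adjacent halves
        rows = []
        for iv in f:
            if iv.length > 1:
                mid = iv.start + iv.length // 2
                rows += [(iv.chrom, iv.start, mid), (iv.chrom, mid, iv.end)]
            else:
                rows.append((iv.chrom, iv.start, iv.end))
        split = IntervalSet(pd.DataFrame(rows, columns=["chrom", "start", "end"]))
        assert base_overlap_fraction(q, split) == pytest.approx(base, abs=1e-12)

    def test_agrees_with_bedtools(self, tmp_path, rng):
        """Independent cross-check of the base-level statistic."""
        import shutil
        import subprocess
        if shutil.which("bedtools") is None:
            pytest.skip("bedtools not on PATH")
        q = random_intervals(rng, 60, chrom_len=200_000, max_len=3_000)
        f = random_intervals(rng, 60, chrom_len=200_000, max_len=3_000)
        qp, fp = tmp_path / "q.bed", tmp_path / "f.bed"
        write_bed(q, qp)
        write_bed(merge_intervals(f), fp)
        out = subprocess.run(
            ["bedtools", "intersect", "-a", qp, "-b", fp],
            capture_output=True, text=True, check=True).stdout
        covered = sum(int(l.split("\t")[2]) - int(l.split("\t")[1])
                      for l in out.strip().splitlines() if l)
        assert base_overlap_fraction(q, f) == pytest.approx(
            covered / q.total_bp, abs=1e-12)


class TestMerge:
    def test_adjacent_and_overlapping_coalesce(self):
        s = IntervalSet.from_intervals([
            lk.Interval("chr1", 0, 100), lk.Interval("chr1", 100, 200),
            lk.Interval("chr1", 150, 400), lk.Interval("chr1", 500, 600)])
        m = merge_intervals(s)
        assert [(i.start, i.end) for i in m] == [(0, 400), (500, 600)]

    def test_layout_validation(self):
        with pytest.raises(ValueError):
            IntervalSet(pd.DataFrame({"chrom": ["chr1"], "start": [0],
                                      "end": [2_000_000]}), layout=LAYOUT)


class TestMergeProperties:
    """Union semantics of merge_intervals on arbitrary interval sets."""

    from hypothesis import given, settings, strategies as st

    @staticmethod
    def _build(raw):
        rows = [("chr1", s, s + l) for s, l in raw]
        return IntervalSet(pd.DataFrame(rows,
                                        columns=["chrom", "start", "end"]))

    @given(st.lists(st.tuples(st.integers(0, 10_000),
                              st.integers(1, 2_000)), min_size=1,
                    max_size=40))
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_merge_is_disjoint_idempotent_and_mass_preserving(self, raw):
        s = self._build(raw)
        m = merge_intervals(s)
        assert m.is_disjoint()
        assert merge_intervals(m).df[["chrom", "start", "end"]].equals(
            m.df[["chrom", "start", "end"]])
        # union mass equals the per-base mask count
        mask = np.zeros(13_000, dtype=bool)
        for i in s:
            mask[i.start:i.end] = True
        assert m.total_bp == int(mask.sum())
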