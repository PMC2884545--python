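"""Read IO, deduplication, fragment-size estimation, coverage and counting."""

import numpy as np
import pandas as pd
import pytest

from chromstate.reads import (ReadLibrary, coverage_track, count_in_window,
                              count_windows, deduplicate,
                              estimate_fragment_size, load_reads,
                              tss_metaprofile, write_bed, write_wiggle)

from conftest import make_library


class TestLoadReads:
    def test_four_line_bed(self, tmp_path):
        path = tmp_path / "r.bed"
        path.write_text("".join(
            f"chr2L\t{s}\t{s + 25}\tr\t0\t{st}\n"
            for s, st in [(100, "+"), (50, "-"), (300, "+"), (200, "-")]))
        lib = load_reads(path)
        assert lib.total_unique == 4
        assert list(lib.reads.start) == sorted(lib.reads.start)

    def test_minus_strand_five_prime(self, tmp_path):
        path = tmp_path / "r.bed"
        path.write_text("chr2L\t100\t125\tr\t0\t-\n")
        lib = load_reads(path)
        assert lib.reads.five_prime.iloc[0] == 124

    def test_missing_strand_column_rejected(self, tmp_path):
        path = tmp_path / "r.bed"
        path.write_text("chr2L\t100\t125\n")
        with pytest.raises(ValueError, match="strand"):
            load_reads(path)

    def test_bed_roundtrip(self, tmp_path):
        lib = make_library([100, 300], [200])
        write_bed(lib, tmp_path / "out.bed")
        back = load_reads(tmp_path / "out.bed")
        pd.testing.assert_frame_equal(back.reads, lib.reads)


class TestDeduplicate:
    @pytest.mark.parametrize("copies,kept", [(5, 3), (3, 3), (2, 2), (1, 1)])
    def test_identical_reads_capped(self, copies, kept):
        df = pd.DataFrame({"chrom": ["c"] * copies, "start": 100,
                           "end": 125, "strand": "+"})
        lib = deduplicate(ReadLibrary("t", df))
        assert lib.total_unique == kept

    def test_distinct_reads_untouched(self):
        lib = make_library(np.arange(10) * 50, [])
        assert deduplicate(lib).total_unique == 10

    def test_opposite_strands_are_distinct_fragments(self):
        df = pd.DataFrame({"chrom": ["c"] * 8, "start": 100, "end": 125,
                           "strand": ["+", "-"] * 4})
        lib = deduplicate(ReadLibrary("t", df))
        assert lib.total_unique == 6      # 3 per strand

    def test_never_increases_counts(self, small_dataset):
        lib = small_dataset["libraries"]["k4"]
        assert deduplicate(lib).total_unique <= lib.total_unique


class TestFragmentSize:
    def test_planted_offsets_recovered(self):
        rng = np.random.default_rng(0)
        for offset in (160, 200):
            p = rng.normal(1000, 5, 2000).astype(int)
            m = rng.normal(1000 + offset, 5, 2000).astype(int)
            est = estimate_fragment_size(make_library(p, m))
            assert abs(est - offset) <= 10

    def test_zero_offset_degenerate(self):
        rng = np.random.default_rng(1)
        p = rng.normal(1000, 5, 2000).astype(int)
        m = rng.normal(1000, 5, 2000).astype(int)
        assert estimate_fragment_size(make_library(p, m)) <= 10

    def test_single_strand_errors(self):
        with pytest.raises(ValueError, match="both strands"):
            estimate_fragment_size(make_library([100, 200], []))

    def test_planted_generator_offset_on_polII(self, small_dataset):
        # a 300-gene library localizes the (flat-topped) correlation peak
        # only coarsely; the full-scale dataset pins it within +-10
        est = estimate_fragment_size(small_dataset["libraries"]["polII"])
        assert abs(est - small_dataset["config"].fragment_size) <= 30


class TestCoverageTrack:
    def test_single_fragment_span(self):
        lib = make_library([100], [])
        track = coverage_track(lib, {"c": 400}, bin=4, fragment=160)
        cov = track["c"]
        assert cov[100 // 4] == 1 and cov[(260 - 1) // 4] == 1
        assert cov[99 // 4] == 0 and cov[260 // 4] == 0

    def test_overlap_adds(self):
        lib = make_library([100, 150], [])
        cov = coverage_track(lib, {"c": 400}, bin=4, fragment=160)["c"]
        assert cov[150 // 4] == 2

    def test_minus_strand_extends_leftward(self):
        lib = make_library([], [300])
        cov = coverage_track(lib, {"c": 400}, bin=1, fragment=160)["c"]
        assert cov[141] == 1 and cov[300] == 1 and cov[301] == 0
        assert cov[140] == 0

    def test_mass_conservation(self):
        # fragment ends aligned to bin boundaries: total mass is exact
        lib = make_library([0, 400, 800], [])
        for bin in (4, 8, 16):
            cov = coverage_track(lib, {"c": 2000}, bin=bin, fragment=160)["c"]
            assert cov.sum() == 3 * 160 // bin

    def test_wiggle_serialization(self, tmp_path):
        lib = make_library([100], [])
        track = coverage_track(lib, {"c": 400}, bin=4)
        write_wiggle(track, tmp_path / "t.wig", bin=4)
        text = (tmp_path / "t.wig").read_text()
        assert "fixedStep chrom=c" in text


class TestCountWindows:
    def test_empty_library(self):
        lib = make_library([], [100])
        assert count_in_window(lib, "c", 0, 500) == 1
        assert count_in_window(lib, "other", 0, 500) == 0

    def test_five_prime_mode_definition(self):
        lib = make_library(np.arange(1000, 1550, 50), [])  # 11 reads
        assert count_in_window(lib, "c", 1000, 1500) == 10
        assert count_in_window(lib, "c", 1000, 1501) == 11

    def test_midpoint_mode(self):
        lib = make_library([990], [], fragment_size=160)
        assert count_in_window(lib, "c", 1000, 1500, mode="five_prime") == 0
        assert count_in_window(lib, "c", 1000, 1500, mode="midpoint") == 1

    def test_midpoint_minus_strand(self):
        lib = make_library([], [1010], fragment_size=160)
        # midpoint = 1010 - 80 = 930
        assert count_in_window(lib, "c", 900, 1000, mode="midpoint") == 1

    def test_partition_sums_to_chromosome_total(self, small_dataset):
        lib = small_dataset["libraries"]["h3"]
        G = small_dataset["config"].genome_bp
        edges = np.linspace(0, G, 7, dtype=int)
        windows = pd.DataFrame({"chrom": "chrS", "start": edges[:-1],
                                "end": edges[1:]})
        total = count_windows(lib, windows).sum()
        assert total == (lib.positions().pos < G).sum()

    def test_vectorized_matches_scalar(self, small_dataset):
        lib = small_dataset["libraries"]["k4"]
        rng = np.random.default_rng(0)
        starts = rng.integers(0, 3_000_000, 20)
        windows = pd.DataFrame({"chrom": "chrS", "start": starts,
                                "end": starts + 500})
        vec = count_windows(lib, windows)
        for i, s in enumerate(starts):
            assert vec[i] == count_in_window(lib, "chrS", s, s + 500)


class TestMetaprofile:
    def test_planted_peak_at_plus100(self):
        rng = np.random.default_rng(0)
        tss = [("c", 10_000, "+"), ("c", 30_000, "+")]
        pos = np.concatenate([t + 100 + rng.integers(-2, 3, 500)
                              for _, t, _ in tss])
        prof = tss_metaprofile(make_library(pos, []), tss, flank=500, bin=5)
        peak = prof.loc[prof.density.idxmax(), "offset"]
        assert 90 <= peak <= 105

    def test_minus_strand_mirrored(self):
        # reads 100 bp downstream of a minus-strand TSS (i.e. at TSS-100)
        tss = [("c", 10_000, "-")]
        lib = make_library(np.full(200, 9_900), [])
        prof = tss_metaprofile(lib, tss, flank=500, bin=5)
        peak = prof.loc[prof.density.idxmax(), "offset"]
        assert 90 <= peak <= 105

    def test_uniform_background_is_flat(self):
        rng = np.random.default_rng(2)
        lib = make_library(rng.integers(0, 100_000, 40_000), [])
        prof = tss_metaprofile(lib, [("c", 50_000, "+")], flank=2000, bin=100)
        assert prof.density.max() < 3 * prof.density.mean()
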