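import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

import poolcnv as pc
from conftest import simulate_counts


def counts_from_arrays(grid, per_chrom):
    arrays = {c: np.asarray(per_chrom[c], dtype=np.int64)
              for c in grid.genome.names}
    total = int(sum(a.sum() for a in arrays.values()))
    return pc.WindowCounts(grid, arrays, total)


class TestGrid:
    def test_tiling_and_short_last_window(self):
        genome = pc.GenomeIndex((("chr1", 100_000),))
        grid = pc.WindowGrid(genome, 40_000)
        assert grid.n_windows("chr1") == 3
        assert grid.window_bounds("chr1", 0) == (0, 40_000)
        assert grid.window_bounds("chr1", 2) == (80_000, 100_000)
        assert grid.is_short_window("chr1", 2)
        assert not grid.is_short_window("chr1", 0)


class TestCounting:
    def test_boundary_assignment_half_open(self):
        genome = pc.GenomeIndex((("chr1", 80_000),))
        grid = pc.WindowGrid(genome, 40_000)
        reads = [pc.MappedRead("chr1", p) for p in (0, 39_999, 40_000)]
        counts = pc.count_reads_in_windows(reads, grid)
        assert counts.counts["chr1"].tolist() == [2, 1]

    def test_empty_stream(self):
        genome = pc.GenomeIndex((("chr1", 80_000),))
        counts = pc.count_reads_in_windows([], pc.WindowGrid(genome, 40_000))
        assert counts.total_reads == 0
        assert counts.counts["chr1"].tolist() == [0, 0]

    def test_out_of_bounds_read_is_hard_error(self):
        genome = pc.GenomeIndex((("chr1", 80_000),))
        with pytest.raises(ValueError):
            pc.count_reads_in_windows([pc.MappedRead("chr1", 80_000)],
                                      pc.WindowGrid(genome, 40_000))

    def test_uniform_counts_within_poisson_band(self):
        """1000 uniform starts over 10 windows: every count inside the
        central 99.9% band of Poisson(100), totals conserved."""
        genome = pc.GenomeIndex((("chr1", 400_000),))
        rng = np.random.default_rng(31)
        reads = [pc.MappedRead("chr1", int(p))
                 for p in rng.integers(0, 400_000, size=1000)]
        counts = pc.count_reads_in_windows(reads, pc.WindowGrid(genome, 40_000))
        assert counts.total_reads == 1000
        lo, hi = stats.poisson.ppf([0.0005, 0.9995], 100)
        assert all(lo <= c <= hi for c in counts.counts["chr1"])

    def test_matches_brute_force_on_random_fixtures(self):
        """Vector path vs an independent per-read loop, 100 random fixtures."""
        rng = np.random.default_rng(5)
        for _ in range(100):
            length = int(rng.integers(50_000, 300_000))
            window = int(rng.choice([10_000, 25_000, 40_000]))
            genome = pc.GenomeIndex((("c", length),))
            starts = rng.integers(0, length, size=int(rng.integers(0, 400)))
            reads = [pc.MappedRead("c", int(s)) for s in starts]
            counts = pc.count_reads_in_windows(reads, pc.WindowGrid(genome, window))
            n_windows = -(-length // window)
            expected = [0] * n_windows
            for s in starts:
                expected[s // window] += 1
            assert counts.counts["c"].tolist() == expected


class TestLogRatio:
    GENOME = pc.GenomeIndex((("chr1", 160_000),))
    GRID = pc.WindowGrid(GENOME, 40_000)

    def test_four_to_one_symmetry(self):
        """4:1 gives +2, 1:4 gives -2 — reciprocal dosage, equal magnitude."""
        s = counts_from_arrays(self.GRID, {"chr1": [4, 1, 5, 5]})
        r = counts_from_arrays(self.GRID, {"chr1": [1, 4, 5, 5]})
        track = pc.log2_ratio_track(s, r, pseudocount=0.0, normalize=False)
        assert track.log2_ratio["chr1"][0] == pytest.approx(2.0)
        assert track.log2_ratio["chr1"][1] == pytest.approx(-2.0)

    def test_identity(self):
        s = counts_from_arrays(self.GRID, {"chr1": [7, 3, 9, 1]})
        track = pc.log2_ratio_track(s, s, normalize=True)
        assert np.allclose(track.log2_ratio["chr1"], 0.0)

    def test_zero_counts_marked_undefined(self):
        s = counts_from_arrays(self.GRID, {"chr1": [0, 5, 0, 5]})
        r = counts_from_arrays(self.GRID, {"chr1": [10, 0, 0, 5]})
        track = pc.log2_ratio_track(s, r, pseudocount=0.0, normalize=False)
        v = track.log2_ratio["chr1"]
        assert np.isnan(v[[0, 1, 2]]).all() and v[3] == 0.0

    def test_pseudocount_formula(self):
        s = counts_from_arrays(self.GRID, {"chr1": [0, 5, 5, 5]})
        r = counts_from_arrays(self.GRID, {"chr1": [10, 5, 5, 5]})
        track = pc.log2_ratio_track(s, r, pseudocount=0.5, normalize=False)
        assert track.log2_ratio["chr1"][0] == pytest.approx(math.log2(0.5 / 10.5))

    def test_normalization_scales_reference(self):
        s = counts_from_arrays(self.GRID, {"chr1": [10, 10, 10, 10]})
        r = counts_from_arrays(self.GRID, {"chr1": [20, 20, 20, 20]})
        track = pc.log2_ratio_track(s, r, normalize=True)
        assert np.allclose(track.log2_ratio["chr1"], 0.0)

    def test_grid_mismatch_errors(self):
        other = pc.WindowGrid(self.GENOME, 20_000)
        s = counts_from_arrays(self.GRID, {"chr1": [1, 1, 1, 1]})
        r = counts_from_arrays(other, {"chr1": [1] * 8})
        with pytest.raises(ValueError):
            pc.log2_ratio_track(s, r)

    @settings(derandomize=True, max_examples=60)
    @given(st.lists(st.tuples(st.integers(0, 500), st.integers(0, 500)),
                    min_size=1, max_size=30))
    def test_antisymmetry_property(self, pairs):
        """Swapping sample and reference negates every defined ratio."""
        genome = pc.GenomeIndex((("c", 40_000 * len(pairs)),))
        grid = pc.WindowGrid(genome, 40_000)
        a = counts_from_arrays(grid, {"c": [p[0] for p in pairs]})
        b = counts_from_arrays(grid, {"c": [p[1] for p in pairs]})
        fwd = pc.log2_ratio_track(a, b, normalize=False).log2_ratio["c"]
        rev = pc.log2_ratio_track(b, a, normalize=False).log2_ratio["c"]
        defined = ~np.isnan(fwd)
        assert (np.isnan(fwd) == np.isnan(rev)).all()
        assert np.allclose(fwd[defined], -rev[defined])


class TestFoldChange:
    @pytest.mark.parametrize("value, expected", [(2.0, 4.0), (-2.0, 4.0), (0.0, 1.0)])
    def test_fold_change(self, value, expected):
        assert pc.fold_change(value) == pytest.approx(expected)

    def test_undefined_propagates(self):
        assert math.isnan(pc.fold_change(float("nan")))


class TestDosageRecovery:
    def test_hemizygous_deletion_recovers_minus_one(self, toy_genome, grid,
                                                    reference_counts):
        """A one-copy deletion in all 4 pool members halves the sampling
        rate: mean log2 over affected windows ~ -1, elsewhere ~ 0."""
        _, genome, _ = toy_genome
        cnv = pc.CnvSpec("chr2", 80_000, 240_000, 1, (0, 1, 2, 3))
        counts = simulate_counts(genome, grid, [cnv], seed=23)
        track = pc.log2_ratio_track(counts, reference_counts)
        affected = track.log2_ratio["chr2"][2:6]
        rest = np.concatenate(
            [track.log2_ratio["chr2"][:2], track.log2_ratio["chr2"][6:]]
            + [track.log2_ratio[c] for c in genome.names if c != "chr2"])
        assert np.nanmean(affected) == pytest.approx(-1.0, abs=0.15)
        assert abs(np.nanmean(rest)) < 0.1

    def test_triplication_recovers_log2_1p5(self, toy_genome, grid,
                                            reference_counts):
        """3 copies in all members: mean log2 ~ log2(1.5) ~ +0.585."""
        _, genome, _ = toy_genome
        cnv = pc.CnvSpec("chr3", 40_000, 200_000, 3, (0, 1, 2, 3))
        counts = simulate_counts(genome, grid, [cnv], seed=29)
        track = pc.log2_ratio_track(counts, reference_counts)
        affected = track.log2_ratio["chr3"][1:5]
        assert np.nanmean(affected) == pytest.approx(math.log2(1.5), abs=0.15)


class TestSerialization:
    def test_bedgraph_round_numbers(self, tmp_path):
        genome = pc.GenomeIndex((("chr1", 90_000),))
        grid = pc.WindowGrid(genome, 40_000)
        counts = counts_from_arrays(grid, {"chr1": [3, 0, 1]})
        path = tmp_path / "c.bedgraph"
        pc.write_bedgraph(counts, path)
        assert path.read_text() == (
            "chr1\t0\t40000\t3\nchr1\t40000\t80000\t0\nchr1\t80000\t90000\t1\n")

    def test_ratio_tsv_marks_short_window(self, tmp_path):
        genome = pc.GenomeIndex((("chr1", 90_000),))
        grid = pc.WindowGrid(genome, 40_000)
        s = counts_from_arrays(grid, {"chr1": [2, 2, 2]})
        track = pc.log2_ratio_track(s, s)
        path = tmp_path / "r.tsv"
        pc.write_ratio_tsv(track, path)
        lines = path.read_text().splitlines()
        assert lines[0].split("\t") == ["chrom", "window_index", "start", "end",
                                        "short_window", "log2_ratio"]
        assert lines[3].split("\t")[4] == "1"  # last window flagged short
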