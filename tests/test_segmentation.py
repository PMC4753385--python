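import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import poolcnv as pc
from conftest import simulate_counts


def track_from_values(values_per_chrom, window=40_000):
    entries = tuple((c, window * len(v)) for c, v in values_per_chrom.items())
    genome = pc.GenomeIndex(entries)
    grid = pc.WindowGrid(genome, window)
    arrays = {c: np.asarray(v, dtype=float) for c, v in values_per_chrom.items()}
    return pc.RatioTrack(grid, arrays)


class TestCallSegments:
    def test_flat_track_calls_nothing(self):
        track = track_from_values({"chr1": [0.0] * 10})
        assert pc.call_segments(track) == []

    def test_single_long_loss_run(self):
        track = track_from_values({"chr1": [-1.2] * 10})
        config = pc.CallConfig(loss_threshold=-0.5, gain_threshold=0.5,
                               min_consecutive_windows=3)
        (seg,) = pc.call_segments(track, config)
        assert (seg.direction, seg.n_windows) == ("loss", 10)
        assert (seg.start_bp, seg.end_bp) == (0, 400_000)
        assert seg.mean_log2 == pytest.approx(-1.2)

    @pytest.mark.parametrize("max_gap, n_expected", [(1, 1), (0, 2)])
    def test_gap_bridging(self, max_gap, n_expected):
        """[-1,-1,0,-1,-1]: gap budget 1 merges, budget 0 splits — matches
        exhaustive run enumeration on the 5-window vector."""
        track = track_from_values({"chr1": [-1, -1, 0, -1, -1]})
        config = pc.CallConfig(min_consecutive_windows=2, max_gap_windows=max_gap)
        segments = pc.call_segments(track, config)
        assert len(segments) == n_expected
        if n_expected == 1:
            assert segments[0].n_windows == 5
            assert segments[0].mean_log2 == pytest.approx(-0.8)

    def test_undefined_windows_do_not_break_within_gap(self):
        track = track_from_values({"chr1": [-1, -1, np.nan, -1, -1]})
        config = pc.CallConfig(min_consecutive_windows=2, max_gap_windows=1)
        (seg,) = pc.call_segments(track, config)
        assert seg.n_windows == 5
        assert seg.mean_log2 == pytest.approx(-1.0)  # NaN excluded from mean

    def test_short_runs_dropped(self):
        track = track_from_values({"chr1": [0, -1, -1, 0, 0, 0.8, 0, 0]})
        config = pc.CallConfig(min_consecutive_windows=3, max_gap_windows=0)
        assert pc.call_segments(track, config) == []

    def test_gains_and_losses_called_independently(self):
        track = track_from_values({"chr1": [0.9, 0.9, 0.9, 0, -0.7, -0.7, -0.7, 0]})
        config = pc.CallConfig(min_consecutive_windows=3, max_gap_windows=0)
        segments = pc.call_segments(track, config)
        assert [s.direction for s in segments] == ["gain", "loss"]

    def test_segments_sorted_and_disjoint_property(self):
        rng = np.random.default_rng(61)
        for _ in range(50):
            values = rng.choice([-1.0, -0.6, 0.0, 0.6, 1.0, np.nan],
                                size=rng.integers(5, 60))
            track = track_from_values({"chr1": list(values)})
            segs = pc.call_segments(track, pc.DEFAULT_CALL_CONFIG)
            by_dir = {}
            for s in segs:
                by_dir.setdefault(s.direction, []).append(s)
            for group in by_dir.values():
                for a, b in zip(group, group[1:]):
                    assert a.end_bp <= b.start_bp


class TestIntersect:
    def seg(self, chrom, start, end, direction="loss", mean=-1.0):
        n = max(1, (end - start) // 40_000)
        return pc.CnvSegment(chrom, start, end, direction, n, mean)

    def test_identical_segment_idempotent(self):
        a = [self.seg("chr1", 0, 120_000)]
        out = pc.intersect_segments([a, a], "loss")
        assert [(s.chrom, s.start_bp, s.end_bp) for s in out] == [("chr1", 0, 120_000)]

    def test_partial_overlap(self):
        a = [self.seg("chr1", 0, 100_000)]
        b = [self.seg("chr1", 40_000, 200_000)]
        (out,) = pc.intersect_segments([a, b], "loss")
        assert (out.start_bp, out.end_bp) == (40_000, 100_000)

    def test_direction_filtered(self):
        a = [self.seg("chr1", 0, 100_000, "loss", -1)]
        b = [self.seg("chr1", 0, 100_000, "gain", 1)]
        assert pc.intersect_segments([a, b], "loss") == []

    def test_three_pools_equal_pairwise_fold(self):
        """k-of-k intersection over three pools equals per-base membership
        on a 1-Mb toy chromosome (brute-force oracle)."""
        rng = np.random.default_rng(71)
        for _ in range(20):
            pools = []
            for _p in range(3):
                segs, cursor = [], 0
                while cursor < 900_000 and len(segs) < 4:
                    start = cursor + int(rng.integers(0, 200_000))
                    end = start + int(rng.integers(40_000, 300_000))
                    end = min(end, 1_000_000)
                    if end > start:
                        segs.append(self.seg("chr1", start, end))
                    cursor = end + 40_000
                pools.append(segs)
            out = pc.intersect_segments(pools, "loss")
            # brute-force per-base membership oracle
            covered = np.zeros(1_000_000, dtype=np.int8)
            for pool in pools:
                mask = np.zeros(1_000_000, dtype=bool)
                for s in pool:
                    mask[s.start_bp:s.end_bp] = True
                covered += mask
            expected_mask = covered == 3
            got_mask = np.zeros(1_000_000, dtype=bool)
            for s in out:
                got_mask[s.start_bp:s.end_bp] = True
            assert (expected_mask == got_mask).all()

    def test_commutative_under_pool_permutation(self):
        pools = [
            [self.seg("chr1", 0, 200_000), self.seg("chr2", 40_000, 120_000)],
            [self.seg("chr1", 80_000, 280_000)],
            [self.seg("chr1", 40_000, 240_000), self.seg("chr2", 0, 80_000)],
        ]
        baseline = pc.intersect_segments(pools, "loss")
        for perm in itertools.permutations(pools):
            assert pc.intersect_segments(list(perm), "loss") == baseline

    def test_k_of_n_mode(self):
        pools = [
            [self.seg("chr1", 0, 100_000)],
            [self.seg("chr1", 0, 100_000)],
            [self.seg("chr1", 500_000, 600_000)],
        ]
        assert pc.intersect_segments(pools, "loss") == []
        (out,) = pc.intersect_segments(pools, "loss", min_pools=2)
        assert (out.start_bp, out.end_bp) == (0, 100_000)


class TestAnnotation:
    BANDS = [
        pc.CytoBand("chr5", 0, 68_500_000, "q13.1", "gneg"),
        pc.CytoBand("chr5", 68_500_000, 71_000_000, "q13.2", "gpos50"),
        pc.CytoBand("chr5", 71_000_000, 90_000_000, "q13.3", "gneg"),
    ]

    def seg(self, start, end):
        return pc.CnvSegment("chr5", start, end, "loss", 3, -1.0)

    def test_contained_segment_single_band(self):
        seg = pc.annotate_bands(self.seg(68_500_000, 71_000_000), self.BANDS)
        assert seg.bands == ("q13.2",)

    def test_spanning_segment_all_bands_in_order(self):
        seg = pc.annotate_bands(self.seg(60_000_000, 75_000_000), self.BANDS)
        assert seg.bands == ("q13.1", "q13.2", "q13.3")

    def test_single_bp_overlap_included(self):
        seg = pc.annotate_bands(self.seg(70_999_999, 71_000_001), self.BANDS)
        assert seg.bands == ("q13.2", "q13.3")

    def test_no_bands_for_chromosome(self):
        seg = pc.annotate_bands(
            pc.CnvSegment("chr9", 0, 40_000, "loss", 1, -1.0), self.BANDS)
        assert seg.bands == ()


class TestSpanAndGenes:
    @pytest.mark.parametrize("start, end, expected", [
        (68_500_000, 71_000_000, 2.5),
        (20_000_000, 22_500_000, 2.5),
        (28_400_000, 33_400_000, 5.0),
    ])
    def test_span_mb(self, start, end, expected):
        seg = pc.CnvSegment("chr5", start, end, "loss", 3, -1.0)
        assert pc.segment_span_mb(seg) == pytest.approx(expected)

    def test_zero_length_forbidden(self):
        with pytest.raises(ValueError):
            pc.CnvSegment("chr1", 100, 100, "loss", 1, -1.0)

    def test_gene_count_overlap(self, tmp_path):
        genes_bed = tmp_path / "genes.bed"
        genes_bed.write_text(
            "chr1\t0\t5000\tg1\nchr1\t90000\t95000\tg2\nchr2\t0\t5000\tg3\n")
        genes = pc.load_gene_intervals(genes_bed)
        seg = pc.CnvSegment("chr1", 0, 100_000, "loss", 3, -1.0)
        assert pc.count_genes(seg, genes) == 2

    def test_gene_count_from_gff3(self, tmp_path):
        gff = tmp_path / "genes.gff3"
        gff.write_text(
            "##gff-version 3\n"
            "chr1\tsrc\tgene\t1\t5000\t.\t+\t.\tID=g1\n"
            "chr1\tsrc\tmRNA\t1\t5000\t.\t+\t.\tID=t1\n"
            "chr1\tsrc\tgene\t200000\t210000\t.\t-\t.\tID=g2\n")
        genes = pc.load_gene_intervals(gff)
        assert genes == [("chr1", 0, 5000), ("chr1", 199_999, 210_000)]


class TestEndToEndSharedLoss:
    def test_shared_deletion_recovered_private_ones_rejected(
            self, toy_genome, grid, reference_counts):
        """Two pools share one deletion and each carries a private one;
        the cross-pool intersection keeps only the shared event, with
        boundaries within one window of the engineered truth."""
        _, genome, _ = toy_genome
        shared = ("chr1", 120_000, 280_000)
        pool_a = simulate_counts(genome, grid, [
            pc.CnvSpec(*shared, 1, (0, 1, 2, 3)),
            pc.CnvSpec("chr4", 0, 160_000, 1, (0, 1, 2, 3)),
        ], seed=83)
        pool_b = simulate_counts(genome, grid, [
            pc.CnvSpec(*shared, 1, (0, 1, 2, 3)),
            pc.CnvSpec("chr5", 120_000, 280_000, 1, (0, 1, 2, 3)),
        ], seed=89)
        segs = []
        for counts in (pool_a, pool_b):
            track = pc.log2_ratio_track(counts, reference_counts)
            segs.append(pc.call_segments(track, pc.DEFAULT_CALL_CONFIG))
        out = pc.intersect_segments(segs, "loss")
        assert len(out) == 1
        seg = out[0]
        assert seg.chrom == "chr1"
        assert abs(seg.start_bp - 120_000) <= 40_000
        assert abs(seg.end_bp - 280_000) <= 40_000
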