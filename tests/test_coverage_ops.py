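"""Track operations: extension, normalization, binning, merging, TSS windows."""

import numpy as np
import pytest

from dotwave.coverage_ops import (
    CoverageTrack,
    GeneAnnotation,
    bin_array,
    bin_coverage,
    coverage_from_start_counts,
    extend_reads,
    merge_replicates,
    metagene,
    normalize_rpgc,
    normalize_rpm,
    tss_matrix,
)


def make_track(per_chrom, total_reads=100, **kw):
    return CoverageTrack(
        data={c: np.asarray(v, dtype=float) for c, v in per_chrom.items()},
        total_reads=total_reads,
        **kw,
    )


class TestExtendReads:
    def test_plus_strand_read_extends_forward(self):
        t = extend_reads({"chr1": ([0], ["+"])}, {"chr1": 300})
        assert np.all(t.data["chr1"][:150] == 1)
        assert np.all(t.data["chr1"][150:] == 0)

    def test_minus_strand_read_extends_backward_from_its_end(self):
        t = extend_reads({"chr1": ([200], ["-"])}, {"chr1": 300})
        cov = t.data["chr1"]
        assert np.all(cov[50:200] == 1)
        assert cov[:50].sum() == 0 and cov[200:].sum() == 0

    def test_overlapping_reads_add(self):
        t = extend_reads({"chr1": ([0, 100], ["+", "+"])}, {"chr1": 300})
        assert np.all(t.data["chr1"][100:150] == 2)

    def test_coverage_conserves_extended_bases(self, rng):
        """Total coverage equals the sum of clipped extension lengths."""
        size = 1000
        pos = rng.integers(0, size, 200)
        strands = rng.choice(["+", "-"], 200)
        pos[strands == "-"] += 1  # minus positions are exclusive ends
        t = extend_reads({"chr1": (pos, strands)}, {"chr1": size})
        expected = sum(
            min(150, size - p) if s == "+" else min(150, p)
            for p, s in zip(pos, strands)
        )
        assert t.data["chr1"].sum() == expected

    def test_out_of_bounds_reads_skipped_and_counted(self):
        t = extend_reads({"chr1": ([-5, 500, 10], ["+", "+", "+"])}, {"chr1": 300})
        assert t.skipped_reads == 2
        assert t.total_reads == 1

    def test_fast_path_matches_positional_extension(self, rng):
        """Dual route: per-base start counts give the same coverage as
        materialized read positions."""
        size = 400
        cp = rng.poisson(0.3, size)
        cm = rng.poisson(0.3, size)
        fast = coverage_from_start_counts(cp, cm, 150)
        pos = np.concatenate(
            [np.repeat(np.arange(size), cp), np.repeat(np.arange(1, size + 1), cm)]
        )
        strands = ["+"] * int(cp.sum()) + ["-"] * int(cm.sum())
        slow = extend_reads({"chr1": (pos, strands)}, {"chr1": size})
        assert np.array_equal(fast, slow.data["chr1"])


class TestNormalization:
    def test_rpgc_worked_example(self):
        # 1000 reads x 150 bp on a 1 Mb genome: raw depth 3 -> RPGC 20
        t = make_track({"chr1": np.full(1000, 3.0)}, total_reads=1000)
        n = normalize_rpgc(t, genome_size=1_000_000)
        assert np.allclose(n.data["chr1"], 20.0)
        assert n.units == "rpgc"

    def test_uniform_one_x_genome_maps_to_one(self):
        size = 30_000
        reads = 200
        t = make_track({"chr1": np.full(size, reads * 150 / size)}, total_reads=reads)
        assert np.allclose(normalize_rpgc(t).data["chr1"], 1.0)

    def test_rpgc_invariant_to_joint_scaling(self):
        t1 = make_track({"chr1": np.arange(100.0)}, total_reads=50)
        t2 = make_track({"chr1": 3 * np.arange(100.0)}, total_reads=150)
        assert np.allclose(
            normalize_rpgc(t1).data["chr1"], normalize_rpgc(t2).data["chr1"]
        )

    def test_units_tag_blocks_double_normalization(self):
        t = normalize_rpgc(make_track({"chr1": np.ones(100)}, total_reads=10))
        with pytest.raises(ValueError):
            normalize_rpgc(t)
        with pytest.raises(ValueError):
            normalize_rpm(t)

    def test_zero_reads_rejected(self):
        with pytest.raises(ValueError):
            normalize_rpgc(make_track({"chr1": np.zeros(10)}, total_reads=0))

    def test_rpm_scales_by_million_reads(self):
        t = make_track({"chr1": np.full(10, 2.0)}, total_reads=500)
        assert np.allclose(normalize_rpm(t).data["chr1"], 2.0 * 1e6 / 500)


class TestBinning:
    def test_hand_example(self):
        v = np.array([1, 1, 2, 2, 4, 4, 4, 4, 0, 0], dtype=float)
        assert np.array_equal(bin_array(v, 2), [1, 2, 4, 4, 0])

    def test_bin_one_is_identity(self, rng):
        v = rng.random(57)
        assert np.array_equal(bin_array(v, 1), v)

    def test_partial_trailing_bin_uses_actual_width(self):
        v = np.array([1.0, 1.0, 1.0, 5.0])
        assert np.array_equal(bin_array(v, 3), [1.0, 5.0])

    def test_matches_brute_force_oracle(self, rng):
        for _ in range(20):
            n = int(rng.integers(5, 200))
            b = int(rng.integers(1, 17))
            v = rng.random(n)
            brute = np.array(
                [v[i : i + b].mean() for i in range(0, n, b)]
            )
            assert np.allclose(bin_array(v, b), brute)

    def test_width_weighted_mean_is_conserved(self, rng):
        v = rng.random(103)
        binned = bin_array(v, 10)
        widths = np.array([10] * 10 + [3])
        assert np.average(binned, weights=widths) == pytest.approx(v.mean())

    def test_bin_coverage_track(self):
        t = make_track({"chr1": np.arange(20.0)})
        b = bin_coverage(t, 10)
        assert b.bin_size == 10
        with pytest.raises(ValueError):
            bin_coverage(b, 10)  # already binned


class TestMergeReplicates:
    def test_identical_tracks_merge_to_themselves(self):
        t1 = make_track({"chr1": np.arange(100.0)}, total_reads=10, mark="m")
        t2 = make_track({"chr1": np.arange(100.0)}, total_reads=10, mark="m")
        merged, rep = merge_replicates([t1, t2])
        assert rep.pearson_r == pytest.approx(1.0)
        assert rep.merged
        assert np.allclose(merged.data["chr1"], t1.data["chr1"])

    def test_correlation_is_scale_invariant(self):
        t1 = make_track({"chr1": np.arange(100.0)}, total_reads=10)
        t2 = make_track({"chr1": 2 * np.arange(100.0)}, total_reads=20)
        _, rep = merge_replicates([t1, t2])
        assert rep.pearson_r == pytest.approx(1.0)

    def test_poisson_replicates_merge_and_beat_either_replicate(self, rng):
        """Two 30x replicates of a structured expectation correlate above the
        threshold, and their merge is closer to the truth than either one."""
        expectation = np.repeat(rng.gamma(2.0, 15.0, 300), 100)  # blocky track
        reps = []
        for _ in range(2):
            noisy = rng.poisson(expectation).astype(float)
            reps.append(
                make_track({"chr1": noisy}, total_reads=int(noisy.sum() // 150) or 1, mark="m")
            )
        merged, rep = merge_replicates(reps)
        assert rep.merged and rep.pearson_r > 0.8
        mse = lambda t: np.mean((t.data["chr1"] - expectation) ** 2)
        assert mse(merged) < min(mse(reps[0]), mse(reps[1]))

    def test_discordant_tracks_returned_unmerged(self, rng):
        t1 = make_track({"chr1": rng.random(1000)}, total_reads=10, mark="m")
        t2 = make_track({"chr1": rng.random(1000)}, total_reads=10, mark="m")
        result, rep = merge_replicates([t1, t2])
        assert not rep.merged
        assert isinstance(result, list) and len(result) == 2

    def test_mismatched_conditions_rejected(self):
        t1 = make_track({"chr1": np.ones(10)}, mark="a")
        t2 = make_track({"chr1": np.ones(10)}, mark="b")
        with pytest.raises(ValueError):
            merge_replicates([t1, t2])


class TestTssMatrix:
    def test_uniform_track_fills_matrix(self):
        t = make_track({"chr1": np.full(10_000, 7.0)})
        genes = [GeneAnnotation("a", "chr1", 3000, 4500, "+")]
        m = tss_matrix(t, genes, window=(-500, 1000))
        assert m.values.shape == (1, 1500)
        assert np.all(m.values == 7.0)

    def test_strand_mirror_gives_identical_rows(self, rng):
        size = 5000
        pattern = rng.random(1500)
        fwd = np.zeros(size)
        tss_f = 2000
        fwd[tss_f - 500 : tss_f + 1000] = pattern
        rev = np.zeros(size)
        tss_r = 3000
        rev[tss_r - 999 : tss_r + 501] = pattern[::-1]
        tf = make_track({"chr1": fwd})
        tr = make_track({"chr1": rev})
        mf = tss_matrix(tf, [GeneAnnotation("f", "chr1", tss_f, tss_f + 1200, "+")])
        mr = tss_matrix(tr, [GeneAnnotation("r", "chr1", tss_r - 1199, tss_r + 1, "-")])
        assert np.allclose(mf.values, mr.values)

    def test_column_count_scales_with_bin(self):
        t = make_track({"chr1": np.ones(10_000)})
        genes = [GeneAnnotation("a", "chr1", 3000, 4000, "+")]
        assert tss_matrix(t, genes, bin_size=10).values.shape[1] == 150
        assert tss_matrix(t, genes, bin_size=1).values.shape[1] == 1500

    def test_matches_slice_and_flip_oracle(self, rng):
        """Brute-force per-gene slicing (with strand flip and NaN clipping)
        reproduces the matrix exactly on random genes."""
        size = 3000
        v = rng.random(size)
        t = make_track({"chr1": v})
        genes = []
        for i in range(20):
            start = int(rng.integers(0, size - 200))
            end = int(rng.integers(start + 100, min(start + 2000, size)))
            strand = str(rng.choice(["+", "-"]))
            genes.append(GeneAnnotation(f"g{i}", "chr1", start, end, strand))
        m = tss_matrix(t, genes, window=(-500, 1000))
        for row, g in zip(m.values, genes):
            brute = np.full(1500, np.nan)
            for col, off in enumerate(range(-500, 1000)):
                pos = g.tss + off if g.strand == "+" else g.tss - off
                if 0 <= pos < size:
                    brute[col] = v[pos]
            assert np.array_equal(np.isnan(row), np.isnan(brute))
            assert np.allclose(row[~np.isnan(row)], brute[~np.isnan(brute)])

    def test_unknown_chromosome_skipped(self):
        t = make_track({"chr1": np.ones(5000)})
        genes = [
            GeneAnnotation("a", "chr1", 2000, 3000, "+"),
            GeneAnnotation("b", "chrX", 2000, 3000, "+"),
        ]
        m = tss_matrix(t, genes)
        assert m.gene_ids == ["a"]


class TestMetagene:
    def test_single_row_is_identity(self):
        t = make_track({"chr1": np.arange(10_000.0)})
        m = tss_matrix(t, [GeneAnnotation("a", "chr1", 3000, 4500, "+")])
        profile, counts = metagene(m)
        assert np.allclose(profile, m.values[0])
        assert np.all(counts == 1)

    def test_mean_of_rows(self):
        t = make_track({"chr1": np.concatenate([np.zeros(5000), np.full(5000, 2.0)])})
        genes = [
            GeneAnnotation("lo", "chr1", 1000, 2500, "+"),
            GeneAnnotation("hi", "chr1", 6000, 7500, "+"),
        ]
        profile, _ = metagene(tss_matrix(t, genes))
        assert np.allclose(profile, 1.0)

    def test_clipping_reduces_per_column_counts(self):
        t = make_track({"chr1": np.ones(2000)})
        genes = [
            GeneAnnotation("edge", "chr1", 200, 1500, "+"),  # window starts at -300
            GeneAnnotation("mid", "chr1", 600, 1900, "+"),
        ]
        _, counts = metagene(tss_matrix(t, genes))
        assert counts[0] == 1 and counts[-1] == 2

    def test_empty_matrix_rejected(self):
        t = make_track({"chr1": np.ones(5000)})
        m = tss_matrix(t, [])
        with pytest.raises(ValueError):
            metagene(m)
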