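import numpy as np
import pytest

from rcprof.coverage import condense_array
from rcprof.gc import GCBucketMap
from rcprof.scaling import (
    CoverageVector,
    ScaledProfile,
    ScalingError,
    aggregate_to_kb,
    characteristic_vector,
    characteristic_vector_from_bins,
    scale,
    target_vector,
)


def _uniform_gcmap(chrom_bins, n_buckets=25, seed=0):
    """A bucket map whose bins cycle deterministically through all buckets."""
    rng = np.random.default_rng(seed)
    gc = {c: rng.uniform(0.3, 0.6, n) for c, n in chrom_bins.items()}
    return GCBucketMap.from_gc(gc, bin_size=1000, n_buckets=n_buckets)


class TestCharacteristicVector:
    def test_single_bucket_total(self):
        gcmap = _uniform_gcmap({"chr1": 30})
        depth = np.zeros(30_000)
        target_bucket = gcmap.buckets["chr1"][4]
        depth[4000:5000] = 10.0  # only bin 4 covered
        track = condense_array({"chr1": depth})
        vec = characteristic_vector(track, gcmap, ["chr1"])
        assert vec.values[target_bucket] == pytest.approx(500.0)  # 50 windows x 10
        assert vec.values.sum() == pytest.approx(500.0)

    def test_overflow_windows_excluded(self):
        gcmap = _uniform_gcmap({"chr1": 25})
        base = np.full(25_000, 50.0)
        with_overflow = base.copy()
        with_overflow[:20] = 9000.0
        v_base = characteristic_vector(condense_array({"chr1": base}), gcmap, ["chr1"])
        v_over = characteristic_vector(
            condense_array({"chr1": with_overflow}), gcmap, ["chr1"]
        )
        assert v_over.values.sum() == pytest.approx(v_base.values.sum() - 50.0)

    def test_sex_chromosome_only_coverage_gives_zero_vector(self):
        gcmap = _uniform_gcmap({"chr1": 25, "chrX": 25})
        track = condense_array({"chrX": np.full(25_000, 30.0)}, {"chrX": 25_000})
        vec = characteristic_vector(track, gcmap, ["chr1"])
        assert np.all(vec.values == 0)

    def test_disjoint_naming_rejected(self):
        gcmap = _uniform_gcmap({"chr1": 25})
        track = condense_array({"1": np.full(25_000, 30.0)})
        with pytest.raises(ScalingError):
            characteristic_vector(track, gcmap, ["chr1"])

    def test_depth_ratio_preserved(self):
        """Vectors of the same genome at two depths differ by one constant."""
        gcmap = _uniform_gcmap({"chr1": 50})
        rng = np.random.default_rng(1)
        depth = rng.poisson(60, 50_000).astype(float)
        v1 = characteristic_vector(condense_array({"chr1": depth}), gcmap, ["chr1"])
        v2 = characteristic_vector(condense_array({"chr1": 2 * depth}), gcmap, ["chr1"])
        ratio = v2.values / v1.values
        assert np.allclose(ratio, 2.0, rtol=0.02)


class TestTargetVector:
    def test_single_vector_identity(self):
        v = CoverageVector(np.arange(1.0, 26.0))
        assert target_vector([v]).values == pytest.approx(v.values)

    def test_geometric_mean(self):
        a = CoverageVector(np.full(25, 4.0))
        b = CoverageVector(np.full(25, 9.0))
        assert target_vector([a, b]).values == pytest.approx(np.full(25, 6.0))

    def test_zero_entries_excluded_with_warning(self):
        a = CoverageVector(np.full(25, 4.0))
        vals = np.full(25, 9.0)
        vals[7] = 0.0
        b = CoverageVector(vals)
        with pytest.warns(UserWarning, match="zero entries"):
            t = target_vector([a, b])
        assert t.values[7] == pytest.approx(4.0)
        assert t.values[0] == pytest.approx(6.0)

    def test_empty_input_rejected(self):
        with pytest.raises(ScalingError):
            target_vector([])

    def test_idempotent(self):
        t = target_vector([CoverageVector(np.linspace(1, 50, 25))])
        assert target_vector([t]).values == pytest.approx(t.values)

    def test_tsv_round_trip(self, tmp_path):
        v = CoverageVector(np.linspace(0.5, 100, 25))
        path = str(tmp_path / "vec.tsv")
        v.to_tsv(path)
        assert CoverageVector.from_tsv(path).values == pytest.approx(v.values, abs=1e-5)


class TestAggregateToKb:
    def test_uniform_bin(self):
        track = condense_array({"chr1": np.full(1000, 40.0)})
        assert aggregate_to_kb(track)["chr1"] == pytest.approx([40.0])

    def test_overflow_contributes_full_resolution(self):
        depth = np.full(1000, 40.0)
        depth[:20] = 8123.0
        track = condense_array({"chr1": depth})
        expected = (49 * 40 + 8123) / 50  # = 201.66
        assert aggregate_to_kb(track)["chr1"][0] == pytest.approx(expected)

    def test_terminal_partial_bin(self):
        track = condense_array({"chr1": np.full(1200, 40.0)})
        assert aggregate_to_kb(track)["chr1"] == pytest.approx([40.0, 40.0])


class TestScale:
    @pytest.fixture
    def gcmap(self):
        return _uniform_gcmap({"chr1": 100})

    def test_identity_when_own_equals_target(self, gcmap, rng):
        binned = {"chr1": rng.uniform(30, 50, 100)}
        own = CoverageVector(np.linspace(10, 50, 25))
        out = scale(binned, gcmap, own, CoverageVector(own.values, role="target"))
        assert out.values["chr1"] == pytest.approx(binned["chr1"])

    def test_double_depth_halved(self, gcmap, rng):
        binned = {"chr1": rng.uniform(30, 50, 100)}
        own = CoverageVector(np.full(25, 20.0))
        target = CoverageVector(np.full(25, 10.0), role="target")
        out = scale(binned, gcmap, own, target)
        assert out.values["chr1"] == pytest.approx(binned["chr1"] / 2)

    def test_single_bucket_rescaled(self, gcmap, rng):
        binned = {"chr1": rng.uniform(30, 50, 100)}
        own_vals = np.full(25, 10.0)
        own_vals[7] = 15.0  # 1.5x the target in bucket 7 only
        out = scale(
            binned, gcmap,
            CoverageVector(own_vals),
            CoverageVector(np.full(25, 10.0), role="target"),
        )
        in_bucket7 = gcmap.buckets["chr1"] == 7
        assert out.values["chr1"][in_bucket7] == pytest.approx(
            binned["chr1"][in_bucket7] / 1.5
        )
        assert out.values["chr1"][~in_bucket7] == pytest.approx(
            binned["chr1"][~in_bucket7]
        )

    def test_scale_invariance_unencoded(self, gcmap, rng):
        """Multiplying depth by c > 0 leaves the scaled profile unchanged."""
        binned = {"chr1": rng.uniform(30, 50, 100)}
        own = characteristic_vector_from_bins(binned, gcmap, ["chr1"])
        target = CoverageVector(np.full(25, 1000.0), role="target")
        ref = scale(binned, gcmap, own, target)
        for c in (0.5, 2.0, 5.0):
            scaled_depth = {"chr1": binned["chr1"] * c}
            own_c = characteristic_vector_from_bins(scaled_depth, gcmap, ["chr1"])
            out = scale(scaled_depth, gcmap, own_c, target)
            assert out.values["chr1"] == pytest.approx(ref.values["chr1"])

    def test_post_scaling_totals_match_target(self, gcmap, rng):
        binned = {"chr1": rng.uniform(30, 50, 100)}
        own = characteristic_vector_from_bins(binned, gcmap, ["chr1"])
        targets = [
            characteristic_vector_from_bins({"chr1": rng.uniform(20, 60, 100)},
                                            gcmap, ["chr1"]),
            own,
        ]
        target = target_vector(targets)
        out = scale(binned, gcmap, own, target)
        after = characteristic_vector_from_bins(out.values, gcmap, ["chr1"])
        occupied = own.values > 0
        assert after.values[occupied] == pytest.approx(target.values[occupied])


class TestBedgraphIO:
    def test_round_trip(self, tmp_path, rng):
        values = rng.uniform(0, 100, 50)
        values[10:12] = np.nan
        prof = ScaledProfile(1000, {"chr1": values})
        path = str(tmp_path / "p.bedgraph")
        prof.to_bedgraph(path)
        loaded = ScaledProfile.from_bedgraph(path, {"chr1": 50})
        assert np.isnan(loaded.values["chr1"][10:12]).all()
        ok = ~np.isnan(values)
        assert loaded.values["chr1"][ok] == pytest.approx(values[ok], abs=1e-3)
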