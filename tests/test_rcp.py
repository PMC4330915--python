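import numpy as np
import pytest

from rcprof.rcp import (
    MAX_COHORT,
    RCPError,
    RCPEstimatorParams,
    ReferenceCoverageProfile,
    bin_mad,
    build_rcp,
    correlate_profiles,
    estimate_diploid_level,
    uniformity_stats,
)
from rcprof.scaling import ScaledProfile


def _flat_profiles(n, level=1.0, n_bins=50):
    return [ScaledProfile(1000, {"chr1": np.full(n_bins, level)}) for _ in range(n)]


class TestBinMad:
    def test_constant(self):
        assert bin_mad(np.full(10, 3.0)) == 0.0

    def test_outlier_robust(self):
        assert bin_mad(np.array([1, 2, 3, 4, 100.0])) == 1.0

    def test_scale_equivariance(self, rng):
        x = rng.normal(10, 2, 100)
        assert bin_mad(7 * x) == pytest.approx(7 * bin_mad(x))

    def test_empty_rejected(self):
        with pytest.raises(RCPError):
            bin_mad(np.array([]))


class TestDiploidLevel:
    def test_tight_unimodal_uses_median(self, rng):
        x = rng.normal(1.0, 0.03, 200)
        level, flag = estimate_diploid_level(x)
        assert flag == "median"
        assert level == pytest.approx(1.0, abs=0.01)

    def test_hwe_mixture_moderate_deletion(self, rng):
        g = rng.binomial(2, 0.3, 300)
        x = np.maximum(rng.normal((2 - g) / 2, 0.03), 0)
        level, _ = estimate_diploid_level(x)
        assert level == pytest.approx(1.0, abs=0.05)

    def test_aliasing_common_deletion(self, rng):
        """Hemizygotes/nullizygotes modal: the level must not collapse to 0.5."""
        g = rng.binomial(2, 0.8, 300)
        x = np.maximum(rng.normal((2 - g) / 2, 0.03), 0)
        level, flag = estimate_diploid_level(x)
        assert flag == "peak-model"
        assert level == pytest.approx(1.0, abs=0.1)

    def test_common_duplication_not_inflated(self, rng):
        g = rng.binomial(2, 0.8, 300)
        x = rng.normal((2 + g) / 2, 0.03)
        level, _ = estimate_diploid_level(x)
        assert level == pytest.approx(1.0, abs=0.1)

    def test_all_zero_masked(self):
        level, flag = estimate_diploid_level(np.zeros(100))
        assert flag == "masked" and np.isnan(level)

    def test_median_and_peak_paths_agree_on_unimodal(self, rng):
        """Consistency: forcing the peak model on a clean bin changes little."""
        x = rng.normal(1.0, 0.03, 300)
        med_level, _ = estimate_diploid_level(x)
        forced = RCPEstimatorParams(dispersion_trigger=1e-9,
                                    outlier_fraction_trigger=1e-9)
        peak_level, flag = estimate_diploid_level(x, forced)
        assert flag == "peak-model"
        assert peak_level == pytest.approx(med_level, rel=0.02)


class TestBuildRCP:
    def test_identical_flat_profiles(self):
        rcp = build_rcp(_flat_profiles(10))
        assert rcp.level["chr1"] == pytest.approx(np.ones(50))
        assert rcp.mad["chr1"] == pytest.approx(np.zeros(50))
        assert np.all(rcp.n["chr1"] == 10)

    def test_cohort_capped(self):
        profiles = _flat_profiles(MAX_COHORT + 5, n_bins=5)
        with pytest.warns(UserWarning, match="capped"):
            rcp = build_rcp(profiles)
        assert np.all(rcp.n["chr1"] == MAX_COHORT)

    def test_minority_hemizygosity_does_not_deflate(self, rng):
        profiles = _flat_profiles(10, n_bins=20)
        for p in profiles[:3]:  # 3 of 10 hemizygous in one bin
            p.values["chr1"][5] = 0.5
        rcp = build_rcp(profiles)
        assert rcp.level["chr1"][5] == pytest.approx(1.0, abs=0.05)

    def test_too_few_profiles(self):
        with pytest.raises(RCPError):
            build_rcp(_flat_profiles(1))

    def test_mostly_missing_bins_masked(self):
        profiles = _flat_profiles(10, n_bins=10)
        for p in profiles[:6]:
            p.values["chr1"][3] = np.nan
        rcp = build_rcp(profiles)
        assert np.isnan(rcp.level["chr1"][3])
        assert not np.isnan(rcp.level["chr1"][4])

    def test_equivariance_under_global_scaling(self, rng):
        base = [
            ScaledProfile(1000, {"chr1": rng.uniform(0.8, 1.2, 30)})
            for _ in range(12)
        ]
        scaled = [
            ScaledProfile(1000, {"chr1": 3.0 * p.values["chr1"]}) for p in base
        ]
        a, b = build_rcp(base), build_rcp(scaled)
        assert b.level["chr1"] == pytest.approx(3.0 * a.level["chr1"])

    def test_tsv_round_trip(self, tmp_path, rng):
        profiles = [
            ScaledProfile(1000, {"chr1": rng.uniform(0.9, 1.1, 20)})
            for _ in range(8)
        ]
        rcp = build_rcp(profiles)
        path = str(tmp_path / "rcp.tsv")
        rcp.to_tsv(path)
        loaded = ReferenceCoverageProfile.from_tsv(path)
        assert loaded.level["chr1"] == pytest.approx(rcp.level["chr1"], abs=1e-3)
        assert np.array_equal(loaded.flag["chr1"], rcp.flag["chr1"])


class TestProfileCorrelation:
    def _random_rcp(self, rng, n=10_000):
        profiles = [
            ScaledProfile(1000, {"chr1": rng.uniform(0.5, 1.5, n)}) for _ in range(3)
        ]
        return build_rcp(profiles)

    def test_self_correlation(self, rng):
        a = self._random_rcp(rng, n=100)
        assert correlate_profiles(a, a) == pytest.approx(1.0)

    def test_scale_invariance(self, rng):
        a = self._random_rcp(rng, n=100)
        b = ReferenceCoverageProfile(
            a.bin_size, {"chr1": 2 * a.level["chr1"]}, a.mad, a.n, a.flag
        )
        assert correlate_profiles(a, b) == pytest.approx(1.0)

    def test_independent_profiles_uncorrelated(self, rng):
        a, b = self._random_rcp(rng), self._random_rcp(rng)
        assert abs(correlate_profiles(a, b)) < 0.05

    def test_too_few_joint_bins(self, rng):
        a = self._random_rcp(rng, n=100)
        empty = ReferenceCoverageProfile(
            1000, {"chr1": np.full(100, np.nan)},
            {"chr1": np.zeros(100)}, {"chr1": np.zeros(100, dtype=int)},
            {"chr1": np.full(100, 2, dtype=np.int8)},
        )
        with pytest.raises(RCPError):
            correlate_profiles(a, empty)


class TestUniformityStats:
    def test_flat_profile_step_function(self):
        stats = uniformity_stats(_flat_profiles(1, level=40.0))
        values, frac = stats["per_genome_level"][0]
        assert np.all(values == 40.0)
        assert frac[-1] == 1.0

    def test_two_level_profile(self):
        vals = np.concatenate([np.ones(25), np.full(25, 2.0)])
        stats = uniformity_stats([ScaledProfile(1000, {"chr1": vals})])
        values, frac = stats["per_genome_level"][0]
        assert frac[np.searchsorted(values, 1.0, side="right") - 1] == 0.5
        assert frac[-1] == 1.0

    def test_noise_widens_the_curve(self, rng):
        quiet = [
            ScaledProfile(1000, {"chr1": rng.normal(1, 0.01, 500)}) for _ in range(5)
        ]
        noisy = [
            ScaledProfile(1000, {"chr1": rng.normal(1, 0.2, 500)}) for _ in range(5)
        ]
        def iqr(stats):
            v, f = stats["per_genome_level"][0]
            return v[np.searchsorted(f, 0.75)] - v[np.searchsorted(f, 0.25)]
        assert iqr(uniformity_stats(noisy)) > iqr(uniformity_stats(quiet))
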