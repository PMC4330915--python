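import numpy as np
import pytest

from rcprof.simulate import CNVLocus, simulate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """60 founders, 1000 bins, planted CNVs spanning the frequency range."""
    loci = [
        CNVLocus("chr1", 100_000, 110_000, "deletion", 0.3),
        CNVLocus("chr1", 300_000, 308_000, "duplication", 0.2),
        CNVLocus("chr1", 500_000, 520_000, "deletion", 0.8),
        CNVLocus("chr1", 700_000, 706_000, "deletion", 0.05),
    ]
    return simulate_cohort(n_founders=60, n_trios=0, n_bins=1000, loci=loci, seed=7)


@pytest.fixture(scope="session")
def small_cohort_result(small_cohort):
    from rcprof.pipeline import run_cohort_pipeline

    return run_cohort_pipeline(small_cohort)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
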