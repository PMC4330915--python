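import numpy as np
import pandas as pd
import pytest

from _oracles import single_linkage_bruteforce
from rcprof.population import (
    PanelStates,
    allele_frequency,
    cluster_junctions,
    filter_rare_deletions,
    gene_impact,
    genotype_frequency,
    read_panel_manifest,
    read_state_track,
    write_state_track,
)
from rcprof.segment import CopyNumberSegment


def _segment(state, start=0, end=3000, freq=None):
    return CopyNumberSegment(
        chrom="chr1", start=start, end=end, state=state,
        n_bins=(end - start) // 1000, median_ncp=50.0, genotype_freq=freq,
    )


def _panel(state_matrix):
    """Panel from a (individuals, bins) state matrix on chr1."""
    matrix = np.asarray(state_matrix, dtype=np.int8)
    return PanelStates(
        1000, [f"I{i}" for i in range(len(matrix))], {"chr1": matrix}
    )


class TestGenotypeFrequency:
    def test_uniform_match_fraction(self):
        matrix = np.full((100, 3), 2)
        matrix[:10] = 1
        assert genotype_frequency(_segment(1), _panel(matrix)) == pytest.approx(0.10)

    def test_median_over_bins(self):
        matrix = np.full((100, 3), 2)
        matrix[:5, 0] = 1
        matrix[:10, 1] = 1
        matrix[:15, 2] = 1
        assert genotype_frequency(_segment(1), _panel(matrix)) == pytest.approx(0.10)

    def test_no_match_is_zero(self):
        assert genotype_frequency(_segment(0), _panel(np.full((50, 3), 2))) == 0.0

    def test_no_overlap_missing(self):
        seg = CopyNumberSegment("chr9", 0, 1000, 1, 1, 50.0)
        assert np.isnan(genotype_frequency(seg, _panel(np.full((50, 3), 2))))


class TestAlleleFrequency:
    def test_deletion_alleles_integrated(self):
        # 90 diploid, 9 hemizygous, 1 nullizygous in 100 -> (9 + 2) / 200
        matrix = np.full((100, 3), 2)
        matrix[:9] = 1
        matrix[9] = 0
        assert allele_frequency(_segment(1), _panel(matrix)) == pytest.approx(0.055)

    def test_all_diploid_zero(self):
        assert allele_frequency(_segment(1), _panel(np.full((100, 3), 2))) == 0.0

    def test_duplication_alleles(self):
        matrix = np.full((100, 3), 2)
        matrix[:10] = 3
        assert allele_frequency(_segment(3), _panel(matrix)) == pytest.approx(0.05)

    def test_diploid_segment_undefined(self):
        assert np.isnan(allele_frequency(_segment(2), _panel(np.full((10, 3), 2))))

    def test_bounded_by_direct_count(self, rng):
        """AF stays within [0,1] and <= (het + 2 hom) / 2n from a direct count."""
        for _ in range(20):
            matrix = rng.integers(0, 5, size=(50, 4)).astype(np.int8)
            af = allele_frequency(_segment(1, end=4000), _panel(matrix))
            per_bin = (np.maximum(2 - matrix, 0)).sum(axis=0) / 100.0
            assert 0.0 <= af <= 1.0
            assert af <= per_bin.max() + 1e-12

    def test_hwe_panel_recovers_allele_frequency(self, rng):
        for p in (0.1, 0.3):
            g = rng.binomial(2, p, 500)
            matrix = (2 - g)[:, None] * np.ones((1, 5), dtype=int)
            af = allele_frequency(_segment(1, end=5000), _panel(matrix))
            assert af == pytest.approx(p, abs=0.02)


class TestJunctionClusters:
    def test_cutoff_splits_far_junctions(self):
        rows = [("a", "chr1", 1000), ("b", "chr1", 1200), ("c", "chr1", 5000)]
        clusters = cluster_junctions(rows, n_assemblies=3)
        assert [(c.start, c.end) for c in clusters] == [(1000, 1200), (5000, 5000)]

    def test_single_linkage_chains(self):
        rows = [("a", "chr1", 0), ("b", "chr1", 300), ("c", "chr1", 600)]
        clusters = cluster_junctions(rows, n_assemblies=3)
        assert len(clusters) == 1
        assert clusters[0].n_members == 3

    def test_frequency_counts_each_assembly_once(self):
        rows = [("a", "chr1", 100), ("a", "chr1", 200), ("b", "chr1", 300)]
        (cluster,) = cluster_junctions(rows, n_assemblies=1584)
        assert cluster.frequency == pytest.approx(2 / 1584)

    def test_order_invariant_and_matches_bruteforce(self, rng):
        positions = sorted(int(p) for p in rng.integers(0, 50_000, 150))
        rows = [("a", "chr1", p) for p in positions]
        shuffled = [rows[i] for i in rng.permutation(len(rows))]
        for variant in (rows, shuffled):
            clusters = cluster_junctions(variant, n_assemblies=1)
            got = sorted(
                tuple(sorted(p for p in positions if c.start <= p <= c.end))
                for c in clusters
            )
            assert got == single_linkage_bruteforce(positions, 400)


class TestRareDeletions:
    def test_kept(self):
        kept = filter_rare_deletions([_segment(1, 0, 5000, freq=0.005)])
        assert len(kept) == 1

    def test_too_short_dropped(self):
        assert filter_rare_deletions([_segment(1, 0, 2000, freq=0.005)]) == []

    def test_too_frequent_dropped(self):
        assert filter_rare_deletions([_segment(1, 0, 5000, freq=0.02)]) == []

    def test_non_deletion_states_dropped(self):
        assert filter_rare_deletions([_segment(3, 0, 5000, freq=0.001)]) == []


class TestGeneImpact:
    @pytest.fixture
    def exons(self):
        return pd.DataFrame(
            {
                "chrom": ["chr1", "chr1", "chr1"],
                "start": [15_200, 10_100, 25_500],
                "end": [15_800, 10_900, 26_000],
                "gene": ["GENE_MID", "GENE_EDGE", "GENE_NULL"],
            }
        )

    def test_interior_exon_affected(self, exons):
        table = gene_impact([_segment(1, 10_000, 20_000)], exons)
        row = table[table["gene"] == "GENE_MID"].iloc[0]
        assert row["affected"] and not row["knocked_out"]

    def test_terminal_bin_exon_excluded(self, exons):
        table = gene_impact([_segment(1, 10_000, 20_000)], exons)
        assert "GENE_EDGE" not in set(table["gene"])

    def test_nullizygous_knockout(self, exons):
        table = gene_impact([_segment(0, 24_000, 28_000)], exons)
        row = table[table["gene"] == "GENE_NULL"].iloc[0]
        assert row["knocked_out"]

    def test_two_bin_deletion_trims_to_nothing(self, exons):
        assert gene_impact([_segment(1, 15_000, 17_000)], exons).empty


class TestStateTrackIO:
    def test_round_trip(self, tmp_path, rng):
        states = {"chr1": rng.integers(0, 5, 40).astype(np.int8)}
        path = str(tmp_path / "states.bed")
        write_state_track(states, path)
        loaded = read_state_track(path)
        assert np.array_equal(loaded["chr1"], states["chr1"])

    def test_manifest(self, tmp_path, rng):
        manifest = tmp_path / "panel.tsv"
        lines = []
        for ind in ("A", "B"):
            states = {"chr1": rng.integers(0, 5, 20).astype(np.int8)}
            write_state_track(states, str(tmp_path / f"{ind}.bed"))
            lines.append(f"{ind}\t{ind}.bed")
        manifest.write_text("\n".join(lines) + "\n")
        panel = read_panel_manifest(str(manifest))
        assert panel.individuals == ["A", "B"]
        assert panel.states["chr1"].shape == (2, 20)
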