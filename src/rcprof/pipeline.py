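"""End-to-end orchestration: depth -> condense -> scale -> RCP -> NCP -> segments.

Convenience wrappers that run the full calling pipeline over a simulated
cohort (or any set of coverage inputs sharing a GC map), plus truth-based
scoring of the resulting segment calls.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .coverage import CondensedTrack, condense_array
from .gc import GCBucketMap
from .rcp import RCPEstimatorParams, ReferenceCoverageProfile, build_rcp
from .scaling import (
    CoverageVector,
    ScaledProfile,
    aggregate_to_kb,
    characteristic_vector,
    characteristic_vector_from_bins,
    scale,
    target_vector,
)
from .segment import (
    CopyNumberSegment,
    HMMParams,
    NormalizedCoverageProfile,
    call_segments,
    normalize,
    viterbi,
)
from .simulate import CNVLocus, CohortTruth


@dataclass
class CohortCallResult:
    """Everything the pipeline produces for a cohort."""

    gcmap: GCBucketMap
    rcp: ReferenceCoverageProfile
    scaled: dict[str, ScaledProfile]
    ncp: dict[str, NormalizedCoverageProfile]
    states: dict[str, dict[str, np.ndarray]]
    segments: dict[str, list[CopyNumberSegment]]
    target: "CoverageVector | None" = None


def gcmap_from_model(truth: CohortTruth) -> GCBucketMap:
    """GC bucket map taken directly from the simulation's per-bin %GC."""
    model = truth.model
    return GCBucketMap.from_gc(
        {model.chrom: model.gc}, bin_size=model.bin_size, n_buckets=model.n_buckets
    )


def _finish(
    gcmap: GCBucketMap,
    binned: dict[str, dict[str, np.ndarray]],
    autosomes: list[str],
    rcp_params: RCPEstimatorParams,
    hmm_params: HMMParams,
) -> CohortCallResult:
    vectors = {
        ind: characteristic_vector_from_bins(b, gcmap, autosomes)
        for ind, b in binned.items()
    }
    target = target_vector(list(vectors.values()))
    scaled = {
        ind: scale(binned[ind], gcmap, vectors[ind], target) for ind in binned
    }
    rcp = build_rcp(list(scaled.values()), rcp_params)
    ncp, states, segs = {}, {}, {}
    for ind in binned:
        ncp[ind] = normalize(scaled[ind], rcp)
        states[ind] = {
            chrom: viterbi(ncp[ind].values[chrom], hmm_params)
            for chrom in ncp[ind].chromosomes
        }
        segs[ind] = call_segments(ncp[ind], hmm_params)
    return CohortCallResult(gcmap, rcp, scaled, ncp, states, segs, target)


def run_cohort_pipeline(
    truth: CohortTruth,
    per_base: bool = False,
    gcmap: GCBucketMap | None = None,
    rcp_params: RCPEstimatorParams | None = None,
    hmm_params: HMMParams | None = None,
) -> CohortCallResult:
    """Call CNVs across a simulated cohort.

    With ``per_base=True`` the full storage path is exercised (per-base
    Poisson depth, 20-bp condensing, decode, 1-kb aggregation); otherwise
    bin-level depth feeds the scaling directly, which is statistically
    identical and far cheaper.
    """
    rcp_params = rcp_params or RCPEstimatorParams()
    hmm_params = hmm_params or HMMParams()
    gcmap = gcmap or gcmap_from_model(truth)
    chrom = truth.model.chrom
    binned: dict[str, dict[str, np.ndarray]] = {}
    for ind in truth.individuals:
        if per_base:
            track = condense_array({chrom: truth.depth(ind, per_base=True)})
            binned[ind] = aggregate_to_kb(track, truth.model.bin_size)
        else:
            binned[ind] = {chrom: truth.depth(ind)}
    return _finish(gcmap, binned, [chrom], rcp_params, hmm_params)


def run_tracks_pipeline(
    tracks: dict[str, CondensedTrack],
    gcmap: GCBucketMap,
    autosomes: list[str],
    rcp_params: RCPEstimatorParams | None = None,
    hmm_params: HMMParams | None = None,
) -> CohortCallResult:
    """Call CNVs from already-condensed coverage tracks (the file-based path)."""
    rcp_params = rcp_params or RCPEstimatorParams()
    hmm_params = hmm_params or HMMParams()
    binned = {ind: aggregate_to_kb(t, gcmap.bin_size) for ind, t in tracks.items()}
    # fingerprints from the tracks proper, so overflow exclusion applies
    vectors = {
        ind: characteristic_vector(tracks[ind], gcmap, autosomes) for ind in tracks
    }
    target = target_vector(list(vectors.values()))
    scaled = {ind: scale(binned[ind], gcmap, vectors[ind], target) for ind in tracks}
    rcp = build_rcp(list(scaled.values()), rcp_params)
    ncp, states, segs = {}, {}, {}
    for ind in tracks:
        ncp[ind] = normalize(scaled[ind], rcp)
        states[ind] = {
            chrom: viterbi(ncp[ind].values[chrom], hmm_params)
            for chrom in ncp[ind].chromosomes
        }
        segs[ind] = call_segments(ncp[ind], hmm_params)
    return CohortCallResult(gcmap, rcp, scaled, ncp, states, segs, target)


def true_events(truth: CohortTruth, individual: str) -> list[tuple[str, int, int, str]]:
    """Planted non-diploid intervals carried by one individual."""
    out = []
    for j, locus in enumerate(truth.loci):
        if truth.haplotypes[individual][j].sum() > 0:
            out.append((locus.chrom, locus.start, locus.end, locus.kind))
    return out


def evaluate_calls(
    result: CohortCallResult,
    truth: CohortTruth,
    min_length: int = 5000,
    boundary_tol_bins: int = 2,
) -> dict:
    """Recall / precision / boundary accuracy of calls against planted truth.

    An event matches a call when both boundaries agree within the bin
    tolerance and the call is on the correct side of diploid.  Recall is
    over planted events of at least ``min_length``; precision over called
    non-diploid segments of at least ``min_length`` minus the boundary
    tolerance (so a truncated-but-matching call still counts as a call).
    """
    tol = boundary_tol_bins * truth.model.bin_size
    n_true = n_found = n_called = n_good = 0
    boundary_errors = []
    for ind in truth.individuals:
        events = [e for e in true_events(truth, ind) if e[2] - e[1] >= min_length]
        calls = [
            s
            for s in result.segments[ind]
            if s.state != 2 and (s.end - s.start) >= min_length - tol
        ]
        n_true += len(events)
        n_called += len(calls)
        for chrom, start, end, kind in events:
            for s in calls:
                side_ok = (s.state < 2) if kind == "deletion" else (s.state > 2)
                if (
                    s.chrom == chrom and side_ok
                    and abs(s.start - start) <= tol and abs(s.end - end) <= tol
                ):
                    n_found += 1
                    boundary_errors.append(
                        max(abs(s.start - start), abs(s.end - end))
                        / truth.model.bin_size
                    )
                    break
        for s in calls:
            for chrom, start, end, kind in true_events(truth, ind):
                side_ok = (s.state < 2) if kind == "deletion" else (s.state > 2)
                if (
                    s.chrom == chrom and side_ok
                    and abs(s.start - start) <= tol and abs(s.end - end) <= tol
                ):
                    n_good += 1
                    break
    return {
        "recall": n_found / n_true if n_true else float("nan"),
        "precision": n_good / n_called if n_called else float("nan"),
        "n_true_events": n_true,
        "n_calls": n_called,
        "max_boundary_error_bins": max(boundary_errors) if boundary_errors else 0.0,
    }
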