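"""Depth equalization across genomes via %GC-bucket coverage vectors.

Genomes are sequenced to different total depths and carry different
GC-bias curves.  Each genome is fingerprinted by a *characteristic
coverage vector*: the total autosomal coverage in each of the 25 %GC
buckets, excluding overflow windows.  A cohort's *target coverage vector*
is the entry-wise geometric mean of its members' characteristic vectors.
Scaling multiplies each 1-kb bin's coverage by ``target[bucket] /
own[bucket]``, which equalizes every genome's per-bucket totals to the
target — removing both overall depth and per-bucket GC bias, so that
coverage values are comparable across the cohort.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .coverage import OVERFLOW_SENTINEL, CondensedTrack
from .gc import GCBucketMap

N_BUCKETS = 25


class ScalingError(ValueError):
    pass


@dataclass(frozen=True)
class CoverageVector:
    """25 per-%GC-bucket autosomal coverage totals.

    ``role`` is "characteristic" for one genome, "target" for a cohort.
    """

    values: np.ndarray
    role: str = "characteristic"

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=np.float64)
        if v.shape != (N_BUCKETS,):
            raise ScalingError(f"coverage vector must have {N_BUCKETS} entries")
        if (v < 0).any():
            raise ScalingError("coverage vector entries must be non-negative")
        object.__setattr__(self, "values", v)

    def to_tsv(self, path: str) -> None:
        with open(path, "w") as fh:
            for b, v in enumerate(self.values):
                fh.write(f"{b}\t{v:.6f}\n")

    @classmethod
    def from_tsv(cls, path: str, role: str = "characteristic") -> "CoverageVector":
        frame = pd.read_csv(path, sep="\t", names=["bucket", "total"])
        values = np.zeros(N_BUCKETS)
        values[frame["bucket"].to_numpy()] = frame["total"].to_numpy()
        return cls(values, role)


@dataclass
class ScaledProfile:
    """Per-1-kb-bin coverage on the cohort's common scale; NaN = masked bin."""

    bin_size: int
    values: dict[str, np.ndarray] = field(repr=False)

    @property
    def chromosomes(self) -> list[str]:
        return list(self.values)

    def to_bedgraph(self, path: str) -> None:
        with open(path, "w") as fh:
            for chrom, vals in self.values.items():
                for i, v in enumerate(vals):
                    if not np.isnan(v):
                        s = i * self.bin_size
                        fh.write(f"{chrom}\t{s}\t{s + self.bin_size}\t{v:.4f}\n")

    @classmethod
    def from_bedgraph(cls, path: str, chrom_bins: dict[str, int] | None = None,
                      bin_size: int = 1000) -> "ScaledProfile":
        frame = pd.read_csv(path, sep="\t", names=["chrom", "start", "end", "value"])
        if len(frame):
            bin_size = int((frame["end"] - frame["start"]).iloc[0])
        sizes = dict(chrom_bins) if chrom_bins else {
            str(c): int(g["end"].max()) // bin_size
            for c, g in frame.groupby("chrom", sort=False)
        }
        values = {c: np.full(n, np.nan) for c, n in sizes.items()}
        for chrom, grp in frame.groupby("chrom", sort=False):
            idx = grp["start"].to_numpy() // bin_size
            values[str(chrom)][idx] = grp["value"].to_numpy()
        return cls(bin_size, values)


def aggregate_to_kb(track: CondensedTrack, bin_size: int = 1000) -> dict[str, np.ndarray]:
    """Mean decoded coverage per 1-kb bin (overflow windows at full resolution).

    Terminal partial bins average over their existing windows only.
    """
    per_bin = bin_size // track.window_size
    out = {}
    for chrom in track.chromosomes:
        values = track.decoded(chrom)
        edges = np.arange(0, len(values), per_bin)
        sums = np.add.reduceat(values, edges)
        counts = np.minimum(edges + per_bin, len(values)) - edges
        out[chrom] = sums / counts
    return out


def characteristic_vector(
    track: CondensedTrack, gcmap: GCBucketMap, autosomes: Sequence[str]
) -> CoverageVector:
    """Total decoded autosomal coverage per %GC bucket, skipping overflow windows."""
    shared = [c for c in track.chromosomes if c in set(autosomes) and c in gcmap.gc]
    if not shared:
        # an autosome-free track is a legitimate degenerate fingerprint only
        # when the track has no autosomes at all; disjoint naming is an error
        if not any(c in gcmap.gc for c in track.chromosomes):
            raise ScalingError("track and GC map share no chromosomes")
    totals = np.zeros(N_BUCKETS)
    per_bin = gcmap.bin_size // track.window_size
    for chrom in shared:
        raw = track.data[chrom]
        decoded = track.decoded(chrom)
        keep = raw != OVERFLOW_SENTINEL  # overflow windows excluded from the fingerprint
        win_bin = np.arange(len(raw)) // per_bin
        buckets = gcmap.buckets[chrom]
        win_bucket = buckets[np.minimum(win_bin, len(buckets) - 1)]
        ok = keep & (win_bucket >= 0)
        np.add.at(totals, win_bucket[ok], decoded[ok])
    return CoverageVector(totals, role="characteristic")


def characteristic_vector_from_bins(
    binned: dict[str, np.ndarray], gcmap: GCBucketMap, autosomes: Sequence[str]
) -> CoverageVector:
    """Fingerprint from per-1-kb binned coverage instead of a condensed track.

    Totals of bin means per bucket differ from window totals only by the
    constant windows-per-bin factor, which cancels in scaling ratios.
    """
    totals = np.zeros(N_BUCKETS)
    auto = set(autosomes)
    seen = False
    for chrom, vals in binned.items():
        if chrom not in auto or chrom not in gcmap.buckets:
            continue
        seen = True
        buckets = gcmap.buckets[chrom][: len(vals)]
        ok = (buckets >= 0) & ~np.isnan(vals)
        np.add.at(totals, buckets[ok], np.asarray(vals, dtype=np.float64)[ok])
    if not seen and not any(c in gcmap.buckets for c in binned):
        raise ScalingError("coverage and GC map share no chromosomes")
    return CoverageVector(totals, role="characteristic")


def target_vector(vectors: Sequence[CoverageVector]) -> CoverageVector:
    """Entry-wise geometric mean of characteristic vectors (computed in log space).

    A genome with a zero entry is excluded from that entry's mean (with a
    warning) rather than zeroing the whole cohort entry.
    """
    if not vectors:
        raise ScalingError("target_vector requires at least one vector")
    matrix = np.stack([v.values for v in vectors])
    target = np.zeros(N_BUCKETS)
    for b in range(N_BUCKETS):
        col = matrix[:, b]
        positive = col[col > 0]
        if len(positive) < len(col):
            warnings.warn(
                f"bucket {b}: {len(col) - len(positive)} zero entries excluded "
                "from geometric mean",
                stacklevel=2,
            )
        if len(positive):
            target[b] = np.exp(np.mean(np.log(positive)))
    return CoverageVector(target, role="target")


def scale(
    binned: dict[str, np.ndarray],
    gcmap: GCBucketMap,
    own: CoverageVector,
    target: CoverageVector,
    literal_divide: bool = False,
) -> ScaledProfile:
    """Equalize per-1-kb coverage to the cohort scale.

    Default: ``scaled = raw * target[bucket] / own[bucket]``, which makes the
    genome's per-bucket totals equal the target's.  ``literal_divide``
    instead divides raw coverage by the target entry alone (no per-genome
    depth removal) for users who want the plain ratio.
    """
    factors = np.full(N_BUCKETS, np.nan)
    for b in range(N_BUCKETS):
        if literal_divide:
            factors[b] = 1.0 / target.values[b] if target.values[b] > 0 else np.nan
        elif own.values[b] > 0 and target.values[b] > 0:
            factors[b] = target.values[b] / own.values[b]
    out = {}
    for chrom, raw in binned.items():
        if chrom not in gcmap.buckets:
            continue
        buckets = gcmap.buckets[chrom][: len(raw)]
        vals = np.full(len(raw), np.nan)
        ok = buckets >= 0
        f = np.where(ok, factors[np.maximum(buckets, 0)], np.nan)
        bad = ok & np.isnan(f) & (np.asarray(raw) > 0)
        if bad.any() and not literal_divide:
            raise ScalingError(
                f"{chrom}: nonzero coverage in a bucket with zero own-vector total"
            )
        vals[ok] = np.asarray(raw, dtype=np.float64)[ok] * f[ok]
        out[chrom] = vals
    if not out:
        raise ScalingError("no chromosomes shared between coverage and GC map")
    return ScaledProfile(gcmap.bin_size, out)
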