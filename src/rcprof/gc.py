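"""Genome stratification by %GC.

Base composition biases depth of coverage, and the bias drifts between
sequencing batches.  To correct for it without leaning on sparsely
populated extreme-%GC ranges, the genome is cut into 1-kb bins and the
bins are stratified by *rank* into 25 buckets of approximately equal
genomic span.  The bucket cutoffs are empirical quantiles of the per-bin
GC fraction; bins that are mostly assembly gap (N) are masked.

A reference preset of cutoffs computed on GRCh37 at 1-kb resolution is
available as :data:`GRCH37_PRESET_CUTOFFS` for users who want to reuse
the published stratification rather than recompute one.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from pyfaidx import Fasta

BIN_SIZE = 1000
N_BUCKETS = 25

# GRCh37 1-kb quantile cutoffs, in percent. One adjacent pair is ordered
# here (39.6, 39.8); always-recomputed cutoffs are the default.
GRCH37_PRESET_CUTOFFS = (
    30.1, 31.7, 32.9, 33.9, 34.8, 35.6, 36.3, 37.0, 37.7, 38.3, 39.6, 39.8,
    40.3, 41.0, 41.8, 42.6, 43.4, 44.4, 45.4, 46.5, 47.9, 49.5, 51.9, 56.0,
)

_VALID = frozenset("ACGTNacgtn")


class GCError(ValueError):
    pass


def gc_fraction(sequence: str) -> float:
    """GC fraction of a window, ignoring N; NaN if more than half is N."""
    counts = {b: 0 for b in "ACGTN"}
    for base in sequence:
        if base not in _VALID:
            raise GCError(f"non-nucleotide character: {base!r}")
        counts[base.upper()] += 1
    n_real = len(sequence) - counts["N"]
    if n_real * 2 < len(sequence) or n_real == 0:
        return float("nan")
    return (counts["G"] + counts["C"]) / n_real


def _gc_fraction_bytes(window: np.ndarray) -> float:
    """Vectorized variant over an uint8 array of sequence bytes."""
    upper = window & ~np.uint8(0x20)  # fold lowercase
    n_n = int((upper == ord("N")).sum())
    n_real = len(window) - n_n
    if n_real * 2 < len(window) or n_real == 0:
        return float("nan")
    gc = int(((upper == ord("G")) | (upper == ord("C"))).sum())
    return gc / n_real


def compute_cutoffs(gc_values: Iterable[float], n_buckets: int = N_BUCKETS) -> np.ndarray:
    """Rank-based bucket cutoffs: the k/n empirical quantiles, k = 1..n-1.

    Uses the type-1 empirical quantile (cutoff k is the ceil(k*m/n)-th
    smallest of the m non-missing values), so permuting the input never
    changes the result.
    """
    values = np.sort(np.asarray(list(gc_values), dtype=np.float64))
    values = values[~np.isnan(values)]
    m = len(values)
    if m < n_buckets:
        raise GCError(f"need at least {n_buckets} non-missing values, got {m}")
    ranks = np.ceil(np.arange(1, n_buckets) * m / n_buckets).astype(int) - 1
    return values[ranks]


def assign_bucket(gc: float, cutoffs: Sequence[float]) -> int:
    """Bucket index of a GC fraction; values equal to a cutoff go to the lower bucket."""
    if np.isnan(gc):
        return -1
    return int(np.searchsorted(np.asarray(cutoffs), gc, side="left"))


@dataclass
class GCBucketMap:
    """Per-1-kb-bin GC fraction and rank-based bucket index for a genome.

    ``buckets`` holds -1 for masked bins (mostly-N windows).
    """

    bin_size: int
    n_buckets: int
    cutoffs: np.ndarray
    chrom_bins: dict[str, int]
    gc: dict[str, np.ndarray] = field(repr=False)
    buckets: dict[str, np.ndarray] = field(repr=False)

    @property
    def chromosomes(self) -> list[str]:
        return list(self.chrom_bins)

    @classmethod
    def from_fasta(
        cls,
        fasta_path: str,
        bin_size: int = BIN_SIZE,
        n_buckets: int = N_BUCKETS,
        autosomes_only_cutoffs: bool = False,
        autosomes: set[str] | None = None,
        cutoffs: Sequence[float] | None = None,
    ) -> "GCBucketMap":
        """Compute per-bin GC from a reference FASTA and stratify into buckets.

        ``cutoffs`` overrides recomputation (e.g. with a published preset,
        given as fractions); by default cutoffs are the empirical quantiles
        of all unmasked bins, or of autosomal bins only when requested.
        """
        fasta = Fasta(fasta_path, as_raw=True, sequence_always_upper=False)
        gc: dict[str, np.ndarray] = {}
        chrom_bins: dict[str, int] = {}
        for name in fasta.keys():
            seq = np.frombuffer(str(fasta[name][:]).encode(), dtype=np.uint8)
            n_bins = -(-len(seq) // bin_size)
            chrom_bins[name] = n_bins
            vals = np.empty(n_bins)
            for i in range(n_bins):
                vals[i] = _gc_fraction_bytes(seq[i * bin_size : (i + 1) * bin_size])
            gc[name] = vals
        return cls.from_gc(
            gc, bin_size, n_buckets,
            autosomes_only_cutoffs=autosomes_only_cutoffs,
            autosomes=autosomes, cutoffs=cutoffs,
        )

    @classmethod
    def from_gc(
        cls,
        gc: dict[str, np.ndarray],
        bin_size: int = BIN_SIZE,
        n_buckets: int = N_BUCKETS,
        autosomes_only_cutoffs: bool = False,
        autosomes: set[str] | None = None,
        cutoffs: Sequence[float] | None = None,
    ) -> "GCBucketMap":
        chrom_bins = {c: len(v) for c, v in gc.items()}
        if cutoffs is None:
            if autosomes_only_cutoffs:
                if autosomes is None:
                    raise GCError("autosomes_only_cutoffs requires an autosome set")
                pool = np.concatenate([gc[c] for c in gc if c in autosomes])
            else:
                pool = np.concatenate(list(gc.values()))
            cut = compute_cutoffs(pool, n_buckets)
        else:
            cut = np.asarray(cutoffs, dtype=np.float64)
            if len(cut) != n_buckets - 1:
                raise GCError(f"expected {n_buckets - 1} cutoffs, got {len(cut)}")
            if (np.diff(cut) <= 0).any():
                raise GCError("cutoffs must be strictly ascending")
        buckets = {}
        for chrom, vals in gc.items():
            idx = np.searchsorted(cut, vals, side="left").astype(np.int32)
            idx[np.isnan(vals)] = -1
            buckets[chrom] = idx
        return cls(bin_size, n_buckets, cut, chrom_bins, gc, buckets)

    def to_bed(self, path: str) -> None:
        """Write ``chrom start end gc bucket`` (0-based half-open) TSV."""
        rows = []
        for chrom, vals in self.gc.items():
            starts = np.arange(len(vals)) * self.bin_size
            rows.append(
                pd.DataFrame(
                    {
                        "chrom": chrom,
                        "start": starts,
                        "end": starts + self.bin_size,
                        "gc": np.round(vals, 6),
                        "bucket": self.buckets[chrom],
                    }
                )
            )
        pd.concat(rows).to_csv(path, sep="\t", header=False, index=False)

    @classmethod
    def from_bed(cls, path: str, n_buckets: int = N_BUCKETS) -> "GCBucketMap":
        frame = pd.read_csv(
            path, sep="\t", names=["chrom", "start", "end", "gc", "bucket"]
        )
        bin_size = int((frame["end"] - frame["start"]).iloc[0])
        gc, buckets = {}, {}
        for chrom, grp in frame.groupby("chrom", sort=False):
            gc[str(chrom)] = grp["gc"].to_numpy(dtype=np.float64)
            buckets[str(chrom)] = grp["bucket"].to_numpy(dtype=np.int32)
        pool = np.concatenate(list(gc.values()))
        cut = compute_cutoffs(pool, n_buckets)
        chrom_bins = {c: len(v) for c, v in gc.items()}
        return cls(bin_size, n_buckets, cut, chrom_bins, gc, buckets)

    def bucket_spans(self) -> np.ndarray:
        """Fraction of unmasked bins per bucket (QC for the equal-span goal)."""
        all_b = np.concatenate(list(self.buckets.values()))
        all_b = all_b[all_b >= 0]
        return np.bincount(all_b, minlength=self.n_buckets) / len(all_b)
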