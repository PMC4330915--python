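"""Normalization to the reference profile and HMM copy-number segmentation.

Dividing a genome's scaled 1-kb coverage by the reference (diploid)
level yields its normalized coverage profile (NCP), expressed in percent
of diploid: 100 is two copies, 50 hemizygous, 0 nullizygous, 150/200
three/four-plus copies.  A five-state HMM with Gaussian emissions
centered at those values decodes each chromosome into the most probable
copy-state path (Viterbi); maximal runs of a constant state become
copy-number segments.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .rcp import ReferenceCoverageProfile
from .scaling import ScaledProfile

# normalized coverage, percent of diploid, for states 0..4
EMISSION_MEANS = (0.0, 50.0, 100.0, 150.0, 200.0)
RCP_LEVEL_FLOOR_FRACTION = 0.10  # of the genome-wide median level


class SegmentationError(ValueError):
    pass


@dataclass
class NormalizedCoverageProfile:
    """Per-1-kb-bin coverage in percent of diploid; NaN = masked bin."""

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
                        fh.write(f"{chrom}\t{s}\t{s + self.bin_size}\t{v:.2f}\n")

    @classmethod
    def from_bedgraph(cls, path: str) -> "NormalizedCoverageProfile":
        prof = ScaledProfile.from_bedgraph(path)
        return cls(prof.bin_size, prof.values)


@dataclass
class HMMParams:
    """Five-state copy-number HMM.

    Emission means are fixed at 0/50/100/150/200% of diploid; the state-4
    emission is wide because it stands for "four or more copies".
    Self-transitions near 1 encode that copy state is locally constant at
    the 1-kb scale.
    """

    emission_sds: tuple[float, ...] = (12.0, 12.0, 12.0, 18.0, 30.0)
    self_transition: float = 1.0 - 1e-4
    initial: tuple[float, ...] = (0.001, 0.01, 0.978, 0.01, 0.001)
    emission_means: tuple[float, ...] = EMISSION_MEANS

    def transition_matrix(self) -> np.ndarray:
        n = len(self.emission_means)
        off = (1.0 - self.self_transition) / (n - 1)
        matrix = np.full((n, n), off)
        np.fill_diagonal(matrix, self.self_transition)
        return matrix

    def validate(self) -> None:
        n = len(self.emission_means)
        if len(self.emission_sds) != n or len(self.initial) != n:
            raise SegmentationError("parameter vectors must match the state count")
        if any(s <= 0 for s in self.emission_sds):
            raise SegmentationError("emission SDs must be positive")
        if not np.allclose(sum(self.initial), 1.0):
            raise SegmentationError("initial distribution must sum to 1")
        if not np.allclose(self.transition_matrix().sum(axis=1), 1.0):
            raise SegmentationError("transition matrix rows must sum to 1")
        if not 0 < self.self_transition <= 1:
            raise SegmentationError("self-transition must be in (0, 1]")


@dataclass(frozen=True)
class CopyNumberSegment:
    """A maximal run of bins in one copy-number state (0-based half-open)."""

    chrom: str
    start: int
    end: int
    state: int
    n_bins: int
    median_ncp: float
    genotype_freq: float | None = None
    allele_freq: float | None = None


def normalize(
    scaled: ScaledProfile,
    rcp: ReferenceCoverageProfile,
    level_floor_fraction: float = RCP_LEVEL_FLOOR_FRACTION,
) -> NormalizedCoverageProfile:
    """Divide scaled coverage by the reference diploid level, in percent.

    Bins with a masked reference level, or a level below a fraction of the
    genome-wide median level (dropout regions), are masked.
    """
    shared = [c for c in scaled.chromosomes if c in rcp.level]
    if not shared:
        raise SegmentationError("scaled profile and reference share no chromosomes")
    all_levels = np.concatenate([rcp.level[c] for c in rcp.chromosomes])
    ok_levels = all_levels[~np.isnan(all_levels)]
    floor = level_floor_fraction * (np.median(ok_levels) if len(ok_levels) else 0.0)
    out = {}
    for chrom in shared:
        raw = scaled.values[chrom]
        lv = rcp.level[chrom]
        m = min(len(raw), len(lv))
        vals = np.full(len(raw), np.nan)
        with np.errstate(invalid="ignore", divide="ignore"):
            good = ~np.isnan(raw[:m]) & ~np.isnan(lv[:m]) & (lv[:m] >= max(floor, 1e-12))
            vals[:m][good] = 100.0 * raw[:m][good] / lv[:m][good]
        out[chrom] = vals
    return NormalizedCoverageProfile(scaled.bin_size, out)


def _log_emissions(values: np.ndarray, params: HMMParams) -> np.ndarray:
    """(bins, states) Gaussian log densities; masked bins emit uniformly."""
    means = np.asarray(params.emission_means)
    sds = np.asarray(params.emission_sds)
    logb = (
        -0.5 * ((values[:, None] - means[None, :]) / sds[None, :]) ** 2
        - np.log(sds)[None, :]
    )
    logb[np.isnan(values)] = 0.0  # no evidence: bridge through masked bins
    return logb


def viterbi(values: np.ndarray, params: HMMParams = HMMParams()) -> np.ndarray:
    """Most probable state path for one chromosome's NCP values.

    Masked (NaN) bins contribute no emission evidence and are bridged by
    the transition structure.  Ties in the dynamic program break toward
    the lower state index, so a value exactly equidistant between two
    state means resolves to the lower state.
    """
    params.validate()
    values = np.asarray(values, dtype=np.float64)
    if len(values) == 0:
        return np.empty(0, dtype=np.int8)
    logb = _log_emissions(values, params)
    loga = np.log(params.transition_matrix())
    delta = np.log(np.asarray(params.initial)) + logb[0]
    n_states = len(params.emission_means)
    back = np.empty((len(values), n_states), dtype=np.int8)
    # exact ties occur (e.g. symmetric routes across masked stretches); a
    # small tolerance keeps the lower-state tie-break robust to float noise
    tie_eps = 1e-9
    for t in range(1, len(values)):
        cand = delta[:, None] + loga  # (from, to)
        best = cand.max(axis=0)
        back[t] = np.argmax(cand >= best - tie_eps, axis=0)  # lowest predecessor
        delta = cand[back[t], np.arange(n_states)] + logb[t]
    path = np.empty(len(values), dtype=np.int8)
    path[-1] = int(np.argmax(delta >= delta.max() - tie_eps))
    for t in range(len(values) - 1, 0, -1):
        path[t - 1] = back[t, path[t]]
    return path


def segments(
    states: np.ndarray,
    ncp_values: np.ndarray,
    chrom: str,
    bin_size: int = 1000,
) -> list[CopyNumberSegment]:
    """Collapse a per-bin state path into maximal constant-state segments."""
    states = np.asarray(states)
    if len(states) == 0:
        return []
    boundaries = np.nonzero(np.diff(states))[0] + 1
    starts = np.concatenate([[0], boundaries])
    ends = np.concatenate([boundaries, [len(states)]])
    out = []
    for s, e in zip(starts, ends):
        vals = np.asarray(ncp_values[s:e], dtype=np.float64)
        vals = vals[~np.isnan(vals)]
        med = float(np.median(vals)) if len(vals) else float("nan")
        out.append(
            CopyNumberSegment(
                chrom=chrom,
                start=int(s) * bin_size,
                end=int(e) * bin_size,
                state=int(states[s]),
                n_bins=int(e - s),
                median_ncp=med,
            )
        )
    return out


def call_segments(
    ncp: NormalizedCoverageProfile, params: HMMParams = HMMParams()
) -> list[CopyNumberSegment]:
    """Segment every chromosome of an NCP (chromosomes are independent)."""
    out: list[CopyNumberSegment] = []
    for chrom in ncp.chromosomes:
        values = ncp.values[chrom]
        if np.isnan(values).all():
            continue
        path = viterbi(values, params)
        out.extend(segments(path, values, chrom, ncp.bin_size))
    return out


def median_event_ncp(
    ncp: NormalizedCoverageProfile, chrom: str, start: int, end: int
) -> float:
    """Median NCP over the unmasked bins a genomic interval overlaps.

    The representative coverage level for evaluating an external CNV call
    against the profile; returns NaN when no unmasked bin is overlapped.
    Even bin counts use the mean-of-middle-two median convention.
    """
    if chrom not in ncp.values:
        return float("nan")
    b0 = max(start // ncp.bin_size, 0)
    b1 = min(-(-end // ncp.bin_size), len(ncp.values[chrom]))
    vals = ncp.values[chrom][b0:b1]
    vals = vals[~np.isnan(vals)]
    if len(vals) == 0:
        return float("nan")
    return float(np.median(vals))


def write_segments(segs: list[CopyNumberSegment], path: str) -> None:
    """BED5+: chrom start end state n_bins median_ncp [genotype_freq allele_freq]."""
    with open(path, "w") as fh:
        for s in segs:
            row = [s.chrom, s.start, s.end, s.state, s.n_bins, f"{s.median_ncp:.2f}"]
            if s.genotype_freq is not None or s.allele_freq is not None:
                row.append("." if s.genotype_freq is None else f"{s.genotype_freq:.4f}")
                row.append("." if s.allele_freq is None else f"{s.allele_freq:.4f}")
            fh.write("\t".join(map(str, row)) + "\n")


def read_segments(path: str) -> list[CopyNumberSegment]:
    frame = pd.read_csv(
        path, sep="\t", header=None, na_values=".",
        names=["chrom", "start", "end", "state", "n_bins", "median_ncp",
               "genotype_freq", "allele_freq"],
    )
    out = []
    for row in frame.itertuples(index=False):
        out.append(
            CopyNumberSegment(
                chrom=str(row.chrom), start=int(row.start), end=int(row.end),
                state=int(row.state), n_bins=int(row.n_bins),
                median_ncp=float(row.median_ncp),
                genotype_freq=None if pd.isna(row.genotype_freq) else float(row.genotype_freq),
                allele_freq=None if pd.isna(row.allele_freq) else float(row.allele_freq),
            )
        )
    return out
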