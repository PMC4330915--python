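"""Reference coverage profiles: cohort-level diploid coverage estimation.

For most 1-kb bins the median scaled coverage across a cohort is an
excellent estimate of the diploid coverage level.  Where a deletion or
duplication is common in the population the median is biased — in the
extreme, when hemizygotes or nullizygotes are the majority, the median
sits a full haploid unit (or more) below the diploid level.  The
estimator here recognizes such bins by their dispersion (MAD/median above
a trigger) and switches to a one-dimensional peak model: scaled coverage
values should cluster near integer multiples of a haploid level ``h``,
the most abundant non-zero cluster should be the diploid one, and the
implied genotype counts should not deviate wildly from Hardy–Weinberg
proportions.  A grid search over ``h`` maximizes a Gaussian-mixture
log-likelihood minus a chi-square-style HWE penalty; the reported diploid
level is ``2 h*``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .scaling import ScaledProfile

MAX_COHORT = 500  # genomes per profile; more are ignored with a note

_FLAG_CODES = {"median": 0, "peak-model": 1, "masked": 2}
_FLAG_NAMES = {v: k for k, v in _FLAG_CODES.items()}


class RCPError(ValueError):
    pass


@dataclass(frozen=True)
class RCPEstimatorParams:
    """Tunables of the diploid-level estimator.

    dispersion_trigger: MAD/median ratio above which the peak model
        replaces the plain median.
    copy_cap: maximum modeled copy number per genome.
    cluster_cv: assumed coefficient of variation of one copy-number
        cluster, relative to the bin's robust coverage scale (sets the
        Gaussian cluster width in the peak model).
    hwe_weight: multiplier on the Hardy–Weinberg chi-square penalty.
    grid_points: number of haploid-level candidates searched.
    min_support: minimum genomes with data for a bin to be estimated.
    """

    dispersion_trigger: float = 0.15
    copy_cap: int = 6
    cluster_cv: float = 0.12
    hwe_weight: float = 2.0
    grid_points: int = 200
    min_support: int = 20
    # secondary trigger: the MAD is blind to a minority cluster smaller than
    # half the cohort (e.g. hemizygotes at allele frequency 0.2, or the
    # non-modal genotypes of a common duplication), so the peak model also
    # engages when this fraction of genomes sits far from the median
    outlier_fraction_trigger: float = 0.20
    outlier_threshold: float = 0.20  # relative deviation from the median
    # prior weight (per genome) against solutions implying a deletion and a
    # duplication allele at the same locus; a single biallelic CNV cannot
    # produce genotypes on both sides of diploid
    mixed_weight: float = 2.0
    # prior weight (per genome) against "fixed duplication" readings in which
    # every genome sits above diploid: relabeling all copies upward is a
    # trivial re-scaling of the haploid level and is HWE-silent (allele
    # frequency 1), so the chi-square alone cannot reject it
    trivial_weight: float = 2.0

    def __post_init__(self) -> None:
        for name in ("dispersion_trigger", "cluster_cv", "hwe_weight", "grid_points",
                     "min_support"):
            if getattr(self, name) <= 0:
                raise RCPError(f"{name} must be positive")
        if self.copy_cap < 4:
            raise RCPError("copy_cap must be at least 4")


def bin_mad(values: np.ndarray) -> float:
    """Median absolute deviation from the median."""
    v = np.asarray(values, dtype=np.float64)
    v = v[~np.isnan(v)]
    if len(v) == 0:
        raise RCPError("bin_mad of empty input")
    return float(np.median(np.abs(v - np.median(v))))


def _hwe_chi2(counts: np.ndarray) -> np.ndarray:
    """HWE chi-square per grid row from per-copy-number genotype counts.

    ``counts`` is (grid, copy_cap+1).  A deletion component is scored over
    copies {0,1,2} and a duplication component over {2,3,>=4}; each uses
    the allele frequency implied by its own counts, so a bin with no
    variant alleles contributes zero.
    """
    g = counts.shape[0]
    chi2 = np.zeros(g)
    n0, n1, n2 = counts[:, 0], counts[:, 1], counts[:, 2]
    n_del = n0 + n1 + n2
    with np.errstate(invalid="ignore", divide="ignore"):
        q = np.where(n_del > 0, (n1 + 2.0 * n0) / np.maximum(2.0 * n_del, 1), 0.0)
        p = 1.0 - q
        for obs, expfrac in ((n2, p * p), (n1, 2 * p * q), (n0, q * q)):
            exp = n_del * expfrac
            chi2 += np.where(n_del > 0, (obs - exp) ** 2 / np.maximum(exp, 0.5), 0.0)
    n3 = counts[:, 3]
    n4 = counts[:, 4:].sum(axis=1)
    n_dup = n2 + n3 + n4
    with np.errstate(invalid="ignore", divide="ignore"):
        q = np.where(n_dup > 0, (n3 + 2.0 * n4) / np.maximum(2.0 * n_dup, 1), 0.0)
        p = 1.0 - q
        for obs, expfrac in ((n2, p * p), (n3, 2 * p * q), (n4, q * q)):
            exp = n_dup * expfrac
            chi2 += np.where(n_dup > 0, (obs - exp) ** 2 / np.maximum(exp, 0.5), 0.0)
    return chi2


def _score_grid(x: np.ndarray, h: np.ndarray, params: RCPEstimatorParams):
    """HWE-penalized mixture score for each haploid-level candidate.

    The cluster width is anchored to a robust scale of the data, not to
    the candidate haploid level: were it proportional to ``h``, every
    integer submultiple of the true level would fit the clusters equally
    well but with ever narrower (hence higher-likelihood) Gaussians, and
    the search would collapse to aliased solutions.  With a fixed width,
    aliases tie on likelihood and the Hardy–Weinberg penalty and modal-
    cluster re-anchoring decide between them.
    """
    pos = x[x > 0.05 * np.max(x)]
    scale_ref = float(np.median(pos)) if len(pos) else float(np.max(x))
    sd = params.cluster_cv * max(scale_ref, 1e-12)
    k = np.clip(np.round(x[None, :] / h[:, None]), 0, params.copy_cap)
    mu = k * h[:, None]
    resid = (x[None, :] - mu) / sd
    loglik = -0.5 * (resid ** 2).sum(axis=1) - len(x) * np.log(sd)
    counts = np.stack(
        [(k == c).sum(axis=1) for c in range(params.copy_cap + 1)], axis=1
    ).astype(np.float64)
    # single-CNV prior: genotypes below and above diploid at once are
    # implausible; penalize by the size of the minority side
    n_below = counts[:, :2].sum(axis=1)
    n_above = counts[:, 3:].sum(axis=1)
    all_above_diploid = counts[:, :3].sum(axis=1) == 0
    score = (
        loglik
        - params.hwe_weight * _hwe_chi2(counts)
        - params.mixed_weight * np.minimum(n_below, n_above)
        - params.trivial_weight * len(x) * all_above_diploid
    )
    return score, k


def estimate_diploid_level(
    values: np.ndarray, params: RCPEstimatorParams = RCPEstimatorParams()
) -> tuple[float, str]:
    """Estimate the diploid-equivalent coverage level of one 1-kb bin.

    Returns ``(level, flag)`` with flag "median", "peak-model" or
    "masked" (all-zero or unusable bins).
    """
    x = np.asarray(values, dtype=np.float64)
    x = x[~np.isnan(x)]
    if len(x) == 0 or np.max(x) <= 0:
        return float("nan"), "masked"
    med = float(np.median(x))
    mad = bin_mad(x)
    outlier_frac = float((np.abs(x - med) > params.outlier_threshold * med).mean())
    if (
        med > 0
        and mad / med <= params.dispersion_trigger
        and outlier_frac <= params.outlier_fraction_trigger
    ):
        return med, "median"

    vmax = float(np.max(x))
    h_grid = np.geomspace(vmax / (params.copy_cap + 0.49), vmax * 1.02,
                          params.grid_points)
    score, k = _score_grid(x, h_grid, params)
    best = int(np.argmax(score))
    h_star, k_star, score_star = h_grid[best], k[best], score[best]

    # the most abundant non-zero cluster should be the diploid one
    nonzero_counts = np.bincount(k_star.astype(int), minlength=params.copy_cap + 1)[1:]
    modal = int(np.argmax(nonzero_counts)) + 1
    if modal != 2 and nonzero_counts.sum() > 0:
        h_alt = np.array([h_star * modal / 2.0])
        score_alt, k_alt = _score_grid(x, h_alt, params)
        if score_alt[0] >= score_star:
            h_star, k_star, score_star = float(h_alt[0]), k_alt[0], float(score_alt[0])

    frac_below = float((k_star < 2).mean())
    frac_above = float((k_star > 2).mean())
    if frac_below > 0.02 and frac_above > 0.02:
        # bin implies both a deletion and a duplication allele; the peak
        # model is unidentifiable here, fall back to the median
        warnings.warn("bin implies both deletion and duplication; using median",
                      stacklevel=2)
        return med, "median"
    return 2.0 * float(h_star), "peak-model"


@dataclass
class ReferenceCoverageProfile:
    """Per-1-kb-bin diploid coverage level, MAD, support count and method flag."""

    bin_size: int
    level: dict[str, np.ndarray] = field(repr=False)
    mad: dict[str, np.ndarray] = field(repr=False)
    n: dict[str, np.ndarray] = field(repr=False)
    flag: dict[str, np.ndarray] = field(repr=False)

    @property
    def chromosomes(self) -> list[str]:
        return list(self.level)

    def to_tsv(self, path: str) -> None:
        with open(path, "w") as fh:
            for chrom, lv in self.level.items():
                for i in range(len(lv)):
                    s = i * self.bin_size
                    level = "." if np.isnan(lv[i]) else f"{lv[i]:.4f}"
                    fh.write(
                        f"{chrom}\t{s}\t{s + self.bin_size}\t{level}\t"
                        f"{self.mad[chrom][i]:.4f}\t{int(self.n[chrom][i])}\t"
                        f"{_FLAG_NAMES[int(self.flag[chrom][i])]}\n"
                    )

    @classmethod
    def from_tsv(cls, path: str) -> "ReferenceCoverageProfile":
        frame = pd.read_csv(
            path, sep="\t",
            names=["chrom", "start", "end", "level", "mad", "n", "flag"],
            na_values=".",
        )
        bin_size = int((frame["end"] - frame["start"]).iloc[0])
        level, mad, n, flag = {}, {}, {}, {}
        for chrom, grp in frame.groupby("chrom", sort=False):
            c = str(chrom)
            level[c] = grp["level"].to_numpy(dtype=np.float64)
            mad[c] = grp["mad"].fillna(0.0).to_numpy(dtype=np.float64)
            n[c] = grp["n"].fillna(0).to_numpy(dtype=np.int32)
            flag[c] = np.array(
                [_FLAG_CODES.get(str(f), 2) for f in grp["flag"]], dtype=np.int8
            )
        return cls(bin_size, level, mad, n, flag)


def build_rcp(
    profiles: list[ScaledProfile],
    params: RCPEstimatorParams = RCPEstimatorParams(),
) -> ReferenceCoverageProfile:
    """Estimate the reference coverage profile from a cohort of scaled profiles.

    At most 500 genomes are used.  Bins missing in more than half the
    cohort, or supported by fewer genomes than the (cohort-size-capped)
    minimum support, are masked.
    """
    if len(profiles) < 2:
        raise RCPError("building a reference profile requires at least 2 genomes")
    if len(profiles) > MAX_COHORT:
        warnings.warn(f"cohort capped at {MAX_COHORT} genomes", stacklevel=2)
        profiles = profiles[:MAX_COHORT]
    n_genomes = len(profiles)
    support = max(2, min(params.min_support, n_genomes))
    bin_size = profiles[0].bin_size
    chroms = profiles[0].chromosomes
    level, madd, nn, flag = {}, {}, {}, {}
    for chrom in chroms:
        matrix = np.stack([p.values[chrom] for p in profiles])  # (genomes, bins)
        n_bins = matrix.shape[1]
        n_ok = (~np.isnan(matrix)).sum(axis=0)
        lv = np.full(n_bins, np.nan)
        md = np.zeros(n_bins)
        fl = np.full(n_bins, _FLAG_CODES["masked"], dtype=np.int8)
        usable = (n_ok >= support) & (n_ok * 2 >= n_genomes)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            med = np.nanmedian(matrix, axis=0)
            mad = np.nanmedian(np.abs(matrix - med[None, :]), axis=0)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            outlier_frac = np.nanmean(
                np.abs(matrix - med[None, :]) > params.outlier_threshold * med[None, :],
                axis=0,
            )
        easy = (
            usable
            & (med > 0)
            & (mad / np.maximum(med, 1e-300) <= params.dispersion_trigger)
            & (outlier_frac <= params.outlier_fraction_trigger)
        )
        lv[easy] = med[easy]
        fl[easy] = _FLAG_CODES["median"]
        for i in np.nonzero(usable & ~easy)[0]:
            lv[i], name = estimate_diploid_level(matrix[:, i], params)
            fl[i] = _FLAG_CODES[name]
        md[usable] = mad[usable]
        level[chrom], madd[chrom] = lv, md
        nn[chrom] = n_ok.astype(np.int32)
        flag[chrom] = fl
    return ReferenceCoverageProfile(bin_size, level, madd, nn, flag)


def correlate_profiles(a: ReferenceCoverageProfile, b: ReferenceCoverageProfile) -> float:
    """Pearson correlation of diploid levels over jointly unmasked bins."""
    xs, ys = [], []
    for chrom in a.chromosomes:
        if chrom not in b.level:
            continue
        la, lb = a.level[chrom], b.level[chrom]
        m = min(len(la), len(lb))
        ok = ~np.isnan(la[:m]) & ~np.isnan(lb[:m])
        xs.append(la[:m][ok])
        ys.append(lb[:m][ok])
    x = np.concatenate(xs) if xs else np.empty(0)
    y = np.concatenate(ys) if ys else np.empty(0)
    if len(x) < 2:
        raise RCPError("profile correlation needs at least 2 jointly unmasked bins")
    return float(np.corrcoef(x, y)[0, 1])


def cumulative_curve(values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Sorted values with cumulative genome fractions (for uniformity plots)."""
    v = np.sort(np.asarray(values, dtype=np.float64))
    v = v[~np.isnan(v)]
    return v, np.arange(1, len(v) + 1) / len(v)


def uniformity_stats(profiles: list[ScaledProfile]) -> dict:
    """Coverage-uniformity QC: per-genome level curves and the cohort MAD curve.

    Returns cumulative value/fraction pairs suitable for plotting; no
    plotting is performed here.
    """
    if not profiles:
        raise RCPError("uniformity_stats requires at least one profile")
    per_genome = []
    for p in profiles:
        allv = np.concatenate([p.values[c] for c in p.chromosomes])
        per_genome.append(cumulative_curve(allv))
    matrix = np.vstack([
        np.concatenate([p.values[c] for c in p.chromosomes]) for p in profiles
    ])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        med = np.nanmedian(matrix, axis=0)
        mad = np.nanmedian(np.abs(matrix - med[None, :]), axis=0)
    return {"per_genome_level": per_genome, "per_bin_mad": cumulative_curve(mad)}
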