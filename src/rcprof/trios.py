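"""Mendelian trio concordance of copy-number state tracks.

A child's copy state at a bin should be the sum of one transmitted
haplotype copy count from each parent.  Under the parsimonious haplotype
model, a parent in state ``s`` can transmit: 0 → {0}, 1 → {0,1},
2 → {1}, 3 → {1,2}, 4 → {2,3} copies (state 2 is assumed 1+1, state 3
is 1+2, and state 4 — "four or more" — transmits 2 or 3).  The loose
concordance metric is the fraction of analyzed bins where the child's
state lies in the expected set; the strict metric restricts the
denominator to bins where not all three members are diploid, removing
the trivially concordant bulk of the genome.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

MISSING_STATE = -1
DEFAULT_MASK_THRESHOLD = 100  # trios
SEX_MITO_CHROMS = frozenset({"X", "Y", "M", "MT", "chrX", "chrY", "chrM", "chrMT"})

# copies a parent in each state can transmit on one haplotype
TRANSMISSIBLE = {0: (0,), 1: (0, 1), 2: (1,), 3: (1, 2), 4: (2, 3)}


class TrioError(ValueError):
    pass


def expected_child_states(father_state: int, mother_state: int) -> frozenset[int]:
    """States consistent with Mendelian transmission from the parents.

    Pairwise sums of transmissible haplotype copies, capped at state 4.
    Symmetric in its arguments.
    """
    for s in (father_state, mother_state):
        if s not in TRANSMISSIBLE:
            raise TrioError(f"invalid copy state: {s}")
    return frozenset(
        min(a + b, 4)
        for a, b in product(TRANSMISSIBLE[father_state], TRANSMISSIBLE[mother_state])
    )


_EXPECTED_TABLE = {
    (f, m): expected_child_states(f, m) for f in range(5) for m in range(5)
}


@dataclass(frozen=True)
class TrioResult:
    """Concordance summary for one father-mother-child trio."""

    loose_concordance: float  # NaN when no bins analyzed
    strict_concordance: float  # NaN when every analyzed bin is all-diploid
    analyzed_span: int  # bases
    discordant_span: int  # bases


@dataclass
class DiscordanceMask:
    """Bins recurrently discordant across many trios, excluded from scoring."""

    bin_size: int
    threshold: int
    counts: dict[str, np.ndarray] = field(repr=False)  # per-bin trio-discordance count

    def masked(self, chrom: str) -> np.ndarray:
        return self.counts[chrom] >= self.threshold

    def segments(self) -> list[tuple[str, int, int]]:
        """Masked bins merged into maximal (chrom, start, end) segments."""
        out = []
        for chrom, counts in self.counts.items():
            m = counts >= self.threshold
            if not m.any():
                continue
            edges = np.nonzero(np.diff(m.astype(np.int8)))[0] + 1
            starts = np.concatenate([[0], edges])
            ends = np.concatenate([edges, [len(m)]])
            for s, e in zip(starts, ends):
                if m[s]:
                    out.append((chrom, int(s) * self.bin_size, int(e) * self.bin_size))
        return out

    def to_bed(self, path: str) -> None:
        with open(path, "w") as fh:
            for chrom, start, end in self.segments():
                fh.write(f"{chrom}\t{start}\t{end}\n")


StateTracks = Mapping[str, np.ndarray]  # chrom -> per-bin states


def _analyzable(
    chrom: str,
    n_bins: int,
    gap_bins: Mapping[str, np.ndarray] | None,
    mask: DiscordanceMask | None,
    excluded_chroms: frozenset[str],
) -> np.ndarray | None:
    if chrom in excluded_chroms:
        return None
    keep = np.ones(n_bins, dtype=bool)
    if gap_bins is not None and chrom in gap_bins:
        keep &= ~np.asarray(gap_bins[chrom][:n_bins], dtype=bool)
    if mask is not None and chrom in mask.counts:
        keep &= ~mask.masked(chrom)[:n_bins]
    return keep


def discordant_bins(
    child: StateTracks,
    father: StateTracks,
    mother: StateTracks,
    expected_table: Mapping[tuple[int, int], frozenset[int]] | None = None,
) -> dict[str, np.ndarray]:
    """Boolean per-bin discordance (bins with any missing state are concordant).

    ``expected_table`` replaces the built-in transmission model with a
    custom ``(father_state, mother_state) -> expected child states`` map.
    """
    table = _EXPECTED_TABLE if expected_table is None else expected_table
    out = {}
    for chrom in child:
        c = np.asarray(child[chrom])
        f = np.asarray(father[chrom])
        m = np.asarray(mother[chrom])
        disc = np.zeros(len(c), dtype=bool)
        observed = (c != MISSING_STATE) & (f != MISSING_STATE) & (m != MISSING_STATE)
        for (fs, ms), expected in table.items():
            sel = observed & (f == fs) & (m == ms)
            if sel.any():
                ok = np.isin(c[sel], list(expected))
                disc[np.nonzero(sel)[0][~ok]] = True
        out[chrom] = disc
    return out


def trio_concordance(
    child: StateTracks,
    father: StateTracks,
    mother: StateTracks,
    gap_bins: Mapping[str, np.ndarray] | None = None,
    mask: DiscordanceMask | None = None,
    bin_size: int = 1000,
    excluded_chroms: frozenset[str] = SEX_MITO_CHROMS,
    expected_table: Mapping[tuple[int, int], frozenset[int]] | None = None,
) -> TrioResult:
    """Loose and strict Mendelian concordance over all analyzable bins.

    Excludes sex/mitochondrial chromosomes, reference-gap bins and
    recurrently discordant (masked) bins.  Bins where any member's state
    is missing never count as discordant.
    """
    disc_all = discordant_bins(child, father, mother, expected_table)
    n_analyzed = n_disc = n_strict = n_strict_disc = 0
    for chrom in child:
        keep = _analyzable(chrom, len(child[chrom]), gap_bins, mask, excluded_chroms)
        if keep is None:
            continue
        c = np.asarray(child[chrom])[: len(keep)]
        f = np.asarray(father[chrom])[: len(keep)]
        m = np.asarray(mother[chrom])[: len(keep)]
        disc = disc_all[chrom][: len(keep)] & keep
        all_diploid = (c == 2) & (f == 2) & (m == 2)
        n_analyzed += int(keep.sum())
        n_disc += int(disc.sum())
        strict = keep & ~all_diploid
        n_strict += int(strict.sum())
        n_strict_disc += int((disc & strict).sum())
    loose = 1.0 - n_disc / n_analyzed if n_analyzed else float("nan")
    strict_c = 1.0 - n_strict_disc / n_strict if n_strict else float("nan")
    return TrioResult(
        loose_concordance=loose,
        strict_concordance=strict_c,
        analyzed_span=n_analyzed * bin_size,
        discordant_span=n_disc * bin_size,
    )


def recurrent_discordance_mask(
    per_trio_discordance: Sequence[Mapping[str, np.ndarray]],
    threshold: int = DEFAULT_MASK_THRESHOLD,
    bin_size: int = 1000,
) -> DiscordanceMask:
    """Mask bins discordant in at least ``threshold`` trios.

    Such recurrently discordant segments behave as systematic artifacts
    (e.g. reference-sequence compressions) rather than inheritance errors.
    """
    if not per_trio_discordance:
        raise TrioError("need at least one trio")
    counts: dict[str, np.ndarray] = {}
    for disc in per_trio_discordance:
        for chrom, bins in disc.items():
            arr = np.asarray(bins, dtype=np.int32)
            if chrom not in counts:
                counts[chrom] = np.zeros(len(arr), dtype=np.int32)
            counts[chrom][: len(arr)] += arr
    return DiscordanceMask(bin_size=bin_size, threshold=threshold, counts=counts)


@dataclass(frozen=True)
class Family:
    child: str
    father: str
    mother: str
    family_id: str = "."


def read_pedigree(path: str) -> list[Family]:
    """TSV pedigree: ``family child father mother`` (family column optional)."""
    frame = pd.read_csv(path, sep="\t", header=None, dtype=str, comment="#")
    if frame.shape[1] >= 4:
        return [Family(r[1], r[2], r[3], r[0]) for r in frame.itertuples(index=False)]
    return [Family(r[0], r[1], r[2]) for r in frame.itertuples(index=False)]


def shuffle_trios(families: Sequence[Family], seed: int) -> list[Family]:
    """Re-pair each child with random non-parent substitutes.

    Fathers are drawn from the cohort's fathers and mothers from its
    mothers, never the child's own; deterministic under ``seed``.
    """
    if len(families) < 2:
        raise TrioError("shuffling requires at least 2 families")
    rng = np.random.default_rng(seed)
    fathers = [f.father for f in families]
    mothers = [f.mother for f in families]
    if len(set(fathers)) < 2 or len(set(mothers)) < 2:
        raise TrioError("cohort too small to avoid true parents")
    out = []
    for fam in families:
        other_f = [p for p in fathers if p != fam.father]
        other_m = [p for p in mothers if p != fam.mother]
        out.append(
            Family(
                child=fam.child,
                father=other_f[int(rng.integers(len(other_f)))],
                mother=other_m[int(rng.integers(len(other_m)))],
                family_id=fam.family_id,
            )
        )
    return out
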