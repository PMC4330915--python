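"""Population-level annotation of copy-number segments.

Segments called in one genome are annotated against a reference panel of
unrelated ("founder") genomes whose per-bin copy states are known:
genotype frequency (how often the panel shows the same state), allele
frequency (integrating copy observations over the panel), recurrent
junction clustering, and the downstream rare-deletion / gene-impact
reports.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .segment import CopyNumberSegment

JUNCTION_CLUSTER_CUTOFF = 400  # bp
RARE_DELETION_MIN_LENGTH = 3000  # bp
RARE_DELETION_MAX_FREQ = 0.01
NCP_DELETION_CUTOFF = 75.0  # percent of diploid
JUNCTION_FREQ_FILTER = 0.1

MISSING_STATE = -1


class PanelError(ValueError):
    pass


@dataclass
class PanelStates:
    """Per-individual per-1-kb-bin copy states (0-4, -1 missing), shared binning."""

    bin_size: int
    individuals: list[str]
    states: dict[str, np.ndarray] = field(repr=False)  # chrom -> (individuals, bins)

    @property
    def n_individuals(self) -> int:
        return len(self.individuals)

    @classmethod
    def from_tracks(
        cls, tracks: dict[str, dict[str, np.ndarray]], bin_size: int = 1000
    ) -> "PanelStates":
        """Build from ``{individual: {chrom: per-bin states}}``."""
        individuals = list(tracks)
        if not individuals:
            raise PanelError("empty panel")
        chroms = list(tracks[individuals[0]])
        states = {}
        for chrom in chroms:
            states[chrom] = np.stack(
                [np.asarray(tracks[ind][chrom], dtype=np.int8) for ind in individuals]
            )
        return cls(bin_size, individuals, states)


def write_state_track(states: dict[str, np.ndarray], path: str, bin_size: int = 1000) -> None:
    """Per-bin copy states as BED-like runs: ``chrom start end state``."""
    with open(path, "w") as fh:
        for chrom, arr in states.items():
            arr = np.asarray(arr)
            edges = np.nonzero(np.diff(arr))[0] + 1
            starts = np.concatenate([[0], edges])
            ends = np.concatenate([edges, [len(arr)]])
            for s, e in zip(starts, ends):
                fh.write(f"{chrom}\t{s * bin_size}\t{e * bin_size}\t{int(arr[s])}\n")


def read_state_track(path: str, bin_size: int = 1000) -> dict[str, np.ndarray]:
    frame = pd.read_csv(path, sep="\t", names=["chrom", "start", "end", "state"])
    out: dict[str, np.ndarray] = {}
    for chrom, grp in frame.groupby("chrom", sort=False):
        n_bins = int(grp["end"].max()) // bin_size
        arr = np.full(n_bins, MISSING_STATE, dtype=np.int8)
        for row in grp.itertuples(index=False):
            arr[int(row.start) // bin_size : int(row.end) // bin_size] = int(row.state)
        out[str(chrom)] = arr
    return out


def read_panel_manifest(path: str, bin_size: int = 1000) -> PanelStates:
    """Manifest TSV ``individual<TAB>state-track-path`` (paths relative to it)."""
    import os

    base = os.path.dirname(os.path.abspath(path))
    tracks = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            ind, rel = line.rstrip("\n").split("\t")[:2]
            track_path = rel if os.path.isabs(rel) else os.path.join(base, rel)
            tracks[ind] = read_state_track(track_path, bin_size)
    return PanelStates.from_tracks(tracks, bin_size)


def _segment_bins(segment: CopyNumberSegment, panel: PanelStates) -> np.ndarray | None:
    if segment.chrom not in panel.states:
        return None
    b0 = segment.start // panel.bin_size
    b1 = -(-segment.end // panel.bin_size)
    block = panel.states[segment.chrom][:, b0:b1]
    return block if block.shape[1] else None


def genotype_frequency(segment: CopyNumberSegment, panel: PanelStates) -> float:
    """Fraction of panel individuals sharing the segment's copy state.

    Computed per overlapped bin and summarized as the median matching
    count over bins, divided by the panel size.
    """
    block = _segment_bins(segment, panel)
    if block is None:
        return float("nan")
    counts = (block == segment.state).sum(axis=0)
    return float(np.median(counts)) / panel.n_individuals


def allele_frequency(segment: CopyNumberSegment, panel: PanelStates) -> float:
    """Deletion or duplication allele frequency implied by the panel states.

    For a deletion segment (state < 2) each panel state ``s`` contributes
    ``max(2 - s, 0)`` deletion alleles; for a duplication segment each
    contributes ``max(min(s, 4) - 2, 0)`` extra-copy alleles (state 4
    counted as exactly four copies).  Per-bin frequencies are summarized
    by their median.  Diploid segments have no variant allele: NaN.
    """
    if segment.state == 2:
        return float("nan")
    block = _segment_bins(segment, panel)
    if block is None:
        return float("nan")
    observed = np.where(block == MISSING_STATE, 2, block)  # missing treated as diploid
    if segment.state < 2:
        alleles = np.maximum(2 - observed, 0)
    else:
        alleles = np.maximum(np.minimum(observed, 4) - 2, 0)
    per_bin = alleles.sum(axis=0) / (2.0 * panel.n_individuals)
    return float(np.median(per_bin))


def annotate_segments(
    segs: Sequence[CopyNumberSegment], panel: PanelStates
) -> list[CopyNumberSegment]:
    """Attach genotype and allele frequencies to every non-diploid segment."""
    out = []
    for s in segs:
        gf = genotype_frequency(s, panel)
        af = allele_frequency(s, panel)
        out.append(
            CopyNumberSegment(
                chrom=s.chrom, start=s.start, end=s.end, state=s.state,
                n_bins=s.n_bins, median_ncp=s.median_ncp,
                genotype_freq=None if np.isnan(gf) else gf,
                allele_freq=None if np.isnan(af) else af,
            )
        )
    return out


@dataclass(frozen=True)
class JunctionCluster:
    """A recurring structural-variant junction range across assemblies."""

    chrom: str
    start: int
    end: int
    n_members: int
    frequency: float  # fraction of assemblies with a junction in range


def cluster_junctions(
    junctions: Iterable[tuple[str, str, int]],
    n_assemblies: int,
    cutoff: int = JUNCTION_CLUSTER_CUTOFF,
) -> list[JunctionCluster]:
    """Single-linkage clustering of ``(assembly_id, chrom, pos)`` junctions.

    Consecutive sorted junctions at most ``cutoff`` bp apart chain into one
    cluster; the cluster frequency counts each assembly at most once.
    """
    per_chrom: dict[str, list[tuple[int, str]]] = defaultdict(list)
    for assembly, chrom, pos in junctions:
        per_chrom[chrom].append((int(pos), assembly))
    clusters = []
    for chrom in sorted(per_chrom):
        items = sorted(per_chrom[chrom])
        run: list[tuple[int, str]] = []
        for item in items:
            if run and item[0] - run[-1][0] > cutoff:
                clusters.append(_make_cluster(chrom, run, n_assemblies))
                run = []
            run.append(item)
        if run:
            clusters.append(_make_cluster(chrom, run, n_assemblies))
    return clusters


def _make_cluster(chrom: str, run: list[tuple[int, str]], n_assemblies: int) -> JunctionCluster:
    assemblies = {a for _, a in run}
    return JunctionCluster(
        chrom=chrom,
        start=run[0][0],
        end=run[-1][0],
        n_members=len(run),
        frequency=len(assemblies) / n_assemblies,
    )


def filter_rare_deletions(
    segs: Sequence[CopyNumberSegment],
    min_length: int = RARE_DELETION_MIN_LENGTH,
    max_freq: float = RARE_DELETION_MAX_FREQ,
) -> list[CopyNumberSegment]:
    """Keep hemizygous/nullizygous segments that are long and rare.

    A segment passes when its state is 0 or 1, its span is at least
    ``min_length`` and its annotated genotype frequency is below
    ``max_freq``.
    """
    out = []
    for s in segs:
        if s.state not in (0, 1):
            continue
        if s.end - s.start < min_length:
            continue
        if s.genotype_freq is None or s.genotype_freq >= max_freq:
            continue
        out.append(s)
    return out


def read_exons(path: str) -> pd.DataFrame:
    """Exon intervals from a BED ('chrom start end gene') or GTF file."""
    if path.endswith((".gtf", ".gff", ".gff3")):
        rows = []
        with open(path) as fh:
            for line in fh:
                if line.startswith("#"):
                    continue
                f = line.rstrip("\n").split("\t")
                if len(f) < 9 or f[2] != "exon":
                    continue
                gene = "."
                for part in f[8].split(";"):
                    part = part.strip()
                    if part.startswith(("gene_id", "gene_name")):
                        gene = part.split(" ", 1)[1].strip('" ')
                rows.append((f[0], int(f[3]) - 1, int(f[4]), gene))
        return pd.DataFrame(rows, columns=["chrom", "start", "end", "gene"])
    return pd.read_csv(path, sep="\t", names=["chrom", "start", "end", "gene"],
                       usecols=[0, 1, 2, 3])


def gene_impact(
    rare_deletions: Sequence[CopyNumberSegment],
    exons: pd.DataFrame,
    bin_size: int = 1000,
) -> pd.DataFrame:
    """Genes affected (hemizygous exon) or knocked out (nullizygous exon).

    The first and last bin of each deletion are trimmed before overlap, so
    an exon must fall inside the deletion's interior to count; deletions of
    two bins or fewer trim to nothing.  Returns one row per gene with
    boolean ``affected`` and ``knocked_out`` columns.
    """
    status: dict[str, dict[str, bool]] = defaultdict(
        lambda: {"affected": False, "knocked_out": False}
    )
    for s in rare_deletions:
        t_start = s.start + bin_size
        t_end = s.end - bin_size
        if t_end <= t_start:
            continue
        hit = exons[
            (exons["chrom"] == s.chrom)
            & (exons["start"] < t_end)
            & (exons["end"] > t_start)
        ]
        for gene in hit["gene"].unique():
            if s.state == 1:
                status[gene]["affected"] = True
            elif s.state == 0:
                status[gene]["knocked_out"] = True
    if not status:
        return pd.DataFrame(columns=["gene", "affected", "knocked_out"])
    return pd.DataFrame(
        [(g, v["affected"], v["knocked_out"]) for g, v in sorted(status.items())],
        columns=["gene", "affected", "knocked_out"],
    )
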