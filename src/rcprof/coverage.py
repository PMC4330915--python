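"""Condensed depth-of-coverage tracks.

Per-base sequencing depth is stored as one byte per non-overlapping 20-bp
window.  The byte encoding has three regimes: mean window coverage up to
200x is stored unmodified; coverage between 200x and 2700x is compressed as
``int(sqrt(c - 200) + 200)``; coverage of 2700x and above is recorded at
full resolution in an "overflow" sidecar, with the window byte set to a
sentinel (255).  This keeps a whole-genome coverage trace at roughly 1/20th
of a byte per base while remaining nearly lossless where copy-number signal
lives (the diploid regime is far below 200x for typical 40x genomes).
"""

from __future__ import annotations

import io
import math
import struct
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

WINDOW_SIZE = 20
IDENTITY_LIMIT = 200
OVERFLOW_LIMIT = 2700
OVERFLOW_SENTINEL = 255
# bytes 251-254 are reserved; the encoder never produces them
_MAX_REGULAR_BYTE = 250

_MAGIC = b"RCPC"
_VERSION = 1


class CoverageError(ValueError):
    """Invalid coverage value or malformed condensed data."""


def encode_value(mean_coverage: float) -> tuple[int, bool]:
    """Encode one window's mean coverage as ``(byte, is_overflow)``.

    Values below the identity limit are rounded (half-up) and stored
    unchanged; the square-root regime compresses 200-2700x into bytes
    201-249; anything >= 2700x overflows to the sentinel byte.
    """
    if mean_coverage < 0 or not math.isfinite(mean_coverage):
        raise CoverageError(f"coverage must be finite and non-negative, got {mean_coverage}")
    if mean_coverage >= OVERFLOW_LIMIT:
        return OVERFLOW_SENTINEL, True
    if mean_coverage <= IDENTITY_LIMIT:
        return int(math.floor(mean_coverage + 0.5)), False
    return int(math.sqrt(mean_coverage - IDENTITY_LIMIT) + IDENTITY_LIMIT), False


def decode_value(byte: int, overflow_value: float | None = None) -> float:
    """Invert :func:`encode_value` to an approximate mean coverage.

    Identity-regime bytes decode exactly.  Square-root-regime bytes decode
    to the midpoint of their integer preimage interval, which minimises the
    worst-case absolute error.  The sentinel requires the overflow record's
    full-resolution value.
    """
    if not 0 <= byte <= 255:
        raise CoverageError(f"byte out of range: {byte}")
    if byte == OVERFLOW_SENTINEL:
        if overflow_value is None:
            raise CoverageError("sentinel byte with no overflow record")
        return float(overflow_value)
    if byte > _MAX_REGULAR_BYTE:
        raise CoverageError(f"reserved byte value: {byte}")
    if byte <= IDENTITY_LIMIT:
        return float(byte)
    lo = (byte - IDENTITY_LIMIT) ** 2 + IDENTITY_LIMIT
    hi = (byte - IDENTITY_LIMIT - 1 + 2) ** 2 + IDENTITY_LIMIT - 1  # (b-199)^2 + 199
    return (lo + hi) / 2.0


def _decode_table() -> np.ndarray:
    table = np.empty(256, dtype=np.float64)
    for b in range(251):
        table[b] = decode_value(b)
    table[251:] = np.nan  # reserved + sentinel; sentinel patched via sidecar
    return table


_DECODE_LUT = _decode_table()


@dataclass(frozen=True)
class OverflowRecord:
    """Full-resolution mean coverage for a window beyond the byte range."""

    chromosome: str
    window_start: int  # 0-based base offset, multiple of the window size
    value: float

    def __post_init__(self) -> None:
        if self.value < OVERFLOW_LIMIT:
            raise CoverageError(
                f"overflow record value {self.value} below limit {OVERFLOW_LIMIT}"
            )
        if self.window_start % WINDOW_SIZE:
            raise CoverageError("window_start must be a multiple of the window size")


@dataclass
class CondensedTrack:
    """One byte per 20-bp window per chromosome, plus an overflow sidecar."""

    chrom_lengths: dict[str, int]
    data: dict[str, np.ndarray] = field(repr=False)
    overflow: dict[tuple[str, int], float] = field(default_factory=dict)
    window_size: int = WINDOW_SIZE

    def __post_init__(self) -> None:
        for name, length in self.chrom_lengths.items():
            n = -(-length // self.window_size)
            if len(self.data[name]) != n:
                raise CoverageError(
                    f"{name}: expected {n} window bytes, got {len(self.data[name])}"
                )
        for (chrom, start), _ in self.overflow.items():
            if start // self.window_size >= len(self.data[chrom]):
                raise CoverageError(f"overflow window beyond {chrom}")

    @property
    def chromosomes(self) -> list[str]:
        return list(self.chrom_lengths)

    def n_windows(self, chrom: str) -> int:
        return len(self.data[chrom])

    def decoded(self, chrom: str) -> np.ndarray:
        """All window values of a chromosome, overflow values substituted."""
        if chrom not in self.data:
            raise KeyError(f"unknown chromosome: {chrom}")
        values = _DECODE_LUT[self.data[chrom]]
        for (c, start), v in self.overflow.items():
            if c == chrom:
                values[start // self.window_size] = v
        return values

    def query(self, chrom: str, start: int, end: int) -> np.ndarray:
        """Decoded values for windows overlapping [start, end), 0-based half-open.

        Random access: only the touched byte range is decoded.
        """
        if chrom not in self.data:
            raise KeyError(f"unknown chromosome: {chrom}")
        if start < 0 or end > self.chrom_lengths[chrom]:
            raise CoverageError(f"region {chrom}:{start}-{end} out of bounds")
        if end <= start:
            return np.empty(0, dtype=np.float64)
        w0 = start // self.window_size
        w1 = -(-end // self.window_size)
        values = _DECODE_LUT[self.data[chrom][w0:w1]]
        if np.isnan(values).any():
            for i in np.nonzero(np.isnan(values))[0]:
                key = (chrom, (w0 + int(i)) * self.window_size)
                if key not in self.overflow:
                    raise CoverageError(f"sentinel window without overflow record at {key}")
                values[i] = self.overflow[key]
        return values

    # ---------------------------------------------------------------- IO

    def to_file(self, path: str) -> None:
        """Write the binary payload; overflow sidecar goes to ``path + '.overflow'``."""
        with open(path, "wb") as fh:
            fh.write(_MAGIC)
            fh.write(struct.pack("<HHI", _VERSION, self.window_size, len(self.chrom_lengths)))
            for name, length in self.chrom_lengths.items():
                raw = name.encode()
                fh.write(struct.pack("<H", len(raw)))
                fh.write(raw)
                fh.write(struct.pack("<Q", length))
            for name in self.chrom_lengths:
                fh.write(self.data[name].tobytes())
        with open(path + ".overflow", "w") as fh:
            for (chrom, start), value in sorted(self.overflow.items()):
                fh.write(f"{chrom}\t{start}\t{value:.6g}\n")

    @classmethod
    def from_file(cls, path: str) -> "CondensedTrack":
        with open(path, "rb") as fh:
            if fh.read(4) != _MAGIC:
                raise CoverageError(f"{path}: not a condensed coverage track")
            version, window, n_chroms = struct.unpack("<HHI", fh.read(8))
            if version != _VERSION:
                raise CoverageError(f"unsupported track version {version}")
            lengths: dict[str, int] = {}
            for _ in range(n_chroms):
                (name_len,) = struct.unpack("<H", fh.read(2))
                name = fh.read(name_len).decode()
                (lengths[name],) = struct.unpack("<Q", fh.read(8))
            data = {}
            for name, length in lengths.items():
                n = -(-length // window)
                data[name] = np.frombuffer(fh.read(n), dtype=np.uint8).copy()
        overflow: dict[tuple[str, int], float] = {}
        try:
            with open(path + ".overflow") as fh:
                for line in fh:
                    chrom, start, value = line.rstrip("\n").split("\t")
                    overflow[(chrom, int(start))] = float(value)
        except FileNotFoundError:
            pass
        return cls(chrom_lengths=lengths, data=data, overflow=overflow, window_size=window)


def _window_means(depth: np.ndarray, window: int) -> np.ndarray:
    """Mean depth per window; a terminal partial window averages its own bases."""
    n = len(depth)
    edges = np.arange(0, n, window)
    sums = np.add.reduceat(depth.astype(np.float64), edges)
    counts = np.minimum(edges + window, n) - edges
    return sums / counts


def condense_array(
    depths: Mapping[str, np.ndarray],
    chrom_lengths: Mapping[str, int] | None = None,
    window_size: int = WINDOW_SIZE,
) -> CondensedTrack:
    """Condense per-chromosome per-base depth arrays (0-based) into a track."""
    lengths = dict(chrom_lengths) if chrom_lengths else {c: len(a) for c, a in depths.items()}
    data: dict[str, np.ndarray] = {}
    overflow: dict[tuple[str, int], float] = {}
    for chrom, length in lengths.items():
        depth = np.asarray(depths[chrom], dtype=np.float64)
        if len(depth) != length:
            raise CoverageError(f"{chrom}: depth array length {len(depth)} != {length}")
        if (depth < 0).any():
            raise CoverageError(f"{chrom}: negative depth")
        means = _window_means(depth, window_size)
        over = means >= OVERFLOW_LIMIT
        mid = (~over) & (means > IDENTITY_LIMIT)
        encoded = np.floor(means + 0.5)  # identity regime rounds half-up
        encoded[mid] = np.floor(np.sqrt(means[mid] - IDENTITY_LIMIT)) + IDENTITY_LIMIT
        encoded[over] = OVERFLOW_SENTINEL
        data[chrom] = encoded.astype(np.uint8)
        for idx in np.nonzero(over)[0]:
            overflow[(chrom, int(idx) * window_size)] = float(means[idx])
    return CondensedTrack(
        chrom_lengths=lengths, data=data, overflow=overflow, window_size=window_size
    )


def condense(
    depth_stream: Iterable[tuple[str, int, float]],
    chrom_lengths: Mapping[str, int],
    window_size: int = WINDOW_SIZE,
) -> CondensedTrack:
    """Condense a sorted per-base ``(chrom, 1-based pos, depth)`` stream.

    Positions absent from the stream count as depth zero.
    """
    arrays = {c: np.zeros(n, dtype=np.float64) for c, n in chrom_lengths.items()}
    last: dict[str, int] = {}
    for chrom, pos, depth in depth_stream:
        if chrom not in arrays:
            raise CoverageError(f"unknown chromosome in depth stream: {chrom}")
        if pos < 1 or pos > chrom_lengths[chrom]:
            raise CoverageError(f"position {chrom}:{pos} beyond chromosome length")
        if pos <= last.get(chrom, 0):
            raise CoverageError(f"depth stream not sorted at {chrom}:{pos}")
        last[chrom] = pos
        arrays[chrom][pos - 1] = depth
    return condense_array(arrays, chrom_lengths, window_size)


def read_depth_text(path: str) -> Iterator[tuple[str, int, float]]:
    """Stream a ``chrom<TAB>pos<TAB>depth`` file (e.g. samtools depth output)."""
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            chrom, pos, depth = line.split("\t")[:3]
            yield chrom, int(pos), float(depth)


def read_coverage_tsv(
    path: str,
    coverage_column: str,
    chrom_column: str = "chromosome",
    pos_column: str = "position",
) -> Iterator[tuple[str, int, float]]:
    """Stream a generic headered coverage report with a configurable depth column.

    Accepts integer or real-valued coverage columns.
    """
    frame = pd.read_csv(path, sep="\t")
    for col in (chrom_column, pos_column, coverage_column):
        if col not in frame.columns:
            raise CoverageError(f"{path}: missing column {col!r}")
    for chrom, pos, cov in zip(
        frame[chrom_column], frame[pos_column], frame[coverage_column]
    ):
        yield str(chrom), int(pos), float(cov)


def autocorr(values: Sequence[float], max_lag: int) -> np.ndarray:
    """Pearson autocorrelation at lags 0..max_lag (lag 0 is 1 by definition).

    Zero-variance (constant) series have undefined autocorrelation and
    return NaN at every lag, including lag 0.
    """
    x = np.asarray(values, dtype=np.float64)
    if len(x) <= max_lag:
        raise CoverageError("series must be longer than max_lag")
    out = np.full(max_lag + 1, np.nan)
    if np.ptp(x) == 0:
        return out
    out[0] = 1.0
    for k in range(1, max_lag + 1):
        a, b = x[:-k], x[k:]
        if np.ptp(a) == 0 or np.ptp(b) == 0:
            continue
        out[k] = np.corrcoef(a, b)[0, 1]
    return out
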