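"""Core genomic containers shared by all pipeline stages.

Coordinates are 0-based half-open throughout, as in BED. Interval sets are
thin wrappers around a pandas DataFrame so they read/write BED directly and
stay cheap to slice; contact matrices are dense symmetric numpy arrays (the
simulated genomes are small enough that sparsity buys nothing).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "PolyhubError",
    "PlacementError",
    "CalibrationError",
    "ConvergenceError",
    "GenomeModel",
    "GenomicInterval",
    "IntervalSet",
    "ContactMatrix",
    "read_bed",
]


class PolyhubError(Exception):
    """Base class for pipeline errors."""


class PlacementError(PolyhubError):
    """The genome cannot accommodate the requested interval placement."""


class CalibrationError(PolyhubError):
    """Spike-in calibration is undefined for the given samples."""


class ConvergenceError(PolyhubError):
    """Iterative procedure failed to converge; carries the last residual."""

    def __init__(self, message: str, residual: float):
        super().__init__(f"{message} (last residual {residual:.3g})")
        self.residual = residual


@dataclass(frozen=True)
class GenomeModel:
    """Chromosome names/lengths plus a fixed analysis bin size.

    Stands in for a real assembly: everything downstream only needs lengths
    and a contiguous bin index per chromosome.
    """

    chrom_sizes: Mapping[str, int]
    bin_size: int = 10_000

    def __post_init__(self) -> None:
        if self.bin_size <= 0:
            raise ValueError("bin_size must be positive")
        for name, length in self.chrom_sizes.items():
            if length <= 0:
                raise ValueError(f"chromosome {name!r} has non-positive length")

    @property
    def chroms(self) -> list[str]:
        return list(self.chrom_sizes)

    def length(self, chrom: str) -> int:
        return self.chrom_sizes[chrom]

    def n_bins(self, chrom: str) -> int:
        return -(-self.chrom_sizes[chrom] // self.bin_size)

    def bin_of(self, chrom: str, pos: int) -> int:
        if not 0 <= pos < self.chrom_sizes[chrom]:
            raise ValueError(f"position {pos} outside {chrom}")
        return pos // self.bin_size

    def total_length(self) -> int:
        return int(sum(self.chrom_sizes.values()))


@dataclass(frozen=True)
class GenomicInterval:
    """A 0-based half-open genomic span."""

    chrom: str
    start: int
    end: int
    name: str | None = None
    score: float | None = None
    strand: str | None = None

    def __post_init__(self) -> None:
        if not 0 <= self.start < self.end:
            raise ValueError(f"invalid interval {self.chrom}:{self.start}-{self.end}")
        if self.strand not in (None, "+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


_BED_COLS = ["chrom", "start", "end", "name", "score", "strand"]


class IntervalSet:
    """An ordered collection of genomic intervals backed by a DataFrame."""

    def __init__(self, df: pd.DataFrame):
        df = df.copy().reset_index(drop=True)
        for col in ("chrom", "start", "end"):
            if col not in df.columns:
                raise ValueError(f"interval table missing column {col!r}")
        for col in ("name", "score", "strand"):
            if col not in df.columns:
                df[col] = None
        df["start"] = df["start"].astype(np.int64)
        df["end"] = df["end"].astype(np.int64)
        if ((df["start"] < 0) | (df["start"] >= df["end"])).any():
            raise ValueError("intervals must satisfy 0 <= start < end")
        self.df = df[_BED_COLS]

    @classmethod
    def from_intervals(cls, intervals: Sequence[GenomicInterval]) -> "IntervalSet":
        rows = [
            (iv.chrom, iv.start, iv.end, iv.name, iv.score, iv.strand)
            for iv in intervals
        ]
        return cls(pd.DataFrame(rows, columns=_BED_COLS))

    def __len__(self) -> int:
        return len(self.df)

    def __iter__(self) -> Iterator[GenomicInterval]:
        for row in self.df.itertuples(index=False):
            yield GenomicInterval(
                row.chrom,
                int(row.start),
                int(row.end),
                None if pd.isna(row.name) else row.name,
                None if row.score is None or pd.isna(row.score) else float(row.score),
                None if row.strand is None or pd.isna(row.strand) else row.strand,
            )

    def __getitem__(self, i):
        if isinstance(i, slice):
            return list(self)[i]
        row = self.df.iloc[i]
        return GenomicInterval(
            row["chrom"],
            int(row["start"]),
            int(row["end"]),
            None if pd.isna(row["name"]) else row["name"],
            None if row["score"] is None or pd.isna(row["score"]) else float(row["score"]),
            None if row["strand"] is None or pd.isna(row["strand"]) else row["strand"],
        )

    def sorted(self) -> "IntervalSet":
        return IntervalSet(
            self.df.sort_values(["chrom", "start", "end"], kind="mergesort")
        )

    def subset(self, mask) -> "IntervalSet":
        return IntervalSet(self.df[mask])

    def validate_against(self, genome: GenomeModel) -> None:
        for chrom, grp in self.df.groupby("chrom"):
            if chrom not in genome.chrom_sizes:
                raise ValueError(f"unknown chromosome {chrom!r}")
            if (grp["end"] > genome.length(chrom)).any():
                raise ValueError(f"interval exceeds {chrom} length")

    def to_bed(self, path) -> None:
        out = self.df.copy()
        out["name"] = [n if n is not None and not pd.isna(n) else "." for n in out["name"]]
        out["score"] = [0 if s is None or pd.isna(s) else s for s in out["score"]]
        out["strand"] = [s if s is not None and not pd.isna(s) else "." for s in out["strand"]]
        out.to_csv(path, sep="\t", header=False, index=False, float_format="%.6g")

    @classmethod
    def from_bed(cls, path) -> "IntervalSet":
        return read_bed(path)


def read_bed(path) -> IntervalSet:
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    df = df.iloc[:, : len(_BED_COLS)]
    df.columns = _BED_COLS[: df.shape[1]]
    return IntervalSet(df)


@dataclass
class ContactMatrix:
    """Symmetric intra-chromosomal contact matrix at fixed resolution.

    ``counts`` holds raw or balanced values; ``weights`` the ICE bias vector
    when balanced; ``mask`` marks excluded (zero-coverage) bins.
    """

    chrom: str
    resolution: int
    counts: np.ndarray
    weights: np.ndarray | None = None
    mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        m = np.asarray(self.counts, dtype=float)
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise ValueError("contact matrix must be square")
        if not np.allclose(m, m.T):
            raise ValueError("contact matrix must be symmetric")
        if (m < 0).any():
            raise ValueError("contact matrix must be non-negative")
        self.counts = m
        if self.mask is None:
            self.mask = np.zeros(m.shape[0], dtype=bool)

    @property
    def n_bins(self) -> int:
        return self.counts.shape[0]

    def to_triplets(self, path) -> None:
        i, j = np.nonzero(np.triu(self.counts))
        pd.DataFrame(
            {"chrom": self.chrom, "bin_i": i, "bin_j": j, "count": self.counts[i, j]}
        ).to_csv(path, sep="\t", index=False, float_format="%.10g")

    @classmethod
    def from_triplets(cls, path, resolution: int, n_bins: int | None = None):
        df = pd.read_csv(path, sep="\t")
        chrom = str(df["chrom"].iloc[0]) if len(df) else "chr1"
        n = n_bins or int(max(df["bin_i"].max(), df["bin_j"].max())) + 1
        m = np.zeros((n, n))
        m[df["bin_i"], df["bin_j"]] = df["count"]
        m[df["bin_j"], df["bin_i"]] = df["count"]
        return cls(chrom, resolution, m)
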