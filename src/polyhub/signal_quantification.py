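"""Interval read-count annotation, heatmap/metaplot matrices and QC.

Coverage is a per-basepair (or per-bin) vector per chromosome. All window
arithmetic is 0-based half-open; anchor windows are centered on the interval
midpoint, or on the strand-aware start (TSS) when the anchor carries a
strand, with minus-strand rows reversed so every row reads 5'->3'.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .core import GenomeModel, IntervalSet

__all__ = [
    "Coverage",
    "SignalMatrix",
    "count_in_intervals",
    "build_signal_matrix",
    "sort_rows",
    "metaplot",
    "replicate_correlation",
]


@dataclass
class Coverage:
    """Per-chromosome coverage vectors at a fixed step (default per-bp)."""

    data: dict[str, np.ndarray]
    step: int = 1

    def __post_init__(self) -> None:
        if self.step < 1:
            raise ValueError("step must be >= 1")
        self.data = {c: np.asarray(v, dtype=float) for c, v in self.data.items()}

    @classmethod
    def from_bedgraph(cls, path, genome: GenomeModel) -> "Coverage":
        df = pd.read_csv(
            path, sep="\t", header=None, names=["chrom", "start", "end", "value"]
        )
        data = {c: np.zeros(genome.length(c)) for c in genome.chroms}
        for row in df.itertuples(index=False):
            data[row.chrom][row.start : row.end] += row.value
        return cls(data, step=1)

    def to_bedgraph(self, path) -> None:
        with open(path, "w") as fh:
            for chrom, vec in self.data.items():
                # run-length encode constant stretches
                edges = np.flatnonzero(np.diff(vec)) + 1
                starts = np.concatenate([[0], edges])
                ends = np.concatenate([edges, [len(vec)]])
                for s, e in zip(starts, ends):
                    if vec[s] != 0:
                        fh.write(
                            f"{chrom}\t{s * self.step}\t{e * self.step}\t{vec[s]:.10g}\n"
                        )

    def window_sum(self, chrom: str, start: int, end: int) -> float:
        """Sum of coverage over the half-open span [start, end)."""
        vec = self.data[chrom]
        if self.step == 1:
            return float(vec[start:end].sum())
        # binned coverage: fractional overlap weighting (density semantics)
        b0, b1 = start // self.step, -(-end // self.step)
        total = 0.0
        for b in range(b0, min(b1, len(vec))):
            lo = max(start, b * self.step)
            hi = min(end, (b + 1) * self.step)
            total += vec[b] * (hi - lo) / self.step
        return float(total)


@dataclass
class SignalMatrix:
    """Per-anchor binned signal density around a common reference point."""

    anchors: list[str]
    half_width: int
    bin_size: int
    matrix: np.ndarray
    row_order: np.ndarray = field(default=None)  # type: ignore[assignment]
    flagged: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        n_cols = 2 * self.half_width // self.bin_size
        if self.matrix.shape != (len(self.anchors), n_cols):
            raise ValueError(
                f"matrix shape {self.matrix.shape} != ({len(self.anchors)}, {n_cols})"
            )
        if self.row_order is None:
            self.row_order = np.arange(len(self.anchors))
        if self.flagged is None:
            self.flagged = np.zeros(len(self.anchors), dtype=bool)

    def row_sums(self) -> np.ndarray:
        return self.matrix.sum(axis=1)

    def to_tsv(self, path) -> None:
        pd.DataFrame(
            self.matrix[self.row_order],
            index=[self.anchors[i] for i in self.row_order],
        ).to_csv(path, sep="\t", float_format="%.10g")


def count_in_intervals(coverage: Coverage, intervals: IntervalSet) -> pd.Series:
    """Sum of coverage overlapping each half-open interval."""
    values, names = [], []
    for k, iv in enumerate(intervals):
        if iv.chrom not in coverage.data:
            raise ValueError(f"interval on unknown chromosome {iv.chrom!r}")
        n_pos = len(coverage.data[iv.chrom]) * coverage.step
        if iv.end > n_pos:
            raise ValueError(f"interval {iv.chrom}:{iv.start}-{iv.end} off chromosome")
        values.append(coverage.window_sum(iv.chrom, iv.start, iv.end))
        names.append(iv.name or f"iv{k}")
    return pd.Series(values, index=names, dtype=float)


def _reference_point(iv) -> int:
    if iv.strand == "+":
        return iv.start
    if iv.strand == "-":
        return iv.end
    return iv.midpoint


def build_signal_matrix(
    coverage: Coverage,
    anchors: IntervalSet,
    half_width: int = 2500,
    bin_size: int = 50,
) -> SignalMatrix:
    """Binned signal around each anchor's reference point.

    Stranded anchors are centered on the strand-aware start and minus-strand
    rows are reversed; unstranded anchors are centered on the midpoint.
    Windows running off the chromosome are zero-padded and flagged.
    """
    if half_width % bin_size != 0:
        raise ValueError("half_width must be a multiple of bin_size")
    if coverage.step != 1:
        raise ValueError("signal matrices require per-bp coverage")
    n_bins = 2 * half_width // bin_size
    names, rows, flags = [], [], []
    for k, iv in enumerate(anchors):
        vec = coverage.data[iv.chrom]
        ref = _reference_point(iv)
        lo, hi = ref - half_width, ref + half_width
        row = np.zeros(2 * half_width)
        flagged = lo < 0 or hi > len(vec)
        src_lo, src_hi = max(lo, 0), min(hi, len(vec))
        if src_hi > src_lo:
            row[src_lo - lo : src_hi - lo] = vec[src_lo:src_hi]
        binned = row.reshape(n_bins, bin_size).sum(axis=1)
        if iv.strand == "-":
            binned = binned[::-1]
        names.append(iv.name or f"anchor{k}")
        rows.append(binned)
        flags.append(flagged)
    return SignalMatrix(
        anchors=names,
        half_width=half_width,
        bin_size=bin_size,
        matrix=np.array(rows).reshape(len(names), n_bins),
        flagged=np.array(flags, dtype=bool),
    )


def sort_rows(matrix: SignalMatrix, reference: SignalMatrix) -> SignalMatrix:
    """Order rows by decreasing reference row sum; ties break on anchor id."""
    if matrix.anchors != reference.anchors:
        raise ValueError("matrices must share the same anchors")
    sums = reference.row_sums()
    order = sorted(
        range(len(sums)), key=lambda i: (-sums[i], matrix.anchors[i])
    )
    return SignalMatrix(
        anchors=matrix.anchors,
        half_width=matrix.half_width,
        bin_size=matrix.bin_size,
        matrix=matrix.matrix,
        row_order=np.array(order),
        flagged=matrix.flagged,
    )


def metaplot(matrix: SignalMatrix) -> np.ndarray:
    """Column-wise mean profile of a signal matrix."""
    if matrix.matrix.shape[0] == 0:
        raise ValueError("metaplot of an empty matrix is undefined")
    return matrix.matrix.mean(axis=0)


def replicate_correlation(counts_a, counts_b) -> float:
    """Pearson correlation between replicate count vectors.

    Warns (without failing) when r <= 0.9, the conventional pooling QC bar.
    """
    a = np.asarray(counts_a, dtype=float)
    b = np.asarray(counts_b, dtype=float)
    if a.shape != b.shape or a.size < 3:
        raise ValueError("replicate vectors must have equal length >= 3")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ValueError("correlation undefined for zero-variance input")
    r = float(stats.pearsonr(a, b).statistic)
    if r <= 0.9:
        warnings.warn(
            f"replicate correlation r={r:.3f} <= 0.9; check before pooling",
            stacklevel=2,
        )
    return r
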