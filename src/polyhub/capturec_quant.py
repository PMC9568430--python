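"""Capture-C promoter-interaction quantification.

Works on per-bait restriction-fragment count tables that already carry an
interaction significance score per fragment (score calling itself is
upstream of this package; scores are inputs). Two steps:

1. depth normalization: every raw count is scaled by
   ``(1 / cov) * nprom * 100000`` where ``cov`` is the sample's total
   captured read count and ``nprom`` the number of baited promoters — so a
   sample's normalized counts always sum to ``nprom * 100000``;
2. promoter-interval statistics: a promoter "interacts" with an interval
   when at least one fragment overlapping the interval reaches the score
   cutoff (default >= 5); the reported value is then the mean normalized
   count (and mean score) over ALL interval-overlapping fragments.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import GenomicInterval, IntervalSet

__all__ = [
    "FragmentTable",
    "IntervalInteraction",
    "BoxStats",
    "normalize_table",
    "interval_interaction",
    "promoter_set_summary",
    "boxplot_stats",
]

_FRAG_COLS = ["bait", "chrom", "start", "end", "raw_count", "score"]


@dataclass
class FragmentTable:
    """Per-bait, per-fragment Capture-C counts and interaction scores."""

    df: pd.DataFrame
    nprom: int | None = None
    normalized: bool = False

    def __post_init__(self) -> None:
        df = self.df.copy().reset_index(drop=True)
        for col in _FRAG_COLS:
            if col not in df.columns:
                raise ValueError(f"fragment table missing column {col!r}")
        if (df["raw_count"] < 0).any():
            raise ValueError("raw counts must be non-negative")
        if "norm_count" not in df.columns:
            df["norm_count"] = np.nan
        self.df = df

    def __len__(self) -> int:
        return len(self.df)

    @property
    def total_count(self) -> float:
        return float(self.df["raw_count"].sum())

    def to_tsv(self, path) -> None:
        self.df.to_csv(path, sep="\t", index=False, float_format="%.10g")

    @classmethod
    def from_tsv(cls, path, **kwargs) -> "FragmentTable":
        return cls(pd.read_csv(path, sep="\t"), **kwargs)


@dataclass(frozen=True)
class IntervalInteraction:
    """Summary of one promoter-interval interaction."""

    promoter: str
    interval_name: str
    n_fragments: int
    mean_norm_count: float
    mean_score: float
    qualifies: bool


@dataclass(frozen=True)
class BoxStats:
    """Boxplot summary: quartiles, 1.5 x IQR whiskers and median notch."""

    n: int
    median: float
    q1: float
    q3: float
    whisker_lo: float
    whisker_hi: float
    notch: float

    @property
    def iqr(self) -> float:
        return self.q3 - self.q1


def normalize_table(table: FragmentTable, nprom: int) -> FragmentTable:
    """Scale every fragment count by (1/cov) * nprom * 100000.

    ``cov`` is the total captured read count of the sample, so the factor is
    invariant to uniform depth changes and the normalized counts sum to
    ``nprom * 100000`` exactly.
    """
    if nprom < 1:
        raise ValueError("nprom must be >= 1")
    cov = table.total_count
    if cov <= 0:
        raise ValueError("total captured read count is zero; cannot normalize")
    df = table.df.copy()
    df["norm_count"] = df["raw_count"] * (1.0 / cov) * nprom * 100000
    return FragmentTable(df, nprom=nprom, normalized=True)


def _overlap_mask(df: pd.DataFrame, interval: GenomicInterval) -> pd.Series:
    # any-basepair overlap, half-open arithmetic
    return (
        (df["chrom"] == interval.chrom)
        & (df["start"] < interval.end)
        & (df["end"] > interval.start)
    )


def interval_interaction(
    table: FragmentTable,
    promoter: str,
    interval: GenomicInterval,
    score_threshold: float = 5.0,
    with_reason: bool = False,
):
    """Promoter-interval interaction statistic, or None.

    A pair qualifies when any interval-overlapping fragment of the bait
    reaches the score threshold; the means then run over all overlapping
    fragments. Returns None when nothing overlaps or no fragment reaches the
    threshold (``with_reason=True`` additionally returns ``"no_fragments"``
    or ``"below_threshold"`` / ``"ok"``).
    """
    if not table.normalized:
        raise ValueError("table must be normalized before quantification")
    sub = table.df[table.df["bait"] == promoter]
    hits = sub[_overlap_mask(sub, interval)]
    name = interval.name or f"{interval.chrom}:{interval.start}-{interval.end}"
    if len(hits) == 0:
        return (None, "no_fragments") if with_reason else None
    if not (hits["score"] >= score_threshold).any():
        return (None, "below_threshold") if with_reason else None
    res = IntervalInteraction(
        promoter=promoter,
        interval_name=name,
        n_fragments=len(hits),
        mean_norm_count=float(hits["norm_count"].sum() / len(hits)),
        mean_score=float(hits["score"].sum() / len(hits)),
        qualifies=True,
    )
    return (res, "ok") if with_reason else res


def _pair_means(table: FragmentTable, prom: str, interval: GenomicInterval):
    sub = table.df[table.df["bait"] == prom]
    hits = sub[_overlap_mask(sub, interval)]
    if len(hits) == 0:
        return None
    return (
        len(hits),
        float(hits["norm_count"].sum() / len(hits)),
        float(hits["score"].sum() / len(hits)),
    )


def promoter_set_summary(
    tables: dict[str, FragmentTable],
    promoters: list[str],
    intervals: IntervalSet,
    score_threshold: float = 5.0,
    qualify_in: str = "each",
) -> pd.DataFrame:
    """Per-condition, per promoter-interval pair mean values for boxplots.

    One row per qualifying pair per condition; promoters with no qualifying
    pair are simply absent. Pairs are deliberately not distance-matched.
    ``qualify_in="each"`` applies the score cutoff within each condition
    separately (the literal called-interaction rule); ``"union"`` reports a
    pair in every condition once it qualifies in any of them, so paired
    between-condition comparisons cover the same interaction set.
    """
    if not promoters:
        raise ValueError("empty promoter set")
    if qualify_in not in ("each", "union"):
        raise ValueError(f"unknown qualify_in mode {qualify_in!r}")
    iv_list = list(intervals)
    qualifying: set[tuple[str, str]] = set()
    if qualify_in == "union":
        for table in tables.values():
            for prom in promoters:
                for iv in iv_list:
                    res = interval_interaction(table, prom, iv, score_threshold)
                    if res is not None:
                        name = iv.name or f"{iv.chrom}:{iv.start}-{iv.end}"
                        qualifying.add((prom, name))
    rows = []
    for condition, table in tables.items():
        for prom in promoters:
            for iv in iv_list:
                name = iv.name or f"{iv.chrom}:{iv.start}-{iv.end}"
                if qualify_in == "each":
                    res = interval_interaction(table, prom, iv, score_threshold)
                    if res is None:
                        continue
                    n_frag, mean_nc, mean_sc = (
                        res.n_fragments,
                        res.mean_norm_count,
                        res.mean_score,
                    )
                else:
                    if (prom, name) not in qualifying:
                        continue
                    means = _pair_means(table, prom, iv)
                    if means is None:
                        continue
                    n_frag, mean_nc, mean_sc = means
                rows.append(
                    {
                        "condition": condition,
                        "promoter": prom,
                        "interval": name,
                        "n_fragments": n_frag,
                        "mean_norm_count": mean_nc,
                        "mean_score": mean_sc,
                    }
                )
    return pd.DataFrame(
        rows,
        columns=[
            "condition",
            "promoter",
            "interval",
            "n_fragments",
            "mean_norm_count",
            "mean_score",
        ],
    )


def boxplot_stats(values) -> BoxStats:
    """Boxplot statistics with notches.

    Quartiles use linear interpolation between order statistics; whiskers
    extend to the most extreme observation within 1.5 x IQR of the box; the
    notch half-width is 1.58 x IQR / sqrt(n), an approximate 95% interval
    for comparing medians.
    """
    x = np.asarray(list(values), dtype=float)
    if x.size == 0:
        raise ValueError("boxplot_stats requires at least one value")
    q1, med, q3 = np.percentile(x, [25, 50, 75])
    iqr = q3 - q1
    in_lo = x[x >= q1 - 1.5 * iqr]
    in_hi = x[x <= q3 + 1.5 * iqr]
    # when no observation lies between a quartile and its fence, the whisker
    # collapses onto the box edge
    return BoxStats(
        n=int(x.size),
        median=float(med),
        q1=float(q1),
        q3=float(q3),
        whisker_lo=float(min(in_lo.min(), q1)),
        whisker_hi=float(max(in_hi.max(), q3)),
        notch=float(1.58 * iqr / np.sqrt(x.size)),
    )
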