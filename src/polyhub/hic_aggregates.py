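"""ICE balancing and aggregate contact analyses.

All aggregates operate on observed/expected (O/E) signal: the balanced
matrix divided by its per-distance mean, which removes the power-law
distance decay so a featureless matrix aggregates to 1 everywhere.

* APA — mean O/E submatrix centered on loop-anchor pixel pairs; the
  enrichment score is the center pixel over the short-range corner quadrant.
* ATA — each TAD plus 50% flanks rescaled to a common grid by area-weighted
  interpolation, then averaged.
* PE-SCAn — mean O/E submatrix between the flanking windows of every
  qualifying same-chromosome anchor pair, optionally winsorizing the pooled
  pixel values to tame outliers (the ``super_enhancer`` preset trims 5%).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .core import ContactMatrix, ConvergenceError, IntervalSet

__all__ = [
    "AggregateMap",
    "ice_balance",
    "expected_by_distance",
    "observed_over_expected",
    "apa",
    "ata",
    "pescan",
    "polycomb_pair_aggregate",
    "PESCAN_PRESETS",
]

PESCAN_PRESETS = {
    "polycomb": dict(flank=100_000, bin_size=10_000, trim=0.0),
    "super_enhancer": dict(flank=1_000_000, bin_size=20_000, trim=0.05),
}


@dataclass
class AggregateMap:
    """Mean O/E signal over a set of anchor pairs (or rescaled TAD frames)."""

    matrix: np.ndarray
    resolution: int
    n_pairs: int
    trim: float = 0.0

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[0] != self.matrix.shape[1]:
            raise ValueError("aggregate map must be square")
        if self.n_pairs < 1:
            raise ValueError("aggregate map needs at least one contributing pair")

    @property
    def side(self) -> int:
        return self.matrix.shape[0]

    def center_value(self) -> float:
        if self.side % 2 == 0:
            raise ValueError("center pixel undefined for even-sided map")
        c = self.side // 2
        return float(self.matrix[c, c])

    def center_score(self, corner_frac: float = 0.25) -> float:
        """Center pixel over the mean of the short-range corner quadrant.

        The corner block (side * corner_frac per edge, at least one pixel)
        sits at short genomic distance on both axes, giving a local
        background estimate.
        """
        c = self.center_value()
        k = max(1, int(self.side * corner_frac))
        corner = self.matrix[-k:, :k]
        return c / float(np.nanmean(corner))

    def to_tsv(self, path) -> None:
        np.savetxt(path, self.matrix, delimiter="\t", fmt="%.10g")

    def to_png(self, path, title: str | None = None) -> None:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(4, 4))
        vmax = np.nanmax(np.abs(self.matrix))
        diverging = np.nanmin(self.matrix) < 0
        im = ax.imshow(
            self.matrix,
            cmap="RdBu_r" if diverging else "Reds",
            vmin=-vmax if diverging else None,
            vmax=vmax if diverging else None,
        )
        fig.colorbar(im, ax=ax, shrink=0.8)
        ax.set_title(title or f"aggregate over {self.n_pairs} pairs")
        fig.tight_layout()
        fig.savefig(path, dpi=150)
        plt.close(fig)


def ice_balance(
    matrix: ContactMatrix, tol: float = 1e-5, max_iter: int = 200
) -> ContactMatrix:
    """Iterative correction: equalize unmasked row sums of a symmetric matrix.

    Zero-coverage bins are masked and left untouched. Converges when the
    maximum relative deviation of the unmasked row sums from their mean is
    at most ``tol``; otherwise raises with the last residual.
    """
    w = matrix.counts.astype(float).copy()
    mask = matrix.mask | (w.sum(axis=1) == 0)
    w[mask, :] = 0.0
    w[:, mask] = 0.0
    bias = np.ones(matrix.n_bins)
    unmasked = ~mask
    if not unmasked.any():
        raise ConvergenceError("matrix has no unmasked bins", np.inf)
    residual = np.inf
    for _ in range(max_iter):
        s = w.sum(axis=1)
        mean_s = s[unmasked].mean()
        residual = float(np.abs(s[unmasked] / mean_s - 1).max())
        if residual <= tol:
            # rescale so unmasked marginals are exactly their common mean of 1
            w[np.ix_(unmasked, unmasked)] /= mean_s
            return ContactMatrix(
                matrix.chrom, matrix.resolution, w, weights=bias, mask=mask
            )
        delta = np.where(unmasked, s / mean_s, 1.0)
        w /= np.outer(delta, delta)
        bias *= delta
    raise ConvergenceError(
        f"ICE did not converge in {max_iter} iterations", residual
    )


def expected_by_distance(matrix: ContactMatrix) -> np.ndarray:
    """Mean signal per diagonal offset, over unmasked bin pairs."""
    m = matrix.counts
    n = matrix.n_bins
    keep = ~matrix.mask
    expected = np.zeros(n)
    for d in range(n):
        vals = np.diagonal(m, offset=d)
        ok = keep[: n - d] & keep[d:]
        expected[d] = vals[ok].mean() if ok.any() else np.nan
    return expected


def observed_over_expected(matrix: ContactMatrix) -> np.ndarray:
    """O/E matrix; masked bins and zero-expected distances become NaN."""
    n = matrix.n_bins
    expected = expected_by_distance(matrix)
    i, j = np.indices((n, n))
    exp_mat = expected[np.abs(i - j)]
    with np.errstate(divide="ignore", invalid="ignore"):
        oe = np.where(exp_mat > 0, matrix.counts / exp_mat, np.nan)
    oe[matrix.mask, :] = np.nan
    oe[:, matrix.mask] = np.nan
    return oe


def _as_dict(matrices) -> dict[str, ContactMatrix]:
    if isinstance(matrices, ContactMatrix):
        return {matrices.chrom: matrices}
    return dict(matrices)


def _center_bin(interval, resolution: int) -> int:
    return interval.midpoint // resolution


def _extract_stack(
    matrices: dict[str, ContactMatrix],
    pairs,
    w: int,
    min_sep_bins: int | None = None,
    max_sep_bins: int | None = None,
) -> list[np.ndarray]:
    """O/E submatrices of half-width ``w`` around each anchor-pair pixel.

    Pairs are symmetrized (bi <= bj); pairs too close to the diagonal, out
    of separation range, inter-chromosomal, or with windows leaving the
    matrix are skipped.
    """
    oe_cache: dict[str, np.ndarray] = {}
    stack = []
    for a, b in pairs:
        if a.chrom != b.chrom or a.chrom not in matrices:
            continue
        cm = matrices[a.chrom]
        if a.chrom not in oe_cache:
            oe_cache[a.chrom] = observed_over_expected(cm)
        bi, bj = _center_bin(a, cm.resolution), _center_bin(b, cm.resolution)
        if bi > bj:
            bi, bj = bj, bi
        sep = bj - bi
        if sep <= 2 * w:
            continue
        if min_sep_bins is not None and sep < min_sep_bins:
            continue
        if max_sep_bins is not None and sep > max_sep_bins:
            continue
        n = cm.n_bins
        if bi - w < 0 or bj + w >= n:
            continue
        stack.append(
            oe_cache[a.chrom][bi - w : bi + w + 1, bj - w : bj + w + 1]
        )
    return stack


def _aggregate(stack: list[np.ndarray], resolution: int, trim: float) -> AggregateMap:
    if not stack:
        raise ValueError("no usable anchor pairs")
    arr = np.stack(stack)
    if trim > 0:
        pooled = arr[~np.isnan(arr)]
        lo, hi = np.quantile(pooled, [trim, 1 - trim])
        arr = np.clip(arr, lo, hi)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN pixels
        mean = np.nanmean(arr, axis=0)
    return AggregateMap(mean, resolution=resolution, n_pairs=len(stack), trim=trim)


def apa(matrices, loop_pairs, half_window: int = 10) -> AggregateMap:
    """Aggregate peak analysis over loop-anchor pairs.

    ``loop_pairs`` is a sequence of (interval, interval) anchor pairs; the
    aggregated window spans ``half_window`` bins around the loop pixel.
    Pairs whose anchors are separated by <= 2 x half_window bins are
    skipped so the window never crosses the diagonal.
    """
    mats = _as_dict(matrices)
    res = next(iter(mats.values())).resolution
    stack = _extract_stack(mats, loop_pairs, half_window)
    return _aggregate(stack, res, trim=0.0)


def ata(matrices, tads: IntervalSet, grid: int = 100) -> AggregateMap:
    """Aggregate TAD analysis: rescale each TAD plus 50% flanks to a grid.

    TADs shorter than 5 bins, or whose flanked window leaves the matrix,
    are skipped. Rescaling is area-weighted so the frame of a TAD of any
    length averages the same O/E signal.
    """
    mats = _as_dict(matrices)
    res = next(iter(mats.values())).resolution
    oe_cache: dict[str, np.ndarray] = {}
    frames = []
    for tad in tads:
        if tad.chrom not in mats:
            continue
        cm = mats[tad.chrom]
        ts, te = tad.start / res, tad.end / res
        length = te - ts
        if length < 5:
            continue
        lo, hi = ts - 0.5 * length, te + 0.5 * length
        if lo < 0 or hi > cm.n_bins:
            continue
        if tad.chrom not in oe_cache:
            oe_cache[tad.chrom] = observed_over_expected(cm)
        wmat = _rescale_weights(lo, hi, grid, cm.n_bins)
        frames.append(wmat @ oe_cache[tad.chrom] @ wmat.T)
    if not frames:
        raise ValueError("no usable TADs")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN pixels
        mean = np.nanmean(np.stack(frames), axis=0)
    return AggregateMap(mean, resolution=res, n_pairs=len(frames))


def _rescale_weights(lo: float, hi: float, grid: int, n_bins: int) -> np.ndarray:
    """Grid x bins matrix of fractional bin overlaps, rows normalized to 1."""
    w = np.zeros((grid, n_bins))
    edges = np.linspace(lo, hi, grid + 1)
    for g in range(grid):
        a, b = edges[g], edges[g + 1]
        b0, b1 = int(np.floor(a)), int(np.ceil(b))
        for bin_ix in range(max(b0, 0), min(b1, n_bins)):
            ov = min(b, bin_ix + 1) - max(a, bin_ix)
            if ov > 0:
                w[g, bin_ix] = ov
        total = w[g].sum()
        if total > 0:
            w[g] /= total
    return w


def pescan(
    matrices,
    anchors: IntervalSet,
    flank: int = 100_000,
    bin_size: int = 10_000,
    min_sep: int = 200_000,
    max_sep: int = 5_000_000,
    trim: float = 0.05,
    preset: str | None = None,
) -> AggregateMap:
    """Paired-end spatial chromatin analysis between all anchor-pair windows.

    Every same-chromosome anchor pair with center separation in
    [min_sep, max_sep] contributes the O/E submatrix spanning ``flank``
    around each anchor. ``trim`` winsorizes the pooled pixel values at the
    trim / (1 - trim) quantiles before averaging. Presets: ``polycomb``
    (100 kb flanks, 10 kb bins, no trimming) and ``super_enhancer``
    (1 Mb flanks, 20 kb bins, 5% trimming).
    """
    if preset is not None:
        cfg = PESCAN_PRESETS[preset]
        flank, bin_size, trim = cfg["flank"], cfg["bin_size"], cfg["trim"]
    if flank % bin_size != 0:
        raise ValueError("flank must be a multiple of bin_size")
    if min_sep >= max_sep:
        raise ValueError("min_sep must be smaller than max_sep")
    mats = _as_dict(matrices)
    res = next(iter(mats.values())).resolution
    if res != bin_size:
        raise ValueError(f"matrix resolution {res} != requested bin size {bin_size}")
    w = flank // bin_size
    ivs = list(anchors)
    pairs = [
        (ivs[i], ivs[j])
        for i in range(len(ivs))
        for j in range(i + 1, len(ivs))
        if ivs[i].chrom == ivs[j].chrom
    ]
    stack = _extract_stack(
        mats,
        pairs,
        w,
        min_sep_bins=-(-min_sep // res),
        max_sep_bins=max_sep // res,
    )
    return _aggregate(stack, res, trim=trim)


def polycomb_pair_aggregate(
    matrices_wt,
    matrices_ko,
    domain_pairs,
    flank: int = 200_000,
) -> tuple[AggregateMap, AggregateMap, AggregateMap]:
    """Aggregate O/E at Polycomb-domain pairs in two conditions + difference.

    Windows span ``flank`` around each domain midpoint; returns the WT map,
    the KO map and their element-wise difference (WT - KO). Only pairs
    usable in both conditions are kept so the difference is paired.
    """
    wt = _as_dict(matrices_wt)
    ko = _as_dict(matrices_ko)
    res = next(iter(wt.values())).resolution
    if res != next(iter(ko.values())).resolution:
        raise ValueError("WT and KO matrices must share resolution")
    if flank % res != 0:
        raise ValueError("flank must be a multiple of the matrix resolution")
    w = flank // res
    stack_wt = _extract_stack(wt, domain_pairs, w)
    stack_ko = _extract_stack(ko, domain_pairs, w)
    if len(stack_wt) != len(stack_ko):
        raise ValueError("conditions disagree on usable domain pairs")
    map_wt = _aggregate(stack_wt, res, trim=0.0)
    map_ko = _aggregate(stack_ko, res, trim=0.0)
    diff = AggregateMap(
        map_wt.matrix - map_ko.matrix, resolution=res, n_pairs=map_wt.n_pairs
    )
    return map_wt, map_ko, diff
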