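"""Spike-in-anchored differential expression.

Size factors are computed by median-of-ratios on the spike-in genes only and
then applied to the target genes, so a genuine global shift in target
expression (invisible to ordinary library-size normalization, because it
rescales every library equally) is recovered as a fold change. Testing is a
transparent negative-binomial Wald test: per-gene means with size-factor
offsets, moment-based dispersion, two-sided normal p-value, Benjamini-
Hochberg adjustment, and the > 1.5-fold / adjusted p < 0.05 significance
classification.

By default the dispersion used in the Wald variance is the median of the
per-gene moment estimates ("pooled"); per-gene moment estimates from a
handful of replicates are individually so noisy that they make the normal
reference anticonservative. ``dispersion="per-gene"`` keeps the raw
per-gene estimates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CountTable",
    "DEResult",
    "spikein_size_factors",
    "libsize_size_factors",
    "nb_test",
    "adjust_bh",
    "classify",
    "induction_analysis",
]

_DISP_FLOOR = 1e-8


@dataclass
class CountTable:
    """Gene x sample integer counts with a target/spike-in origin flag."""

    counts: pd.DataFrame          # genes x samples
    origin: pd.Series             # per gene: "target" | "spike"
    conditions: pd.Series         # per sample: condition label

    def __post_init__(self) -> None:
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")
        if not self.origin.index.equals(self.counts.index):
            raise ValueError("origin index must match gene index")
        if not self.conditions.index.equals(self.counts.columns):
            raise ValueError("conditions index must match sample columns")
        if not set(self.origin.unique()) <= {"target", "spike"}:
            raise ValueError("origin must be 'target' or 'spike'")
        if (self.origin == "spike").sum() == 0:
            raise ValueError("count table needs at least one spike-in gene")
        for cond, n in self.conditions.value_counts().items():
            if n < 2:
                raise ValueError(f"condition {cond!r} has fewer than 2 replicates")

    def samples_of(self, condition: str) -> list[str]:
        cols = self.conditions[self.conditions == condition].index.tolist()
        if not cols:
            raise ValueError(f"no samples with condition {condition!r}")
        return cols

    def to_tsv(self, path) -> None:
        out = self.counts.copy()
        out.insert(0, "origin", self.origin)
        out.index.name = "gene"
        with open(path, "w") as fh:
            fh.write("# conditions: " + ",".join(
                f"{s}={c}" for s, c in self.conditions.items()) + "\n")
            out.to_csv(fh, sep="\t")

    @classmethod
    def from_tsv(cls, path) -> "CountTable":
        with open(path) as fh:
            header = fh.readline().strip()
            body = pd.read_csv(fh, sep="\t", index_col=0)
        cond = dict(
            kv.split("=") for kv in header.removeprefix("# conditions: ").split(",")
        )
        origin = body.pop("origin")
        body.index.name = None
        origin.index.name = None
        return cls(body, origin, pd.Series(cond).loc[body.columns])


@dataclass
class DEResult:
    """Per-gene differential expression results for one contrast."""

    table: pd.DataFrame  # log2fc, se, p, padj, class, testable
    contrast: tuple[str, str]  # (B, A): log2fc is B relative to A

    def genes_in_class(self, cls: str) -> pd.Index:
        return self.table.index[self.table["class"] == cls]


def _geomean_reference(spike: pd.DataFrame) -> pd.Series:
    usable = spike[(spike > 0).all(axis=1)]
    if usable.empty:
        raise ValueError("no spike-in gene is nonzero in every sample")
    return np.exp(np.log(usable).mean(axis=1)), usable


def spikein_size_factors(table: CountTable) -> pd.Series:
    """Median-of-ratios size factors computed on spike-in genes only.

    Genes with a zero in any sample are excluded from the geometric-mean
    reference (no pseudocounts). Factors are rescaled to geometric mean 1.
    """
    spike = table.counts[table.origin == "spike"]
    ref, usable = _geomean_reference(spike)
    factors = usable.div(ref, axis=0).median(axis=0)
    factors /= np.exp(np.log(factors).mean())
    return factors


def libsize_size_factors(table: CountTable) -> pd.Series:
    """Ablation: factors from target-gene library sizes (geometric mean 1).

    Blind to global shifts by construction — kept to demonstrate why
    spike-in anchoring matters.
    """
    totals = table.counts[table.origin == "target"].sum(axis=0).astype(float)
    return totals / np.exp(np.log(totals).mean())


def _moment_dispersions(
    q: pd.DataFrame, inv_s: pd.Series, groups: list[list[str]]
) -> pd.Series:
    """Per-gene moment estimate of the NB dispersion from normalized counts.

    Within each condition, Var(K/s) = mu * E[1/s] + alpha * mu^2; the excess
    of the pooled within-condition variance over the Poisson part, relative
    to mu^2, estimates alpha.
    """
    num = pd.Series(0.0, index=q.index)
    den = pd.Series(0.0, index=q.index)
    for cols in groups:
        sub = q[cols]
        mu = sub.mean(axis=1)
        var = sub.var(axis=1, ddof=1)
        poisson = mu * np.mean([inv_s[c] for c in cols])
        num += (var - poisson) * (len(cols) - 1)
        den += mu**2 * (len(cols) - 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        alpha = num / den
    return alpha.replace([np.inf, -np.inf], np.nan)


def nb_test(
    table: CountTable,
    factors: pd.Series,
    condition_a: str,
    condition_b: str,
    dispersion: str = "pooled",
) -> DEResult:
    """NB Wald test of target genes: log2 fold change of B relative to A.

    Counts are divided by the size factors; the Wald variance of each
    condition mean is (1/n^2) * sum(mu/s_i + alpha*mu^2). Genes with zero
    mean in either condition are flagged untestable and excluded from the
    multiple-testing adjustment.
    """
    if (factors <= 0).any():
        raise ValueError("size factors must be positive")
    if dispersion not in ("pooled", "per-gene"):
        raise ValueError(f"unknown dispersion mode {dispersion!r}")
    cols_a = table.samples_of(condition_a)
    cols_b = table.samples_of(condition_b)
    target = table.counts[table.origin == "target"]
    q = target.div(factors, axis=1)
    inv_s = 1.0 / factors

    alpha = _moment_dispersions(q, inv_s, [cols_a, cols_b])
    if dispersion == "pooled":
        # mean, not median: per-gene moment estimates are chi-square-skewed,
        # so their median sits below the true dispersion and would make the
        # Wald test anticonservative
        pooled = float(np.nanmean(alpha))
        alpha = pd.Series(pooled, index=alpha.index)
    alpha = alpha.fillna(0.0).clip(lower=_DISP_FLOOR)

    mu_a = q[cols_a].mean(axis=1)
    mu_b = q[cols_b].mean(axis=1)
    testable = (mu_a > 0) & (mu_b > 0)

    def _var_mean(mu: pd.Series, cols: list[str]) -> pd.Series:
        per_sample = pd.concat(
            [mu * inv_s[c] + alpha * mu**2 for c in cols], axis=1
        )
        return per_sample.sum(axis=1) / len(cols) ** 2

    with np.errstate(divide="ignore", invalid="ignore"):
        log2fc = np.log2(mu_b / mu_a)
        var_log2 = (
            _var_mean(mu_a, cols_a) / mu_a**2 + _var_mean(mu_b, cols_b) / mu_b**2
        ) / np.log(2) ** 2
        se = np.sqrt(var_log2)
        z = log2fc / se
    p = pd.Series(2 * stats.norm.sf(np.abs(z)), index=target.index)

    out = pd.DataFrame(
        {
            "log2fc": log2fc,
            "se": se,
            "p": p,
            "padj": np.nan,
            "class": "unchanged",
            "testable": testable,
        }
    )
    out.loc[~testable, ["log2fc", "se", "p"]] = np.nan
    out.loc[testable, "padj"] = adjust_bh(out.loc[testable, "p"].to_numpy())
    result = DEResult(out, contrast=(condition_b, condition_a))
    result.table["class"] = classify(result)
    return result


def adjust_bh(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(pvalues, dtype=float)
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    n = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * n / np.arange(1, n + 1)
    # enforce step-up monotonicity from the largest p downwards
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.empty(n)
    adj[order] = np.minimum(ranked, 1.0)
    return adj


def classify(
    result: DEResult, fc_min: float = 1.5, alpha: float = 0.05
) -> pd.Series:
    """Significance classes: up / down / unchanged (strict thresholds)."""
    t = result.table
    fold = 2.0 ** t["log2fc"]
    sig = t["padj"] < alpha
    cls = pd.Series("unchanged", index=t.index)
    cls[(fold > fc_min) & sig] = "up"
    cls[(fold < 1.0 / fc_min) & sig] = "down"
    cls[~t["testable"]] = "untestable"
    return cls


def induction_analysis(
    table_esc: CountTable,
    table_ra_wt: CountTable,
    table_ra_ko: CountTable,
    fc_min: float = 1.5,
    alpha: float = 0.05,
    dispersion: str = "pooled",
) -> tuple[pd.Index, pd.DataFrame]:
    """Genes whose induction during differentiation depends on the KO'd factor.

    A gene is called dependent when it is significantly induced in the WT
    differentiation contrast (RA vs ESC, class up) and significantly
    attenuated in the KO contrast (KO-RA vs WT-RA, class down). Returns the
    dependent gene index and the merged per-gene table.
    """
    for other in (table_ra_wt, table_ra_ko):
        if not other.counts.index.equals(table_esc.counts.index):
            raise ValueError("count tables must share the same genes")

    induction = _pairwise(table_esc, table_ra_wt, "ESC", "RA_WT",
                          fc_min, alpha, dispersion)
    dependence = _pairwise(table_ra_wt, table_ra_ko, "RA_WT", "RA_KO",
                           fc_min, alpha, dispersion)

    merged = induction.table.join(
        dependence.table, lsuffix="_induction", rsuffix="_dependence"
    )
    dependent = merged.index[
        (merged["class_induction"] == "up") & (merged["class_dependence"] == "down")
    ]
    return dependent, merged


def _pairwise(
    ta: CountTable, tb: CountTable, label_a: str, label_b: str,
    fc_min: float, alpha: float, dispersion: str,
) -> DEResult:
    counts = pd.concat([ta.counts, tb.counts], axis=1)
    counts.columns = [f"{label_a}:{c}" for c in ta.counts.columns] + [
        f"{label_b}:{c}" for c in tb.counts.columns
    ]
    conditions = pd.Series(
        [label_a] * ta.counts.shape[1] + [label_b] * tb.counts.shape[1],
        index=counts.columns,
    )
    combined = CountTable(counts, ta.origin, conditions)
    factors = spikein_size_factors(combined)
    res = nb_test(combined, factors, label_a, label_b, dispersion=dispersion)
    res.table["class"] = classify(res, fc_min=fc_min, alpha=alpha)
    return res
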