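"""Ground-truth synthetic data for every pipeline stage.

The generator emulates, at desk scale, the data modalities of a Polycomb
contact-hub study in mouse embryonic stem cells:

* interval sets (Polycomb domains, TADs, peaks, baits) placed without
  overlap on a small multi-chromosome genome;
* intra-chromosomal Hi-C contact matrices with power-law distance decay,
  TAD blocks, loop pixels and hub blocks between paired Polycomb domains
  whose enrichment differs between a "WT" and a "KO" condition (Poisson
  counts);
* dual-genome ChIP IP/input count pairs with known per-domain occupancy and
  a deliberately confounded per-sample IP efficiency, to exercise spike-in
  calibration;
* Capture-C fragment tables with distance decay, elevated counts at hub
  partners, and synthetic interaction scores drawn from two separated gamma
  families so the >= 5 cutoff splits hub partners from background by
  construction;
* negative-binomial expression counts with a known induced-gene set, known
  per-gene log2 fold changes, an unchanged spike-in gene set and an optional
  global shift that only spike-in anchoring can see.

Every sampler is deterministic given its seed and has closed-form expected
values, so downstream estimates can be checked against analytic truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import (
    ContactMatrix,
    GenomeModel,
    GenomicInterval,
    IntervalSet,
    PlacementError,
)
from .capturec_quant import FragmentTable
from .diffexpr_spikein import CountTable
from .spikein_calibration import ChipSample

__all__ = [
    "TruthSet",
    "ChipExperiment",
    "default_genome",
    "default_truth",
    "simulate_intervals",
    "simulate_contact_matrix",
    "simulate_chip_experiment",
    "make_fragment_map",
    "simulate_capturec",
    "simulate_expression",
    "simulate_induction_experiment",
]


def default_genome(
    n_chroms: int = 3, chrom_length: int = 30_000_000, bin_size: int = 10_000
) -> GenomeModel:
    """A small stand-in assembly: a few tens of Mb is enough for every stage."""
    return GenomeModel(
        {f"chr{i + 1}": chrom_length for i in range(n_chroms)}, bin_size=bin_size
    )


@dataclass
class TruthSet:
    """Known ground truth shared by all simulators.

    ``hub_factors`` maps condition labels to the contact enrichment between
    paired Polycomb domains (the WT hubs collapse in the KO);
    ``occupancy`` maps condition labels to the per-domain ChIP occupancy
    multiplier over background. Gene-level truth covers a simple
    two-condition contrast (``gene_log2fc``) and a three-condition
    differentiation design (``induction_log2fc`` for RA vs ESC in WT,
    ``dependence_log2fc`` added on top in the KO differentiation).
    """

    domains: IntervalSet
    tads: IntervalSet
    loops: list[tuple[GenomicInterval, GenomicInterval]]
    hub_pairs: list[tuple[int, int]]
    hub_factors: dict[str, float]
    occupancy: dict[str, np.ndarray]
    gene_log2fc: np.ndarray = field(default_factory=lambda: np.zeros(0))
    induction_log2fc: np.ndarray = field(default_factory=lambda: np.zeros(0))
    dependence_log2fc: np.ndarray = field(default_factory=lambda: np.zeros(0))

    def __post_init__(self) -> None:
        for cond, fac in self.hub_factors.items():
            if fac < 0:
                raise ValueError(f"hub factor for {cond!r} must be >= 0")
        n_dom = len(self.domains)
        for a, b in self.hub_pairs:
            if not (0 <= a < n_dom and 0 <= b < n_dom):
                raise ValueError("hub pair indexes outside domain set")
            if self.domains[a].chrom != self.domains[b].chrom:
                raise ValueError("hub pairs must be intra-chromosomal")

    def validate_against(self, genome: GenomeModel) -> None:
        self.domains.validate_against(genome)
        self.tads.validate_against(genome)

    @property
    def induced_mask(self) -> np.ndarray:
        return self.induction_log2fc > 0

    @property
    def dependent_mask(self) -> np.ndarray:
        return self.induced_mask & (self.dependence_log2fc < 0)

    def hub_domain_pairs(self) -> list[tuple[GenomicInterval, GenomicInterval]]:
        return [(self.domains[a], self.domains[b]) for a, b in self.hub_pairs]


def simulate_intervals(
    genome: GenomeModel,
    n: int = 2097,
    length_range: tuple[int, int] = (5_000, 20_000),
    seed: int = 0,
) -> IntervalSet:
    """Place n non-overlapping intervals, sorted by position.

    Intervals are apportioned to chromosomes in proportion to length, then
    laid out by distributing the free space uniformly at random between
    them. Raises PlacementError when the genome cannot hold them.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    lo, hi = length_range
    if not 0 < lo <= hi:
        raise ValueError("invalid length range")
    rng = np.random.default_rng(seed)
    chroms = genome.chroms
    sizes = np.array([genome.length(c) for c in chroms], dtype=float)
    counts = rng.multinomial(n, sizes / sizes.sum())
    rows = []
    for chrom, k in zip(chroms, counts):
        if k == 0:
            continue
        lengths = rng.integers(lo, hi + 1, size=k)
        free = genome.length(chrom) - int(lengths.sum())
        if free < 0:
            raise PlacementError(
                f"cannot place {k} intervals of {lengths.sum()} bp on {chrom}"
            )
        gaps = np.sort(rng.integers(0, free + 1, size=k))
        starts = gaps + np.concatenate([[0], np.cumsum(lengths[:-1])])
        for s, ln in zip(starts, lengths):
            rows.append((chrom, int(s), int(s + ln)))
    df = pd.DataFrame(rows, columns=["chrom", "start", "end"])
    df["name"] = [f"iv{i}" for i in range(len(df))]
    return IntervalSet(df).sorted()


def default_truth(
    genome: GenomeModel,
    n_domains: int = 70,
    domain_length: tuple[int, int] = (5_000, 20_000),
    n_tads: int = 40,
    tad_length: tuple[int, int] = (500_000, 1_200_000),
    n_loops: int = 50,
    loop_sep: tuple[int, int] = (300_000, 2_000_000),
    n_hub_pairs: int | None = 40,
    hub_sep: tuple[int, int] = (400_000, 5_000_000),
    hub_factors: dict[str, float] | None = None,
    occupancy: dict[str, float] | None = None,
    n_genes: int = 2000,
    seed: int = 0,
) -> TruthSet:
    """Assemble a TruthSet with the study's default conditions.

    Hub contact enrichment 3x in WT collapsing to 1x in KO; domain ChIP
    occupancy 8x background in WT, halved in KO. Gene-level effects default
    to null (set by the expression helpers for DE scenarios).
    """
    rng = np.random.default_rng(seed)
    empty = IntervalSet(pd.DataFrame(columns=["chrom", "start", "end"]))
    domains = simulate_intervals(
        genome, n_domains, domain_length, seed=int(rng.integers(2**31))
    )
    tads = (
        simulate_intervals(genome, n_tads, tad_length, seed=int(rng.integers(2**31)))
        if n_tads > 0
        else empty
    )

    # loop anchor pairs: pick peak pairs on the same chromosome within range
    if n_loops > 0:
        peaks = simulate_intervals(
            genome, max(n_loops * 3, 30), (2_000, 4_000), seed=int(rng.integers(2**31))
        )
        loops = _pick_pairs(list(peaks), n_loops, loop_sep, rng)
    else:
        loops = []
    # hub pairs: domain index pairs on the same chromosome within range
    dom_list = list(domains)
    idx_pairs = []
    by_chrom: dict[str, list[int]] = {}
    for i, iv in enumerate(dom_list):
        by_chrom.setdefault(iv.chrom, []).append(i)
    candidates = []
    for idxs in by_chrom.values():
        for ai in range(len(idxs)):
            for bi in range(ai + 1, len(idxs)):
                a, b = idxs[ai], idxs[bi]
                sep = abs(dom_list[b].midpoint - dom_list[a].midpoint)
                if hub_sep[0] <= sep <= hub_sep[1]:
                    candidates.append((a, b))
    if candidates:
        if n_hub_pairs is None:  # every in-range domain pair is a hub pair
            idx_pairs = candidates
        elif n_hub_pairs > 0:
            take = rng.choice(
                len(candidates), size=min(n_hub_pairs, len(candidates)), replace=False
            )
            idx_pairs = [candidates[t] for t in sorted(take)]

    hub_factors = dict(hub_factors or {"WT": 3.0, "KO": 1.0})
    occupancy = dict(occupancy or {"WT": 8.0, "KO": 4.0})
    occ = {
        cond: np.full(len(domains), float(mult)) for cond, mult in occupancy.items()
    }
    return TruthSet(
        domains=domains,
        tads=tads,
        loops=loops,
        hub_pairs=idx_pairs,
        hub_factors=hub_factors,
        occupancy=occ,
        gene_log2fc=np.zeros(n_genes),
        induction_log2fc=np.zeros(n_genes),
        dependence_log2fc=np.zeros(n_genes),
    )


def _pick_pairs(intervals, n, sep_range, rng):
    candidates = []
    for i in range(len(intervals)):
        for j in range(i + 1, len(intervals)):
            a, b = intervals[i], intervals[j]
            if a.chrom != b.chrom:
                continue
            sep = abs(b.midpoint - a.midpoint)
            if sep_range[0] <= sep <= sep_range[1]:
                candidates.append((a, b))
    if not candidates:
        return []
    take = rng.choice(len(candidates), size=min(n, len(candidates)), replace=False)
    return [candidates[t] for t in sorted(take)]


# ---------------------------------------------------------------------------
# Hi-C


def contact_expectation(
    genome: GenomeModel,
    truth: TruthSet,
    condition: str,
    decay_exponent: float = 1.0,
    tad_factor: float = 2.0,
    loop_factor: float = 3.0,
) -> dict[str, np.ndarray]:
    """Unscaled expected contact intensity per chromosome.

    Power-law decay (1 + d)^-exponent times a TAD block factor, a loop
    pixel factor and a hub block factor between paired domains (condition
    specific).
    """
    if condition not in truth.hub_factors:
        raise ValueError(f"unknown condition {condition!r}")
    hub_factor = truth.hub_factors[condition]
    res = genome.bin_size
    out = {}
    for chrom in genome.chroms:
        n = genome.n_bins(chrom)
        d = np.abs(np.subtract.outer(np.arange(n), np.arange(n)))
        m = (1.0 + d) ** (-decay_exponent)
        for tad in truth.tads:
            if tad.chrom != chrom:
                continue
            b0, b1 = tad.start // res, -(-tad.end // res)
            m[b0:b1, b0:b1] *= tad_factor
        for a, b in truth.loops:
            if a.chrom != chrom:
                continue
            bi, bj = a.midpoint // res, b.midpoint // res
            m[bi, bj] *= loop_factor
            if bi != bj:
                m[bj, bi] *= loop_factor
        for ai, bi_ in truth.hub_pairs:
            da, db = truth.domains[ai], truth.domains[bi_]
            if da.chrom != chrom:
                continue
            a0, a1 = da.start // res, -(-da.end // res)
            b0, b1 = db.start // res, -(-db.end // res)
            m[a0:a1, b0:b1] *= hub_factor
            m[b0:b1, a0:a1] *= hub_factor
        out[chrom] = m
    return out


def simulate_contact_matrix(
    genome: GenomeModel,
    truth: TruthSet,
    condition: str,
    decay_exponent: float = 1.0,
    depth: int = 20_000_000,
    seed: int = 0,
    tad_factor: float = 2.0,
    loop_factor: float = 3.0,
) -> dict[str, ContactMatrix]:
    """Poisson-sampled symmetric contact matrices, one per chromosome.

    ``depth`` is the expected total count over the full (symmetric)
    genome-wide matrix. Sampling draws the upper triangle and mirrors it,
    so matrices are exactly symmetric.
    """
    if depth <= 0:
        raise ValueError("depth must be positive")
    expected = contact_expectation(
        genome, truth, condition, decay_exponent, tad_factor, loop_factor
    )
    total = sum(m.sum() for m in expected.values())
    scale = depth / total
    rng = np.random.default_rng(seed)
    out = {}
    for chrom, m in expected.items():
        lam = np.triu(m * scale)
        upper = rng.poisson(lam)
        counts = upper + np.triu(upper, 1).T
        out[chrom] = ContactMatrix(chrom, genome.bin_size, counts.astype(float))
    return out


# ---------------------------------------------------------------------------
# ChIP


@dataclass
class ChipExperiment:
    """Simulated ChIP samples plus the bin layout and true domain mask."""

    samples: list[ChipSample]
    bin_map: pd.DataFrame  # chrom, start, end per target bin
    domain_bins: np.ndarray  # bool: bin overlaps a Polycomb domain


def _target_bins(genome: GenomeModel, bin_size: int) -> pd.DataFrame:
    rows = []
    for chrom in genome.chroms:
        length = genome.length(chrom)
        for s in range(0, length, bin_size):
            rows.append((chrom, s, min(s + bin_size, length)))
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])


def simulate_chip_experiment(
    truth: TruthSet,
    genome: GenomeModel,
    conditions: tuple[str, ...] = ("WT", "KO"),
    replicates: int = 3,
    ip_efficiency: float | dict[str, float] = 1.0,
    spikein_fraction: float | dict[str, float] = 0.05,
    depth: int = 2_000_000,
    bin_size: int = 2_000,
    n_spike_bins: int = 2_000,
    seed: int = 0,
) -> ChipExperiment:
    """IP + matched input count pairs for each condition and replicate.

    Target IP counts are Poisson with mean proportional to true occupancy x
    IP efficiency; spike-in IP counts are proportional to IP efficiency
    only; input counts see neither. ``ip_efficiency`` and
    ``spikein_fraction`` may vary per condition (mapping) to confound the
    comparison on purpose.
    """
    if depth <= 0:
        raise ValueError("depth must be positive")
    if replicates < 1:
        raise ValueError("replicates must be >= 1")

    def per_cond(value, cond, name):
        v = value[cond] if isinstance(value, dict) else value
        if name == "spikein_fraction" and not 0 < v < 1:
            raise ValueError("spikein_fraction must lie in (0, 1)")
        if name == "ip_efficiency" and v <= 0:
            raise ValueError("ip_efficiency must be positive")
        return float(v)

    bin_map = _target_bins(genome, bin_size)
    n_bins = len(bin_map)
    occ_base = np.ones(n_bins)
    domain_bins = np.zeros(n_bins, dtype=bool)
    starts = bin_map["start"].to_numpy()
    chrom_arr = bin_map["chrom"].to_numpy()
    occupancy_by_cond = {}
    for cond in conditions:
        occ = occ_base.copy()
        for d_ix, dom in enumerate(truth.domains):
            sel = (
                (chrom_arr == dom.chrom)
                & (starts < dom.end)
                & (starts + bin_size > dom.start)
            )
            occ[sel] = truth.occupancy[cond][d_ix]
            domain_bins |= sel
        occupancy_by_cond[cond] = occ

    rng = np.random.default_rng(seed)
    samples: list[ChipSample] = []
    for cond in conditions:
        e = per_cond(ip_efficiency, cond, "ip_efficiency")
        phi = per_cond(spikein_fraction, cond, "spikein_fraction")
        occ = occupancy_by_cond[cond]
        lam_t_ip = depth * (1 - phi) / n_bins * e * occ
        lam_s_ip = np.full(n_spike_bins, depth * phi / n_spike_bins * e)
        lam_t_in = np.full(n_bins, depth * (1 - phi) / n_bins)
        lam_s_in = np.full(n_spike_bins, depth * phi / n_spike_bins)
        for rep in range(1, replicates + 1):
            input_id = f"{cond}_rep{rep}_input"
            samples.append(
                ChipSample(
                    f"{cond}_rep{rep}_IP",
                    cond,
                    "IP",
                    rng.poisson(lam_t_ip),
                    rng.poisson(lam_s_ip),
                    input_id=input_id,
                )
            )
            samples.append(
                ChipSample(
                    input_id,
                    cond,
                    "input",
                    rng.poisson(lam_t_in),
                    rng.poisson(lam_s_in),
                )
            )
    return ChipExperiment(samples, bin_map, domain_bins)


# ---------------------------------------------------------------------------
# Capture-C


def make_fragment_map(genome: GenomeModel, fragment_size: int = 500) -> IntervalSet:
    """Fixed-length virtual restriction fragments tiling the genome."""
    rows = []
    for chrom in genome.chroms:
        length = genome.length(chrom)
        for s in range(0, length, fragment_size):
            rows.append((chrom, s, min(s + fragment_size, length)))
    df = pd.DataFrame(rows, columns=["chrom", "start", "end"])
    df["name"] = [f"frag{i}" for i in range(len(df))]
    return IntervalSet(df)


def simulate_capturec(
    baits: IntervalSet,
    fragments: IntervalSet,
    truth: TruthSet,
    condition: str = "WT",
    depth: int = 1_000_000,
    seed: int = 0,
    decay_exponent: float = 1.0,
    decay_scale: float = 20_000.0,
    max_range: int = 5_000_000,
    score_seed_offset: int = 1,
) -> FragmentTable:
    """Per-bait fragment counts with distance decay and hub-partner signal.

    Counts are Poisson with mean decaying as (1 + d/decay_scale)^-exponent
    from the bait, multiplied by the condition's hub factor at fragments in
    hub-partner domains; the expected total over the table is ``depth``.
    Interaction scores come from two separated gamma families: hub partners
    in an interacting condition (hub factor > 1) score >= 5 by construction,
    everything else scores < 5.
    """
    if condition not in truth.hub_factors:
        raise ValueError(f"unknown condition {condition!r}")
    if depth <= 0:
        raise ValueError("depth must be positive")
    hub_factor = truth.hub_factors[condition]
    interacting = hub_factor > 1.0

    frag_df = fragments.df
    rows = []
    dom_list = list(truth.domains)
    for bait in baits:
        mask = (
            (frag_df["chrom"] == bait.chrom)
            & (frag_df["start"] < bait.end)
            & (frag_df["end"] > bait.start)
        )
        if not mask.any():
            raise PlacementError(
                f"bait {bait.name or bait.chrom}:{bait.start} outside fragment map"
            )
        # domains containing the bait, and their hub partners
        bait_doms = {
            i for i, d in enumerate(dom_list) if d.overlaps(bait)
        }
        partner_doms = set()
        for a, b in truth.hub_pairs:
            if a in bait_doms:
                partner_doms.add(b)
            if b in bait_doms:
                partner_doms.add(a)

        near = frag_df[
            (frag_df["chrom"] == bait.chrom)
            & ((frag_df["start"] + frag_df["end"]) // 2 - bait.midpoint).abs().le(
                max_range
            )
        ]
        mids = ((near["start"] + near["end"]) // 2).to_numpy()
        dist = np.abs(mids - bait.midpoint)
        lam = (1.0 + dist / decay_scale) ** (-decay_exponent)
        is_partner = np.zeros(len(near), dtype=bool)
        for p in partner_doms:
            dom = dom_list[p]
            is_partner |= (near["start"].to_numpy() < dom.end) & (
                near["end"].to_numpy() > dom.start
            )
        lam = lam * np.where(is_partner, hub_factor, 1.0)
        rows.append((bait, near, lam, is_partner))

    total_lam = sum(r[2].sum() for r in rows)
    if not rows:
        return FragmentTable(
            pd.DataFrame(
                columns=["bait", "chrom", "start", "end", "raw_count", "score"]
            )
        )
    scale = depth / total_lam
    rng = np.random.default_rng(seed)
    score_rng = np.random.default_rng(seed + score_seed_offset)
    frames = []
    for k, (bait, near, lam, is_partner) in enumerate(rows):
        counts = rng.poisson(lam * scale)
        n = len(near)
        background = np.minimum(score_rng.gamma(2.0, 0.6, size=n), 4.99)
        hub_scores = 5.0 + score_rng.gamma(2.0, 2.0, size=n)
        scores = np.where(is_partner & interacting, hub_scores, background)
        frames.append(
            pd.DataFrame(
                {
                    "bait": bait.name or f"bait{k}",
                    "chrom": near["chrom"].to_numpy(),
                    "start": near["start"].to_numpy(),
                    "end": near["end"].to_numpy(),
                    "raw_count": counts,
                    "score": scores,
                }
            )
        )
    return FragmentTable(pd.concat(frames, ignore_index=True))


# ---------------------------------------------------------------------------
# Expression


def _nb_draw(rng, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """Negative binomial with mean/dispersion parameterization.

    var = mean + dispersion * mean^2; dispersion -> 0 degenerates to
    Poisson.
    """
    if dispersion <= 0:
        return rng.poisson(mean)
    size = 1.0 / dispersion
    p = size / (size + mean)
    return rng.negative_binomial(size, p)


def _base_means(rng, n: int, log_mean: float, log_sd: float) -> np.ndarray:
    return rng.lognormal(mean=log_mean, sigma=log_sd, size=n)


def simulate_expression(
    n_genes: int,
    n_spike_genes: int,
    truth: TruthSet,
    global_shift: float = 1.0,
    replicates: int = 4,
    depth_mean: float = 100.0,
    dispersion: float = 0.05,
    conditions: tuple[str, str] = ("WT", "KO"),
    seed: int = 0,
) -> CountTable:
    """Two-condition NB count table with known per-gene truth.

    The second condition's target-gene means are the first's times
    2^gene_log2fc times ``global_shift``; spike-in genes are identical in
    expectation across conditions. ``global_shift`` emulates a genome-wide
    transcriptional change that library-size normalization cannot see.
    """
    if n_spike_genes < 1:
        raise ValueError("spike-in anchoring undefined without spike-in genes")
    if replicates < 2:
        raise ValueError("at least 2 replicates per condition are required")
    if len(truth.gene_log2fc) != n_genes:
        raise ValueError("truth.gene_log2fc length must equal n_genes")
    if global_shift <= 0:
        raise ValueError("global_shift must be positive")
    rng = np.random.default_rng(seed)
    base_t = _base_means(rng, n_genes, np.log(depth_mean), 1.0)
    base_s = _base_means(rng, n_spike_genes, np.log(depth_mean), 1.0)
    cond_a, cond_b = conditions
    mean_by_cond = {
        cond_a: base_t,
        cond_b: base_t * (2.0 ** truth.gene_log2fc) * global_shift,
    }
    genes = [f"gene{i}" for i in range(n_genes)] + [
        f"spike{i}" for i in range(n_spike_genes)
    ]
    origin = pd.Series(
        ["target"] * n_genes + ["spike"] * n_spike_genes, index=genes
    )
    data, cond_labels = {}, {}
    for cond in conditions:
        for rep in range(1, replicates + 1):
            col = f"{cond}_rep{rep}"
            counts = np.concatenate(
                [
                    _nb_draw(rng, mean_by_cond[cond], dispersion),
                    _nb_draw(rng, base_s, dispersion),
                ]
            )
            data[col] = counts
            cond_labels[col] = cond
    counts = pd.DataFrame(data, index=genes)
    return CountTable(counts, origin, pd.Series(cond_labels))


def simulate_induction_experiment(
    truth: TruthSet,
    n_genes: int,
    n_spike_genes: int,
    replicates: int = 4,
    depth_mean: float = 100.0,
    dispersion: float = 0.05,
    seed: int = 0,
) -> tuple[CountTable, CountTable, CountTable]:
    """ESC / WT-differentiated / KO-differentiated count tables.

    Induced genes carry ``truth.induction_log2fc`` in the WT
    differentiation; in the KO differentiation, dependent genes are
    additionally shifted by ``truth.dependence_log2fc`` (negative =
    attenuated induction). Spike-in genes are identical in expectation in
    all three tables.
    """
    if n_spike_genes < 1:
        raise ValueError("spike-in anchoring undefined without spike-in genes")
    if replicates < 2:
        raise ValueError("at least 2 replicates per condition are required")
    if len(truth.induction_log2fc) != n_genes:
        raise ValueError("truth.induction_log2fc length must equal n_genes")
    rng = np.random.default_rng(seed)
    base_t = _base_means(rng, n_genes, np.log(depth_mean), 1.0)
    base_s = _base_means(rng, n_spike_genes, np.log(depth_mean), 1.0)
    means = {
        "ESC": base_t,
        "RA_WT": base_t * 2.0 ** truth.induction_log2fc,
        "RA_KO": base_t
        * 2.0 ** (truth.induction_log2fc + truth.dependence_log2fc),
    }
    genes = [f"gene{i}" for i in range(n_genes)] + [
        f"spike{i}" for i in range(n_spike_genes)
    ]
    origin = pd.Series(["target"] * n_genes + ["spike"] * n_spike_genes, index=genes)
    tables = []
    for cond in ("ESC", "RA_WT", "RA_KO"):
        data, labels = {}, {}
        for rep in range(1, replicates + 1):
            col = f"{cond}_rep{rep}"
            data[col] = np.concatenate(
                [
                    _nb_draw(rng, means[cond], dispersion),
                    _nb_draw(rng, base_s, dispersion),
                ]
            )
            labels[col] = cond
        tables.append(
            CountTable(pd.DataFrame(data, index=genes), origin, pd.Series(labels))
        )
    return tuple(tables)
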