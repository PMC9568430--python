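"""End-to-end orchestration of the synthetic study.

``run_all`` drives generate -> calibrate -> aggregate -> quantify -> test
from a single YAML-serializable config, writing plain-text artifacts and a
JSON run report. Every stage derives its seed from the master seed plus a
stable hash of the stage name, so stages are individually reproducible and
the whole run is byte-deterministic.
"""

from __future__ import annotations

import json
import logging
import time
import zlib
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import (
    capturec_quant as cc,
    diffexpr_spikein as de,
    hic_aggregates as hic,
    signal_quantification as sq,
    spikein_calibration as cal,
    synthetic_data as syn,
)
from .core import GenomeModel, GenomicInterval, IntervalSet, PolyhubError

__all__ = ["RunConfig", "RunReport", "ConfigError", "run_all", "stage_seed"]

log = logging.getLogger("polyhub")


class ConfigError(PolyhubError):
    """A run configuration field is missing or invalid."""


def stage_seed(master: int, stage: str) -> int:
    """Per-stage seed: master seed combined with a stable stage-name hash."""
    return (int(master) * 1_000_003 + zlib.crc32(stage.encode())) % (2**31)


@dataclass
class RunConfig:
    """All parameters of a full synthetic run (YAML round-trippable)."""

    seed: int = 0
    outdir: str = "results/run"
    genome: dict = field(
        default_factory=lambda: dict(
            n_chroms=2, chrom_length=8_000_000, bin_size=10_000
        )
    )
    truth: dict = field(
        default_factory=lambda: dict(
            n_domains=24,
            domain_length=[10_000, 30_000],
            n_tads=8,
            tad_length=[500_000, 1_000_000],
            n_loops=20,
            n_hub_pairs=20,
            hub_factors={"WT": 3.0, "KO": 1.0},
            occupancy={"WT": 8.0, "KO": 4.0},
        )
    )
    hic: dict = field(
        default_factory=lambda: dict(
            depth=8_000_000, decay_exponent=1.0, pair_flank=200_000
        )
    )
    chip: dict = field(
        default_factory=lambda: dict(
            replicates=3,
            depth=1_000_000,
            ip_efficiency={"WT": 1.0, "KO": 2.0},
            spikein_fraction=0.05,
            bin_size=5_000,
        )
    )
    capturec: dict = field(
        default_factory=lambda: dict(depth=500_000, fragment_size=500)
    )
    expression: dict = field(
        default_factory=lambda: dict(
            n_genes=1200,
            n_spike_genes=300,
            replicates=4,
            global_shift=0.5,
            n_induced=120,
            induction_log2fc=3.0,
            n_dependent=60,
            dependence_log2fc=-2.0,
        )
    )

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        cfg = cls()
        known = set(cfg.__dataclass_fields__)
        for key, value in raw.items():
            if key not in known:
                raise ConfigError(f"unknown config field {key!r}")
            if isinstance(value, dict) and isinstance(getattr(cfg, key), dict):
                merged = dict(getattr(cfg, key))
                merged.update(value)
                setattr(cfg, key, merged)
            else:
                setattr(cfg, key, value)
        cfg.validate()
        return cfg

    def validate(self) -> None:
        if not isinstance(self.seed, int):
            raise ConfigError("config field 'seed' must be an integer")
        for name, block, required in [
            ("genome", self.genome, {"n_chroms", "chrom_length", "bin_size"}),
            ("truth", self.truth, {"n_domains", "hub_factors", "occupancy"}),
            ("hic", self.hic, {"depth"}),
            ("chip", self.chip, {"replicates", "depth"}),
            ("capturec", self.capturec, {"depth"}),
            ("expression", self.expression, {"n_genes", "n_spike_genes"}),
        ]:
            missing = required - set(block)
            if missing:
                raise ConfigError(
                    f"config field '{name}.{sorted(missing)[0]}' is missing"
                )
        if set(self.truth["hub_factors"]) != set(self.truth["occupancy"]):
            raise ConfigError(
                "config field 'truth.occupancy' must cover the same conditions "
                "as 'truth.hub_factors'"
            )

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)


@dataclass
class RunReport:
    """Seeds, parameters and headline metrics of one full run."""

    config: dict
    stage_seeds: dict
    metrics: dict

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "config": self.config,
                    "stage_seeds": self.stage_seeds,
                    "metrics": self.metrics,
                },
                fh,
                indent=2,
                sort_keys=True,
                default=float,
            )
            fh.write("\n")


def _timed(name):
    class _Ctx:
        def __enter__(self):
            self.t0 = time.perf_counter()
            log.info("stage=%s start", name)
            return self

        def __exit__(self, exc_type, exc, tb):
            dt = time.perf_counter() - self.t0
            if exc is None:
                log.info("stage=%s elapsed=%.2fs", name, dt)
            else:
                log.error("stage=%s failed after %.2fs: %s", name, dt, exc)
            return False

    return _Ctx()


def build_genome(cfg: RunConfig) -> GenomeModel:
    g = cfg.genome
    return syn.default_genome(g["n_chroms"], g["chrom_length"], g["bin_size"])


def build_truth(cfg: RunConfig, genome: GenomeModel) -> syn.TruthSet:
    t = dict(cfg.truth)
    expr = cfg.expression
    n_genes = expr["n_genes"]
    truth = syn.default_truth(
        genome,
        n_domains=t.get("n_domains", 24),
        domain_length=tuple(t.get("domain_length", (10_000, 30_000))),
        n_tads=t.get("n_tads", 8),
        tad_length=tuple(t.get("tad_length", (500_000, 1_000_000))),
        n_loops=t.get("n_loops", 20),
        n_hub_pairs=t.get("n_hub_pairs", 20),
        hub_factors=t["hub_factors"],
        occupancy=t["occupancy"],
        n_genes=n_genes,
        seed=stage_seed(cfg.seed, "truth"),
    )
    # gene-level truth for the differentiation design
    rng = np.random.default_rng(stage_seed(cfg.seed, "gene_truth"))
    n_induced = min(expr.get("n_induced", 0), n_genes)
    induced = rng.choice(n_genes, size=n_induced, replace=False)
    truth.induction_log2fc = np.zeros(n_genes)
    truth.induction_log2fc[induced] = expr.get("induction_log2fc", 3.0)
    dependent = rng.choice(
        induced, size=min(expr.get("n_dependent", 0), n_induced), replace=False
    ) if n_induced else np.array([], dtype=int)
    truth.dependence_log2fc = np.zeros(n_genes)
    truth.dependence_log2fc[dependent] = expr.get("dependence_log2fc", -2.0)
    return truth


def run_all(config: RunConfig, outdir: str | Path | None = None) -> RunReport:
    """Run every stage on one synthetic truth; returns the run report."""
    out = Path(outdir or config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = {
        s: stage_seed(config.seed, s)
        for s in ("truth", "gene_truth", "hic", "chip", "capturec", "expression")
    }
    metrics: dict = {}

    genome = build_genome(config)
    truth = build_truth(config, genome)
    truth.validate_against(genome)
    truth.domains.to_bed(out / "truth_domains.bed")
    truth.tads.to_bed(out / "truth_tads.bed")
    pd.DataFrame(truth.hub_pairs, columns=["domain_a", "domain_b"]).to_csv(
        out / "truth_hub_pairs.tsv", sep="\t", index=False
    )

    conditions = sorted(truth.hub_factors)
    wt, ko = _pick_conditions(truth)

    with _timed("hic"):
        maps = {}
        for cond in (wt, ko):
            raw = syn.simulate_contact_matrix(
                genome,
                truth,
                cond,
                decay_exponent=config.hic.get("decay_exponent", 1.0),
                depth=config.hic["depth"],
                seed=seeds["hic"] + (0 if cond == wt else 1),
            )
            maps[cond] = {c: hic.ice_balance(m) for c, m in raw.items()}
        apa_map = hic.apa(maps[wt], truth.loops)
        ata_map = hic.ata(maps[wt], truth.tads)
        m_wt, m_ko, m_diff = hic.polycomb_pair_aggregate(
            maps[wt],
            maps[ko],
            truth.hub_domain_pairs(),
            flank=config.hic.get("pair_flank", 200_000),
        )
        for name, amap in [
            ("apa_wt", apa_map),
            ("ata_wt", ata_map),
            ("pairs_wt", m_wt),
            ("pairs_ko", m_ko),
            ("pairs_diff", m_diff),
        ]:
            amap.to_tsv(out / f"aggregate_{name}.tsv")
        metrics["hic"] = {
            "apa_center_score": apa_map.center_score(),
            "pair_center_wt": m_wt.center_value(),
            "pair_center_ko": m_ko.center_value(),
            "pair_diff_center": m_diff.center_value(),
            "n_hub_pairs_used": m_wt.n_pairs,
        }

    with _timed("chip"):
        exp = syn.simulate_chip_experiment(
            truth,
            genome,
            conditions=(wt, ko),
            replicates=config.chip["replicates"],
            ip_efficiency=config.chip.get("ip_efficiency", 1.0),
            spikein_fraction=config.chip.get("spikein_fraction", 0.05),
            depth=config.chip["depth"],
            bin_size=config.chip.get("bin_size", 5_000),
            seed=seeds["chip"],
        )
        ips = [s for s in exp.samples if s.role == "IP"]
        corr = {}
        for cond in (wt, ko):
            reps = [s for s in ips if s.condition == cond]
            if len(reps) >= 2:
                corr[cond] = sq.replicate_correlation(
                    reps[0].target_counts, reps[1].target_counts
                )
        calibrated, factors = cal.calibrate(exp.samples, seed=seeds["chip"])
        factors.to_tsv(out / "calibration_factors.tsv")
        dom = exp.domain_bins
        sig = {
            cond: np.mean(
                [
                    s.target_counts[dom].sum()
                    for s in calibrated
                    if s.role == "IP" and s.condition == cond
                ]
            )
            for cond in (wt, ko)
        }
        raw_sig = {
            cond: np.mean(
                [
                    s.target_counts.sum()
                    for s in exp.samples
                    if s.role == "IP" and s.condition == cond
                ]
            )
            for cond in (wt, ko)
        }
        metrics["chip"] = {
            "replicate_correlation": corr,
            "uncalibrated_total_ratio": raw_sig[ko] / raw_sig[wt],
            "calibrated_domain_ratio": sig[ko] / sig[wt],
        }

    with _timed("signal"):
        metrics["signal"] = _signal_stage(out, genome, truth, calibrated, wt, ko)

    with _timed("capturec"):
        metrics["capturec"] = _capturec_stage(
            out, genome, truth, config, seeds["capturec"], wt, ko
        )

    with _timed("expression"):
        metrics["expression"] = _expression_stage(
            out, truth, config, seeds["expression"]
        )

    report = RunReport(config=asdict(config), stage_seeds=seeds, metrics=metrics)
    report.to_json(out / "report.json")
    config.to_yaml(out / "config_used.yaml")
    return report


def _pick_conditions(truth: syn.TruthSet) -> tuple[str, str]:
    """WT-like condition = largest hub factor; KO-like = smallest."""
    items = sorted(truth.hub_factors.items(), key=lambda kv: -kv[1])
    return items[0][0], items[-1][0]


def _signal_stage(out, genome, truth, calibrated, wt, ko) -> dict:
    chrom = genome.chroms[0]
    # expand the first chromosome's binned calibrated IP signal to per-bp
    per_cond = {}
    for cond in (wt, ko):
        reps = [
            s for s in calibrated if s.role == "IP" and s.condition == cond
        ]
        pooled = np.sum([s.target_counts for s in reps], axis=0).astype(float)
        per_cond[cond] = pooled
    # bin layout is identical across samples: recompute the chr1 slice
    bin_size = None
    cov = {}
    n_bins_chr = None
    for cond, pooled in per_cond.items():
        # the chip bin map tiles chromosomes in order, chr1 first
        n_total = len(pooled)
        n_bins_chr = genome.length(chrom) // _chip_bin(genome, n_total)
        bin_size = _chip_bin(genome, n_total)
        vec = np.repeat(pooled[:n_bins_chr] / bin_size, bin_size)
        cov[cond] = sq.Coverage({chrom: vec})
    anchors = truth.domains.subset(truth.domains.df["chrom"] == chrom)
    if len(anchors) == 0:
        return {"n_anchors": 0}
    half = 50_000
    mats = {
        cond: sq.build_signal_matrix(cov[cond], anchors, half_width=half,
                                     bin_size=2_000)
        for cond in (wt, ko)
    }
    ordered = {cond: sq.sort_rows(m, mats[wt]) for cond, m in mats.items()}
    for cond, m in ordered.items():
        m.to_tsv(out / f"signal_heatmap_{cond}.tsv")
    profiles = {cond: sq.metaplot(m) for cond, m in mats.items()}
    pd.DataFrame(profiles).to_csv(
        out / "signal_metaplot.tsv", sep="\t", index=False, float_format="%.10g"
    )
    return {
        "n_anchors": len(anchors),
        "metaplot_center_ratio": float(
            profiles[ko][len(profiles[ko]) // 2]
            / profiles[wt][len(profiles[wt]) // 2]
        ),
    }


def _chip_bin(genome: GenomeModel, n_total_bins: int) -> int:
    total = genome.total_length()
    return max(1, round(total / n_total_bins))


def _capturec_stage(out, genome, truth, config, seed, wt, ko) -> dict:
    frag_size = config.capturec.get("fragment_size", 500)
    fragments = syn.make_fragment_map(genome, frag_size)
    hub_doms = sorted({a for a, _ in truth.hub_pairs})
    baits = IntervalSet.from_intervals(
        [
            GenomicInterval(
                truth.domains[i].chrom,
                max(0, truth.domains[i].midpoint - 500),
                truth.domains[i].midpoint + 500,
                name=f"prom{i}",
            )
            for i in hub_doms
        ]
    )
    tables = {}
    for k, cond in enumerate((wt, ko)):
        raw = syn.simulate_capturec(
            baits, fragments, truth, condition=cond,
            depth=config.capturec["depth"], seed=seed + k,
        )
        tables[cond] = cc.normalize_table(raw, nprom=len(baits))
        tables[cond].to_tsv(out / f"capturec_{cond}.tsv")
    summary = cc.promoter_set_summary(
        tables, [f"prom{i}" for i in hub_doms], truth.domains, qualify_in="union"
    )
    summary.to_csv(out / "capturec_summary.tsv", sep="\t", index=False,
                   float_format="%.10g")
    medians = {}
    box_rows = []
    for cond in (wt, ko):
        vals = summary.loc[summary["condition"] == cond, "mean_norm_count"]
        if len(vals):
            stats = cc.boxplot_stats(vals)
            medians[cond] = stats.median
            box_rows.append({"condition": cond, **stats.__dict__})
    pd.DataFrame(box_rows).to_csv(
        out / "capturec_boxstats.tsv", sep="\t", index=False, float_format="%.10g"
    )
    return {
        "n_baits": len(baits),
        "median_norm_count": medians,
        "norm_sum_check": {
            cond: float(t.df["norm_count"].sum()) for cond, t in tables.items()
        },
    }


def _expression_stage(out, truth, config, seed) -> dict:
    e = config.expression
    n_genes, n_spike = e["n_genes"], e["n_spike_genes"]

    # global-shift scenario: spike-in vs library-size anchoring
    shift_truth = truth
    table = syn.simulate_expression(
        n_genes,
        n_spike,
        shift_truth,
        global_shift=e.get("global_shift", 0.5),
        replicates=e.get("replicates", 4),
        seed=seed,
    )
    spike_res = de.nb_test(
        table, de.spikein_size_factors(table), "WT", "KO"
    )
    lib_res = de.nb_test(table, de.libsize_size_factors(table), "WT", "KO")
    spike_res.table.to_csv(out / "de_global_shift_spikein.tsv", sep="\t",
                           float_format="%.10g")

    # differentiation scenario: dependent-gene recovery
    esc, ra_wt, ra_ko = syn.simulate_induction_experiment(
        truth, n_genes, n_spike, replicates=e.get("replicates", 4), seed=seed + 1
    )
    dependent, merged = de.induction_analysis(esc, ra_wt, ra_ko)
    merged.to_csv(out / "de_induction.tsv", sep="\t", float_format="%.10g")
    true_dep = {f"gene{i}" for i in np.flatnonzero(truth.dependent_mask)}
    called = set(dependent)
    recall = len(called & true_dep) / len(true_dep) if true_dep else float("nan")
    fdr = len(called - true_dep) / len(called) if called else 0.0
    return {
        "median_log2fc_spikein": float(
            spike_res.table.loc[spike_res.table["testable"], "log2fc"].median()
        ),
        "median_log2fc_libsize": float(
            lib_res.table.loc[lib_res.table["testable"], "log2fc"].median()
        ),
        "n_dependent_called": len(called),
        "dependent_recall": recall,
        "dependent_fdr": fdr,
    }
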