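#!/usr/bin/env python
"""Spike-in calibration of simulated ChIP samples.

Simulates IP/input pairs in which the KO sample has both halved Polycomb
occupancy and a deliberately doubled IP efficiency, then shows that the raw
signal ratio is confounded (~2x too high) while spike-in calibration
recovers the true 0.5x occupancy at domains.
"""

import argparse
from pathlib import Path

import numpy as np

from polyhub import spikein_calibration as cal, synthetic_data as syn
from polyhub.pipeline import RunConfig, build_genome, build_truth, stage_seed


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--outdir", type=Path, default=Path("results/analysis"))
    args = ap.parse_args()
    args.outdir.mkdir(parents=True, exist_ok=True)

    cfg = RunConfig(seed=args.seed)
    genome = build_genome(cfg)
    truth = build_truth(cfg, genome)
    exp = syn.simulate_chip_experiment(
        truth, genome, replicates=3, depth=1_000_000,
        ip_efficiency={"WT": 1.0, "KO": 2.0},
        seed=stage_seed(args.seed, "chip"),
    )
    calibrated, factors = cal.calibrate(exp.samples, seed=stage_seed(args.seed, "thin"))
    factors.to_tsv(args.outdir / "calibration_factors.tsv")

    dom = exp.domain_bins
    def _mean(samples, cond, bins=None):
        vals = [
            s.target_counts[bins].sum() if bins is not None else s.target_total
            for s in samples if s.role == "IP" and s.condition == cond
        ]
        return np.mean(vals)

    raw_ratio = _mean(exp.samples, "KO") / _mean(exp.samples, "WT")
    cal_ratio = _mean(calibrated, "KO", dom) / _mean(calibrated, "WT", dom)
    print(f"uncalibrated genome-wide KO/WT ratio: {raw_ratio:.3f} "
          f"(occupancy halved but IP efficiency doubled)")
    print(f"calibrated KO/WT ratio at domains:    {cal_ratio:.3f} "
          f"(true value 0.5)")
    print(f"factors written to {args.outdir / 'calibration_factors.tsv'}")


if __name__ == "__main__":
    main()
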