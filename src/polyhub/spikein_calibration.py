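"""Spike-in calibration of ChIP-seq samples.

Each ChIP library carries reads from two genomes: the target genome under
study and a foreign spike-in genome mixed in at fixed cell ratio before
immunoprecipitation. Because spike-in chromatin experiences the same IP and
sequencing as the target chromatin, the spike-in read yield measures the
per-cell recovery of each sample. Calibration randomly downsamples each
sample's target-genome reads so that all samples are anchored to a common
input-corrected spike-in coverage; after that, between-sample target signal
ratios reflect occupancy rather than IP efficiency or depth.

Factors reported per sample:

* ``r`` — spike-in ratio, spike_total / target_total;
* ``c`` — input correction, input_target_total / input_spike_total, which
  cancels variation in the spike-in cell mixing proportion;
* ``f`` — effective spike-in coverage, spike_total x c;
* ``p`` — downsampling fraction, min(f) / f, so the least-covered sample
  keeps all of its reads and no sample is ever upsampled.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .core import CalibrationError

__all__ = [
    "ChipSample",
    "CalibrationFactors",
    "compute_factors",
    "downsample",
    "calibrate",
]


@dataclass
class ChipSample:
    """Per-interval read counts of one ChIP library, split by genome.

    ``role`` is ``"IP"`` or ``"input"``; every IP names its matched input
    via ``input_id``.
    """

    sample_id: str
    condition: str
    role: str
    target_counts: np.ndarray
    spike_counts: np.ndarray
    input_id: str | None = None

    def __post_init__(self) -> None:
        self.target_counts = np.asarray(self.target_counts)
        self.spike_counts = np.asarray(self.spike_counts)
        if self.role not in ("IP", "input"):
            raise ValueError(f"role must be 'IP' or 'input', got {self.role!r}")
        if (self.target_counts < 0).any() or (self.spike_counts < 0).any():
            raise ValueError("counts must be non-negative")

    @property
    def target_total(self) -> int:
        return int(self.target_counts.sum())

    @property
    def spike_total(self) -> int:
        return int(self.spike_counts.sum())

    def to_frame(self) -> pd.DataFrame:
        """Long-format dual-genome count table (compartment, bin, count)."""
        t = pd.DataFrame(
            {
                "compartment": "target",
                "bin": np.arange(len(self.target_counts)),
                "count": self.target_counts,
            }
        )
        s = pd.DataFrame(
            {
                "compartment": "spike",
                "bin": np.arange(len(self.spike_counts)),
                "count": self.spike_counts,
            }
        )
        return pd.concat([t, s], ignore_index=True)

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(
        cls, path, sample_id: str, condition: str, role: str, input_id: str | None = None
    ) -> "ChipSample":
        df = pd.read_csv(path, sep="\t")
        target = df.loc[df["compartment"] == "target", "count"].to_numpy()
        spike = df.loc[df["compartment"] == "spike", "count"].to_numpy()
        return cls(sample_id, condition, role, target, spike, input_id)


@dataclass
class CalibrationFactors:
    """Per-sample calibration factors, keyed by IP sample id."""

    r: dict[str, float] = field(default_factory=dict)
    c: dict[str, float] = field(default_factory=dict)
    f: dict[str, float] = field(default_factory=dict)
    p: dict[str, float] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        ids = sorted(self.r)
        return pd.DataFrame(
            {
                "sample": ids,
                "r": [self.r[s] for s in ids],
                "c": [self.c[s] for s in ids],
                "f": [self.f[s] for s in ids],
                "p": [self.p[s] for s in ids],
            }
        )

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False, float_format="%.10g")


def _pair_samples(samples: list[ChipSample]) -> list[tuple[ChipSample, ChipSample]]:
    inputs = {s.sample_id: s for s in samples if s.role == "input"}
    pairs = []
    for s in samples:
        if s.role != "IP":
            continue
        if s.input_id is None or s.input_id not in inputs:
            raise CalibrationError(f"IP sample {s.sample_id!r} has no matched input")
        pairs.append((s, inputs[s.input_id]))
    if not pairs:
        raise CalibrationError("no IP samples to calibrate")
    return pairs


def compute_factors(samples: list[ChipSample]) -> CalibrationFactors:
    """Derive spike-in ratios, input corrections and downsampling fractions.

    The downsampling fraction anchors every sample to the input-corrected
    spike-in coverage of the least-covered sample, so exactly one sample has
    p = 1 and all others are thinned.
    """
    pairs = _pair_samples(samples)
    factors = CalibrationFactors()
    for ip, inp in pairs:
        if ip.spike_total == 0 or inp.spike_total == 0:
            raise CalibrationError(
                f"sample {ip.sample_id!r}: zero spike-in total, calibration undefined"
            )
        if ip.target_total == 0 or inp.target_total == 0:
            raise CalibrationError(
                f"sample {ip.sample_id!r}: zero target total, calibration undefined"
            )
        r = ip.spike_total / ip.target_total
        c = inp.target_total / inp.spike_total
        factors.r[ip.sample_id] = r
        factors.c[ip.sample_id] = c
        factors.f[ip.sample_id] = ip.spike_total * c
    f_ref = min(factors.f.values())
    for sid, f in factors.f.items():
        factors.p[sid] = f_ref / f
    return factors


def downsample(sample: ChipSample, fraction: float, seed: int) -> ChipSample:
    """Binomially thin the target-genome counts of one sample.

    Per-interval binomial thinning with retention probability ``fraction``
    is expectation-equivalent to retaining each read independently. The
    spike-in compartment is never modified.
    """
    if not 0 < fraction <= 1:
        raise ValueError(f"fraction must be in (0, 1], got {fraction}")
    if fraction == 1:
        return replace(
            sample,
            target_counts=sample.target_counts.copy(),
            spike_counts=sample.spike_counts.copy(),
        )
    rng = np.random.default_rng(seed)
    thinned = rng.binomial(sample.target_counts.astype(np.int64), fraction)
    return replace(
        sample, target_counts=thinned, spike_counts=sample.spike_counts.copy()
    )


def calibrate(
    samples: list[ChipSample], seed: int, skip: bool = False
) -> tuple[list[ChipSample], CalibrationFactors | None]:
    """Compute factors and thin every IP sample accordingly.

    ``skip=True`` passes samples through untouched (some ChIP experiments,
    e.g. epitope-tag pulldowns without spike-in chromatin, are analysed
    uncalibrated).
    """
    if skip:
        return list(samples), None
    factors = compute_factors(samples)
    out = []
    for i, s in enumerate(sorted(samples, key=lambda s: s.sample_id)):
        if s.role == "IP":
            # seed derived from sample id so the result is invariant to the
            # order samples are supplied in
            sub_seed = (seed + _stable_hash(s.sample_id)) % (2**31)
            out.append(downsample(s, factors.p[s.sample_id], sub_seed))
        else:
            out.append(s)
    return out, factors


def _stable_hash(text: str) -> int:
    import zlib

    return zlib.crc32(text.encode())
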