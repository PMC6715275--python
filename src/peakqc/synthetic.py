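"""Synthetic meta-sets with known ground truth.

The generator emulates the capture-recapture situation the QC metrics
assume: ``n_true`` genuine binding regions are placed non-overlapping on a
linear genome; each of the k simulated datasets independently *detects*
each genuine region with its own probability (Bernoulli per dataset, so a
region's composition is binomial, truncated at zero once unobserved
regions drop out), and additionally contributes a fixed number of
spurious peaks placed to overlap nothing — such peaks are orphans by
construction, mirroring the assumption that nearly all false positives
are orphans.

Detected copies may be jittered: start and end are shifted independently
by a uniform integer in [-jitter, +jitter]. Jitter is capped below the
minimum peak width so every jittered copy still overlaps its true region,
and true regions are separated by more than twice the jitter so copies of
neighbouring regions can never touch — composition bookkeeping stays
exact under jitter.

Everything is driven by a single integer seed through
``numpy.random.default_rng``; identical configs give bit-identical
output.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .errors import SimulationCapacityError
from .peak_io import GenomicInterval, MetaSet, PeakDataset, write_bed

_MAX_FP_RETRIES = 1000


@dataclass
class SimulationConfig:
    """Parameters of one simulated meta-set.

    Defaults model a mid-sized TF experiment scored by four peak callers
    of good but unequal sensitivity, with no spurious peaks: 2000 genuine
    regions of ~200 bp (about the usual ChIP-Seq peak scale) on a 100 Mb
    genome, detection probabilities around 0.8, and 20 bp of caller
    jitter.
    """

    n_true: int = 2000
    detection_prob: tuple[float, ...] = (0.85, 0.80, 0.75, 0.80)
    fp_count: tuple[int, ...] = (0, 0, 0, 0)
    genome_length: int = 100_000_000
    peak_width_mean: float = 200.0
    peak_width_sd: float = 40.0
    peak_width_min: int = 50
    jitter: int = 20
    chrom: str = "chrS"
    seed: int = 0

    @property
    def k(self) -> int:
        return len(self.detection_prob)

    def __post_init__(self):
        if len(self.fp_count) != self.k:
            raise ValueError("fp_count must have one entry per dataset")
        if not all(0.0 < p <= 1.0 for p in self.detection_prob):
            raise ValueError("detection probabilities must lie in (0, 1]")
        if any(c < 0 for c in self.fp_count):
            raise ValueError("fp_count entries must be non-negative")
        if self.jitter < 0:
            raise ValueError("jitter must be non-negative")
        if self.jitter >= self.peak_width_min:
            raise ValueError(
                "jitter must be smaller than the minimum peak width so "
                "jittered copies keep overlapping their true region"
            )
        # feasibility: regions plus inter-region gaps must fit the genome
        gap = 2 * self.jitter + 1
        needed = self.n_true * (self.peak_width_mean + gap)
        if needed > 0.9 * self.genome_length:
            raise SimulationCapacityError(
                f"~{needed:.3g} bp needed for {self.n_true} regions but "
                f"genome_length is {self.genome_length}; increase "
                "genome_length"
            )


@dataclass
class GroundTruth:
    """What the simulator knows and the estimators must recover."""

    true_regions: list[GenomicInterval]
    per_dataset_detected: list[list[int]]  # indices into true_regions
    per_dataset_fp: list[list[GenomicInterval]]

    @property
    def n_true(self) -> int:
        return len(self.true_regions)

    def to_json(self, path: str | Path) -> None:
        d = {
            "n_true": self.n_true,
            "true_regions": [[iv.chrom, iv.start, iv.end]
                             for iv in self.true_regions],
            "per_dataset_detected": self.per_dataset_detected,
            "per_dataset_fp": [[[iv.chrom, iv.start, iv.end] for iv in fps]
                               for fps in self.per_dataset_fp],
        }
        with open(path, "w") as fh:
            json.dump(d, fh)
            fh.write("\n")


def _sample_widths(rng: np.random.Generator,
                   config: SimulationConfig, size: int) -> np.ndarray:
    w = rng.normal(config.peak_width_mean, config.peak_width_sd, size=size)
    return np.maximum(np.round(w).astype(int), config.peak_width_min)


def _place_true_regions(rng: np.random.Generator,
                        config: SimulationConfig) -> list[GenomicInterval]:
    """Place n_true non-overlapping regions uniformly.

    Draws sorted uniform gap positions over the slack left after summing
    widths and mandatory gaps — equivalent to uniform placement
    conditioned on non-overlap, with no rejection loop.
    """
    widths = _sample_widths(rng, config, config.n_true)
    min_gap = 2 * config.jitter + 1  # jittered copies can never touch
    slack = config.genome_length - int(widths.sum()) - min_gap * (config.n_true - 1)
    if slack <= 0:
        raise SimulationCapacityError(
            "genome_length too small for the sampled peak widths; "
            "increase genome_length"
        )
    cuts = np.sort(rng.integers(0, slack, size=config.n_true))
    starts = cuts + np.concatenate(([0], np.cumsum(widths[:-1] + min_gap)))
    return [
        GenomicInterval(config.chrom, int(s), int(s + w))
        for s, w in zip(starts, widths)
    ]


def _jitter_copy(rng: np.random.Generator, iv: GenomicInterval,
                 config: SimulationConfig) -> GenomicInterval:
    if config.jitter == 0:
        return iv
    ds = int(rng.integers(-config.jitter, config.jitter + 1))
    de = int(rng.integers(-config.jitter, config.jitter + 1))
    start = max(0, iv.start + ds)
    end = iv.end + de
    if end - start < config.peak_width_min:
        end = start + config.peak_width_min
    return GenomicInterval(iv.chrom, start, end)


def _place_false_positives(rng: np.random.Generator,
                           config: SimulationConfig,
                           occupied: list[tuple[int, int]],
                           count: int) -> list[GenomicInterval]:
    """Rejection-sample spurious peaks overlapping nothing placed so far.

    ``occupied`` is mutated in place; margin keeps FPs clear of jittered
    detected copies of the true regions.
    """
    out: list[GenomicInterval] = []
    margin = config.jitter
    for _ in range(count):
        for attempt in range(_MAX_FP_RETRIES):
            width = int(_sample_widths(rng, config, 1)[0])
            start = int(rng.integers(0, config.genome_length - width))
            end = start + width
            if all(start - margin >= oe or end + margin <= os
                   for os, oe in occupied):
                occupied.append((start, end))
                out.append(GenomicInterval(config.chrom, start, end))
                break
        else:
            raise SimulationCapacityError(
                f"could not place a spurious peak after {_MAX_FP_RETRIES} "
                "attempts; increase genome_length"
            )
    return out


def simulate_meta_set(config: SimulationConfig) -> tuple[MetaSet, GroundTruth]:
    """Simulate one meta-set and its ground truth, deterministically."""
    rng = np.random.default_rng(config.seed)
    true_regions = _place_true_regions(rng, config)

    detected: list[list[int]] = []
    datasets: list[PeakDataset] = []
    for d_idx, p in enumerate(config.detection_prob):
        hits = np.flatnonzero(rng.random(config.n_true) < p)
        detected.append(hits.tolist())
        ivs = [_jitter_copy(rng, true_regions[t], config) for t in hits]
        datasets.append(PeakDataset(label=f"caller{d_idx + 1}", intervals=ivs))

    occupied = [(iv.start, iv.end) for iv in true_regions]
    per_fp: list[list[GenomicInterval]] = []
    for d_idx, count in enumerate(config.fp_count):
        fps = _place_false_positives(rng, config, occupied, count)
        per_fp.append(fps)
        datasets[d_idx].intervals.extend(fps)

    truth = GroundTruth(
        true_regions=true_regions,
        per_dataset_detected=detected,
        per_dataset_fp=per_fp,
    )
    return MetaSet(datasets), truth


def write_simulation(meta: MetaSet, truth: GroundTruth,
                     out_dir: str | Path) -> list[Path]:
    """Write one BED per dataset plus a ground-truth JSON; returns paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for dataset in meta.datasets:
        p = out_dir / f"{dataset.label}.bed"
        write_bed(dataset, p)
        paths.append(p)
    truth.to_json(out_dir / "ground_truth.json")
    return paths


def recovery_experiment(config: SimulationConfig,
                        replicates: int,
                        threshold: float = 2.0) -> dict:
    """Repeatedly simulate + assess; summarize estimator bias.

    Replicate r uses seed ``config.seed + r``. Returns means and standard
    deviations of the N estimate, FPCM and per-dataset FNCM across
    replicates, alongside the ground-truth n_true and detection
    probabilities they should track.
    """
    from dataclasses import replace

    from .qc_metrics import assess

    if replicates < 2:
        raise ValueError("recovery_experiment needs >= 2 replicates")
    n_est, fpcm_vals = [], []
    fncm_vals: dict[str, list[float]] = {}
    branches = []
    for r in range(replicates):
        meta, _ = simulate_meta_set(replace(config, seed=config.seed + r))
        report = assess(meta, threshold=threshold)
        n_est.append(report.fncm.n_estimate)
        fpcm_vals.append(report.fpcm.fpcm)
        branches.append(report.fncm.branch)
        for label, v in report.fncm.per_dataset.items():
            fncm_vals.setdefault(label, []).append(v)
    return {
        "replicates": replicates,
        "n_true": config.n_true,
        "detection_prob": dict(
            zip(fncm_vals.keys(), config.detection_prob)),
        "n_estimate_mean": float(np.mean(n_est)),
        "n_estimate_sd": float(np.std(n_est, ddof=1)),
        "fpcm_mean": float(np.mean(fpcm_vals)),
        "fpcm_sd": float(np.std(fpcm_vals, ddof=1)),
        "fncm_mean": {lbl: float(np.mean(v)) for lbl, v in fncm_vals.items()},
        "fncm_sd": {lbl: float(np.std(v, ddof=1))
                    for lbl, v in fncm_vals.items()},
        "branches": branches,
    }
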