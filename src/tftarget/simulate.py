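"""Seeded synthetic datasets with planted direct targets.

Emulates the structure of a ChIP-seq + perturbation-expression experiment:
transcripts scattered uniformly over a small genome, a subset of them
planted as direct targets that receive TSS-proximal binding peaks (offsets
from a truncated exponential, so binding concentrates near the start site),
background peaks scattered genome-wide, and signed expression statistics
drawn standard-normal with the planted targets' mean shifted up (inducing),
down (repressive), or not at all (null). The truth table of planted ids
makes recovery measurable end to end.

A single pseudo-random stream keyed by the seed drives everything, so
identical configs give byte-identical output files.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as gio

DIRECTIONS = ("inducing", "repressive", "null")

_TRANSCRIPT_LEN = (1_000, 50_000)  # bp, uniform
_PEAK_WIDTH = (200, 600)  # bp, uniform


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for one synthetic dataset.

    effect_size is the mean shift, in standard-deviation units, of the
    planted targets' expression statistic; decay_D is the half-width (bp)
    within which planted peak midpoints fall.
    """

    n_transcripts: int = 2_000
    n_chromosomes: int = 5
    chrom_length: int = 100_000_000
    n_target: int = 200
    peaks_per_target: float = 3.0
    background_peaks: int = 2_000
    effect_size: float = 2.0
    decay_D: int = 100_000
    direction: str = "inducing"
    seed: int = 0

    def __post_init__(self):
        if self.direction not in DIRECTIONS:
            raise ValueError(f"direction must be one of {DIRECTIONS}, got {self.direction!r}")
        if self.n_target > self.n_transcripts:
            raise ValueError("n_target cannot exceed n_transcripts")
        if min(self.n_transcripts, self.n_chromosomes, self.n_target,
               self.background_peaks) < 0 or self.peaks_per_target < 0:
            raise ValueError("all counts must be >= 0")
        if self.chrom_length < 2 * _TRANSCRIPT_LEN[1]:
            raise ValueError(
                f"chrom_length {self.chrom_length} too small to place transcripts "
                f"(need >= {2 * _TRANSCRIPT_LEN[1]})"
            )


@dataclass
class SimulatedDataset:
    """In-memory result of one simulation; `write` emits the four files."""

    genes: pd.DataFrame  # gene-model table (internal 1-based coordinates)
    peaks: pd.DataFrame
    expression: pd.DataFrame
    truth: pd.DataFrame  # planted target ids
    config: SimConfig = field(repr=False, default=None)

    def write(self, outdir: str | os.PathLike) -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "genes": outdir / "genes.bed",
            "peaks": outdir / "peaks.bed",
            "expression": outdir / "expression.tsv",
            "truth": outdir / "truth.tsv",
        }
        gio.write_gene_models(self.genes, paths["genes"])
        gio.write_peaks(self.peaks, paths["peaks"])
        gio.write_expression(self.expression, paths["expression"])
        self.truth.to_csv(paths["truth"], sep="\t", index=False)
        return paths


def _truncated_exponential(rng: np.random.Generator, scale: float, upper: float, size: int):
    """Exponential(scale) conditioned on < upper, by inverse CDF."""
    u = rng.random(size)
    return -scale * np.log1p(-u * (1.0 - np.exp(-upper / scale)))


def simulate_dataset(config: SimConfig) -> SimulatedDataset:
    """Generate one dataset (gene models, peaks, expression, truth)."""
    rng = np.random.default_rng(config.seed)
    n = config.n_transcripts

    # transcripts: uniform placement, random strand
    lengths = rng.integers(*_TRANSCRIPT_LEN, size=n, endpoint=True)
    chrom_idx = rng.integers(0, config.n_chromosomes, size=n)
    starts = rng.integers(1, config.chrom_length - _TRANSCRIPT_LEN[1], size=n)
    strands = np.where(rng.random(n) < 0.5, "+", "-")
    region_ids = np.array([f"T{i:05d}" for i in range(n)], dtype=object)
    genes = pd.DataFrame(
        {
            "chrom": np.array([f"chr{c + 1}" for c in chrom_idx], dtype=object),
            "start": starts,
            "end": starts + lengths - 1,
            "region_id": region_ids,
            "score": 0,
            "strand": strands,
        }
    )

    planted = np.sort(rng.choice(n, size=config.n_target, replace=False))
    tss = np.where(strands == "-", genes["end"].to_numpy(), starts)

    # planted peaks: Poisson counts, TSS-proximal truncated-exponential offsets
    rows = []
    counts = rng.poisson(config.peaks_per_target, size=config.n_target)
    for t_idx, count in zip(planted, counts):
        if count == 0:
            continue
        offsets = _truncated_exponential(rng, config.decay_D / 4.0, config.decay_D, count)
        signs = np.where(rng.random(count) < 0.5, 1, -1)
        mids = np.clip(tss[t_idx] + (signs * offsets).astype(np.int64), 1, config.chrom_length)
        widths = rng.integers(*_PEAK_WIDTH, size=count, endpoint=True)
        for mid, w in zip(mids, widths):
            rows.append((genes["chrom"].iloc[t_idx], max(1, mid - w // 2), mid + w // 2))

    # background peaks: uniform genome-wide
    bg_chrom = rng.integers(0, config.n_chromosomes, size=config.background_peaks)
    bg_mid = rng.integers(1, config.chrom_length, size=config.background_peaks)
    bg_width = rng.integers(*_PEAK_WIDTH, size=config.background_peaks, endpoint=True)
    for c, mid, w in zip(bg_chrom, bg_mid, bg_width):
        rows.append((f"chr{c + 1}", max(1, mid - w // 2), mid + w // 2))

    peaks = pd.DataFrame(rows, columns=["chrom", "start", "end"])
    peaks["peak_id"] = [f"peak_{i + 1}" for i in range(len(peaks))]

    # expression: standard-normal noise, planted targets shifted
    stats = rng.normal(0.0, 1.0, size=n)
    if config.direction == "inducing":
        stats[planted] += config.effect_size
    elif config.direction == "repressive":
        stats[planted] -= config.effect_size
    expression = pd.DataFrame(
        {
            "region_id": region_ids,
            "stat": stats,
            "symbol": np.array([f"G{i:05d}" for i in range(n)], dtype=object),
        }
    )

    truth = pd.DataFrame({"region_id": region_ids[planted]})
    return SimulatedDataset(
        genes=genes, peaks=peaks, expression=expression, truth=truth, config=config
    )
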