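import numpy as np
import pandas as pd
import pytest

from tftarget.potential import decay


def make_windows(rows):
    """rows: (region_id, chrom, start, end, strand, tss)"""
    return pd.DataFrame(
        rows, columns=["region_id", "chrom", "start", "end", "strand", "tss"]
    )


def make_peaks(rows):
    """rows: (chrom, start, end, peak_id)"""
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "peak_id"])


def brute_force_pairs(peaks: pd.DataFrame, windows: pd.DataFrame, D: int) -> pd.DataFrame:
    """All-pairs overlap oracle: a pair iff same chromosome and the closed
    intervals share >= 1 bp; distance from the peak midpoint, strand-signed."""
    rows = []
    for p in peaks.itertuples():
        mid = (p.start + p.end) // 2
        for w in windows.itertuples():
            if p.chrom != w.chrom:
                continue
            if p.end < w.start or p.start > w.end:
                continue
            dist = mid - w.tss
            if w.strand == "-":
                dist = -dist
            rows.append((p.peak_id, w.region_id, dist, decay(abs(dist), D)))
    out = pd.DataFrame(rows, columns=["peak_id", "region_id", "distance", "score"])
    out["absdist"] = out["distance"].abs()
    out = out.sort_values(
        ["region_id", "absdist", "distance", "peak_id"], kind="stable"
    )
    return out.drop(columns="absdist").reset_index(drop=True)


def random_fixture(rng: np.random.Generator, n_peaks: int, n_regions: int, D: int = 1_000):
    """A random peak/window fixture on a short 2-chromosome genome, dense
    enough that overlaps, multi-window peaks and empty windows all occur."""
    genome = 40 * D
    chroms = ["chr1", "chr2"]
    w_chrom = rng.choice(chroms, n_regions)
    tss = rng.integers(1, genome, n_regions)
    strand = rng.choice(["+", "-", "."], n_regions)
    minus = strand == "-"
    start = np.where(minus, tss - D + 1, tss - D)
    end = np.where(minus, tss + D, tss + D - 1)
    keep = start >= 1  # avoid clipping so width stays exactly 2D
    windows = make_windows(
        list(
            zip(
                [f"r{i}" for i in range(n_regions)],
                w_chrom[keep], start[keep], end[keep], strand[keep], tss[keep],
            )
        )
    )
    windows = windows[["region_id", "chrom", "start", "end", "strand", "tss"]]
    p_chrom = rng.choice(chroms, n_peaks)
    p_start = rng.integers(1, genome, n_peaks)
    p_len = rng.integers(1, 3 * D, n_peaks)
    peaks = make_peaks(
        list(
            zip(
                p_chrom, p_start, p_start + p_len, [f"p{i}" for i in range(n_peaks)]
            )
        )
    )
    return peaks, windows


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def small_sim():
    """One small planted-activator dataset shared across fast tests."""
    from tftarget.simulate import SimConfig, simulate_dataset

    return simulate_dataset(
        SimConfig(
            n_transcripts=300,
            n_chromosomes=2,
            chrom_length=20_000_000,
            n_target=50,
            background_peaks=300,
            seed=7,
        )
    )
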