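"""Regulatory potential: TSS windows, peak assignment, distance decay.

The regulatory potential of a factor on a transcript is the sum, over all
ChIP peaks overlapping a window of half-width D centred on the transcription
start site (TSS), of an exponentially decayed distance score

    score = exp(-(0.5 + 4 * d / D))

where d is the absolute distance between the peak midpoint and the TSS. The
score is e^-0.5 for a peak sitting on the TSS and e^-4.5 at the window edge,
for any choice of D. Normalising the decay by the chosen D keeps the edge
score fixed when the analysis is re-run at a different allowed distance
(e.g., 50 kb instead of the default 100 kb).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

logger = logging.getLogger("tftarget")

WINDOW_COLUMNS = ["region_id", "chrom", "start", "end", "strand", "tss"]
ASSOC_COLUMNS = ["peak_id", "region_id", "distance", "score"]
POTENTIAL_COLUMNS = ["region_id", "potential", "n_peaks"]


def decay(d, D: int):
    """Transform an absolute peak-TSS distance into a peak score.

    Strictly decreasing in ``d``; not capped for d > D, since a peak that
    overlaps the window edge can have its midpoint slightly outside it.
    Accepts scalars or arrays.
    """
    if D <= 0:
        raise ValueError(f"window half-width D must be positive, got {D}")
    d = np.asarray(d, dtype=float)
    if np.any(d < 0):
        raise ValueError("distance must be non-negative (pass absolute distances)")
    out = np.exp(-(0.5 + 4.0 * d / D))
    return out if out.ndim else float(out)


def resize_regions(regions: pd.DataFrame, D: int) -> pd.DataFrame:
    """Build one TSS-centred window of width exactly 2*D per region.

    The TSS is the region start on the + (or strandless) strand and the
    region end on the - strand. Windows are [tss-D, tss+D-1] on +/. and
    [tss-D+1, tss+D] on -, so both conventions give width 2*D with the TSS
    inside. Windows are clipped at coordinate 1 on the left (logged), never
    dropped.
    """
    if D < 1:
        raise ValueError(f"window half-width D must be >= 1, got {D}")
    minus = (regions["strand"] == "-").to_numpy()
    start = regions["start"].to_numpy(dtype=np.int64)
    end = regions["end"].to_numpy(dtype=np.int64)
    tss = np.where(minus, end, start)
    win_start = np.where(minus, tss - D + 1, tss - D)
    win_end = np.where(minus, tss + D, tss + D - 1)
    clipped = win_start < 1
    if clipped.any():
        logger.info("clipped %d windows at the chromosome start", int(clipped.sum()))
        win_start = np.maximum(win_start, 1)
    return pd.DataFrame(
        {
            "region_id": regions["region_id"].to_numpy(),
            "chrom": regions["chrom"].to_numpy(),
            "start": win_start,
            "end": win_end,
            "strand": regions["strand"].to_numpy(),
            "tss": tss,
        }
    )


def associate_peaks(peaks: pd.DataFrame, windows: pd.DataFrame, D: int) -> pd.DataFrame:
    """Assign peaks to every window they overlap by >= 1 bp.

    A peak overlapping k windows yields k (peak, window) pairs. The overlap
    test uses the whole peak interval; the distance uses the peak midpoint
    floor((start+end)/2), signed so positive means downstream of the TSS
    (midpoint - tss, negated on the - strand). Output is sorted by
    (region_id, |distance|).
    """
    trees: dict[str, IntervalTree] = {}
    for chrom, sub in windows.groupby("chrom", sort=False):
        tree = IntervalTree()
        for idx, s, e in zip(sub.index, sub["start"], sub["end"]):
            tree.addi(int(s), int(e) + 1, idx)  # half-open for the tree
        trees[chrom] = tree

    w_tss = windows["tss"].to_numpy(dtype=np.int64)
    w_minus = (windows["strand"] == "-").to_numpy()
    w_id = windows["region_id"].to_numpy()

    peak_ids, region_ids, distances = [], [], []
    for chrom, p_start, p_end, p_id in zip(
        peaks["chrom"], peaks["start"], peaks["end"], peaks["peak_id"]
    ):
        tree = trees.get(chrom)
        if tree is None:
            continue
        mid = (int(p_start) + int(p_end)) // 2
        for hit in tree.overlap(int(p_start), int(p_end) + 1):
            idx = hit.data
            dist = mid - int(w_tss[idx])
            if w_minus[idx]:
                dist = -dist
            peak_ids.append(p_id)
            region_ids.append(w_id[idx])
            distances.append(dist)

    assoc = pd.DataFrame(
        {
            "peak_id": pd.Series(peak_ids, dtype=object),
            "region_id": pd.Series(region_ids, dtype=object),
            "distance": pd.Series(distances, dtype=np.int64),
        }
    )
    assoc["score"] = decay(np.abs(assoc["distance"].to_numpy()), D)
    # (region_id, |distance|) ordering, with (distance, peak_id) tie-breaks
    # so the output is deterministic
    assoc["_absdist"] = assoc["distance"].abs()
    assoc = assoc.sort_values(
        ["region_id", "_absdist", "distance", "peak_id"], kind="stable"
    ).reset_index(drop=True)
    return assoc[ASSOC_COLUMNS]


def regulatory_potential(assoc: pd.DataFrame, windows: pd.DataFrame) -> pd.DataFrame:
    """Sum peak scores per region; zero-peak regions get potential 0.

    Every assoc region_id must exist among the windows (orphans are an
    error); output carries one record per window in window order.
    """
    known = set(windows["region_id"])
    orphans = set(assoc["region_id"]) - known
    if orphans:
        raise ValueError(f"associated peaks reference unknown region ids: {sorted(orphans)[:5]}")
    grouped = assoc.groupby("region_id", sort=False).agg(
        potential=("score", "sum"), n_peaks=("score", "size")
    )
    out = grouped.reindex(windows["region_id"]).reset_index()
    out["potential"] = pd.to_numeric(out["potential"]).fillna(0.0)
    out["n_peaks"] = pd.to_numeric(out["n_peaks"]).fillna(0).astype(int)
    return out[POTENTIAL_COLUMNS]
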