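"""Top-N concordance between ranked target lists.

Concordance at N is the fraction of identifiers shared between the first N
entries of two ranked lists; plotted against N it shows how far down the
rankings two runs of the analysis agree. Lists are compared at the
transcript level by default; ``by="symbol"`` collapses each list to its
best-ranked transcript per gene symbol first.
"""

from __future__ import annotations

from typing import NamedTuple, Sequence

import pandas as pd


class ConcordancePoint(NamedTuple):
    N: int
    fraction: float


def _check_unique(ids: Sequence[str], which: str) -> list:
    ids = list(ids)
    if len(set(ids)) != len(ids):
        seen, dup = set(), None
        for i in ids:
            if i in seen:
                dup = i
                break
            seen.add(i)
        raise ValueError(f"duplicate id {dup!r} in ranked list {which}")
    return ids


def concordance_at(a: Sequence[str], b: Sequence[str], N: int) -> ConcordancePoint:
    """Fraction of shared ids between the top N of two ranked lists."""
    a, b = _check_unique(a, "a"), _check_unique(b, "b")
    if not 1 <= N <= min(len(a), len(b)):
        raise ValueError(f"N must be in [1, {min(len(a), len(b))}], got {N}")
    shared = len(set(a[:N]) & set(b[:N]))
    return ConcordancePoint(N=N, fraction=shared / N)


def concordance_curve(
    a: Sequence[str], b: Sequence[str], N_max: int = 10_000
) -> pd.DataFrame:
    """Concordance at every N from 1 to N_max, incrementally in O(N_max).

    N_max beyond the shorter list is clipped. Returns a DataFrame with
    columns N, fraction.
    """
    import logging

    a, b = _check_unique(a, "a"), _check_unique(b, "b")
    limit = min(len(a), len(b))
    if N_max > limit:
        logging.getLogger("tftarget").warning(
            "N_max %d exceeds list length; clipping to %d", N_max, limit
        )
        N_max = limit
    if N_max < 1:
        raise ValueError("ranked lists must be non-empty")
    seen_a: set = set()
    seen_b: set = set()
    shared = 0
    fractions = []
    for n in range(N_max):
        x, y = a[n], b[n]
        if x == y:
            shared += 1
        else:
            if x in seen_b:
                shared += 1
            if y in seen_a:
                shared += 1
        seen_a.add(x)
        seen_b.add(y)
        fractions.append(shared / (n + 1))
    return pd.DataFrame({"N": range(1, N_max + 1), "fraction": fractions})


def ranked_ids(
    targets: pd.DataFrame, direction: str = "up", by: str = "transcript"
) -> list:
    """Extract the ordered id list from a target table for comparison.

    Orders by the rank product of the requested direction with a stable
    region_id tie-break, so curves are deterministic. ``by="symbol"`` keeps
    the best-ranked transcript per symbol and returns symbols.
    """
    col = {"up": "rp_up", "down": "rp_down"}.get(direction)
    if col is None:
        raise ValueError(f"direction must be 'up' or 'down', got {direction!r}")
    ordered = targets.sort_values(
        [col, "region_id"], kind="stable"
    ).reset_index(drop=True)
    if by == "transcript":
        return list(ordered["region_id"])
    if by == "symbol":
        if "symbol" not in ordered.columns:
            raise ValueError("target table has no 'symbol' column")
        return list(ordered.drop_duplicates("symbol", keep="first")["symbol"])
    raise ValueError(f"by must be 'transcript' or 'symbol', got {by!r}")
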