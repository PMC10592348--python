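"""Rank products of regulatory potential and signed expression statistics.

Transcripts are ranked twice: by regulatory potential (descending, rank 1 =
strongest binding evidence) and by the signed differential-expression
statistic (descending for the up direction, ascending for down). The rank
product in a direction is

    rp_dir = (rank_potential * rank_dir) / n**2

i.e., the product of the two fractional ranks, so rp lies in [1/n^2, 1] and
smaller means stronger direct-target evidence. Ranking operates at the
transcript level; no per-gene collapsing.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

logger = logging.getLogger("tftarget")

GROUP_UP = "up"
GROUP_DOWN = "down"
GROUP_NONE = "none"


def rank_values(x, direction: str = "descending") -> np.ndarray:
    """Rank values 1..n with ties broken by first occurrence (stable sort).

    ``descending`` gives rank 1 to the largest value. The result is always a
    permutation of 1..n, even with ties ("different values are given to tied
    features").
    """
    x = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("values to rank must be finite")
    if direction == "descending":
        order = np.argsort(-x, kind="stable")
    elif direction == "ascending":
        order = np.argsort(x, kind="stable")
    else:
        raise ValueError(f"direction must be 'ascending' or 'descending', got {direction!r}")
    ranks = np.empty(len(x), dtype=np.int64)
    ranks[order] = np.arange(1, len(x) + 1)
    return ranks


def rank_products(
    potentials: pd.DataFrame,
    expression: pd.DataFrame,
    direction: str = "up",
) -> pd.DataFrame:
    """Join potentials with expression on region_id and compute rank products.

    Regions missing from either side are dropped with a logged count. Rows
    are sorted by region_id before ranking so that the stable tie rule makes
    the result invariant to input row order, then output best-first by the
    rank product of the requested direction.
    """
    if direction not in (GROUP_UP, GROUP_DOWN):
        raise ValueError(f"direction must be 'up' or 'down', got {direction!r}")
    joined = potentials.merge(expression, on="region_id", how="inner")
    n = len(joined)
    if n == 0:
        raise ValueError(
            "join of potentials and expression on column 'region_id' produced 0 rows"
        )
    dropped = (len(potentials) - n) + (len(expression) - n)
    if dropped:
        logger.info("dropped %d records unmatched across potential/expression join", dropped)
    if n < 2:
        raise ValueError(f"need at least 2 joined records to rank, got {n}")

    joined = joined.sort_values("region_id", kind="stable").reset_index(drop=True)
    joined["rank_potential"] = rank_values(joined["potential"], "descending")
    joined["rank_up"] = rank_values(joined["stat"], "descending")
    joined["rank_down"] = rank_values(joined["stat"], "ascending")
    joined["rp_up"] = joined["rank_potential"] * joined["rank_up"] / float(n) ** 2
    joined["rp_down"] = joined["rank_potential"] * joined["rank_down"] / float(n) ** 2
    sort_col = "rp_up" if direction == GROUP_UP else "rp_down"
    return joined.sort_values(sort_col, kind="stable").reset_index(drop=True)


def _tail_count(q: float, n: int) -> int:
    """Number of members in a tail of fraction q of n, nearest-rank style."""
    k = q * n
    if abs(k - round(k)) < 1e-9:  # guard 0.2*2000 = 400.0000...6
        return int(round(k))
    return int(np.ceil(k))


def assign_groups(stats, lower_q: float = 0.1, upper_q: float = 0.9) -> np.ndarray:
    """Label each statistic up/down/none by empirical quantile cutoffs.

    The down group is every stat at or below the nearest-rank lower_q
    quantile (the ceil(lower_q*n)-th smallest value); the up group mirrors
    it from the top with fraction 1-upper_q. Ties at a threshold enlarge the
    tail. If all stats are identical the grouping is degenerate and every
    record is labelled none, with a warning.
    """
    if not (0 <= lower_q < upper_q <= 1):
        raise ValueError(
            f"need 0 <= lower_q < upper_q <= 1, got ({lower_q}, {upper_q})"
        )
    stats = np.asarray(stats, dtype=float)
    n = len(stats)
    labels = np.full(n, GROUP_NONE, dtype=object)
    if n == 0:
        return labels
    if np.all(stats == stats[0]):
        logger.warning("all statistics identical; degenerate grouping, labelling all 'none'")
        return labels
    ordered = np.sort(stats)
    k_down = _tail_count(lower_q, n)
    k_up = _tail_count(1.0 - upper_q, n)
    if k_down > 0:
        labels[stats <= ordered[k_down - 1]] = GROUP_DOWN
    if k_up > 0:
        labels[stats >= ordered[n - k_up]] = GROUP_UP
    return labels
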