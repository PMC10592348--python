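"""Statistical testing of target groups and prediction of factor function.

The transcripts are grouped into up-, down- and none-regulated by quantile
cutoffs on the signed expression statistic. If the factor induces its
targets, the up group should be shifted toward better (smaller) regulatory
potential ranks than the none group; a repressor shifts the down group. Each
regulated group is compared against the none group with a two-sample,
two-sided Kolmogorov-Smirnov test on the potential ranks (KS is invariant
under the rank transform, so this equals testing the raw potentials), and
the direction of the shift is read from the group mean ranks.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .ranking import GROUP_DOWN, GROUP_NONE, GROUP_UP, assign_groups

#: the quantile-pair grid used when sweeping the grouping cutoff
DEFAULT_QUANTILE_PAIRS: tuple[tuple[float, float], ...] = (
    (0.1, 0.9),
    (0.2, 0.8),
    (0.3, 0.7),
    (0.4, 0.6),
)

LABEL_INDUCING = "inducing"
LABEL_REPRESSIVE = "repressive"
LABEL_BOTH = "both"
LABEL_NONE = "none"


class KSResult(NamedTuple):
    group: str
    statistic: float
    p_value: float
    n_group: int
    n_none: int


@dataclass(frozen=True)
class FunctionCall:
    """Predicted regulatory function of the factor, with its KS evidence."""

    label: str
    alpha: float
    up: KSResult
    down: KSResult


def ecdf_by_group(records: pd.DataFrame) -> pd.DataFrame:
    """Per-group ECDF of the regulatory-potential ranks.

    Returns a long table (group, rank, ecdf): for each group, the fraction
    of the group at or below each of its distinct rank values. Each curve
    steps up to exactly 1 at the group maximum. Empty groups are omitted.
    """
    frames = []
    for group in (GROUP_DOWN, GROUP_NONE, GROUP_UP):
        ranks = records.loc[records["group"] == group, "rank_potential"].to_numpy()
        if len(ranks) == 0:
            continue
        values, counts = np.unique(ranks, return_counts=True)
        frames.append(
            pd.DataFrame(
                {
                    "group": group,
                    "rank": values,
                    "ecdf": np.cumsum(counts) / len(ranks),
                }
            )
        )
    return pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(
        columns=["group", "rank", "ecdf"]
    )


def ks_test(group_ranks, none_ranks, group: str = GROUP_UP) -> KSResult:
    """Two-sample two-sided KS test of a regulated group against none.

    The statistic is the exact sup-difference of the two step ECDFs; the
    p-value is asymptotic, so the result is deterministic at any sample
    size.
    """
    group_ranks = np.asarray(group_ranks, dtype=float)
    none_ranks = np.asarray(none_ranks, dtype=float)
    if len(group_ranks) < 2 or len(none_ranks) < 2:
        raise ValueError(
            f"KS test needs >= 2 observations per sample, got "
            f"{len(group_ranks)} and {len(none_ranks)}"
        )
    res = sps.ks_2samp(group_ranks, none_ranks, alternative="two-sided", method="asymp")
    return KSResult(
        group=group,
        statistic=float(res.statistic),
        p_value=float(min(res.pvalue, 1.0)),
        n_group=len(group_ranks),
        n_none=len(none_ranks),
    )


def predict_function(records: pd.DataFrame, alpha: float = 0.05) -> FunctionCall:
    """Call the factor inducing, repressive, both, or none.

    A group counts as shifted toward stronger binding when its mean
    potential rank is smaller than the none group's mean AND its KS p-value
    is below alpha. Up shifted -> inducing; down shifted -> repressive; both
    shifted -> both; neither -> none.
    """
    ranks = {
        g: records.loc[records["group"] == g, "rank_potential"].to_numpy(dtype=float)
        for g in (GROUP_UP, GROUP_DOWN, GROUP_NONE)
    }
    up_res = ks_test(ranks[GROUP_UP], ranks[GROUP_NONE], GROUP_UP)
    down_res = ks_test(ranks[GROUP_DOWN], ranks[GROUP_NONE], GROUP_DOWN)
    none_mean = ranks[GROUP_NONE].mean()
    up_shifted = up_res.p_value < alpha and ranks[GROUP_UP].mean() < none_mean
    down_shifted = down_res.p_value < alpha and ranks[GROUP_DOWN].mean() < none_mean
    if up_shifted and down_shifted:
        label = LABEL_BOTH
    elif up_shifted:
        label = LABEL_INDUCING
    elif down_shifted:
        label = LABEL_REPRESSIVE
    else:
        label = LABEL_NONE
    return FunctionCall(label=label, alpha=alpha, up=up_res, down=down_res)


def cutoff_sweep(
    records: pd.DataFrame,
    quantile_pairs: Sequence[tuple[float, float]] = DEFAULT_QUANTILE_PAIRS,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Re-group and re-test at each quantile pair.

    For every (lower, upper) pair the records are re-labelled from their
    stat values and both directions are tested against the new none group.
    Returns one row per pair with the down/up KS statistics and p-values and
    the function label, mirroring a per-factor robustness table. Raw
    p-values are reported; no multiple-testing correction across cells.
    """
    if len(quantile_pairs) == 0:
        raise ValueError("need at least one quantile pair")
    rows = []
    for lower_q, upper_q in quantile_pairs:
        regrouped = records.copy()
        regrouped["group"] = assign_groups(
            regrouped["stat"].to_numpy(), lower_q, upper_q
        )
        call = predict_function(regrouped, alpha=alpha)
        rows.append(
            {
                "lower_q": lower_q,
                "upper_q": upper_q,
                "down_stat": call.down.statistic,
                "down_p": call.down.p_value,
                "up_stat": call.up.statistic,
                "up_p": call.up.p_value,
                "label": call.label,
            }
        )
    return pd.DataFrame(rows)
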