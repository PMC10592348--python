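"""End-to-end analysis: peaks + gene models + expression -> ranked targets.

`analyze` is the in-memory core shared by the CLI and the tests;
`run_pipeline` is the file-to-file composite workflow that also serializes
its configuration next to the outputs so a run can be reproduced exactly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, asdict, field
from pathlib import Path

import pandas as pd
import yaml

from . import io as gio
from .potential import associate_peaks, regulatory_potential, resize_regions
from .ranking import assign_groups, rank_products
from .inference import (
    DEFAULT_QUANTILE_PAIRS,
    FunctionCall,
    cutoff_sweep,
    ecdf_by_group,
    predict_function,
)

logger = logging.getLogger("tftarget")

#: Table-2-style column order for the ranked output
RANKED_COLUMNS = [
    "chrom", "start", "end", "region_id", "symbol", "rank",
    "potential", "stat", "group",
    "rank_potential", "rank_up", "rank_down", "rp_up", "rp_down", "n_peaks",
]


@dataclass
class RunConfig:
    peaks: str
    genes: str
    expression: str
    distance: int = 100_000  # allowed peak-TSS distance D (bp)
    lower_q: float = 0.1
    upper_q: float = 0.9
    direction: str = "up"
    alpha: float = 0.05
    quantile_pairs: tuple = DEFAULT_QUANTILE_PAIRS
    seed: int | None = None  # recorded for simulated inputs
    log_level: str = "info"


def analyze(
    peaks: pd.DataFrame,
    genes: pd.DataFrame,
    expression: pd.DataFrame,
    distance: int = 100_000,
    lower_q: float = 0.1,
    upper_q: float = 0.9,
    direction: str = "up",
) -> pd.DataFrame:
    """Compute the full target table from in-memory inputs.

    Resizes every gene model to a 2*distance window around its TSS, sums
    decayed peak scores into regulatory potentials, joins with the signed
    expression statistics into normalized rank products, and labels the
    up/down/none groups by the quantile cutoffs. Returns one row per joined
    transcript with the resized window coordinates, sorted best-first in
    the requested direction.
    """
    windows = resize_regions(genes, distance)
    assoc = associate_peaks(peaks, windows, distance)
    potentials = regulatory_potential(assoc, windows)
    targets = rank_products(potentials, expression, direction=direction)
    targets["group"] = assign_groups(targets["stat"].to_numpy(), lower_q, upper_q)
    targets = targets.merge(
        windows[["region_id", "chrom", "start", "end"]], on="region_id", how="left"
    )
    targets["rank"] = targets["rp_up" if direction == "up" else "rp_down"]
    if "symbol" not in targets.columns:
        targets["symbol"] = ""
    return targets[RANKED_COLUMNS]


def run_pipeline(config: RunConfig, outdir: str | Path) -> dict[str, Path]:
    """Run the composite workflow and write all outputs into `outdir`.

    Writes ranked.tsv (Table-2-shaped target table), tests.tsv (cutoff
    sweep), ecdf.tsv (per-group ECDF curves), function.txt (the predicted
    function with its KS evidence) and config.yaml (the serialized
    RunConfig). Deterministic for fixed inputs.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    peaks = gio.read_peaks(config.peaks)
    genes = gio.read_gene_models(config.genes)
    expression = gio.read_expression(config.expression)

    targets = analyze(
        peaks, genes, expression,
        distance=config.distance,
        lower_q=config.lower_q,
        upper_q=config.upper_q,
        direction=config.direction,
    )
    call = predict_function(targets, alpha=config.alpha)
    sweep = cutoff_sweep(targets, config.quantile_pairs, alpha=config.alpha)
    ecdf = ecdf_by_group(targets)

    paths = {
        "ranked": outdir / "ranked.tsv",
        "tests": outdir / "tests.tsv",
        "ecdf": outdir / "ecdf.tsv",
        "function": outdir / "function.txt",
        "config": outdir / "config.yaml",
    }
    gio.write_table(targets, paths["ranked"])
    gio.write_table(sweep, paths["tests"])
    gio.write_table(ecdf, paths["ecdf"])
    paths["function"].write_text(format_function_call(call) + "\n")
    serialized = asdict(config)
    serialized["quantile_pairs"] = [list(p) for p in config.quantile_pairs]
    paths["config"].write_text(yaml.safe_dump(serialized, sort_keys=False))
    logger.info("wrote %d targets to %s (function: %s)", len(targets), outdir, call.label)
    return paths


def format_function_call(call: FunctionCall) -> str:
    return (
        f"function\t{call.label}\talpha={call.alpha}\n"
        f"up\tstat={call.up.statistic:.6g}\tp={call.up.p_value:.6g}"
        f"\tn={call.up.n_group}/{call.up.n_none}\n"
        f"down\tstat={call.down.statistic:.6g}\tp={call.down.p_value:.6g}"
        f"\tn={call.down.n_group}/{call.down.n_none}"
    )
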