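"""Readers and writers for the genomic and tabular formats the tool touches.

All intervals are held internally as 1-based inclusive coordinates so that a
window of half-width D printed as (start, end) satisfies end - start + 1 = 2*D.
BED input/output converts at the boundary (BED is 0-based half-open).
Chromosome names are matched as exact strings; no "chr" aliasing, because
silent aliasing hides genome-build mismatches.
"""

from __future__ import annotations

import logging
import os
from typing import Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("tftarget")

PEAK_COLUMNS = ["chrom", "start", "end", "peak_id"]
REGION_COLUMNS = ["chrom", "start", "end", "region_id", "score", "strand"]

_VALID_STRANDS = {"+", "-", "."}
# tolerate the unicode minus that sometimes survives copy/paste
_STRAND_ALIASES = {"−": "-"}


class FormatError(ValueError):
    """A malformed input file; the message carries the offending line number."""


def _skip_bed_header(line: str) -> bool:
    return line.startswith(("#", "track", "browser")) or not line.strip()


def _parse_bed_coords(fields: Sequence[str], lineno: int, path: str) -> tuple[int, int]:
    try:
        bed_start, bed_end = int(fields[1]), int(fields[2])
    except ValueError as exc:
        raise FormatError(
            f"{path}:{lineno}: non-integer coordinates {fields[1]!r}, {fields[2]!r}"
        ) from exc
    if bed_start < 0 or bed_end <= bed_start:
        raise FormatError(
            f"{path}:{lineno}: invalid BED interval [{bed_start}, {bed_end})"
        )
    # BED 0-based half-open -> 1-based inclusive
    return bed_start + 1, bed_end


def read_peaks(path: str | os.PathLike) -> pd.DataFrame:
    """Read ChIP peaks from a BED3+ file.

    Returns a DataFrame with columns chrom, start, end, peak_id (1-based
    inclusive coordinates, file order preserved). Column 4 supplies the peak
    id when present, otherwise ``peak_<line-number>``. Extra columns (MACS
    score, summit offset, ...) are ignored.
    """
    rows = []
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            if _skip_bed_header(line):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"{path}:{lineno}: expected >=3 tab-separated columns, got {len(fields)}"
                )
            start, end = _parse_bed_coords(fields, lineno, str(path))
            peak_id = fields[3] if len(fields) > 3 and fields[3] else f"peak_{lineno}"
            rows.append((fields[0], start, end, peak_id))
    if not rows:
        logger.warning("no peaks read from %s", path)
    return pd.DataFrame(rows, columns=PEAK_COLUMNS)


def read_gene_models(path: str | os.PathLike) -> pd.DataFrame:
    """Read transcript/gene models from a BED6 file.

    Returns a DataFrame with columns chrom, start, end, region_id, score,
    strand (1-based inclusive). Duplicate region ids and unknown strand
    symbols are rejected.
    """
    rows = []
    seen: set[str] = set()
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            if _skip_bed_header(line):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 6:
                raise FormatError(
                    f"{path}:{lineno}: expected 6 columns (BED6), got {len(fields)}"
                )
            start, end = _parse_bed_coords(fields, lineno, str(path))
            region_id = fields[3]
            strand = _STRAND_ALIASES.get(fields[5], fields[5])
            if strand not in _VALID_STRANDS:
                raise FormatError(
                    f"{path}:{lineno}: unknown strand symbol {fields[5]!r}"
                )
            if region_id in seen:
                raise FormatError(
                    f"{path}:{lineno}: duplicate region id {region_id!r}"
                )
            seen.add(region_id)
            rows.append((fields[0], start, end, region_id, fields[4], strand))
    if not rows:
        logger.warning("no gene models read from %s", path)
    return pd.DataFrame(rows, columns=REGION_COLUMNS)


def read_expression(
    path: str | os.PathLike,
    id_col: str = "id",
    stat_col: str = "stat",
    fc_col: str = "fc",
    symbol_col: str = "symbol",
) -> pd.DataFrame:
    """Read a differential-expression table (TSV with a header).

    Requires columns `id_col` and `stat_col`; `fc_col`/`symbol_col` are
    carried through when present. Rows with a non-finite statistic are
    dropped with a logged count. Returns columns region_id, stat and
    optionally fc, symbol.
    """
    table = pd.read_csv(path, sep="\t")
    missing = [c for c in (id_col, stat_col) if c not in table.columns]
    if missing:
        raise FormatError(
            f"{path}: missing required column(s) {missing}; "
            f"available: {list(table.columns)}"
        )
    out = pd.DataFrame({"region_id": table[id_col].astype(str)})
    out["stat"] = pd.to_numeric(table[stat_col], errors="coerce")
    if fc_col in table.columns:
        out["fc"] = pd.to_numeric(table[fc_col], errors="coerce")
    if symbol_col in table.columns:
        out["symbol"] = table[symbol_col].astype(str)
    bad = ~np.isfinite(out["stat"].to_numpy())
    if bad.any():
        logger.warning("dropped %d rows with non-finite stat from %s", bad.sum(), path)
        out = out.loc[~bad].reset_index(drop=True)
    return out


def write_peaks(peaks: pd.DataFrame, path: str | os.PathLike) -> None:
    """Write peaks back to BED (inverse of :func:`read_peaks`)."""
    bed = pd.DataFrame(
        {
            "chrom": peaks["chrom"],
            "start": peaks["start"].astype(int) - 1,
            "end": peaks["end"].astype(int),
            "name": peaks["peak_id"],
        }
    )
    bed.to_csv(path, sep="\t", header=False, index=False)


def write_gene_models(regions: pd.DataFrame, path: str | os.PathLike) -> None:
    """Write gene models back to BED6 (inverse of :func:`read_gene_models`)."""
    bed = pd.DataFrame(
        {
            "chrom": regions["chrom"],
            "start": regions["start"].astype(int) - 1,
            "end": regions["end"].astype(int),
            "name": regions["region_id"],
            "score": regions["score"] if "score" in regions else 0,
            "strand": regions["strand"],
        }
    )
    bed.to_csv(path, sep="\t", header=False, index=False)


def write_expression(expression: pd.DataFrame, path: str | os.PathLike) -> None:
    """Write an expression table as TSV with columns id, stat[, fc, symbol]."""
    out = expression.rename(columns={"region_id": "id"})
    out.to_csv(path, sep="\t", index=False)


def write_table(table: pd.DataFrame, path: str | os.PathLike) -> None:
    """Write any result table as TSV with a header."""
    table.to_csv(path, sep="\t", index=False)
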