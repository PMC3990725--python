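"""Tabular I/O: panel and viability TSVs, calls/regions output, BED export.

All tabular files are UTF-8 TSV with a header row; the final report is JSON.
The BED-like track uses ordinal band ranks (0-based, half-open) computed from
the band order relation — cytological coordinates have no physical scale, and
the header comment says so.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
import yaml

from .cytology import (
    CytoInterval,
    CytoParseError,
    format_band,
    format_interval,
    interval_to_ordinal,
    ordinal_ranks,
    parse_interval,
)
from .regions import LethalRegion
from .screen import LethalCall
from .simulate import BACKGROUNDS, VIABILITY_COLUMNS, DuplicationStock

logger = logging.getLogger("dmimap")

__all__ = [
    "read_panel",
    "write_panel",
    "read_viability",
    "write_viability",
    "calls_frame",
    "write_calls",
    "regions_frame",
    "write_regions",
    "write_bed",
    "read_config",
    "write_report",
]

PANEL_COLUMNS = ["stock_id", "dp_name", "interval"]


def read_panel(path: str | Path) -> list[DuplicationStock]:
    """Read a duplication-panel TSV (stock_id, dp_name, interval).

    Malformed or reversed intervals raise with the offending line number;
    duplicate stock ids are rejected.  An empty file yields an empty panel
    with a warning.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = set(PANEL_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"panel file {path} lacks columns: {sorted(missing)}")
    if df.empty:
        logger.warning("panel file %s contains no stocks", path)
        return []
    stocks = []
    seen: dict[str, int] = {}
    for i, row in enumerate(df.itertuples(), start=2):  # 1-based, after header
        try:
            iv = parse_interval(row.interval)
        except CytoParseError as exc:
            raise ValueError(f"{path}, line {i}: {exc}") from None
        if row.stock_id in seen:
            raise ValueError(
                f"{path}, line {i}: duplicate stock id {row.stock_id!r} "
                f"(first seen on line {seen[row.stock_id]})"
            )
        seen[row.stock_id] = i
        stocks.append(DuplicationStock(row.stock_id, row.dp_name, iv))
    return stocks


def write_panel(panel: Sequence[DuplicationStock], path: str | Path) -> None:
    df = pd.DataFrame(
        [(s.stock_id, s.dp_name, format_interval(s.interval)) for s in panel],
        columns=PANEL_COLUMNS,
    )
    df.to_csv(path, sep="\t", index=False)


def read_viability(path: str | Path) -> pd.DataFrame:
    """Read a viability TSV into the tidy per-replicate frame."""
    df = pd.read_csv(path, sep="\t")
    missing = set(VIABILITY_COLUMNS) - {"n_hatched_male"} - set(df.columns)
    if missing:
        raise ValueError(f"viability file {path} lacks columns: {sorted(missing)}")
    if "n_hatched_male" not in df.columns:
        df["n_hatched_male"] = pd.NA
    df["inseminated"] = df["inseminated"].astype(bool)
    for col in ["n_fertilized", "n_hatched", "n_pupae", "n_adults"]:
        df[col] = df[col].astype(int)
    return df[VIABILITY_COLUMNS]


def write_viability(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def _fmt_surv(v: float | None) -> str:
    return "" if v is None else f"{v:.6g}"


def calls_frame(calls: Iterable[LethalCall]) -> pd.DataFrame:
    """Flatten lethality calls to one row per cross (stock x line x background
    pair), with pooled survivals, verdicts and exclusion reasons."""
    rows = []
    for c in calls:
        for bg in BACKGROUNDS:
            v = c.verdicts.get(bg)
            if v is None:
                continue
            surv = v.survivals.as_tuple() if v.survivals else (None, None, None)
            rows.append(
                (
                    c.stock_id, c.species, c.line, bg, v.stage,
                    v.reason or "", *[_fmt_surv(s) for s in surv],
                    v.n_replicates,
                    c.concordant_stage or "none",
                    c.discordant, c.single_background,
                )
            )
    return pd.DataFrame(
        rows,
        columns=[
            "stock_id", "paternal_species", "line", "background", "verdict",
            "exclusion_reason", "surv_embryonic", "surv_larval", "surv_pupal",
            "n_replicates", "concordant_stage", "discordant",
            "single_background",
        ],
    )


def write_calls(calls: Iterable[LethalCall], path: str | Path) -> None:
    calls_frame(calls).to_csv(path, sep="\t", index=False)


def regions_frame(
    regions_per_line: Mapping[tuple[str, str], Sequence[LethalRegion]],
) -> pd.DataFrame:
    rows = []
    for (species, line), regions in sorted(regions_per_line.items()):
        for i, r in enumerate(regions, start=1):
            rows.append(
                (
                    f"{species}:{line}:R{i:02d}", species, line, r.stage,
                    format_interval(r.core), format_band(r.piercing_band),
                    ",".join(r.members),
                )
            )
    return pd.DataFrame(
        rows,
        columns=[
            "region_id", "paternal_species", "line", "stage", "core_interval",
            "piercing_band", "member_stocks",
        ],
    )


def write_regions(
    regions_per_line: Mapping[tuple[str, str], Sequence[LethalRegion]],
    path: str | Path,
) -> None:
    regions_frame(regions_per_line).to_csv(path, sep="\t", index=False)


def write_bed(
    named_intervals: Sequence[tuple[str, CytoInterval]], path: str | Path
) -> None:
    """BED-like export of intervals on the ordinal band axis.

    Coordinates are 0-based half-open RANKS along the cytological band order,
    suitable for browser-style plotting of the panel and regions; they are not
    physical genome positions.
    """
    bands = [b for _, iv in named_intervals for b in (iv.start, iv.end)]
    ranks = ordinal_ranks(bands)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(
            "# coordinates are ordinal cytological band ranks "
            "(0-based, half-open), not physical positions\n"
        )
        for name, iv in named_intervals:
            lo, hi = interval_to_ordinal(iv, ranks)
            fh.write(f"X\t{lo}\t{hi}\t{name}\n")


def read_config(path: str | Path) -> dict:
    """Read a flat key-value configuration file (YAML mapping)."""
    with open(path, encoding="utf-8") as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ValueError(f"config {path} must be a flat key-value mapping")
    return cfg


def write_report(report: Mapping, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")
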