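"""End-to-end orchestration: simulate (or load) → screen → regions → stats.

``run_pipeline`` ties the stages together under one configuration and a
single root seed, writes the stage outputs (viability, calls, regions TSVs;
BED tracks; JSON report) when an output directory is given, and returns the
report as a dictionary.  Every exclusion and discordance is logged with its
machine-parsable reason code.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from . import io as dio
from .regions import (
    LethalRegion,
    count_by_stage,
    regions_by_line,
    snowball_dataset,
)
from .screen import LethalCall, call_table
from .simulate import (
    BACKGROUNDS,
    DuplicationStock,
    PaternalLine,
    PlantedLocus,
    SurvivalTable,
    default_paternal_lines,
    default_planted_loci,
    default_survival_table,
    default_tiling_panel,
    simulate_panel,
)
from .stats import chisq_gof, sidak_threshold, snowball_compare, uniform_expected

logger = logging.getLogger("dmimap")

__all__ = ["PipelineConfig", "SimulationSpec", "run_pipeline"]


@dataclass(frozen=True)
class PipelineConfig:
    """Knobs of the analysis layer (not of the data-generating process)."""

    lethality_threshold: float = 0.10
    alpha: float = 0.05
    denominator: str = "total"
    classification_mode: str = "pooled"
    min_replicates: int = 3
    rss_floor: float = 1e-12
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.lethality_threshold < 1.0:
            raise ValueError("lethality_threshold must lie in (0, 1)")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must lie in (0, 1)")

    @classmethod
    def from_mapping(cls, cfg: Mapping) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(cfg) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**cfg)


@dataclass(frozen=True)
class SimulationSpec:
    """What to simulate when no real viability table is supplied."""

    panel: Sequence[DuplicationStock] = field(default_factory=default_tiling_panel)
    paternal_lines: Sequence[PaternalLine] = field(
        default_factory=default_paternal_lines
    )
    loci: Sequence[PlantedLocus] = field(default_factory=default_planted_loci)
    survival: SurvivalTable | None = None
    clutch_size: int = 300
    n_replicates: int = 3
    backgrounds: Sequence[str] = BACKGROUNDS
    fail_fraction: float = 0.0


def _log_exclusions(calls: Sequence[LethalCall]) -> None:
    for c in calls:
        for bg, v in c.verdicts.items():
            if v.stage == "excluded":
                logger.warning(
                    "excluded cross stock=%s line=%s/%s background=%s reason=%s",
                    c.stock_id, c.species, c.line, bg, v.reason,
                )
        if c.discordant:
            logger.warning(
                "discordant backgrounds for stock=%s line=%s/%s: %s",
                c.stock_id, c.species, c.line,
                {bg: v.stage for bg, v in c.verdicts.items()},
            )
        if c.single_background:
            logger.warning(
                "stock=%s line=%s/%s assayed in a single background; "
                "not callable as lethal", c.stock_id, c.species, c.line,
            )


def run_pipeline(
    config: PipelineConfig,
    panel: Sequence[DuplicationStock] | None = None,
    viability: pd.DataFrame | None = None,
    sim_spec: SimulationSpec | None = None,
    outdir: str | Path | None = None,
) -> dict:
    """Run screen → regions → statistics on real or simulated data.

    Exactly one of ``viability`` (a real per-replicate table) or ``sim_spec``
    drives the input; with ``sim_spec`` the panel defaults to the spec's own.
    Returns the JSON-serialisable report; when ``outdir`` is given, also
    writes viability/calls/regions TSVs, BED tracks and ``report.json``.
    """
    if (viability is None) == (sim_spec is None):
        raise ValueError("provide exactly one of viability or sim_spec")
    if sim_spec is not None:
        panel = list(sim_spec.panel)
        logger.info(
            "simulating panel: %d stocks x %d backgrounds x %d lines, seed=%d",
            len(panel), len(sim_spec.backgrounds),
            len(sim_spec.paternal_lines), config.seed,
        )
        viability = simulate_panel(
            panel, sim_spec.paternal_lines, sim_spec.loci, sim_spec.survival,
            sim_spec.clutch_size, sim_spec.n_replicates, config.seed,
            backgrounds=sim_spec.backgrounds,
            fail_fraction=sim_spec.fail_fraction,
        )
        lines = list(sim_spec.paternal_lines)
    else:
        if panel is None:
            raise ValueError("real-data mode requires a panel")
        pairs = viability[["paternal_species", "line"]].drop_duplicates()
        lines = None  # Ks unknown for real lines unless supplied separately
        logger.info(
            "loaded viability table: %d rows, %d lines",
            len(viability), len(pairs),
        )

    logger.info("classifying crosses (threshold=%g)", config.lethality_threshold)
    calls = call_table(
        viability,
        threshold=config.lethality_threshold,
        min_replicates=config.min_replicates,
        denominator=config.denominator,  # type: ignore[arg-type]
        mode=config.classification_mode,  # type: ignore[arg-type]
    )
    _log_exclusions(calls)

    per_line_regions = regions_by_line(calls, panel)
    report: dict = {
        "config": dataclasses.asdict(config),
        "n_crosses": int(
            viability[["stock_id", "paternal_species", "line", "background"]]
            .drop_duplicates()
            .shape[0]
        ),
        "n_lethal_calls": sum(1 for c in calls if c.lethal),
        "lines": {},
    }

    counts_for_snowball: dict[PaternalLine, int] = {}
    line_keys = sorted({(c.species, c.line) for c in calls})
    for species, line in line_keys:
        regs = per_line_regions.get((species, line), [])
        stage_counts = count_by_stage(regs)
        entry: dict = {
            "n_regions": len(regs),
            "stage_counts": stage_counts,
        }
        total = len(regs)
        if total > 0:
            gof = chisq_gof(
                [stage_counts[s] for s in ("embryonic", "larval", "pupal")],
                uniform_expected(total, 3),
            )
            entry["stage_uniformity_chisq"] = {
                "statistic": gof.statistic, "df": gof.df, "p": gof.p,
            }
        report["lines"][f"{species}:{line}"] = entry
        if lines is not None:
            for pl in lines:
                if pl.species == species and pl.line_label == line:
                    counts_for_snowball[pl] = total

    if lines is not None and len(counts_for_snowball) >= 4:
        data = snowball_dataset(counts_for_snowball)
        cmp_ = snowball_compare(data, rss_floor=config.rss_floor)
        report["snowball"] = {
            "points": [list(p) for p in data.points],
            "linear": dataclasses.asdict(cmp_.linear),
            "quadratic": dataclasses.asdict(cmp_.quadratic),
            "preferred_degree": cmp_.preferred_degree,
        }
        logger.info(
            "snowball comparison: preferred degree %d (AIC linear=%.4g, "
            "quadratic=%.4g)", cmp_.preferred_degree, cmp_.linear.aic,
            cmp_.quadratic.aic,
        )

    report["sidak"] = {
        "alpha": config.alpha,
        "per_line_threshold_m18": sidak_threshold(config.alpha, 18),
        "per_line_threshold_m6": sidak_threshold(config.alpha, 6),
    }

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        dio.write_viability(viability, outdir / "viability.tsv")
        dio.write_panel(panel, outdir / "panel.tsv")
        dio.write_calls(calls, outdir / "calls.tsv")
        dio.write_regions(per_line_regions, outdir / "regions.tsv")
        dio.write_bed(
            [(s.stock_id, s.interval) for s in panel], outdir / "panel.bed"
        )
        region_track = [
            (f"{sp}:{ln}:{r.stage}", r.core)
            for (sp, ln), regs in sorted(per_line_regions.items())
            for r in regs
        ]
        if region_track:
            dio.write_bed(region_track, outdir / "regions.bed")
        dio.write_report(report, outdir / "report.json")
        logger.info("wrote pipeline outputs to %s", outdir)

    return report
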