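"""Lethality classification of duplication crosses.

A duplication is called lethal for a paternal line when, in the pooled
replicates of a cross, fewer than 10% of individuals survive some stage
transition — hatching (embryonic), larva→pupa molt (larval) or pupa→adult
eclosion (pupal) — and the same call must hold in BOTH attached-X maternal
backgrounds (C(1)RM and C(1)DX) before the duplication counts as carrying a
dominant hybrid-lethal allele.  Crosses with no progeny or no observed
insemination are excluded (they measure premating / postmating-prezygotic
isolation, not inviability).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Mapping, Sequence

import pandas as pd

from .simulate import BACKGROUNDS, STAGES, StageCounts

__all__ = [
    "DEFAULT_THRESHOLD",
    "StageSurvival",
    "CrossVerdict",
    "LethalCall",
    "pool_counts",
    "stage_survival",
    "classify_cross",
    "concordant_calls",
    "call_table",
]

DEFAULT_THRESHOLD = 0.10
DEFAULT_MIN_REPLICATES = 3

Denominator = Literal["total", "male_only"]

# machine-parsable exclusion reason codes
EXCL_NO_REPLICATES = "no_replicates"
EXCL_TOO_FEW_REPLICATES = "too_few_replicates"
EXCL_NOT_INSEMINATED = "not_inseminated"
EXCL_NO_PROGENY = "no_progeny"


@dataclass(frozen=True)
class StageSurvival:
    """Survival proportions at the three transitions; ``None`` marks an
    undefined proportion (zero individuals entered the stage) — flagged, never
    silently zero."""

    embryonic: float | None
    larval: float | None
    pupal: float | None

    def as_tuple(self) -> tuple[float | None, float | None, float | None]:
        return (self.embryonic, self.larval, self.pupal)


@dataclass(frozen=True)
class CrossVerdict:
    """Outcome for one (duplication, background, paternal line) series."""

    stage: str  # one of STAGES, "none", or "excluded"
    reason: str | None
    survivals: StageSurvival | None
    n_replicates: int


@dataclass(frozen=True)
class LethalCall:
    """Cross-background verdict for one duplication against one line."""

    stock_id: str
    species: str
    line: str
    verdicts: Mapping[str, CrossVerdict]  # background -> verdict
    concordant_stage: str | None
    discordant: bool
    single_background: bool
    n_replicates: int

    @property
    def lethal(self) -> bool:
        return self.concordant_stage is not None


def pool_counts(replicates: Sequence[StageCounts]) -> StageCounts:
    """Sum replicate censuses into one pooled census."""
    male = [r.n_hatched_male for r in replicates]
    pooled_male = sum(m for m in male if m is not None) if any(
        m is not None for m in male
    ) else None
    return StageCounts(
        replicate_id=0,
        n_fertilized=sum(r.n_fertilized for r in replicates),
        n_hatched=sum(r.n_hatched for r in replicates),
        n_pupae=sum(r.n_pupae for r in replicates),
        n_adults=sum(r.n_adults for r in replicates),
        n_hatched_male=pooled_male,
        inseminated=any(r.inseminated for r in replicates),
    )


def stage_survival(
    counts: StageCounts, denominator: Denominator = "total"
) -> StageSurvival:
    """Survival proportions (hatch, molt-to-pupa, eclosion) from a census.

    ``denominator="total"`` divides hatchlings by all fertilized embryos (the
    screen's printed rule, even though only ~1/4 of zygotes are the assayed
    male class); ``"male_only"`` instead divides the male hatch tally by the
    Mendelian quarter of the clutch, approximating a per-male hatch rate.
    Later transitions always use individuals entering the stage, preferring
    the sex-sorted male tally as the larval denominator when present.
    """
    if denominator == "male_only" and counts.n_hatched_male is not None:
        expected_males = counts.n_fertilized / 4.0
        embryonic = (
            min(1.0, counts.n_hatched_male / expected_males)
            if expected_males > 0
            else None
        )
    else:
        embryonic = (
            counts.n_hatched / counts.n_fertilized
            if counts.n_fertilized > 0
            else None
        )
    larvae_entering = (
        counts.n_hatched_male
        if counts.n_hatched_male is not None
        else counts.n_hatched
    )
    larval = counts.n_pupae / larvae_entering if larvae_entering > 0 else None
    pupal = counts.n_adults / counts.n_pupae if counts.n_pupae > 0 else None
    return StageSurvival(embryonic, larval, pupal)


def _verdict_from_survival(surv: StageSurvival, threshold: float) -> str:
    """Earliest transition whose survival falls below the threshold; later
    stages are unobservable once a cross dies out, so precedence is
    embryonic > larval > pupal."""
    for stage, s in zip(STAGES, surv.as_tuple()):
        if s is not None and s < threshold:
            return stage
    return "none"


def classify_cross(
    replicates: Sequence[StageCounts],
    threshold: float = DEFAULT_THRESHOLD,
    min_replicates: int = DEFAULT_MIN_REPLICATES,
    denominator: Denominator = "total",
    mode: Literal["pooled", "majority"] = "pooled",
) -> CrossVerdict:
    """Classify one cross series as lethal at a stage, non-lethal, or excluded.

    Replicate counts are pooled before thresholding (default); ``majority``
    instead classifies each replicate and requires a strict majority on a
    lethal stage.  Exclusions (no replicates, too few, no observed
    insemination, no embryonic progeny) carry a reason code.
    """
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must lie in (0, 1)")
    n = len(replicates)
    if n == 0:
        return CrossVerdict("excluded", EXCL_NO_REPLICATES, None, 0)
    if not any(r.inseminated for r in replicates):
        return CrossVerdict("excluded", EXCL_NOT_INSEMINATED, None, n)
    if n < min_replicates:
        return CrossVerdict("excluded", EXCL_TOO_FEW_REPLICATES, None, n)
    pooled = pool_counts(replicates)
    if pooled.n_fertilized == 0:
        return CrossVerdict("excluded", EXCL_NO_PROGENY, None, n)
    surv = stage_survival(pooled, denominator)
    if mode == "pooled":
        return CrossVerdict(_verdict_from_survival(surv, threshold), None, surv, n)
    votes = [
        _verdict_from_survival(stage_survival(r, denominator), threshold)
        for r in replicates
        if r.n_fertilized > 0
    ]
    for stage in STAGES:
        if votes.count(stage) * 2 > len(votes):
            return CrossVerdict(stage, None, surv, n)
    return CrossVerdict("none", None, surv, n)


def concordant_calls(
    calls_by_background: Mapping[tuple[str, str, str], Mapping[str, CrossVerdict]],
) -> list[LethalCall]:
    """Apply the dual-background rule across per-background verdicts.

    Input maps ``(stock_id, species, line)`` to ``{background: verdict}``.  A
    duplication is called lethal only when both backgrounds agree on the same
    lethal stage; pairs that disagree (lethal in one background only, or at
    different stages) are retained with a discordance flag, and stocks assayed
    in a single background are flagged and never called lethal.
    """
    out: list[LethalCall] = []
    for (stock_id, species, line), verdicts in sorted(calls_by_background.items()):
        usable = {
            bg: v for bg, v in verdicts.items() if v.stage != "excluded"
        }
        single = len(usable) < 2
        stages = {v.stage for v in usable.values()}
        if not single and len(stages) == 1 and (st := stages.pop()) in STAGES:
            concordant, discordant = st, False
        else:
            concordant = None
            lethal_any = any(v.stage in STAGES for v in usable.values())
            discordant = (not single) and lethal_any
        out.append(
            LethalCall(
                stock_id, species, line, dict(verdicts), concordant,
                discordant, single,
                n_replicates=sum(v.n_replicates for v in verdicts.values()),
            )
        )
    return out


def call_table(
    viability: pd.DataFrame,
    threshold: float = DEFAULT_THRESHOLD,
    min_replicates: int = DEFAULT_MIN_REPLICATES,
    denominator: Denominator = "total",
    mode: Literal["pooled", "majority"] = "pooled",
) -> list[LethalCall]:
    """Run the full classification over a tidy viability frame.

    Expects the viability-TSV schema (``simulate.VIABILITY_COLUMNS``); every
    cross in the input appears exactly once in the output, as a verdict inside
    some :class:`LethalCall` (possibly an exclusion).
    """
    by_cross: dict[tuple[str, str, str], dict[str, CrossVerdict]] = {}
    grouped = viability.groupby(
        ["stock_id", "paternal_species", "line", "background"], sort=True
    )
    for (stock_id, species, line, background), grp in grouped:
        reps = [
            StageCounts(
                replicate_id=int(row.replicate),
                n_fertilized=int(row.n_fertilized),
                n_hatched=int(row.n_hatched),
                n_pupae=int(row.n_pupae),
                n_adults=int(row.n_adults),
                n_hatched_male=(
                    int(row.n_hatched_male)
                    if pd.notna(row.n_hatched_male)
                    else None
                ),
                inseminated=bool(row.inseminated),
            )
            for row in grp.itertuples()
        ]
        verdict = classify_cross(reps, threshold, min_replicates, denominator, mode)
        by_cross.setdefault((stock_id, species, line), {})[background] = verdict
    return concordant_calls(by_cross)
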