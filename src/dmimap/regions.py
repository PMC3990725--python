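"""Minimal distinct lethal regions from overlapping lethal duplications.

When two lethal duplications overlap, the conservative assumption of
deficiency/duplication mapping is that a single shared allele explains both.
Formally this is minimum interval piercing: find the smallest set of bands
("piercing bands") such that every lethal duplication's interval contains at
least one.  The classical right-endpoint greedy solves this exactly on
intervals, and the optimum equals the maximum number of pairwise disjoint
intervals — so the count can only ever underestimate the true number of
incompatibility alleles, never overestimate it.

Regions are computed separately within each developmental-stage class: two
overlapping duplications that kill at different stages cannot share a cause,
and the screen reports stage-specific tallies (a single cytological
neighbourhood can house, e.g., an embryonic and a pupal region).
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from functools import reduce
from typing import Iterable, Mapping, Sequence

from .cytology import (
    CytoBand,
    CytoInterval,
    band_sort_key,
    contains,
    intersect,
)
from .screen import LethalCall
from .simulate import STAGES, DuplicationStock, PaternalLine

__all__ = [
    "LethalRegion",
    "SnowballDataset",
    "minimal_regions",
    "count_by_stage",
    "regions_by_line",
    "snowball_dataset",
]


@dataclass(frozen=True)
class LethalRegion:
    """A distinct lethal region: the shared core of its member duplications.

    ``piercing_band`` witnesses the shared cause — every member interval
    contains it; ``core`` is the intersection of all member intervals.
    """

    core: CytoInterval
    stage: str | None
    members: tuple[str, ...]
    piercing_band: CytoBand


@dataclass(frozen=True)
class SnowballDataset:
    """(divergence, region count) points, one per cross."""

    points: tuple[tuple[float, int], ...]

    @property
    def xs(self) -> list[float]:
        return [p[0] for p in self.points]

    @property
    def ys(self) -> list[int]:
        return [p[1] for p in self.points]


def minimal_regions(
    lethal_intervals: Sequence[tuple[str, CytoInterval]],
    stage: str | None = None,
) -> list[LethalRegion]:
    """Minimum piercing of one stage class of lethal duplication intervals.

    Greedy: scan intervals by increasing right endpoint (ties broken by stock
    id, for determinism); whenever an interval contains no already-chosen
    piercing band, its own right endpoint becomes a new one.  Each region's
    members are ALL input intervals containing its piercing band, and its core
    is their intersection.  Empty input yields an empty list.
    """
    ordered = sorted(
        lethal_intervals, key=lambda t: (band_sort_key(t[1].end), t[0])
    )
    pierces: list[CytoBand] = []
    for _, iv in ordered:
        if not any(contains(iv, p) for p in pierces):
            pierces.append(iv.end)
    regions = []
    for p in pierces:
        members = [(sid, iv) for sid, iv in ordered if contains(iv, p)]
        core = reduce(intersect, (iv for _, iv in members))
        regions.append(
            LethalRegion(core, stage, tuple(sorted(s for s, _ in members)), p)
        )
    return regions


def count_by_stage(regions: Iterable[LethalRegion]) -> dict[str, int]:
    """Tally regions into (embryonic, larval, pupal) counts."""
    counts = {s: 0 for s in STAGES}
    for r in regions:
        if r.stage not in counts:
            raise ValueError(f"region with unknown stage {r.stage!r}")
        counts[r.stage] += 1
    return counts


def regions_by_line(
    calls: Iterable[LethalCall],
    panel: Sequence[DuplicationStock],
) -> dict[tuple[str, str], list[LethalRegion]]:
    """Partition concordant lethal calls by (species, line) and stage, and
    pierce each class.  Returns regions of all stages per line."""
    intervals = {s.stock_id: s.interval for s in panel}
    grouped: dict[tuple[str, str, str], list[tuple[str, CytoInterval]]] = defaultdict(list)
    for call in calls:
        if call.concordant_stage is None:
            continue
        if call.stock_id not in intervals:
            raise KeyError(f"call for unknown stock {call.stock_id!r}")
        grouped[(call.species, call.line, call.concordant_stage)].append(
            (call.stock_id, intervals[call.stock_id])
        )
    out: dict[tuple[str, str], list[LethalRegion]] = defaultdict(list)
    for (species, line, stage), items in sorted(grouped.items()):
        out[(species, line)].extend(minimal_regions(items, stage))
    return dict(out)


def snowball_dataset(
    region_counts_by_line: Mapping[PaternalLine, int],
) -> SnowballDataset:
    """One (Ks, total region count) point per cross.

    Intraspecific control crosses enter at their within-species divergence
    proxy (nucleotide diversity) with however many regions they yielded —
    zero, if the screen behaved.
    """
    points = []
    for line, count in region_counts_by_line.items():
        if line.ks is None:
            raise ValueError(f"line {line.line_label!r} has no Ks value")
        points.append((float(line.ks), int(count)))
    points.sort()
    return SnowballDataset(tuple(points))
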