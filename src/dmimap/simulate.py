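"""Stage-census simulator for attached-X, Dp(1;Y) duplication-screen crosses.

The screen crosses *D. melanogaster* attached-X females carrying a Y-linked X
duplication, ``C(1)RM (or C(1)DX), Dp(1;Y)``, to males of a paternal line
(interspecific: *D. santomea*, *D. simulans*, *D. mauritiana*; intraspecific
control: *D. melanogaster*).  Each clutch segregates four Mendelian genotype
classes in equal expected proportion:

* ``nullo_X``          — Y/Y zygotes with no X; die before cellularisation.
* ``metafemale``       — attached-X over the paternal X (three X doses).
* ``attachedX_female`` — attached-X over the paternal Y.
* ``dp_male``          — paternal X over the Dp(1;Y); the assayed class.

Survival is modelled as binomial thinning through three stage transitions
(embryo→L1 hatch, L1→pupa, pupa→adult) with genotype- and species-specific
probabilities.  A planted dominant lethal locus kills ``dp_male`` carriers at
its stage with probability = penetrance whenever the duplication interval
contains the locus band and the paternal species is in the locus' species set
— the ground truth the downstream screen must recover.

Post-embryonic censuses are male-only by genotype label, emulating the
protocol's mouthpart-pigment / Sxl::GFP sex sorting; set ``sex_sorted=False``
to tally every genotype through all stages instead.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .cytology import LAST_BAND, CytoBand, CytoInterval, contains

__all__ = [
    "BACKGROUNDS",
    "SPECIES",
    "GENOTYPES",
    "STAGES",
    "PaternalLine",
    "PlantedLocus",
    "DuplicationStock",
    "StageCounts",
    "SurvivalTable",
    "default_survival_table",
    "default_paternal_lines",
    "default_tiling_panel",
    "default_planted_loci",
    "simulate_cross",
    "simulate_panel",
    "cross_seed",
]

BACKGROUNDS = ("C1RM", "C1DX")
SPECIES = ("santomea", "simulans", "mauritiana", "melanogaster")
GENOTYPES = ("nullo_X", "metafemale", "attachedX_female", "dp_male")
STAGES = ("embryonic", "larval", "pupal")

# Genome-wide synonymous divergence from D. melanogaster (Ks); the
# intraspecific entry is the maximum reported melanogaster nucleotide
# diversity, used as a conservative within-species divergence proxy.
KS_DEFAULTS = {
    "santomea": 0.24,
    "simulans": 0.11,
    "mauritiana": 0.11,
    "melanogaster": 0.03,
}


@dataclass(frozen=True)
class PaternalLine:
    """A paternal stock: species, line label and its divergence proxy."""

    species: str
    line_label: str
    ks: float | None  # None = divergence unknown; rejected by snowball_dataset

    def __post_init__(self) -> None:
        if self.species not in SPECIES:
            raise ValueError(f"unknown species {self.species!r}")
        if self.ks is not None and self.ks < 0:
            raise ValueError("Ks must be nonnegative")


@dataclass(frozen=True)
class PlantedLocus:
    """A dominant lethal allele planted at a single band.

    A duplication carries the locus iff its interval contains ``position``;
    the locus acts only against paternal species in ``species_set`` (hybrid
    incompatibilities are lineage specific, so intraspecific crosses are
    untouched unless ``melanogaster`` is listed explicitly).
    """

    position: CytoBand
    lethal_stage: str
    penetrance: float
    species_set: frozenset[str]

    def __post_init__(self) -> None:
        if self.lethal_stage not in STAGES:
            raise ValueError(f"unknown stage {self.lethal_stage!r}")
        if not 0.0 <= self.penetrance <= 1.0:
            raise ValueError("penetrance must lie in [0, 1]")
        if not self.species_set:
            raise ValueError("species_set must be nonempty")
        unknown = set(self.species_set) - set(SPECIES)
        if unknown:
            raise ValueError(f"unknown species in species_set: {sorted(unknown)}")


@dataclass(frozen=True)
class DuplicationStock:
    """A Dp(1;Y) stock carrying one cytological X interval."""

    stock_id: str
    dp_name: str
    interval: CytoInterval


@dataclass
class StageCounts:
    """Per-replicate census at the four developmental checkpoints.

    ``n_hatched`` counts hatched L1 of every genotype (hatch scoring cannot
    sex embryos); ``n_hatched_male``, ``n_pupae`` and ``n_adults`` are the
    sex-sorted male (``dp_male``) cohort unless the simulator was run with
    ``sex_sorted=False``.
    """

    replicate_id: int
    n_fertilized: int
    n_hatched: int
    n_pupae: int
    n_adults: int
    n_hatched_male: int | None = None
    inseminated: bool = True

    def __post_init__(self) -> None:
        seq = [self.n_fertilized, self.n_hatched, self.n_pupae, self.n_adults]
        if any(c < 0 for c in seq):
            raise ValueError("stage counts must be nonnegative")
        if any(a < b for a, b in zip(seq, seq[1:])):
            raise ValueError("stage censuses must be nonincreasing")


class SurvivalTable:
    """Per-(species, genotype) stage-transition survival probabilities.

    Each entry is a triple ``(embryo→L1, L1→pupa, pupa→adult)`` in [0, 1].
    """

    def __init__(
        self, entries: Mapping[tuple[str, str], tuple[float, float, float]]
    ) -> None:
        for (species, genotype), probs in entries.items():
            if species not in SPECIES:
                raise ValueError(f"unknown species {species!r}")
            if genotype not in GENOTYPES:
                raise ValueError(f"unknown genotype {genotype!r}")
            if len(probs) != len(STAGES):
                raise ValueError("need one probability per stage transition")
            if any(not 0.0 <= p <= 1.0 for p in probs):
                raise ValueError(
                    f"survival for {(species, genotype)} outside [0, 1]: {probs}"
                )
        self._entries = {k: tuple(float(p) for p in v) for k, v in entries.items()}

    def survival(self, species: str, genotype: str) -> tuple[float, ...]:
        return self._entries[(species, genotype)]

    def items(self):
        return self._entries.items()

    def with_overrides(
        self, overrides: Mapping[tuple[str, str], tuple[float, float, float]]
    ) -> "SurvivalTable":
        merged = dict(self._entries)
        merged.update(overrides)
        return SurvivalTable(merged)


def default_survival_table() -> SurvivalTable:
    """Defaults encoding the qualitative hybrid-viability observations.

    Nullo-X zygotes never complete cellularisation (0 embryonic survival,
    every species).  In *mel/san* crosses both female classes predominantly
    die as embryos (0.05 escaper hatch).  In *mel/sim* and *mel/mau* crosses
    the female classes hatch and feed but fail the larva→pupa transition.
    Intraspecific attached-X females are fully viable while metafemales
    almost never eclose (per-stage 0.05, overall 1.25e-4 — below the ~0.2%
    eclosion ceiling reported for melanogaster metafemales).  Baseline male
    survival is 0.9 per stage, placing unperturbed hatch fractions well above
    the 10% lethality cut-off and fully penetrant lethals well below it.
    """
    entries: dict[tuple[str, str], tuple[float, float, float]] = {}
    for sp in SPECIES:
        entries[(sp, "nullo_X")] = (0.0, 0.0, 0.0)
        entries[(sp, "dp_male")] = (0.9, 0.9, 0.9)
    for sp in ("santomea",):
        entries[(sp, "metafemale")] = (0.05, 0.0, 0.0)
        entries[(sp, "attachedX_female")] = (0.05, 0.0, 0.0)
    for sp in ("simulans", "mauritiana"):
        entries[(sp, "metafemale")] = (0.9, 0.0, 0.0)
        entries[(sp, "attachedX_female")] = (0.9, 0.0, 0.0)
    entries[("melanogaster", "metafemale")] = (0.05, 0.05, 0.05)
    entries[("melanogaster", "attachedX_female")] = (0.9, 0.9, 0.9)
    return SurvivalTable(entries)


def default_paternal_lines() -> list[PaternalLine]:
    """The five crosses of the screen: san, sim, mau and two mel controls."""
    return [
        PaternalLine("santomea", "SYN2005", KS_DEFAULTS["santomea"]),
        PaternalLine("simulans", "sim-line", KS_DEFAULTS["simulans"]),
        PaternalLine("mauritiana", "mau-line", KS_DEFAULTS["mauritiana"]),
        PaternalLine("melanogaster", "Malawi-6-3", KS_DEFAULTS["melanogaster"]),
        PaternalLine("melanogaster", "mel-iso-2", KS_DEFAULTS["melanogaster"]),
    ]


def _slot_band(slot: int, band: int = 1) -> CytoBand:
    """Subdivision slot s (0-based over 20 divisions x A-F) -> a band in it."""
    return CytoBand(slot // 6 + 1, "ABCDEF"[slot % 6], band)


def default_tiling_panel(
    n_stocks: int = 40, span: int = 4, step: int = 3
) -> list[DuplicationStock]:
    """A synthetic overlapping tiling of the euchromatic X.

    Stock ``k`` covers subdivision slots ``[k*step, k*step + span - 1]``
    (clamped to the 120-slot axis), so consecutive stocks share
    ``span - step`` slots, like a real Dp(1;Y) tiling panel.
    """
    n_slots = 20 * 6
    panel = []
    for k in range(n_stocks):
        lo = min(k * step, n_slots - 1)
        hi = min(k * step + span - 1, n_slots - 1)
        start = _slot_band(lo, 1)
        end_slot = hi
        end = CytoBand(end_slot // 6 + 1, "ABCDEF"[end_slot % 6], LAST_BAND)
        panel.append(
            DuplicationStock(f"BSC{k:03d}", f"Dp(1;Y)BSC{k:03d}", CytoInterval(start, end))
        )
    return panel


def default_planted_loci() -> list[PlantedLocus]:
    """The planted incompatibility architecture of the synthetic screen.

    Mirrors the screen's findings: twelve loci acting against *D. santomea*
    (nine embryonic, three pupal) plus two larval loci shared between
    *D. simulans* and *D. mauritiana*; nothing acts intraspecifically.
    Each locus sits in a slot covered by exactly one default-panel tile, and
    carrier tiles are pairwise disjoint, so the minimal-region answer for the
    architecture is exactly the planted counts.
    """
    san = frozenset({"santomea"})
    sim_mau = frozenset({"simulans", "mauritiana"})
    loci = []
    embryonic_tiles = [0, 2, 4, 6, 8, 10, 12, 14, 16]
    pupal_tiles = [18, 20, 22]
    larval_tiles = [26, 30]
    for k in embryonic_tiles:
        loci.append(PlantedLocus(_slot_band(3 * k + 1), "embryonic", 1.0, san))
    for k in pupal_tiles:
        loci.append(PlantedLocus(_slot_band(3 * k + 1), "pupal", 1.0, san))
    for k in larval_tiles:
        loci.append(PlantedLocus(_slot_band(3 * k + 1), "larval", 1.0, sim_mau))
    return loci


def _stage_kill_probs(
    duplication: CytoInterval | None,
    loci: Sequence[PlantedLocus],
    species: str,
) -> list[float]:
    """Per-transition probability that a dp_male carrier is killed by a
    planted lethal (independent loci compound multiplicatively)."""
    keep = [1.0, 1.0, 1.0]
    if duplication is None:
        return [0.0, 0.0, 0.0]
    for locus in loci:
        if species in locus.species_set and contains(duplication, locus.position):
            i = STAGES.index(locus.lethal_stage)
            keep[i] *= 1.0 - locus.penetrance
    return [1.0 - k for k in keep]


def simulate_cross(
    background: str,
    paternal: PaternalLine,
    duplication: CytoInterval | None,
    loci: Sequence[PlantedLocus],
    survival: SurvivalTable,
    clutch_size: int,
    n_replicates: int = 3,
    seed: int | np.random.SeedSequence = 0,
    *,
    inseminated: bool = True,
    sex_sorted: bool = True,
    count_nullo_as_fertilized: bool = True,
) -> list[StageCounts]:
    """Simulate replicate clutches of one cross.

    Genotype counts are multinomial (Mendelian 1/4 each); each genotype is
    thinned binomially through the three stage transitions; planted lethals
    add an extra kill probability for ``dp_male`` at their stage.  Output is
    deterministic given ``seed`` and the parameters.

    ``count_nullo_as_fertilized=False`` drops nullo-X zygotes from the
    fertilized-embryo denominator (they are grossly indistinguishable from
    unfertilized eggs; the default follows the protocol of counting all
    fertilized embryos, dead and hatched).
    """
    if background not in BACKGROUNDS:
        raise ValueError(f"unknown background {background!r}")
    if clutch_size < 1:
        raise ValueError("clutch_size must be a positive count")
    rng = np.random.default_rng(seed)
    kill = _stage_kill_probs(duplication, loci, paternal.species)

    out: list[StageCounts] = []
    for rep in range(1, n_replicates + 1):
        if not inseminated:
            out.append(
                StageCounts(rep, 0, 0, 0, 0, n_hatched_male=0, inseminated=False)
            )
            continue
        counts = rng.multinomial(clutch_size, [0.25] * 4)
        per_genotype = {}
        for genotype, n0 in zip(GENOTYPES, counts):
            s = survival.survival(paternal.species, genotype)
            alive = [int(n0)]
            for t in range(3):
                p = s[t]
                if genotype == "dp_male":
                    p *= 1.0 - kill[t]
                alive.append(int(rng.binomial(alive[-1], p)))
            per_genotype[genotype] = alive  # [embryos, L1, pupae, adults]

        n_fert = int(counts.sum())
        if not count_nullo_as_fertilized:
            n_fert -= per_genotype["nullo_X"][0]
        n_hatched = sum(a[1] for a in per_genotype.values())
        n_hatched_male = per_genotype["dp_male"][1]
        if sex_sorted:
            n_pupae = per_genotype["dp_male"][2]
            n_adults = per_genotype["dp_male"][3]
        else:
            n_pupae = sum(a[2] for a in per_genotype.values())
            n_adults = sum(a[3] for a in per_genotype.values())
        out.append(
            StageCounts(
                rep, n_fert, n_hatched, n_pupae, n_adults,
                n_hatched_male=n_hatched_male, inseminated=True,
            )
        )
    return out


def cross_seed(
    root_seed: int, stock_id: str, background: str, species: str, line: str
) -> np.random.SeedSequence:
    """Derive a per-cross seed by stable hashing of the cross identity, so any
    single cross is reproducible without replaying the whole panel."""
    digest = zlib.crc32(f"{stock_id}|{background}|{species}|{line}".encode())
    return np.random.SeedSequence([int(root_seed), digest])


VIABILITY_COLUMNS = [
    "stock_id", "background", "paternal_species", "line", "replicate",
    "n_fertilized", "n_hatched", "n_hatched_male", "n_pupae", "n_adults",
    "inseminated",
]


def simulate_panel(
    panel: Sequence[DuplicationStock],
    paternal_lines: Sequence[PaternalLine],
    loci: Sequence[PlantedLocus],
    survival: SurvivalTable | None = None,
    clutch_size: int = 300,
    n_replicates: int = 3,
    seed: int = 0,
    *,
    backgrounds: Sequence[str] = BACKGROUNDS,
    fail_fraction: float = 0.0,
    sex_sorted: bool = True,
    count_nullo_as_fertilized: bool = True,
) -> pd.DataFrame:
    """Simulate the full screen: every duplication x background x line.

    Returns a tidy frame with one row per replicate (columns
    ``VIABILITY_COLUMNS``, the on-disk viability-TSV schema).  Per-cross seeds
    are derived from ``seed`` by stable hashing; ``fail_fraction`` marks that
    share of crosses as uninseminated/no-progeny to exercise the screen's
    exclusion filters.
    """
    if not panel:
        raise ValueError("panel must be nonempty")
    ids = [s.stock_id for s in panel]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate stock ids in panel: {dupes}")
    if survival is None:
        survival = default_survival_table()

    rows = []
    for stock in panel:
        for background in backgrounds:
            for line in paternal_lines:
                ss = cross_seed(
                    seed, stock.stock_id, background, line.species, line.line_label
                )
                rng = np.random.default_rng(ss)
                ok = rng.random() >= fail_fraction
                reps = simulate_cross(
                    background, line, stock.interval, loci, survival,
                    clutch_size, n_replicates, rng,
                    inseminated=ok, sex_sorted=sex_sorted,
                    count_nullo_as_fertilized=count_nullo_as_fertilized,
                )
                for r in reps:
                    rows.append(
                        (
                            stock.stock_id, background, line.species,
                            line.line_label, r.replicate_id, r.n_fertilized,
                            r.n_hatched, r.n_hatched_male, r.n_pupae,
                            r.n_adults, r.inseminated,
                        )
                    )
    return pd.DataFrame(rows, columns=VIABILITY_COLUMNS)
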