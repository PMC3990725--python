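"""Cytological band coordinates on the Drosophila melanogaster X chromosome.

Positions on the polytene banding map are written ``<division><letter><band>``
(e.g. ``12E9``): numbered division 1-20 for the euchromatic X, subdivision
letter A-F, and a positive band number within the subdivision.  The centric
heterochromatin is divided into h-blocks (``h25`` .. ``h29``) which lie distal
to ``20F`` and are ordered among themselves by h-number.

The banding map defines a total order but no physical coordinate: interval
arithmetic here is purely ordinal.  Duplication extents such as ``2C1-3E4``
are closed intervals — a duplication carries both its endpoint bands.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable, Iterator, Union

__all__ = [
    "LAST_BAND",
    "CytoBand",
    "CytoInterval",
    "CytoParseError",
    "parse_band",
    "format_band",
    "band_leq",
    "band_sort_key",
    "parse_interval",
    "format_interval",
    "overlaps",
    "intersect",
    "contains",
    "full_axis",
    "ordinal_ranks",
    "interval_to_ordinal",
]

SUBDIVISIONS = "ABCDEF"
EUCHROMATIC_DIVISIONS = range(1, 21)
H_BLOCKS = range(25, 30)  # h25..h29 of the X centric heterochromatin


class _LastBand:
    """Sentinel band number meaning "the last band of this subdivision".

    The map's band count per subdivision varies between map revisions and is
    not needed for ordering: the sentinel simply compares greater than any
    concrete band number, so a right endpoint written without a band number
    (``...-10B``) closes the interval at the end of that subdivision.
    """

    _instance = None

    def __new__(cls):
        if cls._instance is None:
            cls._instance = super().__new__(cls)
        return cls._instance

    def __repr__(self) -> str:
        return "LAST_BAND"


LAST_BAND = _LastBand()

BandNumber = Union[int, _LastBand, None]


class CytoParseError(ValueError):
    """Raised when band or interval notation cannot be parsed."""


@dataclass(frozen=True)
class CytoBand:
    """One position on the banding map.

    ``division`` is 1-20 for euchromatin or the h-number (25-29) when
    ``heterochromatin`` is set.  ``subdivision``/``band`` are optional for
    partially specified positions ("9C"); h-blocks carry neither.
    """

    division: int
    subdivision: str | None = None
    band: BandNumber = None
    heterochromatin: bool = False

    def __post_init__(self) -> None:
        if self.heterochromatin:
            if self.division not in H_BLOCKS:
                raise CytoParseError(
                    f"unknown heterochromatin block 'h{self.division}' "
                    f"(known: h25-h29)"
                )
            if self.subdivision is not None or self.band is not None:
                raise CytoParseError("h-blocks carry no subdivision or band")
            return
        if self.division not in EUCHROMATIC_DIVISIONS:
            raise CytoParseError(
                f"division {self.division!r} outside euchromatic range 1-20"
            )
        if self.subdivision is not None and self.subdivision not in SUBDIVISIONS:
            raise CytoParseError(f"subdivision {self.subdivision!r} not in A-F")
        if self.band is not None:
            if self.subdivision is None:
                raise CytoParseError("band number requires a subdivision letter")
            if isinstance(self.band, int) and self.band < 1:
                raise CytoParseError(f"band number must be positive, got {self.band}")

    def __str__(self) -> str:
        return format_band(self)


def band_sort_key(b: CytoBand) -> tuple:
    """Key realising the total order: euchromatin by (division, letter, band),
    then all h-blocks, by h-number.  A missing letter/band sorts before 'A'/1,
    the LAST_BAND sentinel after every concrete band."""
    if b.heterochromatin:
        return (1, b.division, 0, 0)
    sub = 0 if b.subdivision is None else SUBDIVISIONS.index(b.subdivision) + 1
    if b.band is None:
        num = 0
    elif isinstance(b.band, _LastBand):
        num = 10**9
    else:
        num = b.band
    return (0, b.division, sub, num)


def band_leq(a: CytoBand, b: CytoBand) -> bool:
    """True iff ``a`` does not lie distal to ``b`` on the map."""
    return band_sort_key(a) <= band_sort_key(b)


_BAND_RE = re.compile(r"^(\d{1,2})(?:([A-F])(\d+)?)?$")
_HBLOCK_RE = re.compile(r"^H(\d+)$")


def parse_band(text: str) -> CytoBand:
    """Parse band notation like ``2C1``, ``20F3``, ``9C`` or ``h28``.

    Strings are case-normalised to uppercase first.  Raises
    :class:`CytoParseError` naming the offending token on malformed input or a
    division outside the map.
    """
    token = text.strip().upper()
    m = _HBLOCK_RE.match(token)
    if m:
        return CytoBand(int(m.group(1)), heterochromatin=True)
    m = _BAND_RE.match(token)
    if not m:
        raise CytoParseError(f"malformed band notation {text!r}")
    division = int(m.group(1))
    subdivision = m.group(2)
    band = int(m.group(3)) if m.group(3) is not None else None
    try:
        return CytoBand(division, subdivision, band)
    except CytoParseError as exc:
        raise CytoParseError(f"{text!r}: {exc}") from None


def format_band(b: CytoBand) -> str:
    """Inverse of :func:`parse_band`; the LAST_BAND sentinel is rendered by
    omitting the band number, matching how right-open endpoints are written."""
    if b.heterochromatin:
        return f"h{b.division}"
    out = str(b.division)
    if b.subdivision is not None:
        out += b.subdivision
        if isinstance(b.band, int):
            out += str(b.band)
    return out


@dataclass(frozen=True)
class CytoInterval:
    """Closed, nonempty interval of bands (both endpoints carried)."""

    start: CytoBand
    end: CytoBand

    def __post_init__(self) -> None:
        if not band_leq(self.start, self.end):
            raise CytoParseError(
                f"reversed interval: {format_band(self.start)} lies distal "
                f"to {format_band(self.end)}"
            )

    def __str__(self) -> str:
        return format_interval(self)


def _complete_down(b: CytoBand) -> CytoBand:
    """Left endpoints with missing components extend to the proximal edge."""
    if b.heterochromatin:
        return b
    sub = b.subdivision if b.subdivision is not None else "A"
    band = b.band if b.band is not None else 1
    return CytoBand(b.division, sub, band)


def _complete_up(b: CytoBand) -> CytoBand:
    """Right endpoints with missing components extend to the distal edge."""
    if b.heterochromatin:
        return b
    sub = b.subdivision if b.subdivision is not None else "F"
    band = b.band if b.band is not None else LAST_BAND
    return CytoBand(b.division, sub, band)


def parse_interval(text: str) -> CytoInterval:
    """Parse duplication-extent notation like ``2C1-3E4`` or ``9C-10B``.

    Partially specified endpoints are completed towards the outside of the
    interval: ``9C-10B`` means from the first band of 9C through the last band
    of 10B.  Reversed endpoints raise :class:`CytoParseError`.
    """
    parts = text.strip().split("-")
    if len(parts) != 2:
        raise CytoParseError(f"interval {text!r} is not of the form 'A-B'")
    start = _complete_down(parse_band(parts[0]))
    end = _complete_up(parse_band(parts[1]))
    return CytoInterval(start, end)


def format_interval(iv: CytoInterval) -> str:
    return f"{format_band(iv.start)}-{format_band(iv.end)}"


def overlaps(i1: CytoInterval, i2: CytoInterval) -> bool:
    """True iff the intervals share at least one band."""
    lo = max(i1.start, i2.start, key=band_sort_key)
    hi = min(i1.end, i2.end, key=band_sort_key)
    return band_leq(lo, hi)


def intersect(i1: CytoInterval, i2: CytoInterval) -> CytoInterval:
    """Shared region of two overlapping intervals.

    Raises :class:`ValueError` when the inputs are disjoint.
    """
    if not overlaps(i1, i2):
        raise ValueError(
            f"intervals {format_interval(i1)} and {format_interval(i2)} "
            f"share no bands"
        )
    lo = max(i1.start, i2.start, key=band_sort_key)
    hi = min(i1.end, i2.end, key=band_sort_key)
    return CytoInterval(lo, hi)


def contains(iv: CytoInterval, b: CytoBand) -> bool:
    """True iff band ``b`` lies within the closed interval ``iv``."""
    return band_leq(iv.start, b) and band_leq(b, iv.end)


def full_axis(
    bands_per_subdivision: int = 4,
    divisions: Iterable[int] = EUCHROMATIC_DIVISIONS,
    include_heterochromatin: bool = False,
) -> list[CytoBand]:
    """Enumerate an explicit, ordered band axis at a chosen map density.

    The real map's per-subdivision band counts are revision-dependent; this
    synthetic axis fixes a uniform count, which is all ordinal interval
    arithmetic needs.
    """
    axis = [
        CytoBand(d, s, n)
        for d in divisions
        for s in SUBDIVISIONS
        for n in range(1, bands_per_subdivision + 1)
    ]
    if include_heterochromatin:
        axis.extend(CytoBand(h, heterochromatin=True) for h in H_BLOCKS)
    return axis


def ordinal_ranks(bands: Iterable[CytoBand]) -> dict[CytoBand, int]:
    """Rank each distinct band along the order relation (0-based).

    The ranks are ordinal plotting coordinates, not physical positions.
    """
    distinct = sorted(set(bands), key=band_sort_key)
    return {b: i for i, b in enumerate(distinct)}


def interval_to_ordinal(
    iv: CytoInterval, ranks: dict[CytoBand, int]
) -> tuple[int, int]:
    """Closed band interval -> 0-based half-open ordinal coordinates."""
    return ranks[iv.start], ranks[iv.end] + 1


def iter_bands(iv: CytoInterval, axis: list[CytoBand]) -> Iterator[CytoBand]:
    """Expand an interval to the explicit bands of ``axis`` it covers."""
    for b in axis:
        if contains(iv, b):
            yield b
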