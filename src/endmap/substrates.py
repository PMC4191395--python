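"""Coordinate arithmetic for defined in vitro transcripts.

In vitro substrates are described in codon-relative coordinates: positions
are numbered from the start codon with no position zero (... -2, -1, +1, +2
...), and each T7 transcript carries an extra GGG at the 5' end.  A cleavage
coordinate names the last nucleotide of the upstream product, so a substrate
cut at position c yields an upstream product of prefix + |[start, c]| nt and
a downstream product of |(c, end]| nt; the two always sum to the substrate
length.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Tuple


def axis_offset(coordinate: int) -> int:
    """Monotone unit-step mapping of the no-zero codon axis onto the integers.

    Skips zero so that ``axis_offset(-1) + 1 == axis_offset(+1)``.
    """
    if coordinate == 0:
        raise ValueError("codon-relative coordinates have no position zero")
    return coordinate - 1 if coordinate > 0 else coordinate


def axis_position(offset: int) -> int:
    """Inverse of :func:`axis_offset`."""
    return offset + 1 if offset >= 0 else offset


def axis_successor(coordinate: int) -> int:
    """The next position on the no-zero axis (skipping zero)."""
    return axis_position(axis_offset(coordinate) + 1)


def span_positions(start: int, end: int) -> int:
    """Number of nucleotides in the closed codon-relative span [start, end]."""
    n = axis_offset(end) - axis_offset(start) + 1
    if n < 1:
        raise ValueError(f"empty span [{start}, {end}]")
    return n


@dataclass
class SubstrateSpec:
    """A defined in vitro transcript in codon-relative coordinates."""

    name: str
    start: int
    end: int
    prefix: int = 3  # the 5' GGG from T7 transcription

    def __post_init__(self) -> None:
        if self.start == 0 or self.end == 0:
            raise ValueError("codon-relative coordinates have no position zero")
        if axis_offset(self.start) > axis_offset(self.end):
            raise ValueError("start must not lie after end")
        if self.prefix < 0:
            raise ValueError("prefix length must be >= 0")

    def contains(self, position: int) -> bool:
        return axis_offset(self.start) <= axis_offset(position) <= axis_offset(self.end)


@dataclass
class CleavagePoint:
    """A cut position: the last nucleotide of the upstream product."""

    position: int

    def __post_init__(self) -> None:
        if self.position == 0:
            raise ValueError("codon-relative coordinates have no position zero")


def substrate_length(spec: SubstrateSpec) -> int:
    """Total transcript length in nt: 5' prefix + span size."""
    return spec.prefix + span_positions(spec.start, spec.end)


def product_sizes(spec: SubstrateSpec, cut: CleavagePoint | int) -> Tuple[int, int]:
    """(upstream nt, downstream nt) for a cut inside the substrate.

    The upstream product carries the 5' prefix; the sizes always sum to the
    substrate length.  Cutting at or beyond the 3' end is an error (there
    would be no downstream product).
    """
    position = cut.position if isinstance(cut, CleavagePoint) else int(cut)
    if position == 0:
        raise ValueError("codon-relative coordinates have no position zero")
    if not spec.contains(position) or axis_offset(position) >= axis_offset(spec.end):
        raise ValueError(
            f"cut {position} must lie within [{spec.start}, {spec.end})"
        )
    upstream = spec.prefix + span_positions(spec.start, position)
    downstream = axis_offset(spec.end) - axis_offset(position)
    return upstream, downstream


def relative_product_shift(known_upstream: int, known_offset: int, new_offset: int) -> int:
    """Upstream-product size at a new cut offset from the same reference point.

    If a cut ``known_offset`` nt downstream of a landmark yields an upstream
    product of ``known_upstream`` nt, a cut ``new_offset`` nt downstream
    yields ``known_upstream + (new_offset - known_offset)`` nt.
    """
    return known_upstream + (new_offset - known_offset)


def block_overlap(
    spec: SubstrateSpec, blocked: Tuple[int, int], cut: CleavagePoint | int
) -> bool:
    """Does an annealed oligonucleotide cover the scissile position?

    True iff the cut position or the base immediately 3' of it (the first
    nucleotide of the downstream product) lies within the blocked interval.
    Pure geometry: distal effects of blocking on other sites are biology,
    not arithmetic.
    """
    position = cut.position if isinstance(cut, CleavagePoint) else int(cut)
    lo, hi = (axis_offset(blocked[0]), axis_offset(blocked[1]))
    if lo > hi:
        raise ValueError("blocked interval start must not lie after its end")
    if not (axis_offset(spec.start) <= lo and hi <= axis_offset(spec.end)):
        raise ValueError("blocked interval must lie within the substrate")
    for candidate in (axis_offset(position), axis_offset(position) + 1):
        if lo <= candidate <= hi:
            return True
    return False
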