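"""Shared containers and conventions for 5'-end sequencing analysis.

Coordinate conventions used throughout the package:

* genomic positions are 1-based and intervals are closed; conversion to the
  0-based half-open convention of BED/bedGraph happens only in the readers
  and writers (:mod:`endmap.io`);
* a "read start" is the genomic coordinate of a read's 5'-most base.  On the
  minus strand this is the *larger* coordinate of the aligned segment;
* a cleavage-site coordinate is the last nucleotide of the upstream product,
  so the detectable downstream 5' end sits at ``position + 1`` on the plus
  strand and ``position - 1`` on the minus strand;
* "upstream"/"downstream" are transcript-orientation concepts: on the minus
  strand downstream means decreasing genomic coordinate.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterator, Tuple

import pandas as pd

#: default 5' sequencing adapter used by the simulator and trimmer
DEFAULT_ADAPTER = "ACACGACGCT"

#: Phred+33 quality character emitted for every simulated base
DEFAULT_QUALITY_CHAR = "I"

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

#: key addressing one genomic 5'-end position
Key = Tuple[str, str, int]  # (reference, strand, 1-based position)

STRANDS = ("+", "-")


class EndmapError(Exception):
    """Base class for errors raised by this package."""


class ParseError(EndmapError):
    """A malformed record in an input file (the message names the offender)."""


def revcomp(seq: str) -> str:
    """Reverse complement of a nucleotide string."""
    return seq.translate(_COMPLEMENT)[::-1]


def downstream_end(position: int, strand: str) -> int:
    """Genomic coordinate of the 5' end created by cleavage after ``position``.

    ``position`` is the last nucleotide of the upstream product; the new
    downstream 5' end is the next base in transcript orientation.
    """
    return position + 1 if strand == "+" else position - 1


@dataclass
class ReadRecord:
    """One simulated or parsed sequencing read (FASTQ semantics)."""

    identifier: str
    sequence: str
    quality: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError("read sequence must be non-empty")
        if len(self.quality) != len(self.sequence):
            raise ValueError("quality string length must equal sequence length")


class EndCountTable:
    """Per-position counts of read 5' starts for one library.

    A sparse mapping ``(reference, strand, position) -> count``; zero counts
    are never stored.  ``total_mapped`` records how many reads contributed,
    which for simulated tables equals the library size.
    """

    def __init__(
        self,
        counts: Dict[Key, int] | None = None,
        condition: str = "",
        total_mapped: int | None = None,
    ) -> None:
        self.counts: Dict[Key, int] = {}
        if counts:
            for key, n in counts.items():
                if n < 0:
                    raise ValueError(f"negative count at {key}")
                if n > 0:
                    self.counts[key] = int(n)
        self.condition = condition
        self.total_mapped = (
            int(total_mapped) if total_mapped is not None else sum(self.counts.values())
        )

    def add(self, reference: str, strand: str, position: int, n: int = 1) -> None:
        if strand not in STRANDS:
            raise ValueError(f"strand must be + or -, got {strand!r}")
        key = (reference, strand, int(position))
        self.counts[key] = self.counts.get(key, 0) + n

    def get(self, reference: str, strand: str, position: int) -> int:
        return self.counts.get((reference, strand, position), 0)

    def __len__(self) -> int:
        return len(self.counts)

    def __iter__(self) -> Iterator[Tuple[Key, int]]:
        return iter(sorted(self.counts.items()))

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, EndCountTable):
            return NotImplemented
        return self.counts == other.counts

    def total(self) -> int:
        return sum(self.counts.values())

    def to_dataframe(self) -> pd.DataFrame:
        keys = sorted(self.counts)
        return pd.DataFrame(
            {
                "reference": [k[0] for k in keys],
                "strand": [k[1] for k in keys],
                "position": [k[2] for k in keys],
                "count": [self.counts[k] for k in keys],
            }
        )

    def __repr__(self) -> str:  # pragma: no cover
        return (
            f"EndCountTable(condition={self.condition!r}, positions={len(self)}, "
            f"total_mapped={self.total_mapped})"
        )
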