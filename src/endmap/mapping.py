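"""From raw or aligned reads to strand-specific per-position 5'-end counts.

Raw-read path: anchored 5'-adapter removal, terminal poly(A) stripping, then
exact full-length placement on the toy genome (both strands, unique matches
only).  Aligned-read path: SAM (via pysam) or BED6, taking each record's
5'-most aligned reference base.  Soft-clipped bases are treated as already
trimmed and are never added back when locating the 5' end.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Optional, Tuple, Union

import pysam

from .core import EndCountTable, Key, ParseError, ReadRecord, revcomp
from .io import bed_five_prime, read_bed6, read_fastq


@dataclass(frozen=True)
class Rejection:
    """Why a read was discarded; a reported outcome, not an error."""

    reason: str  # no_adapter | short | unmapped | multimapped


@dataclass
class TrimPolicy:
    """Adapter/poly(A) trimming rules."""

    adapter: str
    max_adapter_mismatches: int = 0
    min_polya_run: int = 5
    min_length: int = 20

    def __post_init__(self) -> None:
        if self.min_length < 12:
            raise ValueError("min post-trim length must be >= 12")
        if not self.adapter:
            raise ValueError("adapter must be non-empty")


def trim_read(read: Union[ReadRecord, str], policy: TrimPolicy) -> Union[str, Rejection]:
    """Remove the anchored 5' adapter and any terminal 3' poly(A) run."""
    seq = read.sequence if isinstance(read, ReadRecord) else read
    adapter = policy.adapter
    if len(seq) < len(adapter):
        return Rejection("no_adapter")
    mismatches = sum(a != b for a, b in zip(adapter, seq))
    if mismatches > policy.max_adapter_mismatches:
        return Rejection("no_adapter")
    trimmed = seq[len(adapter) :]
    run = len(trimmed) - len(trimmed.rstrip("A"))
    if run >= policy.min_polya_run:
        trimmed = trimmed.rstrip("A")
    if len(trimmed) < policy.min_length:
        return Rejection("short")
    return trimmed


class GenomeIndex:
    """Exact-match index over both strands of a toy genome.

    A k-mer prefix table narrows candidates; full-length verification then
    yields every occurrence, so uniqueness can be enforced.
    """

    def __init__(self, genome: Mapping[str, str], k: int = 16) -> None:
        self.genome = {name: seq.upper() for name, seq in genome.items()}
        self.k = k
        self._table: Dict[str, List[Tuple[str, int]]] = {}
        for name, seq in self.genome.items():
            for i in range(len(seq) - k + 1):
                self._table.setdefault(seq[i : i + k], []).append((name, i))

    def occurrences(self, seq: str) -> List[Key]:
        """All genomic 5'-start keys where ``seq`` matches exactly."""
        hits: List[Key] = []
        if len(seq) >= self.k:
            for name, i in self._table.get(seq[: self.k], ()):
                if self.genome[name][i : i + len(seq)] == seq:
                    hits.append((name, "+", i + 1))
            rc = revcomp(seq)
            for name, i in self._table.get(rc[: self.k], ()):
                if self.genome[name][i : i + len(rc)] == rc:
                    hits.append((name, "-", i + len(rc)))
        else:  # shorter than k: exhaustive scan
            rc = revcomp(seq)
            for name, ref_seq in self.genome.items():
                start = ref_seq.find(seq)
                while start != -1:
                    hits.append((name, "+", start + 1))
                    start = ref_seq.find(seq, start + 1)
                start = ref_seq.find(rc)
                while start != -1:
                    hits.append((name, "-", start + len(rc)))
                    start = ref_seq.find(rc, start + 1)
        return hits


def map_read_start(
    seq: str, genome: Union[GenomeIndex, Mapping[str, str]]
) -> Union[Key, Rejection]:
    """Unique exact placement of a trimmed read; the key is its 5'-most base.

    For minus-strand matches the 5'-most base is the larger coordinate of
    the matched segment.
    """
    index = genome if isinstance(genome, GenomeIndex) else GenomeIndex(genome)
    hits = index.occurrences(seq)
    if not hits:
        return Rejection("unmapped")
    if len(hits) > 1:
        return Rejection("multimapped")
    return hits[0]


def count_reads(
    reads: Iterable[ReadRecord],
    genome: Union[GenomeIndex, Mapping[str, str]],
    policy: TrimPolicy,
    condition: str = "",
) -> Tuple[EndCountTable, Dict[str, int]]:
    """Trim, place and count a stream of raw reads.

    Returns the count table and an accounting dict satisfying
    ``input == mapped + no_adapter + short + unmapped + multimapped``.
    """
    index = genome if isinstance(genome, GenomeIndex) else GenomeIndex(genome)
    stats: Counter = Counter(input=0, mapped=0, no_adapter=0, short=0, unmapped=0, multimapped=0)
    table = EndCountTable(condition=condition)
    cache: Dict[str, Union[Key, Rejection]] = {}
    for read in reads:
        stats["input"] += 1
        trimmed = trim_read(read, policy)
        if isinstance(trimmed, Rejection):
            stats[trimmed.reason] += 1
            continue
        result = cache.get(trimmed)
        if result is None:
            result = map_read_start(trimmed, index)
            cache[trimmed] = result
        if isinstance(result, Rejection):
            stats[result.reason] += 1
            continue
        table.add(*result)
        stats["mapped"] += 1
    table.total_mapped = stats["mapped"]
    return table, dict(stats)


def count_reads_from_fastq(
    fastq_path: str | Path,
    genome: Union[GenomeIndex, Mapping[str, str]],
    policy: TrimPolicy,
    condition: str = "",
) -> Tuple[EndCountTable, Dict[str, int]]:
    return count_reads(read_fastq(fastq_path), genome, policy, condition=condition)


# ---------------------------------------------------------------------------
# aligned-read path
# ---------------------------------------------------------------------------

def _count_sam(path: str | Path, table: EndCountTable) -> int:
    used = 0
    try:
        with pysam.AlignmentFile(str(path), "r", check_sq=False) as sam:
            for rec in sam:
                if rec.is_unmapped or rec.is_secondary or rec.is_supplementary:
                    continue
                if rec.cigartuples is None or rec.reference_end is None:
                    raise ParseError(
                        f"{path}: record {rec.query_name!r} lacks a usable CIGAR"
                    )
                if rec.is_reverse:
                    # last aligned reference base (reference_end is exclusive)
                    table.add(rec.reference_name, "-", rec.reference_end)
                else:
                    table.add(rec.reference_name, "+", rec.reference_start + 1)
                used += 1
    except (ValueError, OSError) as exc:
        raise ParseError(f"{path}: malformed SAM record ({exc})") from exc
    return used


def _count_bed(path: str | Path, table: EndCountTable) -> int:
    bed = read_bed6(path)
    ends = bed_five_prime(bed)
    for row in ends.itertuples(index=False):
        table.add(row.reference, row.strand, row.position)
    return len(ends)


def count_starts_from_alignments(
    path: str | Path, fmt: Optional[str] = None, condition: str = ""
) -> EndCountTable:
    """Count read 5' starts from a SAM (text) or BED6 alignment file.

    Forward records contribute their first aligned reference base, reverse
    records their last; BED intervals contribute start+1 (+) or end (-).
    """
    path = Path(path)
    if fmt is None:
        fmt = path.suffix.lstrip(".").lower()
    table = EndCountTable(condition=condition or path.stem)
    if fmt == "sam":
        used = _count_sam(path, table)
    elif fmt == "bed":
        used = _count_bed(path, table)
    else:
        raise ValueError(f"unsupported alignment format {fmt!r}")
    table.total_mapped = used
    return table
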