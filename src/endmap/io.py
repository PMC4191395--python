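"""Readers and writers for the plain-text formats the pipeline exchanges.

All coordinate conversion between the package's 1-based closed convention and
the 0-based half-open convention of BED/bedGraph happens here and nowhere
else.
"""

from __future__ import annotations

import gzip
from pathlib import Path
from typing import Dict, Iterable, Iterator, List, Mapping, Tuple

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .core import DEFAULT_QUALITY_CHAR, EndCountTable, Key, ParseError, ReadRecord


def _open_text(path: str | Path, mode: str = "rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


# ---------------------------------------------------------------------------
# FASTA / FASTQ
# ---------------------------------------------------------------------------

def write_fasta(genome: Mapping[str, str], path: str | Path) -> None:
    records = [SeqRecord(Seq(seq), id=name, description="") for name, seq in genome.items()]
    with open(path, "w") as handle:
        SeqIO.write(records, handle, "fasta")


def read_fasta(path: str | Path) -> Dict[str, str]:
    with _open_text(path) as handle:
        return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(handle, "fasta")}


def write_fastq(reads: Iterable[ReadRecord], path: str | Path) -> None:
    with open(path, "w") as handle:
        for read in reads:
            handle.write(f"@{read.identifier}\n{read.sequence}\n+\n{read.quality}\n")


def read_fastq(path: str | Path) -> Iterator[ReadRecord]:
    """Iterate over a FASTQ file (gz-transparent)."""
    with _open_text(path) as handle:
        for rec in SeqIO.parse(handle, "fastq"):
            quals = rec.letter_annotations.get("phred_quality")
            quality = (
                "".join(chr(q + 33) for q in quals)
                if quals
                else DEFAULT_QUALITY_CHAR * len(rec.seq)
            )
            yield ReadRecord(rec.id, str(rec.seq).upper(), quality)


# ---------------------------------------------------------------------------
# EndCountTable <-> TSV / bedGraph
# ---------------------------------------------------------------------------

_COUNT_COLUMNS = ["reference", "strand", "position_1based", "count"]


def write_counts_tsv(table: EndCountTable, path: str | Path) -> None:
    with open(path, "w") as handle:
        handle.write(f"# condition={table.condition}\ttotal_mapped={table.total_mapped}\n")
        handle.write("\t".join(_COUNT_COLUMNS) + "\n")
        for (ref, strand, pos), n in table:
            handle.write(f"{ref}\t{strand}\t{pos}\t{n}\n")


def read_counts_tsv(path: str | Path) -> EndCountTable:
    condition = ""
    total_mapped = None
    counts: Dict[Key, int] = {}
    with _open_text(path) as handle:
        for lineno, line in enumerate(handle, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                for part in line[1:].split("\t"):
                    if part.strip().startswith("condition="):
                        condition = part.split("=", 1)[1]
                    elif part.strip().startswith("total_mapped="):
                        total_mapped = int(part.split("=", 1)[1])
                continue
            fields = line.split("\t")
            if fields[0] == "reference":
                continue
            if len(fields) != 4:
                raise ParseError(f"{path}:{lineno}: expected 4 columns, got {len(fields)}")
            ref, strand, pos, n = fields
            counts[(ref, strand, int(pos))] = int(n)
    return EndCountTable(counts, condition=condition, total_mapped=total_mapped)


def write_bedgraph(table: EndCountTable, prefix: str | Path) -> Tuple[Path, Path]:
    """Write strand-split bedGraph files ``<prefix>.plus.bedgraph`` etc.

    Internal 1-based closed positions become 0-based half-open width-1
    intervals.
    """
    prefix = Path(prefix)
    paths = (
        prefix.with_suffix(prefix.suffix + ".plus.bedgraph"),
        prefix.with_suffix(prefix.suffix + ".minus.bedgraph"),
    )
    handles = {"+": open(paths[0], "w"), "-": open(paths[1], "w")}
    try:
        for (ref, strand, pos), n in table:
            handles[strand].write(f"{ref}\t{pos - 1}\t{pos}\t{n}\n")
    finally:
        for handle in handles.values():
            handle.close()
    return paths


# ---------------------------------------------------------------------------
# BED6
# ---------------------------------------------------------------------------

def write_bed6(
    rows: Iterable[Tuple[str, int, str, str, int]],
    path: str | Path,
) -> None:
    """Write BED6 from 1-based single-position rows.

    ``rows`` yields (reference, position_1based, strand, name, score).
    """
    with open(path, "w") as handle:
        for ref, pos, strand, name, score in rows:
            handle.write(f"{ref}\t{pos - 1}\t{pos}\t{name}\t{score}\t{strand}\n")


def read_bed6(path: str | Path) -> pd.DataFrame:
    """Read a BED6 file into a frame with 0-based half-open start/end."""
    rows: List[Tuple[str, int, int, str, float, str]] = []
    with _open_text(path) as handle:
        for lineno, line in enumerate(handle, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("track", "browser", "#")):
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise ParseError(f"{path}:{lineno}: BED6 requires >= 6 columns")
            try:
                rows.append(
                    (
                        fields[0],
                        int(fields[1]),
                        int(fields[2]),
                        fields[3],
                        float(fields[4]),
                        fields[5],
                    )
                )
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from None
            if fields[5] not in ("+", "-"):
                raise ParseError(f"{path}:{lineno}: strand must be + or -")
    return pd.DataFrame(rows, columns=["reference", "start", "end", "name", "score", "strand"])


def bed_five_prime(bed: pd.DataFrame) -> pd.DataFrame:
    """1-based 5'-end position of each BED interval (start+1 for +, end for -)."""
    position = bed["start"].where(bed["strand"] == "-", bed["start"] + 1)
    position = position.where(bed["strand"] == "+", bed["end"])
    return pd.DataFrame(
        {
            "reference": bed["reference"],
            "strand": bed["strand"],
            "position": position.astype(int),
        }
    )


# ---------------------------------------------------------------------------
# MA tables and site calls
# ---------------------------------------------------------------------------

def write_ma_tsv(ma: pd.DataFrame, path: str | Path) -> None:
    ma.to_csv(path, sep="\t", index=False)


def read_ma_tsv(path: str | Path) -> pd.DataFrame:
    ma = pd.read_csv(path, sep="\t")
    for col in ("nominal_a", "nominal_b"):
        if col in ma.columns:
            ma[col] = ma[col].astype(bool)
    return ma


def write_report(stats: Mapping[str, object], path: str | Path) -> None:
    """Write a key:value text report (trimming/mapping accounting)."""
    with open(path, "w") as handle:
        for key, value in stats.items():
            handle.write(f"{key}: {value}\n")
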