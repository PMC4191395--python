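"""Synthetic genomes, transcripts and 5'-end sequencing libraries.

The generator emulates the statistical structure that 5'-monophosphorylated-
end sequencing produces:

* only 5'-monophosphorylated ends are detectable; triphosphorylated or
  hydroxylated ends are simply absent from the library.  The fraction of a
  transcript's molecules carrying a detectable native 5' end is
  ``native_end_fraction``;
* endonucleolytic cleavage converts molecules into new detectable downstream
  5' ends (one per cleavage site, at the base after the site in transcript
  orientation) and removes the corresponding native-ended species;
* sequencing draws a fixed total of ``library_size`` reads multinomially over
  the molecule-end weights.  Because the total is fixed, creating new ends
  *dilutes* the pre-existing population: after incubation with an active
  enzyme the unenriched "cone" of positions shifts to a negative log2 ratio,
  exactly as competitive amplification of a fixed library does;
* enzyme-deficient conditions multiply dependence-matched site ends by a
  depletion factor (temperature-inactivated allele) and the nearest upstream
  precursor end by an accumulation factor (knockout that blocks 5'-trimming).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field, replace
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np

from .core import (
    DEFAULT_ADAPTER,
    DEFAULT_QUALITY_CHAR,
    EndCountTable,
    EndmapError,
    Key,
    ReadRecord,
    downstream_end,
    revcomp,
)

BEFORE = "before"  # timepoint label meaning "no incubation yet"


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class CleavageSite:
    """A planted cleavage position within one transcript.

    ``position`` is the last nucleotide of the upstream product (1-based
    genomic); the detectable downstream 5' end is the next base in transcript
    orientation.  ``efficiency_by_time`` maps ordered timepoint labels to the
    fraction of molecules cleaved by that time.
    """

    position: int
    efficiency_by_time: Dict[str, float]
    dependence: str = "independent"

    def __post_init__(self) -> None:
        last = 0.0
        for label, eff in self.efficiency_by_time.items():
            if not 0.0 <= eff <= 1.0:
                raise ValueError(f"efficiency at {label!r} outside [0, 1]: {eff}")
            if eff < last:
                raise ValueError("efficiencies must be non-decreasing over timepoints")
            last = eff
        if self.dependence not in ("independent", "rne_dependent", "rng_dependent"):
            raise ValueError(f"unknown dependence {self.dependence!r}")

    def efficiency(self, timepoint: str) -> float:
        if timepoint == BEFORE:
            return 0.0
        if timepoint not in self.efficiency_by_time:
            raise EndmapError(f"timepoint {timepoint!r} missing from site at {self.position}")
        return self.efficiency_by_time[timepoint]


@dataclass
class TranscriptModel:
    """One transcript: genomic span, abundance and planted cleavage sites."""

    reference: str
    strand: str
    start: int
    end: int
    abundance: float
    native_end_fraction: float = 1.0
    planted_sites: List[CleavageSite] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError("strand must be + or -")
        if self.start > self.end or self.start < 1:
            raise ValueError("invalid span")
        if self.abundance <= 0:
            raise ValueError("abundance must be positive")
        if not 0.0 <= self.native_end_fraction <= 1.0:
            raise ValueError("native_end_fraction must lie in [0, 1]")
        for site in self.planted_sites:
            if not self.start < site.position < self.end:
                raise ValueError(
                    f"site {site.position} not strictly inside span "
                    f"[{self.start}, {self.end}]"
                )

    @property
    def five_prime(self) -> int:
        """Genomic coordinate of the native 5' end."""
        return self.start if self.strand == "+" else self.end

    @property
    def three_prime(self) -> int:
        return self.end if self.strand == "+" else self.start


@dataclass
class LibrarySpec:
    """Sampling parameters for one sequencing library.

    ``depletion_factor`` multiplies the weight of site ends whose dependence
    matches ``target_dependence`` (modelling a ts or knockout condition);
    ``accumulation_factor`` multiplies the nearest upstream (precursor) end of
    each matched site.
    """

    condition: str
    library_size: int
    depletion_factor: float = 1.0
    accumulation_factor: float = 1.0
    seed: int = 0
    target_dependence: Optional[str] = None

    def __post_init__(self) -> None:
        if self.library_size < 1:
            raise ValueError("library_size must be >= 1")
        if not 0.0 < self.depletion_factor <= 1.0:
            raise ValueError("depletion_factor must lie in (0, 1]")
        if self.accumulation_factor < 1.0:
            raise ValueError("accumulation_factor must be >= 1")


# ---------------------------------------------------------------------------
# genome
# ---------------------------------------------------------------------------

def make_genome(seed: int, n_refs: int = 1, length: int = 50_000) -> Dict[str, str]:
    """Uniform-random toy genome, reproducible for a fixed seed."""
    if length < 1000:
        raise ValueError("length must be >= 1000")
    if n_refs < 1:
        raise ValueError("n_refs must be >= 1")
    rng = np.random.default_rng(seed)
    alphabet = np.frombuffer(b"ACGT", dtype="S1")
    genome = {}
    for i in range(n_refs):
        bases = rng.integers(0, 4, size=length)
        genome[f"ref{i + 1}"] = alphabet[bases].tobytes().decode()
    return genome


# ---------------------------------------------------------------------------
# end-count simulation
# ---------------------------------------------------------------------------

def _end_weights(
    transcripts: Sequence[TranscriptModel],
    spec: LibrarySpec,
    timepoint: str,
) -> Dict[Key, float]:
    weights: Dict[Key, float] = {}
    for t in transcripts:
        effs = [site.efficiency(timepoint) for site in t.planted_sites]
        # cleaved molecules no longer contribute their native-ended species
        native_w = t.abundance * t.native_end_fraction * max(0.0, 1.0 - sum(effs))
        ends: List[Tuple[int, float, Optional[CleavageSite]]] = [
            (t.five_prime, native_w, None)
        ]
        for site, eff in zip(t.planted_sites, effs):
            w = t.abundance * eff
            if spec.target_dependence is not None and site.dependence == spec.target_dependence:
                w *= spec.depletion_factor
            ends.append((downstream_end(site.position, t.strand), w, site))
        if spec.target_dependence is not None and spec.accumulation_factor != 1.0:
            for pos, _w, site in list(ends):
                if site is None or site.dependence != spec.target_dependence:
                    continue
                # precursor = nearest detectable end upstream of this site end
                if t.strand == "+":
                    upstream = [i for i, e in enumerate(ends) if e[0] < pos]
                    best = max(upstream, key=lambda i: ends[i][0], default=None)
                else:
                    upstream = [i for i, e in enumerate(ends) if e[0] > pos]
                    best = min(upstream, key=lambda i: ends[i][0], default=None)
                if best is not None:
                    p, w, s = ends[best]
                    ends[best] = (p, w * spec.accumulation_factor, s)
        for pos, w, _site in ends:
            if w > 0.0:
                key = (t.reference, t.strand, pos)
                weights[key] = weights.get(key, 0.0) + w
    return weights


def simulate_end_counts(
    transcripts: Sequence[TranscriptModel],
    spec: LibrarySpec,
    timepoint: str,
) -> EndCountTable:
    """Draw ``spec.library_size`` reads multinomially over molecule-end weights.

    The returned counts always sum exactly to the library size; competition
    for the fixed total is what produces the negative baseline shift when
    cleavage creates new ends.
    """
    if not transcripts:
        raise EndmapError("no transcripts to simulate")
    weights = _end_weights(transcripts, spec, timepoint)
    keys = sorted(weights)
    w = np.array([weights[k] for k in keys], dtype=float)
    total = w.sum()
    if total <= 0.0:
        raise EndmapError("all molecule-end weights are zero; nothing to sequence")
    rng = np.random.default_rng(spec.seed)
    counts = rng.multinomial(spec.library_size, w / total)
    table = EndCountTable(condition=spec.condition, total_mapped=spec.library_size)
    for key, n in zip(keys, counts):
        if n > 0:
            table.counts[key] = int(n)
    return table


# ---------------------------------------------------------------------------
# read emission
# ---------------------------------------------------------------------------

def emit_reads(
    counts: EndCountTable,
    genome: Mapping[str, str],
    adapter: str = DEFAULT_ADAPTER,
    read_length: int = 50,
    polya_len: int = 8,
    seed: int = 0,
    transcripts: Optional[Sequence[TranscriptModel]] = None,
) -> List[ReadRecord]:
    """One read per count unit: adapter + genome fragment (+ poly(A) tail).

    The genome-derived segment starts exactly at the counted position on the
    counted strand (reverse-complemented for minus-strand ends).  When the
    covering transcript's 3' boundary truncates the fragment, a poly(A) run
    is appended, emulating 3' tailing by poly(A) polymerase.
    """
    if read_length < 20:
        raise ValueError("read_length must be >= 20")
    cap = read_length - len(adapter)
    if cap < 1:
        raise ValueError("adapter longer than read")
    by_loc: Dict[Tuple[str, str], List[TranscriptModel]] = {}
    for t in transcripts or ():
        by_loc.setdefault((t.reference, t.strand), []).append(t)

    reads: List[ReadRecord] = []
    serial = 0
    for (ref, strand, pos), n in counts:
        if ref not in genome:
            raise EndmapError(f"reference {ref!r} not in genome")
        seq = genome[ref]
        if not 1 <= pos <= len(seq):
            raise EndmapError(f"position {pos} outside {ref} (length {len(seq)})")
        covering = next(
            (t for t in by_loc.get((ref, strand), ()) if t.start <= pos <= t.end),
            None,
        )
        if strand == "+":
            avail = len(seq) - pos + 1
            if covering is not None:
                avail = min(avail, covering.end - pos + 1)
            frag_len = min(cap, avail)
            frag = seq[pos - 1 : pos - 1 + frag_len]
        else:
            avail = pos
            if covering is not None:
                avail = min(avail, pos - covering.start + 1)
            frag_len = min(cap, avail)
            frag = revcomp(seq[pos - frag_len : pos])
        tail = ""
        if covering is not None and frag_len < cap:
            tail = "A" * polya_len
        read_seq = (adapter + frag + tail)[:read_length]
        for _ in range(n):
            serial += 1
            reads.append(
                ReadRecord(
                    f"sim{serial}",
                    read_seq,
                    DEFAULT_QUALITY_CHAR * len(read_seq),
                )
            )
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(reads))
    return [reads[i] for i in order]


# ---------------------------------------------------------------------------
# scenario builders (the study conditions)
# ---------------------------------------------------------------------------

@dataclass
class Scenario:
    """A toy genome plus transcript models and read-emission parameters."""

    genome: Dict[str, str]
    transcripts: List[TranscriptModel]
    adapter: str = DEFAULT_ADAPTER
    read_length: int = 50
    polya_len: int = 8

    @property
    def reference(self) -> str:
        return next(iter(self.genome))


def _place_spans(
    rng: np.random.Generator,
    genome_len: int,
    n: int,
    length_range: Tuple[int, int],
    gap_range: Tuple[int, int],
    margin: int = 100,
) -> List[Tuple[int, int, str]]:
    spans = []
    cursor = margin
    for _ in range(n):
        length = int(rng.integers(length_range[0], length_range[1] + 1))
        start = cursor
        end = start + length - 1
        if end > genome_len - margin:
            raise EndmapError("genome too short for requested transcripts")
        spans.append((start, end, "+" if rng.random() < 0.5 else "-"))
        cursor = end + 1 + int(rng.integers(gap_range[0], gap_range[1] + 1))
    return spans


def _site_at_distance(span: Tuple[int, int, str], distance: int) -> int:
    """Site position whose downstream end lies ``distance`` nt from the 5' end."""
    start, end, strand = span
    return start + distance - 1 if strand == "+" else end - distance + 1


@dataclass
class DirectEntryExperiment:
    """Paired in vitro (before/after enzyme) and in vivo (WT/ts) libraries."""

    scenario: Scenario
    vitro_transcripts: List[TranscriptModel]
    before: EndCountTable
    after: EndCountTable
    wt: EndCountTable
    mutant: EndCountTable
    truth_sites: List[Key]  # downstream 5' ends of the planted sites


def simulate_direct_entry_experiment(
    seed: int,
    n_transcripts: int = 30,
    n_sites: int = 20,
    efficiency_range: Tuple[float, float] = (0.3, 0.9),
    genome_len: int = 50_000,
    n_reads: int = 200_000,
    depletion: float = 0.01,
    vitro_native_fraction: float = 0.02,
    vivo_native_fraction: float = 0.5,
) -> DirectEntryExperiment:
    """The core study design on a toy genome.

    ``n_sites`` transcripts carry one enzyme-dependent cleavage site each.
    In vitro, the dephosphorylated starting material ("before") is compared
    with the library after incubation with the 5'-sensor-mutant enzyme; in
    vivo, a wild-type strain is compared with a temperature-inactivated
    mutant in which site ends are depleted by ``depletion``.
    """
    rng = np.random.default_rng(seed)
    genome = make_genome(seed, 1, genome_len)
    ref = next(iter(genome))
    spans = _place_spans(rng, genome_len, n_transcripts, (600, 1200), (250, 400))
    transcripts: List[TranscriptModel] = []
    truth: List[Key] = []
    for i, (start, end, strand) in enumerate(spans):
        sites: List[CleavageSite] = []
        if i < n_sites:
            # keep sites well away from both transcript boundaries so the
            # emitted fragments stay long enough to trim and map uniquely
            lo, hi = start + 45, end - 45
            position = int(rng.integers(lo, hi + 1))
            eff = float(rng.uniform(*efficiency_range))
            sites.append(
                CleavageSite(
                    position,
                    {"t10": eff, "t30": min(1.0, eff * 1.15)},
                    dependence="rne_dependent",
                )
            )
            truth.append((ref, strand, downstream_end(position, strand)))
        transcripts.append(
            TranscriptModel(
                ref,
                strand,
                start,
                end,
                abundance=float(rng.lognormal(0.0, 0.5)),
                native_end_fraction=vivo_native_fraction,
                planted_sites=sites,
            )
        )
    vitro = [replace(t, native_end_fraction=vitro_native_fraction) for t in transcripts]
    before = simulate_end_counts(
        vitro, LibrarySpec("before", n_reads, seed=seed * 4 + 1), BEFORE
    )
    after = simulate_end_counts(
        vitro, LibrarySpec("t170v_10min", n_reads, seed=seed * 4 + 2), "t10"
    )
    wt = simulate_end_counts(
        transcripts, LibrarySpec("wt_44C", n_reads, seed=seed * 4 + 3), "t10"
    )
    mutant = simulate_end_counts(
        transcripts,
        LibrarySpec(
            "rne_ts_44C",
            n_reads,
            depletion_factor=depletion,
            target_dependence="rne_dependent",
            seed=seed * 4 + 4,
        ),
        "t10",
    )
    return DirectEntryExperiment(
        Scenario(genome, vitro), vitro, before, after, wt, mutant, sorted(truth)
    )


def simulate_dilution_experiment(
    seed: int,
    dilution: float,
    n_reads: int = 1_000_000,
    n_transcripts: int = 120,
    genome_len: int = 100_000,
) -> Tuple[EndCountTable, EndCountTable]:
    """Before/after pair whose unenriched baseline sits at ``log2(dilution)``.

    Every transcript is fully detectable (native fraction 1) and carries one
    site of efficiency ``1 - dilution``, so the expected post-incubation M of
    every native end is exactly log2(dilution) — the amplification-dilution
    baseline as a pure composition effect.
    """
    if not 0.0 < dilution < 1.0:
        raise ValueError("dilution must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    spans = _place_spans(rng, genome_len, n_transcripts, (300, 600), (100, 200))
    transcripts = []
    for start, end, strand in spans:
        position = _site_at_distance((start, end, strand), int(rng.integers(60, 200)))
        transcripts.append(
            TranscriptModel(
                "ref1",
                strand,
                start,
                end,
                abundance=float(rng.lognormal(0.0, 0.5)),
                native_end_fraction=1.0,
                planted_sites=[CleavageSite(position, {"t": 1.0 - dilution})],
            )
        )
    before = simulate_end_counts(
        transcripts, LibrarySpec("before", n_reads, seed=seed * 4 + 1), BEFORE
    )
    after = simulate_end_counts(
        transcripts, LibrarySpec("after", n_reads, seed=seed * 4 + 2), "t"
    )
    return before, after


@dataclass
class TrimmingExperiment:
    """WT vs knockout libraries with planted 5'-trimming pairs and decoys."""

    transcripts: List[TranscriptModel]
    wt: EndCountTable
    mutant: EndCountTable
    truth_pairs: List[dict]  # processed/precursor keys, distance, tss_match
    decoy_ends: List[Key]  # depleted ends that must stay unpaired
    boundary_control: Key  # depleted end whose precursor sits exactly at max ext
    tss: List[Key]  # native 5' ends (the simulated TSS annotation)


def simulate_trimming_experiment(
    seed: int,
    n_pairs: int = 12,
    n_decoys: int = 12,
    n_reads: int = 200_000,
    depletion: float = 0.05,
    accumulation: float = 8.0,
    max_extension: int = 200,
) -> TrimmingExperiment:
    """Knockout comparison with planted 5'-trimming events.

    ``n_pairs`` transcripts carry a trimming-dependent processed end whose
    precursor (10-150 nt upstream) accumulates in the knockout; the first
    five precursors are the transcripts' native 5' ends (simulated TSS), the
    rest are upstream processing intermediates.  ``n_decoys`` transcripts are
    depleted with no accumulated partner inside the scan window, and one
    boundary-control pair sits exactly at ``max_extension`` nt.
    """
    rng = np.random.default_rng(seed)
    n_tss_pairs = min(5, n_pairs)
    distances = np.linspace(10, 150, n_pairs).round().astype(int)
    n_total = n_pairs + n_decoys + 1
    spans = _place_spans(rng, 80_000, n_total, (600, 800), (260, 400))
    transcripts: List[TranscriptModel] = []
    truth_pairs: List[dict] = []
    decoy_ends: List[Key] = []
    tss: List[Key] = []
    ref = "ref1"
    boundary_control: Key = ("", "", 0)

    for i, span in enumerate(spans):
        start, end, strand = span
        native = start if strand == "+" else end
        tss.append((ref, strand, native))
        sites: List[CleavageSite] = []
        if i < n_pairs:
            dist = int(distances[i])
            if i < n_tss_pairs:
                # precursor is the native end itself
                pos = _site_at_distance(span, dist)
                sites.append(CleavageSite(pos, {"steady": 0.5}, "rng_dependent"))
                precursor = native
                tss_match = True
            else:
                # precursor is an upstream processing intermediate 250 nt in
                upos = _site_at_distance(span, 250)
                sites.append(CleavageSite(upos, {"steady": 0.15}, "independent"))
                pos = _site_at_distance(span, 250 + dist)
                sites.append(CleavageSite(pos, {"steady": 0.5}, "rng_dependent"))
                precursor = downstream_end(upos, strand)
                tss_match = False
            truth_pairs.append(
                {
                    "processed": (ref, strand, downstream_end(pos, strand)),
                    "precursor": (ref, strand, precursor),
                    "distance": dist,
                    "tss_match": tss_match,
                }
            )
        elif i < n_pairs + n_decoys:
            # precursor (the native end) accumulates but sits 300 nt away,
            # outside the scan window: the depleted end must stay unpaired
            pos = _site_at_distance(span, 300)
            sites.append(CleavageSite(pos, {"steady": 0.5}, "rng_dependent"))
            decoy_ends.append((ref, strand, downstream_end(pos, strand)))
        else:
            # strict-boundary negative control: precursor exactly max_extension
            pos = _site_at_distance(span, max_extension)
            sites.append(CleavageSite(pos, {"steady": 0.5}, "rng_dependent"))
            boundary_control = (ref, strand, downstream_end(pos, strand))
        transcripts.append(
            TranscriptModel(
                ref,
                strand,
                start,
                end,
                abundance=float(rng.lognormal(0.0, 0.3)),
                native_end_fraction=0.1,
                planted_sites=sites,
            )
        )

    wt = simulate_end_counts(
        transcripts, LibrarySpec("wt", n_reads, seed=seed * 4 + 1), "steady"
    )
    mutant = simulate_end_counts(
        transcripts,
        LibrarySpec(
            "rng_ko",
            n_reads,
            depletion_factor=depletion,
            accumulation_factor=accumulation,
            target_dependence="rng_dependent",
            seed=seed * 4 + 2,
        ),
        "steady",
    )
    return TrimmingExperiment(
        transcripts, wt, mutant, truth_pairs, decoy_ends, boundary_control, tss
    )
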