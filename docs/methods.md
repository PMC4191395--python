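# Methods

## Model

### End-count observation model

A transcriptome is a set of transcripts on a random genome, each with an
abundance, a native 5′-end fraction, and zero or more planted cleavage
sites. A site is the last nucleotide of the upstream product; the
5′-monophosphorylated downstream end appears one position 3′ of it
(position + 1 on the plus strand, position − 1 on the minus strand).

A library is a single multinomial draw of N reads over candidate 5′ ends.
End weights are:

- native 5′ end: `abundance × native_end_fraction × max(0, 1 − Σ efficiencies)`
  — cleavage consumes intact molecules, so high total cleavage suppresses
  the native end;
- cleavage-derived end: `abundance × efficiency`, multiplied by a
  depletion factor when the site's dependence does not match the library
  (an rne-dependent site in the mutant strain, or any site in the
  before-activation library), and by an accumulation factor when the end is
  the nearest upstream precursor of a matched trimming site.

Because the total N is fixed, creating new ends necessarily dilutes old
ones: an unchanged native end with pre/post weight ratio 1/d lands at
M = log2(d). This is the amplification-dilution baseline the analysis
estimates empirically rather than assuming.

### Read emission and mapping

Reads begin exactly at the counted 5′ position, carry a ligated 5′ adapter,
and receive a poly(A) tail only when the fragment is truncated by the
transcript's 3′ boundary. Mapping is deliberately minimal: anchored
adapter removal (Hamming budget, default 0 mismatches), removal of a
trailing A-run of ≥ 5, then exact unique placement via a 16-mer prefix
index with full-length verification. Multimapped reads are discarded, not
fractionally assigned, because positional precision is the product.
Rejections are accounted per reason (`no_adapter`, `short`, `unmapped`,
`multimapped`) and input = kept + rejected always holds.

SAM input is read through pysam; the 5′ end is `reference_start + 1` for
forward and `reference_end` (last aligned base) for reverse alignments.
5′-side soft clips are not added back. Unmapped, secondary, and
supplementary records are skipped. Malformed records (including bad CIGAR
strings, which pysam surfaces as `OSError`) raise `ParseError`.

### M–A analysis

For each position in the union of two tables, M = log2(a/b) and
A = (log2 a + log2 b)/2. A nominal count of 1 substitutes for the absent
side and is flagged (`nominal_a` / `nominal_b`); positions absent from both
are excluded. The transform is exactly invertible: a = 2^(A+M/2),
b = 2^(A−M/2).

The baseline is the mode of the M histogram over non-nominal records,
with bins of width 0.1 centred on multiples of 0.1, ties broken toward the
smaller M, and the result clipped to the observed M range. At least 100
usable records are required; fewer is an error, not a silent guess.

Site calling keeps positions with M ≥ threshold (inclusive) and
reads_a ≥ min_reads (default 5). Defaults encode a 5-log2 enrichment over
the baseline: threshold 3.4 against baseline −1.6 in vitro; threshold 5.0
against baseline 0.0 in vivo (where the comparison is between two
independently normalised strains rather than a before/after pair).
`count_by_threshold` uses strict `>` so that threshold sweeps partition
cleanly.

### Comparison and classification

Spearman reproducibility ranks shared positions (absent partners take
M = 0) and computes rank-then-Pearson via `scipy.stats.spearmanr`; with
n ≤ 10 a seeded two-sided permutation p-value replaces the asymptotic one.
In vivo and in vitro site lists intersect with a coordinate tolerance
(default 0); each in vitro site may match at most once, nearest wins,
distance ties go to the smaller coordinate. Classes are
`direct_entry_candidate`, `in_vivo_only`, `in_vitro_only`.

### Trim-pair detection

A trimming event is a depleted processed end (M ≥ 2, default) with an
accumulated precursor (M ≤ −2) strictly less than 200 nt upstream in
transcript orientation. The best partner is the most negative M, ties
broken by shortest distance; `all_pairs=True` returns every partner.
Events can be annotated against a TSS list with ±1 nt tolerance, since a
precursor that is itself a primary transcript start implies the processed
end was generated by trimming from the native 5′ end.

### Substrate arithmetic

In vitro substrates are specified on a codon-relative axis with no zero
(−1 is followed by +1). `substrate_length = prefix + span(start, end)`
where the prefix models a transcription-start GGG leader. A cut at
position c yields an upstream product of `prefix + span(start, c)` nt and
a downstream product covering the rest. This reproduces the worked
examples exactly: a 358-nt substrate over +354..+708 with products
(209, 149) at +559 and (65, 293) at +415; a 490-nt substrate over
−22..+465; a 209-nt product predicted from a 172-nt one by a +2 → +39
boundary shift; products (191, 33) from a 224-nt fragment cut at 191.

## Parameter defaults and rationale

| Parameter | Default | Rationale |
|---|---|---|
| adapter | `ACACGACGCT` | 10-nt anchored ligation adapter; long enough for unambiguous anchored matching |
| min poly(A) run | 5 | shorter runs are common in genomic sequence |
| min read length | 20 | below this, exact 16-mer-seeded mapping loses specificity |
| k-mer seed | 16 | unique on a 50–100 kb random genome with overwhelming probability |
| M–A nominal | 1 | smallest observable count; keeps single-sided records finite and flagged |
| baseline bin width | 0.1 | resolves dilutions between 0.25 and 0.5 (log2 spacing ≥ 0.3) |
| baseline min records | 100 | a mode over fewer bins is noise |
| in vitro threshold | 3.4 over −1.6 | 5 log2 (32-fold) over the dilution cone at d ≈ 1/3 |
| in vivo threshold | 5.0 over 0.0 | same 32-fold, no shared-library dilution |
| min_reads | 5 | suppresses single-read artefacts |
| trim window | < 200 nt | trimming is processive over tens of nt; longer gaps are distinct sites |
| trim thresholds | ±2 | 4-fold depletion/accumulation |
| TSS tolerance | ±1 | start-site micro-heterogeneity |

Generator problem sizes (30 transcripts / 20 sites / 50-kb genome /
2×10⁵ reads; 120 transcripts / 10⁶ reads for baseline studies; 12 pairs +
12 decoys for trimming) are chosen so every acceptance property runs in
seconds to a few minutes on one CPU while keeping multinomial noise far
below the tested tolerances. Trimming-scenario amplitudes (site depletion
0.05, precursor accumulation 8, native-end fraction 0.1) were fixed by
composition arithmetic *before* any recovery run, so the ≥/≤ 2 thresholds
test the detector, not tuned inputs.

## What the generator emulates — and does not

Emulated: 5′-monophosphate-specific cloning, fixed-total sampling and its
dilution baseline, condition-dependent site activity, exonucleolytic
trim-pair signatures, native-end suppression by cleavage, poly(A) tailing
at transcript 3′ boundaries, strand conventions.

Not emulated: sequence-dependent cleavage preferences, RNA secondary
structure, ligation or PCR bias, sequencing errors and quality decay,
rho-independent terminator readthrough, overlapping genes, or genome-scale
repeat content. Consequently recovery rates here are upper bounds on what
real libraries achieve; the package's claims are about the correctness of
the arithmetic and the detectors, not about biological completeness.

## Numerical choices

- Counts are exact integers end to end; M–A uses float64 log2, giving the
  10⁻⁹ invertibility bound (tested).
- Multinomial sampling uses `numpy.random.default_rng` with explicit
  sub-seeds (`seed*4 + 1..4` per library) so every scenario is reproducible
  from one integer; derived seeds stay below 2³¹.
- Sorting uses mergesort where stable tie-breaking is part of the contract
  (site ranking, trim-partner selection).

## Limitations

- Exact-match mapping cannot place reads across sequencing errors; real
  data should be aligned externally and imported via SAM/BED.
- The baseline estimator assumes a unimodal bulk of unchanged positions;
  it will mislead if most positions genuinely change.
- The trim scanner pairs each depleted end with a single best precursor;
  branched or multi-step trimming paths collapse to one edge.
- In vivo threshold 5.0/0.0 presumes independent normalisation of the two
  strains; partially shared library preparation would reintroduce a
  dilution baseline that the defaults do not model.
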