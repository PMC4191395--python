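"""The library simulator: determinism, weight model and read emission."""

import numpy as np
import pytest

from endmap import (
    BEFORE,
    CleavageSite,
    EndmapError,
    LibrarySpec,
    TranscriptModel,
    downstream_end,
    emit_reads,
    make_genome,
    revcomp,
    simulate_dilution_experiment,
    simulate_end_counts,
)


class TestMakeGenome:
    def test_deterministic_and_seed_sensitive(self):
        assert make_genome(1, 1, 5000) == make_genome(1, 1, 5000)
        assert make_genome(1, 1, 5000) != make_genome(2, 1, 5000)

    def test_alphabet_and_gc(self):
        genome = make_genome(1, 2, 50_000)
        assert set(genome) == {"ref1", "ref2"}
        seq = genome["ref1"]
        assert set(seq) <= set("ACGT")
        gc = (seq.count("G") + seq.count("C")) / len(seq)
        assert 0.45 <= gc <= 0.55

    def test_short_genome_rejected(self):
        with pytest.raises(ValueError):
            make_genome(1, 1, 10)


def one_transcript(eff, native_fraction=1.0, strand="+", dependence="independent"):
    site = CleavageSite(500, {"t": eff}, dependence)
    return TranscriptModel(
        "ref1", strand, 100, 900, abundance=1.0,
        native_end_fraction=native_fraction, planted_sites=[site],
    )


class TestSimulateEndCounts:
    def test_counts_conserve_library_size(self):
        table = simulate_end_counts(
            [one_transcript(0.5)], LibrarySpec("c", 12_345, seed=3), "t"
        )
        assert table.total() == 12_345

    def test_before_timepoint_gives_only_native_ends(self):
        table = simulate_end_counts(
            [one_transcript(0.9)], LibrarySpec("c", 1000, seed=0), BEFORE
        )
        assert set(table.counts) == {("ref1", "+", 100)}

    def test_full_cleavage_without_native_ends(self):
        table = simulate_end_counts(
            [one_transcript(1.0, native_fraction=0.0)],
            LibrarySpec("c", 1000, seed=0),
            "t",
        )
        assert set(table.counts) == {("ref1", "+", 501)}

    def test_minus_strand_end_convention(self):
        table = simulate_end_counts(
            [one_transcript(1.0, native_fraction=0.0, strand="-")],
            LibrarySpec("c", 100, seed=0),
            "t",
        )
        # downstream of position 500 on the minus strand is 499
        assert set(table.counts) == {("ref1", "-", 499)}

    def test_half_efficiency_splits_weight_evenly(self):
        table = simulate_end_counts(
            [one_transcript(0.5)], LibrarySpec("c", 1_000_000, seed=1), "t"
        )
        ratio = table.get("ref1", "+", 501) / table.get("ref1", "+", 100)
        assert ratio == pytest.approx(1.0, abs=0.01)

    def test_identical_seeds_identical_tables(self):
        spec = LibrarySpec("c", 5000, seed=9)
        t1 = simulate_end_counts([one_transcript(0.4)], spec, "t")
        t2 = simulate_end_counts([one_transcript(0.4)], spec, "t")
        assert t1 == t2

    def test_depletion_factor_hits_matched_dependence_only(self):
        transcripts = [
            one_transcript(0.5, dependence="rne_dependent"),
            TranscriptModel(
                "ref1", "+", 2000, 2900, 1.0, 1.0,
                [CleavageSite(2400, {"t": 0.5}, "independent")],
            ),
        ]
        spec = LibrarySpec(
            "mut", 1_000_000, depletion_factor=0.1,
            target_dependence="rne_dependent", seed=2,
        )
        table = simulate_end_counts(transcripts, spec, "t")
        depleted = table.get("ref1", "+", 501)
        untouched = table.get("ref1", "+", 2401)
        assert depleted < untouched * 0.2

    def test_empty_transcripts_and_zero_weights_rejected(self):
        with pytest.raises(EndmapError):
            simulate_end_counts([], LibrarySpec("c", 10, seed=0), "t")
        with pytest.raises(EndmapError):
            simulate_end_counts(
                [one_transcript(0.0, native_fraction=0.0)],
                LibrarySpec("c", 10, seed=0),
                "t",
            )

    def test_unknown_timepoint_rejected(self):
        with pytest.raises(EndmapError):
            simulate_end_counts([one_transcript(0.5)], LibrarySpec("c", 10, seed=0), "t99")


class TestInvariantDepletion:
    def test_wt_vs_mutant_m_approaches_log2_depletion(self):
        """At a dependent-only end, M(WT/mutant) -> -log2(d) for deep libraries."""
        from endmap import compute_ma

        transcripts = [
            TranscriptModel(
                "ref1", "+", 1000 * (i + 1), 1000 * (i + 1) + 800, 1.0, 1.0,
                [CleavageSite(1000 * (i + 1) + 400, {"t": 0.1}, "rne_dependent")]
                if i == 0
                else [],
            )
            for i in range(30)
        ]
        for d in (0.25, 0.5):
            wt = simulate_end_counts(
                transcripts, LibrarySpec("wt", 1_000_000, seed=5), "t"
            )
            mut = simulate_end_counts(
                transcripts,
                LibrarySpec(
                    "mut", 1_000_000, depletion_factor=d,
                    target_dependence="rne_dependent", seed=6,
                ),
                "t",
            )
            ma = compute_ma(wt, mut)
            row = ma.loc[ma["position"] == 1401]
            assert float(row["M"].iloc[0]) == pytest.approx(-np.log2(d), abs=0.2)


class TestEmitReads:
    genome = make_genome(4, 1, 5000)

    def test_plus_strand_fragment_matches_genome(self):
        from endmap import EndCountTable

        table = EndCountTable({("ref1", "+", 1000): 3})
        reads = emit_reads(table, self.genome, adapter="ACGT", read_length=30, seed=0)
        assert len(reads) == 3
        for read in reads:
            assert read.sequence.startswith("ACGT")
            assert read.sequence[4:] == self.genome["ref1"][999 : 999 + 26]

    def test_minus_strand_fragment_is_reverse_complement(self):
        from endmap import EndCountTable

        table = EndCountTable({("ref1", "-", 2000): 1})
        reads = emit_reads(table, self.genome, adapter="ACGT", read_length=30, seed=0)
        frag = reads[0].sequence[4:]
        assert frag == revcomp(self.genome["ref1"][2000 - 26 : 2000])

    def test_polya_appended_at_transcript_boundary(self):
        from endmap import EndCountTable

        t = TranscriptModel("ref1", "+", 900, 1010, 1.0, 1.0, [])
        table = EndCountTable({("ref1", "+", 1000): 1})
        reads = emit_reads(
            table, self.genome, adapter="ACGT", read_length=30,
            polya_len=6, seed=0, transcripts=[t],
        )
        seq = reads[0].sequence
        assert seq[4:15] == self.genome["ref1"][999:1010]
        assert seq[15:] == "A" * 6

    def test_position_outside_genome_rejected(self):
        from endmap import EndCountTable

        with pytest.raises(EndmapError):
            emit_reads(EndCountTable({("ref1", "+", 99999): 1}), self.genome)


class TestBaselineEmergence:
    """Fixed-total sampling shifts unenriched ends to log2(dilution)."""

    @pytest.mark.parametrize("dilution", [0.25, 0.5])
    def test_native_end_median_m(self, dilution):
        from endmap import compute_ma

        before, after = simulate_dilution_experiment(8, dilution, n_reads=1_000_000)
        ma = compute_ma(after, before)
        native = ma.loc[~(ma["nominal_a"] | ma["nominal_b"]), "M"]
        assert float(native.median()) == pytest.approx(np.log2(dilution), abs=0.1)
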