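"""Tandem array detection, TRF input, consensus building, classification."""

import numpy as np
import pytest

from chromqc import synthetic
from chromqc.exceptions import ParseError, ValidationError
from chromqc.repeats import (
    TandemArray,
    build_monomer_consensus,
    classify_arrays,
    detect_tandem_arrays,
    read_arrays_tsv,
    read_trf_dat,
    tally_telomere_units,
    unit_length_histogram,
    write_arrays_tsv,
)
from conftest import random_dna

MONOMER_181 = synthetic.CENTROMERE_MONOMER_181

# flanks whose junction bases cannot extend a TTTAGGG-pattern array
LEFT_FLANK = random_dna(400, 91)[:-1] + "C"   # pattern would need G before a T start
RIGHT_FLANK = "C" + random_dna(400, 92)[1:]   # pattern continuation would be T


TRF_DAT = """\
Tandem Repeats Finder Program written by some authors

Sequence: scaffA extra description

Parameters: 2 7 7 80 10 50 500

1 21 7 3.0 7 100 0 42 30 10 30 30 1.92 TTTAGGG TTTAGGGTTTAGGGTTTAGGG
101 462 181 2.0 181 95 0 500 25 25 25 25 2.0 ACGT ACGTACGT

Sequence: scaffB

50 70 7 3.0 7 90 0 30 30 10 30 30 1.92 TTGAGGG TTGAGGGTTGAGGGTTGAGGG
"""


class TestReadTrfDat:
    def test_coordinate_conversion_and_purity(self, tmp_path):
        p = tmp_path / "trf.dat"
        p.write_text(TRF_DAT)
        arrays = read_trf_dat(p)
        first = arrays[0]
        assert (first.seqid, first.start, first.end) == ("scaffA", 0, 21)
        assert first.unit_length == 7
        assert first.purity == 1.0
        assert first.consensus_monomer == "TTTAGGG"

    def test_multiple_sequence_blocks(self, tmp_path):
        p = tmp_path / "trf.dat"
        p.write_text(TRF_DAT)
        arrays = read_trf_dat(p)
        assert [a.seqid for a in arrays] == ["scaffA", "scaffA", "scaffB"]

    def test_truncated_row_names_line(self, tmp_path):
        p = tmp_path / "trf.dat"
        p.write_text("Sequence: s\n\n1 21 7 3.0 7 100\n")
        with pytest.raises(ParseError, match=":3"):
            read_trf_dat(p)

    def test_arrays_tsv_roundtrip(self, tmp_path):
        arr = TandemArray("s", 10, 52, 7, "TTTAGGG", 6.0, 0.97, "telomeric")
        write_arrays_tsv([arr], tmp_path / "a.tsv")
        back = read_arrays_tsv(tmp_path / "a.tsv")[0]
        assert (back.seqid, back.start, back.end, back.unit_length) == ("s", 10, 52, 7)
        assert back.array_class == "telomeric"


class TestDetectTandemArrays:
    def test_planted_exact_heptamer_array(self):
        seq = LEFT_FLANK + "TTTAGGG" * 10 + RIGHT_FLANK
        arrays = detect_tandem_arrays(seq)
        assert len(arrays) == 1
        a = arrays[0]
        assert (a.start, a.end) == (400, 470)
        assert a.unit_length == 7
        assert a.copy_number == 10.0
        assert a.purity == 1.0

    def test_planted_mutated_181mer_boundaries_within_one_unit(self):
        # oracle: the planted TruthSet interval
        for seed in range(5):
            arr = synthetic.make_repeat_array(
                synthetic.RepeatUnitSpec(
                    monomer=MONOMER_181, copies=50, per_base_mutation_rate=0.02
                ),
                seed=seed,
            )
            seq = random_dna(2_000, seed + 50) + arr.sequence + random_dna(2_000, seed + 80)
            hits = [a for a in detect_tandem_arrays(seq) if a.span > 1_000]
            assert len(hits) == 1
            a = hits[0]
            assert a.unit_length == 181
            assert abs(a.start - 2_000) <= 181
            assert abs(a.end - (2_000 + 50 * 181)) <= 181

    def test_random_sequence_yields_no_long_unit_arrays(self):
        # brute-force scan of the same sequence confirms absence of any
        # detectable run of unit >= 5 at <= 20% divergence
        seq = random_dna(10_000, 123)
        arrays = [a for a in detect_tandem_arrays(seq) if a.unit_length >= 5]
        assert arrays == []
        codes = np.frombuffer(seq.encode(), dtype=np.uint8)
        for u in (5, 7, 11):
            x = codes[:-u] != codes[u:]
            window = np.convolve(x.astype(int), np.ones(u, dtype=int), mode="valid")
            ok = window <= 0.2 * u
            longest, run = 0, 0
            for v in ok:
                run = run + 1 if v else 0
                longest = max(longest, run)
            # longest periodic stretch stays below the reportable span
            assert longest - 1 + 2 * u < max(3 * u, 20)

    def test_n_breaks_arrays(self):
        seq = "TTTAGGG" * 10 + "N" * 100 + "TTTAGGG" * 10
        arrays = detect_tandem_arrays(seq)
        assert len(arrays) == 2
        assert all(a.unit_length == 7 for a in arrays)

    def test_span_recovery_at_2pct_over_20_seeds(self, planted_scaffold_spec):
        recovered, total = 0, 0
        for seed in range(20):
            asm = synthetic.build_assembly([planted_scaffold_spec], seed=seed)
            seq = asm.sequences["chrT"]
            arrays = detect_tandem_arrays(seq, seqid="chrT")
            for t in asm.truth.arrays:
                total += t.end - t.start
                recovered += sum(
                    max(0, min(a.end, t.end) - max(a.start, t.start)) for a in arrays
                )
        assert recovered / total >= 0.95

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValidationError):
            detect_tandem_arrays("ACGT", max_divergence=1.5)
        with pytest.raises(ValidationError):
            detect_tandem_arrays("ACGT", min_copies=1)


class TestUnitLengthHistogram:
    def test_span_weighted_peaks_on_planted_assembly(self, planted_assembly):
        seq = planted_assembly.sequences["chrT"]
        arrays = detect_tandem_arrays(seq, seqid="chrT")
        hist = unit_length_histogram(arrays)
        assert 7 in hist.peaks and 181 in hist.peaks
        # centromeric span (9 kb) exceeds the two telomeres (1.4 kb)
        assert hist.modal_unit == 181

    def test_single_array(self):
        arr = TandemArray("s", 0, 70, 7, "TTTAGGG", 10.0, 1.0)
        hist = unit_length_histogram([arr])
        assert hist.peaks == [7]
        assert hist.spans == {7: 70}

    def test_equal_span_arrays_ordered_by_span_then_unit(self):
        arrays = [
            TandemArray("s", 0, 700, 7, "TTTAGGG", 100.0, 1.0),
            TandemArray("s", 1000, 1700, 181, MONOMER_181, 3.87, 1.0),
        ]
        hist = unit_length_histogram(arrays)
        assert hist.spans == {7: 700, 181: 700}
        assert hist.peaks == [7, 181]

    def test_empty_input(self):
        hist = unit_length_histogram([])
        assert hist.spans == {} and hist.peaks == []
        assert hist.modal_unit is None


class TestBuildMonomerConsensus:
    def test_exact_array(self):
        seq = "TTGAGGG" * 5
        arr = TandemArray("s", 0, 35, 7, "TTGAGGG", 5.0, 1.0)
        assert build_monomer_consensus(arr, seq) == "TTGAGGG"

    def test_planted_181mer_recovered_exactly(self):
        # majority vote at 2% per-base error over 50 copies fixes every column
        for seed in range(5):
            arr = synthetic.make_repeat_array(
                synthetic.RepeatUnitSpec(
                    monomer=MONOMER_181, copies=50, per_base_mutation_rate=0.02
                ),
                seed=seed,
            )
            det = TandemArray("s", 0, len(arr.sequence), 181, MONOMER_181, 50.0, 0.98)
            assert build_monomer_consensus(det, arr.sequence) == MONOMER_181

    def test_recovery_across_mutation_grid(self):
        # planted monomer recovered exactly for >= 10 copies at <= 5% mutation
        monomer = random_dna(90, 7)
        for copies in (10, 30):
            for rate in (0.0, 0.02, 0.05):
                arr = synthetic.make_repeat_array(
                    synthetic.RepeatUnitSpec(
                        monomer=monomer, copies=copies, per_base_mutation_rate=rate
                    ),
                    seed=17,
                )
                det = TandemArray("s", 0, len(arr.sequence), 90, monomer, copies, 1.0)
                assert build_monomer_consensus(det, arr.sequence) == monomer

    def test_alternating_array_consensus_is_one_heptamer(self):
        seq = "TTTAGGGTTGAGGG" * 20
        arr = TandemArray("s", 0, len(seq), 7, "TTTAGGG", 40.0, 0.93)
        consensus = build_monomer_consensus(arr, seq)
        assert consensus in ("TTTAGGG", "TTGAGGG")
        # direct column tally: heptamers differ at one column, where the
        # minor-allele frequency is exactly 0.5
        blocks = [seq[i : i + 7] for i in range(0, len(seq), 7)]
        diff_cols = [
            i for i in range(7) if len({b[i] for b in blocks}) > 1
        ]
        assert diff_cols == [2]
        col = [b[2] for b in blocks]
        assert col.count("T") == col.count("G") == len(blocks) // 2

    def test_array_shorter_than_two_copies_rejected(self):
        with pytest.raises(ValidationError):
            TandemArray("s", 0, 13, 7, "TTTAGGG", 1.9, 1.0)



class TestTallyTelomereUnits:
    def test_strict_alternation(self):
        seq = "TTTAGGGTTGAGGG" * 10
        arr = TandemArray("s", 0, len(seq), 7, "TTTAGGG", 20.0, 0.93)
        tally = tally_telomere_units(arr, seq)
        assert tally.counts["TTTAGGG"] == tally.counts["TTGAGGG"] == 10
        assert tally.counts["other"] == 0
        assert tally.alternation_rate == 1.0

    def test_pure_array_never_alternates(self):
        seq = "TTTAGGG" * 12
        arr = TandemArray("s", 0, len(seq), 7, "TTTAGGG", 12.0, 1.0)
        tally = tally_telomere_units(arr, seq)
        assert tally.counts == {"TTTAGGG": 12, "TTGAGGG": 0, "other": 0}
        assert tally.alternation_rate == 0.0

    def test_mutated_alternating_array_near_equal_counts(self):
        spec = synthetic.RepeatUnitSpec(
            monomer="TTTAGGG", alternate_monomer="TTGAGGG", copies=400,
            per_base_mutation_rate=0.01,
        )
        arr_seq = synthetic.make_repeat_array(spec, seed=3).sequence
        arr = TandemArray("s", 0, len(arr_seq), 7, "TTTAGGG", 400.0, 0.9)
        tally = tally_telomere_units(arr, arr_seq)
        a, b = tally.counts["TTTAGGG"], tally.counts["TTGAGGG"]
        assert abs(a - b) / max(a, b) < 0.05
        assert tally.total_units == 400

    def test_requires_heptamer_unit(self):
        arr = TandemArray("s", 0, 362, 181, MONOMER_181, 2.0, 1.0)
        with pytest.raises(ValidationError):
            tally_telomere_units(arr, MONOMER_181 * 2)


class TestClassifyArrays:
    LENGTHS = {"chr": 100_000}

    def _arr(self, start, end, unit, consensus, copies=10.0):
        return TandemArray("chr", start, end, unit, consensus, copies, 0.95)

    def test_end_proximal_heptamer_is_telomeric(self):
        arrays = classify_arrays(
            [self._arr(100, 800, 7, "TTTAGGG")], self.LENGTHS, end_window=10_000
        )
        assert arrays[0].array_class == "telomeric"

    def test_large_interior_181mer_is_centromeric(self):
        arrays = classify_arrays(
            [self._arr(40_000, 49_050, 181, MONOMER_181, 50.0)],
            self.LENGTHS, end_window=10_000,
        )
        assert arrays[0].array_class == "centromeric"

    def test_dimer_unit_folds_into_centromeric(self):
        arrays = classify_arrays(
            [self._arr(40_000, 49_052, 362, MONOMER_181 * 2, 25.0)],
            self.LENGTHS, end_window=10_000,
        )
        assert arrays[0].array_class == "centromeric"

    def test_interior_canonical_heptamer_stays_telomeric(self):
        arrays = classify_arrays(
            [self._arr(50_000, 50_700, 7, "TTGAGGG", 100.0)],
            self.LENGTHS, end_window=10_000,
        )
        assert arrays[0].array_class == "telomeric"

    def test_interior_noncanonical_heptamer_unclassified(self):
        arrays = classify_arrays(
            [self._arr(50_000, 50_700, 7, "ACACACA", 100.0)],
            self.LENGTHS, end_window=10_000,
        )
        assert arrays[0].array_class == "unclassified"

    def test_small_interior_181mer_unclassified(self):
        arrays = classify_arrays(
            [self._arr(50_000, 50_724, 181, MONOMER_181, 4.0)],
            self.LENGTHS, end_window=10_000, centromere_min_span=5_000,
        )
        assert arrays[0].array_class == "unclassified"

    def test_classification_is_a_partition(self, planted_assembly):
        seq = planted_assembly.sequences["chrT"]
        arrays = detect_tandem_arrays(seq, seqid="chrT")
        classified = classify_arrays(arrays, {"chrT": len(seq)}, end_window=10_000)
        assert len(classified) == len(arrays)
        assert all(
            a.array_class in ("telomeric", "centromeric", "unclassified")
            for a in classified
        )
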