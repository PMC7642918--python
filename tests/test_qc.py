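"""Gap accounting, completeness status, mis-assembly detection, Nx statistics."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from chromqc import synthetic
from chromqc.exceptions import ValidationError
from chromqc.qc import (
    GapRecord,
    assembly_summary,
    assess_scaffold,
    cluster_centromeres,
    detect_misassemblies,
    find_gaps,
    nx_statistic,
    split_scaffold,
    total_gap_length,
)
from chromqc.repeats import TandemArray, classify_arrays, detect_tandem_arrays

# synthetic-scale thresholds used throughout (published-scale defaults are
# 100 kb merge / 1 Mb separation)
SMALL = dict(end_window=5_000, cluster_merge_distance=5_000, centromere_separation=20_000)


def _tel(seqid, start, end):
    return TandemArray(seqid, start, end, 7, "TTTAGGG", (end - start) / 7, 0.95, "telomeric")


def _cen(seqid, start, end):
    return TandemArray(
        seqid, start, end, 181, synthetic.CENTROMERE_MONOMER_181,
        (end - start) / 181, 0.95, "centromeric",
    )


class TestFindGaps:
    def test_no_n_no_gaps(self):
        assert find_gaps("ACGT" * 100) == []
        assert total_gap_length([]) == 0

    def test_unknown_gap_rule_without_truth(self):
        seq = "A" * 50 + "N" * 100 + "C" * 50 + "N" * 100 + "G" * 50 + "N" * 250 + "T" * 50
        gaps = find_gaps(seq, seqid="s")
        assert [g.known_size for g in gaps] == [False, False, True]
        assert total_gap_length(gaps) == 100 + 100 + 250

    def test_truth_overrides_length_heuristic(self, planted_assembly):
        seq = planted_assembly.sequences["chrT"]
        truth = planted_assembly.truth.gaps
        gaps = find_gaps(seq, seqid="chrT", gap_truth=truth)
        assert len(gaps) == len(truth)
        assert all(not g.known_size for g in gaps)

    def test_benchmark_unknown_gap_totals(self):
        # all-unknown gap lists: total = count x 100
        chr1 = [GapRecord("chr1", i, i + 100, known_size=False) for i in range(4_415)]
        chr7 = [GapRecord("chr7", i, i + 100, known_size=False) for i in range(2_790)]
        assert total_gap_length(chr1) == 441_500
        assert total_gap_length(chr7) == 279_000


class TestAssessScaffold:
    LENGTH = 100_000

    @pytest.mark.parametrize(
        "arrays,status,n_tel,has_cen",
        [
            ([_tel("s", 0, 700), _tel("s", 99_300, 100_000), _cen("s", 45_000, 54_000)],
             "T2T", 2, True),
            ([_tel("s", 0, 700), _cen("s", 45_000, 54_000)], "near_complete", 1, True),
            ([_tel("s", 0, 700)], "arm", 1, False),
            ([], "fragment", 0, False),
            ([_cen("s", 45_000, 54_000)], "fragment", 0, True),
            ([_tel("s", 0, 700), _tel("s", 99_300, 100_000)], "T2T", 2, False),
        ],
    )
    def test_status_mapping(self, arrays, status, n_tel, has_cen):
        report = assess_scaffold("s", self.LENGTH, arrays, [], **SMALL)
        assert (report.status, report.n_telomeres, report.has_centromere) == (
            status, n_tel, has_cen,
        )

    def test_multiple_arrays_at_one_end_count_once(self):
        arrays = [_tel("s", 0, 300), _tel("s", 400, 700), _tel("s", 900, 1_200)]
        report = assess_scaffold("s", self.LENGTH, arrays, [], **SMALL)
        assert report.n_telomeres == 1

    def test_nearby_centromeric_arrays_merge_into_one_cluster(self):
        arrays = [_cen("s", 40_000, 44_000), _cen("s", 46_000, 50_000)]
        clusters = cluster_centromeres(arrays, merge_distance=5_000)
        assert clusters == [(40_000, 50_000)]
        report = assess_scaffold("s", self.LENGTH, arrays, [], **SMALL)
        assert report.has_centromere
        assert not report.anomalies


class TestDetectMisassemblies:
    def test_clean_scaffold_has_no_flags(self):
        arrays = [_tel("s", 0, 700), _tel("s", 99_300, 100_000), _cen("s", 45_000, 54_000)]
        assert detect_misassemblies("s", 100_000, arrays, [], **SMALL) == []

    def test_two_separated_centromeres_without_interior_telomere(self):
        arrays = [_cen("s", 10_000, 19_000), _cen("s", 70_000, 79_000)]
        flags = detect_misassemblies("s", 100_000, arrays, [], **SMALL)
        assert [f.kind for f in flags] == ["multiple_centromeres"]
        assert flags[0].proposed_split == (19_000 + 70_000) // 2

    def test_interior_telomere_alone_has_no_split(self):
        arrays = [_tel("s", 50_000, 50_700), _cen("s", 20_000, 29_000)]
        flags = detect_misassemblies("s", 100_000, arrays, [], **SMALL)
        assert [f.kind for f in flags] == ["interior_telomere"]
        assert flags[0].proposed_split is None

    def test_cooccurring_flags_split_at_gap_between_clusters(self):
        arrays = [
            _cen("s", 10_000, 19_000),
            _tel("s", 44_000, 44_700),  # interior telomere near the junction
            _cen("s", 70_000, 79_000),
        ]
        gaps = [GapRecord("s", 45_000, 45_100, False), GapRecord("s", 90_000, 90_100, False)]
        flags = detect_misassemblies("s", 100_000, arrays, gaps, **SMALL)
        kinds = {f.kind for f in flags}
        assert kinds == {"multiple_centromeres", "interior_telomere"}
        assert all(f.proposed_split == 45_000 for f in flags)

    def test_fused_fixture_detected_and_split_near_junction(self, fused_assembly):
        # oracle: the TruthSet junction coordinate
        seqid = "fused1"
        seq = fused_assembly.sequences[seqid]
        arrays = detect_tandem_arrays(seq, seqid=seqid)
        classified = classify_arrays(arrays, {seqid: len(seq)}, end_window=5_000)
        gaps = find_gaps(seq, seqid=seqid)
        flags = detect_misassemblies(seqid, len(seq), classified, gaps, **SMALL)
        assert {f.kind for f in flags} == {"multiple_centromeres", "interior_telomere"}
        junction = fused_assembly.truth.junctions[0].position
        assert abs(flags[0].proposed_split - junction) <= 100

    def test_no_false_calls_over_20_seeds(self):
        """Fused scaffolds always flagged, clean ones never, split within one gap."""
        fn = fp = 0
        for seed in range(20):
            fused_spec = synthetic.fused_preset(seed=seed, component_length=30_000,
                                                telomere_copies=60, centromere_copies=30)
            clean_spec = synthetic.ScaffoldSpec(
                name="clean",
                length=60_000,
                telomere_5p=synthetic.RepeatUnitSpec(
                    monomer="TTTAGGG", alternate_monomer="TTGAGGG", copies=60,
                    per_base_mutation_rate=0.01),
                telomere_3p=synthetic.RepeatUnitSpec(
                    monomer="TTTAGGG", alternate_monomer="TTGAGGG", copies=60,
                    per_base_mutation_rate=0.01),
                centromere=(
                    synthetic.RepeatUnitSpec(
                        monomer=synthetic.CENTROMERE_MONOMER_181, copies=30,
                        per_base_mutation_rate=0.02),
                    0.5,
                ),
            )
            asm = synthetic.build_assembly([fused_spec, clean_spec], seed=seed)
            for seqid, seq in asm.sequences.items():
                arrays = detect_tandem_arrays(seq, seqid=seqid)
                classified = classify_arrays(arrays, {seqid: len(seq)}, end_window=5_000)
                gaps = find_gaps(seq, seqid=seqid)
                flags = detect_misassemblies(seqid, len(seq), classified, gaps, **SMALL)
                if seqid == "fused1":
                    if not flags:
                        fn += 1
                    else:
                        junction = asm.truth.junctions[0].position
                        assert abs(flags[0].proposed_split - junction) <= 100
                elif flags:
                    fp += 1
        assert fn == 0 and fp == 0


class TestSplitScaffold:
    def test_split_arithmetic(self):
        seq = "A" * 400 + "C" * 600
        from chromqc.qc import MisassemblyFlag

        flag = MisassemblyFlag("s", "multiple_centromeres", ((0, 10), (500, 510)), 400)
        left, right = split_scaffold(seq, flag)
        assert (len(left.sequence), len(right.sequence)) == (400, 600)
        assert left.name == "s_L" and right.name == "s_R"
        assert left.sequence + right.sequence == seq

    def test_annotation_lift(self):
        from chromqc.qc import MisassemblyFlag

        seq = "A" * 1_000
        flag = MisassemblyFlag("s", "multiple_centromeres", (), 400)
        arrays = [_tel("s", 450, 460 + 4)]  # wholly right of the split
        gaps = [GapRecord("s", 100, 200, True)]
        left, right = split_scaffold(seq, flag, arrays=arrays, gaps=gaps)
        assert right.arrays[0].start == 50 and right.arrays[0].end == 64
        assert right.arrays[0].seqid == "s_R"
        assert left.gaps[0].start == 100 and left.gaps[0].seqid == "s_L"
        assert not left.arrays and not right.gaps

    def test_fused_pieces_match_component_lengths(self, fused_assembly):
        seqid = "fused1"
        seq = fused_assembly.sequences[seqid]
        arrays = detect_tandem_arrays(seq, seqid=seqid)
        classified = classify_arrays(arrays, {seqid: len(seq)}, end_window=5_000)
        gaps = find_gaps(seq, seqid=seqid)
        flags = detect_misassemblies(seqid, len(seq), classified, gaps, **SMALL)
        left, right = split_scaffold(seq, flags[0], arrays=classified, gaps=gaps)
        junction = fused_assembly.truth.junctions[0]
        assert abs(len(left.sequence) - junction.left_length) <= 100
        assert abs(len(right.sequence) - (junction.right_length + 100)) <= 100
        assert len(left.sequence) + len(right.sequence) == len(seq)

    def test_split_at_bounds_rejected(self):
        from chromqc.qc import MisassemblyFlag

        with pytest.raises(ValidationError):
            split_scaffold("ACGT", MisassemblyFlag("s", "x", (), 0))
        with pytest.raises(ValidationError):
            split_scaffold("ACGT", MisassemblyFlag("s", "x", (), 4))


class TestNxStatistics:
    def test_known_example(self):
        assert nx_statistic([5, 4, 3, 2, 1], 50) == 4

    def test_single_scaffold(self):
        assert nx_statistic([42], 50) == 42
        assert nx_statistic([42], 90) == 42

    @given(
        lengths=st.lists(st.integers(min_value=1, max_value=10_000), min_size=1, max_size=40),
        x=st.integers(min_value=1, max_value=100),
    )
    def test_matches_exhaustive_threshold_oracle(self, lengths, x):
        # oracle: smallest candidate L (over observed lengths) with
        # sum(lengths >= L) >= x% of total
        total = sum(lengths)
        candidates = [
            L for L in sorted(set(lengths))
            if sum(v for v in lengths if v >= L) >= x / 100 * total
        ]
        assert nx_statistic(lengths, x) == max(candidates)

    @given(lengths=st.lists(st.integers(min_value=1, max_value=10_000), min_size=1, max_size=40))
    def test_nx_non_increasing_in_x(self, lengths):
        assert nx_statistic(lengths, 50) >= nx_statistic(lengths, 90)

    def test_empty_rejected(self):
        with pytest.raises(ValidationError):
            nx_statistic([], 50)


class TestAssemblySummary:
    def test_summary_table_and_nx(self):
        reports = [
            assess_scaffold("a", 5_000, [], [], **SMALL),
            assess_scaffold("b", 4_000, [], [], **SMALL),
            assess_scaffold("c", 3_000, [], [], **SMALL),
            assess_scaffold("d", 2_000, [], [], **SMALL),
            assess_scaffold("e", 1_000, [], [], **SMALL),
        ]
        table, nx = assembly_summary(reports)
        assert list(table.seqid) == ["a", "b", "c", "d", "e"]
        assert nx["N50"] == 4_000
        assert nx["N50"] >= nx["N90"]

    def test_empty_rejected(self):
        with pytest.raises(ValidationError):
            assembly_summary([])
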