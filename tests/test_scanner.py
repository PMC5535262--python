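import itertools

import pytest

from helpers_brute import brute_force_calls, call_as_tuple

from csiscan.alignment_io import Alignment, AlignmentError, Row, TaxonPartition
from csiscan.scanner import (
    ScanConfig,
    classify_specificity,
    conservation_profile,
    find_indel_candidates,
    scan_csi,
    score_flanks,
)
from csiscan.simulate import PlantedIndel, SyntheticSpec, degrade_flanks, simulate_msa
from conftest import random_tiny_alignment


def _aln(rows):
    return Alignment.from_pairs([(f"s{i}", r) for i, r in enumerate(rows)])


def _part(n_in, n_total):
    ids = [f"s{i}" for i in range(n_total)]
    return TaxonPartition(frozenset(ids[:n_in]), frozenset(ids[n_in:]))


class TestConservationProfile:
    @pytest.mark.parametrize(
        "column_residues, expected_fraction, expected_conserved",
        [
            ("AAAA", 1.0, True),
            ("AACC", 0.5, False),
            ("AAA-", 0.75, False),  # gap stays in the denominator
            ("AAAX", 0.75, False),  # X never matches
            ("----", 0.0, False),
        ],
    )
    def test_single_column(self, column_residues, expected_fraction, expected_conserved):
        rows = [ch + "K" for ch in column_residues]  # pad to keep columns honest
        aln = _aln(rows)
        profile = conservation_profile(aln, _part(2, len(rows)), ScanConfig())
        assert profile[0].majority_fraction == pytest.approx(expected_fraction)
        assert profile[0].is_conserved is expected_conserved

    def test_rows_outside_partition_ignored(self):
        aln = _aln(["AK", "AK", "CK", "CK"])
        part = TaxonPartition(frozenset({"s0"}), frozenset({"s1"}))
        profile = conservation_profile(aln, part, ScanConfig())
        assert profile[0].majority_fraction == 1.0


class TestFindCandidates:
    def test_forced_insert(self):
        aln = _aln(["ACDEFG", "ACDEFG", "AC--FG", "AC--FG"])
        cands = find_indel_candidates(aln, _part(2, 4), ScanConfig())
        assert len(cands) == 1
        cand = cands[0]
        assert (cand.span.start, cand.span.end, cand.type) == (2, 4, "insert")
        assert cand.per_row_lengths == {"s0": 2, "s1": 2, "s2": 0, "s3": 0}

    def test_no_discriminating_columns(self):
        aln = _aln(["ACDEFG"] * 4)
        assert find_indel_candidates(aln, _part(2, 4), ScanConfig()) == []

    def test_deletion_is_mirror(self):
        aln = _aln(["AC--FG", "AC--FG", "ACDEFG", "ACDEFG"])
        cands = find_indel_candidates(aln, _part(2, 4), ScanConfig())
        assert len(cands) == 1
        assert cands[0].type == "deletion"
        assert (cands[0].span.start, cands[0].span.end) == (2, 4)

    def test_single_row_insertion_rejected_by_region_presence(self):
        # only one of three in-group rows carries material: not a clade signature
        aln = _aln(["ACDEFG", "AC--FG", "AC--FG", "AC--FG", "AC--FG"])
        assert find_indel_candidates(aln, _part(3, 5), ScanConfig()) == []

    def test_length_variable_insert_kept_whole(self):
        # ragged final column still belongs to the insert region
        aln = _aln(["ACDEFG", "ACDE-G", "AC---G", "AC---G"])
        cands = find_indel_candidates(aln, _part(2, 4), ScanConfig())
        assert len(cands) == 1
        assert (cands[0].span.start, cands[0].span.end) == (2, 5)
        assert cands[0].per_row_lengths["s0"] == 3
        assert cands[0].per_row_lengths["s1"] == 2

    def test_merge_gap_cols_bridges_runs(self):
        aln = _aln(["ACDEFGH", "ACDEFGH", "AC-E-GH", "AC-E-GH"])
        strict = find_indel_candidates(aln, _part(2, 4), ScanConfig())
        assert [(c.span.start, c.span.end) for c in strict] == [(2, 3), (4, 5)]
        merged = find_indel_candidates(
            aln, _part(2, 4), ScanConfig(merge_gap_cols=1)
        )
        assert [(c.span.start, c.span.end) for c in merged] == [(2, 5)]


class TestScoreFlanks:
    def test_edge_span_has_empty_window(self):
        aln = _aln(["DEFG", "DEFG", "--FG", "--FG"])
        part = _part(2, 4)
        config = ScanConfig(flank_window_aa=2, min_flank_conserved=0)
        cands = find_indel_candidates(aln, part, config)
        profile = conservation_profile(aln, part, config)
        left, right = score_flanks(aln, cands[0], profile, config, "s0")
        assert left == 0  # span starts at column 0
        assert right == 2

    def test_window_measured_in_reference_residues(self):
        # the reference-gap column (col 2) must not consume a window slot:
        # the 3-residue window reaches back to K over cols 3, 1, 0
        aln = _aln(["KL-MNWPQRS", "KLAMNWPQRS", "KLAM--PQRS", "KLAM--PQRS"])
        part = _part(2, 4)
        config = ScanConfig(flank_window_aa=3, min_flank_conserved=0)
        (cand,) = find_indel_candidates(aln, part, config)
        assert (cand.span.start, cand.span.end) == (4, 6)
        profile = conservation_profile(aln, part, config)
        left, right = score_flanks(aln, cand, profile, config, "s0")
        assert (left, right) == (3, 3)

    def test_unknown_reference_rejected(self):
        aln = _aln(["ACDEFG", "ACDEFG", "AC--FG", "AC--FG"])
        part = _part(2, 4)
        config = ScanConfig()
        cands = find_indel_candidates(aln, part, config)
        profile = conservation_profile(aln, part, config)
        with pytest.raises(AlignmentError):
            score_flanks(aln, cands[0], profile, config, "nope")


class TestClassifySpecificity:
    def test_exclusive_insert(self):
        aln = _aln(["ACDEFG", "ACDEFG", "AC--FG", "AC--FG"])
        part = _part(2, 4)
        (cand,) = find_indel_candidates(aln, part, ScanConfig())
        assert classify_specificity(aln, cand, part, ScanConfig()) == ("exclusive", ())

    def test_insert_shared_with_one_outgroup_row(self):
        aln = _aln(["ACDEFG", "ACDEFG", "ACDEFG", "AC--FG", "AC--FG"])
        part = _part(2, 5)
        config = ScanConfig(outgroup_absence_fraction=0.6)
        (cand,) = find_indel_candidates(aln, part, config)
        spec, exceptions = classify_specificity(aln, cand, part, config)
        assert spec == "shared_with_exceptions"
        assert exceptions == ("s2",)

    def test_deletion_shared_with_two_outgroup_rows(self):
        aln = _aln(["AC--FG", "AC--FG", "AC--FG", "AC--FG", "ACDEFG", "ACDEFG"])
        part = _part(2, 6)
        config = ScanConfig(ingroup_presence_fraction=0.5)
        (cand,) = find_indel_candidates(aln, part, config)
        spec, exceptions = classify_specificity(aln, cand, part, config)
        assert spec == "shared_with_exceptions"
        assert exceptions == ("s2", "s3")


class TestScanCsi:
    def test_planted_insert_detected(self, noiseless_insert_fixture):
        alignment, partition, truth = noiseless_insert_fixture
        calls = scan_csi(alignment, partition)
        assert len(calls) == 1
        call = calls[0]
        assert call.type == "insert"
        assert (call.ingroup_length_min, call.ingroup_length_max) == (4, 4)
        assert call.specificity == "exclusive"
        assert call.span == truth.entries[0].span

    def test_degraded_flank_suppresses_call(self, noiseless_insert_fixture):
        alignment, partition, truth = noiseless_insert_fixture
        config = ScanConfig()
        degraded = degrade_flanks(
            alignment, truth, "left", config.min_flank_conserved - 1,
            config, seed=5, partition=partition,
        )
        assert scan_csi(degraded, partition, config) == []

    def test_length_range_reported(self):
        spec = SyntheticSpec(
            seed=3,
            substitution_rate=0.0,
            planted_indels=(PlantedIndel(position=150, length_aa=(43, 44), type="insert"),),
        )
        alignment, partition, _ = simulate_msa(spec)
        (call,) = scan_csi(alignment, partition)
        assert (call.ingroup_length_min, call.ingroup_length_max) == (43, 44)

    def test_zero_calls_is_normal(self):
        aln = _aln(["ACDEFGHIKL"] * 4)
        assert scan_csi(aln, _part(2, 4)) == []

    def test_reference_position_maps_to_ungapped_coordinates(
        self, noiseless_insert_fixture
    ):
        alignment, partition, truth = noiseless_insert_fixture
        (call,) = scan_csi(alignment, partition)
        # the planted insert sits after ancestor residue 100 and the
        # reference row carries no other indel
        assert call.reference_position == 100


class TestOracleEquivalence:
    @pytest.mark.parametrize("seed", range(100))
    def test_matches_brute_force_on_tiny_alignments(self, seed):
        alignment, partition, config, reference_id = random_tiny_alignment(seed)
        expected = brute_force_calls(alignment, partition, config, reference_id)
        got = [
            call_as_tuple(c)
            for c in scan_csi(alignment, partition, config, reference_id)
        ]
        assert got == expected


class TestScanProperties:
    def test_insert_deletion_duality_under_partition_swap(self, spectrum_fixture):
        alignment, partition, _ = spectrum_fixture
        config = ScanConfig(min_flank_conserved=0)
        ref_in = scan_csi(alignment, partition, config)
        ref_out = scan_csi(
            alignment, partition.swapped(), config,
            reference_id=sorted(partition.outgroup)[0],
        )
        flip = {"insert": "deletion", "deletion": "insert"}
        assert [(c.span, flip[c.type]) for c in ref_in] == [
            (c.span, c.type) for c in ref_out
        ]

    def test_row_permutation_invariance(self, spectrum_fixture):
        alignment, partition, _ = spectrum_fixture
        baseline = [call_as_tuple(c) for c in scan_csi(alignment, partition)]
        reordered = Alignment(
            rows=tuple(sorted(alignment.rows, key=lambda r: r.seq_id[::-1])),
            n_cols=alignment.n_cols,
        )
        ref = scan_csi(alignment, partition)[0].reference_id
        permuted = [
            call_as_tuple(c)
            for c in scan_csi(reordered, partition, reference_id=ref)
        ]
        assert permuted == baseline

    def test_call_count_monotone_in_flank_threshold(self, spectrum_fixture):
        alignment, partition, _ = spectrum_fixture
        counts = [
            len(scan_csi(alignment, partition, ScanConfig(min_flank_conserved=k)))
            for k in range(0, 41, 8)
        ]
        assert counts == sorted(counts, reverse=True)

    def test_call_count_monotone_in_conservation_fraction(self, spectrum_fixture):
        alignment, partition, _ = spectrum_fixture
        counts = [
            len(scan_csi(alignment, partition, ScanConfig(conservation_fraction=f)))
            for f in (0.5, 0.7, 0.9, 1.0)
        ]
        assert counts == sorted(counts, reverse=True)

    def test_call_count_monotone_in_outgroup_absence(self, spectrum_fixture):
        alignment, partition, _ = spectrum_fixture
        counts = [
            len(scan_csi(alignment, partition, ScanConfig(outgroup_absence_fraction=f)))
            for f in (1.0, 0.8, 0.6, 0.4)
        ]
        assert counts == sorted(counts)
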