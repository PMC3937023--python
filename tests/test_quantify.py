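"""Read filtering, category assignment, RPKM, expression calls, sharing."""

import math

import numpy as np
import pandas as pd
import pytest

from plateletome.annotation import AnnotationBundle, FeatureRecord, GenomicInterval, attach_derived_tracks
from plateletome.quantify import (
    ExpressionMatrix,
    MappedRead,
    assign_read_category,
    category_fractions,
    compute_rpkm,
    count_reads_per_feature,
    filter_reads,
    normalize_and_call,
    sharing_table,
    threshold_cycles,
)


def read(chrom, start, end, rid="r"):
    return MappedRead(GenomicInterval(chrom, start, end), rid)


@pytest.fixture()
def small_bundle():
    bundle = AnnotationBundle(genome={"chr1": 3000})
    bundle.add_track(
        "protein_coding_gene_span",
        [FeatureRecord(GenomicInterval("chr1", 100, 1100, "+"), "protein_coding_gene_span", "g1", "g1")],
    )
    bundle.add_track(
        "protein_coding_exon",
        [
            FeatureRecord(GenomicInterval("chr1", 100, 200, "+"), "protein_coding_exon", "g1:e0", "g1"),
            FeatureRecord(GenomicInterval("chr1", 1000, 1100, "+"), "protein_coding_exon", "g1:e1", "g1"),
        ],
    )
    bundle.add_track("SINE", [FeatureRecord(GenomicInterval("chr1", 150, 260, "-"), "SINE", "s1")])
    bundle.add_track("rRNA", [FeatureRecord(GenomicInterval("chr1", 1500, 1700, "."), "rRNA", "rr1")])
    return attach_derived_tracks(bundle)


class TestFilterReads:
    @pytest.mark.parametrize("length, kept", [(14, False), (15, False), (16, True), (17, True)])
    def test_length_boundary_is_inclusive_at_16(self, length, kept):
        out = filter_reads([read("chr1", 0, length)])
        assert (len(out) == 1) is kept

    def test_empty_input_and_order_preserved(self):
        assert filter_reads([]) == []
        reads = [read("chr1", 0, 30, "a"), read("chr1", 5, 15, "b"), read("chr1", 9, 60, "c")]
        assert [r.read_id for r in filter_reads(reads)] == ["a", "c"]

    def test_negative_length_frame_raises(self):
        frame = pd.DataFrame({"chrom": ["chr1"], "start": [10], "end": [10]})
        with pytest.raises(ValueError, match="non-positive length"):
            filter_reads(frame)


class TestAssignment:
    def test_exon_beats_repeat_under_default_precedence(self, small_bundle):
        # read overlaps both exon g1:e0 and the SINE
        assert assign_read_category(read("chr1", 150, 200), small_bundle) == "protein_coding_exon"

    def test_rrna_only_read(self, small_bundle):
        assert assign_read_category(read("chr1", 1550, 1600), small_bundle) == "rRNA"

    def test_intergenic_fallback(self, small_bundle):
        assert assign_read_category(read("chr1", 2000, 2050), small_bundle) == "unannotated_intergenic"

    def test_intronic_read(self, small_bundle):
        assert assign_read_category(read("chr1", 500, 550), small_bundle) == "purely_intronic"

    def test_custom_precedence_flips_label(self, small_bundle):
        got = assign_read_category(
            read("chr1", 150, 200),
            small_bundle,
            precedence=("SINE", "protein_coding_exon", "purely_intronic", "unannotated_intergenic"),
        )
        assert got == "SINE"

    def test_unknown_chromosome_raises(self, small_bundle):
        with pytest.raises(ValueError, match="unknown chromosome"):
            assign_read_category(read("chrX", 0, 50), small_bundle)

    def test_fractions_sum_to_100_and_match_counts(self, small_bundle):
        reads = (
            [read("chr1", 110, 150, f"e{i}") for i in range(4)]
            + [read("chr1", 1500, 1550, f"r{i}") for i in range(3)]
            + [read("chr1", 2000, 2040, f"i{i}") for i in range(2)]
            + [read("chr1", 400, 440, "n0")]
        )
        bd = category_fractions(reads, small_bundle)
        assert bd.counts == {
            "protein_coding_exon": 4,
            "rRNA": 3,
            "purely_intronic": 1,
            "unannotated_intergenic": 2,
        }
        assert bd.fractions["protein_coding_exon"] == pytest.approx(40.0)
        assert sum(bd.fractions.values()) == pytest.approx(100.0)

    def test_empty_read_list_rejected(self, small_bundle):
        with pytest.raises(ValueError, match="non-empty"):
            category_fractions([], small_bundle)


class TestPerFeatureCounting:
    def test_larger_overlap_wins_ties_lexicographic(self):
        features = {
            "gA": [("chr1", 0, 100)],
            "gB": [("chr1", 80, 200)],
        }
        reads = pd.DataFrame(
            {
                "chrom": ["chr1"] * 3,
                "start": [0, 90, 60],
                "end": [50, 140, 120],  # third read overlaps gA by 40, gB by 40 -> tie -> gA
            }
        )
        counts = count_reads_per_feature(reads, features)
        assert counts.to_dict() == {"gA": 2, "gB": 1}

    def test_read_spanning_two_intervals_of_same_feature_counts_once(self):
        features = {"g": [("chr1", 0, 50), ("chr1", 100, 150)]}
        reads = pd.DataFrame({"chrom": ["chr1"], "start": [40], "end": [110]})
        assert count_reads_per_feature(reads, features).to_dict() == {"g": 1}


class TestRPKM:
    def test_formula_example(self):
        got = compute_rpkm({"g": 10}, {"g": 2000}, 1_000_000)
        assert got["g"] == pytest.approx(5.0)

    def test_zero_counts_and_scale_invariance(self):
        assert compute_rpkm({"g": 0}, {"g": 500}, 10_000)["g"] == 0.0
        a = compute_rpkm({"g": 7}, {"g": 1234}, 55_000)["g"]
        b = compute_rpkm({"g": 14}, {"g": 1234}, 110_000)["g"]
        assert a == pytest.approx(b, rel=1e-12)

    def test_matches_independent_arithmetic_oracle(self):
        rng = np.random.default_rng(3)
        counts = {f"g{i}": int(c) for i, c in enumerate(rng.integers(0, 500, 20))}
        lengths = {f"g{i}": int(l) for i, l in enumerate(rng.integers(100, 5000, 20))}
        total = 123_456
        got = compute_rpkm(counts, lengths, total)
        for g in counts:
            oracle = counts[g] * 1e9 / (lengths[g] * total)
            assert got[g] == pytest.approx(oracle, rel=1e-12)

    def test_bad_inputs(self):
        with pytest.raises(ValueError):
            compute_rpkm({"g": 1}, {"g": 0}, 100)
        with pytest.raises(ValueError):
            compute_rpkm({"g": 1}, {"g": 100}, 0)


class TestCalls:
    def _matrix(self, values):
        return ExpressionMatrix(values=pd.DataFrame(values), reference_id="ACTB_T")

    def test_threshold_boundary_inclusive(self):
        m = normalize_and_call(
            self._matrix({"s1": {"ACTB_T": 50_000.0, "g_at": 5.0, "g_below": 4.95}})
        )
        assert m.normalized.loc["g_at", "s1"] == pytest.approx(1e-4)
        assert bool(m.calls.loc["g_at", "s1"]) is True
        assert bool(m.calls.loc["g_below", "s1"]) is False

    def test_reference_normalizes_to_one_everywhere(self):
        m = normalize_and_call(
            self._matrix({"s1": {"ACTB_T": 10.0, "g": 1.0}, "s2": {"ACTB_T": 99.0, "g": 5.0}})
        )
        assert (m.normalized.loc["ACTB_T"] == 1.0).all()
        assert m.calls.loc["ACTB_T"].all()

    def test_missing_or_zero_reference_names_the_problem(self):
        with pytest.raises(ValueError, match="ACTB_T"):
            normalize_and_call(self._matrix({"s1": {"g": 1.0}}))
        with pytest.raises(ValueError, match="s2"):
            normalize_and_call(
                self._matrix({"s1": {"ACTB_T": 10.0, "g": 1.0}, "s2": {"ACTB_T": 0.0, "g": 1.0}})
            )


class TestSharing:
    def test_three_sample_example(self):
        calls = pd.DataFrame(
            {"s1": [True, True, False], "s2": [True, True, False], "s3": [True, False, True]},
            index=["g1", "g2", "g3"],
        )
        t = sharing_table(calls)
        assert t.at_least == {1: 3, 2: 2, 3: 1}
        assert t.exactly == {1: 1, 2: 1, 3: 1}
        assert t.union == 3 and t.intersection == 1

    def test_identical_columns_make_union_equal_intersection(self):
        calls = pd.DataFrame({"s1": [True, False], "s2": [True, False]}, index=["g1", "g2"])
        t = sharing_table(calls)
        assert t.union == t.intersection == 1

    def test_no_expressed_genes(self):
        calls = pd.DataFrame({"s1": [False], "s2": [False]}, index=["g1"])
        t = sharing_table(calls)
        assert t.union == 0 and all(v == 0 for v in t.at_least.values())

    def test_curve_monotone_and_exactly_sums_to_union(self, cohort_quantified):
        matrix, _breakdown, feature_category = cohort_quantified
        genes = [f for f, c in feature_category.items() if c == "protein_coding"]
        t = sharing_table(matrix.calls.loc[matrix.calls.index.isin(genes)])
        ks = sorted(t.at_least)
        assert all(t.at_least[k] >= t.at_least[k + 1] for k in ks[:-1])
        assert sum(t.exactly.values()) == t.union


def test_threshold_in_pcr_cycles():
    assert threshold_cycles(1e-4) == pytest.approx(math.log2(10_000))
    assert round(threshold_cycles(1e-4)) == 13


def test_reads_are_counted_exactly_once(cohort_quantified, cohort_reads):
    _m, breakdown, _fc = cohort_quantified
    per_sample = breakdown.groupby("sample")["count"].sum()
    for sample, reads in cohort_reads.items():
        assert per_sample[sample] == len(reads)
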