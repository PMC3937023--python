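"""Interval algebra and derived-track construction."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from plateletome import _intervals as ia
from plateletome.annotation import (
    AnnotationBundle,
    FeatureRecord,
    GenomicInterval,
    attach_derived_tracks,
    derive_purely_intronic,
    derive_unannotated_intergenic,
    subtract_intervals,
)

from _oracles import base_mask, mask_to_intervals, oracle_purely_intronic, oracle_unannotated_intergenic, random_bundle


def pairs(records):
    return [(r.interval.start, r.interval.end) for r in records]


@pytest.mark.parametrize(
    "a, b, expected",
    [
        ([(0, 100)], [], [(0, 100)]),  # identity
        ([(0, 100)], [(0, 100)], []),  # full subtraction
        ([(0, 100)], [(10, 20), (50, 120)], [(0, 10), (20, 50)]),
        ([(0, 50), (40, 100)], [(60, 70)], [(0, 60), (70, 100)]),  # overlapping input a
    ],
)
def test_subtract_intervals_examples(a, b, expected):
    assert subtract_intervals(a, b) == expected


def test_subtract_intervals_rejects_mixed_chromosomes():
    with pytest.raises(ValueError, match="single chromosome"):
        subtract_intervals([GenomicInterval("chr1", 0, 10)], [GenomicInterval("chr2", 0, 5)])


interval_lists = st.lists(
    st.tuples(st.integers(0, 500), st.integers(1, 80)).map(lambda t: (t[0], t[0] + t[1])),
    max_size=15,
)


@settings(max_examples=200, derandomize=True)
@given(a=interval_lists, b=interval_lists)
def test_subtract_matches_per_base_oracle_and_is_idempotent(a, b):
    result = subtract_intervals(a, b)
    expected = mask_to_intervals(base_mask(a, 600) & ~base_mask(b, 600))
    assert result == expected
    # subtracting b twice changes nothing
    assert subtract_intervals(result, b) == result
    # output is sorted, disjoint, non-adjacent
    for (s1, e1), (s2, e2) in zip(result, result[1:]):
        assert e1 < s2


def _bundle_one_gene(features=()):
    bundle = AnnotationBundle(genome={"chr1": 2000})
    gene = FeatureRecord(GenomicInterval("chr1", 0, 1000, "+"), "protein_coding_gene_span", "g1", "g1")
    exons = [
        FeatureRecord(GenomicInterval("chr1", 0, 100, "+"), "protein_coding_exon", "g1:e0", "g1"),
        FeatureRecord(GenomicInterval("chr1", 900, 1000, "+"), "protein_coding_exon", "g1:e1", "g1"),
    ]
    bundle.add_track("protein_coding_gene_span", [gene])
    bundle.add_track("protein_coding_exon", exons)
    for rec in features:
        bundle.add_track(rec.category, [rec])
    return bundle


def test_purely_intronic_removes_sense_feature():
    # sense ncRNA inside the intron punches a hole
    mirna_like = FeatureRecord(GenomicInterval("chr1", 200, 210, "+"), "snRNA", "n1")
    got = derive_purely_intronic(_bundle_one_gene([mirna_like]))
    assert pairs(got) == [(100, 200), (210, 900)]


def test_purely_intronic_keeps_antisense_feature():
    antisense = FeatureRecord(GenomicInterval("chr1", 300, 400, "-"), "SINE", "s1")
    got = derive_purely_intronic(_bundle_one_gene([antisense]))
    assert pairs(got) == [(100, 900)]


def test_purely_intronic_unstranded_feature_counts_as_sense():
    unstranded = FeatureRecord(GenomicInterval("chr1", 300, 400, "."), "Simple_repeat", "r1")
    got = derive_purely_intronic(_bundle_one_gene([unstranded]))
    assert pairs(got) == [(100, 300), (400, 900)]


def test_single_exon_gene_yields_no_intron():
    bundle = AnnotationBundle(genome={"chr1": 2000})
    bundle.add_track(
        "protein_coding_gene_span",
        [FeatureRecord(GenomicInterval("chr1", 100, 500, "+"), "protein_coding_gene_span", "g1", "g1")],
    )
    bundle.add_track(
        "protein_coding_exon",
        [FeatureRecord(GenomicInterval("chr1", 100, 500, "+"), "protein_coding_exon", "g1:e0", "g1")],
    )
    assert derive_purely_intronic(bundle) == []


def test_exon_outside_gene_span_is_an_error():
    bundle = AnnotationBundle(genome={"chr1": 2000})
    bundle.add_track(
        "protein_coding_gene_span",
        [FeatureRecord(GenomicInterval("chr1", 100, 500, "+"), "protein_coding_gene_span", "g1", "g1")],
    )
    bundle.add_track(
        "protein_coding_exon",
        [FeatureRecord(GenomicInterval("chr1", 50, 150, "+"), "protein_coding_exon", "g1:e0", "g1")],
    )
    with pytest.raises(ValueError, match="outside gene span"):
        derive_purely_intronic(bundle)


def test_unannotated_intergenic_examples():
    bundle = AnnotationBundle(genome={"chr1": 1000})
    bundle.add_track(
        "SINE",
        [
            FeatureRecord(GenomicInterval("chr1", 0, 100, "+"), "SINE", "s1"),
            FeatureRecord(GenomicInterval("chr1", 900, 1000, "-"), "SINE", "s2"),
        ],
    )
    assert pairs(derive_unannotated_intergenic(bundle)) == [(100, 900)]
    # no features -> whole chromosome; fully annotated -> nothing
    empty = AnnotationBundle(genome={"chr1": 1000})
    assert pairs(derive_unannotated_intergenic(empty)) == [(0, 1000)]
    full = AnnotationBundle(genome={"chr1": 1000})
    full.add_track("rRNA", [FeatureRecord(GenomicInterval("chr1", 0, 1000, "."), "rRNA", "r1")])
    assert derive_unannotated_intergenic(full) == []


@pytest.mark.parametrize("seed", range(12))
def test_derivations_match_per_base_oracle_on_random_genomes(seed):
    """Both derived tracks equal brute-force per-base membership on messy genomes."""
    rng = np.random.default_rng(1000 + seed)
    bundle = random_bundle(rng, max_len=20_000)
    attach_derived_tracks(bundle)
    bundle.validate()

    want = oracle_purely_intronic(bundle)
    got: dict = {}
    for rec in bundle.track("purely_intronic"):
        key = (rec.interval.chrom, rec.interval.strand)
        got.setdefault(key, []).append((rec.interval.start, rec.interval.end))
    assert set(got) == set(want)
    for key, ivs in got.items():
        assert ivs == mask_to_intervals(want[key])

    want_ig = oracle_unannotated_intergenic(bundle)
    got_ig: dict = {}
    for rec in bundle.track("unannotated_intergenic"):
        got_ig.setdefault(rec.interval.chrom, []).append((rec.interval.start, rec.interval.end))
    assert set(got_ig) == set(want_ig)
    for chrom, ivs in got_ig.items():
        assert ivs == mask_to_intervals(want_ig[chrom])


def test_overlap_join_agrees_with_quadratic_scan():
    rng = np.random.default_rng(7)
    qs = rng.integers(0, 900, 200)
    qe = qs + rng.integers(1, 80, 200)
    fs = rng.integers(0, 900, 50)
    fe = fs + rng.integers(1, 200, 50)
    qi, fi, ov = ia.overlap_join(qs, qe, fs, fe)
    got = {(int(a), int(b)): int(c) for a, b, c in zip(qi, fi, ov)}
    want = {}
    for i in range(200):
        for j in range(50):
            o = min(qe[i], fe[j]) - max(qs[i], fs[j])
            if o > 0:
                want[(i, j)] = int(o)
    assert got == want


def test_bundle_validate_flags_out_of_bounds():
    bundle = AnnotationBundle(genome={"chr1": 100})
    bundle.add_track("rRNA", [FeatureRecord(GenomicInterval("chr1", 50, 200, "."), "rRNA", "r1")])
    with pytest.raises(ValueError, match="exceeds chromosome"):
        bundle.validate()
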