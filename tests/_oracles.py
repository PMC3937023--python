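"""Brute-force per-base oracles and random toy-genome generators.

These stay deliberately independent of the interval-sweep implementation:
every set operation is done on boolean per-base membership arrays.
"""

from __future__ import annotations

import numpy as np

from plateletome.annotation import (
    DERIVED_CATEGORIES,
    AnnotationBundle,
    FeatureRecord,
    GenomicInterval,
)


def base_mask(intervals, length: int) -> np.ndarray:
    mask = np.zeros(length, dtype=bool)
    for s, e in intervals:
        mask[s:e] = True
    return mask


def mask_to_intervals(mask: np.ndarray) -> list[tuple[int, int]]:
    idx = np.flatnonzero(np.diff(np.concatenate([[0], mask.view(np.int8), [0]])))
    return [(int(idx[i]), int(idx[i + 1])) for i in range(0, len(idx), 2)]


def records_to_mask(records, chrom: str, length: int, strands=("+", "-", ".")) -> np.ndarray:
    return base_mask(
        [
            (r.interval.start, r.interval.end)
            for r in records
            if r.interval.chrom == chrom and r.interval.strand in strands
        ],
        length,
    )


def oracle_purely_intronic(bundle: AnnotationBundle) -> dict[tuple[str, str], np.ndarray]:
    """Per-(chrom, strand) base mask of the stringent intronic track."""
    out: dict[tuple[str, str], np.ndarray] = {}
    exons_by_gene: dict[str, list] = {}
    for rec in bundle.track("protein_coding_exon"):
        exons_by_gene.setdefault(rec.gene_id, []).append(rec)
    for gene in bundle.track("protein_coding_gene_span"):
        chrom = gene.interval.chrom
        length = bundle.genome[chrom]
        strand = gene.interval.strand if gene.interval.strand in "+-" else "+"
        gene_mask = base_mask([(gene.interval.start, gene.interval.end)], length)
        own_exons = records_to_mask(exons_by_gene.get(gene.feature_id, []), chrom, length)
        sense = np.zeros(length, dtype=bool)
        for category in bundle.categories():
            if category in DERIVED_CATEGORIES or category == "protein_coding_gene_span":
                continue
            sense |= records_to_mask(bundle.track(category), chrom, length, strands=(strand, "."))
        seg = gene_mask & ~own_exons & ~sense
        key = (chrom, strand)
        out[key] = out.get(key, np.zeros(length, dtype=bool)) | seg
    return {k: v for k, v in out.items() if v.any()}


def oracle_unannotated_intergenic(bundle: AnnotationBundle) -> dict[str, np.ndarray]:
    out = {}
    for chrom, length in bundle.genome.items():
        annotated = np.zeros(length, dtype=bool)
        for category in bundle.categories():
            if category in DERIVED_CATEGORIES:
                continue
            annotated |= records_to_mask(bundle.track(category), chrom, length)
        out[chrom] = ~annotated
    return {k: v for k, v in out.items() if v.any()}


def random_bundle(rng: np.random.Generator, max_len: int = 100_000) -> AnnotationBundle:
    """A random, possibly messy toy genome: overlaps between tracks allowed."""
    n_chroms = int(rng.integers(1, 3))
    genome = {f"c{i}": int(rng.integers(2_000, max_len // n_chroms + 1)) for i in range(n_chroms)}
    bundle = AnnotationBundle(genome=genome)
    genes, exons = [], []
    gi = 0
    for chrom, length in genome.items():
        for _ in range(int(rng.integers(1, 6))):
            span_len = int(rng.integers(300, min(5_000, length)))
            start = int(rng.integers(0, length - span_len + 1))
            strand = "+" if rng.random() < 0.5 else "-"
            gid = f"g{gi}"
            gi += 1
            genes.append(
                FeatureRecord(GenomicInterval(chrom, start, start + span_len, strand), "protein_coding_gene_span", gid, gid)
            )
            n_exons = int(rng.integers(1, 5))
            for j in range(n_exons):
                el = int(rng.integers(20, max(21, span_len // 3)))
                es = int(rng.integers(start, start + span_len - el + 1))
                exons.append(
                    FeatureRecord(GenomicInterval(chrom, es, es + el, strand), "protein_coding_exon", f"{gid}:e{j}", gid)
                )
    bundle.add_track("protein_coding_gene_span", genes)
    bundle.add_track("protein_coding_exon", exons)
    for category in ("SINE", "rRNA", "snRNA"):
        recs = []
        for chrom, length in genome.items():
            for k in range(int(rng.integers(0, 8))):
                fl = int(rng.integers(20, 400))
                fs = int(rng.integers(0, length - fl + 1))
                strand = rng.choice(["+", "-", "."])
                recs.append(FeatureRecord(GenomicInterval(chrom, fs, fs + fl, str(strand)), category, f"{category}_{chrom}_{k}"))
        if recs:
            bundle.add_track(category, recs)
    return bundle
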