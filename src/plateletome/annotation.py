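"""Genomic annotation hierarchy and derived interval tracks.

The analysis classifies every uniquely-mapped read against a hierarchy of
annotation categories: protein-coding exons and gene spans, pseudogenes,
lncRNAs, the 14 RepeatMasker repeat/ncRNA classes, plus two *derived* tracks
that are deliberately stringent:

* ``purely_intronic`` — intronic sequence of each gene left after removing
  every annotated feature lying *sense* to the pre-mRNA (exons of any gene
  on that strand, sense repeats, sense ncRNAs, ...). Antisense features are
  not removed.
* ``unannotated_intergenic`` — genomic sequence left after removing all
  protein-coding loci (full gene spans) and every other characterised
  feature, regardless of strand.

All coordinates are 0-based half-open. GTF input (1-based closed) is
converted at the reader boundary (:mod:`plateletome.io`).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from . import _intervals as ia

#: RepeatMasker repeat / ncRNA classes used for annotation.
REPEAT_CLASSES: tuple[str, ...] = (
    "DNA",
    "RNA",
    "LINE",
    "SINE",
    "LTR",
    "RC",
    "Simple_repeat",
    "rRNA",
    "Satellite",
    "scRNA",
    "snRNA",
    "srpRNA",
    "tRNA",
    "Unknown",
)

#: Closed category vocabulary for FeatureRecord.
CATEGORIES: tuple[str, ...] = (
    "protein_coding_exon",
    "protein_coding_gene_span",
    "pseudogene",
    "lncRNA",
    *REPEAT_CLASSES,
    "purely_intronic",
    "unannotated_intergenic",
)

DERIVED_CATEGORIES: tuple[str, ...] = ("purely_intronic", "unannotated_intergenic")

STRANDS = ("+", "-", ".")


@dataclass(frozen=True)
class GenomicInterval:
    """Half-open genomic span with optional strand ('.' = unstranded)."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid interval [{self.start}, {self.end})")
        if self.strand not in STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class FeatureRecord:
    """An annotated feature: an interval plus its category and stable id.

    ``gene_id`` links exon records to their parent gene model; it is None
    for features that do not belong to a gene.
    """

    interval: GenomicInterval
    category: str
    feature_id: str
    gene_id: str | None = None

    def __post_init__(self):
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown category {self.category!r}")


@dataclass
class AnnotationBundle:
    """Genome table plus all category tracks.

    ``genome`` maps chromosome name to its length in bases; ``tracks`` maps
    category name to the list of features in that category.
    """

    genome: dict[str, int]
    tracks: dict[str, list[FeatureRecord]] = field(default_factory=dict)

    def add_track(self, category: str, records: Iterable[FeatureRecord]) -> None:
        records = list(records)
        for rec in records:
            if rec.category != category:
                raise ValueError(f"record {rec.feature_id} has category {rec.category}, expected {category}")
        self.tracks.setdefault(category, []).extend(records)

    def track(self, category: str) -> list[FeatureRecord]:
        return self.tracks.get(category, [])

    def categories(self) -> list[str]:
        return [c for c in CATEGORIES if self.tracks.get(c)]

    def track_arrays(self, category: str, chrom: str, strands: Sequence[str] = STRANDS):
        """(starts, ends) arrays for one category on one chromosome."""
        pairs = [
            (r.interval.start, r.interval.end)
            for r in self.track(category)
            if r.interval.chrom == chrom and r.interval.strand in strands
        ]
        return ia.as_arrays(pairs)

    def merged_track(self, category: str) -> dict[str, tuple[np.ndarray, np.ndarray]]:
        """Per-chromosome merged (disjoint, sorted) interval arrays."""
        out = {}
        for chrom in self.genome:
            s, e = self.track_arrays(category, chrom)
            if s.size:
                out[chrom] = ia.merge_arrays(s, e)
        return out

    def validate(self) -> None:
        """Check interval bounds, id uniqueness and derived-track disjointness."""
        for category, records in self.tracks.items():
            seen = set()
            for rec in records:
                iv = rec.interval
                if iv.chrom not in self.genome:
                    raise ValueError(f"{rec.feature_id}: unknown chromosome {iv.chrom}")
                if iv.end > self.genome[iv.chrom]:
                    raise ValueError(f"{rec.feature_id}: interval exceeds chromosome {iv.chrom}")
                if rec.feature_id in seen:
                    raise ValueError(f"duplicate feature_id {rec.feature_id} in {category}")
                seen.add(rec.feature_id)
        for chrom in self.genome:
            ug_s, ug_e = self.track_arrays("unannotated_intergenic", chrom)
            if ug_s.size:
                for category in self.categories():
                    if category in DERIVED_CATEGORIES:
                        continue
                    t_s, t_e = self.track_arrays(category, chrom)
                    if t_s.size and ia.intersect_size(ug_s, ug_e, t_s, t_e) > 0:
                        raise ValueError(f"unannotated_intergenic overlaps {category} on {chrom}")
            for strand in "+-":
                pi = [
                    (r.interval.start, r.interval.end)
                    for r in self.track("purely_intronic")
                    if r.interval.chrom == chrom and r.interval.strand == strand
                ]
                if not pi:
                    continue
                pi_s, pi_e = ia.as_arrays(pi)
                for category in self.categories():
                    if category in DERIVED_CATEGORIES or category == "protein_coding_gene_span":
                        continue
                    t_s, t_e = self.track_arrays(category, chrom, strands=(strand, "."))
                    if t_s.size and ia.intersect_size(pi_s, pi_e, t_s, t_e) > 0:
                        raise ValueError(f"purely_intronic ({strand}) overlaps sense {category} on {chrom}")


def subtract_intervals(a, b):
    """Maximal disjoint sorted intervals covering {bases in a} \\ {bases in b}.

    Inputs are sequences of ``GenomicInterval`` or ``(start, end)`` pairs; all
    intervals must lie on a single chromosome. Returns plain (start, end)
    tuples, or ``GenomicInterval`` when the inputs were ``GenomicInterval``.
    """

    def _split(items):
        chroms = set()
        pairs = []
        strand = "."
        for it in items:
            if isinstance(it, GenomicInterval):
                chroms.add(it.chrom)
                pairs.append((it.start, it.end))
                strand = it.strand
            else:
                s, e = it
                pairs.append((int(s), int(e)))
        return chroms, pairs, strand

    a_chroms, a_pairs, a_strand = _split(a)
    b_chroms, b_pairs, _ = _split(b)
    if len(a_chroms | b_chroms) > 1:
        raise ValueError(f"subtract_intervals requires a single chromosome, got {sorted(a_chroms | b_chroms)}")
    a_s, a_e = ia.as_arrays(a_pairs)
    b_s, b_e = ia.as_arrays(b_pairs)
    r_s, r_e = ia.subtract_arrays(a_s, a_e, b_s, b_e)
    if a_chroms:
        chrom = next(iter(a_chroms))
        return [GenomicInterval(chrom, int(s), int(e), a_strand) for s, e in zip(r_s, r_e)]
    return [(int(s), int(e)) for s, e in zip(r_s, r_e)]


def _sense_feature_arrays(bundle: AnnotationBundle, chrom: str, strand: str):
    """All annotated feature intervals sense to ``strand`` on ``chrom``.

    Unstranded features count as sense to both strands. Gene spans and the
    derived tracks are excluded: a span is not itself a characterised
    feature beyond its exons.
    """
    pairs = []
    for category in bundle.categories():
        if category in DERIVED_CATEGORIES or category == "protein_coding_gene_span":
            continue
        s, e = bundle.track_arrays(category, chrom, strands=(strand, "."))
        pairs.append((s, e))
    if not pairs:
        return ia.as_arrays([])
    return (
        np.concatenate([p[0] for p in pairs]),
        np.concatenate([p[1] for p in pairs]),
    )


def derive_purely_intronic(bundle: AnnotationBundle) -> list[FeatureRecord]:
    """Stringent intronic track: gene introns minus all sense features.

    For every gene span, subtract that gene's exons, then every annotated
    feature on the same strand (or unstranded). Per-gene segments are then
    unioned per (chromosome, strand) and emitted as ``purely_intronic``
    records carrying the strand of the source gene(s).
    """
    genes = bundle.track("protein_coding_gene_span")
    exons_by_gene: dict[str, list[tuple[int, int]]] = {}
    for rec in bundle.track("protein_coding_exon"):
        if rec.gene_id is not None:
            exons_by_gene.setdefault(rec.gene_id, []).append((rec.interval.start, rec.interval.end))

    per_strand: dict[tuple[str, str], list[tuple[int, int]]] = {}
    sense_cache: dict[tuple[str, str], tuple[np.ndarray, np.ndarray]] = {}
    for gene in genes:
        iv = gene.interval
        exons = exons_by_gene.get(gene.feature_id, [])
        for es, ee in exons:
            if es < iv.start or ee > iv.end:
                raise ValueError(f"gene {gene.feature_id}: exon [{es}, {ee}) outside gene span")
        strand = iv.strand if iv.strand in "+-" else "+"
        key = (iv.chrom, strand)
        if key not in sense_cache:
            sense_cache[key] = _sense_feature_arrays(bundle, iv.chrom, strand)
        sense_s, sense_e = sense_cache[key]
        intron_s, intron_e = ia.subtract_arrays(*ia.as_arrays([(iv.start, iv.end)]), *ia.as_arrays(exons))
        res_s, res_e = ia.subtract_arrays(intron_s, intron_e, sense_s, sense_e)
        per_strand.setdefault(key, []).extend(zip(res_s.tolist(), res_e.tolist()))

    records: list[FeatureRecord] = []
    i = 0
    for (chrom, strand) in sorted(per_strand):
        s, e = ia.merge_arrays(*ia.as_arrays(per_strand[(chrom, strand)]))
        for start, end in zip(s.tolist(), e.tolist()):
            records.append(
                FeatureRecord(
                    GenomicInterval(chrom, start, end, strand),
                    "purely_intronic",
                    f"intron_{i:06d}",
                )
            )
            i += 1
    return records


def derive_unannotated_intergenic(bundle: AnnotationBundle) -> list[FeatureRecord]:
    """Chromosome space minus the union of every annotated track (strand-blind)."""
    records: list[FeatureRecord] = []
    i = 0
    for chrom, length in bundle.genome.items():
        pairs = []
        for category in bundle.categories():
            if category in DERIVED_CATEGORIES:
                continue
            s, e = bundle.track_arrays(category, chrom)
            pairs.append((s, e))
        if pairs:
            all_s = np.concatenate([p[0] for p in pairs])
            all_e = np.concatenate([p[1] for p in pairs])
        else:
            all_s, all_e = ia.as_arrays([])
        res_s, res_e = ia.subtract_arrays(*ia.as_arrays([(0, length)]), all_s, all_e)
        for start, end in zip(res_s.tolist(), res_e.tolist()):
            records.append(
                FeatureRecord(
                    GenomicInterval(chrom, start, end, "."),
                    "unannotated_intergenic",
                    f"intergenic_{i:06d}",
                )
            )
            i += 1
    return records


def attach_derived_tracks(bundle: AnnotationBundle) -> AnnotationBundle:
    """Compute both derived tracks and store them on the bundle (in place)."""
    bundle.tracks["purely_intronic"] = derive_purely_intronic(bundle)
    bundle.tracks["unannotated_intergenic"] = derive_unannotated_intergenic(bundle)
    return bundle
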