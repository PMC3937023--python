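"""Read filtering, category assignment, RPKM and expression calls.

Quantification follows the study design the package implements:

* mapped reads shorter than 16 nt are discarded;
* every uniquely-mapped read is assigned to exactly one annotation
  category by a configurable precedence order (exons first, the derived
  unannotated-intergenic track last), giving category percentages that
  sum to 100;
* gene abundance is RPKM over the union of exonic bases;
* abundances are normalized to the beta-actin transcript
  (ENST00000331789) and a gene is called *expressed* in a sample when its
  normalized abundance is >= 1/10,000 of beta-actin's.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from . import _intervals as ia
from .annotation import AnnotationBundle, GenomicInterval

DEFAULT_MIN_READ_LEN = 16
DEFAULT_REFERENCE_ID = "ENST00000331789"
DEFAULT_THRESHOLD = 1e-4

#: Single-label assignment order for reads overlapping several tracks.
DEFAULT_PRECEDENCE: tuple[str, ...] = (
    "protein_coding_exon",
    "rRNA",
    "pseudogene",
    "lncRNA",
    "scRNA",
    "snRNA",
    "srpRNA",
    "tRNA",
    "RNA",
    "DNA",
    "LINE",
    "SINE",
    "LTR",
    "RC",
    "Simple_repeat",
    "Satellite",
    "Unknown",
    "purely_intronic",
    "unannotated_intergenic",
)


@dataclass(frozen=True)
class MappedRead:
    """A uniquely-mapped read; length is end - start."""

    interval: GenomicInterval
    read_id: str

    @property
    def length(self) -> int:
        return self.interval.length


@dataclass
class CategoryBreakdown:
    """Per-category read counts and percentages of the uniquely-mapped total."""

    counts: dict[str, int]
    fractions: dict[str, float]

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    def to_frame(self) -> pd.DataFrame:
        cats = list(self.counts)
        return pd.DataFrame(
            {"count": [self.counts[c] for c in cats], "percent": [self.fractions[c] for c in cats]},
            index=pd.Index(cats, name="category"),
        )


def reads_to_frame(reads: Iterable[MappedRead]) -> pd.DataFrame:
    rows = [
        (r.interval.chrom, r.interval.start, r.interval.end, r.read_id, r.interval.strand)
        for r in reads
    ]
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "read_id", "strand"])


def _as_frame(reads) -> pd.DataFrame:
    if isinstance(reads, pd.DataFrame):
        return reads
    return reads_to_frame(reads)


def filter_reads(reads, min_len: int = DEFAULT_MIN_READ_LEN):
    """Drop reads shorter than ``min_len`` bases (boundary inclusive: keep >=).

    Accepts a list of :class:`MappedRead` or a reads DataFrame; order is
    preserved and the return type matches the input.
    """
    if min_len < 1:
        raise ValueError("min_len must be >= 1")
    if isinstance(reads, pd.DataFrame):
        lengths = reads["end"] - reads["start"]
        if (lengths <= 0).any():
            raise ValueError("read with non-positive length")
        return reads.loc[lengths >= min_len].reset_index(drop=True)
    out = []
    for r in reads:
        if r.length <= 0:
            raise ValueError(f"read {r.read_id} has non-positive length")
        if r.length >= min_len:
            out.append(r)
    return out


def assign_categories(
    reads, bundle: AnnotationBundle, precedence: Sequence[str] = DEFAULT_PRECEDENCE
) -> pd.Series:
    """Vectorized single-label assignment for a whole read set.

    Returns a Series of category labels aligned to the reads. A read gets
    the first category in ``precedence`` it overlaps by >= 1 base.
    """
    frame = _as_frame(reads)
    unknown = set(frame["chrom"]) - set(bundle.genome)
    if unknown:
        raise ValueError(f"reads on unknown chromosome(s): {sorted(unknown)}")
    result = pd.Series(pd.NA, index=frame.index, dtype="object")
    for chrom, idx in frame.groupby("chrom", sort=False).groups.items():
        sub = frame.loc[idx]
        starts = sub["start"].to_numpy(np.int64)
        ends = sub["end"].to_numpy(np.int64)
        unassigned = np.ones(len(sub), dtype=bool)
        labels = np.empty(len(sub), dtype=object)
        for category in precedence:
            if not unassigned.any():
                break
            t_s, t_e = bundle.track_arrays(category, chrom)
            if t_s.size == 0:
                continue
            rows = np.flatnonzero(unassigned)
            hit = ia.overlaps_any(starts[rows], ends[rows], t_s, t_e)
            labels[rows[hit]] = category
            unassigned[rows[hit]] = False
        if unassigned.any():
            missing = sub.index[unassigned][:3].tolist()
            raise ValueError(
                f"{int(unassigned.sum())} reads on {chrom} overlap no category "
                f"(first read rows: {missing}); precedence must end with a covering track"
            )
        result.loc[idx] = labels
    return result


def assign_read_category(
    read: MappedRead, bundle: AnnotationBundle, precedence: Sequence[str] = DEFAULT_PRECEDENCE
) -> str:
    return assign_categories([read], bundle, precedence).iloc[0]


def category_fractions(
    reads, bundle: AnnotationBundle, precedence: Sequence[str] = DEFAULT_PRECEDENCE
) -> CategoryBreakdown:
    """Counts and percentages per category over the uniquely-mapped total."""
    frame = _as_frame(reads)
    if len(frame) == 0:
        raise ValueError("category_fractions requires a non-empty read list")
    labels = assign_categories(frame, bundle, precedence)
    counts = labels.value_counts()
    total = int(counts.sum())
    ordered = [c for c in precedence if c in counts.index]
    return CategoryBreakdown(
        counts={c: int(counts[c]) for c in ordered},
        fractions={c: 100.0 * counts[c] / total for c in ordered},
    )


def count_reads_per_feature(
    reads, features: Mapping[str, list[tuple[str, int, int]]] | pd.DataFrame
) -> pd.Series:
    """Count reads per feature, assigning each read to one feature.

    ``features`` maps feature id -> list of (chrom, start, end) intervals
    (e.g. the exons of a gene). A read counts toward a feature when it
    overlaps any of its intervals by >= 1 base; a read overlapping several
    features goes to the one with the larger total overlap, ties broken by
    lexicographically smallest feature id.
    """
    frame = _as_frame(reads)
    ids = sorted(features)
    rank = {fid: i for i, fid in enumerate(ids)}  # ids sorted -> rank is lexicographic
    rows = []
    for fid, ivs in features.items():
        for chrom, s, e in ivs:
            rows.append((chrom, s, e, rank[fid]))
    feat = pd.DataFrame(rows, columns=["chrom", "start", "end", "rank"])
    counts = np.zeros(len(ids), dtype=np.int64)
    for chrom, idx in frame.groupby("chrom", sort=False).groups.items():
        sub = frame.loc[idx]
        fsub = feat[feat["chrom"] == chrom]
        if fsub.empty:
            continue
        qi, fi, ov = ia.overlap_join(
            sub["start"].to_numpy(np.int64),
            sub["end"].to_numpy(np.int64),
            fsub["start"].to_numpy(np.int64),
            fsub["end"].to_numpy(np.int64),
        )
        if qi.size == 0:
            continue
        franks = fsub["rank"].to_numpy(np.int64)[fi]
        # sum overlap per (read, feature) in case a read spans two intervals
        # of the same feature, then pick argmax overlap / min rank per read
        key = qi * np.int64(len(ids)) + franks
        uniq, inv = np.unique(key, return_inverse=True)
        tot = np.zeros(uniq.size, dtype=np.int64)
        np.add.at(tot, inv, ov)
        u_q = uniq // len(ids)
        u_r = uniq % len(ids)
        order = np.lexsort((u_r, -tot, u_q))
        first = np.ones(order.size, dtype=bool)
        first[1:] = u_q[order][1:] != u_q[order][:-1]
        winners = u_r[order][first]
        np.add.at(counts, winners, 1)
    return pd.Series(counts, index=pd.Index(ids, name="feature_id"), dtype=np.int64)


def gene_exon_unions(bundle: AnnotationBundle) -> dict[str, list[tuple[str, int, int]]]:
    """Per-gene merged exon intervals, for counting and gene lengths."""
    by_gene: dict[str, dict[str, list[tuple[int, int]]]] = {}
    for rec in bundle.track("protein_coding_exon"):
        gid = rec.gene_id or rec.feature_id
        by_gene.setdefault(gid, {}).setdefault(rec.interval.chrom, []).append(
            (rec.interval.start, rec.interval.end)
        )
    out: dict[str, list[tuple[str, int, int]]] = {}
    for gid, per_chrom in by_gene.items():
        ivs = []
        for chrom, pairs in per_chrom.items():
            s, e = ia.merge_arrays(*ia.as_arrays(pairs))
            ivs.extend((chrom, int(a), int(b)) for a, b in zip(s, e))
        out[gid] = ivs
    return out


def feature_intervals(bundle: AnnotationBundle, category: str) -> dict[str, list[tuple[str, int, int]]]:
    """Per-feature interval map for a single-interval category (e.g. pseudogene)."""
    return {
        r.feature_id: [(r.interval.chrom, r.interval.start, r.interval.end)]
        for r in bundle.track(category)
    }


def compute_rpkm(counts, lengths, total_mapped: int) -> pd.Series:
    """RPKM[g] = counts[g] / (lengths[g]/1000 * total_mapped/1e6)."""
    counts = pd.Series(counts, dtype=float)
    lengths = pd.Series(lengths, dtype=float).reindex(counts.index)
    if total_mapped <= 0:
        raise ValueError("total_mapped must be > 0")
    if lengths.isna().any() or (lengths <= 0).any():
        bad = lengths.index[lengths.isna() | (lengths <= 0)][:3].tolist()
        raise ValueError(f"missing or non-positive feature length for {bad}")
    return counts / (lengths / 1_000.0 * total_mapped / 1_000_000.0)


@dataclass
class ExpressionMatrix:
    """Feature x sample abundances with beta-actin-normalized ratios and calls."""

    values: pd.DataFrame
    reference_id: str = DEFAULT_REFERENCE_ID
    threshold: float = DEFAULT_THRESHOLD
    normalized: pd.DataFrame | None = None
    calls: pd.DataFrame | None = None

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)


def normalize_and_call(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Populate normalized ratios and boolean expression calls.

    The threshold comparison is inclusive: normalized >= threshold counts
    as expressed, so a gene at exactly 1/10,000 of beta-actin is called.
    """
    values = matrix.values
    if matrix.reference_id not in values.index:
        raise ValueError(f"reference gene {matrix.reference_id!r} absent from expression matrix")
    ref = values.loc[matrix.reference_id]
    zero = ref[ref <= 0]
    if len(zero):
        raise ValueError(
            f"reference gene {matrix.reference_id!r} has non-positive abundance in sample(s) "
            f"{list(zero.index)}"
        )
    normalized = values.div(ref, axis=1)
    calls = normalized >= matrix.threshold
    return replace(matrix, normalized=normalized, calls=calls)


@dataclass
class SharingTable:
    """How many features are expressed in at least / exactly k samples."""

    at_least: dict[int, int]
    exactly: dict[int, int]
    union: int
    intersection: int

    def to_frame(self) -> pd.DataFrame:
        ks = sorted(self.at_least)
        return pd.DataFrame(
            {"at_least_k": [self.at_least[k] for k in ks], "exactly_k": [self.exactly[k] for k in ks]},
            index=pd.Index(ks, name="k"),
        )


def sharing_table(calls: pd.DataFrame) -> SharingTable:
    """Union/intersection accounting over boolean calls (genes x samples)."""
    n = calls.shape[1]
    if n < 1:
        raise ValueError("sharing_table requires >= 1 sample")
    per_gene = calls.sum(axis=1).to_numpy()
    at_least = {k: int((per_gene >= k).sum()) for k in range(1, n + 1)}
    exactly = {k: int((per_gene == k).sum()) for k in range(1, n + 1)}
    return SharingTable(at_least=at_least, exactly=exactly, union=at_least[1], intersection=at_least[n])


def threshold_cycles(threshold: float = DEFAULT_THRESHOLD) -> float:
    """Expression cutoff as PCR doubling cycles below the reference.

    A ratio threshold of 1/10,000 of beta-actin corresponds to
    log2(10,000) ~ 13 doubling cycles.
    """
    if not 0 < threshold < 1:
        raise ValueError("threshold must be in (0, 1)")
    return math.log2(1.0 / threshold)


def quantify_samples(
    reads_by_sample: Mapping[str, pd.DataFrame],
    bundle: AnnotationBundle,
    categories: Sequence[str] = ("protein_coding", "pseudogene"),
    min_len: int = DEFAULT_MIN_READ_LEN,
    precedence: Sequence[str] = DEFAULT_PRECEDENCE,
    with_breakdown: bool = True,
) -> tuple[pd.DataFrame, pd.DataFrame, dict[str, str]]:
    """Per-sample RPKM for genes (exon unions) and single-interval categories.

    Returns (rpkm matrix features x samples, category breakdown long table,
    feature_id -> category map). ``total_mapped`` per sample is the number
    of uniquely-mapped reads surviving the length filter.
    """
    feature_maps: dict[str, dict[str, list[tuple[str, int, int]]]] = {}
    for cat in categories:
        if cat == "protein_coding":
            feature_maps[cat] = gene_exon_unions(bundle)
        else:
            feature_maps[cat] = feature_intervals(bundle, cat)
    lengths = {
        fid: sum(e - s for _c, s, e in ivs)
        for fmap in feature_maps.values()
        for fid, ivs in fmap.items()
    }
    feature_category = {fid: cat for cat, fmap in feature_maps.items() for fid in fmap}

    rpkm_cols: dict[str, pd.Series] = {}
    breakdown_rows = []
    for sample, reads in reads_by_sample.items():
        kept = filter_reads(reads, min_len=min_len)
        total = len(kept)
        if with_breakdown:
            breakdown = category_fractions(kept, bundle, precedence)
            for cat, cnt in breakdown.counts.items():
                breakdown_rows.append((sample, cat, cnt, breakdown.fractions[cat]))
        counts = pd.concat([count_reads_per_feature(kept, fmap) for fmap in feature_maps.values()])
        rpkm_cols[sample] = compute_rpkm(counts, pd.Series(lengths), total)
    rpkm = pd.DataFrame(rpkm_cols)
    rpkm.index.name = "feature_id"
    breakdown_df = pd.DataFrame(breakdown_rows, columns=["sample", "category", "count", "percent"])
    return rpkm, breakdown_df, feature_category
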