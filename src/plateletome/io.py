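"""Readers and writers for the plain-text formats the pipeline uses.

* chromosome-length table: two-column TSV (chrom, length)
* category tracks and derived tracks: BED6 (0-based half-open, native)
* gene models: GTF (1-based closed; converted here at the boundary)
* mapped reads: BED6, one file per sample
* run manifests: JSON
"""

from __future__ import annotations

import hashlib
import json
import re
from pathlib import Path
from typing import Iterable

import pandas as pd

from .annotation import AnnotationBundle, FeatureRecord, GenomicInterval

BED_COLUMNS = ["chrom", "start", "end", "name", "score", "strand"]

_GTF_ATTR = re.compile(r'(\w+) "([^"]*)"')


def read_chrom_sizes(path) -> dict[str, int]:
    df = pd.read_csv(path, sep="\t", header=None, names=["chrom", "length"], dtype={"chrom": str})
    return dict(zip(df["chrom"], df["length"].astype(int)))


def write_chrom_sizes(genome: dict[str, int], path) -> None:
    pd.DataFrame(genome.items(), columns=["chrom", "length"]).to_csv(path, sep="\t", header=False, index=False)


def read_bed(path) -> pd.DataFrame:
    """BED6 -> DataFrame. Missing name/score/strand columns are filled."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype={0: str})
    df = df.iloc[:, : len(BED_COLUMNS)]
    df.columns = BED_COLUMNS[: df.shape[1]]
    for col, default in (("name", "."), ("score", 0), ("strand", ".")):
        if col not in df.columns:
            df[col] = default
    df["start"] = df["start"].astype(int)
    df["end"] = df["end"].astype(int)
    return df


def write_bed(df: pd.DataFrame, path) -> None:
    df.loc[:, BED_COLUMNS].to_csv(path, sep="\t", header=False, index=False)


def features_to_bed(records: Iterable[FeatureRecord]) -> pd.DataFrame:
    rows = [
        (r.interval.chrom, r.interval.start, r.interval.end, r.feature_id, 0, r.interval.strand)
        for r in records
    ]
    return pd.DataFrame(rows, columns=BED_COLUMNS)


def read_feature_bed(path, category: str) -> list[FeatureRecord]:
    df = read_bed(path)
    return [
        FeatureRecord(GenomicInterval(row.chrom, row.start, row.end, row.strand), category, str(row.name))
        for row in df.itertuples(index=False)
    ]


def read_gtf(path) -> tuple[list[FeatureRecord], list[FeatureRecord]]:
    """Parse gene models from GTF: (gene span records, exon records).

    Uses feature rows ``gene`` and ``exon`` and the ``gene_id`` attribute.
    GTF coordinates (1-based closed) are converted to 0-based half-open.
    """
    genes: list[FeatureRecord] = []
    exons: list[FeatureRecord] = []
    exon_counter: dict[str, int] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 9:
                raise ValueError(f"malformed GTF line: {line!r}")
            chrom, _source, feature, start, end, _score, strand, _frame, attrs = fields[:9]
            if feature not in ("gene", "exon"):
                continue
            attr = dict(_GTF_ATTR.findall(attrs))
            gene_id = attr.get("gene_id")
            if gene_id is None:
                raise ValueError(f"GTF {feature} row without gene_id: {line!r}")
            iv = GenomicInterval(chrom, int(start) - 1, int(end), strand if strand in "+-" else ".")
            if feature == "gene":
                genes.append(FeatureRecord(iv, "protein_coding_gene_span", gene_id, gene_id))
            else:
                n = exon_counter.get(gene_id, 0)
                exon_counter[gene_id] = n + 1
                exons.append(FeatureRecord(iv, "protein_coding_exon", f"{gene_id}:exon{n}", gene_id))
    return genes, exons


def write_gtf(genes: Iterable[FeatureRecord], exons: Iterable[FeatureRecord], path) -> None:
    with open(path, "w") as fh:
        for rec, feature in [(g, "gene") for g in genes] + [(e, "exon") for e in exons]:
            iv = rec.interval
            gene_id = rec.gene_id or rec.feature_id
            attrs = f'gene_id "{gene_id}"; feature_id "{rec.feature_id}";'
            fh.write(
                f"{iv.chrom}\tplateletome\t{feature}\t{iv.start + 1}\t{iv.end}\t.\t{iv.strand}\t.\t{attrs}\n"
            )


def read_reads_bed(path) -> pd.DataFrame:
    """Mapped reads BED -> DataFrame with chrom/start/end/read_id/strand."""
    df = read_bed(path)
    df = df.rename(columns={"name": "read_id"})
    if (df["end"] - df["start"] <= 0).any():
        raise ValueError(f"{path}: read with non-positive length")
    return df[["chrom", "start", "end", "read_id", "strand"]]


def write_reads_bed(reads: pd.DataFrame, path) -> None:
    out = reads.rename(columns={"read_id": "name"}).copy()
    out["score"] = 0
    write_bed(out, path)


def write_tsv(df: pd.DataFrame, path, index: bool = True) -> None:
    df.to_csv(path, sep="\t", index=index)


def read_matrix_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def sha256_file(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(path, payload: dict) -> None:
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True, default=str) + "\n")


def read_manifest(path) -> dict:
    return json.loads(Path(path).read_text())


def bundle_to_files(bundle: AnnotationBundle, outdir) -> dict[str, str]:
    """Write a bundle as chrom sizes + GTF gene models + per-category BEDs."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, str] = {}
    sizes = outdir / "genome.chrom.sizes"
    write_chrom_sizes(bundle.genome, sizes)
    paths["genome"] = str(sizes)
    gtf = outdir / "genes.gtf"
    write_gtf(bundle.track("protein_coding_gene_span"), bundle.track("protein_coding_exon"), gtf)
    paths["genes_gtf"] = str(gtf)
    for category in bundle.categories():
        if category in ("protein_coding_gene_span", "protein_coding_exon"):
            continue
        bed = outdir / f"{category}.bed"
        write_bed(features_to_bed(bundle.track(category)), bed)
        paths[category] = str(bed)
    return paths


def bundle_from_files(genome_path, gtf_path, category_beds: dict[str, str]) -> AnnotationBundle:
    bundle = AnnotationBundle(genome=read_chrom_sizes(genome_path))
    genes, exons = read_gtf(gtf_path)
    bundle.add_track("protein_coding_gene_span", genes)
    bundle.add_track("protein_coding_exon", exons)
    for category, path in category_beds.items():
        bundle.add_track(category, read_feature_bed(path, category))
    return bundle
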