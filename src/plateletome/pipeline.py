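"""End-to-end orchestration: simulate -> annotate -> quantify -> enrich ->
correlate -> compare-proteome.

Every stage reads its inputs from files, writes plain TSV/BED/GTF outputs
into its own subdirectory of the run directory, and records a JSON
manifest with the configuration, seed, package version and input
checksums. Runs are fully deterministic under a fixed seed; re-runs can
resume from existing stage outputs when the recorded input checksums still
match.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from . import io
from .annotation import attach_derived_tracks
from .correlation import cross_platform_spearman, group_contrast, pairwise_pearson
from .enrichment import enrichment_table
from .proteome import build_concordance, filter_proteome, partition_percentages
from .quantify import (
    DEFAULT_MIN_READ_LEN,
    DEFAULT_REFERENCE_ID,
    DEFAULT_THRESHOLD,
    ExpressionMatrix,
    normalize_and_call,
    quantify_samples,
    sharing_table,
)
from .simulate import (
    CohortConfig,
    ProteomeSimConfig,
    make_genome,
    simulate_microarray,
    simulate_proteome,
    simulate_read_sets,
)

logger = logging.getLogger("plateletome")

STAGES = ("simulate", "annotate", "quantify", "enrich", "correlate", "compare_proteome")

#: Categories tested for enrichment by default (those the cohort expresses).
DEFAULT_ENRICH_CATEGORIES = (
    "pseudogene",
    "rRNA",
    "snRNA",
    "srpRNA",
    "tRNA",
    "scRNA",
    "RNA",
    "SINE",
    "lncRNA",
)


class StageError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r} failed: {message}")
        self.stage = stage


@dataclass
class RunConfig:
    """All knobs of an end-to-end run, with the study's stated defaults."""

    outdir: str = "plateletome_run"
    threshold: float = DEFAULT_THRESHOLD
    reference_id: str = DEFAULT_REFERENCE_ID
    min_read_len: int = DEFAULT_MIN_READ_LEN
    n_shuffles: int = 1000
    fold_cutoff: float = 1.5
    p_cutoff: float = 0.05
    seed: int = 0
    log_level: str = "INFO"
    cohort: CohortConfig = field(default_factory=CohortConfig)
    proteome: ProteomeSimConfig = field(default_factory=ProteomeSimConfig)
    enrich_categories: tuple[str, ...] = DEFAULT_ENRICH_CATEGORIES
    enrich_per_sample: bool = True

    def __post_init__(self):
        # one master seed drives every stage
        self.cohort.seed = self.seed
        self.proteome.seed = self.seed + 1

    def to_dict(self) -> dict:
        d = asdict(self)
        return d


def _config_digest(config: RunConfig) -> str:
    import hashlib

    return hashlib.sha256(json.dumps(config.to_dict(), sort_keys=True, default=str).encode()).hexdigest()


def _stage_dir(config: RunConfig, stage: str) -> Path:
    d = Path(config.outdir) / stage
    d.mkdir(parents=True, exist_ok=True)
    return d


def _write_stage_manifest(config: RunConfig, stage: str, inputs: list[str], outputs: list[str]) -> None:
    io.write_manifest(
        Path(config.outdir) / stage / "manifest.json",
        {
            "stage": stage,
            "version": __version__,
            "seed": config.seed,
            "config": config.to_dict(),
            "config_digest": _config_digest(config),
            "inputs": {p: io.sha256_file(p) for p in inputs},
            "outputs": {p: io.sha256_file(p) for p in outputs},
        },
    )


def _stage_is_fresh(config: RunConfig, stage: str) -> bool:
    path = Path(config.outdir) / stage / "manifest.json"
    if not path.exists():
        return False
    try:
        manifest = io.read_manifest(path)
    except json.JSONDecodeError:
        return False
    if manifest.get("config_digest") != _config_digest(config):
        return False
    for group in ("inputs", "outputs"):
        for p, digest in manifest.get(group, {}).items():
            if not Path(p).exists() or io.sha256_file(p) != digest:
                return False
    return True


def stage_simulate(config: RunConfig) -> dict[str, str]:
    outdir = _stage_dir(config, "simulate")
    cohort = config.cohort
    bundle = make_genome(cohort)
    paths = io.bundle_to_files(bundle, outdir)
    reads = simulate_read_sets(bundle, cohort)
    for sample, df in reads.items():
        p = outdir / f"reads_{sample}.bed"
        io.write_reads_bed(df, p)
        paths[f"reads_{sample}"] = str(p)
    groups_path = outdir / "sample_groups.tsv"
    pd.DataFrame(cohort.sample_groups.items(), columns=["sample", "group"]).to_csv(
        groups_path, sep="\t", index=False
    )
    paths["sample_groups"] = str(groups_path)
    _write_stage_manifest(config, "simulate", [], sorted(paths.values()))
    return paths


def _load_bundle(config: RunConfig):
    sim = Path(config.outdir) / "simulate"
    category_beds = {
        p.stem: str(p)
        for p in sorted(sim.glob("*.bed"))
        if not p.name.startswith("reads_") and p.stem not in ("purely_intronic", "unannotated_intergenic")
    }
    return io.bundle_from_files(sim / "genome.chrom.sizes", sim / "genes.gtf", category_beds)


def stage_annotate(config: RunConfig) -> dict[str, str]:
    outdir = _stage_dir(config, "annotate")
    bundle = attach_derived_tracks(_load_bundle(config))
    bundle.validate()
    paths = {}
    for category in ("purely_intronic", "unannotated_intergenic"):
        p = outdir / f"{category}.bed"
        io.write_bed(io.features_to_bed(bundle.track(category)), p)
        paths[category] = str(p)
    sim = Path(config.outdir) / "simulate"
    inputs = [str(sim / "genome.chrom.sizes"), str(sim / "genes.gtf")]
    _write_stage_manifest(config, "annotate", inputs, sorted(paths.values()))
    return paths


def _load_annotated_bundle(config: RunConfig):
    bundle = _load_bundle(config)
    ann = Path(config.outdir) / "annotate"
    bundle.add_track("purely_intronic", io.read_feature_bed(ann / "purely_intronic.bed", "purely_intronic"))
    bundle.add_track(
        "unannotated_intergenic",
        io.read_feature_bed(ann / "unannotated_intergenic.bed", "unannotated_intergenic"),
    )
    return bundle


def _read_paths(config: RunConfig) -> dict[str, Path]:
    sim = Path(config.outdir) / "simulate"
    return {p.stem.removeprefix("reads_"): p for p in sorted(sim.glob("reads_*.bed"))}


def stage_quantify(config: RunConfig) -> dict[str, str]:
    outdir = _stage_dir(config, "quantify")
    bundle = _load_annotated_bundle(config)
    read_files = _read_paths(config)
    if not read_files:
        raise StageError("quantify", "no reads_*.bed files found under simulate/")
    reads = {s: io.read_reads_bed(p) for s, p in read_files.items()}
    rpkm, breakdown, feature_category = quantify_samples(
        reads, bundle, categories=("protein_coding", "pseudogene"), min_len=config.min_read_len
    )
    matrix = ExpressionMatrix(values=rpkm, reference_id=config.reference_id, threshold=config.threshold)
    try:
        matrix = normalize_and_call(matrix)
    except ValueError as exc:
        raise StageError("quantify", str(exc)) from exc
    gene_ids = [f for f, c in feature_category.items() if c == "protein_coding"]
    share = sharing_table(matrix.calls.loc[matrix.calls.index.isin(gene_ids)])
    paths = {}
    for name, df, index in (
        ("category_breakdown", breakdown, False),
        ("rpkm", rpkm, True),
        ("normalized", matrix.normalized, True),
        ("calls", matrix.calls, True),
        ("sharing_table", share.to_frame(), True),
        (
            "feature_categories",
            pd.DataFrame(feature_category.items(), columns=["feature_id", "category"]),
            False,
        ),
    ):
        p = outdir / f"{name}.tsv"
        df.to_csv(p, sep="\t", index=index)
        paths[name] = str(p)
    _write_stage_manifest(config, "quantify", [str(p) for p in read_files.values()], sorted(paths.values()))
    return paths


def stage_enrich(config: RunConfig) -> dict[str, str]:
    outdir = _stage_dir(config, "enrich")
    bundle = _load_annotated_bundle(config)
    read_files = _read_paths(config)
    seeds = np.random.SeedSequence(config.seed + 17).spawn(len(read_files))
    tables = []
    for (sample, path), ss in zip(read_files.items(), seeds):
        reads = io.read_reads_bed(path)
        tab = enrichment_table(
            reads,
            bundle,
            [c for c in config.enrich_categories if bundle.track(c)],
            n_shuffles=config.n_shuffles,
            seed=ss,
            fold_cutoff=config.fold_cutoff,
            p_cutoff=config.p_cutoff,
        ).reset_index()
        tab.insert(0, "sample", sample)
        tables.append(tab)
        if not config.enrich_per_sample:
            break
    long = pd.concat(tables, ignore_index=True)
    mean = (
        long.groupby("category")
        .agg(mean_log2_fold=("log2_fold", "mean"), n_significant=("significant", "sum"))
        .sort_index()
    )
    paths = {}
    for name, df, index in (("enrichment", long, False), ("enrichment_mean", mean, True)):
        p = outdir / f"{name}.tsv"
        df.to_csv(p, sep="\t", index=index)
        paths[name] = str(p)
    _write_stage_manifest(config, "enrich", [str(p) for p in read_files.values()], sorted(paths.values()))
    return paths


def _load_expression(config: RunConfig) -> tuple[ExpressionMatrix, dict[str, str]]:
    q = Path(config.outdir) / "quantify"
    values = io.read_matrix_tsv(q / "rpkm.tsv")
    matrix = normalize_and_call(
        ExpressionMatrix(values=values, reference_id=config.reference_id, threshold=config.threshold)
    )
    fc = pd.read_csv(q / "feature_categories.tsv", sep="\t", index_col=0)["category"].to_dict()
    return matrix, fc


def stage_correlate(config: RunConfig) -> dict[str, str]:
    outdir = _stage_dir(config, "correlate")
    matrix, feature_category = _load_expression(config)
    groups = pd.read_csv(Path(config.outdir) / "simulate" / "sample_groups.tsv", sep="\t", index_col=0)[
        "group"
    ].to_dict()
    gene_ids = [f for f, c in feature_category.items() if c == "protein_coding"]
    psg_ids = [f for f, c in feature_category.items() if c == "pseudogene"]
    mrna = pairwise_pearson(matrix, gene_ids, shared_only=True, restriction="mRNA_shared")
    psg = pairwise_pearson(matrix, psg_ids, shared_only=True, restriction="pseudogene_shared")
    contrast = group_contrast(psg, groups, n_perm=10_000, seed=config.seed + 29)
    array = simulate_microarray(matrix, seed=config.seed + 31)
    xplat = cross_platform_spearman(matrix, array)
    paths = {}
    outputs = (
        ("pearson_mrna", mrna.values, True),
        ("pearson_pseudogene", psg.values, True),
        ("microarray_values", array.values, True),
        ("cross_platform_spearman", xplat.to_frame(), True),
        (
            "group_contrast",
            pd.DataFrame(
                [
                    {
                        "restriction": "pseudogene_shared",
                        "mean_within": contrast.mean_within,
                        "mean_between": contrast.mean_between,
                        "contrast": contrast.contrast,
                        "p_perm": contrast.p_perm,
                        "n_perm": contrast.n_perm,
                    }
                ]
            ),
            False,
        ),
    )
    for name, df, index in outputs:
        p = outdir / f"{name}.tsv"
        df.to_csv(p, sep="\t", index=index)
        paths[name] = str(p)
    q = Path(config.outdir) / "quantify"
    _write_stage_manifest(config, "correlate", [str(q / "rpkm.tsv")], sorted(paths.values()))
    return paths


def stage_compare_proteome(config: RunConfig) -> dict[str, str]:
    outdir = _stage_dir(config, "compare_proteome")
    matrix, feature_category = _load_expression(config)
    gene_ids = [f for f, c in feature_category.items() if c == "protein_coding"]
    calls = matrix.calls.loc[matrix.calls.index.isin(gene_ids)]
    n_samples = calls.shape[1]
    n_expressed = calls.sum(axis=1)
    pconf = config.proteome.scaled_to(
        int((n_expressed == n_samples).sum()), int(((n_expressed >= 1) & (n_expressed < n_samples)).sum())
    )
    gene_matrix = ExpressionMatrix(
        values=matrix.values.loc[calls.index],
        reference_id=config.reference_id,
        threshold=config.threshold,
        normalized=matrix.normalized.loc[calls.index],
        calls=calls,
    )
    try:
        raw_proteome, mapping = simulate_proteome(gene_matrix, pconf)
    except ValueError as exc:
        raise StageError("compare_proteome", str(exc)) from exc
    proteome = filter_proteome(raw_proteome)
    concordance = build_concordance(
        calls, proteome, mapping, gene_matrix.normalized.mean(axis=1), overlap="all"
    )
    sizes = {label: len(ids) for label, ids in concordance.groups.items()}
    summary = pd.DataFrame(
        [
            {
                "n_pairs": len(concordance.pairs),
                "spearman_rho": concordance.spearman_r,
                "spearman_p": concordance.spearman_p,
                **{f"n_{k}": v for k, v in sizes.items()},
                **partition_percentages(sizes),
            }
        ]
    )
    membership = pd.DataFrame(
        [(label, i) for label in sorted(concordance.groups) for i in sorted(concordance.groups[label])],
        columns=["group", "id"],
    )
    paths = {}
    for name, df in (
        ("proteome_filtered", proteome),
        ("id_mapping", mapping),
        ("concordance_pairs", concordance.pairs),
        ("group_membership", membership),
        ("concordance_summary", summary),
    ):
        p = outdir / f"{name}.tsv"
        df.to_csv(p, sep="\t", index=False)
        paths[name] = str(p)
    q = Path(config.outdir) / "quantify"
    _write_stage_manifest(config, "compare_proteome", [str(q / "rpkm.tsv")], sorted(paths.values()))
    return paths


_STAGE_FUNCS = {
    "simulate": stage_simulate,
    "annotate": stage_annotate,
    "quantify": stage_quantify,
    "enrich": stage_enrich,
    "correlate": stage_correlate,
    "compare_proteome": stage_compare_proteome,
}


def run_all(config: RunConfig, resume: bool = False) -> dict:
    """Execute every stage in order; returns the run manifest payload."""
    logging.basicConfig(
        level=getattr(logging, config.log_level.upper(), logging.INFO),
        format="%(asctime)s %(name)s %(levelname)s %(message)s",
    )
    Path(config.outdir).mkdir(parents=True, exist_ok=True)
    all_paths: dict[str, dict[str, str]] = {}
    for stage in STAGES:
        if resume and _stage_is_fresh(config, stage):
            logger.info("stage %s: outputs up to date, skipping", stage)
            manifest = io.read_manifest(Path(config.outdir) / stage / "manifest.json")
            all_paths[stage] = {Path(p).stem: p for p in manifest["outputs"]}
            continue
        logger.info("stage %s: running", stage)
        try:
            all_paths[stage] = _STAGE_FUNCS[stage](config)
        except StageError:
            raise
        except Exception as exc:  # surface the failing stage
            raise StageError(stage, str(exc)) from exc
    payload = {
        "version": __version__,
        "seed": config.seed,
        "config": config.to_dict(),
        "config_digest": _config_digest(config),
        "stages": all_paths,
    }
    io.write_manifest(Path(config.outdir) / "run_manifest.json", payload)
    return payload
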