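"""Synthetic cohorts with the statistical structure the analysis assumes.

The generator emulates, at desk scale, the structure of a 10-donor platelet
total-RNA sequencing study:

* a toy genome with multi-exon genes (one designated beta-actin), a
  pseudogene track, repeat/ncRNA tracks and guaranteed unannotated gaps;
* per-donor read sets whose category mix targets ~43% exonic, ~36.6% rRNA,
  ~14% unannotated intergenic and ~6% other loci;
* a shared log-normal mRNA abundance profile with small per-donor noise,
  so inter-individual Pearson correlations are high;
* group-specific pseudogene profiles (two donor groups, W and B), highly
  correlated within a group and uncorrelated between groups by default;
* a quantitative proteome whose abundances follow a Gaussian copula
  against transcript abundances, so the planted Spearman correlation is
  analytically (6/pi) * asin(rho/2).

Everything is deterministic under the configured seed; read length is
fixed at 50 nt.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .annotation import AnnotationBundle, FeatureRecord, GenomicInterval, attach_derived_tracks
from .quantify import DEFAULT_REFERENCE_ID, DEFAULT_THRESHOLD, ExpressionMatrix, normalize_and_call

DEFAULT_GROUPS = ("W", "W", "W", "W", "W", "B", "B", "B", "B", "B")

#: Gaussian-copula correlation planting a Spearman concordance of 0.311
#: (rho_S = (6/pi) * asin(rho_G / 2), inverted at 0.311).
DEFAULT_COPULA_RHO = float(2.0 * np.sin(0.311 * np.pi / 6.0))

#: Read fractions by category; "other" is split by ``other_mix``.
DEFAULT_CATEGORY_MIX = {
    "protein_coding_exon": 0.43,
    "rRNA": 0.366,
    "unannotated_intergenic": 0.14,
    "other": 0.06,
}

DEFAULT_OTHER_MIX = {
    "pseudogene": 0.35,
    "lncRNA": 0.10,
    "SINE": 0.15,
    "purely_intronic": 0.15,
    "tRNA": 0.05,
    "snRNA": 0.05,
    "srpRNA": 0.05,
    "scRNA": 0.05,
    "RNA": 0.05,
}

DEFAULT_REPEAT_COUNTS = {
    "rRNA": 12,
    "SINE": 40,
    "lncRNA": 20,
    "tRNA": 15,
    "snRNA": 10,
    "srpRNA": 8,
    "scRNA": 8,
    "RNA": 10,
}


@dataclass
class CohortConfig:
    """Study conditions for the synthetic cohort."""

    n_individuals: int = 10
    groups: tuple[str, ...] = DEFAULT_GROUPS
    n_genes: int = 300
    n_pseudogenes: int = 120
    n_repeat_features: dict[str, int] = field(default_factory=lambda: dict(DEFAULT_REPEAT_COUNTS))
    category_mix: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_CATEGORY_MIX))
    other_mix: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_OTHER_MIX))
    abundance_mu: float = 0.0
    abundance_sigma: float = 2.0  # natural-log scale
    individual_noise_sd: float = 0.25  # natural-log scale
    pseudogene_group_divergence: float = 0.0  # correlation between group profiles
    reads_per_sample: int = 50_000
    read_length: int = 50
    n_chromosomes: int = 4
    chromosome_length: int | None = None  # None = auto-size to fit
    reference_id: str = DEFAULT_REFERENCE_ID
    seed: int = 0

    def __post_init__(self):
        if self.n_individuals != len(self.groups):
            raise ValueError("groups must have one label per individual")
        if min(self.n_genes, self.n_pseudogenes, self.reads_per_sample) <= 0:
            raise ValueError("counts must be positive")
        if sum(self.category_mix.values()) > 1 + 1e-9:
            raise ValueError("category_mix sums to > 1")
        if not -1 < self.pseudogene_group_divergence < 1 + 1e-12:
            raise ValueError("pseudogene_group_divergence must be in (-1, 1]")

    @property
    def sample_ids(self) -> list[str]:
        counters: dict[str, int] = {}
        out = []
        for g in self.groups:
            counters[g] = counters.get(g, 0) + 1
            out.append(f"{g}{counters[g]}")
        return out

    @property
    def sample_groups(self) -> dict[str, str]:
        return dict(zip(self.sample_ids, self.groups))

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class ProteomeSimConfig:
    """Target sizes for the five transcriptome/proteome groups.

    Defaults are the headline set sizes of the 10-donor study: 2,338
    overlapping pairs, 432 protein-only entries, 3,226 mRNAs shared by all
    donors without a protein, plus the 1-to-9-donor groups (3,634 without
    and 774 with a protein). The default ``copula_rho`` ~ 0.3242 plants a
    Spearman concordance of (6/pi)*asin(rho/2) = 0.311 for the overlapping
    pairs, matching the weak transcriptome-proteome link the analysis is
    designed to expose.
    """

    n_overlap_pairs: int = 2338
    n_protein_only: int = 432
    n_mrna_only_all: int = 3226
    n_mrna_only_partial: int = 3634
    n_overlap_partial: int = 774
    copula_rho: float = DEFAULT_COPULA_RHO
    seed: int = 0

    def __post_init__(self):
        if min(
            self.n_overlap_pairs,
            self.n_protein_only,
            self.n_mrna_only_all,
            self.n_mrna_only_partial,
            self.n_overlap_partial,
        ) < 0:
            raise ValueError("group sizes must be >= 0")
        if not -1 < self.copula_rho < 1:
            raise ValueError("copula_rho must be in (-1, 1)")

    def planted_spearman(self) -> float:
        return float(6.0 / np.pi * np.arcsin(self.copula_rho / 2.0))

    def scaled_to(self, n_all_samples: int, n_partial: int) -> "ProteomeSimConfig":
        """Proportionally shrink the group sizes to fit a smaller cohort."""
        f_all = min(1.0, n_all_samples / max(1, self.n_overlap_pairs + self.n_mrna_only_all))
        f_part = min(1.0, n_partial / max(1, self.n_overlap_partial + self.n_mrna_only_partial))
        f = min(f_all, f_part)
        return ProteomeSimConfig(
            n_overlap_pairs=max(3, int(self.n_overlap_pairs * f)),
            n_protein_only=max(1, int(self.n_protein_only * f)),
            n_mrna_only_all=max(1, int(self.n_mrna_only_all * f)),
            n_mrna_only_partial=max(1, int(self.n_mrna_only_partial * f)),
            n_overlap_partial=max(1, int(self.n_overlap_partial * f)),
            copula_rho=self.copula_rho,
            seed=self.seed,
        )

    def to_dict(self) -> dict:
        return asdict(self)


def _rngs(seed, n: int) -> list[np.random.Generator]:
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def make_genome(config: CohortConfig) -> AnnotationBundle:
    """Build a non-pathological toy genome with derived tracks attached.

    Features are laid out sequentially (round-robin across chromosomes)
    with random gaps of 300-1,500 nt, so no two features overlap and every
    chromosome keeps unannotated space. Exons are 150-400 nt, introns
    200-800 nt; all features are longer than the read length.
    """
    rng = _rngs(config.seed, 8)[0]
    plan: list[tuple[str, str, object]] = []
    for i in range(config.n_genes):
        gene_id = config.reference_id if i == 0 else f"GENE{i:05d}"
        if i == 0:
            exon_lens = [400, 400, 400]  # designated beta-actin: 1.2 kb mRNA
        else:
            n_exons = int(rng.integers(2, 6))
            exon_lens = [int(rng.integers(150, 401)) for _ in range(n_exons)]
        intron_lens = [int(rng.integers(200, 801)) for _ in range(len(exon_lens) - 1)]
        strand = "+" if rng.random() < 0.5 else "-"
        plan.append(("gene", gene_id, (exon_lens, intron_lens, strand)))
    for i in range(config.n_pseudogenes):
        plan.append(("pseudogene", f"PSG{i:05d}", int(rng.integers(300, 1001))))
    for category, count in config.n_repeat_features.items():
        lo, hi = (500, 2001) if category == "rRNA" else (80, 301)
        for i in range(count):
            plan.append((category, f"{category}_{i:04d}", int(rng.integers(lo, hi))))

    order = rng.permutation(len(plan))
    cursors = [0] * config.n_chromosomes
    chrom_names = [f"chr{i + 1}" for i in range(config.n_chromosomes)]
    bundle = AnnotationBundle(genome={c: 0 for c in chrom_names})
    gene_spans: list[FeatureRecord] = []
    exons: list[FeatureRecord] = []
    others: dict[str, list[FeatureRecord]] = {}
    for k, idx in enumerate(order):
        kind, fid, payload = plan[idx]
        ci = k % config.n_chromosomes
        chrom = chrom_names[ci]
        gap = int(rng.integers(300, 1501))
        start = cursors[ci] + gap
        if kind == "gene":
            exon_lens, intron_lens, strand = payload
            pos = start
            for j, el in enumerate(exon_lens):
                exons.append(
                    FeatureRecord(
                        GenomicInterval(chrom, pos, pos + el, strand),
                        "protein_coding_exon",
                        f"{fid}:exon{j}",
                        fid,
                    )
                )
                pos += el
                if j < len(intron_lens):
                    pos += intron_lens[j]
            gene_spans.append(
                FeatureRecord(GenomicInterval(chrom, start, pos, strand), "protein_coding_gene_span", fid, fid)
            )
            end = pos
        else:
            length = payload
            strand = "+" if rng.random() < 0.5 else "-"
            end = start + length
            category = kind
            others.setdefault(category, []).append(
                FeatureRecord(GenomicInterval(chrom, start, end, strand), category, fid)
            )
        cursors[ci] = end
    for ci, chrom in enumerate(chrom_names):
        bundle.genome[chrom] = cursors[ci] + 1000
    if config.chromosome_length is not None:
        if max(cursors) + 1 > config.chromosome_length:
            raise ValueError(
                f"cannot pack features into chromosomes of length {config.chromosome_length}"
            )
        bundle.genome = {c: config.chromosome_length for c in chrom_names}
    bundle.add_track("protein_coding_gene_span", gene_spans)
    bundle.add_track("protein_coding_exon", exons)
    for category, records in others.items():
        bundle.add_track(category, records)
    attach_derived_tracks(bundle)
    bundle.validate()
    return bundle


def _category_probs(config: CohortConfig) -> dict[str, float]:
    probs = {k: v for k, v in config.category_mix.items() if k != "other"}
    other = config.category_mix.get("other", 0.0)
    o_tot = sum(config.other_mix.values())
    for cat, w in config.other_mix.items():
        probs[cat] = probs.get(cat, 0.0) + other * w / o_tot
    total = sum(probs.values())
    return {k: v / total for k, v in probs.items()}


def _placement_units(bundle: AnnotationBundle, category: str, read_length: int):
    """(chrom, start, len, feature_index, strand) units a read can fall in."""
    units = []
    if category == "protein_coding_exon":
        feats: dict[str, int] = {}
        for rec in bundle.track("protein_coding_exon"):
            gid = rec.gene_id
            fi = feats.setdefault(gid, len(feats))
            room = rec.interval.length - read_length + 1
            if room > 0:
                units.append((rec.interval.chrom, rec.interval.start, room, fi, rec.interval.strand))
        ids = list(feats)
    else:
        ids = []
        for rec in bundle.track(category):
            room = rec.interval.length - read_length + 1
            if room > 0:
                units.append((rec.interval.chrom, rec.interval.start, room, len(ids), rec.interval.strand))
                ids.append(rec.feature_id)
    return units, ids


class _CategorySampler:
    """Draws read positions for one category given per-feature weights."""

    def __init__(self, bundle: AnnotationBundle, category: str, read_length: int):
        self.read_length = read_length
        units, self.feature_ids = _placement_units(bundle, category, read_length)
        if not units:
            raise ValueError(f"category {category} has no feature able to hold a {read_length} nt read")
        self.chroms = np.array([u[0] for u in units])
        self.starts = np.array([u[1] for u in units], dtype=np.int64)
        self.rooms = np.array([u[2] for u in units], dtype=np.int64)
        self.feat_idx = np.array([u[3] for u in units], dtype=np.int64)
        self.strands = np.array([u[4] for u in units])
        self.n_features = len(self.feature_ids)

    def draw(self, n_reads: int, feature_weights: np.ndarray | None, rng: np.random.Generator):
        """Return (chrom, start, end, strand) arrays for n_reads reads."""
        if feature_weights is None:
            feature_weights = np.ones(self.n_features)
        feat_tot = np.zeros(self.n_features)
        np.add.at(feat_tot, self.feat_idx, self.rooms.astype(float))
        unit_probs = feature_weights[self.feat_idx] * self.rooms / feat_tot[self.feat_idx]
        unit_probs = unit_probs / unit_probs.sum()
        counts = rng.multinomial(n_reads, unit_probs)
        unit_of_read = np.repeat(np.arange(len(counts)), counts)
        offsets = (rng.random(n_reads) * self.rooms[unit_of_read]).astype(np.int64)
        starts = self.starts[unit_of_read] + offsets
        return (
            self.chroms[unit_of_read],
            starts,
            starts + self.read_length,
            self.strands[unit_of_read],
        )


def _group_profiles(rng, n: int, mu: float, sigma: float, divergence: float, groups):
    """One log-abundance profile per group with the requested correlation."""
    d = max(divergence, 0.0)
    common = rng.standard_normal(n)
    profiles = {}
    for g in sorted(set(groups)):
        own = rng.standard_normal(n)
        profiles[g] = mu + sigma * (np.sqrt(d) * common + np.sqrt(1 - d) * own)
    return profiles


def simulate_read_sets(bundle: AnnotationBundle, config: CohortConfig) -> dict[str, pd.DataFrame]:
    """Per-individual mapped-read tables (chrom/start/end/read_id/strand).

    Reads are drawn category-by-category following the configured mix;
    within mRNA (and within each expressed ncRNA category) reads follow
    exp(shared log-profile + individual noise), pseudogene reads follow the
    donor-group profile, and reads inside the derived intronic/intergenic
    tracks are uniform. Positions are uniform within the chosen feature and
    every read is ``read_length`` nt.
    """
    if config.reads_per_sample <= 0:
        raise ValueError("reads_per_sample must be > 0")
    rng_profile, rng_reads = _rngs(config.seed, 8)[1:3]
    probs = _category_probs(config)
    categories = sorted(probs)
    samplers = {c: _CategorySampler(bundle, c, config.read_length) for c in categories}

    shared_profiles: dict[str, np.ndarray] = {}
    for cat in categories:
        if cat in ("purely_intronic", "unannotated_intergenic", "pseudogene"):
            continue
        n = samplers[cat].n_features
        prof = rng_profile.normal(config.abundance_mu, config.abundance_sigma, n)
        if cat == "protein_coding_exon":
            ref_pos = samplers[cat].feature_ids.index(config.reference_id)
            prof[ref_pos] = config.abundance_mu + 2.0 * config.abundance_sigma
        shared_profiles[cat] = prof
    group_profiles = _group_profiles(
        rng_profile,
        samplers["pseudogene"].n_features,
        config.abundance_mu,
        config.abundance_sigma,
        config.pseudogene_group_divergence,
        config.groups,
    )

    p_vec = np.array([probs[c] for c in categories])
    out: dict[str, pd.DataFrame] = {}
    for sample, group in zip(config.sample_ids, config.groups):
        cat_counts = rng_reads.multinomial(config.reads_per_sample, p_vec)
        chroms, starts, ends, strands = [], [], [], []
        for cat, n_cat in zip(categories, cat_counts):
            if n_cat == 0:
                continue
            if cat in ("purely_intronic", "unannotated_intergenic"):
                weights = None
            elif cat == "pseudogene":
                noise = rng_reads.normal(0.0, config.individual_noise_sd, samplers[cat].n_features)
                weights = np.exp(group_profiles[group] + noise)
            else:
                noise = rng_reads.normal(0.0, config.individual_noise_sd, samplers[cat].n_features)
                weights = np.exp(shared_profiles[cat] + noise)
            c, s, e, st = samplers[cat].draw(int(n_cat), weights, rng_reads)
            chroms.append(c)
            starts.append(s)
            ends.append(e)
            strands.append(st)
        df = pd.DataFrame(
            {
                "chrom": np.concatenate(chroms),
                "start": np.concatenate(starts),
                "end": np.concatenate(ends),
                "strand": np.concatenate(strands),
            }
        ).sort_values(["chrom", "start", "end"], kind="stable").reset_index(drop=True)
        df.insert(3, "read_id", [f"{sample}_r{i:06d}" for i in range(len(df))])
        out[sample] = df
    return out


def simulate_microarray(
    expression: ExpressionMatrix,
    seed=None,
    probe_fraction: float = 0.9,
    noise_sd: float = 0.5,
) -> ExpressionMatrix:
    """Microarray-style re-measurement of the same samples.

    A random subset of genes is "probed"; per sample, the array value is
    the log2 abundance plus Gaussian measurement noise (RMA-normalized
    arrays are on a log2 scale). Monotone in true abundance up to noise, so
    cross-platform rank correlations are high but imperfect.
    """
    rng = np.random.default_rng(seed)
    genes = expression.values.index
    n_probed = max(3, int(round(probe_fraction * len(genes))))
    probed = pd.Index(sorted(rng.choice(genes, size=n_probed, replace=False)))
    base = np.log2(expression.values.loc[probed].to_numpy(dtype=float) + 1e-6)
    noisy = base + rng.normal(0.0, noise_sd, base.shape)
    values = pd.DataFrame(noisy, index=probed, columns=expression.values.columns)
    values.index.name = "feature_id"
    return ExpressionMatrix(values=values, reference_id=expression.reference_id, threshold=expression.threshold)


def _copula_abundances(transcript: np.ndarray, rho: float, rng) -> np.ndarray:
    """Protein abundances with a planted Gaussian copula against transcripts."""
    n = transcript.size
    ranks = stats.rankdata(transcript, method="average")
    z_t = stats.norm.ppf(ranks / (n + 1))
    z_p = rho * z_t + np.sqrt(1 - rho**2) * rng.standard_normal(n)
    return np.exp(z_p)


def simulate_proteome(
    expression: ExpressionMatrix, config: ProteomeSimConfig
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Proteome table + gene->protein mapping with planted group structure.

    Overlapping proteins get copula-correlated abundances against the
    gene's mean normalized transcript abundance; protein-only entries are
    independent log-normals with no mapping row. All confidences are 99 or
    100 (the filtered regime). Raises when the expression matrix cannot
    supply the requested group sizes.
    """
    if expression.calls is None or expression.normalized is None:
        raise ValueError("expression matrix must be normalized and called first")
    rng = np.random.default_rng(config.seed)
    n_samples = expression.calls.shape[1]
    n_expressed = expression.calls.sum(axis=1)
    all_genes = n_expressed.index[n_expressed == n_samples]
    partial_genes = n_expressed.index[(n_expressed >= 1) & (n_expressed < n_samples)]
    need_all = config.n_overlap_pairs + config.n_mrna_only_all
    need_partial = config.n_overlap_partial + config.n_mrna_only_partial
    if len(all_genes) < need_all or len(partial_genes) < need_partial:
        raise ValueError(
            f"insufficient genes: need {need_all} expressed in all samples "
            f"(have {len(all_genes)}) and {need_partial} in 1..n-1 (have {len(partial_genes)})"
        )
    pick_all = rng.choice(all_genes, size=need_all, replace=False)
    overlap_all = pick_all[: config.n_overlap_pairs]
    pick_partial = rng.choice(partial_genes, size=need_partial, replace=False)
    overlap_partial = pick_partial[: config.n_overlap_partial]

    mean_abund = expression.normalized.mean(axis=1)
    rows = []
    mapping_rows = []
    for i, genes in enumerate((overlap_all, overlap_partial)):
        if len(genes) == 0:
            continue
        abund = _copula_abundances(mean_abund.loc[genes].to_numpy(dtype=float), config.copula_rho, rng)
        for j, (gene, a) in enumerate(zip(genes, abund)):
            pid = f"P{i}{j:05d}"
            conf = 99.0 if rng.random() < 0.5 else 100.0
            rows.append((pid, float(a), conf))
            mapping_rows.append((gene, pid))
    for j in range(config.n_protein_only):
        pid = f"PX{j:05d}"
        conf = 99.0 if rng.random() < 0.5 else 100.0
        rows.append((pid, float(np.exp(rng.standard_normal())), conf))
    proteome = pd.DataFrame(rows, columns=["protein_id", "abundance", "confidence"])
    mapping = pd.DataFrame(mapping_rows, columns=["gene_id", "protein_id"])
    return proteome, mapping


def simulate_reference_scale_expression(
    config: ProteomeSimConfig, n_samples: int = 10, seed=None
) -> ExpressionMatrix:
    """Abundance-and-calls matrix matching the configured group sizes.

    Used to exercise the partition/concordance stage at the full printed
    scale without simulating reads: genes destined for the "all samples"
    groups are expressed everywhere, partial genes in a uniform 1..n-1
    subset of samples. Abundances are log-uniform over ~4.5 decades above
    the expression threshold; unexpressed cells are 0. The reference gene
    row is fixed at 1 so normalized == values.
    """
    rng = np.random.default_rng(seed if seed is not None else config.seed)
    n_all = config.n_overlap_pairs + config.n_mrna_only_all
    n_partial = config.n_overlap_partial + config.n_mrna_only_partial
    genes = [f"G{i:06d}" for i in range(n_all + n_partial)]
    abund = 10.0 ** rng.uniform(np.log10(DEFAULT_THRESHOLD) + 0.5, 1.0, n_all + n_partial)
    samples = [f"S{i + 1}" for i in range(n_samples)]
    values = np.tile(abund[:, None], (1, n_samples))
    for i in range(n_all, n_all + n_partial):
        k = int(rng.integers(1, n_samples))
        off = rng.choice(n_samples, size=n_samples - k, replace=False)
        values[i, off] = 0.0
    df = pd.DataFrame(values, index=pd.Index(genes, name="feature_id"), columns=samples)
    df.loc[DEFAULT_REFERENCE_ID] = 1.0
    matrix = ExpressionMatrix(values=df, reference_id=DEFAULT_REFERENCE_ID, threshold=DEFAULT_THRESHOLD)
    return normalize_and_call(matrix)
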