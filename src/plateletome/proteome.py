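"""Transcriptome-proteome concordance.

The quantitative platelet proteome is filtered (confidence >= 99%,
duplicates collapsed to the most abundant entry), joined to the
transcriptome through a gene-to-protein id mapping (many genes mapping to
one protein keep the most abundant gene), and partitioned into five
mutually exclusive groups by presence in the proteome and in how many of
the n RNA-seq profiles the transcript is called expressed:

* ``both_all10``             - protein present, mRNA expressed in all n samples
* ``mrna_all10_no_protein``  - mRNA in all n samples, no protein
* ``protein_no_mrna``        - protein present, mRNA in no sample
* ``mrna_1to9_no_protein``   - mRNA in 1..n-1 samples, no protein
* ``protein_and_mrna_1to9``  - protein present, mRNA in 1..n-1 samples

Group labels keep the "10" of the 10-donor cohort the analysis was designed
around but apply to any sample count. Abundance concordance over the
overlapping pairs is the Spearman rank correlation with midrank ties.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

MIN_CONFIDENCE = 99.0

GROUP_LABELS = (
    "both_all10",
    "mrna_all10_no_protein",
    "protein_no_mrna",
    "mrna_1to9_no_protein",
    "protein_and_mrna_1to9",
)


@dataclass(frozen=True)
class ProteomeEntry:
    protein_id: str
    abundance: float
    confidence: float

    def __post_init__(self):
        if not 0 <= self.confidence <= 100:
            raise ValueError(f"{self.protein_id}: confidence {self.confidence} outside [0, 100]")


@dataclass
class ConcordanceSet:
    """Joined transcript/protein abundances plus the five-group partition."""

    pairs: pd.DataFrame  # columns: gene_id, protein_id, transcript_abundance, protein_abundance
    groups: dict[str, set[str]]
    spearman_r: float
    spearman_p: float


def _proteome_frame(entries) -> pd.DataFrame:
    if isinstance(entries, pd.DataFrame):
        df = entries.copy()
    else:
        df = pd.DataFrame(
            [(e.protein_id, e.abundance, e.confidence) for e in entries],
            columns=["protein_id", "abundance", "confidence"],
        )
    return df


def filter_proteome(entries) -> pd.DataFrame:
    """Keep confidence >= 99% entries; collapse duplicate ids to max abundance.

    Idempotent: filtering an already-filtered table returns it unchanged.
    """
    df = _proteome_frame(entries)
    if df.empty:
        return df.reindex(columns=["protein_id", "abundance", "confidence"])
    if (df["abundance"] < 0).any():
        bad = df.loc[df["abundance"] < 0, "protein_id"].head(3).tolist()
        raise ValueError(f"negative abundance for {bad}")
    df = df[df["confidence"] >= MIN_CONFIDENCE]
    # stable sort so equal-abundance duplicates keep the first occurrence
    df = df.sort_values("abundance", ascending=False, kind="stable")
    df = df.drop_duplicates("protein_id", keep="first")
    return df.sort_values("protein_id", kind="stable").reset_index(drop=True)


def collapse_ids(mapping: pd.DataFrame, abundances: pd.Series) -> pd.DataFrame:
    """One gene per protein id: the gene with maximal transcript abundance.

    ``mapping`` has columns gene_id/protein_id and may be many-to-one;
    ``abundances`` maps gene_id -> transcript abundance. Ties are broken by
    the lexicographically smallest gene id. Genes absent from
    ``abundances`` are treated as abundance 0.
    """
    df = mapping[["gene_id", "protein_id"]].copy()
    df["abundance"] = df["gene_id"].map(abundances).fillna(0.0)
    df = df.sort_values(["protein_id", "abundance", "gene_id"], ascending=[True, False, True], kind="stable")
    df = df.drop_duplicates("protein_id", keep="first")
    return df.set_index("protein_id")[["gene_id", "abundance"]]


def partition_groups(
    calls: pd.DataFrame,
    proteome: pd.DataFrame,
    mapping: pd.DataFrame,
    transcript_abundance: pd.Series | None = None,
) -> dict[str, set[str]]:
    """Partition ids into the five transcriptome/proteome groups.

    ``calls`` is the boolean gene x sample matrix; ``proteome`` the filtered
    proteome; ``mapping`` the gene->protein table. Groups containing a
    protein are keyed by protein id; transcript-only groups by gene id.
    Mapping rows naming unknown gene or protein ids are skipped with a
    warning. The three protein-side groups partition the filtered proteome.
    """
    n = calls.shape[1]
    n_expressed = calls.sum(axis=1)
    proteome_ids = set(proteome["protein_id"])
    known_mask = mapping["gene_id"].isin(calls.index)
    skipped = int((~known_mask).sum())
    if skipped:
        warnings.warn(f"partition_groups: skipped {skipped} mapping rows with unknown gene ids")
    mapping = mapping[known_mask]
    # collapse many-to-one gene->protein at the protein level
    if transcript_abundance is None:
        transcript_abundance = n_expressed.astype(float)
    mapped_in_proteome = mapping[mapping["protein_id"].isin(proteome_ids)]
    rep = collapse_ids(mapped_in_proteome, transcript_abundance) if len(mapped_in_proteome) else pd.DataFrame(columns=["gene_id", "abundance"])

    groups: dict[str, set[str]] = {label: set() for label in GROUP_LABELS}
    # protein side: every filtered proteome entry lands in exactly one group
    for protein_id in proteome["protein_id"]:
        if protein_id in rep.index:
            gene = rep.loc[protein_id, "gene_id"]
            k = int(n_expressed.get(gene, 0))
            if k == n:
                groups["both_all10"].add(protein_id)
            elif k >= 1:
                groups["protein_and_mrna_1to9"].add(protein_id)
            else:
                groups["protein_no_mrna"].add(protein_id)
        else:
            groups["protein_no_mrna"].add(protein_id)
    # transcript side: genes without a protein representation
    represented_genes = set(rep["gene_id"])
    for gene, k in n_expressed.items():
        if k == 0 or gene in represented_genes:
            continue
        if k == n:
            groups["mrna_all10_no_protein"].add(gene)
        else:
            groups["mrna_1to9_no_protein"].add(gene)
    return groups


def concordance_spearman(pairs: pd.DataFrame) -> tuple[float, float]:
    """Spearman rho (midrank ties) and large-sample p over abundance pairs."""
    if len(pairs) < 3:
        raise ValueError("concordance_spearman requires >= 3 pairs")
    x = pairs["transcript_abundance"].to_numpy(dtype=float)
    y = pairs["protein_abundance"].to_numpy(dtype=float)
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValueError("constant abundance vector; Spearman undefined")
    rho, p = stats.spearmanr(x, y)
    return float(rho), float(p)


def build_concordance(
    calls: pd.DataFrame,
    proteome: pd.DataFrame,
    mapping: pd.DataFrame,
    transcript_abundance: pd.Series,
    overlap: str = "all",
) -> ConcordanceSet:
    """Full join: filter is assumed done; partition and rank-correlate.

    ``overlap`` picks which overlapping pairs enter the Spearman: "all"
    (any expressed gene with a protein) or "all_samples" (only genes
    expressed in every sample, the intersection set).
    """
    groups = partition_groups(calls, proteome, mapping, transcript_abundance)
    proteome_idx = proteome.set_index("protein_id")["abundance"]
    rep = collapse_ids(
        mapping[mapping["protein_id"].isin(proteome_idx.index) & mapping["gene_id"].isin(calls.index)],
        transcript_abundance,
    )
    if overlap == "all_samples":
        keep_proteins = groups["both_all10"]
    elif overlap == "all":
        keep_proteins = groups["both_all10"] | groups["protein_and_mrna_1to9"]
    else:
        raise ValueError(f"unknown overlap mode {overlap!r}")
    rep = rep.loc[rep.index.isin(keep_proteins)]
    pairs = pd.DataFrame(
        {
            "gene_id": rep["gene_id"].to_numpy(),
            "protein_id": rep.index.to_numpy(),
            "transcript_abundance": rep["abundance"].to_numpy(),
            "protein_abundance": proteome_idx.reindex(rep.index).to_numpy(),
        }
    ).sort_values("protein_id", kind="stable").reset_index(drop=True)
    rho, p = concordance_spearman(pairs)
    return ConcordanceSet(pairs=pairs, groups=groups, spearman_r=rho, spearman_p=p)


def partition_percentages(sizes: Mapping[str, int]) -> dict[str, float]:
    """Derived counts and percentages from the five group sizes.

    All denominators are explicit in the key names; percentages are on the
    0-100 scale.
    """
    s = {label: int(sizes[label]) for label in GROUP_LABELS}
    n_proteome = s["both_all10"] + s["protein_no_mrna"] + s["protein_and_mrna_1to9"]
    n_mrna_union = (
        s["both_all10"] + s["mrna_all10_no_protein"] + s["mrna_1to9_no_protein"] + s["protein_and_mrna_1to9"]
    )
    n_mrna_all = s["both_all10"] + s["mrna_all10_no_protein"]
    out = {
        "n_proteome": float(n_proteome),
        "n_mrna_union": float(n_mrna_union),
        "n_mrna_all_samples": float(n_mrna_all),
        "pct_proteins_with_mrna_any": 100.0 * (n_proteome - s["protein_no_mrna"]) / n_proteome,
        "pct_proteins_without_mrna": 100.0 * s["protein_no_mrna"] / n_proteome,
        "pct_proteins_with_mrna_all_samples": 100.0 * s["both_all10"] / n_proteome,
        "pct_mrna_all10_without_protein_of_union": 100.0 * s["mrna_all10_no_protein"] / n_mrna_union,
        "pct_mrna_all10_without_protein_of_all10": 100.0 * s["mrna_all10_no_protein"] / n_mrna_all,
    }
    return out
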