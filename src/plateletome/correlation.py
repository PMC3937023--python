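"""Inter-individual correlation structure and the group-contrast statistic.

Pairwise Pearson correlations between individuals are computed on
log2(beta-actin-normalized abundance + pseudocount), optionally restricted
to the genes called expressed in *both* members of a pair ("shared").
Cross-platform agreement (RNA-seq vs microarray) is summarised per
individual by the Spearman rank correlation over the genes present on both
platforms. The within- vs between-group contrast formalises a categorical
split of the cohort (e.g. the two donor groups whose pseudogene profiles
diverge): contrast = mean(within-group r) - mean(between-group r), with a
label-permutation p-value (b+1)/(n+1) for permuted contrasts >= observed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .quantify import ExpressionMatrix

DEFAULT_PSEUDOCOUNT = 1e-6
MIN_GENES_PER_PAIR = 3


@dataclass
class CorrelationMatrix:
    """Symmetric sample x sample correlation matrix with metadata."""

    values: pd.DataFrame
    restriction: str = "all"
    log_transformed: bool = True
    pseudocount: float = DEFAULT_PSEUDOCOUNT
    groups: dict[str, str] = field(default_factory=dict)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.index)

    def mean_offdiagonal(self) -> float:
        m = self.values.to_numpy(dtype=float)
        mask = ~np.eye(m.shape[0], dtype=bool)
        return float(np.nanmean(m[mask]))


@dataclass
class GroupContrast:
    """Within- minus between-group mean correlation, with permutation p."""

    mean_within: float
    mean_between: float
    contrast: float
    p_perm: float
    n_perm: int


def pairwise_pearson(
    matrix: ExpressionMatrix,
    category_genes: Sequence[str] | None = None,
    shared_only: bool = True,
    log: bool = True,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    restriction: str = "",
) -> CorrelationMatrix:
    """Pairwise inter-individual Pearson correlations.

    For each sample pair the correlation is over ``category_genes``
    (default: all genes), restricted when ``shared_only`` to genes called
    expressed in both samples; pairs left with < 3 genes get NaN.
    """
    if matrix.normalized is None or matrix.calls is None:
        raise ValueError("expression matrix must be normalized and called first")
    if matrix.normalized.shape[1] < 2:
        raise ValueError("need >= 2 samples")
    data = matrix.normalized
    calls = matrix.calls
    if category_genes is not None:
        keep = data.index.intersection(pd.Index(category_genes))
        data = data.loc[keep]
        calls = calls.loc[keep]
    x = np.log2(data.to_numpy(dtype=float) + pseudocount) if log else data.to_numpy(dtype=float)
    c = calls.to_numpy(dtype=bool)
    samples = list(data.columns)
    n = len(samples)
    out = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            mask = (c[:, i] & c[:, j]) if shared_only else np.ones(x.shape[0], dtype=bool)
            if mask.sum() < MIN_GENES_PER_PAIR:
                out[i, j] = out[j, i] = np.nan
                continue
            xi, xj = x[mask, i], x[mask, j]
            if xi.std() == 0 or xj.std() == 0:
                out[i, j] = out[j, i] = np.nan
                continue
            out[i, j] = out[j, i] = float(np.corrcoef(xi, xj)[0, 1])
    return CorrelationMatrix(
        values=pd.DataFrame(out, index=samples, columns=samples),
        restriction=restriction or ("shared" if shared_only else "all"),
        log_transformed=log,
        pseudocount=pseudocount,
    )


def cross_platform_spearman(
    rnaseq: ExpressionMatrix, microarray: ExpressionMatrix
) -> pd.Series:
    """Per-sample Spearman rho between platforms over the common genes.

    Ties are handled by midranks (scipy default). Samples must carry the
    same identifiers on both platforms.
    """
    common_samples = [s for s in rnaseq.values.columns if s in microarray.values.columns]
    if not common_samples:
        raise ValueError("no common samples between platforms")
    common_genes = rnaseq.values.index.intersection(microarray.values.index)
    if len(common_genes) == 0:
        raise ValueError("no common genes between platforms")
    rho = {}
    for s in common_samples:
        r, _p = stats.spearmanr(
            rnaseq.values.loc[common_genes, s], microarray.values.loc[common_genes, s]
        )
        rho[s] = float(r)
    return pd.Series(rho, name="spearman_rho")


def _contrast_stat(m: np.ndarray, labels: np.ndarray) -> tuple[float, float, float]:
    same = labels[:, None] == labels[None, :]
    offdiag = ~np.eye(m.shape[0], dtype=bool)
    within = float(np.nanmean(m[same & offdiag]))
    between = float(np.nanmean(m[~same]))
    return within, between, within - between


def group_contrast(
    corr: CorrelationMatrix | pd.DataFrame,
    labels: Mapping[str, str],
    n_perm: int = 10_000,
    seed=None,
) -> GroupContrast:
    """Permutation test of within- vs between-group mean correlation.

    Requires exactly two groups with >= 2 samples each. The p-value counts
    label permutations whose contrast is >= the observed one.
    """
    values = corr.values if isinstance(corr, CorrelationMatrix) else corr
    samples = list(values.index)
    lab = np.asarray([labels[s] for s in samples])
    uniq, counts = np.unique(lab, return_counts=True)
    if len(uniq) != 2 or counts.min() < 2:
        raise ValueError(f"group_contrast requires exactly 2 groups with >= 2 samples each, got {dict(zip(uniq, counts))}")
    m = values.to_numpy(dtype=float)
    within, between, observed = _contrast_stat(m, lab)
    rng = np.random.default_rng(seed)
    b = 0
    for _ in range(n_perm):
        perm = rng.permutation(lab)
        if _contrast_stat(m, perm)[2] >= observed:
            b += 1
    p = (b + 1) / (n_perm + 1)
    return GroupContrast(
        mean_within=within, mean_between=between, contrast=observed, p_perm=p, n_perm=n_perm
    )
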