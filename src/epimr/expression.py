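"""Differential expression and sample structure from raw count matrices.

Counts are modelled per gene as negative binomial with a gene-wise
dispersion estimated by method of moments and shrunk toward a mean–dispersion
trend; the tumour-vs-origin contrast is tested with a Wald statistic on the
log2 fold change of normalized group means, with Benjamini–Hochberg
correction across genes. Normalization uses the median-of-ratios size-factor
estimator.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

LN2 = np.log(2.0)


@dataclass
class CountMatrix:
    """Raw gene x sample counts with a condition label per sample."""

    counts: pd.DataFrame  # genes x samples, non-negative integers
    groups: pd.Series  # sample_id -> group label

    def __post_init__(self) -> None:
        if (self.counts.values < 0).any():
            raise ValueError("counts must be non-negative")
        if self.counts.index.duplicated().any():
            raise ValueError("gene ids must be unique")
        missing = set(self.counts.columns) - set(self.groups.index)
        if missing:
            raise ValueError(f"samples without group label: {sorted(missing)}")
        self.groups = self.groups.loc[self.counts.columns]

    def samples_in(self, group: str) -> list[str]:
        sel = [s for s in self.counts.columns if self.groups[s] == group]
        if not sel:
            raise ValueError(f"group {group!r} has no samples")
        return sel


def size_factors(counts: pd.DataFrame, pseudocount: float = 0.0) -> pd.Series:
    """Median-of-ratios size factors (one positive scalar per sample).

    Uses genes with non-zero counts in every sample as the reference set;
    with ``pseudocount > 0`` all genes enter after count shifting.
    """
    mat = counts.to_numpy(dtype=float) + pseudocount
    expressed = (mat > 0).all(axis=1)
    if not expressed.any():
        raise ValueError(
            "no gene has non-zero counts in all samples; rerun with pseudocount > 0"
        )
    logs = np.log(mat[expressed])
    log_geo_mean = logs.mean(axis=1, keepdims=True)
    factors = np.exp(np.median(logs - log_geo_mean, axis=0))
    return pd.Series(factors, index=counts.columns, name="size_factor")


def normalized_counts(counts: pd.DataFrame, factors: pd.Series | None = None) -> pd.DataFrame:
    if factors is None:
        factors = size_factors(counts)
    return counts / factors


def _dispersion_estimates(norm: np.ndarray, group_idx: list[np.ndarray]) -> np.ndarray:
    """Gene-wise NB dispersion: pooled method of moments, shrunk to a trend.

    Per gene, the within-group residual variance is compared with the NB
    mean–variance relation Var = mu + alpha * mu^2. The raw moment estimate
    is then shrunk (in log space, weight 0.5) toward the parametric trend
    alpha(mu) = a1 / mu + a0 fitted across genes, stabilizing the handful of
    residual degrees of freedom available in small designs.
    """
    n_genes = norm.shape[0]
    means = np.stack([norm[:, idx].mean(axis=1) for idx in group_idx], axis=1)
    resid_ss = np.zeros(n_genes)
    df = 0
    for k, idx in enumerate(group_idx):
        resid = norm[:, idx] - means[:, [k]]
        resid_ss += (resid**2).sum(axis=1)
        df += len(idx) - 1
    pooled_var = resid_ss / max(df, 1)
    grand_mean = np.average(
        means, axis=1, weights=[len(idx) for idx in group_idx]
    )
    with np.errstate(divide="ignore", invalid="ignore"):
        alpha_mom = (pooled_var - grand_mean) / grand_mean**2
    alpha_mom = np.where(np.isfinite(alpha_mom), alpha_mom, 0.0)
    alpha_mom = np.clip(alpha_mom, 1e-8, 10.0)

    # parametric trend alpha = a1/mu + a0 on informative genes
    usable = (grand_mean > 0) & (alpha_mom > 1e-8)
    if usable.sum() >= 10:
        X = np.column_stack([1.0 / grand_mean[usable], np.ones(usable.sum())])
        coef, *_ = np.linalg.lstsq(X, alpha_mom[usable], rcond=None)
        a1, a0 = coef
        a0 = max(a0, 1e-8)
        a1 = max(a1, 0.0)
    else:
        a1, a0 = 0.0, float(np.median(alpha_mom[usable])) if usable.any() else 1e-2
    with np.errstate(divide="ignore"):
        alpha_trend = np.where(grand_mean > 0, a1 / np.maximum(grand_mean, 1e-8) + a0, a0)
    alpha_trend = np.clip(alpha_trend, 1e-8, 10.0)
    shrunk = np.exp(0.5 * np.log(alpha_mom) + 0.5 * np.log(alpha_trend))
    return np.clip(shrunk, 1e-8, 10.0)


def call_degs(
    cm: CountMatrix,
    origin_group: str,
    tumour_group: str,
    alpha: float = 0.05,
    lfc_min: float = 0.0,
) -> pd.DataFrame:
    """Tumour-vs-origin differential expression (NB Wald test).

    Returns a per-gene table with ``base_mean``, ``log2fc`` (tumour over
    origin), ``p``, ``q`` (BH) and ``direction`` in {UP, DOWN, NS}. Genes
    with all-zero counts get p = q = 1 and direction NS.
    """
    o_samples = cm.samples_in(origin_group)
    t_samples = cm.samples_in(tumour_group)
    if len(o_samples) < 2 or len(t_samples) < 2:
        raise ValueError("each group needs at least 2 replicates")

    sub = cm.counts[o_samples + t_samples]
    all_zero = (sub.sum(axis=1) == 0).to_numpy()
    if all_zero.any():
        logger.info("excluding %d all-zero genes from normalization", int(all_zero.sum()))
    factors = size_factors(sub.loc[~all_zero]) if (~all_zero).any() else None
    if factors is None:
        raise ValueError("count matrix is entirely zero")
    norm = (sub / factors).to_numpy(dtype=float)

    cols = list(sub.columns)
    o_idx = np.array([cols.index(s) for s in o_samples])
    t_idx = np.array([cols.index(s) for s in t_samples])
    alpha_disp = _dispersion_estimates(norm, [o_idx, t_idx])

    mu_o = norm[:, o_idx].mean(axis=1)
    mu_t = norm[:, t_idx].mean(axis=1)
    eps = 0.5  # half-read pseudo-mean keeps zero groups finite
    log2fc = np.log2((mu_t + eps) / (mu_o + eps))
    # delta-method SE of log2 of a NB group mean: Var(log mu_hat) ~ (1/mu + alpha)/n
    se2 = (
        (1.0 / (mu_o + eps) + alpha_disp) / len(o_idx)
        + (1.0 / (mu_t + eps) + alpha_disp) / len(t_idx)
    ) / LN2**2
    wald = log2fc / np.sqrt(se2)
    # moderated reference: the 50/50 trend shrinkage of the dispersion adds
    # roughly one residual-df worth of prior information per gene, so the
    # Wald statistic is referred to t with df = residual + prior
    resid_df = len(o_idx) + len(t_idx) - 2
    p = 2.0 * stats.t.sf(np.abs(wald), df=2 * resid_df)
    p[all_zero] = 1.0
    log2fc[all_zero] = 0.0
    _, q, _, _ = multipletests(p, method="fdr_bh")

    direction = np.where(
        (q <= alpha) & (np.abs(log2fc) >= lfc_min),
        np.where(log2fc > 0, "UP", "DOWN"),
        "NS",
    )
    direction[all_zero] = "NS"
    return pd.DataFrame(
        {
            "base_mean": norm.mean(axis=1),
            "log2fc": log2fc,
            "p": p,
            "q": q,
            "direction": direction,
        },
        index=sub.index,
    )


def display_matrix(cm: CountMatrix, log_offset: float = 1.0) -> pd.DataFrame:
    """Row-wise z-scores of log2 normalized expression (heatmap transform)."""
    norm = normalized_counts(cm.counts)
    logged = np.log2(norm + log_offset)
    centred = logged.sub(logged.mean(axis=1), axis=0)
    sd = logged.std(axis=1, ddof=0)
    sd = sd.where(sd > 0, 1.0)
    return centred.div(sd, axis=0)


def _pearson_distance(dm: pd.DataFrame) -> tuple[np.ndarray, pd.DataFrame]:
    keep = dm.std(axis=1, ddof=0) > 0
    if (~keep).any():
        warnings.warn(f"{int((~keep).sum())} constant rows dropped from distance computation")
    sub = dm.loc[keep]
    corr = np.corrcoef(sub.to_numpy().T)
    dist = 1.0 - corr
    np.fill_diagonal(dist, 0.0)
    dist = np.clip((dist + dist.T) / 2.0, 0.0, None)
    return dist, sub


def cluster_samples(dm: pd.DataFrame, method: str = "average") -> dict:
    """Hierarchical clustering of samples on 1 - Pearson correlation."""
    if dm.shape[1] < 2:
        raise ValueError("need at least 2 samples to cluster")
    dist, _ = _pearson_distance(dm)
    linkage = hierarchy.linkage(squareform(dist, checks=False), method=method)
    order = hierarchy.leaves_list(linkage)
    return {
        "linkage": linkage,
        "order": [dm.columns[i] for i in order],
    }


def pca_samples(dm: pd.DataFrame, n_components: int = 2) -> dict:
    """PCA of samples on row-centred expression.

    Returns sample coordinates on the leading components and the Pearson
    correlation of each (centred) sample profile with the first component's
    gene loadings — the 'variable factor map' representation.
    """
    if dm.shape[1] < 2:
        raise ValueError("need at least 2 samples")
    X = dm.to_numpy(dtype=float)
    X = X - X.mean(axis=1, keepdims=True)
    U, S, Vt = np.linalg.svd(X, full_matrices=False)
    k = min(n_components, len(S))
    coords = pd.DataFrame(
        (Vt[:k].T * S[:k]),
        index=dm.columns,
        columns=[f"PC{i + 1}" for i in range(k)],
    )
    pc1 = U[:, 0]
    corr = {}
    for j, s in enumerate(dm.columns):
        col = X[:, j]
        denom = np.linalg.norm(col) * np.linalg.norm(pc1)
        corr[s] = float(abs(col @ pc1) / denom) if denom > 0 else np.nan
    explained = S[:k] ** 2 / (S**2).sum()
    return {"coordinates": coords, "pc1_correlation": pd.Series(corr), "explained": explained}


def batch_specific_clusters(
    cm: CountMatrix, batches: list[str] | None = None, alpha: float = 0.05
) -> dict[str, set[str]]:
    """Genes selectively high in one batch: up vs *every* other batch.

    A gene joins batch B's cluster iff each pairwise contrast B vs other
    calls it UP at q < alpha (BH within each comparison); the selectivity
    requirement makes clusters disjoint by construction.
    """
    if batches is None:
        batches = sorted(cm.groups.unique())
    if len(batches) < 3:
        raise ValueError("need at least 3 batches")
    up: dict[tuple[str, str], set[str]] = {}
    for b in batches:
        for other in batches:
            if other == b:
                continue
            if len(cm.samples_in(b)) < 2 or len(cm.samples_in(other)) < 2:
                up[(b, other)] = _fold_change_rank_up(cm, b, other)
                continue
            deg = call_degs(cm, origin_group=other, tumour_group=b, alpha=alpha)
            up[(b, other)] = set(deg.index[deg["direction"] == "UP"])
    clusters: dict[str, set[str]] = {}
    for b in batches:
        sets = [up[(b, other)] for other in batches if other != b]
        clusters[b] = set.intersection(*sets) if sets else set()
    return clusters


def _fold_change_rank_up(cm: CountMatrix, b: str, other: str, top_frac: float = 0.05) -> set[str]:
    warnings.warn(
        f"batch {b} vs {other}: <2 replicates, falling back to fold-change rank rule"
    )
    norm = normalized_counts(cm.counts)
    fc = np.log2(
        (norm[cm.samples_in(b)].mean(axis=1) + 0.5)
        / (norm[cm.samples_in(other)].mean(axis=1) + 0.5)
    )
    k = max(1, int(top_frac * len(fc)))
    top = fc.sort_values(ascending=False).head(k)
    return set(top.index[top > 1.0])
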