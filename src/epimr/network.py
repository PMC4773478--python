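"""TF-centred co-expression, gene-set enrichment, and cluster retention.

``gsea`` implements the weighted Kolmogorov–Smirnov running-sum enrichment
score with a gene-label permutation null (sample permutation is impossible
in 3-vs-3 designs); ``coexpression_neighborhood`` extracts the high-
confidence co-expression partners of a focal gene from an expression
compendium; ``retention_fraction`` measures how much of a batch-specific
gene cluster keeps its expression state in the matched tumour, against a
size-matched random-draw null.
"""

from __future__ import annotations

from itertools import combinations
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .expression import CountMatrix, call_degs


def coexpression_neighborhood(
    compendium: pd.DataFrame,
    focal_gene: str,
    min_abs_r: float = 0.5,
    top_k: int | None = None,
) -> pd.Series:
    """Pearson co-expression partners of ``focal_gene`` across profiles.

    Keeps genes with |r| >= ``min_abs_r`` (or the ``top_k`` by |r| when
    given); the focal gene is excluded from its own neighborhood.
    """
    if focal_gene not in compendium.index:
        raise ValueError(f"focal gene {focal_gene!r} not in compendium")
    if compendium.shape[1] < 3:
        raise ValueError("need at least 3 expression profiles")
    focal = compendium.loc[focal_gene].to_numpy(dtype=float)
    if np.std(focal) == 0:
        raise ValueError("focal gene has constant expression")
    X = compendium.to_numpy(dtype=float)
    Xc = X - X.mean(axis=1, keepdims=True)
    fc = focal - focal.mean()
    denom = np.sqrt((Xc**2).sum(axis=1)) * np.sqrt((fc**2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (Xc @ fc) / denom
    r = pd.Series(r, index=compendium.index).drop(focal_gene).dropna()
    if top_k is not None:
        return r.reindex(r.abs().sort_values(ascending=False).index).head(top_k)
    return r[r.abs() >= min_abs_r].sort_values(key=np.abs, ascending=False)


def tf_dependent_genes(
    cm: CountMatrix, base_group: str, oe_group: str, alpha: float = 0.05
) -> set[str]:
    """Genes responding to TF overexpression in one batch (UP or DOWN)."""
    deg = call_degs(cm, origin_group=base_group, tumour_group=oe_group, alpha=alpha)
    return set(deg.index[deg["direction"] != "NS"])


def venn(sets: Mapping[str, set[str]]) -> dict[tuple[str, ...], int]:
    """Cardinality of every exclusive region of a k-set Venn diagram.

    Keys are the sorted tuples of set names whose exclusive intersection the
    count refers to; region counts sum to the size of the union.
    """
    names = sorted(sets)
    out: dict[tuple[str, ...], int] = {}
    for r in range(1, len(names) + 1):
        for combo in combinations(names, r):
            inside = set.intersection(*(sets[n] for n in combo))
            outside = set.union(set(), *(sets[n] for n in names if n not in combo))
            out[combo] = len(inside - outside)
    return out


def gsea_running_sum(
    ranked_genes: Sequence[str],
    scores: np.ndarray,
    gene_set: set[str],
    weight: float = 1.0,
) -> tuple[float, np.ndarray]:
    """Weighted KS running sum and its signed maximum deviation.

    Hits increment proportionally to |score|^weight (normalized to sum 1
    over set members), misses decrement by 1/(N - |S|); the enrichment score
    is the running-sum value of largest absolute magnitude.
    """
    N = len(ranked_genes)
    hits = np.array([g in gene_set for g in ranked_genes])
    n_hits = int(hits.sum())
    if n_hits == 0:
        raise ValueError("gene set does not intersect the ranked list")
    if n_hits == N:
        raise ValueError("gene set covers the entire ranked list")
    w = np.abs(np.asarray(scores, dtype=float)) ** weight
    hit_weights = np.where(hits, w, 0.0)
    total = hit_weights.sum()
    if total == 0:  # all member scores zero: fall back to unweighted steps
        hit_weights = hits.astype(float)
        total = hit_weights.sum()
    steps = np.where(hits, hit_weights / total, -1.0 / (N - n_hits))
    running = np.cumsum(steps)
    es = float(running[np.argmax(np.abs(running))])
    return es, running


def gsea(
    ranked: pd.Series,
    gene_set: set[str],
    weight: float = 1.0,
    n_perm: int = 1000,
    seed: int = 0,
) -> dict:
    """GSEA of one gene set against a score-ranked gene list.

    ``ranked`` maps gene id -> ranking score (e.g. transition log2fc); the
    list is sorted descending internally. The null permutes set-membership
    labels over the ranked list; nominal p uses the +1 correction and is
    therefore in (0, 1]. Deterministic under (n_perm, seed).
    """
    ranked = ranked.sort_values(ascending=False)
    genes = list(ranked.index)
    scores = ranked.to_numpy(dtype=float)
    members = gene_set & set(genes)
    if not members:
        raise ValueError("gene set does not intersect the ranked list")
    es, running = gsea_running_sum(genes, scores, members, weight=weight)
    n_hits = len(members)
    rng = np.random.default_rng(seed)
    null = np.empty(n_perm)
    N = len(genes)
    w = np.abs(scores) ** weight
    miss_step = -1.0
    for i in range(n_perm):
        idx = rng.choice(N, size=n_hits, replace=False)
        hit_mask = np.zeros(N, dtype=bool)
        hit_mask[idx] = True
        hw = np.where(hit_mask, w, 0.0)
        total = hw.sum()
        if total == 0:
            hw = hit_mask.astype(float)
            total = float(n_hits)
        steps = np.where(hit_mask, hw / total, miss_step / (N - n_hits))
        running_p = np.cumsum(steps)
        null[i] = running_p[np.argmax(np.abs(running_p))]
    nominal_p = (1 + int(np.sum(np.abs(null) >= abs(es)))) / (n_perm + 1)
    nes = float(es / np.mean(np.abs(null))) if np.mean(np.abs(null)) > 0 else np.nan
    peak = int(np.argmax(np.abs(running)))
    if es >= 0:
        leading = [g for g in genes[: peak + 1] if g in members]
    else:
        leading = [g for g in genes[peak:] if g in members]
    return {
        "es": es,
        "nes": nes,
        "nominal_p": nominal_p,
        "n_perm": n_perm,
        "seed": seed,
        "leading_edge": leading,
        "running": running,
    }


def _retained_mask(
    cluster: Sequence[str],
    batch_expr: pd.Series,
    pt_expr: pd.Series,
    quantile: float,
) -> np.ndarray:
    qb = float(batch_expr.quantile(quantile))
    qp = float(pt_expr.quantile(quantile))
    b = batch_expr.loc[list(cluster)].to_numpy(dtype=float)
    p = pt_expr.loc[list(cluster)].to_numpy(dtype=float)
    return np.sign(b - qb) == np.sign(p - qp)


def retention_fraction(
    cluster: set[str],
    batch_expr: pd.Series,
    pt_expr: pd.Series,
    quantile: float = 0.5,
    n_shuffles: int = 0,
    seed: int = 0,
) -> dict:
    """Fraction of a batch cluster whose expression state persists in PT.

    A gene is retained when it sits on the same side of the expression
    quantile threshold (default: median) in the batch and in the matched
    tumour — i.e. it stays expressed, in the same direction. With
    ``n_shuffles > 0`` a size-matched random-gene null yields a z-score and
    an empirical p (+1 corrected).
    """
    if not cluster:
        raise ValueError("empty cluster")
    shared = set(batch_expr.index) & set(pt_expr.index)
    if not set(cluster) <= shared:
        raise ValueError("cluster genes missing from expression vectors")
    genes = sorted(cluster)
    frac = float(_retained_mask(genes, batch_expr, pt_expr, quantile).mean())
    out = {"fraction": frac, "n": len(genes)}
    if n_shuffles > 0:
        rng = np.random.default_rng(seed)
        pool = np.array(sorted(shared))
        null = np.empty(n_shuffles)
        for i in range(n_shuffles):
            draw = rng.choice(pool, size=len(genes), replace=False)
            null[i] = _retained_mask(draw, batch_expr, pt_expr, quantile).mean()
        sd = float(null.std(ddof=0))
        out["null_mean"] = float(null.mean())
        out["null_sd"] = sd
        out["z"] = float((frac - null.mean()) / sd) if sd > 0 else np.nan
        out["empirical_p"] = float((1 + np.sum(null >= frac)) / (n_shuffles + 1))
        out["n_shuffles"] = n_shuffles
        out["seed"] = seed
    return out
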