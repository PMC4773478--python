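"""Integration core: overlap statistics, ORA, and master-regulator ranking.

A candidate master regulator is a transcription factor whose binding motif
is over-represented among DEG promoters (Bonferroni p < alpha), whose own
gene is significantly downregulated in the tumour condition, and whose
promoter acquires H3K27me3 *de novo* — the configuration that singles out a
Polycomb-silenced regulator of the transition.
"""

from __future__ import annotations

import logging
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)


def hypergeom_upper_tail(overlap: int, universe: int, set_a: int, set_b: int) -> float:
    """P(X >= overlap) for X ~ Hypergeom(universe, set_a, set_b)."""
    return float(stats.hypergeom.sf(overlap - 1, universe, set_a, set_b))


def ora_fisher(
    query: set[str], collection: Mapping[str, set[str]], universe: set[str]
) -> pd.DataFrame:
    """Right-tailed Fisher (hypergeometric upper-tail) ORA with BH q-values.

    Sets are intersected with the universe before testing; the query must be
    a subset of the universe.
    """
    if not universe:
        raise ValueError("empty universe")
    if not query <= universe:
        raise ValueError("query set must be a subset of the universe")
    N = len(universe)
    n_q = len(query)
    rows = []
    for name, genes in collection.items():
        genes = genes & universe
        k = len(query & genes)
        K = len(genes)
        p = hypergeom_upper_tail(k, N, K, n_q)
        # sample odds ratio of the 2x2 (query x set) table
        a, b = k, n_q - k
        c, d = K - k, N - n_q - (K - k)
        odds = (a * d) / (b * c) if b * c > 0 else np.inf
        rows.append({"set": name, "overlap": k, "set_size": K, "odds_ratio": odds, "p": p})
    df = pd.DataFrame(rows).set_index("set")
    if len(df):
        _, q, _, _ = multipletests(df["p"].values, method="fdr_bh")
        df["q"] = q
    return df


def overlap_significance(
    set_a: set[str], set_b: set[str], universe: set[str]
) -> dict[str, float]:
    """Overlap of two gene sets with its hypergeometric upper-tail p."""
    if not universe:
        raise ValueError("empty universe")
    if not (set_a <= universe and set_b <= universe):
        raise ValueError("both sets must be subsets of the universe")
    k = len(set_a & set_b)
    return {
        "overlap": k,
        "p": hypergeom_upper_tail(k, len(universe), len(set_a), len(set_b)),
    }


def intersect_down_denovo(deg: pd.DataFrame, denovo: set[str]) -> pd.DataFrame:
    """Downregulated DEGs that are also de novo H3K27me3 targets.

    Returns the DEG rows of the intersection with annotations carried
    through, sorted by q then gene id.
    """
    down = deg.index[deg["direction"] == "DOWN"]
    core = [g for g in down if g in denovo]
    return deg.loc[core].sort_values(["q", "log2fc"]).copy()


def rank_master_regulators(
    enrichment: pd.DataFrame,
    deg: pd.DataFrame,
    denovo: set[str],
    tf_to_gene: Mapping[str, str],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Rank motif-enriched TFs by expression significance and mark status.

    Rows are the TFs with Bonferroni motif p < alpha, sorted by DE q-value
    ascending, then |log2fc| descending, then gene id. ``mark_status`` is
    MARKED when the TF's own gene is a de novo H3K27me3 target, and
    ``shortlisted`` is True iff the motif is enriched AND the TF's gene is
    DOWN at q < alpha AND its promoter is MARKED.
    """
    enriched = enrichment[enrichment["p_bonferroni"] < alpha]
    rows = []
    for pwm_id, erow in enriched.iterrows():
        gene = tf_to_gene.get(pwm_id)
        if gene is None or gene not in deg.index:
            logger.warning("PWM %s has no mappable gene in the DEG universe; excluded", pwm_id)
            continue
        drow = deg.loc[gene]
        marked = gene in denovo
        shortlisted = bool(
            (drow["direction"] == "DOWN") and (drow["q"] < alpha) and marked
        )
        rows.append(
            {
                "pwm_id": pwm_id,
                "gene_id": gene,
                "motif_p_bonferroni": erow["p_bonferroni"],
                "de_log2fc": drow["log2fc"],
                "de_q": drow["q"],
                "direction": drow["direction"],
                "mark_status": "MARKED" if marked else "UNMARKED",
                "shortlisted": shortlisted,
            }
        )
    table = pd.DataFrame(
        rows,
        columns=[
            "pwm_id",
            "gene_id",
            "motif_p_bonferroni",
            "de_log2fc",
            "de_q",
            "direction",
            "mark_status",
            "shortlisted",
        ],
    )
    if len(table):
        table["abs_lfc"] = table["de_log2fc"].abs()
        table = table.sort_values(
            ["de_q", "abs_lfc", "gene_id"], ascending=[True, False, True]
        ).drop(columns="abs_lfc")
        table = table.reset_index(drop=True)
    return table


def shortlist(table: pd.DataFrame) -> list[str]:
    if len(table) == 0:
        return []
    return list(table.loc[table["shortlisted"], "gene_id"])
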