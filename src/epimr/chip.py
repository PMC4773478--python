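"""TSS-window H3K27me3 quantification, target calling and pattern classes.

Each gene is summarized over a window centred on its TSS (default 6 kb: 3 kb
upstream + 3 kb downstream, 100-bp bins), strand-corrected so that negative
bins are biologically upstream. A gene is called a target in a sample when
its summed window signal exceeds the control-scaled expectation under a
one-sided Poisson test (BH across genes). Called targets fall into three
spatial classes — enrichment centred on the TSS with a sharp central dip,
prevalently upstream, or prevalently downstream — and *de novo* targets are
genes marked in every tumour sample and in no origin sample.
"""

from __future__ import annotations

import os
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from . import io as eio

PATTERNS = ("TSS", "UP", "DOWN", "NONE")


@dataclass
class ChipProfile:
    """Per-gene binned tag densities over a TSS-centred window for one track.

    ``values`` holds the mean bedGraph value per bin (genes x bins); bins that
    fall off the chromosome end are NaN. ``library_size`` is the track total
    on the same per-bin scale, used for between-track normalization. Bin
    order is strand-corrected exactly once at construction.
    """

    sample: str
    genes: list[str]
    values: np.ndarray  # genes x bins, NaN = off-chromosome
    window_half: int = 3000
    bin_size: int = 100
    library_size: float = 1.0

    def __post_init__(self) -> None:
        expected = 2 * self.window_half // self.bin_size
        if self.values.shape != (len(self.genes), expected):
            raise ValueError(
                f"profile shape {self.values.shape} does not match "
                f"{len(self.genes)} genes x {expected} bins"
            )

    @property
    def n_bins(self) -> int:
        return 2 * self.window_half // self.bin_size

    def bin_starts(self) -> np.ndarray:
        """Window-relative start of each bin (TSS at 0)."""
        return np.arange(-self.window_half, self.window_half, self.bin_size)

    def densities(self) -> np.ndarray:
        """Library-size normalized values (reads-per-million equivalent)."""
        return self.values * 1e6 / self.library_size

    def window_sums(self) -> np.ndarray:
        return np.nansum(self.values, axis=1)


def _coverage_arrays(bedgraph: pd.DataFrame) -> dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]]:
    out = {}
    for chrom, sub in bedgraph.groupby("chrom", sort=False):
        sub = sub.sort_values("start")
        starts = sub["start"].to_numpy(dtype=np.int64)
        ends = sub["end"].to_numpy(dtype=np.int64)
        values = sub["value"].to_numpy(dtype=float)
        # integral of coverage up to each interval start
        cum = np.concatenate([[0.0], np.cumsum((ends - starts) * values)])
        out[chrom] = (starts, ends, values, cum)
    return out


def _integral_at(positions: np.ndarray, starts, ends, values, cum) -> np.ndarray:
    """F(x) = integral of coverage over [0, x) for sorted interval tracks."""
    idx = np.searchsorted(starts, positions, side="right") - 1
    idx = np.clip(idx, 0, len(starts) - 1)
    base = cum[idx]
    inside = np.clip(positions - starts[idx], 0, ends[idx] - starts[idx])
    before_first = positions <= starts[0]
    res = base + inside * values[idx]
    res[before_first] = 0.0
    return res


def tss_profile(
    bedgraph: pd.DataFrame | str | os.PathLike,
    annotation: pd.DataFrame | str | os.PathLike,
    window_half: int = 3000,
    bin_size: int = 100,
    sample: str = "sample",
) -> ChipProfile:
    """Bin coverage into a strand-corrected TSS-centred window per gene."""
    if (2 * window_half) % bin_size != 0:
        raise ValueError("bin size must divide the window")
    if not isinstance(bedgraph, pd.DataFrame):
        bedgraph = eio.read_bedgraph(bedgraph)
    if not isinstance(annotation, pd.DataFrame):
        annotation = eio.read_bed6(annotation)

    cov = _coverage_arrays(bedgraph)
    tss = eio.tss_positions(annotation)
    strands = pd.Series(annotation["strand"].values, index=annotation["name"].values)
    chroms = pd.Series(annotation["chrom"].values, index=annotation["name"].values)
    n_bins = 2 * window_half // bin_size
    genes = list(annotation["name"])
    values = np.full((len(genes), n_bins), np.nan)

    chrom_ends = {c: int(arr[1].max()) for c, arr in cov.items()}
    for i, g in enumerate(genes):
        chrom = chroms[g]
        if chrom not in cov:
            continue
        starts, ends, vals, cum = cov[chrom]
        edges = tss[g] + np.arange(-window_half, window_half + 1, bin_size)
        valid = (edges >= 0) & (edges <= chrom_ends[chrom])
        F = _integral_at(np.clip(edges, 0, chrom_ends[chrom]).astype(float), starts, ends, vals, cum)
        binned = (F[1:] - F[:-1]) / bin_size
        bin_ok = valid[1:] & valid[:-1]
        binned[~bin_ok] = np.nan
        if strands[g] == "-":
            binned = binned[::-1]
        values[i] = binned

    total = sum(float(((e - s) * v).sum()) for s, e, v, _ in cov.values()) / bin_size
    return ChipProfile(
        sample=sample,
        genes=genes,
        values=values,
        window_half=window_half,
        bin_size=bin_size,
        library_size=max(total, 1e-12),
    )


def _poisson_vs_control_p(
    obs_signal: np.ndarray, obs_control: np.ndarray, lib_signal: float, lib_control: float
) -> np.ndarray:
    """One-sided Poisson comparison of window counts vs a control track.

    Exact conditional form: under equal per-read window propensity,
    conditional on the total T = S + C the signal count is binomial with
    success probability lib_signal / (lib_signal + lib_control), which keeps
    the test calibrated when the control is itself a noisy count.
    """
    S = np.round(np.maximum(obs_signal, 0.0)).astype(np.int64)
    C = np.round(np.maximum(obs_control, 0.0)).astype(np.int64)
    T = S + C
    rho = lib_signal / (lib_signal + lib_control)
    p = np.ones_like(S, dtype=float)
    pos = S > 0
    p[pos] = stats.binom.sf(S[pos] - 1, T[pos], rho)
    return p


def call_targets(
    profile: ChipProfile,
    control: ChipProfile,
    fdr: float = 0.05,
    per_bin: bool = False,
) -> pd.DataFrame:
    """One-sided Poisson test of window signal vs control-scaled expectation.

    The default statistic is the whole-window sum (robust for broad marks
    like H3K27me3); ``per_bin=True`` instead tests the most enriched bin,
    Bonferroni-corrected over bins within the gene. BH across genes;
    ``is_target`` iff q < fdr.
    """
    if profile.genes != control.genes:
        raise ValueError("signal and control profiles cover different genes")
    ctrl_total = control.window_sums()
    if not (ctrl_total > 0).any():
        raise ValueError("control track has zero signal genome-wide")
    scale = profile.library_size / control.library_size
    if per_bin:
        sig = np.nan_to_num(profile.values)
        ctrl = np.nan_to_num(control.values)
        p_bins = _poisson_vs_control_p(
            sig.ravel(), ctrl.ravel(), profile.library_size, control.library_size
        ).reshape(sig.shape)
        p_bins[np.isnan(profile.values)] = 1.0
        n_ok = np.sum(~np.isnan(profile.values), axis=1)
        p = np.clip(p_bins.min(axis=1) * np.maximum(n_ok, 1), 0, 1)
        obs = np.nanmax(profile.values, axis=1)
        expected = np.nanmax(ctrl * scale, axis=1)
    else:
        obs = profile.window_sums()
        expected = ctrl_total * scale
        p = _poisson_vs_control_p(obs, ctrl_total, profile.library_size, control.library_size)
    _, q, _, _ = multipletests(p, method="fdr_bh")
    with np.errstate(divide="ignore", invalid="ignore"):
        score = np.log2(np.maximum(obs, 1e-9) / np.maximum(expected, 1e-9))
    return pd.DataFrame(
        {
            "sample": profile.sample,
            "score": score,
            "p": p,
            "q": q,
            "is_target": q < fdr,
        },
        index=pd.Index(profile.genes, name="gene_id"),
    )


def de_novo_targets(
    origin_calls: list[pd.DataFrame], tumour_calls: list[pd.DataFrame]
) -> set[str]:
    """Genes marked in every tumour sample and in no origin sample."""
    if not tumour_calls:
        return set()
    tum_sets = [set(c.index[c["is_target"]]) for c in tumour_calls]
    org_sets = [set(c.index[c["is_target"]]) for c in origin_calls]
    consistent = set.intersection(*tum_sets)
    ever_origin = set.union(*org_sets) if org_sets else set()
    return consistent - ever_origin


def classify_pattern(
    row: np.ndarray, n_bins: int | None = None, log_ratio_cutoff: float = 1.0
) -> str:
    """Spatial class of one target profile row: TSS, UP or DOWN.

    U and D are the mean densities over the upstream ([-window, 0)) and
    downstream ((0, +window]) bin halves; |log2(U/D)| >= cutoff assigns UP or
    DOWN by sign, otherwise the profile counts as TSS-centred. NaN bins
    (chromosome edges) are excluded from the means.
    """
    row = np.asarray(row, dtype=float)
    half = row.shape[0] // 2
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        U = np.nanmean(row[:half])
        D = np.nanmean(row[half:])
    if not np.isfinite(U) or not np.isfinite(D) or (U == 0 and D == 0):
        raise ValueError("called target has empty window halves; inconsistent call")
    if U == 0 or D == 0:
        ratio = np.inf if D == 0 else -np.inf
    else:
        ratio = np.log2(U / D)
    if abs(ratio) >= log_ratio_cutoff:
        return "UP" if ratio > 0 else "DOWN"
    return "TSS"


def classify_patterns(
    profile: ChipProfile, target_genes: set[str], log_ratio_cutoff: float = 1.0
) -> pd.Series:
    """Pattern per gene: targets get their spatial class, others NONE."""
    out = {}
    for i, g in enumerate(profile.genes):
        if g in target_genes:
            out[g] = classify_pattern(profile.values[i], log_ratio_cutoff=log_ratio_cutoff)
        else:
            out[g] = "NONE"
    return pd.Series(out, name="pattern")


def mann_whitney(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Two-sided Mann–Whitney U; exact null when both n <= 12, else normal
    approximation with tie correction."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ties = len(np.unique(np.concatenate([x, y]))) < len(x) + len(y)
    if len(x) <= 12 and len(y) <= 12 and not ties:
        method = "exact"
    else:
        method = "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def expression_by_pattern(
    classes: pd.Series, expression: pd.Series
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Expression consequence of the spatial classes.

    Returns per-class summary statistics and all pairwise two-sided
    Mann–Whitney comparisons; classes with fewer than 2 members are excluded
    with a warning.
    """
    shared = classes.index.intersection(expression.index)
    classes = classes.loc[shared]
    expression = expression.loc[shared]
    by_class = {
        c: expression[classes == c].to_numpy()
        for c in classes.unique()
        if c != "NONE"
    }
    kept = {}
    for c, vals in by_class.items():
        if len(vals) < 2:
            warnings.warn(f"class {c}: fewer than 2 members, excluded")
        else:
            kept[c] = vals
    if len(kept) < 2:
        raise ValueError("need at least 2 non-empty classes")
    summary = pd.DataFrame(
        {
            c: {
                "n": len(v),
                "median": float(np.median(v)),
                "mean": float(np.mean(v)),
            }
            for c, v in kept.items()
        }
    ).T
    pairs = []
    names = sorted(kept)
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            u, p = mann_whitney(kept[a], kept[b])
            pairs.append({"class_a": a, "class_b": b, "U": u, "p": p})
    return summary, pd.DataFrame(pairs)
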