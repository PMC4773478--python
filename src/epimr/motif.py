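"""Promoter motif scanning and enrichment.

The enrichment statistic follows the Pscan convention: every promoter in the
genome is scored with the best (min–max normalized) log-odds match of a PWM
on either strand, and a foreground gene set is compared against the promoter
population with a one-sided z-test, Bonferroni-corrected over motifs.
"""

from __future__ import annotations

import io as _io
import os
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import motifs as bio_motifs
from scipy import stats

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}


class MotifFormatError(ValueError):
    """Raised for malformed JASPAR PFM input."""


@dataclass
class PWM:
    """Position weight matrix with log-odds scoring against a background.

    ``counts`` is a 4 x L array in A, C, G, T row order. Frequencies are
    obtained by adding ``pseudocount`` to every cell and renormalizing each
    column; ``score_min``/``score_max`` are the per-column extremes of the
    log-odds matrix, used for min–max normalization of match scores.
    """

    id: str
    name: str
    counts: np.ndarray
    pseudocount: float = 0.01
    background: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    frequencies: np.ndarray = field(init=False)
    log_odds: np.ndarray = field(init=False)
    score_min: float = field(init=False)
    score_max: float = field(init=False)

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=float)
        if counts.ndim != 2 or counts.shape[0] != 4 or counts.shape[1] < 1:
            raise MotifFormatError(f"PWM {self.id}: matrix must be 4 x L with L >= 1")
        if (counts < 0).any():
            raise MotifFormatError(f"PWM {self.id}: negative counts")
        col_sums = counts.sum(axis=0)
        if (col_sums == 0).any():
            bad = int(np.argmax(col_sums == 0))
            raise MotifFormatError(f"PWM {self.id}: column {bad} has zero total count")
        self.counts = counts
        freqs = counts / col_sums + self.pseudocount
        self.frequencies = freqs / freqs.sum(axis=0)
        bg = np.asarray(self.background, dtype=float)[:, None]
        self.log_odds = np.log(self.frequencies / bg)
        self.score_min = float(self.log_odds.min(axis=0).sum())
        self.score_max = float(self.log_odds.max(axis=0).sum())
        if not self.score_max > self.score_min:
            raise MotifFormatError(f"PWM {self.id}: degenerate matrix (flat log-odds)")

    @property
    def length(self) -> int:
        return self.counts.shape[1]

    @property
    def raw_frequencies(self) -> np.ndarray:
        """Count-based per-column base distribution, without pseudocount."""
        return self.counts / self.counts.sum(axis=0)

    @property
    def consensus(self) -> str:
        return "".join(BASES[i] for i in self.frequencies.argmax(axis=0))

    def reverse_complement_log_odds(self) -> np.ndarray:
        # complement = reversed base axis (A<->T, C<->G), reversed columns
        return self.log_odds[::-1, ::-1]


def read_jaspar(path: str | os.PathLike, pseudocount: float = 0.01) -> list[PWM]:
    """Parse a JASPAR PFM text file (">ID NAME" headers, A/C/G/T rows)."""
    with open(path) as fh:
        text = fh.read()
    try:
        parsed = bio_motifs.parse(_io.StringIO(text), "jaspar")
    except Exception as exc:  # Bio raises bare ValueError/KeyError on bad rows
        raise MotifFormatError(f"{path}: not valid JASPAR PFM format ({exc})") from exc
    pwms = []
    for m in parsed:
        counts = np.array([m.counts[b] for b in BASES], dtype=float)
        pwms.append(PWM(id=m.matrix_id or m.name, name=m.name, counts=counts, pseudocount=pseudocount))
    if not pwms:
        raise MotifFormatError(f"{path}: no motifs found")
    return pwms


def write_jaspar(pwms: Iterable[PWM], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for pwm in pwms:
            fh.write(f">{pwm.id} {pwm.name}\n")
            for i, base in enumerate(BASES):
                row = " ".join(format(v, ".6g") for v in pwm.counts[i])
                fh.write(f"{base} [ {row} ]\n")


def encode_sequence(seq: str) -> np.ndarray:
    """Map a DNA string to indices 0..3; non-ACGT becomes -1."""
    arr = np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)
    out = np.full(arr.shape, -1, dtype=np.int64)
    for base, idx in _BASE_INDEX.items():
        out[arr == ord(base)] = idx
    return out


def _window_scores(encoded: np.ndarray, log_odds: np.ndarray) -> np.ndarray:
    """Log-odds sum at every offset; offsets touching non-ACGT are NaN."""
    L = log_odds.shape[1]
    n = encoded.shape[0] - L + 1
    if n <= 0:
        raise ValueError("sequence shorter than motif")
    windows = np.lib.stride_tricks.sliding_window_view(encoded, L)
    valid = (windows >= 0).all(axis=1)
    safe = np.where(windows >= 0, windows, 0)
    scores = log_odds[safe, np.arange(L)].sum(axis=1)
    scores[~valid] = np.nan
    return scores


def best_site_score(seq: str, pwm: PWM) -> float:
    """Best match of ``pwm`` on either strand, min–max normalized to [0, 1].

    Offsets containing non-ACGT characters are skipped; NaN is returned when
    no offset is scorable.
    """
    encoded = encode_sequence(seq)
    if encoded.shape[0] < pwm.length:
        raise ValueError("sequence shorter than motif")
    fwd = _window_scores(encoded, pwm.log_odds)
    rev = _window_scores(encoded, pwm.reverse_complement_log_odds())
    stacked = np.concatenate([fwd, rev])
    if np.isnan(stacked).all():
        return float("nan")
    best = np.nanmax(stacked)
    return float((best - pwm.score_min) / (pwm.score_max - pwm.score_min))


def score_promoters(
    promoters: Mapping[str, str], pwms: Sequence[PWM]
) -> pd.DataFrame:
    """Best-site score of every promoter (rows) for every PWM (columns)."""
    gene_ids = list(promoters)
    encoded = [encode_sequence(promoters[g]) for g in gene_ids]
    lengths = {e.shape[0] for e in encoded}
    data = np.empty((len(gene_ids), len(pwms)))
    if len(lengths) == 1:
        # equal-length promoters: score all genes for one PWM in one shot
        mat = np.stack(encoded)
        for j, pwm in enumerate(pwms):
            L = pwm.length
            windows = np.lib.stride_tricks.sliding_window_view(mat, L, axis=1)
            valid = (windows >= 0).all(axis=2)
            safe = np.where(windows >= 0, windows, 0)
            span = pwm.score_max - pwm.score_min
            best = np.full(mat.shape[0], -np.inf)
            for lo in (pwm.log_odds, pwm.reverse_complement_log_odds()):
                s = lo[safe, np.arange(L)].sum(axis=2)
                s[~valid] = -np.inf
                best = np.maximum(best, s.max(axis=1))
            with np.errstate(invalid="ignore"):
                data[:, j] = np.where(
                    np.isfinite(best), (best - pwm.score_min) / span, np.nan
                )
    else:
        for j, pwm in enumerate(pwms):
            lo_f = pwm.log_odds
            lo_r = pwm.reverse_complement_log_odds()
            span = pwm.score_max - pwm.score_min
            for i, enc in enumerate(encoded):
                stacked = np.concatenate(
                    [_window_scores(enc, lo_f), _window_scores(enc, lo_r)]
                )
                if np.isnan(stacked).all():
                    data[i, j] = np.nan
                else:
                    data[i, j] = (np.nanmax(stacked) - pwm.score_min) / span
    return pd.DataFrame(data, index=gene_ids, columns=[p.id for p in pwms])


def motif_enrichment(
    fg_gene_ids: Iterable[str],
    promoters: Mapping[str, str],
    pwms: Sequence[PWM],
    scores: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Population z-test of foreground best-site scores per motif.

    The background is the full promoter population (all genes in the bundle),
    treated as the population, so z = (fg_mean - bg_mean) / (bg_sd / sqrt(n_fg))
    with a one-sided upper-tail p, Bonferroni-corrected over motifs.
    """
    fg = [g for g in fg_gene_ids]
    missing = set(fg) - set(promoters)
    if missing:
        raise ValueError(f"foreground genes missing from promoter set: {sorted(missing)[:5]}")
    if scores is None:
        scores = score_promoters(promoters, pwms)
    n_motifs = scores.shape[1]
    rows = []
    fg_idx = scores.index.isin(set(fg))
    for pwm in pwms:
        col = scores[pwm.id]
        bg_mean = float(col.mean())
        bg_sd = float(col.std(ddof=0))
        if bg_sd == 0:
            warnings.warn(f"motif {pwm.id}: zero background variance, skipped")
            continue
        fg_scores = col[fg_idx].dropna()
        n_fg = len(fg_scores)
        fg_mean = float(fg_scores.mean())
        z = (fg_mean - bg_mean) / (bg_sd / np.sqrt(n_fg))
        p = float(stats.norm.sf(z))
        rows.append(
            {
                "pwm_id": pwm.id,
                "name": pwm.name,
                "fg_mean": fg_mean,
                "bg_mean": bg_mean,
                "bg_sd": bg_sd,
                "z": z,
                "p": p,
                "p_bonferroni": min(1.0, p * n_motifs),
                "n_fg": n_fg,
                "n_bg": int(col.notna().sum()),
            }
        )
    return pd.DataFrame(rows).set_index("pwm_id")
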