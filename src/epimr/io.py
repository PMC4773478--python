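"""Readers and writers for the plain-text formats the pipeline exchanges.

All genomic intervals are BED-convention: 0-based, half-open. The TSS of a
minus-strand gene is ``end - 1``.
"""

from __future__ import annotations

import os
from typing import Iterable, Mapping

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

BED6_COLUMNS = ["chrom", "start", "end", "name", "score", "strand"]


def read_fasta(path: str | os.PathLike) -> dict[str, str]:
    """Read a FASTA file into an ordered ``{id: sequence}`` map."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: Mapping[str, str], path: str | os.PathLike) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()
    ]
    SeqIO.write(records, str(path), "fasta")


def read_bed6(path: str | os.PathLike) -> pd.DataFrame:
    df = pd.read_csv(
        path, sep="\t", header=None, names=BED6_COLUMNS, comment="#", dtype={"chrom": str}
    )
    if (df["end"] <= df["start"]).any():
        raise ValueError("BED intervals must satisfy start < end")
    if not df["strand"].isin(["+", "-"]).all():
        raise ValueError("BED strand column must be '+' or '-'")
    return df


def write_bed6(df: pd.DataFrame, path: str | os.PathLike) -> None:
    df[BED6_COLUMNS].to_csv(path, sep="\t", header=False, index=False)


def tss_positions(bed: pd.DataFrame) -> pd.Series:
    """0-based TSS per gene: interval start on '+', ``end - 1`` on '-'."""
    tss = bed["start"].where(bed["strand"] == "+", bed["end"] - 1)
    return pd.Series(tss.values, index=bed["name"].values, name="tss")


def read_bedgraph(path: str | os.PathLike) -> pd.DataFrame:
    df = pd.read_csv(
        path,
        sep="\t",
        header=None,
        names=["chrom", "start", "end", "value"],
        comment="t",  # skips optional "track ..." header lines
        dtype={"chrom": str},
    )
    return df


def write_bedgraph(df: pd.DataFrame, path: str | os.PathLike) -> None:
    df[["chrom", "start", "end", "value"]].to_csv(path, sep="\t", header=False, index=False)


def read_counts(path: str | os.PathLike) -> pd.DataFrame:
    """Counts TSV: rows = genes, columns = samples, first column = gene ids."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if (df.values < 0).any():
        raise ValueError("count matrix contains negative entries")
    return df


def write_counts(df: pd.DataFrame, path: str | os.PathLike) -> None:
    df.to_csv(path, sep="\t", index_label="gene_id")


def read_groups(path: str | os.PathLike) -> pd.Series:
    """Two-column TSV (sample_id, group) mapping samples to condition labels."""
    df = pd.read_csv(path, sep="\t", header=None, names=["sample_id", "group"])
    return pd.Series(df["group"].values, index=df["sample_id"].values, name="group")


def write_groups(groups: pd.Series, path: str | os.PathLike) -> None:
    groups.rename("group").rename_axis("sample_id").to_csv(path, sep="\t", header=False)


def read_gene_list(path: str | os.PathLike) -> list[str]:
    with open(path) as fh:
        return [line.strip() for line in fh if line.strip()]


def write_gene_list(genes: Iterable[str], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for g in genes:
            fh.write(f"{g}\n")


def read_gmt(path: str | os.PathLike) -> dict[str, set[str]]:
    """GMT gene-set file: name <tab> description <tab> gene1 <tab> gene2 ..."""
    sets: dict[str, set[str]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            sets[parts[0]] = {g for g in parts[2:] if g}
    return sets


def write_gmt(sets: Mapping[str, Iterable[str]], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for name, genes in sets.items():
            fh.write("\t".join([name, "na", *sorted(genes)]) + "\n")


def read_survival(path: str | os.PathLike) -> pd.DataFrame:
    """Survival TSV with columns patient_id, time, event, expr."""
    df = pd.read_csv(path, sep="\t")
    required = {"patient_id", "time", "event", "expr"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"survival table missing columns: {sorted(missing)}")
    if (df["time"] <= 0).any():
        raise ValueError("survival times must be positive")
    if not df["event"].isin([0, 1]).all():
        raise ValueError("event indicator must be 0 or 1")
    return df


def write_survival(df: pd.DataFrame, path: str | os.PathLike) -> None:
    cols = ["patient_id", "time", "event", "expr"] + [
        c for c in df.columns if c not in {"patient_id", "time", "event", "expr"}
    ]
    df[cols].to_csv(path, sep="\t", index=False)
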