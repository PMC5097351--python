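"""Readers and writers for the plain-text table formats used across the pipeline.

All tables are tab-separated text. Gene-set collections use the GMT dialect
(one set per line: name, description, then member genes).
"""

from __future__ import annotations

import os
from typing import Dict, List, Mapping, Sequence

import pandas as pd

PAIR_COLUMNS = ["gene1", "gene2", "dup_type", "dS"]
SUBGENOME_COLUMNS = ["gene_id", "subgenome", "block_id", "chrom", "start", "end"]


def read_expression_tsv(path: str) -> pd.DataFrame:
    """Read a gene x sample TPM matrix (first column ``gene_id``)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.isna().any().any():
        bad = df.columns[df.isna().any()].tolist()
        raise ValueError(f"expression matrix contains missing values in columns {bad}")
    if df.index.duplicated().any():
        dupes = df.index[df.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate gene IDs in expression matrix: {dupes[:5]}")
    return df


def write_expression_tsv(df: pd.DataFrame, path: str) -> None:
    df.to_csv(path, sep="\t", index_label="gene_id")


def read_replicate_map(path: str) -> Dict[str, str]:
    """Read a two-column ``column <tab> tissue`` map."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] != 2:
        raise ValueError("replicate map must have exactly two columns")
    col, tissue = df.columns
    return dict(zip(df[col], df[tissue]))


def write_replicate_map(mapping: Mapping[str, str], path: str) -> None:
    pd.DataFrame(
        {"column": list(mapping.keys()), "tissue": list(mapping.values())}
    ).to_csv(path, sep="\t", index=False)


def read_pair_table(path: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in PAIR_COLUMNS[:3] if c not in df.columns]
    if missing:
        raise ValueError(f"pair table missing columns: {missing}")
    return df


def write_pair_table(df: pd.DataFrame, path: str) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_subgenome_map(path: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in SUBGENOME_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"subgenome map missing columns: {missing}")
    if df["gene_id"].duplicated().any():
        raise ValueError("subgenome map has more than one record for some genes")
    return df


def write_subgenome_map(df: pd.DataFrame, path: str) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_gmt(path: str) -> Dict[str, List[str]]:
    """Read gene sets from a GMT file: ``name <tab> description <tab> gene...``."""
    sets: Dict[str, List[str]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"malformed GMT line: {line[:60]!r}")
            sets[fields[0]] = [g for g in fields[2:] if g]
    return sets


def write_gmt(sets: Mapping[str, Sequence[str]], path: str, description: str = "na") -> None:
    with open(path, "w") as fh:
        for name, genes in sets.items():
            fh.write("\t".join([name, description, *genes]) + "\n")


def read_edge_list(path: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    for c in ("gene1", "gene2"):
        if c not in df.columns:
            raise ValueError("edge list must have gene1/gene2 columns")
    return df


def write_edge_list(df: pd.DataFrame, path: str) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_module_table(path: str) -> pd.Series:
    df = pd.read_csv(path, sep="\t")
    return pd.Series(df["module_id"].values, index=df["gene_id"].values, name="module_id")


def write_module_table(assignment: Mapping[str, int], path: str) -> None:
    pd.DataFrame(
        {"gene_id": list(assignment.keys()), "module_id": list(assignment.values())}
    ).to_csv(path, sep="\t", index=False)


def ensure_dir(path: str) -> str:
    os.makedirs(path, exist_ok=True)
    return path
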