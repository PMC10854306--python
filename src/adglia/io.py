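"""Readers and writers for the plain-text formats used throughout the package.

Count matrices are TSV files with features on rows (first column = feature id,
header row = sample ids) and integer counts in the body.  Gene sets use the
standard GMT layout (name, description, then one gene per field).
"""

from __future__ import annotations

import os
from typing import Mapping

import pandas as pd


def read_counts(path: str | os.PathLike) -> pd.DataFrame:
    """Read a feature x sample count matrix from TSV.

    Returns a DataFrame indexed by feature id with sample-id columns and
    integer counts.  Raises ``ValueError`` on duplicate ids or negative
    entries.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.has_duplicates:
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate feature ids: {dups[:5]}")
    if df.columns.has_duplicates:
        raise ValueError("duplicate sample ids in header")
    if (df.to_numpy() < 0).any():
        raise ValueError("negative counts")
    return df


def write_counts(counts: pd.DataFrame, path: str | os.PathLike) -> None:
    counts.to_csv(path, sep="\t", index_label="feature_id")


def read_table(path: str | os.PathLike, index_col=0) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=index_col)


def write_table(df: pd.DataFrame, path: str | os.PathLike, index_label=None) -> None:
    df.to_csv(path, sep="\t", index_label=index_label)


def read_tx2gene(path: str | os.PathLike) -> pd.Series:
    """Read a transcript-to-gene map (two TSV columns: transcript_id, gene_id).

    Returns a Series indexed by transcript id.  Every transcript must map to
    exactly one gene.
    """
    df = pd.read_csv(path, sep="\t")
    if df.shape[1] < 2:
        raise ValueError("tx2gene file needs at least two columns")
    tx, gene = df.columns[0], df.columns[1]
    if df[tx].duplicated().any():
        raise ValueError("a transcript maps to more than one gene")
    return df.set_index(tx)[gene]


def write_tx2gene(tx2gene: pd.Series, path: str | os.PathLike) -> None:
    tx2gene.rename("gene_id").to_csv(path, sep="\t", index_label="transcript_id")


def read_gmt(path: str | os.PathLike) -> dict[str, list[str]]:
    """Read a GMT gene-set collection: ``name<TAB>description<TAB>gene...``."""
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"malformed GMT line: {fields[0]!r}")
            genes = [g for g in fields[2:] if g]
            sets[fields[0]] = genes
    return sets


def write_gmt(sets: Mapping[str, list[str]], path: str | os.PathLike,
              description: str = "na") -> None:
    with open(path, "w") as fh:
        for name, genes in sets.items():
            fh.write("\t".join([name, description, *genes]) + "\n")
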