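"""Readers and writers for the pipeline's tab-separated artifacts.

All tables are TSV with header rows; expression matrices have genes as rows
and sample IDs as the header.  JSON is used for reports and ground truth.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

from .cerna import MiRNATargetDB

__all__ = [
    "read_expression_tsv",
    "write_expression_tsv",
    "read_phenotype_tsv",
    "write_phenotype_tsv",
    "read_biotypes_tsv",
    "write_biotypes_tsv",
    "read_mirna_targets_tsv",
    "write_mirna_targets_tsv",
    "read_edges_tsv",
    "write_edges_tsv",
    "read_gene_list",
    "write_gene_list",
    "read_gmt",
    "write_gmt",
    "read_json",
    "write_json",
]


def read_expression_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index.name = "gene_id"
    return df


def write_expression_tsv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index_label="gene_id", float_format="%.10g")


def read_phenotype_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def write_phenotype_tsv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index_label="sample_id")


def read_biotypes_tsv(path) -> pd.Series:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return df["biotype"]


def write_biotypes_tsv(biotypes: pd.Series, path) -> None:
    biotypes.rename("biotype").to_csv(path, sep="\t", index_label="gene_id")


def read_mirna_targets_tsv(path) -> MiRNATargetDB:
    return MiRNATargetDB.from_frame(pd.read_csv(path, sep="\t"))


def write_mirna_targets_tsv(db: MiRNATargetDB, path) -> None:
    db.to_frame().to_csv(path, sep="\t", index=False)


def read_edges_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_edges_tsv(edges: pd.DataFrame, path) -> None:
    edges.to_csv(path, sep="\t", index=False)


def read_gene_list(path) -> list[str]:
    with open(path) as fh:
        return [line.strip() for line in fh if line.strip()]


def write_gene_list(genes: Iterable[str], path) -> None:
    with open(path, "w") as fh:
        for g in genes:
            fh.write(f"{g}\n")


def read_gmt(path) -> dict[str, frozenset]:
    from .pathways import parse_gmt

    with open(path) as fh:
        return dict(parse_gmt(fh).sets)


def write_gmt(gene_sets: Mapping[str, Iterable[str]], path) -> None:
    with open(path, "w") as fh:
        for name in sorted(gene_sets):
            genes = "\t".join(sorted(gene_sets[name]))
            fh.write(f"{name}\tsynthetic\t{genes}\n")


def read_json(path) -> dict:
    with open(path) as fh:
        return json.load(fh)


def write_json(obj, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")
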