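"""Data containers and plain-text I/O.

Expression data travel as TSV with the gene id in the first column and
sample metadata encoded in the header: ``condition:arm:replicate`` for
replicated treatment/control sets and ``condition:timepoint:replicate``
for time series. Promoters are FASTA with one record per gene.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "ExpressionSet",
    "read_expression_tsv",
    "write_expression_tsv",
    "read_matrix_tsv",
    "write_matrix_tsv",
    "read_promoters_fasta",
    "write_promoters_fasta",
    "read_gene_list",
    "write_gene_list",
    "read_annotation_tsv",
]


@dataclass
class ExpressionSet:
    """Replicated log2 expression for one or more conditions.

    Attributes
    ----------
    values : pandas.DataFrame
        genes x samples matrix of finite log2 intensities; index = unique
        gene ids, columns = sample names.
    samples : pandas.DataFrame
        one row per sample (index aligned with ``values.columns``) with
        columns ``condition``, ``arm`` ('treated'/'control'), ``replicate``.
    """

    values: pd.DataFrame
    samples: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        if self.values.index.duplicated().any():
            raise ValueError("duplicate gene ids in ExpressionSet")
        if not np.isfinite(self.values.to_numpy(dtype=float)).all():
            raise ValueError("non-finite expression values")
        if not self.values.columns.equals(self.samples.index):
            raise ValueError("sample metadata does not match value columns")

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    def conditions(self) -> list[str]:
        return list(dict.fromkeys(self.samples["condition"]))

    def arm(self, condition: str, arm: str) -> pd.DataFrame:
        """Sub-matrix of samples for one condition/arm, ordered by replicate."""
        mask = (self.samples["condition"] == condition) & (self.samples["arm"] == arm)
        cols = self.samples.index[mask]
        if len(cols) == 0:
            raise KeyError(f"no samples for condition={condition!r} arm={arm!r}")
        order = self.samples.loc[cols, "replicate"].sort_values(kind="stable").index
        return self.values[order]


def _encode_columns(samples: pd.DataFrame) -> list[str]:
    return [
        f"{r.condition}:{r.arm}:{r.replicate}" for r in samples.itertuples(index=False)
    ]


def write_expression_tsv(es: ExpressionSet, path: str | Path) -> None:
    df = es.values.copy()
    df.columns = _encode_columns(es.samples)
    df.to_csv(path, sep="\t", index_label="gene")


def read_expression_tsv(path: str | Path) -> ExpressionSet:
    df = pd.read_csv(path, sep="\t", index_col=0)
    meta = []
    for col in df.columns:
        parts = col.split(":")
        if len(parts) != 3:
            raise ValueError(f"sample header {col!r} is not condition:arm:replicate")
        meta.append(parts)
    samples = pd.DataFrame(meta, columns=["condition", "arm", "replicate"], index=df.columns)
    return ExpressionSet(values=df, samples=samples)


def write_matrix_tsv(df: pd.DataFrame, path: str | Path) -> None:
    """Plain genes x columns matrix (time series, presence matrices, PPMs)."""
    df.to_csv(path, sep="\t", index_label="gene")


def read_matrix_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def write_promoters_fasta(promoters: Mapping[str, str], path: str | Path) -> None:
    records = [SeqRecord(Seq(seq), id=gene, description="") for gene, seq in promoters.items()]
    SeqIO.write(records, str(path), "fasta")


def read_promoters_fasta(path: str | Path) -> dict[str, str]:
    out: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in out:
            raise ValueError(f"duplicate promoter record {rec.id!r}")
        out[rec.id] = str(rec.seq).upper()
    return out


def write_gene_list(genes, path: str | Path) -> None:
    Path(path).write_text("".join(f"{g}\n" for g in genes))


def read_gene_list(path: str | Path) -> list[str]:
    return [ln.strip() for ln in Path(path).read_text().splitlines() if ln.strip()]


def read_annotation_tsv(path: str | Path) -> dict[str, set[str]]:
    """Two-column term<TAB>gene map -> term -> gene set."""
    ann: dict[str, set[str]] = {}
    for ln in Path(path).read_text().splitlines():
        if not ln.strip() or ln.startswith("#"):
            continue
        term, gene = ln.split("\t")[:2]
        ann.setdefault(term, set()).add(gene)
    return ann
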