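"""Readers and writers for the plain-text formats the pipeline exchanges.

Everything on disk is deterministic, ordered text: FASTA (genome, sRNA
reads, 20mers, mature miRNAs), GFF3 gene models (1-based inclusive
coordinates, strand +/-), and TSV tables with a header row (expression
matrices, designs, GO annotations, count tables).
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a FASTA file into an ordered ``{id: sequence}`` mapping."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(path: str | Path, records: Mapping[str, str]) -> None:
    seqrecs = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in records.items()
    ]
    SeqIO.write(seqrecs, str(path), "fasta")


# ---------------------------------------------------------------------------
# GFF3 gene models


@dataclasses.dataclass(frozen=True)
class GeneModel:
    """One mRNA/gene feature: 1-based inclusive coordinates, strand +/-."""

    gene_id: str
    seqid: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if self.start < 1 or self.end < self.start:
            raise ValueError(
                f"invalid coordinates {self.start}..{self.end} for {self.gene_id}"
            )
        if self.strand not in {"+", "-"}:
            raise ValueError(f"invalid strand {self.strand!r} for {self.gene_id}")


def read_gff3(path: str | Path) -> list[GeneModel]:
    """Read mRNA/gene features from a GFF3 file."""
    import gffutils

    db = gffutils.create_db(
        str(path),
        ":memory:",
        merge_strategy="create_unique",
        keep_order=True,
    )
    models = []
    for feat in db.all_features(order_by=("seqid", "start")):
        if feat.featuretype not in {"gene", "mRNA"}:
            continue
        fid = feat.attributes.get("ID", [feat.id])[0]
        models.append(
            GeneModel(
                gene_id=fid,
                seqid=feat.seqid,
                start=feat.start,
                end=feat.end,
                strand=feat.strand,
            )
        )
    return models


def write_gff3(path: str | Path, models: Iterable[GeneModel]) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for m in models:
            fh.write(
                f"{m.seqid}\tmircompass\tgene\t{m.start}\t{m.end}\t.\t{m.strand}\t.\t"
                f"ID={m.gene_id}\n"
            )


# ---------------------------------------------------------------------------
# TSV tables


def read_expression(path: str | Path) -> pd.DataFrame:
    """Read a genes x samples log2 expression matrix (first column = gene id)."""
    return pd.read_csv(path, sep="\t", index_col=0)


def write_expression(path: str | Path, matrix: pd.DataFrame) -> None:
    matrix.to_csv(path, sep="\t", index_label="gene")


def read_design(path: str | Path) -> pd.Series:
    """Read a two-column sample -> group design table."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    return df.iloc[:, 0]


def write_design(path: str | Path, design: pd.Series) -> None:
    design.rename("group").to_csv(path, sep="\t", index_label="sample")


def read_annotations(path: str | Path) -> dict[str, list[str]]:
    """Read a gene -> GO category multimap from a two-column TSV."""
    df = pd.read_csv(path, sep="\t")
    out: dict[str, list[str]] = {}
    for gene, cat in zip(df.iloc[:, 0], df.iloc[:, 1]):
        out.setdefault(str(gene), []).append(str(cat))
    return out


def write_annotations(path: str | Path, annotations: Mapping[str, Iterable[str]]) -> None:
    rows = [
        {"gene": gene, "category": cat}
        for gene in annotations
        for cat in annotations[gene]
    ]
    pd.DataFrame(rows, columns=["gene", "category"]).to_csv(path, sep="\t", index=False)


def read_gene_list(path: str | Path) -> list[str]:
    with open(path) as fh:
        return [line.strip() for line in fh if line.strip()]


def write_gene_list(path: str | Path, genes: Iterable[str]) -> None:
    with open(path, "w") as fh:
        for g in genes:
            fh.write(f"{g}\n")
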