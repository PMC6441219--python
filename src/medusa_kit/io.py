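"""File-format adapters: FASTA, GFF3, BED6 and TSV conventions.

All genomic coordinates are 0-based half-open in memory; GFF3 (1-based
inclusive) is converted at this boundary, BED stays 0-based half-open.
"""

from __future__ import annotations

import os
from typing import Iterable, Mapping

import gffutils
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .rare import GeneModel, RareSite

__all__ = [
    "read_fasta",
    "write_fasta",
    "read_gff3_genes",
    "write_gff3_genes",
    "write_bed6",
    "read_bed6_sites",
    "read_tsv",
    "write_tsv",
]


def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(os.fspath(path), "fasta")}


def write_fasta(path, sequences: Mapping[str, str]) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()
    ]
    SeqIO.write(records, os.fspath(path), "fasta")  # 60-column wrap


def read_gff3_genes(path) -> list[GeneModel]:
    """Read ``gene`` features from a GFF3 file as 0-based GeneModels."""
    db = gffutils.create_db(
        os.fspath(path), dbfn=":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )
    genes = []
    for feat in db.features_of_type("gene"):
        genes.append(
            GeneModel(
                gene_id=feat.id,
                chrom=feat.seqid,
                start=feat.start - 1,   # GFF3 1-based inclusive -> 0-based
                end=feat.end,
                strand=feat.strand,
            )
        )
    genes.sort(key=lambda g: (g.chrom, g.start, g.gene_id))
    return genes


def write_gff3_genes(path, genes: Iterable[GeneModel], source: str = "medusa_kit") -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in sorted(genes, key=lambda g: (g.chrom, g.start, g.gene_id)):
            fh.write(
                f"{g.chrom}\t{source}\tgene\t{g.start + 1}\t{g.end}\t.\t"
                f"{g.strand}\t.\tID={g.gene_id}\n"
            )


def write_bed6(path, sites: Iterable[RareSite]) -> None:
    """BED6: name = motif class, score = number of merged raw matches."""
    with open(path, "w") as fh:
        for s in sites:
            fh.write(
                f"{s.chrom}\t{s.start}\t{s.end}\t{s.motif_class}\t"
                f"{s.merged_from}\t{s.strand}\n"
            )


def read_bed6_sites(path) -> list[RareSite]:
    sites = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            chrom, start, end, name, score, strand = line.split("\t")[:6]
            sites.append(
                RareSite(chrom, int(start), int(end), strand, name, int(score))
            )
    return sites


def read_tsv(path, **kwargs) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", **kwargs)


def write_tsv(df: pd.DataFrame, path, index: bool = False, float_format="%.10g") -> None:
    df.to_csv(path, sep="\t", index=index, float_format=float_format)
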