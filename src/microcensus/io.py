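"""FASTA / TSV readers and writers used across pipeline stages."""

from __future__ import annotations

from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import DataError
from .simulate import RefRecord, ReferenceSet


def read_fasta(path) -> dict[str, str]:
    """Read a FASTA file into an ordered {id: uppercase sequence} dict."""
    seqs: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seqs:
            raise DataError(f"duplicate sequence id {rec.id!r} in {path}")
        seqs[rec.id] = str(rec.seq).upper()
    if not seqs:
        raise DataError(f"no sequences in {path}")
    return seqs


def write_fasta(sequences: dict[str, str], path) -> None:
    records = [SeqRecord(Seq(seq), id=qid, description="")
               for qid, seq in sequences.items()]
    SeqIO.write(records, str(path), "fasta")


def write_reference_set(refs: ReferenceSet, fasta_path, taxonomy_path=None) -> None:
    """Write a reference set as FASTA plus a taxonomy/metadata TSV."""
    write_fasta(refs.sequences(), fasta_path)
    if taxonomy_path is not None:
        pd.DataFrame(
            [(r.id, r.domain, r.taxonomy, r.cultured) for r in refs],
            columns=["id", "domain", "taxonomy", "cultured"],
        ).to_csv(taxonomy_path, sep="\t", index=False)


def read_reference_set(fasta_path, taxonomy_path=None) -> ReferenceSet:
    """Read a reference set; without a taxonomy TSV, placeholder ranks are used."""
    seqs = read_fasta(fasta_path)
    if taxonomy_path is not None:
        tax = pd.read_csv(taxonomy_path, sep="\t").set_index("id")
        records = tuple(
            RefRecord(id=rid, sequence=seq,
                      domain=str(tax.loc[rid, "domain"]),
                      taxonomy=str(tax.loc[rid, "taxonomy"]),
                      cultured=bool(tax.loc[rid, "cultured"]))
            for rid, seq in seqs.items()
        )
    else:
        placeholder = ";".join(["unclassified"] * 7)
        records = tuple(
            RefRecord(id=rid, sequence=seq, domain="bacteria",
                      taxonomy=placeholder)
            for rid, seq in seqs.items()
        )
    return ReferenceSet(records)


def read_metadata(path) -> pd.DataFrame:
    """Read the per-query metadata TSV (query_id, domain, dataset_type, ...)."""
    df = pd.read_csv(path, sep="\t")
    if "query_id" not in df.columns:
        raise DataError(f"metadata {path} lacks a query_id column")
    if df["query_id"].duplicated().any():
        raise DataError(f"duplicate query_id in {path}")
    return df


def write_tsv(df: pd.DataFrame, path, index: bool = False) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=index)


def read_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
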