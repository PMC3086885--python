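"""Readers and writers for the plain-text formats the pipeline exchanges.

FASTA goes through Biopython; the tabular formats (sRNA reads, degradome
tags, gene annotations, HSP tables) are TSVs handled with pandas.  GFF3 is
emitted 1-based inclusive per the standard; everything in memory stays
0-based half-open.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .sequtil import normalize

SRNA_COLUMNS = ["sequence", "dataset_id", "count"]
DEGRADOME_COLUMNS = ["cdna_id", "dataset_id", "position", "count"]


def read_fasta(path: str | Path) -> dict[str, str]:
    """FASTA -> {id: sequence} (uppercase DNA)."""
    return {rec.id: normalize(str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")}


def read_fasta_with_descriptions(path: str | Path) -> dict[str, tuple[str, str]]:
    """FASTA -> {id: (sequence, description)}; description excludes the id."""
    out = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        desc = rec.description
        if desc.startswith(rec.id):
            desc = desc[len(rec.id):].strip()
        out[rec.id] = (normalize(str(rec.seq)), desc)
    return out


def write_fasta(records: Mapping[str, str] | Iterable[tuple[str, str, str]],
                path: str | Path) -> None:
    """Write {id: seq} or an iterable of (id, description, seq) as FASTA."""
    if isinstance(records, Mapping):
        recs = [SeqRecord(Seq(s), id=k, description="") for k, s in records.items()]
    else:
        recs = [SeqRecord(Seq(s), id=k, description=d) for k, d, s in records]
    with open(path, "w") as fh:
        SeqIO.write(recs, fh, "fasta")


def read_srna_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"sequence": str, "dataset_id": str})
    missing = set(SRNA_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"sRNA table {path} lacks columns {sorted(missing)}")
    df["sequence"] = df["sequence"].map(normalize)
    return df


def write_srna_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False, columns=SRNA_COLUMNS)


def read_degradome_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"cdna_id": str, "dataset_id": str})
    missing = set(DEGRADOME_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"degradome table {path} lacks columns {sorted(missing)}")
    return df


def write_degradome_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False, columns=DEGRADOME_COLUMNS)


def read_annotation_table(path: str | Path) -> dict[str, str]:
    """Gene annotation TSV (gene_id, description) -> dict."""
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    return dict(zip(df["gene_id"], df["description"]))


def write_annotation_table(annotations: Mapping[str, str], path: str | Path) -> None:
    pd.DataFrame(
        {"gene_id": list(annotations), "description": list(annotations.values())}
    ).to_csv(path, sep="\t", index=False)


def write_gff3(features: Iterable[dict], path: str | Path) -> None:
    """Write features as GFF3 (1-based inclusive).

    Each feature dict carries: chrom, source, type, start, end (0-based
    half-open), strand, attributes (dict).
    """
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for f in features:
            attrs = ";".join(f"{k}={v}" for k, v in f["attributes"].items())
            fh.write(
                "\t".join([
                    f["chrom"], f.get("source", "temir"), f["type"],
                    str(f["start"] + 1), str(f["end"]), ".",
                    f.get("strand", "+"), ".", attrs,
                ]) + "\n"
            )


def write_json(obj, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_json(path: str | Path):
    with open(path) as fh:
        return json.load(fh)
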