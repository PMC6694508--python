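"""Readers and writers for the plain-text formats the pipeline exchanges.

FASTA parsing goes through Biopython; FASTQ writing is a tight manual loop
because simulated libraries run to hundreds of thousands of records.  GFF3 is
read into a DataFrame (it is a 9-column TSV) and written line by line.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Iterator

import pandas as pd
from Bio import SeqIO

GFF_COLUMNS = [
    "seqid", "source", "type", "start", "end",
    "score", "strand", "phase", "attributes",
]

_COMP = str.maketrans("ACGTUacgtu", "TGCAATGCAA")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def read_fasta(path: str | Path) -> dict[str, str]:
    """Load a FASTA file as {id: uppercase sequence} preserving order."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(seqs: dict[str, str], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_fastq(path: str | Path) -> Iterator[tuple[str, str, str]]:
    """Yield (id, sequence, quality string) tuples."""
    with open(path) as fh:
        while True:
            header = fh.readline()
            if not header:
                return
            seq = fh.readline().rstrip("\n")
            fh.readline()
            qual = fh.readline().rstrip("\n")
            yield header[1:].split()[0], seq, qual


def write_fastq(records: Iterable[tuple[str, str, str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, seq, qual in records:
            fh.write(f"@{name}\n{seq}\n+\n{qual}\n")


def read_gff3(path: str | Path) -> pd.DataFrame:
    """Read GFF3 into a DataFrame with 1-based inclusive start/end."""
    df = pd.read_csv(
        path, sep="\t", comment="#", header=None, names=GFF_COLUMNS,
        dtype={"seqid": str, "source": str, "type": str, "attributes": str},
    )
    df["start"] = df["start"].astype(int)
    df["end"] = df["end"].astype(int)
    ids = df["attributes"].str.extract(r"ID=([^;]+)")[0]
    df["feature_id"] = ids
    return df


def write_gff3(df: pd.DataFrame, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for row in df.itertuples(index=False):
            fh.write(
                f"{row.seqid}\t{row.source}\t{row.type}\t{row.start}\t{row.end}"
                f"\t{row.score}\t{row.strand}\t{row.phase}\t{row.attributes}\n"
            )
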