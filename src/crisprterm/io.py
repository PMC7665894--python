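"""File-format helpers: FASTA/FASTQ via Biopython, bedGraph/BED/TSV via pandas.

All genomic coordinates in this package are 0-based, half-open (BED
convention).  bedGraph tracks are the 4-column variant
(chrom, start, end, value); dense per-position arrays are run-length
encoded on write and expanded on read.
"""

from __future__ import annotations

import gzip
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (N maps to N)."""
    return seq.translate(_COMPLEMENT)[::-1]


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a FASTA file into an ordered {id: sequence} dict (uppercased)."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(records: Iterable[tuple[str, str]], path: str | Path,
                descriptions: dict[str, str] | None = None) -> None:
    descriptions = descriptions or {}
    recs = [
        SeqRecord(Seq(seq), id=name, description=descriptions.get(name, ""))
        for name, seq in records
    ]
    SeqIO.write(recs, str(path), "fasta")


def read_fastq_seqs(path: str | Path) -> list[str]:
    """Read sequences (only) from a FASTQ file, optionally gzip-compressed."""
    path = str(path)
    if path.endswith(".gz"):
        with gzip.open(path, "rt") as fh:
            return [str(r.seq).upper() for r in SeqIO.parse(fh, "fastq")]
    return [str(r.seq).upper() for r in SeqIO.parse(path, "fastq")]


def write_fastq(reads: Iterable[tuple[str, str]], path: str | Path) -> None:
    """Write (read_id, sequence) pairs as FASTQ with uniform quality."""
    with open(path, "w") as fh:
        for rid, seq in reads:
            fh.write(f"@{rid}\n{seq}\n+\n{'I' * len(seq)}\n")


def write_bedgraph(track: np.ndarray, chrom: str, path: str | Path) -> None:
    """Run-length encode a dense per-position track to 4-column bedGraph."""
    vals = np.asarray(track, dtype=float)
    if vals.size == 0:
        Path(path).write_text("")
        return
    change = np.flatnonzero(np.diff(vals) != 0)
    starts = np.concatenate([[0], change + 1])
    ends = np.concatenate([change + 1, [vals.size]])
    with open(path, "w") as fh:
        for s, e in zip(starts, ends):
            v = vals[s]
            if v != 0:
                fh.write(f"{chrom}\t{s}\t{e}\t{v:g}\n")


def read_bedgraph(path: str | Path, length: int, chrom: str | None = None) -> np.ndarray:
    """Expand a 4-column bedGraph into a dense float array of `length`."""
    track = np.zeros(length, dtype=float)
    df = pd.read_csv(path, sep="\t", header=None,
                     names=["chrom", "start", "end", "value"],
                     dtype={"chrom": str})
    if chrom is not None:
        df = df[df["chrom"] == chrom]
    for start, end, value in df[["start", "end", "value"]].itertuples(index=False):
        track[int(start):int(end)] = value
    return track


def read_bed_positions(path: str | Path) -> pd.DataFrame:
    """Read a BED file of peaks; peak position = interval midpoint."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    df = df.rename(columns={0: "chrom", 1: "start", 2: "end"})
    df["position"] = (df["start"] + df["end"]) // 2
    return df[["chrom", "position"]]


def write_tsv(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
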