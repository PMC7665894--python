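"""CRISPR array parsing and cas2-flank extraction/trimming.

A CRISPR array is a run of identical direct repeats alternating with
variable spacers, transcribed from a leader-proximal promoter; spacer 1
is the spacer closest to the leader.  The phylogenetic boxA screen
extracts the 300 bp downstream of each cas2 gene (cas2 usually sits
immediately upstream of the array), trims each flank at the first
recurring 15-mer (the start of the array's first repeat), and discards
flanks without a repeat or trimmed below 20 bp.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import pandas as pd

from .io import revcomp


class CoordinateError(ValueError):
    """Interval falls outside the contig."""


class ParseError(ValueError):
    """Region does not contain a parseable array."""


@dataclass
class Spacer:
    index: int          # 1-based, leader-proximal numbering
    seq: str
    start: int = -1     # genomic coords of the spacer, half-open
    end: int = -1


@dataclass
class CrisprArray:
    array_id: str
    chrom: str
    strand: str
    repeat_seq: str
    spacers: list[Spacer]
    leader: tuple[int, int] | None = None
    boxa: tuple[int, int] | None = None
    boxa_seq: str | None = None

    @property
    def n_spacers(self) -> int:
        return len(self.spacers)

    def spacer_dict(self) -> dict[str, str]:
        """{spacer_id: sequence} with ids like 'CRISPR-I:3'."""
        return {f"{self.array_id}:{s.index}": s.seq for s in self.spacers}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "array_id": self.array_id,
                "chrom": self.chrom,
                "strand": self.strand,
                "repeat": self.repeat_seq,
                "spacer_index": [s.index for s in self.spacers],
                "spacer_seq": [s.seq for s in self.spacers],
                "start": [s.start for s in self.spacers],
                "end": [s.end for s in self.spacers],
            }
        )


@dataclass
class FlankRecord:
    genus: str
    source_id: str
    raw: str
    trimmed: str = ""
    status: str = "raw"           # raw | kept | no_repeat | too_short
    truncated: bool = False


def extract_cas2_flank(genome: str, cas2_start: int, cas2_end: int, strand: str,
                       length: int = 300, genus: str = "", source_id: str = "") -> FlankRecord:
    """Extract `length` bp immediately 3' of a cas2 gene, in cas2's orientation.

    Plus-strand cas2 ending at e yields genome[e, e+length); minus-strand
    cas2 starting at s yields the reverse complement of genome[s-length, s).
    Flanks shorter than `length` because of the contig edge are flagged
    truncated.
    """
    if not (0 <= cas2_start < cas2_end <= len(genome)):
        raise CoordinateError(
            f"cas2 interval [{cas2_start},{cas2_end}) outside contig of length {len(genome)}")
    if strand == "+":
        raw = genome[cas2_end:cas2_end + length]
    elif strand == "-":
        raw = revcomp(genome[max(0, cas2_start - length):cas2_start])
    else:
        raise ValueError(f"strand must be '+' or '-', got {strand!r}")
    return FlankRecord(genus=genus, source_id=source_id, raw=raw.upper(),
                       truncated=len(raw) < length)


def extract_opposite_flank(genome: str, array_start: int, array_end: int,
                           strand: str = "+", length: int = 300) -> tuple[str, bool]:
    """300 bp adjacent to the cas2-distal end of an array, oriented toward it.

    Used to screen type II-C systems whose arrays run opposite to cas2:
    for a plus-strand array with cas2 upstream, this is the reverse
    complement of genome[array_end, array_end+length).  Returns
    (sequence, truncated_flag).
    """
    if not (0 <= array_start < array_end <= len(genome)):
        raise CoordinateError(
            f"array interval [{array_start},{array_end}) outside contig")
    if strand == "+":
        raw = genome[array_end:array_end + length]
        return revcomp(raw), len(raw) < length
    raw = genome[max(0, array_start - length):array_start]
    return raw, len(raw) < length


def find_first_repeat15(seq: str, k: int = 15) -> int | None:
    """Smallest offset p whose k-mer recurs at some q > p; None if no repeat.

    Exact matching only; k-mers containing N never match.
    """
    seq = seq.upper()
    first: dict[str, int] = {}
    duplicated_firsts = []
    for p in range(len(seq) - k + 1):
        kmer = seq[p:p + k]
        if "N" in kmer:
            continue
        if kmer in first:
            duplicated_firsts.append(first[kmer])
        else:
            first[kmer] = p
    return min(duplicated_firsts) if duplicated_firsts else None


def trim_and_filter(flank: FlankRecord, min_keep: int = 20) -> FlankRecord:
    """Trim a flank at the first recurring 15-mer and apply the discard rules.

    kept: a repeat exists at offset p >= min_keep (trimmed = raw[:p]);
    too_short: repeat at p < min_keep; no_repeat: no recurring 15-mer.
    """
    p = find_first_repeat15(flank.raw)
    if p is None:
        return replace(flank, trimmed="", status="no_repeat")
    if p < min_keep:
        return replace(flank, trimmed=flank.raw[:p], status="too_short")
    return replace(flank, trimmed=flank.raw[:p], status="kept")


def _find_occurrences(region: str, repeat: str, max_mismatch: int) -> list[int]:
    """Leftmost-greedy non-overlapping occurrences of `repeat` in `region`."""
    hits = []
    n, m = len(region), len(repeat)
    pos = 0
    while pos <= n - m:
        window = region[pos:pos + m]
        if max_mismatch == 0:
            nxt = region.find(repeat, pos)
            if nxt == -1:
                break
            hits.append(nxt)
            pos = nxt + m
            continue
        mism = sum(1 for a, b in zip(window, repeat)
                   if a != b or a == "N" or b == "N")
        if mism <= max_mismatch:
            hits.append(pos)
            pos += m
        else:
            pos += 1
    return hits


def parse_array(region: str, repeat_seq: str, array_id: str = "array",
                chrom: str = "", strand: str = "+", offset: int = 0,
                max_mismatch: int = 0) -> CrisprArray:
    """Parse repeats/spacers out of a leader-first genomic region.

    Spacers are the maximal segments strictly between consecutive repeat
    occurrences (exact by default; an optional mismatch budget tolerates a
    degenerate terminal repeat), numbered 1..n from the leader-proximal
    end.  `offset` shifts reported coordinates to genome space.
    """
    region = region.upper()
    repeat_seq = repeat_seq.upper()
    occ = _find_occurrences(region, repeat_seq, max_mismatch)
    if len(occ) < 2:
        raise ParseError(
            f"need >= 2 repeat occurrences to define spacers, found {len(occ)}")
    m = len(repeat_seq)
    spacers = []
    for i in range(len(occ) - 1):
        s, e = occ[i] + m, occ[i + 1]
        spacers.append(Spacer(index=i + 1, seq=region[s:e],
                              start=offset + s, end=offset + e))
    return CrisprArray(array_id=array_id, chrom=chrom, strand=strand,
                       repeat_seq=repeat_seq, spacers=spacers,
                       leader=(offset, offset + occ[0]))


def flanks_to_fasta_records(flanks: list[FlankRecord]) -> list[tuple[str, str]]:
    """(id, sequence) pairs for FASTA export; status goes in the id line."""
    return [(f"{f.source_id}|{f.genus}|{f.status}",
             f.trimmed if f.status == "kept" else f.raw) for f in flanks]
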