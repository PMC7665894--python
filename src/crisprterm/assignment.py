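"""Cascade off-target matching: link ChIP-seq peaks to CRISPR spacers.

Type I-E Cascade tolerates extensive mismatches outside the PAM-proximal
seed, so crRNAs direct it to many chromosomal off-target sites.  A peak
region is searched for two kinds of evidence that a given spacer's crRNA
could have recruited Cascade there:

* PAM_SEED5 — an AAG or ATG PAM immediately 5' of a perfect match to
  spacer positions 1-5 (the seed), on either strand;
* SEED5_78 — a perfect match to positions 1-5 and 7-8 with no PAM
  required (position 6 is not read out by Cascade).

A peak is assigned a spacer only when exactly one distinct spacer
identity matches anywhere in its region.  Spacers with identical
sequence are collapsed to a single identity first so duplicates cannot
manufacture ambiguity.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .io import revcomp

DEFAULT_PAMS = ("AAG", "ATG")
PAM_SEED5 = "PAM_SEED5"
SEED5_78 = "SEED5_78"


@dataclass(frozen=True)
class SpacerMatch:
    spacer_id: str
    strand: str          # strand of the protospacer within the region
    offset: int          # protospacer start, in coords of the matched strand
    mode: str            # PAM_SEED5 | SEED5_78
    pam: str             # 3-mer for PAM_SEED5 hits, "" otherwise


@dataclass
class PeakRecord:
    chrom: str
    positions: list[int]                 # input peak positions merged into this region
    region: tuple[int, int]              # 0-based half-open
    center: int
    seq: str = ""
    matches: list[SpacerMatch] = field(default_factory=list)
    candidates: frozenset[str] = frozenset()
    status: str = "unassigned"           # unique | ambiguous | unassigned
    provenance: str = ""                 # direct_unique | ratio_refined
    coverage: dict = field(default_factory=dict)   # sample -> peak-center value

    @property
    def assigned_spacer(self) -> str | None:
        return next(iter(self.candidates)) if self.status == "unique" else None


def build_regions(positions: list[int], width: int = 101,
                  contig_length: int | None = None,
                  chrom: str = "genome") -> list[PeakRecord]:
    """Expand peak positions to `width`-bp regions, merging overlaps.

    Each position p becomes [p - (width-1)/2, p + (width-1)/2] inclusive;
    overlapping or abutting intervals are merged and the floor midpoint of
    the merged interval becomes the peak center.  Regions are clipped to
    the contig.
    """
    if width % 2 != 1:
        raise ValueError("region width must be odd")
    half = (width - 1) // 2
    intervals = sorted((p - half, p + half + 1, p) for p in positions)
    merged: list[list] = []
    for s, e, p in intervals:
        if merged and s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
            merged[-1][2].append(p)
        else:
            merged.append([s, e, [p]])
    records = []
    for s, e, ps in merged:
        s = max(0, s)
        if contig_length is not None:
            e = min(e, contig_length)
        records.append(PeakRecord(chrom=chrom, positions=ps, region=(s, e),
                                  center=(s + e) // 2))
    return records


def _clean(window: str) -> bool:
    return "N" not in window


def find_matches(region_seq: str, spacers: dict[str, str],
                 pams: tuple[str, ...] = DEFAULT_PAMS) -> list[SpacerMatch]:
    """All seed/PAM matches of any spacer in a region, both strands.

    Scans each strand for occurrences of the 5-nt seed and checks the two
    match modes independently at every occurrence; a PAM_SEED5 hit does not
    suppress a SEED5_78 hit.  Windows containing N never match.
    """
    region_seq = region_seq.upper()
    for sid, sp in spacers.items():
        if len(sp) < 8:
            raise ValueError(f"spacer {sid} shorter than 8 nt")
    hits: list[SpacerMatch] = []
    for strand, seq in (("+", region_seq), ("-", revcomp(region_seq))):
        for sid, sp in spacers.items():
            sp = sp.upper()
            seed = sp[:5]
            if "N" in seed:
                continue
            q = seq.find(seed)
            while q != -1:
                if q >= 3:
                    pam = seq[q - 3:q]
                    if pam in pams and _clean(pam):
                        hits.append(SpacerMatch(sid, strand, q, PAM_SEED5, pam))
                if q + 8 <= len(seq):
                    p78 = seq[q + 6:q + 8]
                    if p78 == sp[6:8] and _clean(p78) and _clean(sp[6:8]):
                        hits.append(SpacerMatch(sid, strand, q, SEED5_78, ""))
                q = seq.find(seed, q + 1)
    return hits


def collapse_duplicate_spacers(spacers: dict[str, str]) -> tuple[dict[str, str], dict[str, str]]:
    """Merge spacers with identical sequence into one identity.

    Returns (collapsed {id: seq}, alias map {original_id: canonical_id});
    the canonical id joins member ids with '/' in input order (e.g. a
    spacer duplicated at positions 10 and 26 becomes '10/26').
    """
    by_seq: dict[str, list[str]] = {}
    for sid, seq in spacers.items():
        by_seq.setdefault(seq.upper(), []).append(sid)
    collapsed, alias = {}, {}
    for seq, ids in by_seq.items():
        canon = "/".join(ids)
        collapsed[canon] = seq
        for sid in ids:
            alias[sid] = canon
    return collapsed, alias


def assign(peaks: list[PeakRecord], spacers: dict[str, str],
           pams: tuple[str, ...] = DEFAULT_PAMS) -> list[PeakRecord]:
    """Attach matches and unique/ambiguous/unassigned status to each peak."""
    collapsed, _ = collapse_duplicate_spacers(spacers)
    for pk in peaks:
        pk.matches = find_matches(pk.seq, collapsed, pams)
        pk.candidates = frozenset(m.spacer_id for m in pk.matches)
        if len(pk.candidates) == 1:
            pk.status = "unique"
            pk.provenance = "direct_unique"
        elif len(pk.candidates) == 0:
            pk.status = "unassigned"
        else:
            pk.status = "ambiguous"
    return peaks


def assignment_summary(peaks: list[PeakRecord]) -> dict[str, int]:
    return {
        "total_peaks": len(peaks),
        "unique": sum(p.status == "unique" for p in peaks),
        "ambiguous": sum(p.status == "ambiguous" for p in peaks),
        "unassigned": sum(p.status == "unassigned" for p in peaks),
    }


def peaks_to_frame(peaks: list[PeakRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "chrom": [p.chrom for p in peaks],
            "start": [p.region[0] for p in peaks],
            "end": [p.region[1] for p in peaks],
            "center": [p.center for p in peaks],
            "status": [p.status for p in peaks],
            "provenance": [p.provenance for p in peaks],
            "candidates": [",".join(sorted(p.candidates)) for p in peaks],
            "assigned_spacer": [p.assigned_spacer or "" for p in peaks],
        }
    )
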