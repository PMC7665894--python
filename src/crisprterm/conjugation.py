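"""Pooled-conjugation interference: tag counting and double normalization.

A pool of protospacer-bearing plasmids (plus a no-protospacer control)
is conjugated into an interference-proficient strain and an
effector-deleted control strain; transconjugant amplicons are sequenced
and each read is assigned to a plasmid by an exact 10-nt tag within its
protospacer.  Per-plasmid conjugation efficiency is the read count
normalized first to the effector-deleted sample (removes pool and
transfer biases) and then to the control plasmid (removes sample depth),
expressed in percent.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .io import revcomp


class TaggingError(ValueError):
    pass


class NormalizationError(ValueError):
    pass


@dataclass(frozen=True)
class ProtospacerRef:
    id: str
    seq: str
    tag: str


def _collapse(protospacers: dict[str, str]) -> dict[str, str]:
    """Merge identical protospacer sequences into one reference identity."""
    by_seq: dict[str, list[str]] = {}
    for pid, seq in protospacers.items():
        by_seq.setdefault(seq.upper(), []).append(pid)
    return {"/".join(ids): seq for seq, ids in by_seq.items()}


def select_tags(protospacers: dict[str, str], tag_length: int = 10,
                control_seq: str | None = None) -> list[ProtospacerRef]:
    """Pick one unique tag k-mer per protospacer.

    Identical protospacers are collapsed first (ids joined with '/').  The
    default tag is the centered `tag_length`-mer; on collision — the
    candidate occurs (in either orientation) in another protospacer, in
    the control construct, or equals an already chosen tag — the window
    shifts outward one base at a time until a unique tag is found.
    """
    collapsed = _collapse(protospacers)
    for pid, seq in collapsed.items():
        if len(seq) < tag_length:
            raise TaggingError(f"protospacer {pid} shorter than {tag_length} nt")
    refs: list[ProtospacerRef] = []
    chosen: set[str] = set()
    failed: list[str] = []
    for pid, seq in collapsed.items():
        center = (len(seq) - tag_length) // 2
        offsets = [center]
        for d in range(1, len(seq)):
            for c in (center - d, center + d):
                if 0 <= c <= len(seq) - tag_length:
                    offsets.append(c)
        tag = None
        for off in offsets:
            cand = seq[off:off + tag_length]
            if "N" in cand or cand in chosen or revcomp(cand) in chosen:
                continue
            others = [s for p, s in collapsed.items() if p != pid]
            if control_seq:
                others.append(control_seq.upper())
            if any(cand in o or revcomp(cand) in o for o in others):
                continue
            tag = cand
            break
        if tag is None:
            failed.append(pid)
        else:
            chosen.add(tag)
            refs.append(ProtospacerRef(pid, seq, tag))
    if failed:
        raise TaggingError(f"no unique tag available for: {', '.join(failed)}")
    return refs


def count_reads(reads: list[str], refs: list[ProtospacerRef]
                ) -> tuple[dict[str, int], dict[str, int]]:
    """Assign reads to plasmids by exact tag match, either orientation.

    A read counts for a plasmid iff exactly one tag occurs in the read or
    its reverse complement; reads matching zero or multiple tags are
    discarded and tallied.  Returns (counts, {"no_tag": n, "multi_tag": n}).
    """
    counts = {r.id: 0 for r in refs}
    stats = {"no_tag": 0, "multi_tag": 0}
    for read in reads:
        read = read.upper()
        rc = revcomp(read)
        matched = [r.id for r in refs if r.tag in read or r.tag in rc]
        if len(matched) == 1:
            counts[matched[0]] += 1
        elif not matched:
            stats["no_tag"] += 1
        else:
            stats["multi_tag"] += 1
    return counts, stats


def filter_low(counts: pd.DataFrame, threshold: int = 50,
               control_sample: str = "dcascade") -> tuple[pd.DataFrame, list[str]]:
    """Drop plasmids with < threshold reads in any control-sample replicate.

    The effector-deleted (interference-free) sample measures how much of
    each plasmid entered recipients at all; plasmids below `threshold`
    reads there in either replicate are uninterpretable and removed.
    Returns (filtered counts, dropped plasmid ids).  Exactly `threshold`
    reads is retained.
    """
    ctrl = counts[counts["sample"] == control_sample]
    if ctrl.empty:
        raise ValueError(f"no counts for control sample {control_sample!r}")
    mins = ctrl.groupby("plasmid")["count"].min()
    dropped = sorted(set(counts["plasmid"]) - set(mins.index))  # absent entirely
    dropped += sorted(mins.index[mins < threshold])
    kept = counts[~counts["plasmid"].isin(dropped)].reset_index(drop=True)
    return kept, dropped


def normalize_efficiency(counts: pd.DataFrame, control_id: str = "control",
                         cascade_sample: str = "dcascade") -> pd.DataFrame:
    """Doubly normalized conjugation efficiency (%) per plasmid/sample/replicate.

    eff = [count(p, s, r) / count(p, effector-deleted, r)]
        / [count(ctrl, s, r) / count(ctrl, effector-deleted, r)] * 100.

    The control plasmid therefore scores exactly 100% in every sample.
    """
    wide = counts.pivot_table(index="plasmid", columns=["sample", "replicate"],
                              values="count", aggfunc="sum")
    if control_id not in wide.index:
        raise NormalizationError(f"control plasmid {control_id!r} missing")
    samples = [s for s in wide.columns.get_level_values(0).unique()
               if s != cascade_sample]
    rows = []
    for sample in samples:
        for rep in wide[sample].columns:
            c_ctrl_s = wide.at[control_id, (sample, rep)]
            c_ctrl_d = wide.at[control_id, (cascade_sample, rep)]
            if c_ctrl_s <= 0 or c_ctrl_d <= 0:
                raise NormalizationError(
                    f"control plasmid has zero reads in {sample}/{cascade_sample} rep {rep}")
            for pid in wide.index:
                c_d = wide.at[pid, (cascade_sample, rep)]
                if c_d <= 0:
                    continue   # unreachable after filter_low; defensive
                eff = (wide.at[pid, (sample, rep)] / c_d) / (c_ctrl_s / c_ctrl_d) * 100.0
                rows.append({"plasmid": pid, "sample": sample, "replicate": rep,
                             "efficiency_pct": float(eff)})
    return pd.DataFrame(rows)


def efficiency_range(efficiencies: pd.DataFrame) -> pd.DataFrame:
    """Min-max range of efficiency across replicates, per plasmid and sample."""
    return (efficiencies.groupby(["plasmid", "sample"])["efficiency_pct"]
            .agg(["min", "max", "mean"]).reset_index())
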