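#!/usr/bin/env python
"""Pooled-conjugation interference on a synthetic 39-protospacer pool.

Emulates the plasmid-pool assay: 39 protospacer plasmids plus a
no-protospacer control conjugated into an effector-deleted strain, an
interference-proficient (boxA+) strain, and a boxA-mutant strain in
duplicate.  True efficiencies mirror the published pattern: strong
interference (0.1-1% of control) for most spacers in the boxA+ strain;
in the boxA-mutant, spacers beyond 19 escape interference with fold
increases up to the ~50-250x range; the last two spacers escape in both.
Reads are synthesized with embedded protospacers, tag-counted, filtered
at 50 reads, and doubly normalized.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from crisprterm.conjugation import (count_reads, efficiency_range, filter_low,
                                    normalize_efficiency, select_tags)
from crisprterm.io import write_tsv
from crisprterm.simulate import (make_reads_from_counts, random_dna,
                                 simulate_conjugation_counts)

SEED = 40
DEPTH = 100_000
OUT = Path("results")


def true_efficiencies(rng):
    """Per-protospacer efficiencies for the two interference strains."""
    boxa_wt, boxa_mut = {}, {}
    for i in range(1, 40):
        pid = f"proto{i:02d}"
        strong = float(10 ** rng.uniform(-3, -1))   # 0.1-10% of control
        if i >= 38:              # leader-distal spacers escape in both strains
            boxa_wt[pid] = 1.0 if i == 39 else 0.3
            boxa_mut[pid] = 1.0
        elif i >= 20:            # antitermination-dependent spacers
            boxa_wt[pid] = strong
            boxa_mut[pid] = min(1.0, strong * float(rng.uniform(45, 250)))
        else:                    # leader-proximal: active regardless of boxA
            boxa_wt[pid] = strong
            boxa_mut[pid] = strong
    return boxa_wt, boxa_mut


def main():
    OUT.mkdir(exist_ok=True)
    rng = np.random.default_rng(SEED)
    protos = {f"proto{i:02d}": random_dna(rng, 32) for i in range(1, 40)}
    boxa_wt, boxa_mut = true_efficiencies(rng)
    pool = {k: 1.0 for k in protos} | {"control": 1.0}
    samples = {"dcascade": {k: 1.0 for k in pool},
               "boxA_wt": {**boxa_wt, "control": 1.0},
               "boxA_mut": {**boxa_mut, "control": 1.0}}
    counts = simulate_conjugation_counts(pool, samples, depth=DEPTH, seed=SEED)

    # read-level round trip for one sample, then proceed on counts
    refs = select_tags(protos)
    sub = counts.query("sample=='dcascade' and replicate==1 and plasmid!='control'")
    reads = make_reads_from_counts(sub, protos, seed=SEED + 1)
    got, stats = count_reads(reads[("dcascade", 1)], refs)
    assert got == dict(sub.set_index("plasmid")["count"]), "tag counting drifted"

    kept, dropped = filter_low(counts, threshold=50, control_sample="dcascade")
    eff = normalize_efficiency(kept, control_id="control",
                               cascade_sample="dcascade")
    write_tsv(eff, OUT / "conjugation_efficiency.tsv")
    rng_df = efficiency_range(eff)
    write_tsv(rng_df, OUT / "conjugation_efficiency_range.tsv")

    mean = eff.groupby(["plasmid", "sample"])["efficiency_pct"].mean().unstack()
    fold = (mean["boxA_mut"] / mean["boxA_wt"]).drop("control")
    late = fold[[f"proto{i:02d}" for i in range(20, 38)]]
    print(f"read round-trip exact; dropped plasmids: {dropped or 'none'}")
    print(f"boxA_mut/boxA_wt fold increase, protospacers 20-37: "
          f"{late.min():.1f}-{late.max():.1f} (max overall {fold.max():.1f})")
    print(f"efficiencies -> {OUT / 'conjugation_efficiency.tsv'}")


if __name__ == "__main__":
    main()
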