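#!/usr/bin/env python
"""Generate the reference synthetic dataset.

A 60 kb genome carries two 23-spacer type I-E CRISPR arrays (leader,
boxA 78 bp upstream of the first repeat) and two planted Cascade
off-target sites per spacer.  crRNA abundance follows the Rho survival
model: the antitermination-intact strain keeps a low hazard everywhere;
the boxA-mutant strain's second array jumps to a high hazard after
spacer 8.  Duplicate strand-resolved coverage tracks are written for
both strains.
"""

from pathlib import Path

import pandas as pd

from crisprterm import (ArraySpec, SimulationConfig, TerminationModel,
                        make_crispr_genome, simulate_chip_coverage,
                        simulate_crrna_abundance, step_hazard)
from crisprterm.io import write_bedgraph, write_fasta, write_tsv

SEED = 20
OUT = Path("results/data")
N_SPACERS = 23
DEPTH = 200.0
RHO_PROTECTED = 0.02
RHO_UNPROTECTED = 0.15
CHANGEPOINT = 8


def main():
    OUT.mkdir(parents=True, exist_ok=True)
    cfg = SimulationConfig(
        seed=SEED, genome_length=60_000,
        arrays=[ArraySpec("CRISPR-I", N_SPACERS), ArraySpec("CRISPR-II", N_SPACERS)],
        offtargets_per_spacer=2, depth=DEPTH)
    genome, truth = make_crispr_genome(cfg)
    write_fasta([("chr", genome)], OUT / "genome.fasta")
    write_tsv(truth.sites, OUT / "sites.tsv")
    write_tsv(pd.concat([a.to_frame() for a in truth.arrays]), OUT / "arrays.tsv")

    wt = TerminationModel(rho_per_spacer=RHO_PROTECTED)
    mut = TerminationModel(
        rho_per_spacer=step_hazard(N_SPACERS, CHANGEPOINT,
                                   RHO_PROTECTED, RHO_UNPROTECTED),
        boxA_intact=False)
    rows = []
    ab = {"wt": {}, "boxAmut": {}}
    for arr in truth.arrays:
        a_wt = simulate_crrna_abundance(arr.n_spacers, wt)
        a_mut = (simulate_crrna_abundance(arr.n_spacers, mut)
                 if arr.array_id == "CRISPR-II" else a_wt)
        for i in range(arr.n_spacers):
            sid = f"{arr.array_id}:{i + 1}"
            ab["wt"][sid], ab["boxAmut"][sid] = float(a_wt[i]), float(a_mut[i])
            rows.append({"spacer_id": sid, "abundance_wt": a_wt[i],
                         "abundance_boxAmut": a_mut[i]})
    write_tsv(pd.DataFrame(rows), OUT / "crrna_abundance.tsv")

    for strain in ("wt", "boxAmut"):
        for rep in (1, 2):
            cov = simulate_chip_coverage(
                len(genome), truth.sites, ab[strain], depth=DEPTH,
                seed=SEED * 100 + rep + (0 if strain == "wt" else 50))
            for strand, tag in (("+", "fwd"), ("-", "rev")):
                write_bedgraph(cov[strand], "chr",
                               OUT / f"{strain}_rep{rep}_{tag}.bedgraph")

    print(f"genome: {len(genome)} bp, {len(truth.sites)} planted sites, "
          f"2 arrays x {N_SPACERS} spacers -> {OUT}")
    print(f"hazard: protected {RHO_PROTECTED}/interval; boxA-mutant CRISPR-II "
          f"jumps to {RHO_UNPROTECTED} after spacer {CHANGEPOINT}")


if __name__ == "__main__":
    main()
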