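# crisprterm

Rho termination and BoxA antitermination analysis of bacterial CRISPR
arrays.

CRISPR arrays are transcribed as long untranslated RNAs — exactly the
substrate the bacterial termination factor Rho exists to shut down. A
boxA element upstream of an array recruits the Nus antitermination
complex (NusA/B/E/G-SuhB) to RNA polymerase and protects transcription
through the array; without it, Rho terminates prematurely and
leader-distal spacers lose their crRNAs, their Cascade binding, and
their immunity. This package implements the computational pipeline that
quantifies those effects, together with a synthetic-data generator so
every stage runs and is testable without any external download. It is
aimed at people analyzing Cascade ChIP-seq, pooled-conjugation
interference assays, or cas2-flank motif screens — or building
simulation-backed tests for such analyses.

## The models in brief

**Termination survival.** With per-interval termination probability
ρ_j between spacers j and j+1, expected crRNA abundance of spacer i is
A0 · Π_{j<i}(1 − ρ_j); intact antitermination substitutes a lower
protected hazard, and an optional internal promoter at spacer k adds
initiation that propagates with the same survival.

**Peak-to-spacer assignment.** 101-bp regions around ChIP peaks
(merged when overlapping; floor midpoint = peak center) are searched on
both strands for an AAG/ATG PAM immediately 5' of a perfect match to
spacer seed positions 1–5, or a perfect match to positions 1–5 and 7–8
without a PAM. A peak is assigned iff exactly one spacer identity
matches.

**Occupancy refinement and profiles.** Peak-center coverage
(forward + reverse at one position), replicate sum-scaling, and the
deletion-ratio rule: both replicate ratios (deleted:parent, pseudo-count
1) < 0.2 assign the deleted array's spacer, both > 1.0 the other
array's. Per-spacer mutant/reference ratio profiles are normalized to
the reference array's mean, and a change-point estimator locates where
termination begins.

**Conjugation interference.** Reads are tag-counted (unique 10-mer per
protospacer, either orientation, ambiguous reads discarded), plasmids
with < 50 reads in the effector-deleted sample in either replicate are
dropped, and efficiency is doubly normalized — first to the
effector-deleted sample, then to the no-protospacer control — in
percent.

**boxA discovery.** cas2-downstream flanks (300 bp, one per genus) are
trimmed at the first recurring 15-mer (the array's first repeat),
filtered (< 20 bp or no repeat discarded), and a ZOOPS-EM motif finder
(given strand only, multi-start, column-shift refinement) learns the
shared upstream element.

## Worked example

The numbered drivers run the whole pipeline on synthetic data from the
repository root:

```bash
python analysis/01_simulate_dataset.py
python analysis/02_assign_spacers.py
python analysis/03_occupancy_profiles.py
python analysis/04_conjugation_efficiency.py
python analysis/05_boxa_screen.py
```

Output of a full run:

```
genome: 60000 bp, 92 planted sites, 2 arrays x 23 spacers -> results/data
hazard: protected 0.02/interval; boxA-mutant CRISPR-II jumps to 0.15 after spacer 8
peaks: 92, unique: 92, ambiguous: 0, unassigned: 0
correct unique assignments: 92/92 -> results/assignments.tsv
CRISPR-II normalized mutant/reference profile: mean 1.022 through spacer 8, declining to 0.122 at spacer 23
estimated change-point: after spacer 8 (planted: after spacer 8)
deletion-ratio refinement: 276/276 constructed ambiguous peaks resolved correctly
read round-trip exact; dropped plasmids: none
boxA_mut/boxA_wt fold increase, protospacers 20-37: 13.5-241.0 (max overall 241.0)
efficiencies -> results/conjugation_efficiency.tsv
genera analyzed: 187/187; motif found in 53
discovered consensus: TGCTCTTTAACA (planted TGCTCTTTAACA)
planted instances recovered: 52/52; false hits: 1
report -> results/boxa_screen_report.tsv
```

Reading it: every planted Cascade off-target site is uniquely and
correctly assigned to its spacer; the boxA-mutant occupancy profile
stays at ~1 through spacer 8 of the second array and then declines
~8-fold by spacer 23, and the change-point estimator recovers the
planted jump exactly; ambiguous peaks are fully resolved by the
deletion-ratio rule; protospacers downstream of the planted
antitermination loss show 13–241-fold higher conjugation efficiency in
the boxA-mutant strain; and the motif screen recovers the planted
boxA-like consensus in all 52 carrier genera with one false hit.

There is also a CLI (`crisprterm simulate|arrays|assign|occupancy|
conjugation|boxa|assays|run-all`) over the same library; see
`crisprterm --help` and `configs/demo.yaml`.

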