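# Methods

## Background and scope

Bacterial CRISPR arrays are long, untranslated transcripts and therefore
natural substrates for Rho, the general bacterial terminator of
non-coding RNA. A boxA element just upstream of an array can recruit the
Nus antitermination complex (NusA/B/E/G-SuhB) to the elongating RNA
polymerase and protect transcription through the array; when
antitermination is lost, leader-distal spacers lose crRNA and with it
the ability to direct the Cascade effector or to elicit interference.

`crisprterm` implements the computational side of that analysis as a
reusable pipeline over synthetic data: assignment of Cascade
ChIP-seq peaks to array spacers, peak-center occupancy normalization and
deletion-ratio refinement, per-spacer occupancy-ratio profiles, pooled
conjugation interference quantification, and discovery of boxA-like
motifs upstream of CRISPR arrays. Peak calling, read alignment/coverage
computation, genome-scale Cas2 homology search, and CRISPR system typing
are accepted as inputs, not reimplemented.

## The termination survival model

crRNA abundance along an array is modelled as survival under interval
hazards. With per-interval termination probability ρ_j (the probability
that a polymerase terminates between spacer j and j+1), the expected
abundance of spacer i from initiation A0 is

    abundance_i = A0 · Π_{j<i} (1 − ρ_j)

With BoxA-mediated antitermination intact, a lower protected hazard
applies. An optional internal promoter at spacer k adds initiation a_k
that experiences the same downstream survival, reproducing profiles in
which spacers beyond a certain position are insensitive to upstream
termination.

Defaults (free parameters; the biology provides no measured hazard):
protected hazard 0.02 per interval; unprotected hazard 0.15 per interval
downstream of the change-point. With a jump after spacer 8 of a
23-spacer array these give mutant/reference abundance ratios declining
to ~0.12 at spacer 23 (~8-fold), inside the 3.7-10.7-fold range the
ChIP comparisons of interest show. Arrays default to 2 × 23 spacers of
32 nt with 29-nt repeats, a 100-nt leader and a 12-nt boxA starting
78 bp upstream of the first repeat.

## Synthetic genome and planted off-target sites

Cascade recognizes targets through an AWG PAM (AAG/ATG) and the
PAM-proximal seed of the crRNA spacer. Planted off-target sites are
PAM + protospacer constructs: positions 1-5 exactly match the spacer
seed, positions 7-8 are copied at configurable fidelity (default 1.0),
position 6 and the rest are random; strand is random. Sites and array
cassettes are placed left-to-right with ≥300 bp gaps so each site owns
its own 101-bp peak region.

Two generator properties guarantee the documented "100% sensitivity with
uniquely seeded spacers" invariant:

* spacer seeds are drawn mutually distinct in both orientations, and a
  site construct that happens to contain a match for a *different*
  spacer is redrawn;
* after assembly, chance seed/PAM matches within one region-width of a
  planted site are removed by mutating one non-load-bearing base (the
  8-nt seed/PAM windows of planted constructs and the array bodies are
  protected). At the default seed density, chance 8-mer matches are
  frequent enough (a few per region) that without this step unique
  assignment would fail regularly, which would measure background
  collision rates rather than matcher correctness.

Coverage is background Poisson (rate 1) plus depth × abundance over a
60-bp symmetric footprint per site, identically on both strands;
`noise="none"` returns expectations. What the generator does **not**
emulate: read-level sequencing artifacts, mappability structure,
fragment-length variation, chromatin/protein occupancy biases, or
Rut-site sequence specificity of Rho. Passing tests therefore establish
correctness of the analysis logic under the stated statistical model,
not performance on real ChIP libraries.

## Peak regions, matching and assignment

Peak positions are expanded to 101-bp regions (position ± 50), merged
when overlapping or abutting, and the floor midpoint of each merged
region is the peak center. Two match modes are searched on both strands
of each region:

* `PAM_SEED5`: AAG or ATG immediately 5' of an exact match to spacer
  positions 1-5;
* `SEED5_78`: exact match to positions 1-5 and 7-8, any position 6, no
  PAM required (and not forbidden).

A peak is `unique` when exactly one distinct spacer identity matches in
its region. Spacers with identical sequence are collapsed into a single
identity (ids joined `a/b`) so exact duplicates cannot manufacture
ambiguity. Windows containing N never match. The matcher is verified
against a deliberately naive brute-force enumeration over every offset,
strand, spacer, and mode.

## Occupancy and refinement

Occupancy at a peak is forward + reverse coverage at the single
peak-center position. Replicate 2 is multiplied by
Σ(rep1)/Σ(rep2) over the analyzed peak set so both replicates carry
equal total signal. Ambiguous peaks are refined by the
deleted:parent coverage ratio per replicate with a pseudo-count of 1 on
both numerator and denominator (stabilizes ratios at low coverage
without moving them near the thresholds at realistic depth): both
ratios < 0.2 restrict candidates to the deleted array, both > 1.0 to
the other array; a peak becomes unique only when exactly one candidate
survives, and no peak is ever un-assigned. Ratios are computed on
sum-scaled values (switchable by passing raw columns). The > 1.0 arm is
meaningful because deleting one array redistributes the effector over
the remaining crRNAs; the simulated deletion sample scales remaining
abundances by total/remaining accordingly.

Per-spacer effect profiles: per uniquely assigned peak, the
replicate-averaged mutant/reference occupancy ratio (arithmetic mean of
per-replicate ratios after sum-scaling; the combination rule is a
package choice); per spacer, the mean over its peaks; all values divided
by the mean per-peak ratio over reference-array peaks, which therefore
average to exactly 1. The change-point estimator fits, for each
candidate k, log-ratio = 0 up to k and a non-positive linear decline in
log space beyond k, and returns the least-squares k — matching the
geometric decline the survival model implies.

## Conjugation interference

Each protospacer plasmid is identified by a 10-nt tag: the centered
10-mer, shifted outward one base at a time on collision (occurrence in
another protospacer in either orientation, in the control construct, or
equality with a chosen tag). Identical protospacers are collapsed first.
Reads count for a plasmid iff exactly one tag occurs in the read or its
reverse complement; zero- and multi-tag reads are tallied, not silently
dropped. Plasmids with fewer than 50 reads in the effector-deleted
sample in either replicate are discarded (exactly 50 is retained).
Efficiency is doubly normalized:

    eff(p,s,r) = [c(p,s,r)/c(p,Δ,r)] / [c(ctrl,s,r)/c(ctrl,Δ,r)] × 100

where Δ is the effector-deleted sample; the control plasmid scores
exactly 100% in every sample, and efficiencies are invariant to
per-sample depth rescaling. Replicates are reported individually plus
min-max range. Simulated pools are multinomial over pool proportions ×
efficiencies at fixed depth; read synthesis embeds each protospacer in
adapter context with half the reads reverse-complemented.

## Flank preparation and the boxA screen

For each cas2 gene the 300 bp downstream (in cas2's orientation; minus
strand flanks are reverse-complemented, contig-edge flanks flagged
truncated) are trimmed at the first 15-mer that recurs later in the same
flank — the start of the array's first repeat. Flanks with no recurring
15-mer, or trimmed below 20 bp, are discarded. Interpretation choices:
recurrence is direct-repeat only (CRISPR repeats are direct repeats) and
window-local (within the flank, not genome-wide); the trim point is the
start of the first instance; N-containing 15-mers never match. One
record per genus is kept; the selection is deterministic
(lexicographically first source id) for reproducibility. For genera
whose arrays run opposite to cas2 (type II-C layout), the 300 bp at the
array's cas2-distal end, oriented toward the array, can be substituted.

Motif discovery is a ZOOPS (zero-or-one occurrence per sequence)
mixture: with prior γ a sequence carries one motif occurrence at a
uniform offset emitted by a w×4 position probability matrix, otherwise
pure 0-order background; the search uses the given strand only, matching
how flanks are oriented. EM with Dirichlet(α=0.25 per base) smoothing on
the matrix columns maximizes the posterior; the reported objective
(log-likelihood + α·Σ log p) is non-decreasing every iteration by EM
construction, and the data log-likelihood is recorded alongside.
Defaults: width 12 (the visual width of the boxA consensus class),
20 restarts seeded from randomly chosen input 12-mers (restart seeding
is independent of input order, so results are permutation-stable),
convergence at objective gain < 1e-4, cap 200 iterations. After the
multi-start search, the winning matrix is re-fit from ±1..3
column-shifted copies of itself and the best objective kept — lateral
local optima are the dominant failure mode of subsequence-seeded EM.
Sequences with posterior occurrence > 0.5 are hits. PWM scanning uses
log2-odds scores with a default 8-bit threshold. No E-value statistic is
computed; comparisons with enrichment-score-based tools are qualitative.

## Assays

Miller units: 1000 · A420 / (A600 · time[min] · volume[mL]).
ChIP-qPCR occupancy: both target and mock enrichments are fold signal
over a control region; occupancy is their difference
(background-subtracted enrichment — the arithmetic is under-specified in
the underlying protocol literature; this subtraction is the documented
interpretation here). A ΔΔCq helper converts quantification cycles to
enrichment with configurable amplification efficiency (default 2.0).

## Problem sizes and reproduction

The bundled evaluation workflows (`crisprterm.workflows`, driven by
`scripts/acceptance.py` and `tests/test_acceptance.py`) use: 1000 random
matcher-oracle instances; a 60 kb genome with 2×23 spacers and 92
planted sites; 5-seed refinement benchmark at depth 100 (460 constructed
ambiguous peaks); 20-seed change-point benchmark at depth 200; one
conjugation pool of depth 1e5 over a 24-point efficiency grid
10^-3..1; and one 187-flank motif panel with 52 planted instances.
These sizes make every stage's recovery measurable with comfortable
margins while keeping a full run in tens of seconds.

## Known limitations

* All coordinates assume a single contig; multi-contig genomes must be
  processed per contig.
* The ZOOPS model finds one motif; multi-motif search and E-value
  statistics are out of scope.
* The refinement thresholds (0.2 / 1.0) are taken as given, not
  re-estimated from data.
* The survival model treats termination hazards as independent of
  sequence; it cannot represent Rut-site placement effects.
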