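"""Synthetic data with the statistical structure the analysis assumes.

The generator emulates a bacterial chromosome carrying two type I-E
CRISPR arrays (leader, upstream boxA, alternating repeats and spacers,
spacer 1 leader-proximal) plus planted Cascade off-target sites: an
AAG/ATG PAM followed by an exact match to spacer seed positions 1-5,
with positions 7-8 reproduced at configurable fidelity and the rest of
the protospacer randomized.  Per-spacer crRNA abundance follows a
survival model of Rho termination along the array — each inter-spacer
interval terminates the transcribing polymerase with hazard rho_j, which
BoxA-mediated Nus antitermination lowers — so leader-distal spacers lose
crRNA when antitermination is disrupted.  ChIP coverage, pooled
conjugation counts, and genus flank sets with a planted boxA-like motif
are generated from the same ground truth so every downstream stage can
be exercised against known parameters.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .arrays import CrisprArray, Spacer, find_first_repeat15
from .assignment import DEFAULT_PAMS, SEED5_78, find_matches
from .io import revcomp

BASES = "ACGT"
DEFAULT_BOXA = "TGCTCTTTAACA"   # E. coli-consensus-like boxA element


class CapacityError(RuntimeError):
    """Planted features do not fit in the genome without overlap."""


@dataclass
class TerminationModel:
    """Rho hazard along a CRISPR array, with optional BoxA protection.

    rho_per_spacer: termination probability in each inter-spacer interval
    (scalar, or array of length n_spacers-1).  When boxA_intact is set the
    (lower) rho_protected hazard applies instead; left as None it defaults
    to rho_per_spacer.  An optional internal promoter at 1-based spacer k
    adds initiation a_k that then experiences the same downstream survival.
    """
    rho_per_spacer: float | np.ndarray = 0.02
    boxA_intact: bool = True
    rho_protected: float | np.ndarray | None = None
    internal_promoter_at: int | None = None
    promoter_strength: float = 0.0

    def hazards(self, n_spacers: int) -> np.ndarray:
        if self.boxA_intact and self.rho_protected is not None:
            rho = self.rho_protected
        else:
            rho = self.rho_per_spacer
        rho = np.broadcast_to(np.asarray(rho, dtype=float), (n_spacers - 1,)).copy() \
            if n_spacers > 1 else np.zeros(0)
        return np.clip(rho, 0.0, 1.0)


def step_hazard(n_spacers: int, changepoint: int, rho_before: float,
                rho_after: float) -> np.ndarray:
    """Hazard vector with a jump after 1-based spacer `changepoint`.

    Intervals following spacers 1..changepoint-1 get rho_before; intervals
    following spacers changepoint..n-1 get rho_after, so spacers
    changepoint+1..n feel the raised hazard.
    """
    rho = np.full(max(n_spacers - 1, 0), rho_before, dtype=float)
    rho[changepoint - 1:] = rho_after
    return rho


def simulate_crrna_abundance(n_spacers: int, model: TerminationModel,
                             a0: float = 1.0) -> np.ndarray:
    """Expected crRNA abundance per spacer under the survival model.

    abundance_i = a0 * prod_{j<i} (1 - rho_j), plus, when an internal
    promoter fires at spacer k, a_k propagated with the same downstream
    survival.  With constant hazard rho this is a0 * (1-rho)^(i-1).
    """
    rho = model.hazards(n_spacers)
    surv = np.concatenate([[1.0], np.cumprod(1.0 - rho)])
    abundance = a0 * surv
    k = model.internal_promoter_at
    if k is not None and model.promoter_strength > 0:
        extra = np.zeros(n_spacers)
        # survival from spacer k onward, relative to position k
        tail = np.concatenate([[1.0], np.cumprod(1.0 - rho[k - 1:])])
        extra[k - 1:] = model.promoter_strength * tail[:n_spacers - k + 1]
        abundance = abundance + extra
    return abundance


@dataclass
class ArraySpec:
    array_id: str
    n_spacers: int
    repeat_seq: str = "GTGTTCCCCGCGCCAGCGGGGATAAACCG"   # type I-E-like repeat
    spacer_length: int = 32
    leader_length: int = 100
    boxa_offset: int = 78          # boxA start, bp upstream of the first repeat
    boxa_seq: str = DEFAULT_BOXA


@dataclass
class SimulationConfig:
    seed: int = 0
    genome_length: int = 60_000
    arrays: list[ArraySpec] = field(default_factory=lambda: [
        ArraySpec("CRISPR-I", 23), ArraySpec("CRISPR-II", 23)])
    offtargets_per_spacer: int = 2
    pams: tuple[str, ...] = DEFAULT_PAMS
    pos78_fidelity: float = 1.0    # per-base probability positions 7-8 are copied
    min_feature_gap: int = 300     # keeps one planted site per 101-bp peak region
    depth: float = 200.0
    background_rate: float = 1.0
    footprint: int = 60
    noise: str = "poisson"         # poisson | none
    unique_seeds: bool = True      # distinct 5-nt seeds across all spacers

    def __post_init__(self):
        for spec in self.arrays:
            if spec.n_spacers < 1:
                raise ValueError("n_spacers must be >= 1")
            if spec.spacer_length < 8:
                raise ValueError("spacer_length must be >= 8")
            if spec.boxa_offset > spec.leader_length:
                raise ValueError("boxA offset must fit inside the leader")


@dataclass
class GroundTruth:
    sites: pd.DataFrame            # chrom, start, end, strand, spacer_id, pam, seq
    arrays: list[CrisprArray]
    spacers: dict[str, str]
    abundance: dict[str, float] = field(default_factory=dict)

    def spacer_ids(self) -> list[str]:
        return list(self.spacers)


def random_dna(rng: np.random.Generator, length: int) -> str:
    """Uniform random DNA string."""
    return "".join(np.array(list(BASES))[rng.integers(0, 4, size=length)])


_random_seq = random_dna


def _draw_spacers(rng: np.random.Generator, config: SimulationConfig) -> dict[str, str]:
    """Spacer sequences for every array; seeds made mutually distinct.

    Distinctness covers both orientations (no seed equals another seed or
    its reverse complement), so no two spacer identities can ever claim
    the same seed occurrence.
    """
    spacers: dict[str, str] = {}
    used_seeds: set[str] = set()
    for spec in config.arrays:
        for idx in range(1, spec.n_spacers + 1):
            for _ in range(1000):
                seq = _random_seq(rng, spec.spacer_length)
                seed = seq[:5]
                if not config.unique_seeds or (
                        seed not in used_seeds and revcomp(seed) not in used_seeds):
                    used_seeds.add(seed)
                    spacers[f"{spec.array_id}:{idx}"] = seq
                    break
            else:
                raise CapacityError("could not draw spacers with distinct seeds")
    return spacers


def _array_cassette(spec: ArraySpec, spacer_seqs: list[str],
                    rng: np.random.Generator) -> tuple[str, dict]:
    """Leader (with boxA) + alternating repeats/spacers + terminal repeat."""
    leader = list(_random_seq(rng, spec.leader_length))
    boxa_start = spec.leader_length - spec.boxa_offset
    leader[boxa_start:boxa_start + len(spec.boxa_seq)] = spec.boxa_seq
    parts = ["".join(leader)]
    spacer_local = []
    pos = spec.leader_length
    for seq in spacer_seqs:
        parts.append(spec.repeat_seq)
        pos += len(spec.repeat_seq)
        spacer_local.append((pos, pos + len(seq)))
        parts.append(seq)
        pos += len(seq)
    parts.append(spec.repeat_seq)
    layout = {"boxa_local": (boxa_start, boxa_start + len(spec.boxa_seq)),
              "spacer_local": spacer_local,
              "leader_local": (0, spec.leader_length)}
    return "".join(parts), layout


def _make_site(rng: np.random.Generator, spacer: str, pams: tuple[str, ...],
               fidelity: float, other_spacers: dict[str, str] | None = None,
               max_tries: int = 100) -> tuple[str, str]:
    """PAM + protospacer construct: seed 1-5 exact, 7-8 at given fidelity.

    When `other_spacers` is given, constructs that happen to contain a
    seed/PAM match for a different spacer (either strand) are redrawn, so
    a planted site can never by itself make its peak ambiguous.
    """
    for _ in range(max_tries):
        pam = pams[rng.integers(0, len(pams))]
        proto = list(_random_seq(rng, len(spacer)))
        proto[:5] = spacer[:5]
        for j in (6, 7):
            if rng.random() < fidelity:
                proto[j] = spacer[j]
        construct = pam + "".join(proto)
        if not other_spacers or not find_matches(construct, other_spacers, pams):
            return pam, construct
    raise CapacityError("could not draw a construct free of foreign seed matches")


def _sanitize(genome: list[str], sites: pd.DataFrame, spacers: dict[str, str],
              pams: tuple[str, ...], protected: list[tuple[int, int]],
              window: int = 101, max_rounds: int = 20) -> None:
    """Destroy chance seed/PAM matches near planted sites.

    Only matches inside a planted site's eventual peak region can corrupt
    assignment, so scanning is restricted to +/- `window` bp around each
    site.  A spurious match is removed by mutating one base of its seed
    (falling back to positions 7-8) that lies outside every protected
    interval (planted PAM+seed cores and array bodies).
    """
    prot = sorted(protected)

    def is_protected(pos: int) -> bool:
        for s, e in prot:
            if s <= pos < e:
                return True
            if s > pos:
                break
        return False

    mut_counts: dict[int, int] = {}
    for _ in range(max_rounds):
        dirty = False
        for row in sites.itertuples(index=False):
            lo = max(0, row.start - window)
            hi = min(len(genome), row.end + window)
            region = "".join(genome[lo:hi])
            for m in find_matches(region, spacers, pams):
                if m.spacer_id == row.spacer_id:
                    # extra matches of the site's own spacer cannot change
                    # the candidate set; leave them alone
                    continue
                if m.strand == "+":
                    proto_fwd = lo + m.offset          # forward coord of position 1
                    seed_fwd = [proto_fwd + j for j in range(5)]
                    p78_fwd = [proto_fwd + 6, proto_fwd + 7]
                    pam_fwd = [proto_fwd - 3, proto_fwd - 2, proto_fwd - 1]
                else:
                    # position j (0-based) of the protospacer sits at
                    # forward coordinate hi - m.offset - 1 - j
                    seed_fwd = [hi - m.offset - 1 - j for j in range(5)]
                    p78_fwd = [hi - m.offset - 1 - 6, hi - m.offset - 1 - 7]
                    pam_fwd = [hi - m.offset - 1 + j for j in (1, 2, 3)]
                aux = p78_fwd if m.mode == SEED5_78 else pam_fwd
                targets = [p for p in seed_fwd + aux
                           if 0 <= p < len(genome) and not is_protected(p)]
                if not targets:
                    continue
                # prefer a position not mutated before: a context where every
                # base at one spot completes some match otherwise cycles forever
                p = min(targets, key=lambda q: (mut_counts.get(q, 0), q))
                shift = 1 + mut_counts.get(p, 0) % 3
                old = genome[p]
                genome[p] = BASES[(BASES.index(old) + shift) % 4] if old in BASES else "A"
                mut_counts[p] = mut_counts.get(p, 0) + 1
                dirty = True
        if not dirty:
            return
    raise CapacityError("could not sanitize spurious seed matches")


def make_crispr_genome(config: SimulationConfig) -> tuple[str, GroundTruth]:
    """Generate a genome with planted arrays and off-target sites.

    Deterministic under config.seed.  Features (array cassettes and
    PAM+protospacer constructs, random strand each) are placed left to
    right with at least `min_feature_gap` bp between them; chance seed
    matches near planted sites are sanitized so that uniquely seeded
    spacers are recoverable with full sensitivity.  Raises CapacityError
    if the genome cannot hold all features.
    """
    rng = np.random.default_rng(np.random.SeedSequence(config.seed))
    genome = list(_random_seq(rng, config.genome_length))
    spacers = _draw_spacers(rng, config)

    # lay out features left-to-right with jittered gaps
    cassettes = []
    for spec in config.arrays:
        seqs = [spacers[f"{spec.array_id}:{i}"] for i in range(1, spec.n_spacers + 1)]
        cassettes.append((spec, *_array_cassette(spec, seqs, rng)))
    site_plan = []
    for spec in config.arrays:
        for idx in range(1, spec.n_spacers + 1):
            sid = f"{spec.array_id}:{idx}"
            others = {k: v for k, v in spacers.items() if k != sid}
            for _ in range(config.offtargets_per_spacer):
                pam, construct = _make_site(rng, spacers[sid], config.pams,
                                            config.pos78_fidelity,
                                            other_spacers=others if config.unique_seeds else None)
                site_plan.append((sid, pam, construct))

    features: list[tuple[str, object]] = [("array", c) for c in cassettes]
    features += [("site", s) for s in site_plan]
    total = sum(len(x[1]) if kind == "array" else len(x[2])
                for kind, x in features)
    gap = config.min_feature_gap
    need = total + gap * (len(features) + 1)
    if need > config.genome_length:
        raise CapacityError(
            f"genome_length {config.genome_length} cannot hold {len(features)} "
            f"features ({need} bp needed)")

    cursor = gap
    arrays_out: list[CrisprArray] = []
    site_rows = []
    protected: list[tuple[int, int]] = []
    for kind, payload in features:
        if kind == "array":
            spec, cassette, layout = payload
            start = cursor
            genome[start:start + len(cassette)] = cassette
            spacer_objs = [
                Spacer(index=i + 1,
                       seq=spacers[f"{spec.array_id}:{i + 1}"],
                       start=start + s, end=start + e)
                for i, (s, e) in enumerate(layout["spacer_local"])
            ]
            bs, be = layout["boxa_local"]
            ls, le = layout["leader_local"]
            arrays_out.append(CrisprArray(
                array_id=spec.array_id, chrom="chr", strand="+",
                repeat_seq=spec.repeat_seq, spacers=spacer_objs,
                leader=(start + ls, start + le),
                boxa=(start + bs, start + be), boxa_seq=spec.boxa_seq))
            protected.append((start, start + len(cassette)))
            cursor = start + len(cassette) + gap
        else:
            sid, pam, construct = payload
            strand = "+" if rng.random() < 0.5 else "-"
            placed = construct if strand == "+" else revcomp(construct)
            start = cursor
            genome[start:start + len(placed)] = placed
            site_rows.append({"chrom": "chr", "start": start,
                              "end": start + len(placed), "strand": strand,
                              "spacer_id": sid, "pam": pam, "seq": construct})
            # protect the PAM + seed + positions 6-8 core
            if strand == "+":
                protected.append((start, start + 11))
            else:
                protected.append((start + len(placed) - 11, start + len(placed)))
            cursor = start + len(placed) + gap

    sites = pd.DataFrame(site_rows, columns=["chrom", "start", "end", "strand",
                                             "spacer_id", "pam", "seq"])
    if config.unique_seeds and len(sites):
        _sanitize(genome, sites, spacers, config.pams, protected)
        # refresh stored construct sequences after sanitization
        gstr = "".join(genome)
        sites["seq"] = [
            gstr[r.start:r.end] if r.strand == "+" else revcomp(gstr[r.start:r.end])
            for r in sites.itertuples(index=False)
        ]
    return "".join(genome), GroundTruth(sites=sites, arrays=arrays_out,
                                        spacers=spacers)


def simulate_chip_coverage(genome_length: int, sites: pd.DataFrame,
                           abundance: dict[str, float], depth: float,
                           seed: int, noise: str = "poisson",
                           background_rate: float = 1.0,
                           footprint: int = 60) -> dict[str, np.ndarray]:
    """Per-strand coverage tracks with planted-site enrichment.

    Expected coverage in a symmetric `footprint` window around each site
    center is background + depth * abundance of its spacer, identically
    on both strands.  noise='poisson' draws counts; 'none' returns the
    expectation.  Deterministic under `seed`.
    """
    lam = np.full(genome_length, float(background_rate))
    half = footprint // 2
    for row in sites.itertuples(index=False):
        center = (row.start + row.end) // 2
        lo, hi = max(0, center - half), min(genome_length, center + half)
        lam[lo:hi] += depth * abundance.get(row.spacer_id, 0.0)
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    if noise == "none":
        return {"+": lam.copy(), "-": lam.copy()}
    if noise == "poisson":
        return {"+": rng.poisson(lam).astype(float),
                "-": rng.poisson(lam).astype(float)}
    raise ValueError(f"unknown noise family {noise!r}")


def simulate_conjugation_counts(pool: dict[str, float],
                                efficiency_by_sample: dict[str, dict[str, float]],
                                depth: int, seed: int,
                                n_replicates: int = 2) -> pd.DataFrame:
    """Multinomial read counts for a pooled conjugation experiment.

    `pool` gives pre-conjugation plasmid proportions (including the
    no-protospacer control); each sample's transconjugant pool is
    proportional to pool * per-plasmid efficiency (the interference-free
    control sample uses efficiency 1 everywhere).  Returns a tidy frame
    (plasmid, sample, replicate, count); counts per sample sum to depth.
    """
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    ids = list(pool)
    base = np.array([pool[i] for i in ids], dtype=float)
    rows = []
    for sample, effs in efficiency_by_sample.items():
        eff = np.array([effs.get(i, 1.0) for i in ids], dtype=float)
        if np.any(eff < 0) or np.any(eff > 1):
            raise ValueError("efficiencies must lie in [0, 1]")
        p = base * eff
        p = p / p.sum()
        for rep in range(1, n_replicates + 1):
            counts = rng.multinomial(depth, p)
            rows += [{"plasmid": i, "sample": sample, "replicate": rep,
                      "count": int(c)} for i, c in zip(ids, counts)]
    return pd.DataFrame(rows)


def make_reads_from_counts(counts: pd.DataFrame, sequences: dict[str, str],
                           seed: int, read_length: int = 75,
                           flip_fraction: float = 0.5
                           ) -> dict[tuple[str, int], list[str]]:
    """Expand a counts table into synthetic amplicon reads per sample.

    Each read embeds its plasmid's sequence in fixed adapter context,
    padded/truncated to `read_length`; a `flip_fraction` of reads are
    reverse-complemented to exercise orientation handling.  Returns
    {(sample, replicate): [read, ...]}.
    """
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    left = "ACGTACGTACGTACG"
    out: dict[tuple[str, int], list[str]] = {}
    for row in counts.itertuples(index=False):
        insert = left + sequences[row.plasmid]
        pad = _random_seq(rng, max(0, read_length - len(insert)))
        read = (insert + pad)[:read_length]
        reads = out.setdefault((row.sample, row.replicate), [])
        for _ in range(row.count):
            reads.append(revcomp(read) if rng.random() < flip_fraction else read)
    return out


def make_cas2_flank_set(n_sequences: int, motif: str, planting_fraction: float,
                        seed: int, flank_length: int = 300,
                        repeat_fraction: float = 1.0,
                        motif_offset_range: tuple[int, int] = (25, 100),
                        repeat_offset_range: tuple[int, int] = (150, 270)
                        ) -> tuple[list[tuple[str, str, str]], pd.DataFrame]:
    """Genus flank sequences with a planted motif and 15-bp tandem repeat.

    Exactly round(n * planting_fraction) flanks carry one motif instance
    upstream of the planted repeat pair; the repeat pair (a 15-mer
    duplicated in tandem, one random 15-mer per flank) marks where the
    downstream array would begin.  Returns ([(source_id, genus, seq)],
    truth frame with motif_offset (-1 if absent) and repeat_offset).
    """
    if len(motif) > flank_length:
        raise ValueError("motif longer than flank")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    n_plant = round(n_sequences * planting_fraction)
    planted = set(rng.choice(n_sequences, size=n_plant, replace=False).tolist())
    records, rows = [], []
    for i in range(n_sequences):
        for _ in range(100):
            seq = list(_random_seq(rng, flank_length))
            repeat_offset = -1
            if rng.random() < repeat_fraction:
                repeat_offset = int(rng.integers(*repeat_offset_range))
                r15 = _random_seq(rng, 15)
                seq[repeat_offset:repeat_offset + 30] = r15 + r15
            motif_offset = -1
            if i in planted:
                hi = (repeat_offset if repeat_offset >= 0 else flank_length) - len(motif)
                lo, hi = motif_offset_range[0], min(motif_offset_range[1], hi)
                motif_offset = int(rng.integers(lo, hi + 1))
                seq[motif_offset:motif_offset + len(motif)] = motif
            s = "".join(seq)
            first = find_first_repeat15(s)
            ok = (first == repeat_offset) if repeat_offset >= 0 else (first is None)
            if ok:
                break
        else:
            raise CapacityError("could not draw a clean flank sequence")
        sid, genus = f"seq{i:04d}", f"genus{i:04d}"
        records.append((sid, genus, s))
        rows.append({"source_id": sid, "genus": genus,
                     "motif_offset": motif_offset, "repeat_offset": repeat_offset})
    return records, pd.DataFrame(rows)
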