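"""ZOOPS-EM motif discovery and PWM scanning for the boxA screen.

The boxA element is a short (~12 nt) RNA sequence bound by NusB/E that
nucleates the Nus antitermination complex.  The screen asks whether a
shared motif is enriched in the given-strand sequences between cas2 and
the first CRISPR repeat across bacterial genera.  The model is the
classic ZOOPS mixture: each sequence carries zero or one motif
occurrence (prior gamma), at a uniformly distributed offset, emitted by
a position probability matrix against a 0-order background.  Parameters
are fit by EM with a Dirichlet(alpha) prior on the matrix columns; the
MAP objective is non-decreasing every iteration by construction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

_IDX = {b: i for i, b in enumerate("ACGT")}


class MotifError(ValueError):
    pass


@dataclass
class MotifModel:
    pwm: np.ndarray                 # (width, 4) position probability matrix
    background: np.ndarray          # (4,)
    gamma: float                    # per-sequence occurrence prior

    @property
    def width(self) -> int:
        return self.pwm.shape[0]

    def consensus(self) -> str:
        return "".join("ACGT"[i] for i in self.pwm.argmax(axis=1))

    def information_content(self) -> float:
        """Total information content in bits, relative to the background."""
        with np.errstate(divide="ignore", invalid="ignore"):
            terms = self.pwm * (np.log2(self.pwm) - np.log2(self.background))
        return float(np.nansum(terms))

    def to_meme_text(self, name: str = "MOTIF1") -> str:
        lines = [
            "MEME version 4", "", "ALPHABET= ACGT", "",
            "Background letter frequencies",
            " ".join(f"{b} {f:.4f}" for b, f in zip("ACGT", self.background)), "",
            f"MOTIF {name}",
            f"letter-probability matrix: alength= 4 w= {self.width}",
        ]
        lines += ["  " + "  ".join(f"{p:.6f}" for p in row) for row in self.pwm]
        return "\n".join(lines) + "\n"


def pwm_from_meme_text(text: str) -> MotifModel:
    lines = [l.strip() for l in text.splitlines()]
    bg = np.full(4, 0.25)
    rows: list[list[float]] = []
    width = None
    for i, line in enumerate(lines):
        if line.startswith("Background letter frequencies"):
            toks = lines[i + 1].split()
            bg = np.array([float(toks[j * 2 + 1]) for j in range(4)])
        if line.startswith("letter-probability matrix"):
            width = int(line.split("w=")[1].split()[0])
            for row_line in lines[i + 1:i + 1 + width]:
                rows.append([float(x) for x in row_line.split()[:4]])
            break
    if width is None:
        raise MotifError("no letter-probability matrix found")
    return MotifModel(pwm=np.array(rows), background=bg, gamma=0.5)


@dataclass(frozen=True)
class MotifHit:
    source_id: str
    offset: int
    score: float          # log2 odds of the hit window
    posterior: float      # ZOOPS posterior of any occurrence in the sequence


def dedupe_by_genus(records: list[tuple[str, str, str]]
                    ) -> list[tuple[str, str, str]]:
    """One (source_id, genus, seq) record per genus.

    The selection the screen calls 'arbitrary' is made deterministic: the
    lexicographically first source id within each genus wins.
    """
    best: dict[str, tuple[str, str, str]] = {}
    for rec in records:
        genus = rec[1]
        if genus not in best or rec[0] < best[genus][0]:
            best[genus] = rec
    return [best[g] for g in sorted(best)]


def _encode(seq: str) -> np.ndarray:
    return np.array([_IDX.get(b, -1) for b in seq.upper()], dtype=np.int64)


def _window_scores(x: np.ndarray, log_ratio: np.ndarray) -> np.ndarray:
    """Sum of per-position log(pwm/bg) over every width-window of x.

    Positions outside ACGT (N) contribute 0 (background-equivalent).
    """
    w = log_ratio.shape[0]
    m = len(x) - w + 1
    scores = np.zeros(m)
    for j in range(w):
        xs = x[j:j + m]
        vals = np.where(xs >= 0, log_ratio[j, np.clip(xs, 0, 3)], 0.0)
        scores += vals
    return scores


def _base_counts(x: np.ndarray) -> np.ndarray:
    return np.bincount(x[x >= 0], minlength=4).astype(float)


def discover_motif_zoops(sequences: dict[str, str], width: int = 12,
                         n_starts: int = 20, max_iter: int = 200,
                         tol: float = 1e-4, seed: int = 0,
                         alpha: float = 0.25
                         ) -> tuple[MotifModel, list[MotifHit], dict]:
    """Fit a ZOOPS motif model by multi-start EM on the given strand only.

    Each start seeds the matrix from a randomly chosen width-mer of the
    input; the best start by final objective wins.  Returns (model, hits,
    diagnostics) where hits are sequences with posterior occurrence > 0.5
    and diagnostics carries the objective/log-likelihood trajectories of
    the winning start.  The objective (log posterior with Dirichlet(alpha)
    columns) is non-decreasing across iterations.
    """
    ids = list(sequences)
    if len(ids) < 2:
        raise MotifError("need at least two sequences")
    enc = {i: _encode(sequences[i]) for i in ids}
    if min(len(v) for v in enc.values()) < width:
        raise MotifError("motif width exceeds shortest sequence")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    totals = sum(_base_counts(x) for x in enc.values())
    bg0 = totals / totals.sum()

    sorted_ids = sorted(ids)   # seeding independent of input order
    best = None
    for _ in range(n_starts):
        sid = sorted_ids[rng.integers(0, len(sorted_ids))]
        x = enc[sid]
        off = int(rng.integers(0, len(x) - width + 1))
        pwm = np.full((width, 4), 0.1)
        for j in range(width):
            b = x[off + j]
            pwm[j, b if b >= 0 else rng.integers(0, 4)] = 0.7
        pwm /= pwm.sum(axis=1, keepdims=True)
        fit = _em(enc, pwm, bg0.copy(), 0.5, alpha, max_iter, tol)
        if best is None or fit["objective"][-1] > best["objective"][-1]:
            best = fit

    # column-shift refinement: a start near but off the motif can converge
    # to a laterally shifted optimum; re-seed EM from shifted copies of the
    # winning matrix and keep the best final objective
    for shift in (-3, -2, -1, 1, 2, 3):
        pwm = np.full((width, 4), 0.25)
        for j in range(width):
            if 0 <= j + shift < width:
                pwm[j] = best["pwm"][j + shift]
        fit = _em(enc, pwm, best["bg"].copy(), best["gamma"], alpha,
                  max_iter, tol)
        if fit["objective"][-1] > best["objective"][-1]:
            best = fit

    model = MotifModel(pwm=best["pwm"], background=best["bg"], gamma=best["gamma"])
    hits = []
    log_ratio = np.log(model.pwm) - np.log(model.background)
    for i in ids:
        z, q = _posteriors(enc[i], log_ratio, model.gamma)
        if q > 0.5:
            off = int(np.argmax(z))
            hits.append(MotifHit(i, off, float(_window_scores(
                enc[i][off:off + width], log_ratio / np.log(2))[0]), float(q)))
    diagnostics = {"objective": best["objective"], "loglik": best["loglik"],
                   "n_iter": len(best["objective"])}
    return model, hits, diagnostics


def _posteriors(x: np.ndarray, log_ratio: np.ndarray, gamma: float
                ) -> tuple[np.ndarray, float]:
    """Per-offset responsibilities and occurrence posterior for one sequence."""
    m = len(x) - log_ratio.shape[0] + 1
    s = _window_scores(x, log_ratio)
    smax = s.max()
    w_occ = (gamma / m) * np.exp(s - smax)
    denom = (1.0 - gamma) * np.exp(-smax) + w_occ.sum()
    z = w_occ / denom
    return z, float(w_occ.sum() / denom)


def _em(enc: dict[str, np.ndarray], pwm: np.ndarray, bg: np.ndarray,
        gamma: float, alpha: float, max_iter: int, tol: float) -> dict:
    """Batched EM: sequences grouped by length, N encoded as index 4 with
    zero log-ratio (background-equivalent)."""
    width = pwm.shape[0]
    groups: dict[int, np.ndarray] = {}
    for x in enc.values():
        groups.setdefault(len(x), []).append(np.where(x >= 0, x, 4))
    groups = {L: np.stack(v) for L, v in groups.items()}
    n_seq = len(enc)
    totals = sum(_base_counts(x) for x in enc.values())
    objective_hist: list[float] = []
    loglik_hist: list[float] = []
    eps = 1e-300
    for _ in range(max_iter):
        lr = np.zeros((width, 5))
        lr[:, :4] = np.log(pwm + eps) - np.log(bg + eps)
        lbg5 = np.concatenate([np.log(bg + eps), [0.0]])
        loglik = 0.0
        counts = np.zeros_like(pwm)
        gamma_sum = 0.0
        for L, X in groups.items():
            m = L - width + 1
            S = np.zeros((X.shape[0], m))
            for j in range(width):
                S += lr[j, X[:, j:j + m]]
            lbg = lbg5[X].sum(axis=1)
            smax = S.max(axis=1, keepdims=True)
            w_occ = (gamma / m) * np.exp(S - smax)
            denom = (1.0 - gamma) * np.exp(-smax[:, 0]) + w_occ.sum(axis=1)
            loglik += float((lbg + smax[:, 0] + np.log(denom)).sum())
            z = w_occ / denom[:, None]
            gamma_sum += float(z.sum())
            zf = z.ravel()
            for j in range(width):
                c = np.bincount(X[:, j:j + m].ravel(), weights=zf, minlength=5)
                counts[j] += c[:4]
        # objective = loglik + Dirichlet(alpha+1) log prior on pwm columns
        prior = float(alpha * np.sum(np.log(pwm + eps)))
        objective_hist.append(loglik + prior)
        loglik_hist.append(loglik)
        if len(objective_hist) > 1 and \
                objective_hist[-1] - objective_hist[-2] < tol:
            break
        # M-step
        pwm = (counts + alpha) / (counts.sum(axis=1, keepdims=True) + 4 * alpha)
        motif_mass = counts.sum(axis=0)
        bg_counts = np.maximum(totals - motif_mass, 0.0)
        bg = (bg_counts + eps) / (bg_counts.sum() + 4 * eps)
        gamma = min(max(gamma_sum / n_seq, 1e-6), 1 - 1e-6)
    return {"pwm": pwm, "bg": bg, "gamma": gamma,
            "objective": objective_hist, "loglik": loglik_hist}


def scan_pwm(seq: str, model: MotifModel, threshold_bits: float = 8.0,
             source_id: str = "") -> list[MotifHit]:
    """Log-odds scan of one sequence on the given strand.

    Returns hits (offset, score in bits) at or above the threshold,
    ranked by score.
    """
    x = _encode(seq)
    if len(x) < model.width:
        return []
    log2_ratio = (np.log2(model.pwm + 1e-300)
                  - np.log2(model.background + 1e-300))
    scores = _window_scores(x, log2_ratio)
    hits = [MotifHit(source_id, int(o), float(s), 1.0)
            for o, s in enumerate(scores) if s >= threshold_bits]
    return sorted(hits, key=lambda h: -h.score)


def screen_pipeline(flank_records: list, width: int = 12, n_starts: int = 20,
                    seed: int = 0, pwm: MotifModel | None = None,
                    threshold_bits: float = 8.0,
                    max_iter: int = 200) -> tuple[pd.DataFrame, dict]:
    """End-to-end boxA screen over prepared cas2 flanks.

    `flank_records` are FlankRecord objects (already extracted); the
    pipeline deduplicates genera, applies the trim/discard rules, then
    either discovers a motif by ZOOPS EM or scans a supplied PWM.
    Returns (per-genus report, summary).
    """
    from .arrays import trim_and_filter

    deduped = dedupe_by_genus([(f.source_id, f.genus, f) for f in flank_records])
    processed = [trim_and_filter(rec) for _, _, rec in deduped]
    kept = [f for f in processed if f.status == "kept" and len(f.trimmed) >= width]
    report_rows = {
        f.source_id: {"source_id": f.source_id, "genus": f.genus,
                      "status": f.status, "trimmed_length": len(f.trimmed),
                      "hit_offset": -1, "score": np.nan}
        for f in processed
    }
    summary = {"n_input": len(flank_records), "n_genera": len(deduped),
               "n_analyzed": len(kept), "n_with_motif": 0}
    model = pwm
    if kept:
        seqs = {f.source_id: f.trimmed for f in kept}
        if model is None:
            model, hits, diag = discover_motif_zoops(
                seqs, width=width, n_starts=n_starts, seed=seed,
                max_iter=max_iter)
            summary["em_iterations"] = diag["n_iter"]
        else:
            hits = []
            for sid, s in seqs.items():
                best = scan_pwm(s, model, threshold_bits, source_id=sid)
                if best:
                    hits.append(best[0])
        for h in hits:
            report_rows[h.source_id]["hit_offset"] = h.offset
            report_rows[h.source_id]["score"] = h.score
        summary["n_with_motif"] = len(hits)
        summary["consensus"] = model.consensus()
    report = pd.DataFrame(list(report_rows.values()))
    return report, summary
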