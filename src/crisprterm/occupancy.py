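"""Peak-center occupancy: replicate scaling, deletion-ratio refinement,
and per-spacer effect profiles.

Occupancy at a peak is the strand-summed coverage at the single
peak-center position.  Replicates are put on a common scale by
multiplying the second replicate by the constant that equalizes the
summed values over the analyzed peak set.  Ambiguous peaks are refined
by comparing coverage between an array-deleted strain and its parent:
sites driven by a deleted-array spacer collapse to background
(both-replicate ratio < 0.2), while sites driven by the remaining
array gain occupancy as the effector pool redistributes (> 1.0).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .assignment import PeakRecord


class NormalizationError(ValueError):
    pass


def spacer_array(spacer_id: str) -> str:
    """Array part of a spacer id like 'CRISPR-I:5' (duplicates keep one array)."""
    return spacer_id.split(":", 1)[0]


def peak_center_value(track_fwd: np.ndarray, track_rev: np.ndarray, center: int) -> float:
    """Strand-summed coverage at the peak-center position; out-of-range = 0."""
    val = 0.0
    if 0 <= center < len(track_fwd):
        val += float(track_fwd[center])
    if 0 <= center < len(track_rev):
        val += float(track_rev[center])
    return val


def scale_replicates(values_rep1: np.ndarray, values_rep2: np.ndarray
                     ) -> tuple[np.ndarray, float]:
    """Scale replicate 2 so both replicates have equal summed occupancy.

    Returns (scaled rep2, constant c = sum(rep1)/sum(rep2)).
    """
    v1 = np.asarray(values_rep1, dtype=float)
    v2 = np.asarray(values_rep2, dtype=float)
    s2 = v2.sum()
    if s2 <= 0:
        raise NormalizationError("replicate 2 sums to zero; cannot scale")
    c = v1.sum() / s2
    return v2 * c, c


def occupancy_matrix(peaks: list[PeakRecord], tracks: dict[str, dict[str, np.ndarray]],
                     scale: bool = True) -> pd.DataFrame:
    """Peak-center occupancy for every (sample, replicate) track pair.

    `tracks` maps sample name -> {"+": fwd, "-": rev}; sample names are
    expected to end in '_rep1' / '_rep2'.  When `scale` is set, each
    condition's rep2 column is sum-scaled to its rep1 column.  Values are
    also stored on each PeakRecord's coverage dict.
    """
    df = pd.DataFrame(index=range(len(peaks)))
    for sample, strands in tracks.items():
        df[sample] = [peak_center_value(strands["+"], strands["-"], p.center)
                      for p in peaks]
    if scale:
        for col in df.columns:
            if col.endswith("_rep2"):
                mate = col[:-1] + "1"
                if mate in df.columns:
                    df[col], _ = scale_replicates(df[mate].to_numpy(),
                                                  df[col].to_numpy())
    for i, pk in enumerate(peaks):
        pk.coverage = {c: float(df.at[i, c]) for c in df.columns}
    return df


def deletion_refinement(peaks: list[PeakRecord], occ: pd.DataFrame,
                        reference_sample: str, deleted_sample: str,
                        deleted_array: str,
                        replicates: tuple[str, str] = ("rep1", "rep2"),
                        low: float = 0.2, high: float = 1.0,
                        pseudocount: float = 1.0) -> list[PeakRecord]:
    """Resolve ambiguous peaks with deleted:parent occupancy ratios.

    Per replicate, ratio = (deleted + pseudocount)/(parent + pseudocount).
    Both ratios < `low` restricts candidates to `deleted_array` spacers;
    both > `high` restricts to other-array spacers.  A peak becomes unique
    iff exactly one candidate survives; no peak is ever un-assigned.
    """
    for rep in replicates:
        for sample in (reference_sample, deleted_sample):
            if f"{sample}_{rep}" not in occ.columns:
                raise ValueError(f"missing occupancy column {sample}_{rep}")
    for i, pk in enumerate(peaks):
        if pk.status != "ambiguous":
            continue
        ratios = [
            (occ.at[i, f"{deleted_sample}_{rep}"] + pseudocount)
            / (occ.at[i, f"{reference_sample}_{rep}"] + pseudocount)
            for rep in replicates
        ]
        if all(r < low for r in ratios):
            survivors = {c for c in pk.candidates if spacer_array(c) == deleted_array}
        elif all(r > high for r in ratios):
            survivors = {c for c in pk.candidates if spacer_array(c) != deleted_array}
        else:
            continue
        if len(survivors) == 1:
            pk.candidates = frozenset(survivors)
            pk.status = "unique"
            pk.provenance = "ratio_refined"
    return peaks


def spacer_effect_profile(peaks: list[PeakRecord], occ: pd.DataFrame,
                          mutant_sample: str, reference_sample: str,
                          reference_array: str,
                          replicates: tuple[str, str] = ("rep1", "rep2")
                          ) -> pd.DataFrame:
    """Per-spacer mutant/reference occupancy ratios, reference-array normalized.

    Per uniquely assigned peak: replicate-averaged mutant/reference ratio.
    Per spacer: mean over its peaks.  All values are divided by the mean
    per-peak ratio over peaks assigned to `reference_array`, so that array
    averages to 1 by construction.  Returns a frame indexed by spacer id
    with columns array, spacer_index, n_peaks, ratio.
    """
    rows = []
    for i, pk in enumerate(peaks):
        if pk.status != "unique":
            continue
        per_rep = []
        for rep in replicates:
            denom = occ.at[i, f"{reference_sample}_{rep}"]
            if denom <= 0:
                continue
            per_rep.append(occ.at[i, f"{mutant_sample}_{rep}"] / denom)
        if not per_rep:
            continue
        rows.append((pk.assigned_spacer, float(np.mean(per_rep))))
    if not rows:
        raise NormalizationError("no uniquely assigned peaks with usable coverage")
    df = pd.DataFrame(rows, columns=["spacer_id", "ratio"])
    ref_mask = df["spacer_id"].map(spacer_array) == reference_array
    if not ref_mask.any():
        raise NormalizationError(
            f"no peaks assigned to reference array {reference_array!r}")
    norm = df.loc[ref_mask, "ratio"].mean()
    df["ratio"] /= norm
    out = df.groupby("spacer_id").agg(n_peaks=("ratio", "size"),
                                      ratio=("ratio", "mean")).reset_index()
    out["array"] = out["spacer_id"].map(spacer_array)
    out["spacer_index"] = out["spacer_id"].str.split(":").str[-1].astype(int)
    return out.sort_values(["array", "spacer_index"]).reset_index(drop=True)


def estimate_changepoint(profile: np.ndarray) -> int:
    """Locate a termination change-point in a per-spacer ratio profile.

    Fits, for every candidate spacer k, the two-phase model
    log(ratio_i) = 0 for i <= k and log(ratio_i) = b*(i-k) for i > k
    (b <= 0, least squares), and returns the 1-based k minimizing total
    squared error.  A profile with no decline returns n (no change-point
    inside the array).
    """
    y = np.log(np.clip(np.asarray(profile, dtype=float), 1e-12, None))
    n = len(y)
    best_k, best_sse = n, float(np.sum(y ** 2))
    for k in range(1, n):
        head = y[:k]
        tail = y[k:]
        x = np.arange(1, n - k + 1, dtype=float)
        b = min(0.0, float(np.dot(x, tail) / np.dot(x, x)))
        sse = float(np.sum(head ** 2) + np.sum((tail - b * x) ** 2))
        if sse < best_sse - 1e-12:
            best_sse, best_k = sse, k
    return best_k
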