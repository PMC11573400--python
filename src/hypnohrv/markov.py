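"""Sleep-stage transition matrices and their group comparison.

Sleep macrostructure is modelled as a discrete time-homogeneous Markov
chain over the five stages.  Homogeneity is pursued by estimating one
5x5 transition-probability matrix per 60-minute segment of the
synchronized, 5-hour hypnogram.  The maximum-likelihood estimate of each
entry is the transition count divided by the row total,

    p_ij = n_{i->j} / sum_j n_{i->j},

with a row left *undefined* (not zero-filled) when its state never occurs
as a transition origin within the segment.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .hypnogram import EPOCHS_PER_HOUR, STAGES, Hypnogram, segment_hypnogram
from . import stats as _stats

N_STAGES = len(STAGES)


@dataclass(frozen=True)
class TransitionCounts:
    """5x5 transition counts of one contiguous segment.

    ``counts[i, j]`` is the number of adjacent epoch pairs (stage i at t,
    stage j at t+1); for a contiguous segment the counts sum to
    ``n_epochs - 1``.
    """

    counts: np.ndarray
    n_epochs: int

    def __post_init__(self) -> None:
        c = np.asarray(self.counts, dtype=np.int64)
        object.__setattr__(self, "counts", c)
        if c.shape != (N_STAGES, N_STAGES):
            raise ValueError(f"counts must be 5x5, got {c.shape}")
        if (c < 0).any():
            raise ValueError("transition counts must be non-negative")


@dataclass(frozen=True)
class TransitionMatrix:
    """Row-stochastic 5x5 matrix with possibly undefined rows.

    Undefined rows (zero outgoing transitions) hold NaN and are flagged in
    ``row_defined``; every defined row sums to one.
    """

    probs: np.ndarray
    row_defined: np.ndarray
    partial: bool = False

    def __post_init__(self) -> None:
        p = np.asarray(self.probs, dtype=float)
        d = np.asarray(self.row_defined, dtype=bool)
        object.__setattr__(self, "probs", p)
        object.__setattr__(self, "row_defined", d)
        sums = np.nansum(p, axis=1)
        if not np.allclose(sums[d], 1.0, atol=1e-12):
            raise ValueError("defined rows must sum to 1 within 1e-12")


def count_transitions(segment: Hypnogram) -> TransitionCounts:
    """Count adjacent-epoch transitions within one segment.

    No transitions are counted across segment boundaries; a segment must
    contain at least two epochs.
    """
    s = segment.stages
    if s.size < 2:
        raise ValueError("cannot count transitions in a segment of < 2 epochs")
    c = np.zeros((N_STAGES, N_STAGES), dtype=np.int64)
    np.add.at(c, (s[:-1], s[1:]), 1)
    return TransitionCounts(counts=c, n_epochs=int(s.size))


def estimate_matrix(c: TransitionCounts, partial: bool = False) -> TransitionMatrix:
    """Row-normalize counts into transition probabilities.

    Rows with a zero total are marked undefined and filled with NaN.
    """
    totals = c.counts.sum(axis=1)
    defined = totals > 0
    probs = np.full((N_STAGES, N_STAGES), np.nan)
    probs[defined] = c.counts[defined] / totals[defined, None]
    return TransitionMatrix(probs=probs, row_defined=defined, partial=partial)


def subject_hourly_matrices(h: Hypnogram, segment_min: float = 60) -> list[TransitionMatrix]:
    """One transition matrix per 60-min segment, in temporal order.

    Expects a synchronized, truncated hypnogram; a partial final segment is
    still estimated (if it has >= 2 epochs) and flagged.
    """
    out = []
    for seg in segment_hypnogram(h, segment_min=segment_min):
        if seg.n_epochs < 2:
            continue
        out.append(estimate_matrix(count_transitions(seg), partial=seg.partial))
    return out


def pool_counts(counts: list[TransitionCounts]) -> TransitionCounts:
    """Sum transition counts over segments/subjects (for pooled estimates)."""
    total = np.zeros((N_STAGES, N_STAGES), dtype=np.int64)
    n = 0
    for c in counts:
        total += c.counts
        n += c.n_epochs
    return TransitionCounts(counts=total, n_epochs=n)


def homogeneity_chi2(counts: list[TransitionCounts]) -> tuple[float, float, int]:
    """Optional diagnostic: chi-square test of hour-to-hour homogeneity.

    Compares each segment's transition counts against the pooled
    row-conditional probabilities; rows/cells with insufficient counts are
    dropped.  Returns (statistic, p_value, dof).  Off the main path —
    stationarity is pursued by segmentation, not testing.
    """
    from scipy.stats import chi2 as chi2_dist

    pooled = pool_counts(counts)
    pooled_tot = pooled.counts.sum(axis=1)
    stat = 0.0
    dof = 0
    for c in counts:
        tot = c.counts.sum(axis=1)
        for i in range(N_STAGES):
            if tot[i] == 0 or pooled_tot[i] == 0:
                continue
            expected = tot[i] * pooled.counts[i] / pooled_tot[i]
            ok = expected >= 1
            if ok.sum() < 2:
                continue
            stat += float(((c.counts[i, ok] - expected[ok]) ** 2
                           / expected[ok]).sum())
            dof += int(ok.sum()) - 1
    dof = max(dof - N_STAGES, 1)
    return stat, float(chi2_dist.sf(stat, dof)), dof


def matrices_to_frame(subject_id: str, mats: list[TransitionMatrix]) -> pd.DataFrame:
    """Tidy per-subject table (subject_id, hour, from, to, probability)."""
    rows = []
    for hour, m in enumerate(mats, start=1):
        for i, si in enumerate(STAGES):
            for j, sj in enumerate(STAGES):
                rows.append(
                    {
                        "subject_id": subject_id,
                        "hour": hour,
                        "from": si,
                        "to": sj,
                        "probability": m.probs[i, j],
                        "defined": bool(m.row_defined[i]),
                    }
                )
    return pd.DataFrame(rows)


def compare_transitions(
    group_a: list[list[TransitionMatrix]],
    group_b: list[list[TransitionMatrix]],
    alpha: float = 0.05,
    n_hours: int = 5,
) -> pd.DataFrame:
    """Cell-wise unpaired Mann-Whitney comparison of two groups, with FDR.

    For every hour and matrix cell the subject-level probabilities of the
    two groups are compared, restricted to subjects for whom the cell's row
    is defined in that hour.  Cells with fewer than two defined values in
    either group are reported as not testable.  Benjamini-Hochberg
    adjustment is applied over the whole family of testable cells within
    this one pairwise comparison (25 cells x n_hours).
    """
    rows = []
    for hour in range(n_hours):
        for i, si in enumerate(STAGES):
            for j, sj in enumerate(STAGES):
                xa = np.array(
                    [g[hour].probs[i, j] for g in group_a
                     if hour < len(g) and g[hour].row_defined[i]]
                )
                xb = np.array(
                    [g[hour].probs[i, j] for g in group_b
                     if hour < len(g) and g[hour].row_defined[i]]
                )
                row = {
                    "hour": hour + 1,
                    "from": si,
                    "to": sj,
                    "n_a": xa.size,
                    "n_b": xb.size,
                    "median_a": float(np.median(xa)) if xa.size else np.nan,
                    "median_b": float(np.median(xb)) if xb.size else np.nan,
                    "p_raw": np.nan,
                    "testable": xa.size >= 2 and xb.size >= 2,
                }
                if row["testable"]:
                    res = _stats.mann_whitney_u(xa, xb)
                    row["p_raw"] = res.p_raw
                    row["statistic"] = res.statistic
                rows.append(row)
    df = pd.DataFrame(rows)
    df["p_fdr"] = np.nan
    testable = df["testable"].to_numpy()
    if testable.any():
        df.loc[testable, "p_fdr"] = _stats.bh_fdr(df.loc[testable, "p_raw"].to_numpy())
    df["significant"] = df["p_fdr"] < alpha
    return df
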