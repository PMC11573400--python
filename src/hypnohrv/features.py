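"""Stage-level HRV feature extraction aligned with the hypnogram.

For each sleep stage N1/N2/N3/REM within the first sleep cycle, only the
first occurrence (earliest maximal run of consecutive epochs) is used;
instantaneous HRV trajectories are averaged over the valid grid points of
that run.  The first sleep cycle is taken from sleep onset through the
end of the first REM run of at least two consecutive epochs (one minute);
a single isolated REM epoch is treated as scoring noise.  REM - NREM
difference (delta) rows are derived per subject and parameter.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .hypnogram import Hypnogram, REM, STAGES
from .pphrv import InstantaneousHRV

logger = logging.getLogger(__name__)

FEATURE_PARAMS = ("mu", "sigma2", "lf", "hf", "lfn", "hfn", "lfhf")
STAGE_NAMES = ("N1", "N2", "N3", "REM")


def _runs(stages: np.ndarray):
    """Yield (stage_code, start, stop) maximal runs (half-open epochs)."""
    n = stages.size
    a = 0
    for k in range(1, n + 1):
        if k == n or stages[k] != stages[a]:
            yield int(stages[a]), a, k
            a = k


def first_sleep_cycle(h: Hypnogram, min_rem_run: int = 2) -> tuple[int, int]:
    """Epoch range (half-open) of the first sleep cycle.

    Runs from sleep onset (epoch 0 of a synchronized hypnogram) through
    the last epoch of the first REM run of >= ``min_rem_run`` consecutive
    epochs.  Without such a run the whole record is returned with a
    warning.
    """
    for code, a, b in _runs(h.stages):
        if code == REM and (b - a) >= min_rem_run:
            return 0, b
    logger.warning("%s: no REM run of >= %d epochs; using full record",
                   h.subject_id, min_rem_run)
    return 0, h.n_epochs


def first_occurrence(h: Hypnogram, stage: int | str,
                     cycle: tuple[int, int]) -> tuple[int, int] | None:
    """Earliest maximal run of ``stage`` inside ``cycle`` (clipped to it).

    Returns a half-open epoch range, or None (logged) when the stage is
    absent from the cycle.
    """
    code = STAGES.index(stage) if isinstance(stage, str) else int(stage)
    c0, c1 = cycle
    for run_code, a, b in _runs(h.stages):
        lo, hi = max(a, c0), min(b, c1)
        if run_code == code and lo < hi:
            return lo, hi
    logger.info("%s: stage %s absent in first cycle", h.subject_id, STAGES[code])
    return None


def stage_average(hrv: InstantaneousHRV, run: tuple[int, int],
                  epoch_len: float = 30.0,
                  skip_s: float = 0.0) -> dict[str, float] | None:
    """Mean of each HRV index over valid grid points within the run.

    mu is reported in ms and sigma2 in ms^2 (trajectories are stored in
    seconds).  ``skip_s`` optionally discards the first seconds of the run
    (transient trimming; default off — the estimator adapts within
    seconds).  Returns None (logged by the caller) when no valid grid
    point falls inside the run.
    """
    t0, t1 = run[0] * epoch_len + skip_s, run[1] * epoch_len
    sel = hrv.valid & (hrv.t >= t0) & (hrv.t < t1)
    if not np.any(sel):
        return None
    out = {
        "mu": float(np.nanmean(hrv.mu[sel])) * 1e3,
        "sigma2": float(np.nanmean(hrv.sigma2[sel])) * 1e6,
        "lf": float(np.nanmean(hrv.lf[sel])),
        "hf": float(np.nanmean(hrv.hf[sel])),
        "lfn": float(np.nanmean(hrv.lfn[sel])),
        "hfn": float(np.nanmean(hrv.hfn[sel])),
        "vlf": float(np.nanmean(hrv.vlf[sel])),
    }
    lfhf = hrv.lfhf[sel]
    out["lfhf"] = float(np.nanmean(lfhf)) if np.any(np.isfinite(lfhf)) else np.nan
    out["run_start"] = t0
    out["run_end"] = t1
    out["n_valid_grid_points"] = int(sel.sum())
    return out


def subject_feature_rows(h: Hypnogram, hrv: InstantaneousHRV,
                         min_rem_run: int = 2) -> list[dict]:
    """Stage-level feature rows (long format) for one subject."""
    cycle = first_sleep_cycle(h, min_rem_run=min_rem_run)
    rows: list[dict] = []
    for stage in STAGE_NAMES:
        run = first_occurrence(h, stage, cycle)
        if run is None:
            continue
        feats = stage_average(hrv, run, epoch_len=h.epoch_len)
        if feats is None:
            logger.info("%s: no valid HRV grid points in first %s run",
                        h.subject_id, stage)
            continue
        for param in FEATURE_PARAMS:
            rows.append({
                "subject_id": h.subject_id, "group": h.group, "stage": stage,
                "parameter": param, "value": feats[param],
                "run_start": feats["run_start"], "run_end": feats["run_end"],
                "n_valid_grid_points": feats["n_valid_grid_points"],
            })
    return rows


def delta_features(features: pd.DataFrame) -> pd.DataFrame:
    """Per-subject REM - NREM difference rows per parameter.

    ``features`` is the long table from :func:`subject_feature_rows`.
    Subjects without a REM row contribute no delta rows; a missing NREM
    stage simply omits that contrast.  Deltas are antisymmetric by
    construction (REM - stage).
    """
    rows = []
    for (sid, group), sub in features.groupby(["subject_id", "group"]):
        wide = sub.pivot_table(index="stage", columns="parameter",
                               values="value", aggfunc="first")
        if "REM" not in wide.index:
            logger.info("%s: REM features missing, no delta rows", sid)
            continue
        for nrem in ("N1", "N2", "N3"):
            if nrem not in wide.index:
                continue
            for param in FEATURE_PARAMS:
                if param not in wide.columns:
                    continue
                rows.append({
                    "subject_id": sid, "group": group,
                    "contrast": f"REM-{nrem}", "parameter": param,
                    "value": float(wide.loc["REM", param] - wide.loc[nrem, param]),
                })
    return pd.DataFrame(rows)
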