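"""End-to-end orchestration: hypnogram -> Markov -> beats -> HDIG -> stats.

A :class:`RunConfig` drives the whole analysis: either a synthetic cohort
is generated (``synth``) or hypnogram/beat CSVs are read from a data
directory.  The pipeline synchronizes and truncates each hypnogram,
estimates hourly transition matrices and their pairwise group
comparisons, fits the point-process HRV model over the first sleep cycle
of each subject with usable beats, builds the stage-level feature table
and runs the statistical battery.  Everything is written as tidy CSV plus
a JSON manifest; identical configs yield identical outputs.
"""

from __future__ import annotations

import hashlib
import itertools
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import ecg as _ecg
from . import features as _features
from . import markov as _markov
from . import pphrv as _pphrv
from . import stats as _stats
from . import synth as _synth
from .hypnogram import (Hypnogram, read_hypnogram, read_metadata,
                        synchronize_to_onset, truncate_hours)

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """All pipeline settings (serialized verbatim into the manifest)."""

    out_dir: str = "hypnohrv_out"
    seed: int = 0
    data_dir: str | None = None          # read cohort from disk when set
    synth: _synth.CohortConfig | None = None
    hours: int = 5
    segment_min: float = 60.0
    # HDIG fit settings
    order: int = 9
    delta: float = 0.05
    window_s: float = 90.0
    forgetting: float = 0.98
    resume_after_s: float = 5.0
    fit_margin_s: float = 120.0          # beats kept before the cycle start
    min_rem_run: int = 2
    annotate: bool = True
    alpha: float = 0.05

    def to_manifest(self) -> dict:
        d = asdict(self)
        if self.synth is not None:
            d["synth"] = {k: v for k, v in asdict(self.synth).items()
                          if k not in ("matrices", "stage_params")}
        return d


def _load_subjects(cfg: RunConfig):
    """Yield (Hypnogram, BeatSeries | None) pairs from synth or disk."""
    if cfg.synth is not None:
        synth_cfg = cfg.synth
        if synth_cfg.seed != cfg.seed:
            synth_cfg = _synth.CohortConfig(**{**asdict(synth_cfg),
                                               "seed": cfg.seed})
        cohort = _synth.gen_cohort(synth_cfg)
        return [(s.hypnogram, s.beats) for s in cohort.subjects]
    if cfg.data_dir is None:
        raise ValueError("config must set either synth or data_dir")
    root = Path(cfg.data_dir)
    meta = read_metadata(root / "metadata.csv")
    out = []
    for sid, (group, m) in meta.items():
        h = read_hypnogram(root / f"{sid}_hypnogram.csv", subject_id=sid,
                           group=group, meta=m)
        beats_path = root / f"{sid}_beats.csv"
        beats = _ecg.read_beats_csv(beats_path) if beats_path.exists() else None
        out.append((h, beats))
    return out


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute the full analysis and write the results bundle to disk.

    Returns the in-memory results dict (matrices, comparison tables,
    feature table, stats bundle, manifest).  Subjects whose HRV fit fails
    are kept in the Markov outputs and recorded as skipped.
    """
    from . import __version__
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    subjects = _load_subjects(cfg)
    cfg_dict = cfg.to_manifest()
    cfg_hash = hashlib.sha256(
        json.dumps(cfg_dict, sort_keys=True, default=str).encode()).hexdigest()
    manifest: dict = {"version": __version__, "config": cfg_dict,
                      "config_sha256": cfg_hash,
                      "n_subjects": len(subjects), "skipped_hrv": []}

    # --- sleep structure
    per_subject_mats: dict[str, list] = {}
    prepared: list[tuple[Hypnogram, object]] = []
    tidy_frames = []
    for h, beats in subjects:
        hs = truncate_hours(synchronize_to_onset(h), hours=cfg.hours)
        mats = _markov.subject_hourly_matrices(hs, segment_min=cfg.segment_min)
        per_subject_mats[h.subject_id] = mats
        tidy_frames.append(_markov.matrices_to_frame(h.subject_id, mats))
        prepared.append((hs, beats))
    tidy = pd.concat(tidy_frames, ignore_index=True)
    groups_present = sorted({h.group for h, _ in prepared},
                            key=("CG", "iRBD", "PD_RBD").index)
    tidy.to_csv(out / "transition_probabilities.csv", index=False)

    comparisons = {}
    by_group = {g: [per_subject_mats[h.subject_id]
                    for h, _ in prepared if h.group == g]
                for g in groups_present}
    for ga, gb in itertools.combinations(groups_present, 2):
        if len(by_group[ga]) < 2 or len(by_group[gb]) < 2:
            logger.warning("comparison %s vs %s skipped (too few subjects)",
                           ga, gb)
            continue
        cmp_df = _markov.compare_transitions(
            by_group[ga], by_group[gb], alpha=cfg.alpha,
            n_hours=cfg.hours)
        cmp_df.to_csv(out / f"transitions_{ga}_vs_{gb}.csv", index=False)
        comparisons[(ga, gb)] = cmp_df

    # --- HRV over the first sleep cycle
    feature_rows = []
    for hs, beats in prepared:
        sid = hs.subject_id
        if beats is None or beats.n_beats < cfg.order + 3:
            manifest["skipped_hrv"].append({"subject_id": sid,
                                            "reason": "no usable beats"})
            continue
        if cfg.annotate:
            beats = _ecg.annotate_beats(beats)
        c0, c1 = _features.first_sleep_cycle(hs, min_rem_run=cfg.min_rem_run)
        t1 = c1 * hs.epoch_len
        try:
            fit = _pphrv.fit_hdig(
                beats, order=cfg.order, delta=cfg.delta,
                window_s=cfg.window_s, forgetting=cfg.forgetting,
                resume_after_s=cfg.resume_after_s, t_end=min(t1, beats.times[-1]))
            hrv = _pphrv.hrv_from_fit(fit)
        except (ValueError, _pphrv.FitError) as exc:
            logger.warning("%s: HRV fit failed (%s)", sid, exc)
            manifest["skipped_hrv"].append({"subject_id": sid,
                                            "reason": str(exc)})
            continue
        hrv.to_frame().to_csv(out / f"{sid}_hrv.csv", index=False)
        with (out / f"{sid}_hrv_settings.json").open("w") as fh:
            json.dump(fit.settings, fh, indent=1)
        feature_rows.extend(
            _features.subject_feature_rows(hs, hrv, min_rem_run=cfg.min_rem_run))

    features = pd.DataFrame(feature_rows)
    deltas = _features.delta_features(features) if len(features) else pd.DataFrame()
    features.to_csv(out / "stage_features.csv", index=False)
    deltas.to_csv(out / "stage_feature_deltas.csv", index=False)

    # --- statistics
    meta_rows = [{"subject_id": h.subject_id, "group": h.group,
                  "age": h.meta.age, "sex": h.meta.sex, "center": h.meta.center,
                  "ahi": h.meta.ahi, "plmi": h.meta.plmi}
                 for h, _ in prepared if h.meta is not None]
    metadata = pd.DataFrame(meta_rows)
    battery = None
    if len(features) and len(metadata) and features["group"].nunique() >= 2:
        battery = _stats.run_battery(features, metadata, deltas,
                                     alpha=cfg.alpha, seed=cfg.seed)
        for name in ("normality", "kruskal", "between", "within",
                     "delta", "logistic"):
            battery[name].to_csv(out / f"stats_{name}.csv", index=False)
        manifest["stats"] = battery["manifest"]

    with (out / "manifest.json").open("w") as fh:
        json.dump(manifest, fh, indent=1, default=str)
    return {"matrices": per_subject_mats, "comparisons": comparisons,
            "features": features, "deltas": deltas, "battery": battery,
            "manifest": manifest}
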