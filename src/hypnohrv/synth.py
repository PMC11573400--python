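"""Synthetic cohort generator: hypnograms, RR series, ECG and artifacts.

Every pipeline stage is testable without clinical data by simulating the
study's data-generating assumptions directly: hypnograms are sampled from
prescribed hour-specific transition matrices; RR series from the
history-dependent inverse-Gaussian model with stage-dependent
autoregressive structure (pole pairs placed at LF ~ 0.1 Hz and HF ~
0.25 Hz in the beat domain, so the fitted pipeline recovers prescribed
LF/HF content); ECG waveforms by convolving a QRS template on the beat
times; artifacts as extrasystole pairs and deleted beats with the ground
truth retained for scoring the cleaning stage.

Default cohort: 24 controls (CG), 27 iRBD, 27 PD-RBD.  RBD-like groups
are generated with lower overall HRV (weaker LF pole, higher IG shape)
and more fragmented sleep (lower self-transition probabilities); PD-RBD
additionally with a lower wake self-transition.  All generators are pure
functions of (config, seed).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .ecg import BeatSeries, EcgRecord
from .hypnogram import (EPOCHS_PER_HOUR, GROUPS, STAGES, Hypnogram, N1, N2,
                        N3, REM, SubjectMeta, W)

DEFAULT_GROUP_SIZES = {"CG": 24, "iRBD": 27, "PD_RBD": 27}


# ---------------------------------------------------------------------------
# Hypnogram generator

#: Conditional destination weights given that the chain leaves each stage
#: (rows W, N1, N2, N3, REM; zero diagonal, rows sum to 1).
_OFF_DIAG = np.array([
    [0.00, 0.70, 0.20, 0.02, 0.08],
    [0.30, 0.00, 0.60, 0.02, 0.08],
    [0.20, 0.20, 0.00, 0.45, 0.15],
    [0.15, 0.10, 0.70, 0.00, 0.05],
    [0.30, 0.30, 0.35, 0.05, 0.00],
])

#: Baseline (control) self-transition probabilities per hour, reflecting
#: deep sleep concentrating early in the night and REM late.
_SELF_CG = np.array([
    # W     N1    N2    N3    REM       hour
    [0.80, 0.55, 0.92, 0.96, 0.90],   # 1
    [0.80, 0.55, 0.92, 0.95, 0.92],   # 2
    [0.80, 0.55, 0.92, 0.95, 0.93],   # 3
    [0.80, 0.55, 0.92, 0.93, 0.94],   # 4
    [0.80, 0.55, 0.92, 0.91, 0.94],   # 5
])

#: Fragmentation multipliers on the leave-probability of sleep stages
#: (N1..REM) and replacement wake self-transitions per group.
_GROUP_ARCHITECTURE = {
    "CG": {"frag": 1.0, "w_self": None},
    "iRBD": {"frag": 2.2, "w_self": 0.85},     # fragmented, maintains wake
    "PD_RBD": {"frag": 1.4, "w_self": 0.72},   # milder fragmentation, leaves wake
}


def matrix_from_self(self_probs: np.ndarray) -> np.ndarray:
    """Row-stochastic 5x5 matrix from per-stage self-transition probabilities."""
    m = _OFF_DIAG * (1.0 - np.asarray(self_probs, dtype=float))[:, None]
    m[np.diag_indices(5)] = self_probs
    return m


def default_transition_matrices(group: str, n_hours: int = 5) -> np.ndarray:
    """(n_hours, 5, 5) generator matrices encoding group sleep architecture."""
    arch = _GROUP_ARCHITECTURE[group]
    out = np.empty((n_hours, 5, 5))
    for h in range(n_hours):
        self_p = _SELF_CG[min(h, _SELF_CG.shape[0] - 1)].copy()
        self_p[N1:] = 1.0 - (1.0 - self_p[N1:]) * arch["frag"]
        if arch["w_self"] is not None:
            self_p[W] = arch["w_self"]
        out[h] = matrix_from_self(self_p)
    return out


def gen_hypnogram(
    matrices: np.ndarray,
    n_epochs: int,
    initial_stage: int = N1,
    seed: int | np.random.Generator = 0,
    subject_id: str = "synthetic",
    group: str = "CG",
    meta: SubjectMeta | None = None,
) -> Hypnogram:
    """Sample a Markov-chain hypnogram from per-hour transition matrices.

    ``matrices`` has shape (5, 5) for a single matrix or (H, 5, 5) for
    hour-specific matrices switched at each 120-epoch boundary (the last
    matrix persists beyond H hours).  Deterministic given the seed.
    """
    mats = np.asarray(matrices, dtype=float)
    if mats.ndim == 2:
        mats = mats[None]
    if mats.shape[1:] != (5, 5):
        raise ValueError(f"matrices must be (H, 5, 5), got {mats.shape}")
    if not np.allclose(mats.sum(axis=2), 1.0, atol=1e-9) or (mats < 0).any():
        raise ValueError("generator matrices must be row-stochastic")
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    cum = np.cumsum(mats, axis=2)
    stages = np.empty(n_epochs, dtype=np.int8)
    state = int(initial_stage)
    u = rng.random(n_epochs)
    for k in range(n_epochs):
        hour = min(k // EPOCHS_PER_HOUR, mats.shape[0] - 1)
        state = int(np.searchsorted(cum[hour, state], u[k], side="right"))
        stages[k] = state
    return Hypnogram(subject_id=subject_id, group=group, stages=stages, meta=meta)


# ---------------------------------------------------------------------------
# RR generator (HDIG used generatively)

@dataclass(frozen=True)
class StageHDIG:
    """Per-stage generator settings: stationary mean RR, AR coefficients
    (beat domain, any order), and inverse-Gaussian shape."""

    mean_rr: float
    theta_ar: np.ndarray
    shape: float

    def __post_init__(self) -> None:
        ar = np.asarray(self.theta_ar, dtype=float)
        object.__setattr__(self, "theta_ar", ar)
        if self.mean_rr <= 0 or self.shape <= 0:
            raise ValueError("mean_rr and shape must be positive")

    @property
    def theta0(self) -> float:
        return self.mean_rr * (1.0 - float(self.theta_ar.sum()))


def ar_from_poles(poles: list[tuple[float, float]], mean_rr: float) -> np.ndarray:
    """AR coefficients with complex pole pairs at given (radius, f_hz).

    Frequencies are mapped to the beat domain via phi = f * mean_rr
    cycles/beat, so the fitted spectrum (mapped back by the instantaneous
    mean) peaks near the requested Hz frequencies.
    """
    roots: list[complex] = []
    for r, f_hz in poles:
        if not 0 <= r < 1:
            raise ValueError(f"pole radius must be in [0, 1), got {r}")
        omega = 2.0 * np.pi * f_hz * mean_rr
        roots += [r * np.exp(1j * omega), r * np.exp(-1j * omega)]
    a = np.poly(roots).real  # [1, a1, a2, ...]
    return -a[1:]


def default_stage_params(group: str) -> dict[int, StageHDIG]:
    """Stage-dependent HDIG generator parameters per group.

    Controls get a strong LF resonance and moderate HF; deeper NREM gets
    relatively stronger HF (vagal) content and REM stronger LF.  RBD-like
    groups get a weaker LF pole and a larger IG shape (smaller innovation
    variance), i.e. globally reduced HRV; PD-RBD most reduced.
    """
    lf_r, hf_r, sw = {
        "CG": (0.88, 0.80, 0.020),
        "iRBD": (0.70, 0.74, 0.013),
        "PD_RBD": (0.62, 0.70, 0.010),
    }[group]
    means = {W: 0.80, N1: 0.90, N2: 0.95, N3: 1.00, REM: 0.85}
    # stage-specific emphasis: N3 vagal-dominant, REM LF-dominant
    emph = {
        W: (0.00, 0.00),
        N1: (0.00, 0.00),
        N2: (0.00, 0.02),
        N3: (-0.06, 0.08),
        REM: (0.05, -0.06),
    }
    out = {}
    for stage, mean in means.items():
        d_lf, d_hf = emph[stage]
        r_lf = min(lf_r + d_lf, 0.96)
        r_hf = min(hf_r + d_hf, 0.96)
        ar = ar_from_poles([(r_lf, 0.10), (r_hf, 0.25)], mean)
        shape = mean ** 3 / sw ** 2
        out[stage] = StageHDIG(mean_rr=mean, theta_ar=ar, shape=shape)
    return out


def gen_rr(
    h: Hypnogram,
    stage_params: dict[int, StageHDIG],
    seed: int | np.random.Generator = 0,
    t_end: float | None = None,
) -> BeatSeries:
    """Sample beats sequentially from the stage-switching HDIG model.

    Each next interval is inverse-Gaussian with mean from the current
    stage's AR regression on the simulated history and the stage's shape;
    parameters switch at 30-s stage boundaries, history carries over.
    The history is seeded at the first stage's stationary mean.  Raises if
    the conditional mean drifts outside [0.2, 3] s (unstable AR), naming
    the stage.
    """
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    present = set(int(s) for s in np.unique(h.stages))
    missing = present - set(stage_params)
    if missing:
        raise ValueError(f"stage_params missing stages {sorted(missing)}")
    duration = t_end if t_end is not None else h.duration_s
    epoch_len = h.epoch_len
    stages = h.stages
    n_ep = stages.size
    max_p = max(sp.theta_ar.size for sp in stage_params.values())
    first = stage_params[int(stages[0])]
    hist = [first.mean_rr] * max_p  # most recent first
    t = 0.0
    times = [0.0]
    while t < duration:
        sp = stage_params[int(stages[min(int(t // epoch_len), n_ep - 1)])]
        ar = sp.theta_ar
        mu = sp.theta0
        for j in range(ar.size):
            mu += ar[j] * hist[j]
        if not 0.2 <= mu <= 3.0:
            stage_name = STAGES[int(stages[min(int(t // epoch_len), n_ep - 1)])]
            raise ValueError(
                f"unstable RR generator in stage {stage_name}: mean {mu:.3f} s")
        w = float(rng.wald(mu, sp.shape))
        t += w
        if t > duration:
            break
        times.append(t)
        hist.insert(0, w)
        hist.pop()
    return BeatSeries(times=np.asarray(times))


# ---------------------------------------------------------------------------
# ECG generator

def qrs_template(fs: float = 512.0) -> np.ndarray:
    """A stylized QRS complex: dominant R wave with small Q/S deflections.

    Centered on its maximum so that placing it at a beat time puts the
    R peak exactly there.
    """
    t = np.arange(-0.06, 0.06 + 1.0 / fs, 1.0 / fs)
    r = np.exp(-0.5 * (t / 0.010) ** 2)
    q = -0.15 * np.exp(-0.5 * ((t + 0.030) / 0.008) ** 2)
    s = -0.20 * np.exp(-0.5 * ((t - 0.030) / 0.008) ** 2)
    return r + q + s


def gen_ecg(
    beats: BeatSeries,
    template: np.ndarray | None = None,
    fs: float = 512.0,
    noise_sd: float = 0.0,
    seed: int | np.random.Generator = 0,
    duration_s: float | None = None,
) -> EcgRecord:
    """Place a QRS template at each beat time and add white noise.

    The ground-truth beat times live in ``beats``; the record is suitable
    for scoring the detector against them.  Raises when the template is
    longer than the shortest RR interval.
    """
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    tpl = qrs_template(fs) if template is None else np.asarray(template, float)
    if beats.n_beats >= 2:
        min_rr = float(np.min(np.diff(beats.times)))
        if tpl.size / fs > min_rr:
            raise ValueError("QRS template longer than the minimum RR interval")
    dur = duration_s if duration_s is not None else (
        float(beats.times[-1]) + 1.0 if beats.n_beats else 1.0)
    n = int(round(dur * fs))
    x = np.zeros(n)
    center = int(np.argmax(tpl))
    for t in beats.times:
        i0 = int(round(t * fs)) - center
        a = max(i0, 0)
        b = min(i0 + tpl.size, n)
        if b > a:
            x[a:b] += tpl[a - i0:b - i0]
    if noise_sd > 0:
        x += rng.normal(0.0, noise_sd, size=n)
    return EcgRecord(samples=x, fs=fs)


# ---------------------------------------------------------------------------
# Artifact injection

def inject_artifacts(
    beats: BeatSeries,
    ectopic_rate: float = 0.0,
    missed_rate: float = 0.0,
    seed: int | np.random.Generator = 0,
) -> tuple[BeatSeries, dict]:
    """Inject extrasystoles and missed beats; keep the ground truth separate.

    Rates are events per hour.  An ectopic replaces the next sinus beat by
    an early beat at 0.45x the local median RR after the anchor, creating
    the short + compensatory-pause pair (sum ~ 2x local RR) that the
    cleaning rules target.  A missed beat is a deletion.  The returned
    series carries only ``normal`` labels (classification is the cleaner's
    job); the truth dict records the injected event times.
    """
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    t = beats.times.copy()
    if t.size < 20:
        raise ValueError("too few beats to inject artifacts")
    hours = (t[-1] - t[0]) / 3600.0
    n_ect = int(rng.poisson(ectopic_rate * hours))
    n_miss = int(rng.poisson(missed_rate * hours))
    if (2 * n_ect + n_miss) > 0.2 * t.size:
        raise ValueError("artifact rates too high (> 20% of beats affected)")
    interior = np.arange(6, t.size - 6)
    n_events = n_ect + n_miss
    if n_events == 0:
        return BeatSeries(times=t), {"ectopic_times": [], "missed_times": []}
    chosen = rng.choice(interior, size=min(n_events, interior.size // 4),
                        replace=False)
    # keep injection sites separated so signatures do not overlap
    chosen = np.sort(chosen)
    keep = [chosen[0]]
    for c in chosen[1:]:
        if c - keep[-1] > 6:
            keep.append(c)
    chosen = np.asarray(keep)
    ect_sites = chosen[:n_ect]
    miss_sites = chosen[n_ect:n_ect + n_miss]

    rr = np.diff(t)
    ect_times, miss_times = [], []
    remove = set()
    inserts = []
    for j in ect_sites:
        med = float(np.median(rr[max(0, j - 5):j + 6]))
        ect_t = t[j] + 0.45 * med
        remove.add(j + 1)          # drop the next sinus beat
        inserts.append(ect_t)      # insert the early ectopic
        ect_times.append(float(ect_t))
    for j in miss_sites:
        remove.add(int(j))
        miss_times.append(float(t[j]))
    kept = np.delete(t, sorted(remove))
    out = np.sort(np.concatenate([kept, np.asarray(inserts)]))
    truth = {"ectopic_times": ect_times, "missed_times": miss_times}
    return BeatSeries(times=out), truth


# ---------------------------------------------------------------------------
# Cohort assembly

@dataclass
class CohortConfig:
    """Everything needed to generate a reproducible synthetic study."""

    group_sizes: dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_GROUP_SIZES))
    hours: int = 5
    extra_epochs: int = 40           # generated beyond the study window
    seed: int = 0
    ectopic_per_h: float = 0.0
    missed_per_h: float = 0.0
    matrices: dict[str, np.ndarray] | None = None      # per-group override
    stage_params: dict[str, dict[int, StageHDIG]] | None = None
    with_ecg: bool = False
    ecg_noise_sd: float = 0.05
    #: metadata sampling: (age_mean, age_sd, male_frac, ahi_mean, ahi_sd,
    #: plmi_mean, plmi_sd) per group, mirroring the cohort description
    demographics: dict[str, tuple] = field(default_factory=lambda: {
        "CG": (60.0, 10.0, 0.46, 2.96, 3.07, 12.67, 17.11),
        "iRBD": (67.0, 7.0, 0.63, 3.85, 5.34, 13.29, 15.38),
        "PD_RBD": (68.0, 8.0, 0.74, 5.01, 4.18, 12.78, 15.81),
    })

    def __post_init__(self) -> None:
        for g, n in self.group_sizes.items():
            if g not in GROUPS:
                raise ValueError(f"unknown group {g!r}")
            if n < 0:
                raise ValueError("group sizes must be non-negative")


@dataclass
class SyntheticSubject:
    hypnogram: Hypnogram
    beats: BeatSeries
    ecg: EcgRecord | None = None
    artifact_truth: dict | None = None


@dataclass
class Cohort:
    subjects: list[SyntheticSubject]
    manifest: dict


def _gamma_params(mean: float, sd: float) -> tuple[float, float]:
    k = (mean / sd) ** 2
    return k, mean / k


def gen_cohort(config: CohortConfig) -> Cohort:
    """Generate the full synthetic study from a master seed.

    Each subject draws from an independent seeded sub-stream spawned from
    the master seed; the manifest records every spawned seed so any
    subject can be regenerated in isolation.
    """
    groups = [g for g in GROUPS if config.group_sizes.get(g, 0) > 0]
    n_epochs = config.hours * EPOCHS_PER_HOUR + config.extra_epochs
    master = np.random.SeedSequence(config.seed)
    subjects: list[SyntheticSubject] = []
    manifest: dict = {"seed": config.seed, "subjects": [], "groups": groups,
                      "hours": config.hours}
    total = sum(config.group_sizes.get(g, 0) for g in groups)
    spawned = master.spawn(total)
    k = 0
    for group in groups:
        mats = (config.matrices or {}).get(group)
        if mats is None:
            mats = default_transition_matrices(group, config.hours)
        sparams = (config.stage_params or {}).get(group)
        if sparams is None:
            sparams = default_stage_params(group)
        a_m, a_sd, male, ahi_m, ahi_sd, plmi_m, plmi_sd = config.demographics[group]
        for i in range(config.group_sizes[group]):
            ss = spawned[k]
            k += 1
            rng = np.random.default_rng(ss)
            sid = f"{group}_{i:03d}"
            age = float(np.clip(rng.normal(a_m, a_sd), 40, 90))
            sex = int(rng.random() >= male)  # male=0 with probability male
            center = int(rng.integers(0, 2))
            ka, ta = _gamma_params(ahi_m, ahi_sd)
            kp, tp = _gamma_params(plmi_m, plmi_sd)
            meta = SubjectMeta(age=age, sex=sex, center=center,
                               ahi=float(rng.gamma(ka, ta)),
                               plmi=float(rng.gamma(kp, tp)))
            h = gen_hypnogram(mats, n_epochs, initial_stage=N1, seed=rng,
                              subject_id=sid, group=group, meta=meta)
            beats = gen_rr(h, sparams, seed=rng)
            truth = None
            if config.ectopic_per_h > 0 or config.missed_per_h > 0:
                beats, truth = inject_artifacts(
                    beats, config.ectopic_per_h, config.missed_per_h, seed=rng)
            ecg = None
            if config.with_ecg:
                ecg = gen_ecg(beats, noise_sd=config.ecg_noise_sd, seed=rng)
            subjects.append(SyntheticSubject(
                hypnogram=h, beats=beats, ecg=ecg, artifact_truth=truth))
            manifest["subjects"].append(
                {"subject_id": sid, "group": group,
                 "seed_entropy": int(ss.entropy),
                 "spawn_key": [int(x) for x in ss.spawn_key]})
    return Cohort(subjects=subjects, manifest=manifest)


def write_cohort(cohort: Cohort, outdir: str | Path) -> None:
    """Emit the cohort in the same plain-text formats the readers consume."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    meta_rows = []
    for s in cohort.subjects:
        h = s.hypnogram
        sid = h.subject_id
        pd.DataFrame({"epoch_index": np.arange(h.n_epochs),
                      "stage": h.labels()}).to_csv(
            outdir / f"{sid}_hypnogram.csv", index=False)
        pd.DataFrame({"time_s": s.beats.times,
                      "label": s.beats.labels}).to_csv(
            outdir / f"{sid}_beats.csv", index=False)
        m = h.meta
        meta_rows.append({"subject_id": sid, "group": h.group, "age": m.age,
                          "sex": m.sex, "center": m.center, "ahi": m.ahi,
                          "plmi": m.plmi})
    pd.DataFrame(meta_rows).to_csv(outdir / "metadata.csv", index=False)
    with (outdir / "manifest.json").open("w") as fh:
        json.dump(cohort.manifest, fh, indent=1)
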