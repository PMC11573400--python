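"""Hypnogram parsing, validation, synchronization and segmentation.

A hypnogram is the manually scored sleep-stage sequence of a night of
polysomnography: one label per 30-second epoch over the five AASM states
W (wake), N1, N2, N3 (increasing NREM depth) and REM.  Downstream analysis
works on hypnograms synchronized on sleep onset (first non-wake epoch),
trimmed at the last non-wake epoch, truncated to a fixed study window and
cut into fixed-length segments over which sleep-stage transitions are
assumed time-homogeneous.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

logger = logging.getLogger(__name__)

#: Fixed stage order used everywhere (rows/columns of transition matrices).
STAGES: tuple[str, ...] = ("W", "N1", "N2", "N3", "REM")
STAGE_INDEX: dict[str, int] = {s: i for i, s in enumerate(STAGES)}
W, N1, N2, N3, REM = range(5)

EPOCH_LEN_S = 30.0
EPOCHS_PER_HOUR = 120  # 3600 s / 30 s

GROUPS = ("CG", "iRBD", "PD_RBD")

#: Built-in stage-label dialects.  AASM letters (with both "R" and "REM"
#: accepted) and the common numeric convention where REM is coded 5.
DIALECTS: dict[str, dict[str, int]] = {
    "aasm": {"W": W, "N1": N1, "N2": N2, "N3": N3, "R": REM, "REM": REM},
    "numeric": {"0": W, "1": N1, "2": N2, "3": N3, "5": REM},
}


class HypnogramError(ValueError):
    """Invalid hypnogram content or operation."""


class HypnogramParseError(HypnogramError):
    """Unparseable hypnogram file (reports token and line number)."""


@dataclass(frozen=True)
class SubjectMeta:
    """Per-subject covariates used by the regression layer.

    Encodings are fixed: sex male=0 / female=1; first center=0, second
    center=1.  AHI and PLMI are events per hour (non-negative).
    """

    age: float
    sex: int
    center: int
    ahi: float = 0.0
    plmi: float = 0.0

    def __post_init__(self) -> None:
        if self.sex not in (0, 1):
            raise ValueError(f"sex must be 0 (male) or 1 (female), got {self.sex}")
        if self.center not in (0, 1):
            raise ValueError(f"center must be 0 or 1, got {self.center}")
        if self.ahi < 0 or self.plmi < 0:
            raise ValueError("AHI and PLMI must be non-negative")


@dataclass(frozen=True)
class Hypnogram:
    """A validated 30-s-epoch sleep-stage sequence.

    ``stages`` holds integer codes in the fixed order W=0, N1=1, N2=2,
    N3=3, REM=4.  ``start_epoch`` records the offset of this (possibly
    segmented) sequence relative to the synchronized record, so epoch ``k``
    covers seconds ``[(start_epoch+k)*30, (start_epoch+k+1)*30)``.
    """

    subject_id: str
    group: str
    stages: np.ndarray
    epoch_len: float = EPOCH_LEN_S
    meta: SubjectMeta | None = None
    start_epoch: int = 0
    partial: bool = False

    def __post_init__(self) -> None:
        stages = np.asarray(self.stages, dtype=np.int8)
        object.__setattr__(self, "stages", stages)
        if self.epoch_len != EPOCH_LEN_S:
            raise HypnogramError(f"epoch length is fixed at 30 s, got {self.epoch_len}")
        if stages.ndim != 1 or stages.size < 1:
            raise HypnogramError("hypnogram must contain at least one epoch")
        if stages.min() < 0 or stages.max() > 4:
            bad = stages[(stages < 0) | (stages > 4)][0]
            raise HypnogramError(f"stage code out of range 0..4: {bad}")
        if self.group not in GROUPS:
            raise HypnogramError(f"unknown group {self.group!r}; expected one of {GROUPS}")

    @property
    def n_epochs(self) -> int:
        return int(self.stages.size)

    @property
    def duration_s(self) -> float:
        return self.n_epochs * self.epoch_len

    @property
    def start_s(self) -> float:
        return self.start_epoch * self.epoch_len

    def labels(self) -> list[str]:
        return [STAGES[s] for s in self.stages]


def read_hypnogram(
    path: str | Path,
    dialect: str | Mapping[str, int] = "aasm",
    subject_id: str | None = None,
    group: str = "CG",
    meta: SubjectMeta | None = None,
) -> Hypnogram:
    """Read a hypnogram from a text file.

    Accepted layouts: one stage token per row, or CSV rows
    ``epoch_index,stage`` (a header line is ignored).  Tokens are mapped
    through ``dialect`` (a built-in name or an explicit token->code table).
    Unknown tokens raise :class:`HypnogramParseError` naming the token and
    its line number.
    """
    path = Path(path)
    table = DIALECTS[dialect] if isinstance(dialect, str) else dict(dialect)
    codes: list[int] = []
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            parts = [p.strip() for p in line.split(",")]
            token = parts[-1]  # last column is the stage in the CSV layout
            if lineno == 1 and token.lower() in ("stage", "sleep_stage"):
                continue  # header
            if token not in table:
                raise HypnogramParseError(
                    f"{path.name}:{lineno}: unmappable stage token {token!r}"
                )
            codes.append(table[token])
    if not codes:
        raise HypnogramParseError(f"{path.name}: empty hypnogram file")
    return Hypnogram(
        subject_id=subject_id or path.stem,
        group=group,
        stages=np.asarray(codes, dtype=np.int8),
        meta=meta,
    )


def read_metadata(path: str | Path) -> dict[str, tuple[str, SubjectMeta]]:
    """Read the sidecar metadata CSV.

    Columns: subject_id, group, age, sex, center, ahi, plmi.
    Returns ``{subject_id: (group, SubjectMeta)}``.
    """
    out: dict[str, tuple[str, SubjectMeta]] = {}
    with Path(path).open(newline="") as fh:
        for row in csv.DictReader(fh):
            meta = SubjectMeta(
                age=float(row["age"]),
                sex=int(row["sex"]),
                center=int(row["center"]),
                ahi=float(row.get("ahi", 0) or 0),
                plmi=float(row.get("plmi", 0) or 0),
            )
            out[row["subject_id"]] = (row["group"], meta)
    return out


def synchronize_to_onset(h: Hypnogram) -> Hypnogram:
    """Clip to [first non-wake epoch, last non-wake epoch].

    Sleep onset is the first epoch whose stage differs from W; the record
    end is the last such epoch.  Idempotent.  Raises on all-wake input.
    """
    non_w = np.flatnonzero(h.stages != W)
    if non_w.size == 0:
        raise HypnogramError(f"{h.subject_id}: no sleep onset (all-wake hypnogram)")
    a, b = int(non_w[0]), int(non_w[-1]) + 1
    if a == 0 and b == h.n_epochs:
        return h
    return replace(h, stages=h.stages[a:b], start_epoch=0)


def truncate_hours(h: Hypnogram, hours: int = 5) -> Hypnogram:
    """Keep at most ``hours`` hours (hours*120 epochs) from the start.

    Shorter records are returned unchanged with a logged warning.
    """
    if hours <= 0:
        raise HypnogramError(f"hours must be positive, got {hours}")
    limit = hours * EPOCHS_PER_HOUR
    if h.n_epochs <= limit:
        if h.n_epochs < limit:
            logger.warning(
                "%s: only %d epochs available for a %d-hour window",
                h.subject_id, h.n_epochs, hours,
            )
        return h
    return replace(h, stages=h.stages[:limit])


def segment_hypnogram(h: Hypnogram, segment_min: float = 60) -> list[Hypnogram]:
    """Cut into consecutive non-overlapping segments of ``segment_min`` minutes.

    A final shorter remainder is kept and flagged ``partial``.  Concatenating
    the segments reproduces the input exactly.
    """
    if segment_min <= 0:
        raise HypnogramError(f"segment_min must be positive, got {segment_min}")
    seg_len = int(round(segment_min * 60 / h.epoch_len))
    out: list[Hypnogram] = []
    for a in range(0, h.n_epochs, seg_len):
        b = min(a + seg_len, h.n_epochs)
        out.append(
            replace(
                h,
                stages=h.stages[a:b],
                start_epoch=h.start_epoch + a,
                partial=(b - a) < seg_len,
            )
        )
    return out
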