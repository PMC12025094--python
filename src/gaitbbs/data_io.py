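"""Reading, writing and validating IMU recordings and BBS label tables.

Recordings are plain CSV, one row per 10-ms sample (100 Hz), with a
one-line header naming the 12 channels in the fixed convention

    left_ax,left_ay,left_az,left_gx,left_gy,left_gz,
    right_ax,right_ay,right_az,right_gx,right_gy,right_gz

(three-axis acceleration then three-axis angular velocity, left calf node
first). An optional leading ``t`` column carries timestamps in seconds and
is checked for uniform spacing against the declared sample rate. Columns
given in a different order are normalised to the convention above. Units
are carried as opaque metadata: the downstream static-baseline
standardization makes the pipeline unit-invariant, so no conversion is
attempted.

Label tables are CSV with columns ``subject_id,bbs_score,group`` where
``bbs_score`` is the clinical Berg Balance Scale total (integer 0-56) and
``group`` is one of young_hc / elderly_hc / pd / stroke / unknown.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import (
    DataError,
    DuplicateSubjectError,
    FormatError,
    RangeError,
    TimingError,
)

__all__ = [
    "CHANNELS",
    "GROUPS",
    "ImuRecording",
    "SubjectLabel",
    "read_recording",
    "write_recording",
    "read_labels",
    "write_labels",
]

_AXES = ("ax", "ay", "az", "gx", "gy", "gz")
#: Fixed channel order: left node accel+gyro, then right node accel+gyro.
CHANNELS: tuple[str, ...] = tuple(f"{side}_{axis}" for side in ("left", "right")
                                  for axis in _AXES)
#: Index of the right-node Z-axis angular velocity (default trigger channel).
RIGHT_GZ: int = CHANNELS.index("right_gz")
GROUPS: tuple[str, ...] = ("young_hc", "elderly_hc", "pd", "stroke", "unknown")

#: Static baseline shorter than this duration (the standing protocol) warns.
STATIC_PROTOCOL_SECONDS = 10.0


def _check_matrix(name: str, x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if x.ndim != 2 or x.shape[1] != len(CHANNELS):
        raise FormatError(f"{name} must be a T x {len(CHANNELS)} matrix, got shape {x.shape}")
    bad = np.argwhere(~np.isfinite(x))
    if bad.size:
        r, c = bad[0]
        raise DataError(f"{name} has a missing/non-finite value at row {r}, column {CHANNELS[c]}")
    return x


@dataclass
class ImuRecording:
    """One subject's walking signal plus a static standing baseline."""

    subject_id: str
    walking: np.ndarray
    static: np.ndarray
    group: str = "unknown"
    sample_rate: float = 100.0

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise RangeError(f"unknown group {self.group!r}; expected one of {GROUPS}")
        if self.sample_rate <= 0:
            raise RangeError("sample_rate must be positive")
        self.walking = _check_matrix("walking", self.walking)
        self.static = _check_matrix("static", self.static)
        if self.walking.shape[0] == 0:
            raise DataError(f"{self.subject_id}: walking matrix is empty")
        static_seconds = self.static.shape[0] / self.sample_rate
        if static_seconds < 1.0:
            raise DataError(
                f"{self.subject_id}: static baseline is {static_seconds:.2f} s; need >= 1 s")
        if static_seconds < STATIC_PROTOCOL_SECONDS:
            warnings.warn(
                f"{self.subject_id}: static baseline is {static_seconds:.1f} s, "
                f"shorter than the {STATIC_PROTOCOL_SECONDS:.0f} s standing protocol",
                stacklevel=2)

    @property
    def n_samples(self) -> int:
        return int(self.walking.shape[0])


@dataclass(frozen=True)
class SubjectLabel:
    """A subject's clinician-assigned BBS total score (0-56) and cohort group."""

    subject_id: str
    bbs_score: int
    group: str = "unknown"

    def __post_init__(self) -> None:
        if not 0 <= self.bbs_score <= 56:
            raise RangeError(
                f"{self.subject_id}: bbs_score {self.bbs_score} outside the 0-56 scale")
        if self.group not in GROUPS:
            raise RangeError(f"unknown group {self.group!r}; expected one of {GROUPS}")


def _load_signal_csv(path: str | Path, sample_rate: float) -> np.ndarray:
    path = Path(path)
    df = pd.read_csv(path)
    cols = list(df.columns)
    if cols and cols[0] == "t":
        t = df.pop("t").to_numpy(dtype=float)
        if len(t) > 1:
            dt = np.diff(t)
            nominal = 1.0 / sample_rate
            if np.any(np.abs(dt - nominal) > 0.01 * nominal):
                i = int(np.argmax(np.abs(dt - nominal) > 0.01 * nominal))
                raise TimingError(
                    f"{path.name}: timestamp spacing at row {i + 1} deviates more than "
                    f"1% from 1/{sample_rate:g} s")
        cols = list(df.columns)
    if sorted(cols) != sorted(CHANNELS):
        raise FormatError(
            f"{path.name}: expected the 12 channel columns {list(CHANNELS)} "
            f"(optionally preceded by 't'), got {cols}")
    df = df[list(CHANNELS)]  # normalise column order; idempotent
    arr = df.to_numpy(dtype=float)
    bad = np.argwhere(~np.isfinite(arr))
    if bad.size:
        r, c = bad[0]
        raise DataError(f"{path.name}: missing value at row {r}, column {CHANNELS[c]}")
    return arr


def read_recording(walking_path: str | Path, static_path: str | Path,
                   subject_id: str, group: str = "unknown",
                   sample_rate: float = 100.0) -> ImuRecording:
    """Load and validate one subject's walking + static CSV pair."""
    walking = _load_signal_csv(walking_path, sample_rate)
    static = _load_signal_csv(static_path, sample_rate)
    return ImuRecording(subject_id=subject_id, walking=walking, static=static,
                        group=group, sample_rate=sample_rate)


def write_recording(rec: ImuRecording, walking_path: str | Path,
                    static_path: str | Path, include_time: bool = False) -> None:
    """Write a recording as a CSV pair re-readable by :func:`read_recording`.

    Values are written at full float repr precision, so a write/read
    round-trip is lossless.
    """
    for arr, path in ((rec.walking, walking_path), (rec.static, static_path)):
        df = pd.DataFrame(arr, columns=list(CHANNELS))
        if include_time:
            df.insert(0, "t", np.arange(len(arr)) / rec.sample_rate)
        Path(path).parent.mkdir(parents=True, exist_ok=True)
        df.to_csv(path, index=False)


def read_labels(path: str | Path) -> list[SubjectLabel]:
    """Load a label table; one validated row per subject."""
    df = pd.read_csv(path, dtype={"subject_id": str})
    required = {"subject_id", "bbs_score", "group"}
    if not required.issubset(df.columns):
        raise FormatError(f"label table must have columns {sorted(required)}, "
                          f"got {list(df.columns)}")
    dup = df["subject_id"][df["subject_id"].duplicated()]
    if not dup.empty:
        raise DuplicateSubjectError(f"duplicate subject_id: {dup.iloc[0]!r}")
    return [SubjectLabel(subject_id=row.subject_id, bbs_score=int(row.bbs_score),
                         group=row.group)
            for row in df.itertuples()]


def write_labels(labels: list[SubjectLabel], path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(
        [{"subject_id": l.subject_id, "bbs_score": l.bbs_score, "group": l.group}
         for l in labels]
    ).to_csv(path, index=False)
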