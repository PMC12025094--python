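"""Signal conditioning and windowing: filter, standardize, segment, label.

The pipeline turns each raw recording into fixed-size training windows:

1. **Low-pass filtering** — 4th-order Butterworth, 20 Hz cut-off, applied
   forward-backward (zero phase) so the trigger peak is not shifted.
2. **Static-baseline standardization** — per channel j,
   ``X'[:, j] = (X[:, j] - mean(static[:, j])) / sd(static[:, j])``,
   using that subject's standing-still recording (itself filtered with the
   same filter). This removes sensor offsets and makes the pipeline
   unit-invariant.
3. **Label normalization** — BBS totals are mapped from 0-56 to [0, 1] by
   min-max scaling, ``S' = S / 56``.
4. **Truncation and segmentation** — the unsteady ends of each recording
   are discarded (30 s per end by default), and the remainder is sliced
   into consecutive non-overlapping 2-s windows of exactly 200 x 12 values
   at 100 Hz; a trailing remainder shorter than one window is dropped.
   A 5-min recording therefore yields 120 windows, and a 40-subject cohort
   4800. Alternatively the usable span can start at the first prominent
   peak of a Z-axis angular-velocity channel (the gait "trigger point").

Every window inherits its subject's normalized score — weak labelling of
windows by the subject-level clinical total.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
from scipy import signal as sp_signal

from .data_io import CHANNELS, RIGHT_GZ, ImuRecording, SubjectLabel
from .errors import (
    ConfigError,
    DegenerateBaselineError,
    LengthError,
    MissingLabelError,
    RangeError,
    TooShortError,
    TriggerNotFoundError,
)

__all__ = [
    "BBS_MAX",
    "PreprocessConfig",
    "GaitSegment",
    "GaitDataset",
    "lowpass_filter",
    "standardize",
    "normalize_score",
    "denormalize_score",
    "detect_trigger",
    "truncate_and_segment",
    "segment_matrix",
    "build_dataset",
]

#: Maximum of the Berg Balance Scale (14 tasks x 4 points).
BBS_MAX = 56


@dataclass(frozen=True)
class PreprocessConfig:
    """Filtering, trimming and windowing settings.

    ``trim_policy`` selects how the usable span starts: ``fixed_both_ends``
    drops ``end_trim_seconds`` from both ends (the default; with 5-min
    recordings this yields the canonical 120 windows per subject), while
    ``trigger_plus_fixed`` starts at the first qualifying peak of the
    trigger channel at or after the start trim, still dropping
    ``end_trim_seconds`` at the end.
    """

    filter_order: int = 4
    cutoff_hz: float = 20.0
    window_seconds: float = 2.0
    stride_seconds: float | None = None  # None -> non-overlapping (= window)
    trim_policy: str = "fixed_both_ends"
    end_trim_seconds: float = 30.0
    trigger_channel: int = RIGHT_GZ
    trigger_min_prominence_frac: float = 0.5

    def __post_init__(self) -> None:
        if self.filter_order < 1:
            raise ConfigError("filter_order must be >= 1")
        if self.cutoff_hz <= 0:
            raise ConfigError("cutoff_hz must be positive")
        if self.window_seconds <= 0:
            raise ConfigError("window_seconds must be positive")
        if self.trim_policy not in ("fixed_both_ends", "trigger_plus_fixed"):
            raise ConfigError(f"unknown trim_policy {self.trim_policy!r}")
        if not 0 < self.trigger_min_prominence_frac <= 1:
            raise ConfigError("trigger_min_prominence_frac must be in (0, 1]")
        if not 0 <= self.trigger_channel < len(CHANNELS):
            raise ConfigError("trigger_channel out of range")

    def window_samples(self, sample_rate: float) -> int:
        w = self.window_seconds * sample_rate
        if abs(w - round(w)) > 1e-9:
            raise ConfigError(
                f"window_seconds x sample_rate must be an integer, got {w}")
        return int(round(w))

    def stride_samples(self, sample_rate: float) -> int:
        if self.stride_seconds is None:
            return self.window_samples(sample_rate)
        s = self.stride_seconds * sample_rate
        if abs(s - round(s)) > 1e-9 or round(s) < 1:
            raise ConfigError("stride_seconds x sample_rate must be a positive integer")
        return int(round(s))

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class GaitSegment:
    """One standardized window (window_samples x 12, unit-free)."""

    values: np.ndarray
    subject_id: str
    segment_index: int


def lowpass_filter(x: np.ndarray, sample_rate: float,
                   cfg: PreprocessConfig = PreprocessConfig()) -> np.ndarray:
    """Zero-phase Butterworth low-pass along axis 0; shape-preserving.

    Forward-backward application squares the magnitude response (an
    effective 8th-order rolloff for the default 4th-order design) and
    cancels the phase, so a DC component passes with unit gain and no lag.
    """
    x = np.asarray(x, dtype=float)
    nyq = sample_rate / 2.0
    if cfg.cutoff_hz >= nyq:
        raise ConfigError(
            f"cutoff {cfg.cutoff_hz} Hz must be below the Nyquist frequency {nyq} Hz")
    n = x.shape[0]
    if n <= 3 * cfg.filter_order:
        raise LengthError(
            f"signal length {n} too short for an order-{cfg.filter_order} filter")
    sos = sp_signal.butter(cfg.filter_order, cfg.cutoff_hz, btype="low",
                           fs=sample_rate, output="sos")
    padlen = min(3 * (2 * cfg.filter_order + 1), n - 1)
    return sp_signal.sosfiltfilt(sos, x, axis=0, padlen=padlen)


def standardize(walking: np.ndarray, static: np.ndarray) -> np.ndarray:
    """Per-channel (x - mean(static)) / sd(static); population sd."""
    walking = np.asarray(walking, dtype=float)
    static = np.asarray(static, dtype=float)
    mu = static.mean(axis=0)
    sd = static.std(axis=0)
    low = np.flatnonzero(sd < 1e-12)
    if low.size:
        raise DegenerateBaselineError(
            f"static baseline channel {CHANNELS[low[0]]} has ~zero standard deviation")
    return (walking - mu) / sd


def normalize_score(s: float) -> float:
    """Min-max normalize a BBS total from [0, 56] to [0, 1]."""
    if not 0 <= s <= BBS_MAX:
        raise RangeError(f"BBS score {s} outside [0, {BBS_MAX}]")
    return float(s) / BBS_MAX


def denormalize_score(sp: float | np.ndarray) -> float | np.ndarray:
    """Map a normalized score back to the 0-56 scale, clipping to [0, 1]."""
    arr = np.asarray(sp, dtype=float)
    if np.any(arr < 0) or np.any(arr > 1):
        warnings.warn("normalized score outside [0, 1]; clipping", stacklevel=2)
        arr = np.clip(arr, 0.0, 1.0)
    out = BBS_MAX * arr
    # snap float residue so normalize/denormalize round-trips integers exactly
    near = np.round(out)
    out = np.where(np.abs(out - near) < 1e-9, near, out)
    return float(out) if np.isscalar(sp) or out.ndim == 0 else out


def detect_trigger(x: np.ndarray, cfg: PreprocessConfig = PreprocessConfig(),
                   start: int = 0) -> int:
    """Index of the first qualifying peak of the Z-axis angular velocity.

    A qualifying peak is a local maximum of the configured trigger channel,
    at or after ``start``, whose height is at least
    ``trigger_min_prominence_frac`` of the channel's global maximum.
    """
    x = np.asarray(x, dtype=float)
    ch = x[:, cfg.trigger_channel] if x.ndim == 2 else x
    height = cfg.trigger_min_prominence_frac * ch.max()
    peaks, _ = sp_signal.find_peaks(ch[start:], height=height)
    if peaks.size == 0:
        raise TriggerNotFoundError(
            f"no peak >= {cfg.trigger_min_prominence_frac:.0%} of channel max "
            f"on channel {CHANNELS[cfg.trigger_channel]}")
    return int(peaks[0]) + start


def segment_matrix(x: np.ndarray, sample_rate: float, cfg: PreprocessConfig,
                   subject_id: str = "") -> list[GaitSegment]:
    """Truncate both ends of a T x 12 matrix and slice it into windows."""
    x = np.asarray(x, dtype=float)
    T = x.shape[0]
    W = cfg.window_samples(sample_rate)
    stride = cfg.stride_samples(sample_rate)
    trim = int(round(cfg.end_trim_seconds * sample_rate))
    if cfg.trim_policy == "fixed_both_ends":
        start = trim
    else:  # trigger_plus_fixed
        start = detect_trigger(x, cfg, start=trim)
    end = T - trim
    if end - start < W:
        raise TooShortError(
            f"{subject_id or 'recording'}: {max(end - start, 0)} samples left after "
            f"truncation; need at least one window of {W}")
    kept = x[start:end]
    n = (kept.shape[0] - W) // stride + 1
    return [GaitSegment(values=kept[i * stride:i * stride + W],
                        subject_id=subject_id, segment_index=i)
            for i in range(n)]


def truncate_and_segment(rec: ImuRecording,
                         cfg: PreprocessConfig = PreprocessConfig()) -> list[GaitSegment]:
    """Segment a recording's walking signal (no filtering/standardization)."""
    return segment_matrix(rec.walking, rec.sample_rate, cfg, rec.subject_id)


class GaitDataset:
    """Parallel arrays of windows, normalized labels and subject metadata."""

    def __init__(self, X: np.ndarray, y: np.ndarray, subject_ids: np.ndarray,
                 groups: np.ndarray, manifest: dict | None = None) -> None:
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        subject_ids = np.asarray(subject_ids)
        groups = np.asarray(groups)
        n = len(X)
        if not (len(y) == len(subject_ids) == len(groups) == n):
            raise ValueError("X, y, subject_ids, groups must have equal length")
        if n and (y.min() < 0 or y.max() > 1):
            raise RangeError("normalized labels must lie in [0, 1]")
        self.X, self.y = X, y
        self.subject_ids, self.groups = subject_ids, groups
        self.manifest = manifest or {}

    def __len__(self) -> int:
        return len(self.X)

    def subset(self, idx: np.ndarray) -> "GaitDataset":
        return GaitDataset(self.X[idx], self.y[idx], self.subject_ids[idx],
                           self.groups[idx], manifest=self.manifest)

    def save(self, out_dir: str | Path) -> None:
        """Write arrays (.npz) plus a JSON manifest recording provenance."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        np.savez(out / "data.npz", X=self.X, y=self.y,
                 subject_ids=self.subject_ids.astype(str),
                 groups=self.groups.astype(str))
        (out / "manifest.json").write_text(json.dumps(
            {**self.manifest, "n_segments": len(self)}, indent=2))

    @classmethod
    def load(cls, in_dir: str | Path) -> "GaitDataset":
        in_dir = Path(in_dir)
        with np.load(in_dir / "data.npz") as z:
            X, y = z["X"], z["y"]
            subject_ids, groups = z["subject_ids"], z["groups"]
        manifest = json.loads((in_dir / "manifest.json").read_text())
        return cls(X, y, subject_ids, groups, manifest=manifest)


def build_dataset(recordings: list[ImuRecording], labels: list[SubjectLabel],
                  cfg: PreprocessConfig = PreprocessConfig()) -> GaitDataset:
    """Full per-subject pipeline: filter, standardize, segment, label.

    The static baseline is passed through the same low-pass filter before
    its mean/sd are taken, so both signals see identical conditioning.
    """
    by_id = {l.subject_id: l for l in labels}
    X_parts: list[np.ndarray] = []
    y_parts: list[float] = []
    sid_parts: list[str] = []
    group_parts: list[str] = []
    counts: dict[str, int] = {}
    for rec in recordings:
        label = by_id.get(rec.subject_id)
        if label is None:
            raise MissingLabelError(f"no label for subject {rec.subject_id!r}")
        try:
            walking = lowpass_filter(rec.walking, rec.sample_rate, cfg)
            static = lowpass_filter(rec.static, rec.sample_rate, cfg)
            standardized = standardize(walking, static)
            segments = segment_matrix(standardized, rec.sample_rate, cfg,
                                      rec.subject_id)
        except Exception as exc:
            raise type(exc)(f"subject {rec.subject_id!r}: {exc}") from exc
        s_norm = normalize_score(label.bbs_score)
        for seg in segments:
            X_parts.append(seg.values)
            y_parts.append(s_norm)
            sid_parts.append(rec.subject_id)
            group_parts.append(label.group)
        counts[rec.subject_id] = len(segments)
    manifest = {
        "preprocess_config": cfg.to_dict(),
        "segments_per_subject": counts,
        "config_hash": hashlib.sha256(
            json.dumps(cfg.to_dict(), sort_keys=True).encode()).hexdigest()[:16],
    }
    return GaitDataset(np.stack(X_parts), np.array(y_parts),
                       np.array(sid_parts), np.array(group_parts),
                       manifest=manifest)
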