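"""Synthetic two-node IMU gait generator with score-dependent degradation.

The private clinical dataset behind this pipeline cannot be shared, so this
module provides a statistical stand-in with the structure the pipeline
assumes: 100 Hz sampling, 12 channels (two calf nodes x 3-axis acceleration
+ 3-axis angular velocity), ~1.6-s gait cycles, a 10-s static standing
baseline, and a **monotone mapping from the Berg Balance Scale score to
gait-signal degradation**. Lower scores produce

* larger stride-to-stride period variability (stride-time CV),
* stronger left/right amplitude asymmetry,
* a stronger 4-6 Hz tremor-band component, and
* a smaller overall movement amplitude,

all interpolated linearly between their values at score 0 and score 56.
This is explicitly *not* a biomechanical model: waveforms are harmonic
stacks over a jittered stride phase, chosen only so that (a) every
simulated subject survives the real preprocessing pipeline, (b) the
Z-axis angular velocity shows one clear peak per stride for trigger
detection, and (c) the score is recoverable from the signal by a learner.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
from scipy import stats as sp_stats

from .data_io import (
    CHANNELS,
    ImuRecording,
    SubjectLabel,
    read_labels,
    read_recording,
    write_labels,
    write_recording,
)
from .errors import ConfigError, RangeError
from .preprocessing import BBS_MAX

__all__ = [
    "SimConfig",
    "SimulatedSubject",
    "REFERENCE_GROUP_SIZES",
    "REFERENCE_GROUP_SCORES",
    "gait_waveform",
    "stride_phase",
    "simulate_subject",
    "simulate_subjects",
    "simulate_cohort",
    "write_cohort",
    "read_cohort",
]

#: Cohort composition of the reference study population.
REFERENCE_GROUP_SIZES: dict[str, int] = {
    "young_hc": 12, "elderly_hc": 8, "pd": 8, "stroke": 12,
}
#: Printed BBS mean +/- SD per group of the reference study population.
REFERENCE_GROUP_SCORES: dict[str, tuple[float, float]] = {
    "young_hc": (55.67, 0.75),
    "elderly_hc": (50.63, 3.67),
    "pd": (47.63, 3.04),
    "stroke": (44.50, 2.47),
}

# Fundamental amplitude per axis (ax, ay, az, gx, gy, gz) of one node; the
# Z-axis angular velocity dominates so per-stride peaks are unambiguous.
_NODE_AMPLITUDES = (0.5, 0.3, 0.8, 0.6, 0.4, 1.0)
# Constant sensor offsets (gravity-like on az, small biases elsewhere); the
# same offsets appear in walking and static data, so standardization
# removes them.
_NODE_OFFSETS = (0.05, -0.03, 1.0, 0.02, -0.01, 0.04)


@dataclass(frozen=True)
class SimConfig:
    """Generator settings; defaults are the study conditions emulated."""

    sample_rate: float = 100.0
    duration_seconds: float = 300.0
    static_seconds: float = 10.0
    cycle_seconds: float = 1.6
    n_harmonics: int = 4
    base_amplitudes: tuple = _NODE_AMPLITUDES * 2
    score_range: tuple = (30, 56)
    stride_cv_at_0: float = 0.12
    stride_cv_at_56: float = 0.02
    asymmetry_at_0: float = 0.30
    asymmetry_at_56: float = 0.02
    tremor_amp_at_0: float = 0.5
    amp_at_0: float = 0.6
    noise_sd: float = 0.05
    static_noise_sd: float = 0.02

    def __post_init__(self) -> None:
        if self.cycle_seconds <= 0:
            raise ConfigError("cycle_seconds must be positive")
        if self.n_harmonics < 1:
            raise ConfigError("n_harmonics must be >= 1")
        if len(self.base_amplitudes) != len(CHANNELS):
            raise ConfigError(f"base_amplitudes must have {len(CHANNELS)} entries")
        lo, hi = self.score_range
        if not (0 <= lo <= hi <= BBS_MAX):
            raise ConfigError("score_range must satisfy 0 <= low <= high <= 56")
        for name in ("stride_cv_at_0", "stride_cv_at_56", "asymmetry_at_0",
                     "asymmetry_at_56", "tremor_amp_at_0", "amp_at_0",
                     "noise_sd", "static_noise_sd"):
            if getattr(self, name) < 0 or not np.isfinite(getattr(self, name)):
                raise ConfigError(f"{name} must be finite and non-negative")

    def interp(self, at_0: float, at_56: float, score: float) -> float:
        """Linear interpolation of a degradation parameter in the score."""
        return at_0 + (at_56 - at_0) * score / BBS_MAX

    def to_dict(self) -> dict:
        d = asdict(self)
        d["base_amplitudes"] = list(self.base_amplitudes)
        d["score_range"] = list(self.score_range)
        return d


@dataclass
class SimulatedSubject:
    """A generated recording, its label, and the latent parameters used."""

    recording: ImuRecording
    label: SubjectLabel
    latent: dict


def stride_phase(t: np.ndarray, score: float, cfg: SimConfig,
                 rng: np.random.Generator) -> np.ndarray:
    """Cumulative gait phase (strides completed) over a jittered stride train.

    Successive stride periods are ``cycle_seconds * (1 + cv * eps)`` with
    standard-normal ``eps`` truncated at +/-3; the coefficient of variation
    ``cv`` interpolates from ``stride_cv_at_0`` down to ``stride_cv_at_56``.
    The phase is piecewise linear, increasing by exactly 1 per stride.
    """
    cv = cfg.interp(cfg.stride_cv_at_0, cfg.stride_cv_at_56, score)
    n_strides = int(np.ceil(t[-1] / cfg.cycle_seconds)) + 3
    eps = np.clip(rng.standard_normal(n_strides), -3.0, 3.0)
    periods = cfg.cycle_seconds * (1.0 + cv * eps)
    boundaries = np.concatenate([[0.0], np.cumsum(periods)])
    while boundaries[-1] < t[-1]:
        extra = cfg.cycle_seconds * (1.0 + cv * float(np.clip(rng.standard_normal(), -3, 3)))
        boundaries = np.append(boundaries, boundaries[-1] + extra)
    return np.interp(t, boundaries, np.arange(len(boundaries), dtype=float))


# Deterministic per-(channel, harmonic) phase offsets; the right node runs
# half a cycle out of phase with the left (contralateral stepping).
def _harmonic_phase(channel: int, harmonic: int) -> float:
    base = 2 * np.pi * ((0.13 * channel + 0.41 * harmonic) % 1.0)
    if channel >= len(CHANNELS) // 2:
        base += np.pi * harmonic
    return base


def gait_waveform(score: float, channel: int, t: np.ndarray, cfg: SimConfig,
                  rng: np.random.Generator,
                  phase: np.ndarray | None = None) -> np.ndarray:
    """One channel of score-degraded walking signal on time grid ``t``.

    When ``phase`` is omitted a fresh jittered stride phase is drawn from
    ``rng``; :func:`simulate_subject` passes one shared phase to all 12
    channels so they describe the same stride train.
    """
    t = np.asarray(t, dtype=float)
    if phase is None:
        phase = stride_phase(t, score, cfg, rng)
    amp_scale = cfg.interp(cfg.amp_at_0, 1.0, score)
    asym = cfg.interp(cfg.asymmetry_at_0, cfg.asymmetry_at_56, score)
    side = 1.0 + asym / 2.0 if channel < len(CHANNELS) // 2 else 1.0 - asym / 2.0
    amp = amp_scale * side * cfg.base_amplitudes[channel]
    x = np.zeros_like(t)
    for h in range(1, cfg.n_harmonics + 1):
        x += (amp / h) * np.sin(2 * np.pi * h * phase + _harmonic_phase(channel, h))
    tremor_amp = cfg.interp(cfg.tremor_amp_at_0, 0.0, score) * cfg.base_amplitudes[channel]
    if tremor_amp > 0:
        f_tremor = rng.uniform(4.0, 6.0)
        x += tremor_amp * np.sin(2 * np.pi * f_tremor * t + rng.uniform(0, 2 * np.pi))
    if cfg.noise_sd > 0:
        x += rng.normal(0.0, cfg.noise_sd, size=t.shape)
    return x


def simulate_subject(score: float, cfg: SimConfig, rng: np.random.Generator,
                     subject_id: str = "s00", group: str = "unknown") -> SimulatedSubject:
    """Generate one subject: 12-channel walking matrix + static baseline."""
    lo, hi = cfg.score_range
    if not lo <= score <= hi:
        raise RangeError(f"score {score} outside configured range [{lo}, {hi}]")
    n_walk = int(round(cfg.duration_seconds * cfg.sample_rate))
    n_static = int(round(cfg.static_seconds * cfg.sample_rate))
    t = np.arange(n_walk) / cfg.sample_rate
    phase = stride_phase(t, score, cfg, rng)
    offsets = np.array(_NODE_OFFSETS * 2)
    walking = np.empty((n_walk, len(CHANNELS)))
    for ch in range(len(CHANNELS)):
        walking[:, ch] = offsets[ch] + gait_waveform(score, ch, t, cfg, rng, phase=phase)
    static_sd = max(cfg.static_noise_sd, 1e-6)  # keep standardization well-posed
    static = offsets + rng.normal(0.0, static_sd, size=(n_static, len(CHANNELS)))
    recording = ImuRecording(subject_id=subject_id, walking=walking, static=static,
                             group=group, sample_rate=cfg.sample_rate)
    label = SubjectLabel(subject_id=subject_id, bbs_score=int(round(score)), group=group)
    latent = {
        "score": float(score),
        "stride_cv": cfg.interp(cfg.stride_cv_at_0, cfg.stride_cv_at_56, score),
        "asymmetry": cfg.interp(cfg.asymmetry_at_0, cfg.asymmetry_at_56, score),
        "tremor_amp": cfg.interp(cfg.tremor_amp_at_0, 0.0, score),
        "amp_scale": cfg.interp(cfg.amp_at_0, 1.0, score),
    }
    return SimulatedSubject(recording=recording, label=label, latent=latent)


def simulate_subjects(n: int, cfg: SimConfig, seed: int = 0,
                      group: str = "unknown") -> list[SimulatedSubject]:
    """``n`` subjects with integer scores drawn uniformly from score_range."""
    rng = np.random.default_rng(seed)
    lo, hi = cfg.score_range
    scores = rng.integers(int(lo), int(hi) + 1, size=n)
    return [simulate_subject(float(s), cfg, rng, subject_id=f"s{i:03d}", group=group)
            for i, s in enumerate(scores)]


def simulate_cohort(group_sizes: dict[str, int] | None = None,
                    score_stats: dict[str, tuple[float, float]] | None = None,
                    cfg: SimConfig | None = None,
                    seed: int = 0) -> list[SimulatedSubject]:
    """A stratified cohort with per-group truncated-normal score draws.

    Defaults mirror the reference study population: 12 young HC, 8 elderly
    HC, 8 PD, 12 stroke, with the printed group score means/SDs. Scores are
    clipped to [0, 56] and rounded to integers.
    """
    from dataclasses import replace

    group_sizes = dict(REFERENCE_GROUP_SIZES if group_sizes is None else group_sizes)
    score_stats = dict(REFERENCE_GROUP_SCORES if score_stats is None else score_stats)
    # group draws live on the full scale regardless of cfg.score_range
    cfg = SimConfig(score_range=(0, 56)) if cfg is None \
        else replace(cfg, score_range=(0, 56))
    rng = np.random.default_rng(seed)
    subjects: list[SimulatedSubject] = []
    i = 0
    for group, size in group_sizes.items():
        mean, sd = score_stats[group]
        a, b = (0 - mean) / sd, (BBS_MAX - mean) / sd
        draws = sp_stats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=size,
                                       random_state=rng)
        for score in np.clip(np.round(draws), 0, BBS_MAX):
            subjects.append(simulate_subject(float(score), cfg, rng,
                                             subject_id=f"s{i:03d}", group=group))
            i += 1
    return subjects


def write_cohort(subjects: list[SimulatedSubject], out_dir: str | Path,
                 cfg: SimConfig | None = None) -> None:
    """Write per-subject walking/static CSVs plus a labels table."""
    import json

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for sub in subjects:
        sid = sub.recording.subject_id
        write_recording(sub.recording, out / f"{sid}_walking.csv",
                        out / f"{sid}_static.csv")
    write_labels([s.label for s in subjects], out / "labels.csv")
    if cfg is not None:
        (out / "sim_config.json").write_text(json.dumps(cfg.to_dict(), indent=2))


def read_cohort(in_dir: str | Path,
                sample_rate: float = 100.0) -> tuple[list[ImuRecording], list[SubjectLabel]]:
    """Load a cohort directory written by :func:`write_cohort`."""
    in_dir = Path(in_dir)
    labels = read_labels(in_dir / "labels.csv")
    recordings = [
        read_recording(in_dir / f"{l.subject_id}_walking.csv",
                       in_dir / f"{l.subject_id}_static.csv",
                       subject_id=l.subject_id, group=l.group,
                       sample_rate=sample_rate)
        for l in labels
    ]
    return recordings, labels
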