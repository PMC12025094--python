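"""Agreement and error metrics: MAE/RMSE, Bland-Altman, subgroups, ablation.

MAE is the mean absolute difference between clinician-assigned and
predicted scores; RMSE the root of the mean squared difference (always
>= MAE). Bland-Altman analysis takes one predicted and one reference score
per subject, plots their difference against their average, and declares
limits of agreement at the mean difference +/- 1.96 population standard
deviations of the differences — under approximately normal differences,
~95% of subjects fall within the limits. Subgroup stratification recomputes
MAE/RMSE within participant cohorts (young/elderly healthy controls,
Parkinson's disease, stroke); pooled MSE is the size-weighted mean of group
MSEs, which the pooled metrics honour by re-pooling rather than averaging
group values. The ablation runner trains each module-combination arm on
identical folds with an identical seed so arm differences reflect
architecture only.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np

from .errors import DomainError, ShapeError
from .model import ModelConfig
from .preprocessing import BBS_MAX

__all__ = [
    "BlandAltman",
    "mae",
    "rmse",
    "aggregate_subject_scores",
    "bland_altman",
    "stratified_metrics",
    "run_ablation",
]


def _paired(actual, predicted) -> tuple[np.ndarray, np.ndarray]:
    a = np.asarray(actual, dtype=float)
    p = np.asarray(predicted, dtype=float)
    if a.shape != p.shape:
        raise ShapeError(f"length mismatch: {a.shape} vs {p.shape}")
    if a.size == 0:
        raise DomainError("need at least one pair of scores")
    return a, p


def mae(actual, predicted) -> float:
    """Mean absolute error."""
    a, p = _paired(actual, predicted)
    return float(np.mean(np.abs(p - a)))


def rmse(actual, predicted) -> float:
    """Root mean squared error; >= MAE on the same inputs."""
    a, p = _paired(actual, predicted)
    return float(np.sqrt(np.mean((p - a) ** 2)))


def aggregate_subject_scores(window_predictions) -> float:
    """One score per subject: mean of denormalized window predictions, clipped.

    Accepts predictions already on the 0-56 scale; values outside are
    clipped to the scale bounds after averaging.
    """
    p = np.asarray(window_predictions, dtype=float)
    if p.size == 0:
        raise DomainError("subject has no window predictions")
    return float(np.clip(p.mean(), 0.0, BBS_MAX))


@dataclass
class BlandAltman:
    """Limits-of-agreement summary; differences are predicted - actual."""

    mean_diff: float
    loa_low: float
    loa_high: float
    averages: np.ndarray
    differences: np.ndarray
    within_fraction: float
    degenerate: bool = False

    def to_dict(self) -> dict:
        d = asdict(self)
        d["averages"] = self.averages.tolist()
        d["differences"] = self.differences.tolist()
        return d


def bland_altman(actual, predicted) -> BlandAltman:
    """Agreement analysis with limits at mean_diff +/- 1.96 population SD."""
    a, p = _paired(actual, predicted)
    if a.size < 3:
        raise DomainError("Bland-Altman needs at least 3 pairs")
    diff = p - a
    avg = (p + a) / 2.0
    mean_diff = float(diff.mean())
    sd = float(diff.std())  # population (divide-by-n) form
    degenerate = sd < 1e-12
    loa_low = mean_diff - 1.96 * sd
    loa_high = mean_diff + 1.96 * sd
    within = np.count_nonzero((diff >= loa_low) & (diff <= loa_high))
    return BlandAltman(
        mean_diff=mean_diff,
        loa_low=loa_low,
        loa_high=loa_high,
        averages=avg,
        differences=diff,
        within_fraction=within / a.size,
        degenerate=degenerate,
    )


def stratified_metrics(actual, predicted, groups) -> dict[str, dict[str, float]]:
    """Per-group MAE/RMSE plus pooled metrics under key ``"overall"``."""
    a, p = _paired(actual, predicted)
    g = np.asarray(groups)
    if g.shape != a.shape:
        raise ShapeError("groups must parallel the score arrays")
    out: dict[str, dict[str, float]] = {}
    for group in dict.fromkeys(g.tolist()):  # stable first-appearance order
        m = g == group
        out[str(group)] = {"mae": mae(a[m], p[m]), "rmse": rmse(a[m], p[m]),
                           "n": int(m.sum())}
    out["overall"] = {"mae": mae(a, p), "rmse": rmse(a, p), "n": int(a.size)}
    return out


def run_ablation(dataset, arms: dict[str, ModelConfig], train_cfg) -> list[dict]:
    """Cross-validate each arm on identical folds; rows sorted by RMSE."""
    from .training import cross_validate, make_folds  # deferred: avoids cycle

    if not arms:
        raise DomainError("need at least one ablation arm")
    folds = make_folds(dataset, train_cfg)
    rows = []
    for name, cfg in arms.items():
        result = cross_validate(dataset, cfg, train_cfg, folds=folds)
        rows.append({"arm": name, "mean_rmse": result.mean_rmse,
                     "mean_mae": result.mean_mae})
    return sorted(rows, key=lambda r: r["mean_rmse"])
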