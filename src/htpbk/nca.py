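"""Non-compartmental summary parameters and profile-level log2 error metrics.

AUC(0–last) uses the linear up / log down trapezoid: linear rule on rising
or flat segments, the logarithmic rule ΔC/ln(C_i/C_{i+1})·Δt on strictly
falling segments with both endpoints positive, linear fallback otherwise.

The two profile-level errors are the mean signed and mean unsigned
log2(predicted/observed) over all usable datapoints of a profile: the
signed mean captures bias, the unsigned mean overall closeness.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .engine import ConcentrationTimeProfile

FOLD_RANGES = (1.5, 2.0, 3.0, 5.0, 10.0)

#: floor for non-positive predictions at usable observed points (mg/L)
PREDICTION_FLOOR = 1e-12


@dataclass(frozen=True)
class ProfileMetrics:
    cmax: float   # mg/L
    tmax: float   # h
    auc_0_last: float  # mg*h/L

    def __post_init__(self) -> None:
        if self.cmax < 0 or self.auc_0_last < 0:
            raise ValueError("cmax and AUC must be >= 0")


@dataclass(frozen=True)
class ErrorPair:
    relative_log2: float
    absolute_log2: float
    n_points: int
    n_excluded: int = 0

    def __post_init__(self) -> None:
        if self.n_points <= 0:
            raise ValueError("n_points must be > 0")
        if self.absolute_log2 < 0:
            raise ValueError("absolute_log2 must be >= 0")
        if abs(self.relative_log2) > self.absolute_log2 + 1e-12:
            raise ValueError("|relative| must not exceed absolute log2 error")


def _auc_segment(t0: float, t1: float, c0: float, c1: float) -> float:
    dt = t1 - t0
    if c1 < c0 and c0 > 0 and c1 > 0:
        return (c0 - c1) / math.log(c0 / c1) * dt
    return 0.5 * (c0 + c1) * dt


def nca(profile: ConcentrationTimeProfile) -> ProfileMetrics:
    """Cmax, Tmax (earliest maximum) and linear-up-log-down AUC(0–last)."""
    t = np.asarray(profile.times, dtype=float)
    c = np.asarray(profile.concentrations, dtype=float)
    if len(t) < 2:
        raise ValueError("NCA needs at least 2 datapoints")
    imax = int(np.argmax(c))  # argmax returns the first maximum: earliest-time tie-break
    auc = 0.0
    for i in range(len(t) - 1):
        auc += _auc_segment(t[i], t[i + 1], c[i], c[i + 1])
    return ProfileMetrics(cmax=float(c[imax]), tmax=float(t[imax]), auc_0_last=float(auc))


def profile_log2_errors(pred: ConcentrationTimeProfile,
                        obs: ConcentrationTimeProfile,
                        loq: float = 0.0) -> ErrorPair:
    """Mean signed / unsigned log2(pred/obs) over the observed timepoints.

    ``pred`` must be evaluated at the observed times.  Observed values at or
    below ``loq`` are excluded (their count is reported); non-positive
    predictions at usable points are floored at 1e-12 mg/L with a warning.
    """
    tp = np.asarray(pred.times, dtype=float)
    to = np.asarray(obs.times, dtype=float)
    if len(tp) != len(to) or not np.allclose(tp, to, rtol=1e-9, atol=1e-9):
        raise ValueError("prediction must be evaluated at the observed timepoints")
    p = np.asarray(pred.concentrations, dtype=float)
    o = np.asarray(obs.concentrations, dtype=float)

    usable = o > loq
    n_excluded = int((~usable).sum())
    if not usable.any():
        raise ValueError("no usable datapoints (all observations <= LOQ)")
    p = p[usable]
    o = o[usable]
    if np.any(p <= 0):
        warnings.warn(f"{int((p <= 0).sum())} non-positive predictions floored at {PREDICTION_FLOOR}")
        p = np.maximum(p, PREDICTION_FLOOR)

    ratios = np.log2(p / o)
    return ErrorPair(
        relative_log2=float(np.mean(ratios)),
        absolute_log2=float(np.mean(np.abs(ratios))),
        n_points=int(len(ratios)),
        n_excluded=n_excluded,
    )


def fold_summaries(pairs: Sequence[tuple[float, float]],
                   k_set: Sequence[float] = FOLD_RANGES) -> dict[float, float]:
    """Percent of (pred, obs) pairs with |log2(pred/obs)| <= log2(k), per k."""
    if not len(pairs):
        raise ValueError("fold_summaries needs at least one pair")
    arr = np.asarray(pairs, dtype=float)
    if np.any(arr <= 0):
        raise ValueError("fold summaries require positive pred/obs values")
    logr = np.abs(np.log2(arr[:, 0] / arr[:, 1]))
    return {float(k): float(100.0 * np.mean(logr <= math.log2(k) + 1e-12)) for k in k_set}
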