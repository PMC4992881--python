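"""Deterministic stage-structured population projection.

The projection is an expected-value renewal process driven by the fitted (or
analytic) schedules: a cohort of E eggs whose age-0 day is day b contributes
``E * s_{t-b, j}`` individuals to stage j on day t and lays ``E * lm_{t-b}``
eggs during day t.  Eggs laid during day t are censused as the age-0 cohort
of day t+1 -- the timing consistent with the (x+1) exponent of the renewal
equation, so the asymptotic daily growth factor of the projection equals
``lambda = exp(r)`` of the same schedule.  Counts are real-valued
expectations; there is no demographic stochasticity, and the projection is
exactly linear in the initial egg number.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .cohort import STAGES

__all__ = [
    "ProjectionConfig",
    "ProjectionResult",
    "project",
    "asymptotic_growth",
    "stable_distribution_check",
]


@dataclass(frozen=True)
class ProjectionConfig:
    """Initial egg number (the study used 10) and horizon in days."""

    initial_eggs: float = 10.0
    horizon: int = 600

    def __post_init__(self) -> None:
        if self.horizon < 1:
            raise ValueError("horizon must be at least 1 day")
        if self.initial_eggs < 0:
            raise ValueError("initial_eggs must be non-negative")


@dataclass
class ProjectionResult:
    """Daily expected counts per stage plus totals and the birth series."""

    counts: np.ndarray  # (horizon+1, 5)
    births: np.ndarray  # (horizon+1,) age-0 cohort sizes per day
    config: ProjectionConfig

    @property
    def total(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    @property
    def days(self) -> np.ndarray:
        return np.arange(len(self.births))

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.counts, columns=list(STAGES))
        df.insert(0, "day", self.days)
        df["total"] = self.total
        return df


def project(
    survival: np.ndarray, lm_x: np.ndarray, config: ProjectionConfig
) -> ProjectionResult:
    """Project population size and stage composition from an egg pulse.

    Parameters
    ----------
    survival
        The age-stage survival matrix s_xj of the underlying cohort; stage
    membership of each projected cohort uses these proportions directly
        (mortality is inside s_xj, no re-normalisation).
    lm_x
        Age-specific maternity of the same cohort.
    """
    survival = np.asarray(survival, dtype=float)
    lm = np.asarray(lm_x, dtype=float)
    if survival.shape[0] != lm.shape[0]:
        raise ValueError("survival and lm_x must cover the same ages")
    horizon = config.horizon
    x_max = survival.shape[0] - 1
    births = np.zeros(horizon + 1)
    births[0] = config.initial_eggs
    # eggs laid during day t join as the age-0 cohort of day t+1
    for t in range(1, horizon + 1):
        lo = max(0, t - 1 - x_max)
        seg = births[lo:t]  # cohorts born on days lo..t-1, at ages t-1-b
        births[t] = float(np.dot(seg, lm[: t - lo][::-1]))
    counts = np.zeros((horizon + 1, survival.shape[1]))
    for t in range(horizon + 1):
        lo = max(0, t - x_max)
        seg = births[lo : t + 1]
        ages = np.arange(t - lo, -1, -1)
        counts[t] = seg @ survival[ages]
    return ProjectionResult(counts=counts, births=births, config=config)


def asymptotic_growth(result: ProjectionResult, window: int = 50) -> float:
    """Geometric mean of the daily growth factors over the final `window`
    days; NaN if any total in the window is zero."""
    totals = result.total
    if window < 1 or window >= len(totals):
        raise ValueError("window must satisfy 1 <= window < horizon + 1")
    tail = totals[-(window + 1):]
    if (tail <= 0).any():
        return float("nan")
    return float((tail[-1] / tail[0]) ** (1.0 / window))


def stable_distribution_check(
    result: ProjectionResult, tol: float = 1e-4
) -> Optional[int]:
    """Earliest day after which the stage-proportion vector moves less than
    `tol` (max-norm) between every pair of consecutive days.

    Returns None when the proportions never settle within the horizon (or the
    population dies out, making proportions degenerate).
    """
    totals = result.total
    if (totals <= 0).any():
        return None
    props = result.counts / totals[:, None]
    delta = np.abs(np.diff(props, axis=0)).max(axis=1)  # delta[t-1]: day t-1 -> t
    bad = np.nonzero(delta >= tol)[0]
    if bad.size == 0:
        return 0
    first_stable = int(bad[-1]) + 1
    if first_stable >= len(totals) - 1:
        return None
    return first_stable
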