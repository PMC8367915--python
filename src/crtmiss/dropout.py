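"""Discrete-time Weibull model for cluster dropout.

A cluster leaves the trial at the end of some calendar day and contributes no
later measurements (monotone right-censoring).  Survival to day ``t`` follows
a discrete Weibull: with time rescaled to ``tau = (t - 1) / (t_max - 1)``,

    S(t) = (1 - omega) ** (tau ** gamma),

so ``S(1) = 1`` (every cluster yields at least its first day) and
``S(t_max) = 1 - omega``: ``omega`` is the proportion of clusters lost over a
trial of maximal duration ``t_max`` days.  The shape ``gamma`` controls the
hazard trajectory: constant for ``gamma = 1``, decreasing for ``gamma < 1``
(early dropout), increasing for ``gamma > 1`` (late dropout).

From the survival curve evaluated at a design's measurement days, the
probability ``p_h`` that a cluster yields exactly its first ``h`` measurement
periods is a telescoping difference of survival values; the expected
per-count cluster numbers ``k * p`` feed the variance engine directly, and a
multinomial sampling alternative is provided for validation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .design import DesignError, TrialDesign

__all__ = [
    "DropoutModel",
    "survival",
    "hazard",
    "count_probabilities",
    "expected_counts",
    "sample_counts",
    "survival_table",
]


@dataclass(frozen=True)
class DropoutModel:
    """Weibull cluster-dropout pattern for one treatment arm.

    Parameters
    ----------
    omega
        Proportion of clusters dropping out over a trial of maximal duration
        ``t_max`` days; 0 means no dropout.
    gamma
        Weibull shape (> 0): < 1 decreasing hazard, 1 constant, > 1 increasing.
    t_max
        Maximal trial duration in calendar days (>= 1).
    """

    omega: float
    gamma: float = 1.0
    t_max: int = 28

    def __post_init__(self) -> None:
        if not 0 <= self.omega < 1:
            raise DesignError(f"omega: must be in [0, 1), got {self.omega!r}")
        if self.gamma <= 0:
            raise DesignError(f"gamma: must be > 0, got {self.gamma!r}")
        if not isinstance(self.t_max, int) or self.t_max < 1:
            raise DesignError(f"t_max: must be an integer >= 1, got {self.t_max!r}")

    @property
    def lam(self) -> float:
        """Weibull rate ``-log(1 - omega)``."""
        return -float(np.log1p(-self.omega))

    def survival(self, day: int | np.ndarray) -> float | np.ndarray:
        """Probability of remaining in the trial up to at least ``day``."""
        day_arr = np.asarray(day)
        if np.any(day_arr < 1) or np.any(day_arr > self.t_max):
            raise DesignError(f"day: must be in 1..{self.t_max}, got {day!r}")
        if self.omega == 0.0:
            out = np.ones(day_arr.shape)
            return float(out) if np.isscalar(day) else out
        if self.t_max == 1:
            raise DesignError("t_max = 1 admits no dropout time scale")
        tau = (day_arr - 1.0) / (self.t_max - 1.0)
        out = (1.0 - self.omega) ** (tau**self.gamma)
        return float(out) if np.isscalar(day) else out

    def hazard(self, day: int | np.ndarray) -> float | np.ndarray:
        """Conditional probability of dropping out on ``day`` given survival so far.

        Dropout happens at the end of a day, so the hazard on day 1 is zero
        and ``h(t) = (S(t-1) - S(t)) / S(t-1)`` for later days.
        """
        day_arr = np.asarray(day)
        if np.any(day_arr < 1) or np.any(day_arr > self.t_max):
            raise DesignError(f"day: must be in 1..{self.t_max}, got {day!r}")
        if self.omega == 0.0:
            out = np.zeros(day_arr.shape)
            return float(out) if np.isscalar(day) else out
        prev = self.survival(np.maximum(day_arr - 1, 1))
        cur = self.survival(day_arr)
        out = np.where(day_arr <= 1, 0.0, (prev - cur) / prev)
        return float(out) if np.isscalar(day) else out


def survival(day: int, model: DropoutModel) -> float:
    """Functional form of :meth:`DropoutModel.survival`."""
    return float(model.survival(day))


def hazard(day: int, model: DropoutModel) -> float:
    """Functional form of :meth:`DropoutModel.hazard`."""
    return float(model.hazard(day))


def count_probabilities(design: TrialDesign, model: DropoutModel) -> np.ndarray:
    """Probability vector over 'exactly h measurement periods observed'.

    ``p[h-1] = S(day_h) - S(day_{h+1})`` for ``h < T`` and ``p[T-1] = S(day_T)``,
    where ``day_h`` is the calendar day of the h-th measurement period.
    Dropout on non-measurement days (weekends, say) is absorbed because only
    survival at measurement days enters.  The vector sums to one: dropout at
    the end of a day means the first period is always observed.
    """
    if design.last_day > model.t_max:
        raise DesignError(
            f"design ends on day {design.last_day} but t_max is {model.t_max}"
        )
    days = np.asarray(design.calendar_days)
    S = np.asarray(model.survival(days), dtype=float)
    p = np.empty(design.n_periods)
    p[:-1] = S[:-1] - S[1:]
    p[-1] = S[-1]
    return p


def expected_counts(k: int, p: np.ndarray) -> np.ndarray:
    """Expected number of clusters per measurement count, ``E(K) = k * p``.

    Fractional values are intentional: the information matrix is linear in
    cluster counts, so plugging in the expectation averages the information
    over dropout patterns without enumeration.
    """
    p = np.asarray(p, dtype=float)
    _validate_probability_vector(p)
    return k * p


def sample_counts(
    k: int, p: np.ndarray, rng: np.random.Generator | int | None = None
) -> np.ndarray:
    """One multinomial draw of the per-count cluster numbers ``K``."""
    p = np.asarray(p, dtype=float)
    _validate_probability_vector(p)
    rng = np.random.default_rng(rng)
    return rng.multinomial(k, p / p.sum())


def _validate_probability_vector(p: np.ndarray) -> None:
    if np.any(p < -1e-12):
        raise DesignError("count probabilities must be nonnegative")
    if abs(p.sum() - 1.0) > 1e-9:
        raise DesignError(f"count probabilities sum to {p.sum()!r}, expected 1")


def survival_table(
    models_by_arm: tuple[DropoutModel, DropoutModel], t_max: int | None = None
) -> pd.DataFrame:
    """Daily survival and hazard for both arms, in long format (day, arm, S, h)."""
    frames = []
    for arm, model in enumerate(models_by_arm):
        tm = model.t_max if t_max is None else t_max
        days = np.arange(1, tm + 1)
        frames.append(
            pd.DataFrame(
                {
                    "day": days,
                    "arm": arm,
                    "survival": np.asarray(model.survival(days), dtype=float),
                    "hazard": np.asarray(model.hazard(days), dtype=float),
                }
            )
        )
    return pd.concat(frames, ignore_index=True)
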