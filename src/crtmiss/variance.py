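"""GLS variance of the treatment-effect estimator under decaying correlation.

The outcome model is a two-level mixed model for a repeated cross-sectional
design: subject ``i`` measured in period ``h`` of cluster ``j`` has

    y_hij = beta_h + x_j * theta + u_hj + e_hij,

with a cluster-period random effect ``u_hj`` (variance ``sigma_u^2``) and a
subject-level residual ``e_hij`` (variance ``sigma_e^2``).  Cluster-period
effects within the same cluster are correlated with first-order
autoregressive decay on the *calendar-day* lag ``g``:
``cov(u_hj, u_h'j) = sigma_u^2 * r^g``.  Total variance is normalized to one,
so ``sigma_u^2 = rho`` and covariances equal correlations.

With the fixed-effects vector (beta_1, ..., beta_T, theta) estimated by
generalized least squares, ``cov(gamma_hat)`` is the inverse of the summed
per-cluster information ``X_j' V_j^{-1} X_j``; its last diagonal element is
``var(theta_hat)``, the quantity that measures design efficiency.

Because all fixed-effect covariates are constant within a cluster-period,
each cluster's information reduces exactly from the ``m*h`` subject level to
the ``h`` period level:

    X' V^{-1} X = m * Xt' (sigma_e^2 I_h + m sigma_u^2 R_h)^{-1} Xt,

where ``Xt`` is the period-level design matrix and ``R_h`` the decay
correlation matrix of the observed periods.  This identity is what makes
sweeps over large ``m`` cheap; the test suite verifies it against the
explicit subject-level computation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .design import DesignError, TrialDesign

__all__ = [
    "CorrelationStructure",
    "decayed_correlation",
    "build_cluster_covariance",
    "information_matrix",
    "variance_treatment_effect",
]


@dataclass(frozen=True)
class CorrelationStructure:
    """Intraclass correlation ``rho`` and per-day decay base ``r``.

    ``rho`` is the correlation between two subjects in the same
    cluster-period; ``r^g`` scales it down for subjects ``g`` calendar days
    apart in the same cluster.  ``r = 1`` is compound symmetry, ``r < 1``
    first-order autoregressive decay.  Total outcome variance is normalized
    to one, so ``sigma_u2 = rho`` and ``sigma_e2 = 1 - rho``.
    """

    rho: float
    r: float = 1.0

    def __post_init__(self) -> None:
        if not 0 <= self.rho <= 1:
            raise DesignError(f"rho: must be in [0, 1], got {self.rho!r}")
        if not 0 <= self.r <= 1:
            raise DesignError(f"r: must be in [0, 1], got {self.r!r}")

    @property
    def sigma_u2(self) -> float:
        return self.rho

    @property
    def sigma_e2(self) -> float:
        return 1.0 - self.rho

    def decay_matrix(self, calendar_days: np.ndarray) -> np.ndarray:
        """Correlation matrix ``r^|day_a - day_b|`` of the cluster-period effects."""
        days = np.asarray(calendar_days, dtype=float)
        lags = np.abs(days[:, None] - days[None, :])
        if self.r == 0.0:
            return np.where(lags == 0, 1.0, 0.0)
        return self.r**lags


def decayed_correlation(rho: float, r: float, g: int) -> float:
    """Correlation between two subjects in the same cluster ``g`` days apart.

    Returns ``rho * r**g``; with unit total variance this is both the
    covariance and the correlation.
    """
    if g < 0:
        raise DesignError(f"lag g must be >= 0, got {g!r}")
    corr = CorrelationStructure(rho, r)
    if g == 0:
        return corr.rho
    return float(corr.rho * corr.decay_matrix(np.array([0, g]))[0, 1])


def build_cluster_covariance(
    design: TrialDesign, corr: CorrelationStructure, n_obs_periods: int | None = None
) -> np.ndarray:
    """Subject-level covariance matrix of one cluster's stacked outcomes.

    The cluster is observed for its first ``n_obs_periods`` periods (monotone
    dropout truncation; defaults to all ``T``).  The result is the
    ``(m*h) x (m*h)`` matrix ``sigma_u^2 Z R Z' + sigma_e^2 I`` with subjects
    ordered period-major: unit diagonal, ``sigma_u^2`` within a period, and
    ``sigma_u^2 * r^g`` between periods ``g`` calendar days apart.
    """
    T = design.n_periods
    h = T if n_obs_periods is None else n_obs_periods
    if not 1 <= h <= T:
        raise DesignError(f"n_obs_periods: must be in 1..{T}, got {h!r}")
    m = design.subjects
    days = np.asarray(design.calendar_days[:h], dtype=float)
    R = corr.decay_matrix(days)
    V = corr.sigma_u2 * np.kron(R, np.ones((m, m))) + corr.sigma_e2 * np.eye(m * h)
    return V


def _period_design_matrix(
    period_columns: np.ndarray, n_period_cols: int, arm: int
) -> np.ndarray:
    """Period-level fixed-effects matrix: one dummy per period plus treatment."""
    h = len(period_columns)
    X = np.zeros((h, n_period_cols + 1))
    X[np.arange(h), period_columns] = 1.0
    X[:, -1] = float(arm)
    return X


def _cluster_information(
    calendar_days: np.ndarray,
    period_columns: np.ndarray,
    n_period_cols: int,
    m: int,
    corr: CorrelationStructure,
    arm: int,
) -> np.ndarray:
    """Information contribution of a single cluster observed on ``calendar_days``.

    Uses the exact period-level reduction (see module docstring); the
    ``h x h`` system replaces an ``m*h x m*h`` inversion.
    """
    h = len(calendar_days)
    Xt = _period_design_matrix(period_columns, n_period_cols, arm)
    A = corr.sigma_e2 * np.eye(h) + m * corr.sigma_u2 * corr.decay_matrix(
        calendar_days
    )
    return m * Xt.T @ np.linalg.solve(A, Xt)


def information_matrix(
    design: TrialDesign,
    corr: CorrelationStructure,
    arm: int,
    count_weights: np.ndarray | None = None,
) -> np.ndarray:
    """One arm's contribution to the GLS information of (beta_1..beta_T, theta).

    ``count_weights[h-1]`` is the (possibly fractional) number of clusters in
    this arm observed for exactly their first ``h`` periods; weights must be
    nonnegative and sum to ``k``.  ``None`` means complete data: all ``k``
    clusters observed for all ``T`` periods.  The information is linear in
    the weights, which is what makes the expected-count plug-in exact at the
    information level.
    """
    if arm not in (0, 1):
        raise DesignError(f"arm: must be 0 (control) or 1 (intervention), got {arm!r}")
    T = design.n_periods
    k = design.clusters
    if count_weights is None:
        weights = np.zeros(T)
        weights[-1] = float(k)
    else:
        weights = np.asarray(count_weights, dtype=float)
        if weights.shape != (T,):
            raise DesignError(
                f"count_weights: expected length {T}, got shape {weights.shape}"
            )
        if np.any(weights < 0):
            raise DesignError("count_weights: negative weights are not allowed")
        if abs(weights.sum() - k) > 1e-9:
            raise DesignError(
                f"count_weights: sum {weights.sum()!r} does not equal k={k}"
            )
    days = np.asarray(design.calendar_days, dtype=float)
    cols = np.arange(T)
    info = np.zeros((T + 1, T + 1))
    for h in range(1, T + 1):
        w = weights[h - 1]
        if w == 0.0:
            continue
        info += w * _cluster_information(days[:h], cols[:h], T, design.subjects, corr, arm)
    return info


def _invert_information(info: np.ndarray, n_period_cols: int) -> np.ndarray:
    asym = np.max(np.abs(info - info.T))
    if asym > 1e-8:
        raise AssertionError(f"information matrix asymmetric by {asym:g}")
    info = 0.5 * (info + info.T)
    # A period observed in neither arm leaves its dummy column unidentified.
    diag = np.diag(info)
    dead = np.flatnonzero(diag[:n_period_cols] == 0.0)
    if dead.size:
        raise DesignError(
            "singular information: no observations for period column(s) "
            + ", ".join(str(i + 1) for i in dead)
        )
    try:
        cov = np.linalg.inv(info)
    except np.linalg.LinAlgError as exc:
        raise DesignError(f"singular information matrix: {exc}") from exc
    return cov


def variance_treatment_effect(
    design: TrialDesign,
    corr: CorrelationStructure,
    weights_by_arm: tuple[np.ndarray | None, np.ndarray | None] = (None, None),
) -> float:
    """GLS variance of the treatment-effect estimator for one design.

    Sums the information matrices of the control arm (treatment code 0) and
    intervention arm (code 1), inverts, and returns the last diagonal
    element.  ``weights_by_arm`` carries each arm's measurement-count
    weights; ``None`` per arm means complete data.
    """
    info = information_matrix(design, corr, 0, weights_by_arm[0]) + information_matrix(
        design, corr, 1, weights_by_arm[1]
    )
    cov = _invert_information(info, design.n_periods)
    var = float(cov[-1, -1])
    if var <= 0:
        raise AssertionError(f"non-positive variance {var!r}")
    return var
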